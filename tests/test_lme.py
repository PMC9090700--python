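"""Mixed-effects stage: estimates, model selection, vincentiles, R oracle."""

import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prp_introspect as pi
from prp_introspect.lme import (
    fit_lme,
    lrt_model_selection,
    prepare_lme_frame,
    vincentize,
)


def make_mixed_frame(rng, n_groups=24, n_per=60, sd_int=0.15, sd_slope=0.02,
                     beta=None):
    """Directly constructed mixed-model data with known fixed and random
    effects — independent of the trial simulator."""
    beta = beta or {
        "Intercept": 0.6, "order_va": -0.2, "soa_long": -0.15, "sqrt_gap": -0.005,
        "order_va:soa_long": 0.1, "order_va:sqrt_gap": 0.002, "soa_long:sqrt_gap": 0.0,
    }
    rows = []
    for g in range(n_groups):
        order = float(g % 2)
        soa = float((g // 2) % 2)
        u0, u1 = rng.normal(0, sd_int), rng.normal(0, sd_slope)
        gap = rng.uniform(10, 30, n_per)
        y = (
            beta["Intercept"] + u0
            + beta["order_va"] * order
            + beta["soa_long"] * soa
            + (beta["sqrt_gap"] + u1) * gap
            + beta["order_va:soa_long"] * order * soa
            + beta["order_va:sqrt_gap"] * order * gap
            + beta["soa_long:sqrt_gap"] * soa * gap
            + rng.normal(0, 0.12, n_per)
        )
        rows.append(
            pd.DataFrame(
                {"sqrt_drad": y, "order_va": order, "soa_long": soa,
                 "sqrt_gap": gap, "grp": f"g{g:02d}",
                 "participant": f"g{g:02d}", "modality_order": "VA" if order else "AV"}
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestPrepareFrame:
    def test_transforms_and_coding(self, memory_study):
        frame = prepare_lme_frame(memory_study)
        assert np.allclose(frame["sqrt_drad"] ** 2, frame["delta_rad"])
        assert np.allclose(frame["sqrt_gap"] ** 2, frame["central_gap"])
        assert set(frame["order_va"].unique()) <= {0.0, 1.0}
        assert frame["grp"].nunique() == frame["participant"].nunique() * 2

    def test_degenerate_trials_dropped(self, memory_study):
        spiked = memory_study.copy()
        spiked.loc[spiked.index[0], ["iS1_px", "iS2_px", "iR1_px", "iR2_px"]] = 500.0
        spiked = pi.add_radian_columns(spiked.drop(columns=["rad_obj", "rad_intro", "delta_rad", "central_gap", "degenerate"]))
        frame = prepare_lme_frame(spiked)
        assert spiked.index[0] not in frame.index


class TestFitLme:
    def test_recovers_known_fixed_effects(self, rng):
        frame = make_mixed_frame(rng)
        fit = fit_lme(frame, prepared=True)
        for term, true in (
            ("order_va", -0.2), ("soa_long", -0.15), ("sqrt_gap", -0.005),
        ):
            assert abs(fit.params[term] - true) < 2.5 * fit.bse[term] + 1e-6

    def test_null_modality_difference_recovered(self):
        """Equal AV and VA introspection parameters → order estimate ~ 0."""
        params = pi.MemoryModelParams(
            sigma_base_AV=120.0, sigma_base_VA=120.0,
            lambda_compress_AV=0.15, lambda_compress_VA=0.15,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = pi.simulate_study(
                n_av=1, n_va=1, seed=88, trials_per_cell=60, memory_params=params
            )
            rad = pi.add_radian_columns(pi.run_cascade(df)[0])
            fit = fit_lme(rad)
        assert abs(fit.params["order_va"]) < 2.0 * fit.bse["order_va"]

    def test_ci_is_wald(self, rng):
        fit = fit_lme(make_mixed_frame(rng, n_groups=8, n_per=30), prepared=True)
        for term in fit.params.index:
            assert fit.conf_int.loc[term, 0] == pytest.approx(
                fit.params[term] - 1.96 * fit.bse[term]
            )

    def test_single_order_dataset_drops_constant_terms(self, rng):
        """Modality-order terms are pruned (not crashed on) when the data
        contain a single modality order."""
        frame = make_mixed_frame(rng, n_groups=8, n_per=30)
        frame = frame[frame["order_va"] == 0.0].copy()
        with pytest.warns(UserWarning, match="constant fixed term"):
            fit = fit_lme(frame, prepared=True)
        assert "order_va" not in fit.params.index
        assert "soa_long" in fit.params.index

    def test_transform_guard(self, rng):
        """Fitting untransformed variables must change the estimates."""
        frame = make_mixed_frame(rng, n_groups=8, n_per=30)
        raw = frame.copy()
        raw["sqrt_drad"] = raw["sqrt_drad"] ** 2
        a = fit_lme(frame, prepared=True)
        b = fit_lme(raw, prepared=True)
        assert not np.allclose(a.params, b.params, atol=1e-4)


class TestAgainstLmerTest:
    def test_fixed_effects_match_r_oracle(self, rng, tmp_path):
        """statsmodels fit agrees with lme4/lmerTest on the same data."""
        assert shutil.which("Rscript"), "R oracle unavailable"
        frame = make_mixed_frame(rng)
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lmerTest))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(sqrt_drad ~ order_va + soa_long + sqrt_gap +"
            " order_va:soa_long + order_va:sqrt_gap + soa_long:sqrt_gap +"
            " (1 + sqrt_gap | grp), data=d, REML=TRUE)\n"
            "write.csv(data.frame(term=names(fixef(m)), est=fixef(m)),"
            f" '{tmp_path / 'fe.csv'}', row.names=FALSE)\n"
            f"cat(as.numeric(logLik(m)), file='{tmp_path / 'll.txt'}')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        fit = fit_lme(frame, prepared=True)
        r_fe = pd.read_csv(tmp_path / "fe.csv").set_index("term")["est"]
        r_fe.index = r_fe.index.str.replace("(Intercept)", "Intercept", regex=False)
        for term in fit.params.index:
            assert fit.params[term] == pytest.approx(r_fe[term], abs=2e-3)
        r_ll = float((tmp_path / "ll.txt").read_text())
        assert fit.loglike == pytest.approx(r_ll, abs=0.05)


class TestModelSelection:
    def test_null_term_chisq_follows_chi2_1(self):
        """LRT statistic for a truly absent effect ~ chi-square(1)."""
        rng = np.random.default_rng(20260928)  # own stream: KS is seed-exact
        chis = []
        spec = pi.lme.LmeSpec(fixed_terms=("order_va", "soa_long", "sqrt_gap"))
        for _ in range(60):
            frame = make_mixed_frame(
                rng, n_groups=12, n_per=25,
                beta={"Intercept": 0.6, "order_va": 0.0, "soa_long": -0.15,
                      "sqrt_gap": -0.005, "order_va:soa_long": 0.0,
                      "order_va:sqrt_gap": 0.0, "soa_long:sqrt_gap": 0.0},
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = pi.lme._fit_mixed(frame, spec.fixed_terms, spec, reml=False)
                red = pi.lme._fit_mixed(
                    frame, ("soa_long", "sqrt_gap"), spec, reml=False
                )
            chis.append(max(0.0, 2.0 * (full.llf - red.llf)))
        ks = stats.kstest(chis, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_identical_nested_fits_give_zero_chisq(self, rng):
        """A nested pair whose fits are identical (the extra term duplicates
        one already present) yields chi-square = 0 exactly."""
        frame = make_mixed_frame(rng, n_groups=8, n_per=30)
        spec = pi.lme.LmeSpec()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pi.lme._fit_mixed(frame, ("soa_long", "sqrt_gap"), spec, reml=False)
            b = pi.lme._fit_mixed(
                frame, ("soa_long", "sqrt_gap", "sqrt_gap"), spec, reml=False
            )
        assert 2.0 * abs(b.llf - a.llf) == pytest.approx(0.0, abs=1e-6)

    STRONG_BETA = {
        "Intercept": 0.6, "order_va": -0.2, "soa_long": -0.15, "sqrt_gap": -0.02,
        "order_va:soa_long": 0.1, "order_va:sqrt_gap": 0.01, "soa_long:sqrt_gap": 0.0,
    }

    def test_selection_table_and_random_lrt(self, rng):
        frame = make_mixed_frame(
            rng, n_groups=40, n_per=40, sd_int=0.1, sd_slope=0.004,
            beta=self.STRONG_BETA,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = lrt_model_selection(frame, prepared=True)
        tab = tab.set_index("term")
        # strong true effects are detected, the absent interaction is not
        assert tab.loc["Modality order", "p"] < 0.001
        assert tab.loc["Central gap", "p"] < 0.001
        assert tab.loc["SOA x Central gap", "p"] > 0.01
        # clustered data with strong participant effects: huge random-term chi2
        assert tab.loc["Random structure", "df"] == 3
        assert tab.loc["Random structure", "chisq"] > 100.0

    def test_wald_and_lrt_p_agree_on_strong_effects(self, rng):
        frame = make_mixed_frame(
            rng, n_groups=40, n_per=40, sd_int=0.1, sd_slope=0.004,
            beta=self.STRONG_BETA,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(frame, prepared=True, reml=False)
            tab = lrt_model_selection(frame, prepared=True).set_index("term")
        for term, label in (("order_va", "Modality order"), ("sqrt_gap", "Central gap")):
            assert fit.pvalues[term] < 1e-3 and tab.loc[label, "p"] < 1e-3


class TestVincentize:
    def test_equal_count_bins(self, rng):
        frame = make_mixed_frame(rng, n_groups=4, n_per=10)
        frame["delta_rad"] = frame["sqrt_drad"].abs()
        frame["central_gap"] = frame["sqrt_gap"] ** 2
        frame["soa"] = frame["soa_long"].map({0.0: 50, 1.0: 1250})
        out = vincentize(frame, n_bins=5, prepared=True)
        # 10 trials per participant x panel, 5 bins -> bins of exactly 2:
        # per-panel mean gap strictly increases over vincentiles
        for _, panel in out.groupby(["modality_order", "soa"]):
            gaps = panel.sort_values("vincentile")["mean_central_gap"].to_numpy()
            assert (np.diff(gaps) > 0).all()
            assert panel["vincentile"].tolist() == [1, 2, 3, 4, 5]

    def test_constant_delta_rad_is_flat(self, rng):
        frame = make_mixed_frame(rng, n_groups=8, n_per=20)
        frame["delta_rad"] = 0.3
        frame["central_gap"] = frame["sqrt_gap"] ** 2
        frame["soa"] = frame["soa_long"].map({0.0: 50, 1.0: 1250})
        out = vincentize(frame, n_bins=5, prepared=True)
        assert np.allclose(out["mean_delta_rad"], 0.3)
        assert np.allclose(out["se"], 0.0)

    def test_memory_model_av_profile_decreases_va_flat(self):
        """The memory account's signature: inaccuracy falls across central-gap
        vincentiles in AV short-SOA trials and is nearly flat in VA."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = pi.simulate_study(seed=31)
            rad = pi.add_radian_columns(pi.run_cascade(df)[0])
            out = vincentize(rad)
        short = out[out["soa"] == 50]
        av = short[short["modality_order"] == "AV"].sort_values("vincentile")
        va = short[short["modality_order"] == "VA"].sort_values("vincentile")
        av_drop = av["mean_delta_rad"].iloc[0] - av["mean_delta_rad"].iloc[-1]
        va_drop = va["mean_delta_rad"].iloc[0] - va["mean_delta_rad"].iloc[-1]
        assert av_drop > 0
        assert av_drop > 2.0 * abs(va_drop)
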