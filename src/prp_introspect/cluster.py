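"""Exploratory K-means clustering of recreated trial structures.

Each non-degenerate timeline recreation is reduced to a scale-free shape:
the four marker positions divided by the timeline length, giving a
quadruple in [0, 1].  K-means over these shapes characterises the kinds of
reports participants produce — veridical recreations, evenly spread
markers, reports where the S2 marker is glued to R1 (the signature the
conscious-bottleneck account predicts at short SOA), and so on.  Cluster
descriptions attach the mean introspective inaccuracy (∆rad), the
composition by modality order and SOA, and an S2≈R1 flag.

k is an analyst choice; an inertia profile over a k grid is provided to
support it, and all settings (k, restarts, seed) are explicit arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "TrialShape",
    "ClusterSolution",
    "featurize",
    "kmeans_cluster",
    "describe_clusters",
    "inertia_profile",
]

FEATURE_COLS = ["fS1", "fS2", "fR1", "fR2"]

#: |iS2 - iR1| below this fraction of the report's marker span flags a
#: cluster as showing the S2-tied-to-R1 signature.  The reported S2 of a
#: bottleneck-limited short-SOA trial trails R1 by roughly one motor stage
#: (~0.2 of the span); veridical short-SOA reports sit near 0.6 and evenly
#: spread reports near 0.33, so 0.3 separates the tied family.
S2_R1_TIE_FRACTION = 0.3


@dataclass
class TrialShape:
    """Scale-free marker quadruple of one trial (positions / timeline length)."""

    fS1: float
    fS2: float
    fR1: float
    fR2: float
    soa: float
    modality_order: str


@dataclass
class ClusterSolution:
    """A fitted K-means solution over trial shapes."""

    k: int
    assignments: pd.Series
    centroids: np.ndarray
    inertia: float
    features: pd.DataFrame = field(repr=False, default=None)


def featurize(trials: pd.DataFrame) -> pd.DataFrame:
    """Scale-free shape features of each non-degenerate trial.

    Divides each marker position by the timeline length; trials whose four
    markers coincide carry no shape information and are excluded.  The
    returned frame keeps ``soa`` and ``modality_order`` for composition
    summaries, indexed like the input rows that survive.
    """
    degenerate = (
        (trials["iS1_px"] == trials["iS2_px"])
        & (trials["iS1_px"] == trials["iR1_px"])
        & (trials["iS1_px"] == trials["iR2_px"])
    )
    kept = trials.loc[~degenerate]
    out = pd.DataFrame(
        {
            "fS1": kept["iS1_px"] / kept["timeline_px"],
            "fS2": kept["iS2_px"] / kept["timeline_px"],
            "fR1": kept["iR1_px"] / kept["timeline_px"],
            "fR2": kept["iR2_px"] / kept["timeline_px"],
            "soa": kept["soa"],
            "modality_order": kept["modality_order"],
        },
        index=kept.index,
    )
    return out


def kmeans_cluster(
    shapes: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> ClusterSolution:
    """K-means over shape quadruples; best of ``n_restarts`` initialisations.

    Deterministic for a given seed.
    """
    X = shapes[FEATURE_COLS].to_numpy()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterSolution(
        k=k,
        assignments=pd.Series(labels, index=shapes.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        features=shapes,
    )


def inertia_profile(shapes: pd.DataFrame, k_grid=range(2, 11), seed: int = 0,
                    n_restarts: int = 10) -> pd.DataFrame:
    """Inertia for each k in ``k_grid`` (elbow diagnostic)."""
    rows = []
    for k in k_grid:
        sol = kmeans_cluster(shapes, k=k, seed=seed, n_restarts=n_restarts)
        rows.append({"k": k, "inertia": sol.inertia})
    return pd.DataFrame(rows)


def describe_clusters(
    solution: ClusterSolution, radians: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster summary: size, mean ∆rad, composition, S2≈R1 flag.

    ``radians`` must carry ``delta_rad`` on the same index as the clustered
    shapes.  The S2≈R1 flag is set when the median |iS2 − iR1| distance is
    below :data:`S2_R1_TIE_FRACTION` of the median marker span in the
    cluster.  Empty clusters are omitted with a warning.
    """
    shapes = solution.features
    short_soa = shapes["soa"].min()
    rows = []
    for cid in range(solution.k):
        idx = solution.assignments.index[solution.assignments == cid]
        if len(idx) == 0:
            warnings.warn(f"cluster {cid} is empty and omitted", stacklevel=2)
            continue
        sub = shapes.loc[idx]
        span = (
            sub[FEATURE_COLS].max(axis=1) - sub[FEATURE_COLS].min(axis=1)
        ).median()
        tie = (sub["fS2"] - sub["fR1"]).abs().median()
        comp_order = sub["modality_order"].value_counts(normalize=True).to_dict()
        rows.append(
            {
                "cluster": cid,
                "n": len(idx),
                "mean_delta_rad": float(radians.loc[idx, "delta_rad"].mean()),
                "frac_AV": float(comp_order.get("AV", 0.0)),
                "frac_VA": float(comp_order.get("VA", 0.0)),
                "frac_short_soa": float((sub["soa"] == short_soa).mean()),
                "s2_r1_tied": bool(span > 0 and tie < S2_R1_TIE_FRACTION * span),
            }
        )
    return pd.DataFrame(rows)
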