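"""Cluster-aware group comparisons.

Birds tracked over multiple years contribute repeated measures, so naive
two-sample tests on observations would be pseudo-replicated.  The
comparisons here are permutation tests on whole birds: the test statistic
is the difference of group means of bird-level means, and the null
distribution permutes bird identities (clusters) across groups, never
splitting a bird's repeated measures.  This preserves exactly the
dependence structure a mixed model's random bird-identity term addresses,
while making no distributional assumptions.  Tests are two-sided with no
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ComparisonResult", "cluster_permutation_test", "summarize_metric"]


@dataclass
class ComparisonResult:
    """Outcome of one clustered two-group comparison."""

    metric: str
    grouping: str
    groups: tuple                 # (label_a, label_b)
    observed_diff: float          # mean(a) - mean(b) of cluster means
    p_value: float
    n_clusters: tuple             # clusters per group
    n_perm: int

    def summary(self) -> str:
        a, b = self.groups
        na, nb = self.n_clusters
        return (
            f"{self.metric} by {self.grouping}: {a} - {b} = {self.observed_diff:+.3f} "
            f"(p = {self.p_value:.4f}, {na} vs {nb} clusters, {self.n_perm} permutations)"
        )


def cluster_permutation_test(
    values,
    group_labels,
    cluster_ids,
    n_perm: int = 9999,
    seed: int = 0,
    metric: str = "",
    grouping: str = "",
) -> ComparisonResult:
    """Two-sided permutation test of a group difference, clustered by bird.

    The statistic is the difference of group means of cluster-level means;
    the null permutes whole clusters across groups;
    ``p = (1 + #{|T*| >= |T|}) / (1 + n_perm)``.  A cluster appearing in
    both groups violates the design and raises ``ValueError``; each group
    needs at least 2 clusters.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "group": group_labels, "cluster": cluster_ids}
    )
    spans = df.groupby("cluster")["group"].nunique()
    if (spans > 1).any():
        bad = spans[spans > 1].index.tolist()
        raise ValueError(f"cluster(s) {bad} span both groups; design violation")
    cl = df.groupby("cluster").agg(value=("value", "mean"), group=("group", "first"))
    labels = np.sort(cl["group"].unique())
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.tolist()}")
    a, b = labels
    mask_a = (cl["group"] == a).to_numpy()
    n_a = int(mask_a.sum())
    n_b = int((~mask_a).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 clusters per group")
    vals = cl["value"].to_numpy()
    t_obs = vals[mask_a].mean() - vals[~mask_a].mean()
    rng = np.random.default_rng(seed)
    n = vals.size
    # vectorized label permutations: argsort of uniform noise
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = vals[order]
    t_null = perm_vals[:, :n_a].mean(axis=1) - perm_vals[:, n_a:].mean(axis=1)
    p = (1.0 + np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12)) / (1.0 + n_perm)
    return ComparisonResult(
        metric=metric,
        grouping=grouping,
        groups=(a, b),
        observed_diff=float(t_obs),
        p_value=float(p),
        n_clusters=(n_a, n_b),
        n_perm=n_perm,
    )


def summarize_metric(df: pd.DataFrame, value: str = "value", by=("group",)) -> pd.DataFrame:
    """Mean +/- SD table per cell (results reported as means with 1 SD)."""
    by = list(by)
    out = df.groupby(by)[value].agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
    out["sd"] = out["sd"].fillna(0.0)
    out["formatted"] = [
        f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["sd"])
    ]
    return out.reset_index()
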