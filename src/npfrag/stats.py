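"""Nonparametric group comparison of descriptor distributions.

The comparison protocol: a Kruskal–Wallis omnibus test across datasets,
Dunn's post-hoc pairwise test with Bonferroni correction when the omnibus
test indicates differences, Cohen's d (pooled standard deviation) as the
effect size, and Spearman's rank correlation for trend questions such as
descriptor values versus approval year.  Significance threshold 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class UndefinedStatisticError(ValueError):
    pass


GroupedValues = Mapping[str, Sequence[float]]


def _validate(groups: GroupedValues, min_groups: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise UndefinedStatisticError(f"need >= {min_groups} groups, got {len(groups)}")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise UndefinedStatisticError(f"group {label!r} is empty")
        if not np.isfinite(arr).all():
            raise UndefinedStatisticError(f"non-finite values in group {label!r}")
        out[label] = arr
    return out


def kruskal_wallis(groups: GroupedValues) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    Degenerate all-identical input returns (0, 1) rather than erroring.
    """
    arrays = list(_validate(groups).values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_bonferroni(groups: GroupedValues) -> pd.DataFrame:
    """Dunn's post-hoc z-test on pooled ranks, Bonferroni-adjusted.

    For groups i, j with mean pooled ranks R̄i, R̄j over N total values:

        z = (R̄i − R̄j) / sqrt( (N(N+1)/12 − T) (1/ni + 1/nj) )

    with the tie correction T = Σ(t³ − t) / (12 (N − 1)) over tied-value
    multiplicities t.  Two-sided normal p-values are multiplied by the number
    of pairs and capped at 1.  Returns a symmetric DataFrame with 1 on the
    diagonal.
    """
    arrays = _validate(groups)
    labels = list(arrays)
    pooled = np.concatenate([arrays[k] for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in labels:
        n_k = arrays[k].size
        mean_ranks[k] = ranks[start:start + n_k].mean()
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        denom = np.sqrt(variance_base * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        if denom == 0:
            p_adj = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
            p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
        out.loc[a, b] = out.loc[b, a] = p_adj
    return out


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference (first minus second), pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("cohens_d needs >= 2 values per sample")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedStatisticError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def spearman_trend(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation with tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedStatisticError("spearman_trend needs equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for constant input")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


@dataclass
class ComparisonResult:
    """Group-wise descriptor statistics with a readable summary table."""

    descriptor: str
    kw_H: float
    kw_p: float
    medians: dict[str, float]
    pairwise_p_adj: pd.DataFrame
    cohens_d: pd.DataFrame

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        labels = list(self.pairwise_p_adj.index)
        return [
            (a, b)
            for a, b in combinations(labels, 2)
            if self.pairwise_p_adj.loc[a, b] < alpha
        ]

    def summary(self) -> str:
        lines = [
            f"Descriptor comparison: {self.descriptor}",
            f"Kruskal-Wallis H = {self.kw_H:.3f}, p = {self.kw_p:.3g}",
            "",
            f"{'group':<14}{'median':>10}",
        ]
        for g, m in self.medians.items():
            lines.append(f"{g:<14}{m:>10.4f}")
        lines += ["", f"{'pair':<28}{'p_adj':>10}{'d':>9}"]
        for a, b in combinations(self.pairwise_p_adj.index, 2):
            lines.append(
                f"{a + ' vs ' + b:<28}"
                f"{self.pairwise_p_adj.loc[a, b]:>10.3g}"
                f"{self.cohens_d.loc[a, b]:>9.3f}"
            )
        return "\n".join(lines)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.pairwise_p_adj.index, 2):
            rows.append(
                {
                    "descriptor": self.descriptor,
                    "group_a": a,
                    "group_b": b,
                    "median_a": self.medians[a],
                    "median_b": self.medians[b],
                    "p_adj": self.pairwise_p_adj.loc[a, b],
                    "d": self.cohens_d.loc[a, b],
                }
            )
        return pd.DataFrame(rows)


def compare_groups(groups: GroupedValues, descriptor: str = "") -> ComparisonResult:
    """Full comparison: omnibus, pairwise Dunn–Bonferroni, effect sizes, medians."""
    arrays = _validate(groups)
    h, p = kruskal_wallis(arrays)
    labels = list(arrays)
    d = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        val = cohens_d(arrays[a], arrays[b])
        d.loc[a, b] = val
        d.loc[b, a] = -val
    return ComparisonResult(
        descriptor=descriptor,
        kw_H=h,
        kw_p=p,
        medians={k: float(np.median(v)) for k, v in arrays.items()},
        pairwise_p_adj=dunn_bonferroni(arrays),
        cohens_d=d,
    )


def compare_table(df: pd.DataFrame, descriptors: Sequence[str],
                  group_col: str = "source_tag") -> pd.DataFrame:
    """Long-format comparison table for several descriptor columns."""
    frames = []
    for desc in descriptors:
        groups = {
            str(g): sub[desc].dropna().to_numpy()
            for g, sub in df.groupby(group_col)
            if sub[desc].notna().any()
        }
        frames.append(compare_groups(groups, desc).to_long_frame())
    return pd.concat(frames, ignore_index=True)
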