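"""Stage 1: quintile-restricted differential-methylation screen.

For each probe and binary comparison, samples are ranked by beta value within
each group and only the extreme quintiles enter a two-sided Mann-Whitney U
test; p values are Benjamini-Hochberg adjusted across all testable probes of
the comparison, and a probe is called significant when the adjusted p value
passes the comparison's cutoff AND the full-group mean methylation difference
exceeds the effect-size cutoff.

Three readings of the quintile restriction are implemented:

``pooled`` (default)
    all samples of the comparison are ranked together, and the test compares
    the two phenotypes' values within the union of the bottom and top pooled
    quintiles. Because the restriction is label-blind, label exchangeability
    is preserved and the test is exactly valid under the null, while for a
    truly shifted probe the pooled extremes are dominated by the two group
    bulks and the test has high power.
``within_group_union``
    each group contributes the union of its own bottom and top ``ceil(n/5)``
    samples, and the two groups' extreme subsets are compared. Under the null
    both subsets are drawn identically, so type-I control holds
    (conservatively), but the extreme-value noise caps attainable
    significance well above what a pooled restriction reaches.
``directional``
    the group with the smaller mean contributes its bottom quintile, the
    other its top quintile. This maximises the contrast in the direction of
    the observed difference but compares bottom-ranked to top-ranked values,
    which is anti-conservative by construction (under the null essentially
    every probe reaches significance); it is provided for comparison, not
    screening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ComparisonSpec, ConfigurationError

logger = logging.getLogger(__name__)

#: Largest pooled size for which the Mann-Whitney p value is computed by exact
#: enumeration of all rank arrangements; larger samples use the tie-corrected
#: normal approximation.
EXACT_ENUMERATION_LIMIT = 12


class PipelineError(RuntimeError):
    """A pipeline stage produced no usable output."""


@dataclass(frozen=True)
class DMRThresholds:
    """Significance cutoffs: adjusted p strictly below ``max_p_adj`` and
    absolute mean difference strictly above ``min_abs_diff``."""

    max_p_adj: float
    min_abs_diff: float

    def __post_init__(self) -> None:
        if not 0 < self.max_p_adj < 1:
            raise ConfigurationError("max_p_adj must lie in (0, 1)")
        if not 0 <= self.min_abs_diff < 1:
            raise ConfigurationError("min_abs_diff must lie in [0, 1)")


#: Default cutoffs per comparison: stringent for the strong normal-vs-cancer
#: contrast, permissive for the nearly indistinct LN-negative-vs-LN-positive one.
DEFAULT_THRESHOLDS = {
    "normal_vs_cancer": DMRThresholds(1e-5, 0.2),
    "ln_neg_vs_ln_pos": DMRThresholds(0.01, 0.02),
}


def quintile_size(n: int) -> int:
    return math.ceil(n / 5)


def quintile_subsets(
    values_a: np.ndarray,
    values_b: np.ndarray,
    mode: str = "directional",
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the quintile-restricted subsets of two sample groups.

    In ``pooled`` mode both groups are ranked together and each group
    contributes its members falling in the bottom or top ``ceil((na+nb)/5)``
    of the pooled ranking (either subset may be empty for an extreme shift).
    In ``directional`` mode the lower-mean group (ties resolved toward group
    a) contributes its bottom ``ceil(n/5)`` values and the other group its
    top ``ceil(n/5)``; in ``within_group_union`` mode each group contributes
    the union of its own bottom and top quintiles. Sorting is stable, so
    boundary ties resolve by original sample order.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 usable values")
    if mode == "pooled":
        pooled = np.concatenate([a, b])
        q = quintile_size(pooled.size)
        order = np.argsort(pooled, kind="stable")
        extreme = np.concatenate([order[:q], order[-q:]])
        sub_a = pooled[extreme[extreme < a.size]]
        sub_b = pooled[extreme[extreme >= a.size]]
        return sub_a, sub_b
    qa, qb = quintile_size(a.size), quintile_size(b.size)
    a_sorted = a[np.argsort(a, kind="stable")]
    b_sorted = b[np.argsort(b, kind="stable")]
    if mode == "directional":
        if a.mean() <= b.mean():
            return a_sorted[:qa], b_sorted[-qb:]
        return a_sorted[-qa:], b_sorted[:qb]
    if mode == "within_group_union":
        sub_a = np.concatenate([a_sorted[:qa], a_sorted[-qa:]])
        sub_b = np.concatenate([b_sorted[:qb], b_sorted[-qb:]])
        return sub_a, sub_b
    raise ConfigurationError(f"unknown quintile mode {mode!r}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Number of (x_i, y_j) pairs with x_i < y_j plus half the tied pairs."""
    less = (x[:, None] < y[None, :]).sum()
    tied = (x[:, None] == y[None, :]).sum()
    return float(less) + 0.5 * float(tied)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by enumerating all assignments of the pooled values to x.

    The p value is the fraction of arrangements whose U statistic deviates
    from the null mean nm/2 by at least as much as the observed one; ties in
    the data are handled naturally because arrangements are enumerated over
    the observed multiset.
    """
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    centre = n * m / 2.0
    dev = abs(u_obs - centre) - 1e-12
    total = extreme = 0
    idx = np.arange(pooled.size)
    for chosen in combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - centre) >= dev:
            extreme += 1
    return extreme / total


def _normal_approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n, m = x.size, y.size
    big_n = n + m
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:  # all values tied
        return 1.0
    centre = n * m / 2.0
    z = (abs(u_obs - centre) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * stats.norm.sf(z))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs in which y exceeds x (ties count
    half). The p value is exact (enumeration over all rank arrangements) for
    pooled sizes up to 12 and a tie-corrected normal approximation with
    continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    u_obs = _u_statistic(x, y)
    if x.size + y.size <= EXACT_ENUMERATION_LIMIT:
        p = _exact_two_sided_p(x, y, u_obs)
    else:
        p = _normal_approx_p(x, y, u_obs)
    return u_obs, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_dmr(
    matrix: pd.DataFrame,
    comp: ComparisonSpec,
    thresholds: DMRThresholds,
    quintile_mode: str = "pooled",
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Screen every probe of one comparison.

    Returns a data frame indexed by probe with columns ``mean_diff`` (full
    group means, ``group_b - group_a``), ``p_raw``, ``p_adj`` and
    ``significant``. Probes with more than ``max_missing_fraction`` missing
    values in either group, or fewer than 5 usable values in a group, are
    skipped (logged) and excluded from the BH family.
    """
    missing_a = [s for s in comp.group_a if s not in matrix.columns]
    missing_b = [s for s in comp.group_b if s not in matrix.columns]
    if missing_a or missing_b:
        raise ConfigurationError(
            f"matrix lacks samples for comparison {comp.name!r}: "
            f"{(missing_a + missing_b)[:5]}"
        )
    sub_a = matrix[list(comp.group_a)].to_numpy(dtype=float)
    sub_b = matrix[list(comp.group_b)].to_numpy(dtype=float)

    records: list[tuple[str, float, float]] = []
    n_skipped = 0
    for i, probe in enumerate(matrix.index):
        a, b = sub_a[i], sub_b[i]
        ok_a, ok_b = ~np.isnan(a), ~np.isnan(b)
        frac_missing = max(1 - ok_a.mean(), 1 - ok_b.mean())
        if frac_missing > max_missing_fraction or ok_a.sum() < 5 or ok_b.sum() < 5:
            n_skipped += 1
            continue
        a, b = a[ok_a], b[ok_b]
        qa, qb = quintile_subsets(a, b, mode=quintile_mode)
        if qa.size == 0 or qb.size == 0:
            # one phenotype absent from the pooled extremes: no contrast
            p = 1.0
        else:
            _, p = mann_whitney_u(qa, qb)
        records.append((probe, float(b.mean() - a.mean()), p))
    if n_skipped:
        logger.info(
            "%s: skipped %d probes (missingness or <5 usable values)",
            comp.name, n_skipped,
        )
    if not records:
        raise PipelineError(f"no testable probes for comparison {comp.name!r}")

    out = pd.DataFrame(records, columns=["probe_id", "mean_diff", "p_raw"])
    out = out.set_index("probe_id")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = (out["p_adj"] < thresholds.max_p_adj) & (
        out["mean_diff"].abs() > thresholds.min_abs_diff
    )
    return out


def density_summary(dmr_table: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Histogram summaries of mean_diff and log10 adjusted p, for diagnostics."""
    diff_edges = np.linspace(-1, 1, n_bins + 1)
    logp = np.log10(dmr_table["p_adj"].to_numpy())
    logp_edges = np.linspace(min(logp.min(), -1.0), 0.0, n_bins + 1)
    diff_counts, _ = np.histogram(dmr_table["mean_diff"], bins=diff_edges)
    logp_counts, _ = np.histogram(logp, bins=logp_edges)
    return pd.DataFrame(
        {
            "mean_diff_bin_left": diff_edges[:-1],
            "mean_diff_count": diff_counts,
            "log10_p_adj_bin_left": logp_edges[:-1],
            "log10_p_adj_count": logp_counts,
        }
    )
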