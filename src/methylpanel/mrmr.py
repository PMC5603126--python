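"""Stage 2: minimum-redundancy-maximum-relevance probe ranking.

Beta values are discretised per probe (three levels by the mean +/- sd rule,
the convention of the classic mRMR formulation) and probes are selected
greedily by the MID criterion: at each step the probe maximising

    MI(probe; class) - mean over selected s of MI(probe; s)

is appended, where MI is the plug-in mutual-information estimate in bits.
Only the top ``keep_fraction`` of candidates (by selection order) is retained
for the downstream wrapper search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigurationError
from .dmr import PipelineError


def discretize(matrix: pd.DataFrame, method: str = "mean_sd") -> pd.DataFrame:
    """Discretise each probe's beta values into ordinal levels.

    ``mean_sd`` (default): level 0 below mu - sigma, level 2 above mu + sigma,
    level 1 between (mu, sigma computed per probe over the given samples; a
    constant probe maps entirely to level 1). ``median``: binary split at the
    per-probe median (values > median -> 1).
    """
    values = matrix.to_numpy(dtype=float)
    if method == "mean_sd":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(np.isnan(sd), 0.0, sd)
        states = np.ones_like(values, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            states[values < mu - sd] = 0
            states[values > mu + sd] = 2
    elif method == "median":
        med = np.median(values, axis=1, keepdims=True)
        states = (values > med).astype(np.int8)
    else:
        raise ConfigurationError(f"unknown discretization method {method!r}")
    return pd.DataFrame(states, index=matrix.index, columns=matrix.columns)


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size == 0:
        raise ValueError("empty vectors")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum())
    return max(mi, 0.0)  # clamp -0.0 / rounding noise


@dataclass(frozen=True)
class MRMRResult:
    """Greedy selection order with per-probe scores.

    ``order`` is the full greedy ranking; ``kept`` its leading slice of size
    ``ceil(keep_fraction * n_candidates)``. ``relevance`` maps every candidate
    probe to MI(probe; class); ``incremental_score`` records, per selected
    probe, relevance minus mean redundancy against the probes selected before
    it (so the first entry equals that probe's relevance).
    """

    order: tuple[str, ...]
    kept: tuple[str, ...]
    relevance: dict[str, float]
    incremental_score: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        kept = set(self.kept)
        return pd.DataFrame(
            {
                "probe_id": list(self.order),
                "selection_rank": np.arange(1, len(self.order) + 1),
                "relevance_bits": [self.relevance[p] for p in self.order],
                "incremental_score_bits": list(self.incremental_score),
                "kept": [p in kept for p in self.order],
            }
        ).set_index("probe_id")


def mrmr_rank(
    disc: pd.DataFrame,
    labels,
    keep_fraction: float = 0.10,
    criterion: str = "mid",
    rank_mode: str = "greedy",
) -> MRMRResult:
    """Rank candidate probes by greedy mRMR selection.

    ``criterion`` is ``mid`` (relevance minus mean redundancy, default) or
    ``miq`` (relevance divided by mean redundancy, floored at machine
    epsilon). ``rank_mode="relevance_only"`` skips the redundancy term and
    ranks by MI with the class alone (diagnostic). Ties are broken toward the
    lexicographically smaller probe ID, making the ranking deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ConfigurationError("keep_fraction must lie in (0, 1]")
    if disc.shape[0] == 0:
        raise PipelineError("mrmr_rank: empty candidate set")
    labels = np.asarray(labels)
    if labels.shape[0] != disc.shape[1]:
        raise ValueError("labels length must match sample count")
    if criterion not in ("mid", "miq"):
        raise ConfigurationError(f"unknown mRMR criterion {criterion!r}")

    # iterate probes in lexicographic ID order so ties resolve deterministically
    probes = sorted(disc.index)
    states = {p: disc.loc[p].to_numpy() for p in probes}
    relevance = {p: mutual_information(states[p], labels) for p in probes}

    n_keep = math.ceil(keep_fraction * len(probes))

    if rank_mode == "relevance_only":
        order = sorted(probes, key=lambda p: (-relevance[p], p))
        scores = tuple(relevance[p] for p in order)
        return MRMRResult(tuple(order), tuple(order[:n_keep]), relevance, scores)
    if rank_mode != "greedy":
        raise ConfigurationError(f"unknown rank_mode {rank_mode!r}")

    selected: list[str] = []
    scores: list[float] = []
    remaining = list(probes)
    red_sum = {p: 0.0 for p in probes}  # sum of MI(p; s) over selected s
    while remaining:
        best_probe, best_score = None, -math.inf
        for p in remaining:
            if not selected:
                score = relevance[p]
            elif criterion == "mid":
                score = relevance[p] - red_sum[p] / len(selected)
            else:  # miq
                score = relevance[p] / max(red_sum[p] / len(selected), 1e-12)
            if score > best_score + 1e-12:
                best_probe, best_score = p, score
        selected.append(best_probe)
        scores.append(best_score)
        remaining.remove(best_probe)
        for p in remaining:
            red_sum[p] += mutual_information(states[p], states[best_probe])
    return MRMRResult(
        tuple(selected), tuple(selected[:n_keep]), relevance, tuple(scores)
    )
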