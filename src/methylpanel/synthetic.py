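"""Synthetic DNA-methylation data with planted differential probes.

The generator emulates the structure of a TCGA-style stomach-cancer methylation
study: four clinical groups (normal, LN-negative, LN-positive, unclassified
tumours), a large background of null probes, a set of probes with a strong
normal-vs-cancer effect, a set with a weak LN-negative-vs-LN-positive effect,
and near-duplicate "redundant" copies of informative probes that give
redundancy-aware feature selection something real to remove.

Per-probe beta values are drawn from a beta distribution parameterised by
(mean, concentration); group effects shift the mean. Each probe has its own
RNG substream derived from the global seed, so enlarging ``n_probes_total``
never perturbs the values of earlier probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigurationError

# Keep planted group means inside [MEAN_LO, MEAN_HI] so the beta distribution
# stays proper and the realised shift is not squashed against 0 or 1.
MEAN_LO = 0.05
MEAN_HI = 0.95


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for one synthetic data set.

    Group sizes default to the stomach-cancer cohort (27 normal, 94
    LN-negative, 189 LN-positive, 12 unclassified tumours). ``delta_cancer``
    is the planted mean-beta shift between normal and tumour samples (strong,
    past the usual 0.2 effect threshold); ``delta_ln`` the shift between
    LN-negative and LN-positive tumours (weak — the two node groups are nearly
    indistinguishable). ``concentration`` is the precision of the beta noise
    model: at mid-methylation its default of 20 gives a within-group standard
    deviation near 0.11, a realistic per-probe spread for array beta values.
    """

    n_normal: int = 27
    n_ln_neg: int = 94
    n_ln_pos: int = 189
    n_unclassified: int = 12
    n_probes_total: int = 2000
    n_cancer_informative: int = 100
    delta_cancer: float = 0.3
    n_ln_informative: int = 90
    delta_ln: float = 0.08
    n_redundant_per_informative: int = 2
    redundancy_noise_sd: float = 0.02
    concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_normal, self.n_ln_neg, self.n_ln_pos, self.n_unclassified,
            self.n_probes_total, self.n_cancer_informative, self.n_ln_informative,
            self.n_redundant_per_informative,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all design counts must be >= 0")
        if self.n_planted > self.n_probes_total:
            raise ConfigurationError(
                f"planted probes ({self.n_planted}) exceed n_probes_total "
                f"({self.n_probes_total})"
            )
        for name in ("delta_cancer", "delta_ln"):
            if not 0 <= getattr(self, name) < MEAN_HI - MEAN_LO:
                raise ConfigurationError(f"{name} must lie in [0, {MEAN_HI - MEAN_LO})")
        if self.concentration <= 0:
            raise ConfigurationError("concentration must be > 0")
        if self.redundancy_noise_sd < 0:
            raise ConfigurationError("redundancy_noise_sd must be >= 0")

    @property
    def n_planted(self) -> int:
        per = 1 + self.n_redundant_per_informative
        return (self.n_cancer_informative + self.n_ln_informative) * per

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_ln_neg + self.n_ln_pos + self.n_unclassified


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated data set: which probes carry which effect."""

    cancer_informative_probes: frozenset[str]
    ln_informative_probes: frozenset[str]
    redundancy_map: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def informative_probes(self) -> frozenset[str]:
        return self.cancer_informative_probes | self.ln_informative_probes

    @property
    def redundant_probes(self) -> frozenset[str]:
        out: set[str] = set()
        for copies in self.redundancy_map.values():
            out |= copies
        return frozenset(out)

    def to_json(self, path) -> None:
        payload = {
            "cancer_informative_probes": sorted(self.cancer_informative_probes),
            "ln_informative_probes": sorted(self.ln_informative_probes),
            "redundancy_map": {k: sorted(v) for k, v in self.redundancy_map.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            frozenset(payload["cancer_informative_probes"]),
            frozenset(payload["ln_informative_probes"]),
            {k: frozenset(v) for k, v in payload["redundancy_map"].items()},
        )


def _probe_id(i: int) -> str:
    return f"cg{i:07d}"


def _sample_ids(design: SyntheticDesign) -> tuple[list[str], pd.Series]:
    ids, phenos = [], []
    for prefix, pheno, n in (
        ("N", "normal", design.n_normal),
        ("TN", "LN_negative", design.n_ln_neg),
        ("TP", "LN_positive", design.n_ln_pos),
        ("TU", "unclassified", design.n_unclassified),
    ):
        ids.extend(f"{prefix}{i:04d}" for i in range(n))
        phenos.extend([pheno] * n)
    return ids, pd.Series(phenos, index=ids, name="phenotype")


def _beta_draw(rng: np.random.Generator, means: np.ndarray, conc: float) -> np.ndarray:
    means = np.clip(means, MEAN_LO, MEAN_HI)
    return rng.beta(means * conc, (1.0 - means) * conc)


def generate(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a (beta matrix, phenotype table, ground truth) triple.

    Probe layout is deterministic: cancer-informative probes first, then the
    LN-informative probes, then the redundant copies of each, then the null
    background. The same design (including seed) always yields bit-identical
    output.
    """
    sample_ids, pheno = _sample_ids(design)
    n_samples = len(sample_ids)
    is_cancer = (pheno != "normal").to_numpy()
    is_ln_neg = (pheno == "LN_negative").to_numpy()
    is_ln_pos = (pheno == "LN_positive").to_numpy()

    n_ci, n_li = design.n_cancer_informative, design.n_ln_informative
    n_red = design.n_redundant_per_informative
    parents = n_ci + n_li
    probe_ids = [_probe_id(i) for i in range(design.n_probes_total)]

    substreams = np.random.SeedSequence(design.seed).spawn(design.n_probes_total)
    values = np.empty((design.n_probes_total, n_samples), dtype=float)

    cancer_set: list[str] = []
    ln_set: list[str] = []
    redundancy: dict[str, set[str]] = {}

    for i in range(min(parents, design.n_probes_total)):
        rng = np.random.default_rng(substreams[i])
        if i < n_ci:  # strong normal-vs-cancer shift
            low = rng.uniform(MEAN_LO, MEAN_HI - design.delta_cancer)
            cancer_up = rng.random() < 0.5
            means = np.where(
                is_cancer == cancer_up, low + design.delta_cancer, low
            )
            cancer_set.append(probe_ids[i])
        else:  # weak LN-negative-vs-LN-positive shift
            low = rng.uniform(MEAN_LO, MEAN_HI - design.delta_ln)
            pos_up = rng.random() < 0.5
            mid = low + design.delta_ln / 2.0
            means = np.full(n_samples, mid)
            means[is_ln_neg] = low if pos_up else low + design.delta_ln
            means[is_ln_pos] = low + design.delta_ln if pos_up else low
            ln_set.append(probe_ids[i])
        values[i] = _beta_draw(rng, means, design.concentration)

    # redundant copies: parent value + gaussian jitter, clipped to [0,1]
    for k in range(parents * n_red):
        i = parents + k
        if i >= design.n_probes_total:
            break
        parent = k % parents
        rng = np.random.default_rng(substreams[i])
        noisy = values[parent] + rng.normal(0.0, design.redundancy_noise_sd, n_samples)
        values[i] = np.clip(noisy, 0.0, 1.0)
        redundancy.setdefault(probe_ids[parent], set()).add(probe_ids[i])

    for i in range(design.n_planted, design.n_probes_total):
        rng = np.random.default_rng(substreams[i])
        mean = rng.uniform(MEAN_LO, MEAN_HI)
        values[i] = _beta_draw(rng, np.full(n_samples, mean), design.concentration)

    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    truth = SyntheticTruth(
        frozenset(cancer_set),
        frozenset(ln_set),
        {k: frozenset(v) for k, v in redundancy.items()},
    )
    return matrix, pheno, truth
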