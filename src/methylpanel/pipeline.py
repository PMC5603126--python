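"""End-to-end orchestration: simulate-or-load, screen, rank, search, evaluate.

``run_pipeline`` executes both binary comparisons (normal vs cancer and
LN-negative vs LN-positive) through the three selection stages and the
downstream evaluation, writing every intermediate table plus a manifest of
seeds, thresholds and stage row counts to a run directory. A single global
seed is expanded into fixed named substreams (one per stage and comparison),
so, for example, changing the number of evaluation repeats never perturbs the
wrapper search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dmr import DEFAULT_THRESHOLDS, DMRThresholds, PipelineError, density_summary, run_dmr
from .evaluation import EvalConfig, EvalResult, compare_strategies
from .ga import GAConfig, consensus_counts, consensus_panel, run_ga
from .io import (
    ComparisonSpec,
    ConfigurationError,
    FeaturePanel,
    annotate_probes,
    build_comparisons,
    read_beta_matrix,
    read_phenotype_table,
    read_probe_annotation,
    write_beta_matrix,
    write_phenotype_table,
)
from .mrmr import discretize, mrmr_rank
from .synthetic import SyntheticDesign, generate

logger = logging.getLogger(__name__)

# fixed substream indices: stage results stay reproducible when other stages
# change their consumption of randomness
_SUBSTREAM = {
    "synthetic": 0,
    "ga:normal_vs_cancer": 1,
    "ga:ln_neg_vs_ln_pos": 2,
    "eval:normal_vs_cancer": 3,
    "eval:ln_neg_vs_ln_pos": 4,
}


def _substream_seed(global_seed: int, name: str) -> int:
    child = np.random.SeedSequence(global_seed).spawn(len(_SUBSTREAM))
    return int(child[_SUBSTREAM[name]].generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration.

    Exactly one of ``design`` (synthetic study) or ``matrix_path`` +
    ``pheno_path`` (on-disk data) must be provided. Per-comparison DMR
    thresholds default to the study's: adjusted p < 1e-5 with |mean diff| >
    0.2 for normal-vs-cancer, 0.01 / 0.02 for the LN contrast. GA settings
    default to the study's evolutionary parameters with desk-scale generation
    counts; panels hold 20 (cancer) and 12 (LN) probes with burn-ins of 12
    and 20 generations.
    """

    design: SyntheticDesign | None = None
    matrix_path: str | None = None
    pheno_path: str | None = None
    annotation_path: str | None = None
    thresholds: dict[str, DMRThresholds] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    keep_fraction: float = 0.10
    ga_configs: dict[str, GAConfig] = field(
        default_factory=lambda: {
            "normal_vs_cancer": GAConfig(
                max_generations=30, burn_in_generation=12, panel_size=20
            ),
            "ln_neg_vs_ln_pos": GAConfig(
                max_generations=30, burn_in_generation=20, panel_size=12
            ),
        }
    )
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    quintile_mode: str = "pooled"
    include_unclassified_in_cancer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_synthetic = self.design is not None
        has_paths = self.matrix_path is not None and self.pheno_path is not None
        if has_synthetic == has_paths:
            raise ConfigurationError(
                "provide exactly one of: a synthetic design, or matrix+phenotype paths"
            )
        if not 0 < self.keep_fraction <= 1:
            raise ConfigurationError("keep_fraction must lie in (0, 1]")
        for name in ("normal_vs_cancer", "ln_neg_vs_ln_pos"):
            if name not in self.thresholds or name not in self.ga_configs:
                raise ConfigurationError(f"missing configuration for comparison {name!r}")


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """Study-shaped synthetic configuration at desk scale."""
    return PipelineConfig(design=SyntheticDesign(seed=seed), seed=seed)


@dataclass
class ComparisonResult:
    comparison: ComparisonSpec
    dmr_table: pd.DataFrame
    significant_probes: list[str]
    mrmr_table: pd.DataFrame
    candidates: list[str]
    trace_table: pd.DataFrame
    consensus: pd.Series
    panel: FeaturePanel
    eval_result: EvalResult | None


@dataclass
class PipelineResult:
    out_dir: Path
    comparisons: dict[str, ComparisonResult]
    shared_significant: list[str]
    manifest: dict


def intersect_significant(dmr_a: pd.DataFrame, dmr_b: pd.DataFrame) -> list[str]:
    """Probes called significant in both comparisons."""
    sig_a = set(dmr_a.index[dmr_a["significant"]])
    sig_b = set(dmr_b.index[dmr_b["significant"]])
    return sorted(sig_a & sig_b)


def _binary_labels(comp: ComparisonSpec) -> tuple[list[str], np.ndarray]:
    samples = list(comp.group_a) + list(comp.group_b)
    labels = np.array([0] * len(comp.group_a) + [1] * len(comp.group_b))
    return samples, labels


def _run_comparison(
    matrix: pd.DataFrame,
    comp: ComparisonSpec,
    cfg: PipelineConfig,
    run_evaluation: bool = True,
) -> ComparisonResult:
    name = comp.name
    logger.info("[%s] stage 1: differential-methylation screen", name)
    dmr_table = run_dmr(
        matrix, comp, cfg.thresholds[name], quintile_mode=cfg.quintile_mode
    )
    significant = sorted(dmr_table.index[dmr_table["significant"]])
    logger.info("[%s] %d/%d probes significant", name, len(significant), len(dmr_table))
    if len(significant) < 2:
        raise PipelineError(
            f"comparison {name!r}: only {len(significant)} significant probes; "
            "thresholds too strict for this data"
        )

    samples, labels = _binary_labels(comp)
    sub = matrix.loc[significant, samples]

    logger.info("[%s] stage 2: mRMR ranking of %d probes", name, len(significant))
    disc = discretize(sub)
    mrmr_res = mrmr_rank(disc, labels, keep_fraction=cfg.keep_fraction)
    candidates = list(mrmr_res.kept)
    logger.info("[%s] kept %d candidates", name, len(candidates))
    if len(candidates) < 2:
        raise PipelineError(
            f"comparison {name!r}: fewer than 2 mRMR candidates for the wrapper"
        )

    ga_cfg = replace(cfg.ga_configs[name], seed=_substream_seed(cfg.seed, f"ga:{name}"))
    logger.info(
        "[%s] stage 3: GA wrapper (%d candidates, %d generations)",
        name, len(candidates), ga_cfg.max_generations,
    )
    trace = run_ga(matrix[samples], labels, candidates, ga_cfg)
    counts = consensus_counts(trace, ga_cfg)
    panel = consensus_panel(trace, ga_cfg, comparison=name)

    eval_result = None
    if run_evaluation:
        logger.info("[%s] evaluation: repeated-split AUROC comparison", name)
        eval_cfg = replace(
            cfg.eval_config, seed=_substream_seed(cfg.seed, f"eval:{name}")
        )
        eval_result = compare_strategies(
            matrix[samples],
            labels,
            {"dmr_only": significant, "three_step": list(panel.probes)},
            eval_cfg,
        )
    return ComparisonResult(
        comparison=comp,
        dmr_table=dmr_table,
        significant_probes=significant,
        mrmr_table=mrmr_res.to_frame(),
        candidates=candidates,
        trace_table=trace.to_frame(),
        consensus=counts,
        panel=panel,
        eval_result=eval_result,
    )


def _panel_payload(panel: FeaturePanel) -> dict:
    return {
        "comparison": panel.comparison,
        "probes": list(panel.probes),
        "consensus_counts": panel.counts,
        "genes": {p: sorted(g) for p, g in panel.genes.items()},
        "gene_union": sorted(panel.gene_union),
    }


def run_pipeline(
    cfg: PipelineConfig, out_dir, run_evaluation: bool = True
) -> PipelineResult:
    """Execute the full study and write all stage outputs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.design is not None:
        design = replace(cfg.design, seed=_substream_seed(cfg.seed, "synthetic"))
        matrix, pheno, truth = generate(design)
        write_beta_matrix(matrix, out_dir / "beta_matrix.tsv")
        write_phenotype_table(pheno, out_dir / "phenotypes.tsv")
        truth.to_json(out_dir / "truth.json")
    else:
        pheno = read_phenotype_table(cfg.pheno_path)
        matrix = read_beta_matrix(cfg.matrix_path, known_sample_ids=pheno.index)
        missing = [s for s in pheno.index if s not in matrix.columns]
        if missing:
            raise ConfigurationError(
                f"samples in phenotype table but not in matrix: {missing[:5]}"
            )
    annotation = (
        read_probe_annotation(cfg.annotation_path) if cfg.annotation_path else None
    )

    cmp_cancer, cmp_ln = build_comparisons(
        pheno, include_unclassified_in_cancer=cfg.include_unclassified_in_cancer
    )

    results: dict[str, ComparisonResult] = {}
    for comp in (cmp_cancer, cmp_ln):
        try:
            res = _run_comparison(matrix, comp, cfg, run_evaluation=run_evaluation)
        except (PipelineError, ConfigurationError) as exc:
            raise PipelineError(f"stage failure in comparison {comp.name!r}: {exc}") from exc
        if annotation is not None:
            res.panel = annotate_probes(res.panel, annotation)
        results[comp.name] = res

        prefix = out_dir / comp.name
        res.dmr_table.to_csv(f"{prefix}.dmr.tsv", sep="\t")
        density_summary(res.dmr_table).to_csv(f"{prefix}.dmr_density.tsv", sep="\t", index=False)
        res.mrmr_table.to_csv(f"{prefix}.mrmr.tsv", sep="\t")
        res.trace_table.to_csv(f"{prefix}.ga_trace.tsv", sep="\t")
        res.consensus.rename("count").to_frame().assign(
            selected=lambda d: d.index.isin(res.panel.probes)
        ).to_csv(f"{prefix}.consensus.tsv", sep="\t", index_label="probe_id")
        with open(f"{prefix}.panel.json", "w") as fh:
            json.dump(_panel_payload(res.panel), fh, indent=1)
        if res.eval_result is not None:
            res.eval_result.per_repeat.to_csv(
                f"{prefix}.eval_auroc.tsv", sep="\t", index=False
            )

    shared = intersect_significant(
        results["normal_vs_cancer"].dmr_table, results["ln_neg_vs_ln_pos"].dmr_table
    )

    manifest = {
        "methylpanel_version": __version__,
        "seed": cfg.seed,
        "substream_seeds": {
            name: _substream_seed(cfg.seed, name) for name in _SUBSTREAM
        },
        "config": _config_payload(cfg),
        "stages": {
            name: {
                "n_probes_tested": int(len(res.dmr_table)),
                "n_significant": len(res.significant_probes),
                "n_mrmr_candidates": len(res.candidates),
                "n_ga_generations": int(len(res.trace_table)),
                "panel_size": len(res.panel.probes),
                "final_best_fitness": float(res.trace_table["best_fitness"].iloc[-1]),
            }
            for name, res in results.items()
        },
        "n_shared_significant": len(shared),
    }
    if run_evaluation:
        for name, res in results.items():
            manifest["stages"][name]["median_auroc"] = {
                s: res.eval_result.median(s) for s in ("dmr_only", "three_step")
            }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineResult(
        out_dir=out_dir, comparisons=results, shared_significant=shared,
        manifest=manifest,
    )


def _config_payload(cfg: PipelineConfig) -> dict:
    payload = asdict(cfg)
    payload["thresholds"] = {k: asdict(v) for k, v in cfg.thresholds.items()}
    payload["ga_configs"] = {k: asdict(v) for k, v in cfg.ga_configs.items()}
    payload["eval_config"] = asdict(cfg.eval_config)
    if cfg.design is not None:
        payload["design"] = asdict(cfg.design)
    return payload
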