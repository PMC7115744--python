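"""End-to-end pipeline: simulate -> filter -> score -> cluster -> validate.

A single :class:`PipelineConfig` drives all stages; one global seed is
fanned out to per-stage seeds by fixed offsets so each stage is
individually reproducible.  Every stage writes TSV outputs plus a
machine-readable run report with a file manifest (sha256 hashes), so an
identical config and seed produce an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .clustering import SlopeKMeans, congruence_classification, slope_vectors
from .cohort import DepotPhenotypeAssociation
from .filtering import filter_expressed_genes, log2fc_trajectory
from .scoring import TimeCourseDivergence
from .simulate import (
    CohortConfig,
    SimulationConfig,
    generate_cohort,
    generate_dabg_table,
    generate_literature_counts,
    generate_timecourse,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

# seed offsets per stage (stage seed = global seed + offset)
_SEED_OFFSETS = {"timecourse": 0, "dabg": 101, "litcounts": 202, "cluster": 303,
                 "cohort": 404}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the emulated study design
    (alpha 0.05, k = 8, vis/sc ratio cutoff 0.4)."""

    n_genes: int = 2000
    fraction_divergent: float = 0.05
    noise_sd: float = 0.25
    n_replicates: int = 3
    n_exons_per_gene: int = 4
    expressed_fraction: float = 0.9  # of null genes; divergent genes always detected
    alpha: float = 0.05
    dabg_fraction: float = 0.5
    instability_quantile: float = 0.95
    k: int = 8
    n_restarts: int = 25
    epsilon: float | None = None  # None = data-driven
    cluster_genes: str = "candidates"  # or "expressed"
    ratio_cutoff: float = 0.4
    lean_bmi_cutoff: float = 30.0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    seed: int = 0
    out_dir: str = "adipodyn_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage gene counts, file manifest and config echo."""

    counts: dict
    manifest: dict
    config: dict
    seed: int
    warnings: list

    def validate(self) -> None:
        c = self.counts
        if not (
            set(c.get("top_genes_list", []))
            <= set(c.get("candidates_list", []))
            <= set(c.get("expressed_list", []))
        ):
            raise AssertionError("count containment violated: top ⊆ candidates ⊆ expressed")


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: pathlib.Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def _write_list(items, path: pathlib.Path) -> None:
    path.write_text("".join(f"{g}\n" for g in items))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write their outputs under ``config.out_dir``."""
    cfg = config
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # --- simulate -----------------------------------------------------
    sim_cfg = SimulationConfig(
        n_genes=cfg.n_genes,
        fraction_divergent=cfg.fraction_divergent,
        noise_sd=cfg.noise_sd,
        n_replicates=cfg.n_replicates,
        seed=cfg.seed + _SEED_OFFSETS["timecourse"],
    )
    experiment, truth = generate_timecourse(sim_cfg)
    paths = experiment.to_tsv(out)
    _write_tsv(truth, out / "ground_truth.tsv")

    import numpy as np

    rng = np.random.default_rng(cfg.seed + _SEED_OFFSETS["dabg"])
    nulls = truth.index[~truth["divergent"]]
    keep_nulls = rng.random(len(nulls)) < cfg.expressed_fraction
    expressed_design = sorted(
        set(truth.index[truth["divergent"]]) | set(nulls[keep_nulls])
    )
    dabg = generate_dabg_table(
        experiment,
        n_exons_per_gene=cfg.n_exons_per_gene,
        expressed_genes=expressed_design,
        seed=cfg.seed + _SEED_OFFSETS["dabg"],
        alpha=cfg.alpha,
        fraction=cfg.dabg_fraction,
    )
    _write_tsv(dabg, out / "dabg.tsv", index=False)
    litcounts = generate_literature_counts(
        truth, seed=cfg.seed + _SEED_OFFSETS["litcounts"]
    )
    _write_tsv(litcounts.rename_axis("gene").to_frame(), out / "litcounts.tsv")

    # --- filter -------------------------------------------------------
    expressed = filter_expressed_genes(dabg, alpha=cfg.alpha, fraction=cfg.dabg_fraction)
    _write_list(expressed, out / "expressed_genes.txt")
    sub = experiment.subset(expressed)

    # --- score --------------------------------------------------------
    results = TimeCourseDivergence(sub, literature_counts=litcounts).fit(
        alpha=cfg.alpha, instability_quantile=cfg.instability_quantile
    )
    results.to_tsv(out / "scores.tsv")
    _write_list(results.candidates, out / "candidates.txt")
    _write_list(results.top_genes, out / "top_genes.txt")
    (out / "score_summary.txt").write_text(results.summary() + "\n")

    trajectory = pd.concat(
        [
            log2fc_trajectory(results.curves, expressed, label="all", magnitude=True),
            *(
                [log2fc_trajectory(results.curves, results.candidates,
                                   label="candidates", magnitude=True)]
                if results.candidates
                else []
            ),
        ],
        ignore_index=True,
    )
    _write_tsv(trajectory, out / "trajectory.tsv", index=False)

    # --- cluster ------------------------------------------------------
    cluster_counts: dict = {}
    gene_pool = results.candidates if cfg.cluster_genes == "candidates" else expressed
    if len(gene_pool) * 2 >= cfg.k and len(gene_pool) > 0:
        profiles = slope_vectors(results.curves.subset(gene_pool))
        fit = SlopeKMeans(profiles, k=cfg.k, n_restarts=cfg.n_restarts).fit(
            seed=cfg.seed + _SEED_OFFSETS["cluster"]
        )
        records, combos = congruence_classification(fit, epsilon=cfg.epsilon)
        _write_tsv(
            fit.assignments.reset_index(), out / "cluster_assignments.tsv", index=False
        )
        _write_tsv(fit.centroids, out / "centroids.tsv")
        _write_tsv(records.rename_axis("gene"), out / "congruence.tsv")
        _write_tsv(combos, out / "combination_counts.tsv", index=False)
        (out / "cluster_summary.txt").write_text(fit.summary() + "\n")
        cluster_counts = {
            "n_congruent": int(records["congruent"].sum()),
            "n_divergent_dynamics": int((~records["congruent"]).sum()),
            "n_constant_one_side": int(records["constant_one_side"].sum()),
            "bss_tss": fit.bss_tss,
        }
    else:
        msg = "too few genes for clustering: stage skipped"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    # --- validate (cohort) -------------------------------------------
    cohort_cfg = CohortConfig(
        **{**cfg.cohort, "seed": cfg.seed + _SEED_OFFSETS["cohort"]}
    )
    cohort, cohort_truth = generate_cohort(cohort_cfg)
    _write_tsv(cohort, out / "cohort.tsv")
    _write_tsv(cohort_truth, out / "cohort_ground_truth.tsv", index=False)
    assoc = DepotPhenotypeAssociation(cohort).fit(
        ratio_cutoff=cfg.ratio_cutoff, lean_bmi_cutoff=cfg.lean_bmi_cutoff
    )
    _write_tsv(assoc.correlations, out / "associations.tsv", index=False)
    _write_tsv(assoc.group_tests, out / "group_tests.tsv", index=False)
    _write_tsv(assoc.regressions, out / "regressions.tsv", index=False)
    (out / "cohort_summary.txt").write_text(assoc.summary() + "\n")

    # --- report -------------------------------------------------------
    counts = {
        "n_genes_simulated": cfg.n_genes,
        "n_true_divergent": int(truth["divergent"].sum()),
        "n_expressed": len(expressed),
        "n_scored": len(results.scores),
        "n_significant_any": results.n_significant_any,
        "n_candidates": len(results.candidates),
        "n_top": len(results.top_genes),
        **cluster_counts,
        "cohort_subjects": len(cohort),
        "expressed_list": expressed,
        "candidates_list": results.candidates,
        "top_genes_list": results.top_genes,
    }
    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        and p.suffix in {".tsv", ".txt"}
    }
    if not results.candidates:
        notes.append("no candidate genes: downstream stages are empty")
    report = RunReport(
        counts=counts,
        manifest=manifest,
        config=cfg.to_dict(),
        seed=cfg.seed,
        warnings=notes,
    )
    report.validate()
    write_report(report, out)
    return report


def write_report(report: RunReport, out_dir) -> dict[str, pathlib.Path]:
    """Write machine-readable (JSON) and human-readable (text) summaries."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "seed": report.seed,
        "config": report.config,
        "counts": {
            k: v for k, v in report.counts.items() if not k.endswith("_list")
        },
        "manifest": report.manifest,
        "warnings": report.warnings,
    }
    json_path = out / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    lines = ["adipodyn pipeline run", "=====================", f"seed: {report.seed}", ""]
    for k, v in payload["counts"].items():
        lines.append(f"{k}: {v}")
    if report.warnings:
        lines.append("")
        lines.extend(f"warning: {w}" for w in report.warnings)
    lines.append("")
    lines.append(f"files written: {len(report.manifest)}")
    text_path = out / "report.txt"
    text_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "text": text_path}
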