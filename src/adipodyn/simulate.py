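"""Synthetic data generators with known ground truth.

Three simulators stand in for the undeposited experimental data:

* :func:`generate_timecourse` — a two-depot (epi/ing) differentiation
  course, six harvest days (−2, 0, 2, 4, 6, 8), triplicate arrays, gene
  trajectories drawn from the eight schematic archetypes with Gaussian
  replicate noise.  A configurable fraction of genes is *divergent*
  between depots.
* :func:`generate_dabg_table` — per-exon detection-above-background
  p-values constructed so that a designated set of genes passes the
  expressed-gene rule and nobody else does.
* :func:`generate_cohort` — a paired human adipose-tissue cohort
  (subcutaneous/visceral expression, age, sex, BMI, WHR, vis/sc area
  ratio) with configurable rank correlation between per-depot expression
  and the obesity phenotypes.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .archetypes import ARCHETYPES, DEFAULT_DAYS, get_archetype
from .containers import DEFAULT_CONDITIONS, TimeCourseExperiment

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "DEFAULT_COHORT_TARGETS",
    "generate_timecourse",
    "generate_dabg_table",
    "generate_literature_counts",
    "generate_cohort",
    "divergent_rule",
]

AMPLITUDE_RATIO_BAND: tuple[float, float] = (0.8, 1.25)


# ----------------------------------------------------------------------
# time course
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated differentiation course.

    Defaults mirror the design of the emulated experiment: two depots,
    days −2..8, triplicates.  ``fraction_divergent`` genes differ between
    depots in shape, amplitude and baseline (see
    ``docs/methods.md`` for the precise effect definition); the rest are
    identical in both depots up to replicate noise.
    """

    n_genes: int = 2000
    fraction_divergent: float = 0.05
    amplitude_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.25
    n_replicates: int = 3
    days: tuple[float, ...] = DEFAULT_DAYS
    baseline_range: tuple[float, float] = (6.0, 12.0)
    min_divergent_gap: float = 2.0
    min_divergent_drift: float = 1.0
    baseline_offset_range: tuple[float, float] = (0.25, 0.75)
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if not 0.0 <= self.fraction_divergent <= 1.0:
            raise ValueError("fraction_divergent must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        days = np.asarray(self.days, dtype=float)
        if len(days) < 3 or np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing with >= 3 points")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude_range must satisfy 0 < lo <= hi")


def divergent_rule(
    archetype_a: str,
    archetype_b: str,
    amplitude_a: float,
    amplitude_b: float,
    ratio_band: tuple[float, float] = AMPLITUDE_RATIO_BAND,
) -> bool:
    """Deterministic ground-truth label: a gene is divergent iff its two
    conditions use different archetypes or an amplitude ratio outside
    ``ratio_band``."""
    if archetype_a != archetype_b:
        return True
    if amplitude_b == 0:
        return amplitude_a != 0
    ratio = amplitude_a / amplitude_b
    return not (ratio_band[0] <= ratio <= ratio_band[1])


def _ols_drift(d: np.ndarray, days: np.ndarray) -> float:
    """|least-squares slope| times course duration — sustained drift of d."""
    dev = days - days.mean()
    slope = float(dev @ (d - d.mean()) / (dev @ dev))
    return abs(slope) * (days.max() - days.min())


def _draw_divergent(rng: np.random.Generator, cfg: SimulationConfig, days: np.ndarray):
    """Archetype pair + amplitudes for a divergent gene.

    Resamples until the difference curve shows both a pointwise gap of at
    least ``min_divergent_gap`` log2 units and a sustained drift of at
    least ``min_divergent_drift`` log2 units over the course; this is the
    package's operational definition of divergent dynamics.
    """
    names = [a.name for a in ARCHETYPES]
    lo, hi = cfg.amplitude_range
    for _ in range(200):
        ia, ib = rng.choice(len(names), size=2, replace=False)
        amp_a, amp_b = rng.uniform(lo, hi, size=2)
        curve_a = amp_a * ARCHETYPES[ia].values(days)
        curve_b = amp_b * ARCHETYPES[ib].values(days)
        d = curve_a - curve_b
        if (
            np.max(np.abs(d)) >= cfg.min_divergent_gap
            and _ols_drift(d, days) >= cfg.min_divergent_drift
        ):
            return names[ia], names[ib], float(amp_a), float(amp_b)
    # amplitude ranges too narrow to ever meet the gap: scale the first
    # condition's amplitude directly (keeps determinism and the contract)
    amp_a = max(amp_a, cfg.min_divergent_gap / max(np.max(np.abs(curve_a)), 1e-12) * amp_a)
    return names[ia], names[ib], float(amp_a), float(amp_b)


def generate_timecourse(
    config: SimulationConfig,
) -> tuple[TimeCourseExperiment, pd.DataFrame]:
    """Simulate a balanced two-condition time course.

    Returns the experiment and a ground-truth table (one row per gene:
    archetypes, baselines, amplitudes per condition, and the ``divergent``
    flag given by :func:`divergent_rule`).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    days = np.asarray(cfg.days, dtype=float)
    cond_a, cond_b = cfg.conditions
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    n_div = int(round(cfg.n_genes * cfg.fraction_divergent))
    divergent_idx = set(rng.choice(cfg.n_genes, size=n_div, replace=False).tolist())

    names = [a.name for a in ARCHETYPES]
    lo, hi = cfg.amplitude_range
    off_lo, off_hi = cfg.baseline_offset_range
    rows = []
    mean_curves = {cond_a: np.empty((cfg.n_genes, len(days))),
                   cond_b: np.empty((cfg.n_genes, len(days)))}
    for i in range(cfg.n_genes):
        baseline = rng.uniform(*cfg.baseline_range)
        if i in divergent_idx:
            arch_a, arch_b, amp_a, amp_b = _draw_divergent(rng, cfg, days)
            offset = rng.choice([-1.0, 1.0]) * rng.uniform(off_lo, off_hi)
            base_a, base_b = baseline + offset, baseline
        else:
            arch_a = arch_b = names[rng.integers(len(names))]
            amp_a = amp_b = rng.uniform(lo, hi)
            base_a = base_b = baseline
        mean_curves[cond_a][i] = base_a + amp_a * get_archetype(arch_a).values(days)
        mean_curves[cond_b][i] = base_b + amp_b * get_archetype(arch_b).values(days)
        rows.append(
            {
                "gene": genes[i],
                f"archetype_{cond_a}": arch_a,
                f"archetype_{cond_b}": arch_b,
                f"baseline_{cond_a}": base_a,
                f"baseline_{cond_b}": base_b,
                f"amplitude_{cond_a}": amp_a,
                f"amplitude_{cond_b}": amp_b,
                "divergent": divergent_rule(arch_a, arch_b, amp_a, amp_b),
            }
        )
    truth = pd.DataFrame(rows).set_index("gene")

    sample_ids, meta = [], []
    for cond in cfg.conditions:
        for day in days:
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{cond}_d{day:g}_r{rep}"
                sample_ids.append(sid)
                meta.append({"sample_id": sid, "condition": cond, "day": day,
                             "replicate": rep})
    sheet = pd.DataFrame(meta).set_index("sample_id")

    blocks = []
    for cond in cfg.conditions:
        # replicate axis: repeat each day column n_replicates times
        blocks.append(np.repeat(mean_curves[cond], cfg.n_replicates, axis=1))
    values = np.concatenate(blocks, axis=1)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    experiment = TimeCourseExperiment(values=matrix, samples=sheet,
                                      conditions=cfg.conditions)
    return experiment, truth


# ----------------------------------------------------------------------
# DABG table
# ----------------------------------------------------------------------
def generate_dabg_table(
    experiment: TimeCourseExperiment,
    n_exons_per_gene: int = 4,
    expressed_genes=None,
    seed: int = 0,
    alpha: float = 0.05,
    fraction: float = 0.5,
    present_rate: float = 0.8,
) -> pd.DataFrame:
    """Per-exon detection-above-background p-values (long table).

    Genes in ``expressed_genes`` receive p < ``alpha`` for at least
    ``fraction`` of their exons in at least one sample (guaranteed by
    construction); all other genes receive p >= ``alpha`` everywhere, so
    the expressed-gene filter recovers ``expressed_genes`` exactly.
    """
    if n_exons_per_gene < 1:
        raise ValueError("n_exons_per_gene must be >= 1")
    genes = list(experiment.genes)
    if expressed_genes is None:
        expressed_genes = genes
    expressed = set(expressed_genes)
    unknown = expressed - set(genes)
    if unknown:
        raise ValueError(f"expressed_genes not in experiment: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    samples = list(experiment.values.columns)
    n_s, n_e = len(samples), n_exons_per_gene
    n_forced = int(np.ceil(n_e * fraction))

    frames = []
    for gene in genes:
        if gene in expressed:
            present = rng.random((n_e, n_s)) < present_rate
            p = np.where(
                present,
                rng.uniform(0.0, alpha, size=(n_e, n_s)),
                rng.uniform(alpha, 1.0, size=(n_e, n_s)),
            )
            p[:n_forced, 0] = rng.uniform(0.0, alpha, size=n_forced)
        else:
            p = rng.uniform(alpha, 1.0, size=(n_e, n_s))
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "exon": np.repeat(np.arange(1, n_e + 1), n_s),
                    "sample": samples * n_e,
                    "p": p.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# literature counts
# ----------------------------------------------------------------------
def generate_literature_counts(
    ground_truth: pd.DataFrame,
    seed: int = 0,
    relevant_mean: float = 30.0,
    background_mean: float = 0.3,
) -> pd.Series:
    """Publication counts for the relevance score, coupled to ground truth.

    Divergent genes emulate genuinely stimulus-relevant genes (counts
    ``1 + Poisson(relevant_mean)``); null genes draw from a sparse
    background (``Poisson(background_mean)``, mostly zero), as expected
    for a specific PubMed stimulus term.
    """
    rng = np.random.default_rng(seed)
    div = ground_truth["divergent"].to_numpy(dtype=bool)
    counts = rng.poisson(background_mean, size=len(ground_truth))
    counts[div] = 1 + rng.poisson(relevant_mean, size=int(div.sum()))
    return pd.Series(counts, index=ground_truth.index, name="count")


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------
# Depot-specific rank-correlation targets emulating the magnitudes the
# association stage is meant to recover; keys are (depot, phenotype).
DEFAULT_COHORT_TARGETS: dict[str, dict[tuple[str, str], float]] = {
    "ALX1": {("sc", "BMI"): -0.612, ("vis", "BMI"): -0.356},
    "HOXA5": {("sc", "BMI"): -0.448, ("vis", "BMI"): -0.309},
    "IRX1": {("sc", "BMI"): -0.364, ("vis", "BMI"): -0.349},
    "GATM": {("sc", "BMI"): -0.449},
    "ARHGDIB": {("sc", "BMI"): 0.279, ("sc", "WHR"): 0.315},
    "ACE": {("vis", "BMI"): -0.387, ("sc", "WHR"): 0.311},
    "OAS2": {("vis", "BMI"): -0.327},
    "APOD": {("sc", "BMI"): -0.334},
    "DKK2": {},
    "EPHA3": {},
    "CIDEC": {},
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated paired-biopsy cohort.

    Phenotype moments follow the described cohort (age 53 ± 16 y, BMI
    36.1 ± 14.0 kg/m², WHR 0.953 ± 0.149; lean / sc-obese / vis-obese
    group sizes 25/21/17); truncation bounds are conventional.
    ``gene_targets`` maps gene -> {(depot, phenotype): Spearman rho}.
    """

    n_subjects: int = 63
    group_sizes: tuple[int, int, int] | None = (25, 21, 17)
    age_mean: float = 53.0
    age_sd: float = 16.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    female_fraction: float = 47 / 63
    bmi_mean: float = 36.1
    bmi_sd: float = 14.0
    bmi_bounds: tuple[float, float] = (15.0, 70.0)
    lean_bmi_cutoff: float = 30.0
    whr_mean: float = 0.953
    whr_sd: float = 0.149
    whr_bounds: tuple[float, float] = (0.5, 1.5)
    ratio_mean: float = 0.4
    ratio_sd: float = 0.25
    ratio_bounds: tuple[float, float] = (0.0, 1.5)
    ratio_cutoff: float = 0.4
    gene_targets: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_TARGETS))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.group_sizes is not None and sum(self.group_sizes) != self.n_subjects:
            raise ValueError("group_sizes must sum to n_subjects")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for gene, targets in self.gene_targets.items():
            ss = {"sc": 0.0, "vis": 0.0}
            for (depot, pheno), rho in targets.items():
                if depot not in ("sc", "vis") or pheno not in ("BMI", "WHR"):
                    raise ValueError(f"bad target key {(depot, pheno)} for {gene}")
                if abs(rho) > 1:
                    raise ValueError(f"|target rho| > 1 for {gene}")
                ss[depot] += _latent_r(rho) ** 2
            for depot, total in ss.items():
                if total > 1.0 + 1e-9:
                    raise ValueError(
                        f"targets for {gene}/{depot} jointly infeasible (sum r^2 > 1)"
                    )


def _latent_r(rho_s: float) -> float:
    """Latent Pearson r reproducing Spearman rho_s under a Gaussian copula."""
    return float(np.clip(2.0 * np.sin(np.pi * rho_s / 6.0), -1.0, 1.0))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _rank_latent(x: np.ndarray) -> np.ndarray:
    """Standard-normal latent sharing the ranks of x."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the paired sc/vis cohort.

    Returns the cohort table (one row per subject; expression columns
    named ``<GENE>_sc`` / ``<GENE>_vis``) and a long ground-truth table
    (gene, depot, phenotype, target_rho).  Expression is coupled to a
    phenotype's ranks through a shared latent Gaussian, so the sample
    Spearman correlation approaches the target as n grows and equals ±1
    exactly for |target| = 1.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    if cfg.group_sizes is not None:
        n_lean, n_sc, n_vis = cfg.group_sizes
        bmi = np.concatenate(
            [
                _truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, cfg.bmi_bounds[0],
                           cfg.lean_bmi_cutoff, n_lean),
                _truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, cfg.lean_bmi_cutoff,
                           cfg.bmi_bounds[1], n_sc + n_vis),
            ]
        )
        ratio = np.concatenate(
            [
                _truncnorm(rng, cfg.ratio_mean, cfg.ratio_sd, *cfg.ratio_bounds,
                           size=n_lean),
                _truncnorm(rng, cfg.ratio_mean, cfg.ratio_sd, cfg.ratio_bounds[0],
                           cfg.ratio_cutoff, n_sc),
                _truncnorm(rng, cfg.ratio_mean, cfg.ratio_sd, cfg.ratio_cutoff,
                           cfg.ratio_bounds[1], n_vis),
            ]
        )
    else:
        bmi = _truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, *cfg.bmi_bounds, size=n)
        ratio = _truncnorm(rng, cfg.ratio_mean, cfg.ratio_sd, *cfg.ratio_bounds, size=n)

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=n)
    whr = _truncnorm(rng, cfg.whr_mean, cfg.whr_sd, *cfg.whr_bounds, size=n)
    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")

    latent = {"BMI": _rank_latent(bmi), "WHR": _rank_latent(whr)}
    table = pd.DataFrame(
        {
            "subject": [f"s{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "BMI": bmi,
            "WHR": whr,
            "vis_sc_ratio": ratio,
        }
    ).set_index("subject")

    truth_rows = []
    for gene, targets in cfg.gene_targets.items():
        for depot in ("sc", "vis"):
            r_bmi = _latent_r(targets.get((depot, "BMI"), 0.0))
            r_whr = _latent_r(targets.get((depot, "WHR"), 0.0))
            resid = np.sqrt(max(0.0, 1.0 - r_bmi**2 - r_whr**2))
            x = r_bmi * latent["BMI"] + r_whr * latent["WHR"]
            if resid > 0:
                x = x + resid * rng.standard_normal(n)
            expr = 10.0 * np.exp(0.5 * x)  # positive, rank-preserving AU scale
            if cfg.missing_rate > 0:
                expr = np.where(rng.random(n) < cfg.missing_rate, np.nan, expr)
            table[f"{gene}_{depot}"] = expr
            for pheno in ("BMI", "WHR"):
                truth_rows.append(
                    {
                        "gene": gene,
                        "depot": depot,
                        "phenotype": pheno,
                        "target_rho": targets.get((depot, pheno), 0.0),
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return table, truth
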