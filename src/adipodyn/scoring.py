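"""Time-course divergence scoring.

Four per-gene scores quantify how strongly a gene's expression dynamics
differ between the two conditions, all computed from the condition-mean
difference curve d(day) except the literature-based relevance score:

* **integral** — trapezoidal integral of |d| over a time interval
  (absolute expression change; computed for the early, middle, late and
  whole intervals of the course);
* **dynamic** — |least-squares slope of d against day| x course
  duration (slow, sustained drift);
* **peak** — max over days of |d - median(d)| (fast transient change,
  insensitive to a constant offset);
* **relevance** — ln(1 + publication count) for the gene under a
  configured stimulus term (prior-knowledge weight).

Each score is tested for significance against a robust empirical null
across genes (median/MAD z-score, one-sided upper tail).  Genes with
excessive replicate variance are flagged unstable.  The consensus score
min-max scales the four scores across genes, averages them and rescales
to [0, 1], so the top-ranked gene scores exactly 1.  Candidate genes are
those significant in all four scores and stable; the top set is the
strict upper quartile of candidate consensus scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MeanCurves, TimeCourseExperiment

__all__ = [
    "IntervalSpec",
    "DEFAULT_INTERVALS",
    "integral_scores",
    "dynamic_score",
    "peak_score",
    "relevance_score",
    "instability_flag",
    "score_significance",
    "consensus_scores",
    "select_candidates",
    "select_top_set",
    "TimeCourseDivergence",
    "DivergenceResults",
]


@dataclass(frozen=True)
class IntervalSpec:
    """A named day interval of the differentiation course."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("interval lower bound must be below upper bound")

    def mask(self, days: np.ndarray) -> np.ndarray:
        m = (days >= self.lower) & (days <= self.upper)
        if m.sum() < 2:
            raise ValueError(
                f"interval {self.name!r} [{self.lower}, {self.upper}] covers "
                "fewer than two grid days"
            )
        if self.lower not in days or self.upper not in days:
            raise ValueError(f"interval {self.name!r} bounds must lie on the day grid")
        return m


#: early = before induction, middle = first four days after, late = days
#: 6-8, whole = the full course.  Days 4-6 fall in no named sub-interval
#: and are covered by "whole" only.
DEFAULT_INTERVALS: tuple[IntervalSpec, ...] = (
    IntervalSpec("early", -2, 0),
    IntervalSpec("middle", 0, 4),
    IntervalSpec("late", 6, 8),
    IntervalSpec("whole", -2, 8),
)


# ----------------------------------------------------------------------
# the four scores (vectorized across genes)
# ----------------------------------------------------------------------
def integral_scores(
    curves: MeanCurves, intervals: tuple[IntervalSpec, ...] = DEFAULT_INTERVALS
) -> pd.DataFrame:
    """Trapezoidal integral of |d(day)| per interval (log2·day units)."""
    days = curves.days
    d = np.abs(curves.difference.to_numpy())
    out = {}
    for spec in intervals:
        m = spec.mask(days)
        out[spec.name] = np.trapezoid(d[:, m], days[m], axis=1)
    return pd.DataFrame(out, index=curves.genes)


def dynamic_score(curves: MeanCurves) -> pd.Series:
    """|OLS slope of d vs day| x course duration — sustained drift."""
    days = curves.days
    if len(days) < 3:
        raise ValueError("dynamic score needs at least 3 days")
    d = curves.difference.to_numpy()
    dev = days - days.mean()
    slope = (d - d.mean(axis=1, keepdims=True)) @ dev / (dev @ dev)
    score = np.abs(slope) * (days.max() - days.min())
    return pd.Series(score, index=curves.genes, name="dynamic")


def peak_score(curves: MeanCurves) -> pd.Series:
    """max |d - median(d)| over days — transient change, offset-free."""
    if len(curves.days) < 3:
        raise ValueError("peak score needs at least 3 days")
    d = curves.difference.to_numpy()
    centred = d - np.median(d, axis=1, keepdims=True)
    return pd.Series(np.abs(centred).max(axis=1), index=curves.genes, name="peak")


def relevance_score(genes, counts: pd.Series | dict) -> pd.Series:
    """ln(1 + publication count); genes absent from the table score 0."""
    counts = pd.Series(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("publication counts must be nonnegative")
    aligned = counts.reindex(list(genes)).fillna(0.0)
    return pd.Series(np.log1p(aligned.to_numpy()), index=pd.Index(genes),
                     name="relevance")


def instability_flag(
    experiment: TimeCourseExperiment, quantile: float = 0.95
) -> tuple[pd.Series, pd.Series]:
    """Replicate-variance instability index and flag.

    The index is the mean over (condition, day) cells of the replicate
    variance (ddof=1); a gene is unstable iff its index strictly exceeds
    the given quantile of all genes' indices.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must lie in [0, 1]")
    index = experiment.replicate_variances().mean(axis=1)
    index.name = "instability_index"
    cutoff = float(np.quantile(index.to_numpy(), quantile))
    flag = (index > cutoff).rename("unstable")
    return index, flag


# ----------------------------------------------------------------------
# significance, consensus, selection
# ----------------------------------------------------------------------
def score_significance(scores, alpha: float = 0.05) -> tuple[pd.Series, pd.Series]:
    """Robust-z empirical-null significance of a score across genes.

    z = (score - median) / (1.4826 * MAD); one-sided upper-tail normal p;
    significant iff p < alpha.  If the MAD is zero the standard deviation
    is used instead; if that is also zero no gene is significant.
    Assumes most genes are null.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 10:
        raise ValueError("need >= 10 genes to estimate the empirical null")
    x = s.to_numpy()
    med = np.median(x)
    scale = 1.4826 * np.median(np.abs(x - med))
    if scale == 0:
        scale = float(np.std(x, ddof=1))
    if scale == 0:
        p = pd.Series(1.0, index=s.index)
        return p < alpha, p
    z = (x - med) / scale
    p = pd.Series(stats.norm.sf(z), index=s.index)
    return p < alpha, p


def consensus_scores(scores: pd.DataFrame) -> pd.Series:
    """Double min-max scaled average of the four scores.

    Each column is min-max scaled to [0, 1] across genes (a column that
    is constant across genes scales to 0 for every gene), the four scaled
    scores are averaged, and the averages are min-max rescaled so the top
    gene scores exactly 1 and the bottom exactly 0.
    """
    if len(scores) < 2:
        raise ValueError("consensus needs at least 2 genes")

    def _minmax(v: np.ndarray) -> np.ndarray:
        rng = v.max() - v.min()
        if rng == 0:
            return np.zeros_like(v)
        return (v - v.min()) / rng

    scaled = np.column_stack([_minmax(scores[c].to_numpy(dtype=float))
                              for c in scores.columns])
    return pd.Series(_minmax(scaled.mean(axis=1)), index=scores.index,
                     name="consensus")


def select_candidates(records: pd.DataFrame) -> list[str]:
    """Genes significant in all four scores and not unstable."""
    needed = ["sig_dynamic", "sig_peak", "sig_integral", "sig_relevance", "unstable"]
    if missing := set(needed) - set(records.columns):
        raise ValueError(f"records lack flag columns: {sorted(missing)}")
    mask = (
        records["sig_dynamic"]
        & records["sig_peak"]
        & records["sig_integral"]
        & records["sig_relevance"]
        & ~records["unstable"]
    )
    return list(records.index[mask])


def select_top_set(consensus: pd.Series) -> list[str]:
    """Genes whose consensus strictly exceeds the candidates' upper quartile.

    The quartile uses the linear-interpolation definition; with 137
    distinct scores this selects exactly 34 genes.  With fewer than 4
    candidates the input is returned unchanged with a warning.
    """
    if len(consensus) < 4:
        warnings.warn(
            "fewer than 4 candidates: upper-quartile selection skipped",
            stacklevel=2,
        )
        return list(consensus.index)
    q3 = float(np.quantile(consensus.to_numpy(dtype=float), 0.75))
    return list(consensus.index[consensus > q3])


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class TimeCourseDivergence:
    """Model scoring per-gene divergence between two conditions over time.

    Parameters
    ----------
    experiment : TimeCourseExperiment
        Balanced two-condition time course (log2 values).
    literature_counts : Series or dict, optional
        Gene -> publication count for the stimulus term; missing genes
        count 0.
    intervals : tuple of IntervalSpec
        Integral-score intervals; the consensus uses the ``whole``
        interval.
    stimulus : str
        Label of the stimulus term behind the counts (metadata only).
    """

    def __init__(
        self,
        experiment: TimeCourseExperiment,
        literature_counts=None,
        intervals: tuple[IntervalSpec, ...] = DEFAULT_INTERVALS,
        stimulus: str = "fat distribution",
    ) -> None:
        self.experiment = experiment
        self.literature_counts = (
            pd.Series(dtype=float) if literature_counts is None
            else pd.Series(literature_counts, dtype=float)
        )
        self.intervals = intervals
        self.stimulus = stimulus
        if not any(spec.name == "whole" for spec in intervals):
            raise ValueError("intervals must include a 'whole' interval")

    def fit(
        self, alpha: float = 0.05, instability_quantile: float = 0.95
    ) -> "DivergenceResults":
        exp = self.experiment
        curves = exp.condition_mean_curves()

        integrals = integral_scores(curves, self.intervals)
        dynamic = dynamic_score(curves)
        peak = peak_score(curves)
        relevance = relevance_score(exp.genes, self.literature_counts)
        inst_index, unstable = instability_flag(exp, instability_quantile)

        sig_dynamic, p_dynamic = score_significance(dynamic, alpha)
        sig_peak, _ = score_significance(peak, alpha)
        sig_relevance, _ = score_significance(relevance, alpha)
        sig_by_interval = pd.DataFrame(
            {c: score_significance(integrals[c], alpha)[0] for c in integrals.columns}
        )
        sig_integral = sig_by_interval.any(axis=1)

        records = pd.DataFrame(
            {
                "dynamic": dynamic,
                "peak": peak,
                "relevance": relevance,
                "instability_index": inst_index,
                "sig_dynamic": sig_dynamic,
                "sig_peak": sig_peak,
                "sig_integral": sig_integral,
                "sig_relevance": sig_relevance,
                "unstable": unstable,
            }
        )
        for c in integrals.columns:
            records[f"integral_{c}"] = integrals[c]

        consensus = consensus_scores(
            pd.DataFrame(
                {
                    "dynamic": dynamic,
                    "peak": peak,
                    "integral": integrals["whole"],
                    "relevance": relevance,
                }
            )
        )
        records["consensus"] = consensus
        records = records.sort_values("consensus", ascending=False)

        candidates = select_candidates(records)
        top = select_top_set(records.loc[candidates, "consensus"])
        return DivergenceResults(
            model=self,
            scores=records,
            curves=curves,
            candidates=candidates,
            top_genes=top,
            alpha=alpha,
            instability_quantile=instability_quantile,
        )


@dataclass
class DivergenceResults:
    """Fitted divergence scores, flags and selections."""

    model: TimeCourseDivergence
    scores: pd.DataFrame
    curves: MeanCurves
    candidates: list[str]
    top_genes: list[str]
    alpha: float
    instability_quantile: float

    @property
    def n_significant_any(self) -> int:
        """Genes significant in at least one of the four scores."""
        flags = self.scores[["sig_dynamic", "sig_peak", "sig_integral",
                             "sig_relevance"]]
        return int(flags.any(axis=1).sum())

    def summary(self, top: int = 10) -> str:
        lines = [
            "Time-course divergence scoring",
            "==============================",
            f"conditions:            {self.model.experiment.conditions[0]} vs "
            f"{self.model.experiment.conditions[1]}",
            f"genes scored:          {len(self.scores)}",
            f"significant (any):     {self.n_significant_any}",
            f"candidates (all four, stable): {len(self.candidates)}",
            f"top set (> upper quartile):    {len(self.top_genes)}",
            f"alpha = {self.alpha}, instability quantile = "
            f"{self.instability_quantile}",
            "",
            f"top {min(top, len(self.scores))} genes by consensus score:",
        ]
        cols = ["consensus", "dynamic", "peak", "integral_whole", "relevance"]
        head = self.scores[cols].head(top)
        lines.append(head.round(3).to_string())
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.scores.rename_axis("gene").to_csv(path, sep="\t")

    def plot_trajectory(self, ax=None, magnitude: bool = True):
        """Average |log2 FC| per day for all genes vs the selected set."""
        from .filtering import log2fc_trajectory

        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        all_t = log2fc_trajectory(self.curves, list(self.curves.genes),
                                  label="all", magnitude=magnitude)
        ax.plot(all_t["day"], all_t["mean_log2fc"], label="all genes", color="tab:red")
        if self.candidates:
            sel = log2fc_trajectory(self.curves, self.candidates,
                                    label="candidates", magnitude=magnitude)
            ax.plot(sel["day"], sel["mean_log2fc"], label="candidate genes",
                    color="tab:blue")
        ax.axvline(0.0, ls=":", color="grey")
        ax.set_xlabel("day")
        ax.set_ylabel("mean |log2 FC|" if magnitude else "mean log2 FC")
        ax.legend()
        return ax
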