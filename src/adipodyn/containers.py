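"""In-memory containers for the time-course experiment and derived curves."""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeCourseExperiment", "MeanCurves", "DEFAULT_CONDITIONS"]

DEFAULT_CONDITIONS: tuple[str, str] = ("epi", "ing")


@dataclass
class TimeCourseExperiment:
    """Normalized log2 expression over a two-condition differentiation course.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes x samples matrix of log2 intensities.
    samples : pandas.DataFrame
        Sample sheet indexed by sample id with columns ``condition``,
        ``day`` and ``replicate``.
    conditions : tuple of str
        The two condition labels in difference order: the condition-mean
        difference curve is ``conditions[0] - conditions[1]``.

    The design must be complete and balanced: every (condition, day) cell
    carries the same number of replicates (>= 1) and all values are finite.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    conditions: tuple[str, str] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        required = {"condition", "day", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        observed = set(self.samples["condition"])
        if observed != set(self.conditions):
            raise ValueError(
                f"sample conditions {sorted(observed)} do not match "
                f"declared pair {self.conditions}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        days = np.asarray(sorted(self.samples["day"].unique()), dtype=float)
        if len(days) < 2 or np.any(np.diff(days) <= 0):
            raise ValueError("need at least two strictly increasing days")
        counts = self.samples.groupby(["condition", "day"]).size()
        expected_cells = len(self.conditions) * len(days)
        if len(counts) != expected_cells:
            raise ValueError("incomplete design: a (condition, day) cell is missing")
        if counts.nunique() != 1 or counts.iloc[0] < 1:
            raise ValueError("unbalanced design: replicate counts differ across cells")
        self._days = days
        self._n_replicates = int(counts.iloc[0])

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def days(self) -> np.ndarray:
        return self._days

    @property
    def n_replicates(self) -> int:
        return self._n_replicates

    def subset(self, genes) -> "TimeCourseExperiment":
        return TimeCourseExperiment(
            self.values.loc[list(genes)], self.samples.copy(), self.conditions
        )

    def condition_mean_curves(self) -> "MeanCurves":
        """Arithmetic replicate means per (gene, condition, day)."""
        curves: dict[str, pd.DataFrame] = {}
        for cond in self.conditions:
            cols = self.samples.index[self.samples["condition"] == cond]
            sub = self.values[cols]
            day_of = self.samples.loc[cols, "day"].astype(float)
            means = sub.T.groupby(day_of.values).mean().T
            curves[cond] = means[sorted(means.columns)]
        return MeanCurves(days=self.days.copy(), curves=curves, conditions=self.conditions)

    def replicate_variances(self) -> pd.DataFrame:
        """Per-gene replicate variance (ddof=1) in each (condition, day) cell."""
        if self._n_replicates < 2:
            raise ValueError("replicate variance needs >= 2 replicates per cell")
        pieces = {}
        for (cond, day), cols in self.samples.groupby(["condition", "day"]).groups.items():
            pieces[(cond, float(day))] = self.values[list(cols)].var(axis=1, ddof=1)
        out = pd.DataFrame(pieces)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "day"])
        return out

    # ------------------------------------------------------------------
    def to_tsv(self, out_dir: str | pathlib.Path) -> dict[str, pathlib.Path]:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        expr = out_dir / "expression.tsv"
        sheet = out_dir / "samples.tsv"
        self.values.rename_axis("gene").to_csv(expr, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(sheet, sep="\t")
        return {"expression": expr, "samples": sheet}

    @classmethod
    def from_tsv(
        cls,
        expression: str | pathlib.Path,
        samples: str | pathlib.Path,
        conditions: tuple[str, str] = DEFAULT_CONDITIONS,
    ) -> "TimeCourseExperiment":
        values = pd.read_csv(expression, sep="\t", index_col=0)
        sheet = pd.read_csv(samples, sep="\t", index_col=0)
        return cls(values=values, samples=sheet, conditions=conditions)


@dataclass
class MeanCurves:
    """Condition-mean trajectories and their difference curve.

    ``curves[cond]`` is a genes x days DataFrame; ``difference`` is
    ``curves[conditions[0]] - curves[conditions[1]]`` (log2 fold change
    per day, since inputs are log2).
    """

    days: np.ndarray
    curves: dict[str, pd.DataFrame]
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    _difference: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for cond in self.conditions:
            if cond not in self.curves:
                raise ValueError(f"missing condition {cond!r}")
            if self.curves[cond].shape[1] != len(self.days):
                raise ValueError("curve width does not match day grid")

    @property
    def genes(self) -> pd.Index:
        return self.curves[self.conditions[0]].index

    @property
    def difference(self) -> pd.DataFrame:
        """Per-gene difference curve d(day), first condition minus second."""
        if self._difference is None:
            a, b = self.conditions
            self._difference = self.curves[a] - self.curves[b]
        return self._difference

    def subset(self, genes) -> "MeanCurves":
        genes = list(genes)
        return MeanCurves(
            days=self.days.copy(),
            curves={c: df.loc[genes] for c, df in self.curves.items()},
            conditions=self.conditions,
        )
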