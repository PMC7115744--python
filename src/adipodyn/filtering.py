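"""Expressed-gene detection filter and fold-change trajectory summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MeanCurves, TimeCourseExperiment

__all__ = ["filter_expressed_genes", "condition_mean_curves", "log2fc_trajectory"]


def filter_expressed_genes(
    dabg: pd.DataFrame, alpha: float = 0.05, fraction: float = 0.5
) -> list[str]:
    """Apply the detection-above-background expressed-gene rule.

    A gene is kept iff in at least one sample at least ``fraction`` of its
    exons have detection p strictly below ``alpha`` ("expressed if half of
    its exons were detected above background in at least one sample").

    Parameters
    ----------
    dabg : pandas.DataFrame
        Long table with columns ``gene``, ``exon``, ``sample``, ``p``.

    Returns
    -------
    list of str
        Kept gene ids, sorted.
    """
    if dabg.empty:
        raise ValueError("DABG table is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    required = {"gene", "exon", "sample", "p"}
    if missing := required - set(dabg.columns):
        raise ValueError(f"DABG table lacks columns: {sorted(missing)}")
    p = dabg["p"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("DABG p-values must lie in [0, 1]")

    detected = dabg.assign(hit=p < alpha)
    frac = detected.groupby(["gene", "sample"], sort=False)["hit"].mean()
    kept = frac[frac >= fraction].index.get_level_values("gene").unique()
    return sorted(kept)


def condition_mean_curves(experiment: TimeCourseExperiment) -> MeanCurves:
    """Replicate means per (gene, condition, day) plus the difference curve."""
    return experiment.condition_mean_curves()


def log2fc_trajectory(
    curves: MeanCurves,
    gene_set,
    label: str = "selected",
    magnitude: bool = False,
) -> pd.DataFrame:
    """Average log2 fold change between conditions at each day for a gene set.

    Values are already log2, so the fold change is the per-day difference
    of condition means.  ``magnitude=True`` averages |d| instead of d,
    summarizing divergence strength regardless of direction.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be nonempty")
    missing = set(genes) - set(curves.genes)
    if missing:
        raise ValueError(f"genes not in curves: {sorted(missing)[:5]}")
    d = curves.difference.loc[genes]
    if magnitude:
        d = d.abs()
    return pd.DataFrame(
        {
            "day": curves.days,
            "mean_log2fc": d.mean(axis=0).to_numpy(),
            "gene_set": label,
        }
    )
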