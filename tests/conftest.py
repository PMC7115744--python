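import numpy as np
import pandas as pd
import pytest

from adipodyn import MeanCurves, TimeCourseExperiment

DAYS = (-2.0, 0.0, 2.0, 4.0, 6.0, 8.0)


def make_experiment(curves_by_cond, n_replicates=3, noise_sd=0.0, seed=0, days=DAYS):
    """Build a balanced experiment from per-condition genes x days arrays."""
    rng = np.random.default_rng(seed)
    conds = tuple(curves_by_cond)
    genes = None
    cols, meta, blocks = [], [], []
    for cond in conds:
        mat = np.asarray(curves_by_cond[cond], dtype=float)
        if genes is None:
            genes = [f"g{i}" for i in range(mat.shape[0])]
        for j, day in enumerate(days):
            for rep in range(1, n_replicates + 1):
                sid = f"{cond}_d{day:g}_r{rep}"
                cols.append(sid)
                meta.append({"sample_id": sid, "condition": cond, "day": day,
                             "replicate": rep})
                col = mat[:, j].copy()
                if noise_sd > 0:
                    col = col + rng.normal(0, noise_sd, size=len(col))
                blocks.append(col)
    values = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(genes, name="gene"), columns=cols
    )
    sheet = pd.DataFrame(meta).set_index("sample_id")
    return TimeCourseExperiment(values=values, samples=sheet, conditions=conds)


def make_curves(d_matrix, days=DAYS):
    """MeanCurves whose difference curve equals d_matrix (epi = d, ing = 0)."""
    d = np.atleast_2d(np.asarray(d_matrix, dtype=float))
    genes = pd.Index([f"g{i}" for i in range(d.shape[0])], name="gene")
    days_arr = np.asarray(days, dtype=float)
    epi = pd.DataFrame(d, index=genes, columns=days_arr)
    ing = pd.DataFrame(np.zeros_like(d), index=genes, columns=days_arr)
    return MeanCurves(days=days_arr, curves={"epi": epi, "ing": ing})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
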