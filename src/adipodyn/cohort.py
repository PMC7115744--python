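"""Paired-depot human cohort statistics.

Subjects are classified as lean (BMI below a cutoff, default 30 kg/m²)
or obese, with obese subjects split into subcutaneous-obese and
visceral-obese by the visceral/subcutaneous fat-area ratio at 0.4.
Per-gene and per-depot expression is related to obesity phenotypes via
Spearman rank correlation, between-group Mann-Whitney tests and
age/sex-adjusted ordinary least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "assign_groups",
    "spearman_assoc",
    "mann_whitney_test",
    "adjusted_regression",
    "DepotPhenotypeAssociation",
    "AssociationResults",
    "SpearmanResult",
    "MannWhitneyResult",
]

GROUPS = ("lean", "sc_obese", "vis_obese")


def assign_groups(
    cohort: pd.DataFrame,
    ratio_cutoff: float = 0.4,
    lean_bmi_cutoff: float = 30.0,
) -> pd.Series:
    """Obesity-subtype group per subject.

    lean iff BMI < ``lean_bmi_cutoff``; otherwise sc_obese iff
    vis/sc ratio < ``ratio_cutoff``, else vis_obese (a ratio exactly at
    the cutoff counts as visceral).
    """
    for col in ("BMI", "vis_sc_ratio"):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks column {col!r}")
    ratio = cohort["vis_sc_ratio"].to_numpy(dtype=float)
    if np.any(ratio < 0):
        raise ValueError("vis_sc_ratio must be nonnegative")
    bmi = cohort["BMI"].to_numpy(dtype=float)
    out = np.where(
        bmi < lean_bmi_cutoff, "lean", np.where(ratio < ratio_cutoff, "sc_obese",
                                                "vis_obese")
    )
    return pd.Series(out, index=cohort.index, name="group")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    degenerate: bool = False


def spearman_assoc(expression, phenotype) -> SpearmanResult:
    """Average-rank Spearman correlation on pairwise-complete observations.

    p-value from the t approximation with n − 2 degrees of freedom.  A
    zero-variance input yields a flagged (degenerate) NaN result.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), n)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n_a: int
    n_b: int
    method: str
    all_ties: bool = False


def mann_whitney_test(group_a, group_b, exact_max_n: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration of rank assignments) when the
    combined sample size is at most ``exact_max_n`` and there are no
    ties, and a tie-corrected normal approximation with continuity
    correction otherwise.  If every value in both groups is identical,
    U = n_a·n_b/2 and p = 1 (flagged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(n_a * n_b / 2.0, 1.0, n_a, n_b, "degenerate",
                                 all_ties=True)
    has_ties = len(np.unique(pooled)) < pooled.size
    if n_a + n_b <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), n_a, n_b, method)


def adjusted_regression(
    expression, phenotype, age, sex, phenotype_name: str = "phenotype"
) -> pd.DataFrame:
    """OLS of expression on phenotype adjusted for age and sex.

    Sex is encoded female = 0, male = 1.  Returns one row per term
    (const, phenotype, age, sex) with beta, se and two-sided p.  A
    collinear design raises an error naming the collinear columns.
    """
    y = np.asarray(expression, dtype=float)
    sex_arr = pd.Series(sex)
    if sex_arr.dtype == object:
        mapping = {"female": 0.0, "male": 1.0}
        bad = set(sex_arr.dropna()) - set(mapping)
        if bad:
            raise ValueError(f"unrecognized sex labels: {sorted(bad)}")
        sex_num = sex_arr.map(mapping).to_numpy(dtype=float)
    else:
        sex_num = sex_arr.to_numpy(dtype=float)
    design = pd.DataFrame(
        {
            phenotype_name: np.asarray(phenotype, dtype=float),
            "age": np.asarray(age, dtype=float),
            "sex": sex_num,
        }
    )
    mask = np.isfinite(y) & np.isfinite(design.to_numpy()).all(axis=1)
    y, design = y[mask], design.loc[mask]
    if len(y) <= design.shape[1] + 1:
        raise ValueError("need more observations than covariates")
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        involved = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"collinear design; involved columns: {involved}")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).rename_axis("term")


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class DepotPhenotypeAssociation:
    """Model relating paired sc/vis expression to obesity phenotypes.

    Parameters
    ----------
    cohort : pandas.DataFrame
        One row per subject with columns ``age``, ``sex``, ``BMI``,
        ``WHR``, ``vis_sc_ratio`` and per-gene expression columns named
        ``<GENE>_sc`` / ``<GENE>_vis``.
    genes : list of str, optional
        Genes to analyze; inferred from the expression columns when
        omitted.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        genes: list[str] | None = None,
        depots: tuple[str, str] = ("sc", "vis"),
        phenotypes: tuple[str, ...] = ("BMI", "WHR"),
    ) -> None:
        self.cohort = cohort
        self.depots = depots
        self.phenotypes = phenotypes
        if genes is None:
            genes = sorted(
                {
                    c.rsplit("_", 1)[0]
                    for c in cohort.columns
                    if c.rsplit("_", 1)[-1] in depots
                }
            )
        for g in genes:
            for depot in depots:
                if f"{g}_{depot}" not in cohort.columns:
                    raise ValueError(f"cohort lacks expression column {g}_{depot}")
        self.genes = list(genes)

    def fit(
        self, ratio_cutoff: float = 0.4, lean_bmi_cutoff: float = 30.0
    ) -> "AssociationResults":
        cohort = self.cohort
        groups = assign_groups(cohort, ratio_cutoff, lean_bmi_cutoff)

        corr_rows, reg_rows, group_rows = [], [], []
        for gene, depot in itertools.product(self.genes, self.depots):
            expr = cohort[f"{gene}_{depot}"]
            for pheno in self.phenotypes:
                res = spearman_assoc(expr, cohort[pheno])
                corr_rows.append(
                    {
                        "gene": gene,
                        "depot": depot,
                        "phenotype": pheno,
                        "n": res.n,
                        "rho": res.rho,
                        "p": res.p,
                        "degenerate": res.degenerate,
                    }
                )
                try:
                    reg = adjusted_regression(
                        expr, cohort[pheno], cohort["age"], cohort["sex"],
                        phenotype_name=pheno,
                    )
                    reg_rows.append(
                        {
                            "gene": gene,
                            "depot": depot,
                            "phenotype": pheno,
                            "beta": reg.loc[pheno, "beta"],
                            "se": reg.loc[pheno, "se"],
                            "p": reg.loc[pheno, "p"],
                        }
                    )
                except ValueError:
                    reg_rows.append(
                        {"gene": gene, "depot": depot, "phenotype": pheno,
                         "beta": np.nan, "se": np.nan, "p": np.nan}
                    )
            for ga, gb in itertools.combinations(GROUPS, 2):
                va = expr[groups == ga].dropna()
                vb = expr[groups == gb].dropna()
                if va.empty or vb.empty:
                    continue
                mw = mann_whitney_test(va, vb)
                group_rows.append(
                    {
                        "gene": gene,
                        "depot": depot,
                        "group_a": ga,
                        "group_b": gb,
                        "n_a": mw.n_a,
                        "n_b": mw.n_b,
                        "U": mw.u,
                        "p": mw.p,
                        "method": mw.method,
                    }
                )
        return AssociationResults(
            model=self,
            groups=groups,
            correlations=pd.DataFrame(corr_rows),
            regressions=pd.DataFrame(reg_rows),
            group_tests=pd.DataFrame(group_rows),
            ratio_cutoff=ratio_cutoff,
            lean_bmi_cutoff=lean_bmi_cutoff,
        )


@dataclass
class AssociationResults:
    """Cohort association estimates: correlations, group tests, regressions."""

    model: DepotPhenotypeAssociation
    groups: pd.Series
    correlations: pd.DataFrame
    regressions: pd.DataFrame
    group_tests: pd.DataFrame
    ratio_cutoff: float
    lean_bmi_cutoff: float

    def summary(self, alpha: float = 0.05) -> str:
        counts = self.groups.value_counts()
        sig = self.correlations[self.correlations["p"] < alpha]
        lines = [
            "Depot-phenotype association",
            "===========================",
            f"subjects: {len(self.groups)} "
            f"(lean {counts.get('lean', 0)}, sc obese {counts.get('sc_obese', 0)}, "
            f"vis obese {counts.get('vis_obese', 0)})",
            f"genes: {len(self.model.genes)}",
            f"Spearman correlations with p < {alpha}: {len(sig)}",
        ]
        if not sig.empty:
            lines.append("")
            lines.append(
                sig.sort_values("p")[["gene", "depot", "phenotype", "n", "rho", "p"]]
                .head(12)
                .to_string(index=False)
            )
        return "\n".join(lines)
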