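"""Mass-univariate regional GLMs of coupling on demographics and cognition.

Each region's coupling value (Fisher r-to-z transformed) is regressed on
six main effects — age, sex, years of education, total cognition score,
intracranial volume (ICV) and in-scanner head motion — plus four
interaction terms (age x cognition, sex x cognition, education x
cognition, ICV x motion): ten covariates and an intercept.  Coefficient
p-values are two-sided t-tests; multiplicity across regions is
controlled per covariate with Benjamini-Hochberg FDR at alpha = 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import FormatError, PhenotypeTable, validate_cohort

MAIN_EFFECTS = ("age", "sex", "education", "cognition", "icv", "motion")
INTERACTIONS = (
    ("age", "cognition"),
    ("sex", "cognition"),
    ("education", "cognition"),
    ("icv", "motion"),
)


def build_design(cohort: pd.DataFrame, center: bool = False) -> pd.DataFrame:
    """Build the 10-covariate design matrix (plus intercept) from a cohort table.

    Sex is coded female=0, male=1.  Interaction columns are elementwise
    products of the main-effect columns, uncentered by default (set
    ``center=True`` to center main effects before forming products).
    The returned frame is indexed by subject_id with an ``intercept``
    column first; a rank-deficient design raises, naming the collinear
    columns.
    """
    cohort = validate_cohort(cohort, required=MAIN_EFFECTS)
    x = pd.DataFrame(index=pd.Index(cohort["subject_id"], name="subject_id"))
    x["intercept"] = 1.0
    for col in MAIN_EFFECTS:
        v = cohort[col].to_numpy()
        if col == "sex":
            v = (cohort["sex"] == "male").to_numpy(dtype=float)
        x[col] = np.asarray(v, dtype=float)
    main = {c: x[c].to_numpy() for c in MAIN_EFFECTS}
    if center:
        main = {c: v - v.mean() for c, v in main.items()}
    for a, b in INTERACTIONS:
        x[f"{a}_x_{b}"] = main[a] * main[b]
    _check_rank(x)
    return x


def _check_rank(x: pd.DataFrame) -> None:
    m = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(m)
    if rank < min(m.shape):
        # identify columns whose removal restores full rank
        collinear = []
        for j, col in enumerate(x.columns):
            reduced = np.delete(m, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(col)
        raise FormatError(f"design matrix is rank-deficient; collinear: {collinear}")


def bh_fdr(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: returns (q-values, reject flags)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


class RegionalGLM(BaseEstimator):
    """Per-region ordinary least squares of Fisher-z coupling on covariates.

    A Gaussian GLM with identity link, fitted independently for each
    region.  Coupling values are atanh-transformed before the fit; regions
    with undefined (NaN) values use listwise deletion with the degrees of
    freedom adjusted.  FDR correction is applied across regions,
    separately for each covariate.

    Parameters
    ----------
    alpha : float
        FDR level for the significance calls.
    fisher_transform : bool
        Apply atanh to the phenotype before regression (set False when the
        phenotype is not a correlation).

    Attributes
    ----------
    coef_ : (n_regions, n_terms) array of coefficients.
    t_, p_, q_ : matching arrays of t-statistics, two-sided p, BH q.
    significant_ : boolean array, q <= alpha.
    results_ : tidy DataFrame (region, term, beta, t, p, q, significant).
    term_names_ : list of design column names.
    """

    def __init__(self, alpha: float = 0.05, fisher_transform: bool = True):
        self.alpha = alpha
        self.fisher_transform = fisher_transform

    def fit(self, X: pd.DataFrame, Y):
        """Fit one OLS per region.

        X is the design matrix from :func:`build_design` (subjects x terms,
        intercept included); Y is a subjects x regions array or DataFrame of
        coupling values aligned to X's rows.
        """
        Xv = np.asarray(X, dtype=float)
        terms = list(X.columns) if hasattr(X, "columns") else [
            f"x{j}" for j in range(Xv.shape[1])
        ]
        region_names = list(Y.columns) if hasattr(Y, "columns") else [
            f"region_{k}" for k in range(np.asarray(Y).shape[1])
        ]
        Yv = np.asarray(Y, dtype=float)
        if Yv.shape[0] != Xv.shape[0]:
            raise ValueError("X and Y have different numbers of subjects")
        n, p = Xv.shape
        if n <= p:
            raise ValueError(f"need more subjects ({n}) than design columns ({p})")
        n_regions = Yv.shape[1]
        coef = np.full((n_regions, p), np.nan)
        tval = np.full((n_regions, p), np.nan)
        pval = np.full((n_regions, p), np.nan)
        n_dropped = 0
        # regions sharing a missingness pattern are solved in one batched OLS
        masks = ~np.isnan(Yv)
        for pattern in np.unique(masks, axis=1).T:
            cols = np.flatnonzero((masks == pattern[:, None]).all(axis=0))
            nk = int(pattern.sum())
            if nk <= p:
                n_dropped += len(cols)
                continue
            Xk = Xv[pattern]
            Yk = Yv[np.ix_(pattern, cols)]
            if self.fisher_transform:
                Yk = np.arctanh(Yk)
            xtx_inv = np.linalg.inv(Xk.T @ Xk)
            betas = xtx_inv @ Xk.T @ Yk  # (p, m)
            resid = Yk - Xk @ betas
            dof = nk - p
            sigma2 = (resid**2).sum(axis=0) / dof
            se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
            with np.errstate(divide="ignore", invalid="ignore"):
                tk = betas / se
            pk = 2.0 * t_dist.sf(np.abs(tk), dof)
            coef[cols] = betas.T
            tval[cols] = tk.T
            pval[cols] = pk.T
        if n_dropped:
            warnings.warn(
                f"{n_dropped} region(s) had too few defined values and were skipped",
                stacklevel=2,
            )
        qval = np.full_like(pval, np.nan)
        sig = np.zeros(pval.shape, dtype=bool)
        for j in range(p):
            ok = ~np.isnan(pval[:, j])
            if ok.any():
                qval[ok, j], sig[ok, j] = bh_fdr(pval[ok, j], alpha=self.alpha)
        self.term_names_ = terms
        self.region_names_ = region_names
        self.coef_ = coef
        self.t_ = tval
        self.p_ = pval
        self.q_ = qval
        self.significant_ = sig
        self.df_resid_ = n - p
        rows = []
        for k, region in enumerate(region_names):
            for j, term in enumerate(terms):
                rows.append(
                    {
                        "region": region,
                        "term": term,
                        "beta": coef[k, j],
                        "t": tval[k, j],
                        "p": pval[k, j],
                        "q": qval[k, j],
                        "significant": bool(sig[k, j]),
                    }
                )
        self.results_ = pd.DataFrame(rows)
        return self


def fit_regional_glm(
    coupling: PhenotypeTable,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fisher_transform: bool = True,
) -> pd.DataFrame:
    """Fit the regional GLM and return the tidy result table.

    ``coupling`` must hold one measurement per subject (the four FC scans
    are averaged upstream); rows are aligned to the design by subject_id.
    """
    t = coupling.table
    counts = coupling.measurement_counts()
    if (counts != 1).any():
        raise ValueError("regional GLM expects one measurement per subject")
    aligned = t.set_index("subject_id").loc[design.index]
    Y = aligned[coupling.region_columns]
    model = RegionalGLM(alpha=alpha, fisher_transform=fisher_transform)
    model.fit(design, Y)
    return model.results_
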