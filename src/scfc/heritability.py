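"""Repeated-measures ACE + measurement-error variance components by ReML.

The phenotype of subject i at repeated measurement j is modelled as

    y_ij = x_ij' beta + g_i + c_i + e_i + eps_ij

with g ~ N(0, sigma2_A K) the additive genetic effect (K the pedigree
kinship kernel: 1 for MZ co-twins, 1/2 for DZ co-twins and full
siblings, 0 for unrelated pairs, 1 on the diagonal), c ~ N(0, sigma2_C
Lambda) the shared-environment effect (Lambda_ij = 1 iff i and j share
parents), e ~ N(0, sigma2_E I) the subject-specific stable environment
and eps ~ N(0, sigma2_M I) transient measurement error, independent
across repeated measurements.  Stacking measurements with the 0/1
expansion matrix T (n_total x n_subjects),

    cov[y] = sigma2_A T K T' + sigma2_C T Lambda T'
             + sigma2_E T T' + sigma2_M I.

The four variances are estimated by restricted maximum likelihood with
the fixed effects profiled out by generalized least squares.  The
"non-transient" heritability

    h2 = sigma2_A / (sigma2_A + sigma2_C + sigma2_E)

is the genetic fraction of *stable* inter-subject variance: measurement
error, being estimated separately from the repeated measures, no longer
deflates it.

Implementation notes: the covariance is block-diagonal over families, so
the restricted likelihood factorizes; families with identical
(relationship pattern, measurement counts) share one Cholesky factor and
are solved in a single batched call, which keeps a 941-subject fit fast.
Variances are optimized on the log scale with a bounded quasi-Newton
search from three starts plus a simplex polish; a variance pinned at the
lower bound is reported as a boundary zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .datatypes import Pedigree, PhenotypeTable

COMPONENT_NAMES = ("A", "C", "E", "M")


# ---------------------------------------------------------------------------
# Pedigree-derived matrices


def kinship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Expected additive-genetic similarity K from the pedigree.

    Entries: 1 on the diagonal and for MZ co-twins, 1/2 for any two
    distinct members of the same family (DZ co-twins and full siblings),
    0 across families.
    """
    t = pedigree.table
    n = len(t)
    fam = t["family_id"].to_numpy()
    rel = t["relationship"].to_numpy()
    pair = t["twin_pair_id"].to_numpy()
    same_family = fam[:, None] == fam[None, :]
    k = np.where(same_family, 0.5, 0.0)
    is_mz = rel == "MZ_twin"
    same_pair = (pair[:, None] == pair[None, :]) & (pair[:, None] != "")
    k[same_pair & is_mz[:, None] & is_mz[None, :]] = 1.0
    np.fill_diagonal(k, 1.0)
    return k


def shared_env_matrix(pedigree: Pedigree) -> np.ndarray:
    """Shared-environment indicator Lambda: 1 iff two subjects share parents."""
    fam = pedigree.table["family_id"].to_numpy()
    lam = (fam[:, None] == fam[None, :]).astype(float)
    return lam


def expansion_matrix(
    phenotypes: PhenotypeTable, subject_order: np.ndarray | None = None
) -> np.ndarray:
    """0/1 incidence T (n_total x n_subjects) mapping measurements to subjects.

    Row order follows the phenotype table; column order follows
    ``subject_order`` (defaults to first appearance in the table).
    """
    subs = phenotypes.table["subject_id"].to_numpy()
    if subject_order is None:
        subject_order = phenotypes.subjects
    index = {s: i for i, s in enumerate(subject_order)}
    missing = set(subs) - set(index)
    if missing:
        raise ValueError(f"subjects not in subject_order: {sorted(missing)[:5]}")
    t = np.zeros((len(subs), len(subject_order)))
    for row, s in enumerate(subs):
        t[row, index[s]] = 1.0
    return t


# ---------------------------------------------------------------------------
# Block structure


@dataclass
class _BlockGroup:
    """Families sharing one covariance pattern, batch-solvable together."""

    comps: tuple[np.ndarray, ...]  # four k x k component matrices (A, C, E, M)
    row_idx: np.ndarray  # (g, k) stacked-row indices per family
    k: int
    g: int


def _family_blocks(K: np.ndarray, L: np.ndarray, T: np.ndarray) -> list[_BlockGroup]:
    """Group families by identical (K, Lambda, measurement-count) pattern."""
    n_subj = K.shape[0]
    # connected components of the relatedness graph = families
    adj = (K + L) > 0
    labels = -np.ones(n_subj, dtype=int)
    current = 0
    for i in range(n_subj):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if labels[v] < 0:
                    labels[v] = current
                    stack.append(v)
        current += 1
    subj_rows = [np.flatnonzero(T[:, s]) for s in range(n_subj)]
    groups: dict[bytes, list[tuple[np.ndarray, np.ndarray]]] = {}
    keys: dict[bytes, tuple] = {}
    for f in range(current):
        subjects = np.flatnonzero(labels == f)
        m = np.array([len(subj_rows[s]) for s in subjects])
        order = np.lexsort((subjects, -m))  # canonical order within family
        subjects = subjects[order]
        rows = np.concatenate([subj_rows[s] for s in subjects])
        Kf = K[np.ix_(subjects, subjects)]
        Lf = L[np.ix_(subjects, subjects)]
        mf = m[order]
        key = (
            mf.tobytes()
            + np.round(Kf, 9).tobytes()
            + np.round(Lf, 9).tobytes()
        )
        groups.setdefault(key, []).append(rows)
        keys[key] = (subjects, Kf, Lf, mf)
    out = []
    for key, row_lists in groups.items():
        subjects, Kf, Lf, mf = keys[key]
        k = int(mf.sum())
        Tf = np.zeros((k, len(subjects)))
        pos = 0
        for j, mi in enumerate(mf):
            Tf[pos : pos + mi, j] = 1.0
            pos += mi
        comps = (
            Tf @ Kf @ Tf.T,
            Tf @ Lf @ Tf.T,
            Tf @ Tf.T,
            np.eye(k),
        )
        row_idx = np.stack(row_lists)
        out.append(_BlockGroup(comps=comps, row_idx=row_idx, k=k, g=len(row_lists)))
    return out


class _RemlProblem:
    """Restricted log-likelihood of the four-component model, block-factorized."""

    def __init__(self, y, X, blocks: list[_BlockGroup]):
        self.p = X.shape[1]
        self.blocks = blocks
        # pre-gather y and X per group
        self.ydata = [y[b.row_idx] for b in blocks]  # (g, k)
        self.xdata = [X[b.row_idx] for b in blocks]  # (g, k, p)

    def loglik_and_beta(self, sigma2: np.ndarray):
        """Restricted log-likelihood (up to an additive constant) and GLS beta."""
        p = self.p
        logdet_v = 0.0
        ytviy = 0.0
        xtvix = np.zeros((p, p))
        xtviy = np.zeros(p)
        for b, Yg, Xg in zip(self.blocks, self.ydata, self.xdata):
            V = sum(s * c for s, c in zip(sigma2, b.comps))
            try:
                Lc = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf, None
            logdet_v += b.g * 2.0 * np.log(np.diag(Lc)).sum()
            wy = solve_triangular(Lc, Yg.T, lower=True)  # (k, g)
            ytviy += float((wy**2).sum())
            xr = Xg.transpose(1, 0, 2).reshape(b.k, b.g * p)
            wx = solve_triangular(Lc, xr, lower=True).reshape(b.k, b.g, p)
            xtvix += np.einsum("kgp,kgq->pq", wx, wx)
            xtviy += np.einsum("kgp,kg->p", wx, wy)
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return -np.inf, None
        try:
            cf = cho_factor(xtvix)
        except np.linalg.LinAlgError:
            return -np.inf, None
        beta = cho_solve(cf, xtviy)
        quad = ytviy - float(xtviy @ beta)
        ll = -0.5 * (logdet_v + logdet_x + quad)
        return ll, beta

    def loglik(self, sigma2: np.ndarray) -> float:
        return self.loglik_and_beta(sigma2)[0]


# ---------------------------------------------------------------------------
# Result container and estimator


@dataclass
class VarianceComponents:
    """Fitted variance components, heritability and diagnostics for one trait."""

    sigma2_A: float
    sigma2_C: float
    sigma2_E: float
    sigma2_M: float
    beta_hat: np.ndarray
    h2: float
    reml_loglik: float
    converged: bool
    boundary_flags: tuple[str, ...] = ()
    identifiability_flags: tuple[str, ...] = ()

    @property
    def total_variance(self) -> float:
        return self.sigma2_A + self.sigma2_C + self.sigma2_E + self.sigma2_M

    def variance_fractions(self) -> dict[str, float]:
        tot = self.total_variance
        vals = (self.sigma2_A, self.sigma2_C, self.sigma2_E, self.sigma2_M)
        if tot == 0:
            return {n: np.nan for n in COMPONENT_NAMES}
        return dict(zip(COMPONENT_NAMES, (v / tot for v in vals)))


def heritability(vc: VarianceComponents) -> float:
    """Non-transient heritability sigma2_A / (sigma2_A + sigma2_C + sigma2_E)."""
    denom = vc.sigma2_A + vc.sigma2_C + vc.sigma2_E
    if denom <= 0:
        return np.nan
    return vc.sigma2_A / denom


class ACEModel(BaseEstimator):
    """ACE + measurement-error mixed model fitted by ReML.

    Parameters
    ----------
    kinship, shared_env : (n_subjects, n_subjects) arrays
        Pedigree kernels K and Lambda (see :func:`kinship_matrix`,
        :func:`shared_env_matrix`).
    expansion : (n_total, n_subjects) 0/1 array or None
        Measurement-to-subject incidence T; identity when None (one
        measurement per subject).
    fit_measurement_error : {"auto", True, False}
        Whether to estimate sigma2_M.  "auto" drops it (with a warning)
        when every subject has a single measurement, where it is not
        separable from sigma2_E.
    tol : float
        Convergence tolerance on the restricted log-likelihood.
    n_starts : int
        Number of optimizer starts (equal-split, measurement-dominant,
        genetic-dominant).

    Attributes (after ``fit``)
    --------------------------
    sigma2_a_, sigma2_c_, sigma2_e_, sigma2_m_ : variance estimates (>= 0).
    beta_ : GLS fixed-effect estimates.
    h2_ : non-transient heritability (NaN when undefined).
    reml_loglik_ : restricted log-likelihood at the estimate (constant terms
        dropped).
    converged_ : bool.
    boundary_flags_, identifiability_flags_ : tuples of flag strings.
    """

    def __init__(
        self,
        kinship=None,
        shared_env=None,
        expansion=None,
        fit_measurement_error="auto",
        tol: float = 1e-8,
        n_starts: int = 3,
    ):
        self.kinship = kinship
        self.shared_env = shared_env
        self.expansion = expansion
        self.fit_measurement_error = fit_measurement_error
        self.tol = tol
        self.n_starts = n_starts

    # -- internals ---------------------------------------------------------

    def _structure(self):
        K = np.asarray(self.kinship, dtype=float)
        L = np.asarray(self.shared_env, dtype=float)
        if K.shape != L.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship and shared_env must be equal square matrices")
        T = (
            np.eye(K.shape[0])
            if self.expansion is None
            else np.asarray(self.expansion, dtype=float)
        )
        if T.shape[1] != K.shape[0]:
            raise ValueError("expansion matrix column count != number of subjects")
        key = (K.tobytes(), L.tobytes(), T.tobytes())
        cached = getattr(self, "_blocks_cache", None)
        if cached is None or cached[0] != key:
            blocks = _family_blocks(K, L, T)
            self._blocks_cache = (key, blocks, K, L, T)
        return self._blocks_cache[1:]

    def _identifiability(self, K, L, T):
        flags = []
        m = T.sum(axis=0)
        offdiag = K[~np.eye(K.shape[0], dtype=bool)]
        kin_levels = np.unique(np.round(offdiag[offdiag > 0], 9))
        if kin_levels.size == 0:
            flags.append("ace_inseparable")
        elif kin_levels.size < 2:
            flags.append("a_c_inseparable")
        drop_m = False
        if self.fit_measurement_error == "auto":
            if m.max(initial=0) <= 1:
                drop_m = True
                warnings.warn(
                    "single measurement per subject: sigma2_M is not separable "
                    "from sigma2_E and is dropped from the model",
                    stacklevel=3,
                )
        elif not self.fit_measurement_error:
            drop_m = True
        elif m.max(initial=0) <= 1:
            raise ValueError(
                "sigma2_M requested but every subject has one measurement"
            )
        return tuple(flags), drop_m

    def fit(self, X, y):
        """Fit by ReML.  X: (n_total, p) fixed-effect design; y: (n_total,)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_total, p) aligned with y")
        blocks, K, L, T = self._structure()
        if T.shape[0] != y.size:
            raise ValueError("expansion matrix row count != len(y)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank-deficient")
        id_flags, drop_m = self._identifiability(K, L, T)
        active = [0, 1, 2] if drop_m else [0, 1, 2, 3]
        if y.size <= X.shape[1] + len(active):
            raise ValueError("too few observations for the requested model")

        if np.ptp(y) == 0:  # constant phenotype: nothing to decompose
            self._set_result(
                np.zeros(4),
                np.linalg.lstsq(X, y, rcond=None)[0],
                np.nan,
                True,
                ("degenerate_constant_phenotype",),
                id_flags,
            )
            return self

        problem = _RemlProblem(y, X, blocks)
        vy = float(y.var(ddof=1))
        lo, hi = np.log(vy) - 22.0, np.log(vy) + 5.0

        def neg(params):
            sig = np.zeros(4)
            sig[active] = np.exp(params)
            ll = problem.loglik(sig)
            return 1e12 if not np.isfinite(ll) else -ll

        starts = self._starts(vy, active)[: self.n_starts]
        best = None
        for s0 in starts:
            res = minimize(
                neg,
                np.log(np.maximum(s0, np.exp(lo))),
                method="L-BFGS-B",
                bounds=[(lo, hi)] * len(active),
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        polish = minimize(
            neg,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": self.tol * 1e-2, "maxiter": 4000},
        )
        if polish.fun <= best.fun:
            best = polish
        sigma2 = np.zeros(4)
        sigma2[active] = np.exp(np.clip(best.x, lo, hi))
        ll, beta = problem.loglik_and_beta(sigma2)
        boundary = tuple(
            COMPONENT_NAMES[i]
            for i in active
            if sigma2[i] < max(vy * 1e-6, np.exp(lo) * 2)
        )
        sigma2[[COMPONENT_NAMES.index(b) for b in boundary]] = 0.0
        if drop_m and self.fit_measurement_error == "auto":
            id_flags = id_flags + ("measurement_error_dropped",)
        self._set_result(sigma2, beta, ll, bool(best.success or polish.success),
                         tuple(f"boundary_{b}" for b in boundary), id_flags)
        return self

    def _starts(self, vy, active):
        k = len(active)
        eq = np.full(k, vy / k)
        meas = np.full(k, 0.1 * vy)
        meas[-1] = 0.7 * vy  # last active component (M if present, else E)
        gen = np.full(k, 0.1 * vy)
        gen[0] = 0.7 * vy
        return [eq, meas, gen]

    def _set_result(self, sigma2, beta, ll, converged, boundary, id_flags):
        self.sigma2_a_, self.sigma2_c_, self.sigma2_e_, self.sigma2_m_ = map(
            float, sigma2
        )
        self.beta_ = np.asarray(beta, dtype=float)
        denom = self.sigma2_a_ + self.sigma2_c_ + self.sigma2_e_
        self.h2_ = self.sigma2_a_ / denom if denom > 0 else np.nan
        self.reml_loglik_ = float(ll) if ll is not None else np.nan
        self.converged_ = converged
        self.boundary_flags_ = boundary
        self.identifiability_flags_ = id_flags
        return self

    def variance_components_(self) -> VarianceComponents:
        """Package the fitted attributes as a :class:`VarianceComponents`."""
        return VarianceComponents(
            sigma2_A=self.sigma2_a_,
            sigma2_C=self.sigma2_c_,
            sigma2_E=self.sigma2_e_,
            sigma2_M=self.sigma2_m_,
            beta_hat=self.beta_,
            h2=self.h2_,
            reml_loglik=self.reml_loglik_,
            converged=self.converged_,
            boundary_flags=self.boundary_flags_,
            identifiability_flags=self.identifiability_flags_,
        )


def reml_fit(y, X, K, L, T=None, **kwargs) -> VarianceComponents:
    """Functional wrapper around :class:`ACEModel`."""
    model = ACEModel(kinship=K, shared_env=L, expansion=T, **kwargs)
    model.fit(X, y)
    return model.variance_components_()


# ---------------------------------------------------------------------------
# Region-wise driver


def _stacked_design(
    phenotypes: PhenotypeTable,
    cohort: pd.DataFrame,
    pedigree: Pedigree,
    covariates: tuple[str, ...],
):
    """Row order, T, and the subject-level part of the fixed-effect design."""
    order = pedigree.subject_ids
    t = phenotypes.table
    missing = set(t["subject_id"]) - set(order)
    if missing:
        raise ValueError(f"phenotype subjects missing from pedigree: {sorted(missing)[:5]}")
    pos = {s: i for i, s in enumerate(order)}
    t = t.sort_values(
        by=["subject_id", "measurement_index"],
        key=lambda col: col.map(pos) if col.name == "subject_id" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    pt = PhenotypeTable(t)
    T = expansion_matrix(pt, subject_order=order)
    cov = cohort.set_index("subject_id")
    for c in covariates:
        if c not in cov.columns:
            raise ValueError(f"covariate {c!r} not in cohort table")
        if cov[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
    sub_ids = t["subject_id"]
    cols = [np.ones(len(t))]
    names = ["intercept"]
    for c in covariates:
        v = cov[c].reindex(sub_ids)
        if v.isna().any():
            raise ValueError(f"cohort table lacks rows for some phenotype subjects")
        if c == "sex":
            v = (v == "male").astype(float)
        cols.append(v.to_numpy(dtype=float))
        names.append(c)
    return pt, T, np.column_stack(cols), names


def _broadcast_extra(extra: PhenotypeTable, target: PhenotypeTable) -> pd.DataFrame:
    """Align an extra per-region covariate table to the target's rows.

    A single-measurement table is broadcast across the target's repeated
    measurements; otherwise (subject, measurement) must match exactly.
    """
    tt = target.table[["subject_id", "measurement_index"]]
    et = extra.table
    counts = extra.measurement_counts()
    if (counts == 1).all():
        merged = tt.merge(
            et.drop(columns="measurement_index"), on="subject_id", how="left"
        )
    else:
        merged = tt.merge(et, on=["subject_id", "measurement_index"], how="left")
    return merged


def regional_heritability(
    phenotypes: PhenotypeTable,
    cohort: pd.DataFrame,
    pedigree: Pedigree,
    covariates: tuple[str, ...] = ("age", "sex", "handedness"),
    extra_covariates: dict[str, PhenotypeTable] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Fit the ACE+M model per region and tabulate variance components.

    ``covariates`` names cohort columns used as fixed effects; for the
    coupling model, ``extra_covariates`` supplies per-region SC and FC
    node-strength tables that enter as additional region-specific fixed
    effects (a single-measurement table, e.g. SC strength, is broadcast
    across the phenotype's repeated measurements).  Each region's
    phenotype is z-scored across all stacked measurements before the fit
    (``standardize=False`` disables this).  Regions with any undefined
    phenotype value are skipped with a warning.
    """
    pt, T, Xbase, names = _stacked_design(phenotypes, cohort, pedigree, covariates)
    K = kinship_matrix(pedigree)
    L = shared_env_matrix(pedigree)
    extras = {}
    if extra_covariates:
        for name, table in extra_covariates.items():
            extras[name] = _broadcast_extra(table, pt)
    model = ACEModel(kinship=K, shared_env=L, expansion=T)
    rows = []
    skipped = []
    for region in pt.region_columns:
        y = pt.table[region].to_numpy(dtype=float)
        xcols = [Xbase]
        ok = True
        for name, merged in extras.items():
            if region not in merged.columns:
                raise ValueError(f"extra covariate {name!r} lacks region {region!r}")
            v = merged[region].to_numpy(dtype=float)
            if np.isnan(v).any():
                ok = False
            xcols.append(v[:, None])
        if np.isnan(y).any() or not ok:
            skipped.append(region)
            continue
        if standardize:
            sd = y.std(ddof=1)
            y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        X = np.hstack(xcols)
        model.fit(X, y)
        vc = model.variance_components_()
        frac = vc.variance_fractions()
        rows.append(
            {
                "region": region,
                "sigma2_A": vc.sigma2_A,
                "sigma2_C": vc.sigma2_C,
                "sigma2_E": vc.sigma2_E,
                "sigma2_M": vc.sigma2_M,
                "h2": vc.h2,
                "frac_A": frac["A"],
                "frac_C": frac["C"],
                "frac_E": frac["E"],
                "frac_M": frac["M"],
                "reml_loglik": vc.reml_loglik,
                "converged": vc.converged,
                "flags": ";".join(vc.boundary_flags + vc.identifiability_flags),
            }
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} region(s) with undefined phenotype values: "
            f"{skipped[:5]}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
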