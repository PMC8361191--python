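"""Network-level summaries, pairwise contrasts and permutation inference.

Regional values (coupling, heritability, ...) are grouped by the nine
networks; distributions are summarized by median and quartiles (midpoint
interpolation) and contrasted pairwise with unpaired pooled-variance
t-statistics (row network minus column network, so the matrix is
antisymmetric).

Significance uses a one-sided permutation null: region-to-network labels
are shuffled and p = (1 + #{null >= observed}) / (1 + n_perm), which is
never zero and is uniform under the null.  Label permutation ignores
spatial autocorrelation of brain maps and is therefore anti-conservative
on real data; spatially matched surrogate maps (e.g. variogram-matched
nulls) can be supplied through the ``surrogates`` argument, in which
case the null distribution is computed from them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import bh_fdr
from .datatypes import Parcellation


@dataclass(frozen=True)
class NetworkSummary:
    """Per-network distribution summaries of one regional map."""

    table: pd.DataFrame  # network, n_regions, n_undefined, median, q1, q3, mean, sd

    @property
    def networks(self) -> list[str]:
        return self.table["network"].tolist()


@dataclass(frozen=True)
class PairwiseContrast:
    """Pairwise network t-statistics with optional permutation p and FDR q."""

    networks: list[str]
    t: np.ndarray  # antisymmetric, NaN diagonal
    p_one_sided: np.ndarray | None = None
    q: np.ndarray | None = None


def _grouped(values: np.ndarray, parcellation: Parcellation):
    values = np.asarray(values, dtype=float)
    if values.shape[0] != parcellation.n_regions:
        raise ValueError("values length does not match parcellation")
    nets = parcellation.networks
    names = parcellation.network_names()
    groups = {}
    for name in names:
        v = values[nets == name]
        groups[name] = v[~np.isnan(v)], int(np.isnan(v).sum())
    return names, groups


def network_summary(values, parcellation: Parcellation) -> NetworkSummary:
    """Median/quartile/mean/sd of a regional map within each network."""
    names, groups = _grouped(values, parcellation)
    rows = []
    for name in names:
        v, n_undef = groups[name]
        row = {"network": name, "n_regions": v.size + n_undef, "n_undefined": n_undef}
        if v.size == 0:
            row.update(median=np.nan, q1=np.nan, q3=np.nan, mean=np.nan, sd=np.nan)
            row["empty"] = True
        else:
            row.update(
                median=float(np.quantile(v, 0.5, method="midpoint")),
                q1=float(np.quantile(v, 0.25, method="midpoint")),
                q3=float(np.quantile(v, 0.75, method="midpoint")),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                empty=False,
            )
        rows.append(row)
    return NetworkSummary(pd.DataFrame(rows))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return np.nan
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return np.nan
    se2 = a.var(ddof=1) / na + b.var(ddof=1) / nb
    if se2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def _t_matrix(values: np.ndarray, nets: np.ndarray, names: list[str],
              welch: bool) -> np.ndarray:
    tfun = _welch_t if welch else _pooled_t
    k = len(names)
    t = np.full((k, k), np.nan)
    samples = []
    for name in names:
        v = values[nets == name]
        samples.append(v[~np.isnan(v)])
    for i in range(k):
        for j in range(i + 1, k):
            tij = tfun(samples[i], samples[j])
            t[i, j] = tij
            t[j, i] = -tij
    return t


def pairwise_network_t(
    values, parcellation: Parcellation, welch: bool = False
) -> PairwiseContrast:
    """Unpaired two-sample t for every ordered network pair (row vs column)."""
    names, _ = _grouped(values, parcellation)
    values = np.asarray(values, dtype=float)
    t = _t_matrix(values, parcellation.networks, names, welch)
    return PairwiseContrast(networks=names, t=t)


def permutation_p_t(
    values,
    parcellation: Parcellation,
    n_perm: int = 1000,
    seed: int | None = None,
    welch: bool = False,
    alpha: float = 0.05,
    surrogates: np.ndarray | None = None,
) -> PairwiseContrast:
    """Pairwise network t-matrix with one-sided permutation p and BH q.

    The null shuffles region-to-network assignments; alternatively
    ``surrogates`` (n_surrogates x n_regions array of null maps, e.g.
    spatially autocorrelated surrogates) provides the null maps directly.
    """
    if surrogates is None and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    names, _ = _grouped(values, parcellation)
    values = np.asarray(values, dtype=float)
    nets = parcellation.networks
    t_obs = _t_matrix(values, nets, names, welch)

    rng = np.random.default_rng(seed)
    if surrogates is not None:
        null_iter = (np.asarray(s, dtype=float) for s in surrogates)
        n_null = len(surrogates)
    else:
        null_iter = (values[rng.permutation(values.size)] for _ in range(n_perm))
        n_null = n_perm

    exceed = np.zeros_like(t_obs)
    for null_map in null_iter:
        t_null = _t_matrix(null_map, nets, names, welch)
        exceed += (t_null >= t_obs) & ~np.isnan(t_obs)
    p = (1.0 + exceed) / (1.0 + n_null)
    off = ~np.eye(len(names), dtype=bool) & ~np.isnan(t_obs)
    q = np.full_like(p, np.nan)
    if off.any():
        q[off], _ = bh_fdr(p[off], alpha=alpha)
    p[~off] = np.nan
    return PairwiseContrast(networks=names, t=t_obs, p_one_sided=p, q=q)


def correlation_with_permutation(
    x, y, n_perm: int = 10000, seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Pearson r between two regional maps with a one-sided permutation p.

    The null shuffles the pairing of regions.  ``alternative="greater"``
    counts null correlations >= the observed one; ``"less"`` the reverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, length >= 3")
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 defined pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.clip(xc @ yc / x.size, -1.0, 1.0))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r_null = xc @ yc[rng.permutation(y.size)] / x.size
        if alternative == "greater":
            count += r_null >= r_obs
        elif alternative == "less":
            count += r_null <= r_obs
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
    return r_obs, (1.0 + count) / (1.0 + n_perm)
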