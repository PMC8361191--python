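"""Regional structure-function coupling and node-strength phenotypes.

For each brain region, SC-FC coupling is the Spearman rank correlation
between that region's row of the structural connectome (SC) and the
corresponding row of the functional connectome (FC), excluding the
self-connection.  Spearman is used because SC weights are strongly
non-Gaussian (sparse, heavy-tailed); ties — abundant zeros in SC rows —
receive average ranks, which preserves invariance under strictly
monotone transforms of a row.

Variants restrict the partner set (same network, other networks, same
hemisphere) or partial out the Euclidean distance between region
centroids.  Degenerate rows (all-tied SC, fewer than 3 partners) yield
NaN with the region flagged, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datatypes import Connectome, Parcellation

VARIANTS = (
    "whole_brain",
    "within_network",
    "between_network",
    "partial_distance",
    "intra_hemisphere",
)


@dataclass(frozen=True)
class CouplingVector:
    """Per-region Spearman SC-FC coupling for one subject and one variant."""

    values: np.ndarray  # NaN where undefined
    variant: str
    subject_id: str = ""
    n_pairs_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v), initial=0.0) > 1 + 1e-12:
                raise ValueError("coupling values outside [-1, 1]")
        object.__setattr__(self, "values", v)
        if self.n_pairs_used is None:
            object.__setattr__(
                self, "n_pairs_used", np.full(v.shape, v.size - 1, dtype=int)
            )

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def fisher_z(rho):
    """Fisher r-to-z transform, z = atanh(rho); requires |rho| < 1."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho[~np.isnan(rho)]) >= 1):
        raise ValueError("fisher_z requires |rho| < 1")
    return np.arctanh(rho) if rho.ndim else float(np.arctanh(rho))


def functional_connectivity(timeseries: np.ndarray, subject_id: str = "",
                            measurement_index: int = 1) -> Connectome:
    """Pearson-correlation FC matrix from a T x n_regions time-series array."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be T x n_regions with T >= 3")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series for region(s) {constant.tolist()}")
    fc = np.corrcoef(ts, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return Connectome(fc, "FC", subject_id=subject_id,
                      measurement_index=measurement_index)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return np.nan
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def _masked_spearman(sc: np.ndarray, fc: np.ndarray,
                     partner_masks) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of sc[i] vs fc[i] over partner_masks[i]."""
    n = sc.shape[0]
    vals = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        mask = partner_masks[i].copy()
        mask[i] = False
        counts[i] = int(mask.sum())
        if counts[i] < 3:
            continue
        x = sc[i, mask]
        y = fc[i, mask]
        vals[i] = _pearson(rankdata(x), rankdata(y))  # NaN if a row is all-tied
    return vals, counts


def _check_pair(sc: Connectome, fc: Connectome) -> None:
    if sc.modality != "SC" or fc.modality != "FC":
        raise ValueError("expected (SC, FC) connectome pair")
    if sc.n_regions != fc.n_regions:
        raise ValueError("SC and FC have different sizes")
    if sc.n_regions < 3:
        raise ValueError("need at least 3 regions for Spearman coupling")


def regional_coupling(sc: Connectome, fc: Connectome) -> CouplingVector:
    """Whole-brain coupling: Spearman over all n-1 off-diagonal partners."""
    _check_pair(sc, fc)
    n = sc.n_regions
    masks = [np.ones(n, dtype=bool) for _ in range(n)]
    vals, counts = _masked_spearman(sc.matrix, fc.matrix, masks)
    return CouplingVector(vals, "whole_brain", sc.subject_id, counts)


def network_restricted_coupling(
    sc: Connectome, fc: Connectome, parcellation: Parcellation, mode: str
) -> CouplingVector:
    """Coupling over same-network ("within") or other-network ("between") partners."""
    _check_pair(sc, fc)
    if mode not in ("within", "between"):
        raise ValueError("mode must be 'within' or 'between'")
    nets = parcellation.networks
    if len(nets) != sc.n_regions:
        raise ValueError("parcellation size does not match connectomes")
    same = nets[:, None] == nets[None, :]
    masks = same if mode == "within" else ~same
    vals, counts = _masked_spearman(sc.matrix, fc.matrix, list(masks))
    variant = "within_network" if mode == "within" else "between_network"
    return CouplingVector(vals, variant, sc.subject_id, counts)


def intra_hemisphere_coupling(
    sc: Connectome, fc: Connectome, parcellation: Parcellation
) -> CouplingVector:
    """Coupling restricted to partners in the region's own hemisphere."""
    _check_pair(sc, fc)
    hemi = parcellation.hemispheres
    if len(hemi) != sc.n_regions:
        raise ValueError("parcellation size does not match connectomes")
    masks = hemi[:, None] == hemi[None, :]
    vals, counts = _masked_spearman(sc.matrix, fc.matrix, list(masks))
    return CouplingVector(vals, "intra_hemisphere", sc.subject_id, counts)


def partial_coupling_distance(
    sc: Connectome, fc: Connectome, parcellation: Parcellation
) -> CouplingVector:
    """Partial Spearman coupling controlling for inter-centroid distance.

    All three vectors (SC row, FC row, Euclidean centroid distance to each
    partner) are rank-transformed; the two connectivity rank vectors are
    residualized on the distance ranks by least squares and the residuals
    correlated.  A constant distance covariate makes the residualization a
    no-op, so the result then equals plain whole-brain coupling.
    """
    _check_pair(sc, fc)
    cent = parcellation.centroids
    if cent.shape[0] != sc.n_regions:
        raise ValueError("parcellation size does not match connectomes")
    dist = np.sqrt(((cent[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2))
    n = sc.n_regions
    vals = np.full(n, np.nan)
    counts = np.full(n, n - 1, dtype=int)
    warned = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        rx = rankdata(sc.matrix[i, mask])
        ry = rankdata(fc.matrix[i, mask])
        rd = rankdata(dist[i, mask])
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            continue
        if np.ptp(rd) == 0:
            if not warned:
                warnings.warn(
                    "distance covariate is constant; falling back to plain "
                    "Spearman coupling",
                    stacklevel=2,
                )
                warned = True
            vals[i] = _pearson(rx, ry)
            continue
        z = np.column_stack([np.ones(rd.size), rd])
        coef_x, *_ = np.linalg.lstsq(z, rx, rcond=None)
        coef_y, *_ = np.linalg.lstsq(z, ry, rcond=None)
        res_x = rx - z @ coef_x
        res_y = ry - z @ coef_y
        # a rank vector fully explained by distance leaves only round-off:
        # the partial correlation is then undefined, not noise
        if (np.linalg.norm(res_x) < 1e-9 * np.linalg.norm(rx)
                or np.linalg.norm(res_y) < 1e-9 * np.linalg.norm(ry)):
            continue
        vals[i] = _pearson(res_x, res_y)
    return CouplingVector(vals, "partial_distance", sc.subject_id, counts)


def compute_coupling(
    sc: Connectome,
    fc: Connectome,
    parcellation: Parcellation | None = None,
    variant: str = "whole_brain",
) -> CouplingVector:
    """Dispatch to the requested coupling variant."""
    if variant == "whole_brain":
        return regional_coupling(sc, fc)
    if parcellation is None:
        raise ValueError(f"variant {variant!r} requires a parcellation")
    if variant == "within_network":
        return network_restricted_coupling(sc, fc, parcellation, "within")
    if variant == "between_network":
        return network_restricted_coupling(sc, fc, parcellation, "between")
    if variant == "partial_distance":
        return partial_coupling_distance(sc, fc, parcellation)
    if variant == "intra_hemisphere":
        return intra_hemisphere_coupling(sc, fc, parcellation)
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


@dataclass(frozen=True)
class NodeStrengthVector:
    """Per-region node strength (degree) for one connectome."""

    values: np.ndarray
    modality: str
    subject_id: str = ""


def node_strength(conn: Connectome) -> NodeStrengthVector:
    """Row sums excluding the diagonal; absolute values for FC."""
    m = conn.matrix.copy()
    np.fill_diagonal(m, 0.0)
    if conn.modality == "FC":
        m = np.abs(m)
    return NodeStrengthVector(m.sum(axis=1), conn.modality, conn.subject_id)


def average_fc(fcs: list[Connectome]) -> Connectome:
    """Entrywise mean of several FC matrices (Pearson values, untransformed).

    Used for all analyses except heritability, which keeps the individual
    measurements to separate stable inter-subject variance from
    measurement error.
    """
    if not fcs:
        raise ValueError("need at least one FC matrix")
    mats = np.stack([c.matrix for c in fcs])
    return Connectome(mats.mean(axis=0), "FC", subject_id=fcs[0].subject_id)
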