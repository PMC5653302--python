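"""Spatial eigenvector (PCNM) construction, selection, and scale classing.

Principal Coordinates of Neighbour Matrices decompose the site geometry
into orthogonal descriptors of variation at nested spatial scales: the
inter-site distance matrix is truncated (distances beyond the threshold
replaced by four times the threshold), double-centered, and
eigen-decomposed; positive-eigenvalue eigenvectors are the descriptors.
Descriptors with significant positive spatial autocorrelation (Moran's I,
permutation test) are retained, and each is assigned a coarse/medium/fine
scale class from the practical range of a Gaussian variogram fitted to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .geostat import empirical_variogram, fit_variogram

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialBasis",
    "build_pcnm",
    "classify_scale",
    "classify_basis",
    "morans_i_test",
    "DEFAULT_SCALE_BANDS",
]

#: Scale bands in km of practical range: closed-left, open-right, except the
#: coarse upper bound which is closed.
DEFAULT_SCALE_BANDS = {
    "coarse": (110.0, 250.0),
    "medium": (60.0, 110.0),
    "fine": (30.0, 60.0),
}

#: Classical multiplier replacing beyond-truncation distances.
FAR_DISTANCE_FACTOR = 4.0


@dataclass
class SpatialBasis:
    """PCNM descriptors with their autocorrelation and scale metadata."""

    vectors: pd.DataFrame            # site x descriptor, orthonormal columns
    eigenvalues: np.ndarray
    truncation: float
    morans_i: np.ndarray
    expected_i: float
    p_values: np.ndarray
    selected: np.ndarray             # bool: positive-I significant descriptors
    ranges: np.ndarray | None = None
    scale_class: np.ndarray | None = None
    coords: np.ndarray | None = None

    @property
    def names(self) -> list:
        return list(self.vectors.columns)

    def selected_vectors(self) -> pd.DataFrame:
        return self.vectors.loc[:, self.selected]

    def metadata(self) -> pd.DataFrame:
        md = pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "morans_i": self.morans_i,
                "p_value": self.p_values,
                "selected": self.selected,
            },
            index=self.vectors.columns,
        )
        if self.ranges is not None:
            md["range_km"] = self.ranges
            md["scale"] = self.scale_class
        return md


def _morans_i(W: sparse.spmatrix, Z: np.ndarray, s0: float) -> np.ndarray:
    """Moran's I of each (centered) column of Z under weight matrix W."""
    n = Z.shape[0]
    num = np.einsum("ij,ij->j", Z, W @ Z)
    den = np.einsum("ij,ij->j", Z, Z)
    return (n / s0) * num / den


def morans_i_test(
    values,
    coords,
    truncation: float | None = None,
    n_perm: int = 999,
    seed=None,
) -> tuple[float, float]:
    """Moran's I of one variable with its one-sided permutation p-value.

    Uses the same row-standardized within-truncation connectivity as
    :func:`build_pcnm` (truncation default: largest MST edge).
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    D = squareform(pdist(coords))
    if truncation is None:
        truncation = float(minimum_spanning_tree(D).data.max())
    adj = (D <= truncation) & ~np.eye(n, dtype=bool)
    Wd = adj.astype(float)
    Wd = Wd / np.maximum(Wd.sum(axis=1, keepdims=True), 1.0)
    W = sparse.csr_matrix(Wd)
    s0 = float(Wd.sum())
    z = (values - values.mean())[:, None]
    i_obs = float(_morans_i(W, z, s0)[0])
    rng = np.random.default_rng(seed)
    geq = 1
    for _ in range(n_perm):
        geq += float(_morans_i(W, z[rng.permutation(n)], s0)[0]) >= i_obs
    return i_obs, geq / (n_perm + 1.0)


def build_pcnm(
    coords,
    truncation: float | None = None,
    alpha: float = 0.001,
    n_perm: int = 999,
    seed: int | None = 0,
    eig_tol: float = 1e-9,
) -> SpatialBasis:
    """Build PCNM descriptors and select the spatially structured ones.

    Truncation defaults to the largest edge of the minimum spanning tree of
    the site graph (guaranteeing connectivity).  Moran's I uses the
    row-standardized within-truncation neighbour matrix; one-sided
    permutation p-values test for positive autocorrelation (``n_perm``
    permutations, default 999); descriptors with ``I > E[I]`` and
    ``p <= alpha`` are marked selected.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 5:
        raise ValueError("need at least 5 sites")
    D = squareform(pdist(coords))
    if not np.all(D[np.triu_indices(n, 1)] > 0):
        logger.warning("coincident sites present in PCNM coordinates")
    if truncation is None:
        mst = minimum_spanning_tree(D)
        truncation = float(mst.data.max())
    adj = (D <= truncation) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(sparse.csr_matrix(adj), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"truncation {truncation} km leaves the site graph disconnected "
            f"({n_comp} components)"
        )

    Dt = np.where(D > truncation, FAR_DISTANCE_FACTOR * truncation, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = 0.5 * (G + G.T)
    lam, vec = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = lam > eig_tol * max(abs(lam[0]), 1.0)
    if not keep.any():
        raise ValueError("no positive eigenvalue: sites collinear or coincident?")
    lam, vec = lam[keep], vec[:, keep]
    k = vec.shape[1]
    names = [f"PCNM{i + 1}" for i in range(k)]

    # Moran's I with row-standardized within-truncation connectivity
    Wd = adj.astype(float)
    rs = Wd.sum(axis=1, keepdims=True)
    Wd = Wd / np.maximum(rs, 1.0)
    W = sparse.csr_matrix(Wd)
    s0 = float(Wd.sum())
    Z = vec - vec.mean(axis=0)          # eigenvectors are centered already
    i_obs = _morans_i(W, Z, s0)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    geq = np.ones(k, dtype=int)          # observed counts once
    for _ in range(n_perm):
        perm = rng.permutation(n)
        i_perm = _morans_i(W, Z[perm], s0)
        geq += (i_perm >= i_obs).astype(int)
    p = geq / (n_perm + 1.0)
    selected = (i_obs > expected) & (p <= alpha)

    return SpatialBasis(
        vectors=pd.DataFrame(vec, columns=names),
        eigenvalues=lam,
        truncation=float(truncation),
        morans_i=i_obs,
        expected_i=expected,
        p_values=p,
        selected=selected,
        coords=coords,
    )


def classify_scale(
    descriptor,
    coords,
    bands: dict | None = None,
    cutoff: float | None = None,
    n_bins: int = 15,
):
    """Scale class of one descriptor from its Gaussian-variogram range.

    A Gaussian-family variogram is fitted (weighted least squares) to the
    descriptor's empirical variogram; its practical range (correlation
    0.05) is classified into the configured bands.  Ranges outside every
    band, or fit failures, yield ``("unclassified", range_or_nan)``.
    """
    bands = bands or DEFAULT_SCALE_BANDS
    values = np.asarray(descriptor, dtype=float)
    try:
        emp = empirical_variogram(np.asarray(coords, float), values,
                                  cutoff=cutoff, n_bins=n_bins)
        # a pure-nugget model competes with the Gaussian fit: descriptors
        # without resolvable structure are left unclassified
        model, _ = fit_variogram(emp, families=("gaussian", "nugget"),
                                 method="wls")
        if model.family == "nugget" or model.psill == 0.0 or model.nugget_ratio > 0.8:
            return "unclassified", 0.0
        rng_km = float(model.effective_range)
    except (ValueError, RuntimeError) as exc:
        logger.warning("scale classification failed: %s", exc)
        return "unclassified", float("nan")
    coarse_hi = bands.get("coarse", (np.inf, np.inf))[1]
    for name, (lo, hi) in bands.items():
        closed_right = name == "coarse"
        if (rng_km >= lo) and (rng_km <= hi if closed_right else rng_km < hi):
            return name, rng_km
    return "unclassified", rng_km


def classify_basis(
    basis: SpatialBasis,
    bands: dict | None = None,
    only_selected: bool = True,
    cutoff: float | None = None,
) -> SpatialBasis:
    """Classify every (selected) descriptor of a basis in place."""
    if basis.coords is None:
        raise ValueError("basis lacks coordinates")
    k = basis.vectors.shape[1]
    ranges = np.full(k, np.nan)
    classes = np.array(["unclassified"] * k, dtype=object)
    for j in range(k):
        if only_selected and not basis.selected[j]:
            continue
        cls, r = classify_scale(
            basis.vectors.iloc[:, j].to_numpy(), basis.coords,
            bands=bands, cutoff=cutoff,
        )
        ranges[j], classes[j] = r, cls
    basis.ranges = ranges
    basis.scale_class = classes
    return basis
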