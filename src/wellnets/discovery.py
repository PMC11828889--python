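"""Network discovery: spatial ICA, clade clustering, thresholding, merging.

The voxel × timepoint field of searchlight rho values is decomposed with a
fixed-point spatial ICA (FastICA with whitening) into component spatial
maps and timecourses; the rho field is approximately the product of the
two.  Component timecourses are then clustered with Ward linkage and the
dendrogram is cut into a requested number of clades — groups of
spatially-independent networks that wax and wane together.  Individual
component maps are thresholded by a two-component Gaussian mixture
(retaining voxels whose posterior probability of belonging to the
higher-mean "active" component exceeds 0.5 and whose loading is positive),
filtered to connected clusters of more than a minimum number of voxels,
and maps within a clade are merged by the voxelwise nonzero mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import label as cc_label
from sklearn.decomposition import FastICA
from sklearn.mixture import GaussianMixture

from .types import RhoSeries

__all__ = [
    "ICDecomposition",
    "CladePartition",
    "ThresholdedMap",
    "decompose",
    "reconstruct",
    "cluster_timecourses",
    "gmm_threshold",
    "cluster_size_filter",
    "merge_clade",
    "connectivity_structure",
]

#: Minimum cluster size; clusters must be strictly larger to survive.
DEFAULT_MIN_CLUSTER = 50

#: Neighbourhood rule for connected components: 6 (faces), 18 (+edges) or
#: 26 (+corners).  26 is the default.
DEFAULT_CONNECTIVITY = 26


@dataclass
class ICDecomposition:
    """Spatial ICA of a rho series.

    ``maps`` (components × mask voxels) are z-scored over mask voxels (zero
    mean, unit variance) with the sign convention that each map's
    largest-magnitude loading is positive.  ``timecourses`` (timepoints ×
    components) carry the compensating scale so that
    ``timecourses @ maps + offset`` reconstructs the (imputed) input.
    """

    maps: np.ndarray
    timecourses: np.ndarray
    mask: np.ndarray
    offset: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.maps.shape[0] != self.timecourses.shape[1]:
            raise ValueError("component counts of maps and timecourses differ")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, component: int) -> np.ndarray:
        """One component map scattered back onto the grid (0 outside mask)."""
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.maps[component]
        return vol


@dataclass
class CladePartition:
    """Ward-linkage clustering of component timecourses cut into clades."""

    linkage: np.ndarray
    clade_of: np.ndarray  # component -> clade id, 0-based
    n_clades: int

    def members(self, clade: int) -> np.ndarray:
        return np.flatnonzero(self.clade_of == clade)


@dataclass
class ThresholdedMap:
    """A voxel set surviving thresholding plus the surviving cluster sizes."""

    voxels: np.ndarray  # boolean grid mask
    threshold: float
    cluster_sizes: list[int]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _fit_ica(X: np.ndarray, n_components: int, seed: int) -> FastICA:
    """FastICA with a documented fallback seed schedule on non-convergence."""
    last_err: Exception | None = None
    for attempt in range(5):
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-5,
            random_state=int(seed) + 1000 * attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                ica.fit(X)
            except Exception as err:  # pragma: no cover - defensive
                last_err = err
                continue
            if not any("did not converge" in str(w.message) for w in caught):
                return ica
            last_err = RuntimeError("FastICA did not converge")
    if last_err is None:  # pragma: no cover
        raise RuntimeError("FastICA failed")
    # converged-enough final attempt is still usable; surface the last fit
    warnings.warn(
        "FastICA did not fully converge after 5 seeded restarts; "
        "using the final fit",
        stacklevel=2,
    )
    return ica


def decompose(rho: RhoSeries, n_components: int, seed: int = 0) -> ICDecomposition:
    """Spatial ICA of the rho series into component maps and timecourses.

    Missing rho entries (undefined searchlights) are imputed to 0 before
    decomposition.  Maps are standardised to zero mean and unit variance
    over mask voxels, with each map's largest-magnitude loading made
    positive; timecourses absorb the compensating scale and sign.
    Deterministic given the seed.
    """
    if rho.n_timepoints <= n_components:
        raise ValueError("need more timepoints than components")
    X = rho.masked_matrix()  # (voxels, timepoints)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        warnings.warn(
            f"imputing {n_missing} missing rho entries to 0 before ICA",
            stacklevel=2,
        )
        X = np.nan_to_num(X, nan=0.0)
    ica = _fit_ica(X, n_components, seed)
    sources = ica.transform(X)  # (voxels, k) spatial maps
    mixing = ica.mixing_  # (timepoints, k)
    mean_ = ica.mean_  # per-timepoint mean over voxels

    mu = sources.mean(axis=0)
    sd = sources.std(axis=0)
    sd[sd == 0.0] = 1.0
    zmaps = (sources - mu) / sd  # (voxels, k)
    tcs = mixing * sd  # (timepoints, k)
    offset = mixing @ mu + mean_  # (timepoints,)

    # sign convention: largest-|loading| positive
    flips = np.sign(zmaps[np.abs(zmaps).argmax(axis=0), np.arange(zmaps.shape[1])])
    flips[flips == 0.0] = 1.0
    zmaps *= flips
    tcs *= flips
    return ICDecomposition(
        maps=zmaps.T.copy(),
        timecourses=tcs,
        mask=rho.mask,
        offset=offset,
        seed=seed,
    )


def reconstruct(dec: ICDecomposition) -> np.ndarray:
    """(mask voxels × timepoints) reconstruction from maps and timecourses."""
    return (dec.timecourses @ dec.maps + dec.offset[:, None]).T


def cluster_timecourses(dec: ICDecomposition, n_clades: int) -> CladePartition:
    """Ward-linkage clustering of component timecourses, cut into clades."""
    if n_clades > dec.n_components:
        raise ValueError("cannot cut into more clades than components")
    Z = linkage(dec.timecourses.T, method="ward")
    labels = fcluster(Z, t=n_clades, criterion="maxclust") - 1
    return CladePartition(linkage=Z, clade_of=labels, n_clades=int(labels.max()) + 1)


def gmm_threshold(
    map_volume: np.ndarray,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> ThresholdedMap:
    """Threshold a component map with a two-component 1-D Gaussian mixture.

    Fits k=2 Gaussians to the in-mask loadings; "active" is the component
    with the larger mean.  Retains voxels with posterior probability of the
    active component > 0.5 and positive loading.  Returns an empty map with
    a warning when the fitted mixture is degenerate.
    """
    vol = np.asarray(map_volume, dtype=np.float64)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    vals = vol[mask]
    if np.unique(vals).size < 2:
        raise ValueError("map must contain at least 2 distinct values")
    gmm = GaussianMixture(
        n_components=2, n_init=10, random_state=int(seed), covariance_type="full"
    )
    gmm.fit(vals[:, None])
    active = int(np.argmax(gmm.means_.ravel()))
    post = gmm.predict_proba(vals[:, None])[:, active]
    keep_vals = (post > 0.5) & (vals > 0.0)
    if not keep_vals.any():
        warnings.warn("degenerate mixture: no active voxels", stacklevel=2)
    keep = np.zeros(vol.shape, dtype=bool)
    keep[mask] = keep_vals
    sizes = _cluster_sizes(keep, DEFAULT_CONNECTIVITY)
    return ThresholdedMap(voxels=keep, threshold=0.5, cluster_sizes=sizes)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3×3×3 binary structuring element for 6/18/26-neighbourhoods."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    rng = np.arange(-1, 2)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    dist = np.abs(dx) + np.abs(dy) + np.abs(dz)
    if connectivity == 6:
        return dist <= 1
    if connectivity == 18:
        return dist <= 2
    return np.ones((3, 3, 3), dtype=bool)


def _cluster_sizes(voxels: np.ndarray, connectivity: int) -> list[int]:
    labels, n = cc_label(voxels, structure=connectivity_structure(connectivity))
    return sorted(
        (int(s) for s in np.bincount(labels.ravel())[1:] if s > 0), reverse=True
    )


def cluster_size_filter(
    voxels: np.ndarray,
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = DEFAULT_CONNECTIVITY,
    threshold: float = float("nan"),
) -> ThresholdedMap:
    """Keep only connected clusters strictly larger than ``min_size`` voxels.

    Connectivity is the 3D neighbourhood rule (6, 18 or 26; default 26).
    A cluster of exactly ``min_size`` voxels is removed.
    """
    voxels = np.asarray(voxels, dtype=bool)
    labels, n = cc_label(voxels, structure=connectivity_structure(connectivity))
    keep = np.zeros_like(voxels)
    sizes: list[int] = []
    if n:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] > min_size:
                keep |= labels == lab
                sizes.append(int(counts[lab]))
    return ThresholdedMap(
        voxels=keep, threshold=threshold, cluster_sizes=sorted(sizes, reverse=True)
    )


def merge_clade(
    thresholded: list[ThresholdedMap],
    loadings: list[np.ndarray],
) -> np.ndarray:
    """Merge clade member maps by the voxelwise nonzero mean.

    Each voxel's value is the mean of the loadings of those member maps
    whose thresholded voxel set contains it; voxels in no member map are 0.
    """
    if not thresholded:
        raise ValueError("cannot merge an empty clade")
    if len(thresholded) != len(loadings):
        raise ValueError("need one loading volume per thresholded map")
    shape = thresholded[0].voxels.shape
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for tm, load in zip(thresholded, loadings):
        sel = tm.voxels
        acc[sel] += np.asarray(load)[sel]
        cnt[sel] += 1.0
    out = np.zeros(shape)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    return out
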