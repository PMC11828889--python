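"""Searchlight spatial inter-participant representational similarity analysis.

For every voxel and timepoint, the local brain activity pattern of each
participant (voxels inside a small sphere centred on that voxel) is compared
between every pair of participants using the correlation distance

    d(i, j) = 1 - (i - mean(i)) . (j - mean(j)) / (||i - mean(i)|| ||j - mean(j)||)

yielding a participant-by-participant brain distance matrix.  The same
distance is computed between 7-item wellbeing profiles, once per cohort.
The statistic written back to the sphere's centre voxel is the partial
Spearman rank correlation between the upper triangles of the two matrices,
controlling for pairwise age differences and a same-gender indicator.  A
positive rho means participants with more similar local activity patterns
also report more similar wellbeing profiles at that moment.

The public entry point is :func:`run_ssip_rsa`; the scalar building blocks
(:func:`correlation_distance`, :func:`partial_spearman`, the distance-matrix
constructors) are exposed for reuse by the Mantel stage, which applies them
to whole-mask patterns instead of searchlights.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .types import (
    Cohort,
    PairDistanceMatrix,
    RhoSeries,
    SearchlightError,
    UndefinedStatisticError,
    WellbeingProfile,
    pair_index,
)

__all__ = [
    "correlation_distance",
    "sphere_offsets",
    "brain_distance_matrix",
    "wellbeing_distance_matrix",
    "age_distance_matrix",
    "gender_similarity_matrix",
    "partial_spearman",
    "run_ssip_rsa",
]

#: Default searchlight radius in voxel units.  An inclusive radius of 2.0
#: voxels gives the 33-voxel sphere; see docs/methods.md for the mm-to-voxel
#: discussion.
DEFAULT_RADIUS_VOXELS = 2.0


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation distance ``1 - Pearson(x, y)``; range [0, 2].

    Returns NaN when either vector is constant (the correlation is then
    undefined and the caller treats the pair as missing).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("patterns must contain at least 3 values")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(1.0 - (xc @ yc) / (nx * ny))


def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with dx²+dy²+dz² <= radius² (inclusive).

    Returned in lexicographic order, shape (k, 3).  Radius 2.0 gives the
    33-voxel searchlight sphere.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius_voxels))
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    keep = (offs ** 2).sum(axis=1) <= radius_voxels ** 2 + 1e-12
    return offs[keep]  # meshgrid 'ij' + ravel is already lexicographic


def wellbeing_distance_matrix(
    profiles: Sequence[WellbeingProfile],
) -> PairDistanceMatrix:
    """Pairwise correlation distance between 7-item wellbeing profiles."""
    items = np.stack([p.items for p in profiles])
    if len(profiles) < 4:
        raise ValueError("need at least 4 profiles")
    return PairDistanceMatrix(_pairwise_correlation_distance(items), "correlation-distance")


def age_distance_matrix(profiles: Sequence[WellbeingProfile]) -> PairDistanceMatrix:
    """Pairwise absolute age difference."""
    ages = np.array([p.age for p in profiles], dtype=np.float64)
    return PairDistanceMatrix(
        np.abs(ages[:, None] - ages[None, :]), "absolute-difference"
    )


def gender_similarity_matrix(
    profiles: Sequence[WellbeingProfile],
) -> PairDistanceMatrix:
    """Same-gender indicator: 1 for same label, 0 for different."""
    labels = [p.gender for p in profiles]
    if len(set(labels)) > 2:
        raise ValueError(f"gender labels must be binary, got {sorted(set(labels))}")
    arr = np.array(labels)
    same = (arr[:, None] == arr[None, :]).astype(np.float64)
    return PairDistanceMatrix(same, "same-category-indicator")


def brain_distance_matrix(
    cohort: Cohort,
    centre: tuple[int, int, int],
    timepoint: int,
    mask: np.ndarray,
    radius_voxels: float = DEFAULT_RADIUS_VOXELS,
) -> PairDistanceMatrix:
    """Pairwise correlation distance of searchlight patterns at one timepoint.

    The sphere is clipped to the grid and to the mask; fewer than 3 usable
    voxels raises :class:`SearchlightError`.  A participant whose pattern is
    constant over the sphere has all of their pairs marked NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask[centre]:
        raise SearchlightError(f"centre {centre} is outside the mask")
    offs = sphere_offsets(radius_voxels)
    coords = np.asarray(centre)[None, :] + offs
    shape = np.asarray(mask.shape)
    ok = np.all((coords >= 0) & (coords < shape[None, :]), axis=1)
    coords = coords[ok]
    inmask = mask[coords[:, 0], coords[:, 1], coords[:, 2]]
    coords = coords[inmask]
    if coords.shape[0] < 3:
        raise SearchlightError(
            f"searchlight at {centre} has only {coords.shape[0]} in-mask voxels (< 3)"
        )
    patterns = np.stack(
        [
            r.volume[coords[:, 0], coords[:, 1], coords[:, 2], timepoint]
            for r in cohort.recordings
        ]
    )
    return PairDistanceMatrix(
        _pairwise_correlation_distance(patterns), "correlation-distance"
    )


def _pairwise_correlation_distance(patterns: np.ndarray) -> np.ndarray:
    """All-pairs 1 - Pearson over rows of (n, k); constant rows give NaN."""
    centred = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    bad = norms == 0.0
    safe = np.where(bad, 1.0, norms)
    z = centred / safe[:, None]
    d = 1.0 - z @ z.T
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _as_values(m: PairDistanceMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, PairDistanceMatrix) else np.asarray(m, float)


def _rank_design(
    cov_vectors: list[np.ndarray], m: int
) -> np.ndarray:
    """Intercept + ranked covariates, with collinear columns dropped."""
    cols = [np.ones(m)]
    for v in cov_vectors:
        cols.append(rankdata(v))
    X = np.column_stack(cols)
    # greedily drop covariate columns that do not increase design rank
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(
                f"covariate {j - 1} is collinear after ranking; dropped",
                stacklevel=3,
            )
    return X[:, keep]


def partial_spearman(
    dA: PairDistanceMatrix | np.ndarray,
    dB: PairDistanceMatrix | np.ndarray,
    covariates: Sequence[PairDistanceMatrix | np.ndarray] = (),
) -> float:
    """Partial Spearman correlation between upper triangles of two matrices.

    Both upper-triangle vectors are rank-transformed (average ranks for
    ties), residualised by least squares on an intercept plus the ranked
    covariate vectors, and the Pearson correlation of the residuals is
    returned.  Pairs with a NaN in either matrix or any covariate are
    dropped listwise before ranking.
    """
    a = _as_values(dA)
    b = _as_values(dB)
    n = a.shape[0]
    if b.shape != a.shape or any(_as_values(c).shape != a.shape for c in covariates):
        raise ValueError("all matrices must share one participant count")
    iu = pair_index(n)
    av, bv = a[iu], b[iu]
    cvs = [_as_values(c)[iu] for c in covariates]
    ok = np.isfinite(av) & np.isfinite(bv)
    for cv in cvs:
        ok &= np.isfinite(cv)
    av, bv = av[ok], bv[ok]
    cvs = [cv[ok] for cv in cvs]
    m = av.size
    if m < 6:
        raise UndefinedStatisticError(
            f"only {m} usable participant pairs (< 6); correlation undefined"
        )
    ra = rankdata(av)
    rb = rankdata(bv)
    X = _rank_design(cvs, m)
    ra_res = ra - X @ np.linalg.lstsq(X, ra, rcond=None)[0]
    rb_res = rb - X @ np.linalg.lstsq(X, rb, rcond=None)[0]
    na = np.linalg.norm(ra_res)
    nb = np.linalg.norm(rb_res)
    if na == 0.0 or nb == 0.0:
        raise UndefinedStatisticError("ranked vector constant after residualisation")
    return float((ra_res @ rb_res) / (na * nb))


# ---------------------------------------------------------------------------
# Whole-brain searchlight driver


class _SearchlightPlan:
    """Precomputed sphere membership for all mask voxels, grouped by size.

    Groups allow each timepoint's distance computation to run as a few
    dense gathers + one einsum per sphere size, instead of a Python loop
    over voxels.  Sphere sizes differ only where the mask or grid clips
    the sphere.
    """

    def __init__(self, mask: np.ndarray, radius_voxels: float):
        mask = np.asarray(mask, dtype=bool)
        self.mask = mask
        self.shape = mask.shape
        offs = sphere_offsets(radius_voxels)
        coords = np.argwhere(mask)  # lexicographic order
        self.centre_coords = coords
        neigh = coords[:, None, :] + offs[None, :, :]  # (m, k, 3)
        shp = np.asarray(mask.shape)
        valid = np.all((neigh >= 0) & (neigh < shp[None, None, :]), axis=2)
        flat = (
            neigh[..., 0].clip(0, shp[0] - 1) * (shp[1] * shp[2])
            + neigh[..., 1].clip(0, shp[1] - 1) * shp[2]
            + neigh[..., 2].clip(0, shp[2] - 1)
        )
        valid &= mask.ravel()[flat] & valid
        counts = valid.sum(axis=1)
        self.counts = counts
        self.groups: list[tuple[np.ndarray, np.ndarray]] = []
        for size in np.unique(counts):
            rows = np.flatnonzero(counts == size)
            if size < 3:
                continue  # undefined searchlights; rho stays NaN
            idx = np.empty((rows.size, size), dtype=np.intp)
            for i, r in enumerate(rows):
                idx[i] = flat[r][valid[r]]
            self.groups.append((rows, idx))
        self.n_undefined = int(np.sum(counts < 3))


class _ProjectionContext:
    """Rank-space quantities fixed across voxels and timepoints.

    ``Q`` is an orthonormal basis for the span of the intercept plus the
    ranked covariate pair vectors; ``w_unit`` is the unit-norm residual of
    the ranked wellbeing pair vector.  The raw pair vectors are kept for
    the (rare) listwise-deletion path when a searchlight produces missing
    pairs.
    """

    def __init__(self, profiles: Sequence[WellbeingProfile]):
        n = len(profiles)
        self.iu = pair_index(n)
        self.wb = wellbeing_distance_matrix(profiles).values[self.iu]
        self.covs = [
            age_distance_matrix(profiles).values[self.iu],
            gender_similarity_matrix(profiles).values[self.iu],
        ]
        m = self.wb.size
        rw = rankdata(self.wb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity handled by design drop
            X = _rank_design(self.covs, m)
        Q, _ = np.linalg.qr(X)
        w_res = rw - Q @ (Q.T @ rw)
        nw = np.linalg.norm(w_res)
        if nw == 0.0:
            raise UndefinedStatisticError("wellbeing ranks lie in the covariate span")
        self.Q = Q
        self.w_unit = w_res / nw

    def rho_with_missing(self, dv: np.ndarray) -> float:
        """Listwise-deletion partial Spearman for one pair vector with NaNs."""
        ok = np.isfinite(dv)
        if ok.sum() < 6:
            return float("nan")
        ra = rankdata(dv[ok])
        rb = rankdata(self.wb[ok])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X = _rank_design([c[ok] for c in self.covs], int(ok.sum()))
        ra_res = ra - X @ np.linalg.lstsq(X, ra, rcond=None)[0]
        rb_res = rb - X @ np.linalg.lstsq(X, rb, rcond=None)[0]
        na, nb = np.linalg.norm(ra_res), np.linalg.norm(rb_res)
        if na == 0.0 or nb == 0.0:
            return float("nan")
        return float((ra_res @ rb_res) / (na * nb))


def run_ssip_rsa(
    cohort: Cohort,
    mask: np.ndarray,
    radius_voxels: float = DEFAULT_RADIUS_VOXELS,
    timepoints: range | Sequence[int] | None = None,
) -> RhoSeries:
    """Searchlight partial-Spearman map over every mask voxel and timepoint.

    For each timepoint and mask voxel, computes the participant-pair
    correlation-distance matrix over sphere ∩ mask patterns and its partial
    Spearman correlation (controlling age and gender) with the wellbeing
    profile distance matrix.  Searchlights with fewer than 3 in-mask voxels,
    and voxels where fewer than 6 usable pairs remain, are NaN.

    Results are deterministic and independent of participant ordering.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cohort.grid_shape:
        raise ValueError("mask grid does not match cohort grid")
    if not mask.any():
        raise ValueError("mask is empty")
    T = cohort.n_timepoints
    if timepoints is None:
        timepoints = range(T)
    tps = np.asarray(list(timepoints), dtype=int)
    if tps.size and (tps.min() < 0 or tps.max() >= T):
        raise ValueError("timepoint range outside recording duration")

    plan = _SearchlightPlan(mask, radius_voxels)
    if not plan.groups:
        raise SearchlightError("no searchlight contains >= 3 in-mask voxels")
    ctx = _ProjectionContext(cohort.profiles)
    n = cohort.n_participants
    data = cohort.data_array().reshape(n, -1, T)
    # centring each participant-timepoint field improves the conditioning of
    # the sphere-local centring below; Pearson r is invariant to the shift
    data = data - data.mean(axis=1, keepdims=True)

    m_vox = plan.centre_coords.shape[0]
    rho_flat = np.full((m_vox, tps.size), np.nan)
    pi, pj = ctx.iu

    for ti, t in enumerate(tps):
        V = data[:, :, t]
        for rows, idx in plan.groups:
            A = V[:, idx]  # (n, c, s)
            A = A - A.mean(axis=2, keepdims=True)
            norms = np.linalg.norm(A, axis=2)  # (n, c)
            bad = norms == 0.0
            Z = A / np.where(bad, 1.0, norms)[:, :, None]
            corr = np.einsum("ics,jcs->cij", Z, Z, optimize=True)
            d = 1.0 - corr[:, pi, pj]  # (c, n_pairs)
            if bad.any():
                badpair = bad[pi, :] | bad[pj, :]  # (n_pairs, c)
                d[badpair.T] = np.nan
            rho_flat[rows, ti] = _rho_rows(d, ctx)

    grid_rho = np.full(cohort.grid_shape + (tps.size,), np.nan)
    grid_rho[mask] = rho_flat
    return RhoSeries(grid_rho, mask)


def _rho_rows(d: np.ndarray, ctx: _ProjectionContext) -> np.ndarray:
    """Partial Spearman of each row of d against the precomputed wellbeing
    rank residual; rows with NaN pairs fall back to listwise deletion."""
    out = np.full(d.shape[0], np.nan)
    nan_rows = np.isnan(d).any(axis=1)
    full = ~nan_rows
    if full.any():
        rb = rankdata(d[full], axis=1)
        rb_res = rb - (rb @ ctx.Q) @ ctx.Q.T
        nb = np.linalg.norm(rb_res, axis=1)
        okn = nb > 0.0
        vals = np.full(rb.shape[0], np.nan)
        vals[okn] = (rb_res[okn] @ ctx.w_unit) / nb[okn]
        out[full] = vals
    for r in np.flatnonzero(nan_rows):
        out[r] = ctx.rho_with_missing(d[r])
    return out
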