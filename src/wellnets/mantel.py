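"""Mantel permutation inference on component masks.

For each retained independent component, the component map is normalised by
its maximum loading and thresholded at nine levels (0.1 … 0.9); each
candidate mask is cleaned with the >50-voxel cluster filter.  At the peak
timepoint of the component's timecourse, the whole-mask (non-searchlight)
participant-pair brain distance matrix is computed from the BOLD patterns
inside each candidate mask, and the threshold whose mask yields the highest
partial Spearman rho against the wellbeing distance matrix is selected.
Significance of that rho is assessed with a Mantel permutation test: rows
and columns of the brain distance matrix are jointly shuffled (wellbeing and
covariate matrices fixed), the partial Spearman is recomputed for each
permutation, and the one-tailed p-value is

    p = (1 + #{rho_perm >= rho_obs}) / (n_perm + 1).

Component-wise p-values are Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .discovery import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_MIN_CLUSTER,
    ICDecomposition,
    ThresholdedMap,
    cluster_size_filter,
)
from .rsa import (
    _pairwise_correlation_distance,
    _rank_design,
    age_distance_matrix,
    gender_similarity_matrix,
    partial_spearman,
    wellbeing_distance_matrix,
)
from .types import Cohort, PairDistanceMatrix, UndefinedStatisticError, pair_index

__all__ = [
    "MantelResult",
    "normalize_loadings",
    "multi_threshold_masks",
    "peak_timepoint",
    "select_threshold",
    "mantel_test",
    "fdr_correct",
    "screen_components",
    "test_components",
]

THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.01


@dataclass
class MantelResult:
    """Mantel test outcome for one component."""

    component: int
    threshold: float
    n_voxels: int
    peak_timepoint: int
    rho: float
    p: float
    p_fdr: float = float("nan")
    significant: bool = False


def normalize_loadings(map_volume: np.ndarray) -> np.ndarray:
    """Scale loadings so the maximum equals 1 (requires a positive max)."""
    vol = np.asarray(map_volume, dtype=np.float64)
    mx = np.nanmax(vol)
    if not mx > 0.0:
        raise ValueError("maximum loading must be positive to normalise")
    return vol / mx


def multi_threshold_masks(
    normalized_map: np.ndarray,
    mask: np.ndarray | None = None,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = DEFAULT_CONNECTIVITY,
    thresholds: Sequence[float] = THRESHOLDS,
) -> list[ThresholdedMap]:
    """Cluster-filtered masks of voxels strictly above each threshold.

    Thresholds producing an empty mask after the size filter are dropped;
    an empty return marks the component untestable.
    """
    vol = np.asarray(normalized_map, dtype=np.float64)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    out: list[ThresholdedMap] = []
    for thr in thresholds:
        raw = (vol > thr) & mask
        tm = cluster_size_filter(raw, min_cluster, connectivity, threshold=thr)
        if tm.n_voxels > 0:
            out.append(tm)
    return out


def peak_timepoint(timecourse: np.ndarray) -> int:
    """Index of the maximum timecourse value; ties break to the earliest."""
    tc = np.asarray(timecourse, dtype=np.float64)
    return int(np.argmax(tc))


def _whole_mask_distance(
    cohort: Cohort, voxels: np.ndarray, t: int
) -> PairDistanceMatrix:
    """Participant-pair correlation distance of patterns over a voxel mask."""
    patterns = np.stack(
        [r.volume[..., t][voxels] for r in cohort.recordings]
    )
    return PairDistanceMatrix(
        _pairwise_correlation_distance(patterns), "correlation-distance"
    )


def select_threshold(
    cohort: Cohort,
    masks: Sequence[ThresholdedMap],
    t_peak: int,
) -> tuple[ThresholdedMap, float, PairDistanceMatrix]:
    """Pick the candidate mask whose whole-mask rho is highest at t_peak.

    Returns (best mask, its rho, its brain distance matrix).  Ties break
    toward the larger mask.
    """
    usable = [m for m in masks if m.n_voxels >= 3]
    if not usable:
        raise ValueError("need at least one candidate mask with >= 3 voxels")
    wb = wellbeing_distance_matrix(cohort.profiles)
    age = age_distance_matrix(cohort.profiles)
    gen = gender_similarity_matrix(cohort.profiles)
    best: tuple[float, int] | None = None
    best_mask = None
    best_D = None
    for m in usable:
        D = _whole_mask_distance(cohort, m.voxels, t_peak)
        try:
            rho = partial_spearman(D, wb, [age, gen])
        except UndefinedStatisticError:
            continue
        key = (rho, m.n_voxels)
        if best is None or key > best:
            best = key
            best_mask, best_D = m, D
    if best is None:
        raise UndefinedStatisticError("rho undefined for every candidate mask")
    return best_mask, best[0], best_D


def mantel_test(
    brainD: PairDistanceMatrix | np.ndarray,
    wellD: PairDistanceMatrix | np.ndarray,
    covariates: Sequence[PairDistanceMatrix | np.ndarray] = (),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """One-tailed Mantel permutation test; returns (rho_obs, p).

    Rows and columns of the brain matrix are shuffled in the same random
    order; the wellbeing and covariate matrices are never permuted.  The
    identity arrangement contributes through the +1 smoothing, so
    p >= 1/(n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    B = brainD.values if isinstance(brainD, PairDistanceMatrix) else np.asarray(brainD, float)
    W = wellD.values if isinstance(wellD, PairDistanceMatrix) else np.asarray(wellD, float)
    covs = [
        c.values if isinstance(c, PairDistanceMatrix) else np.asarray(c, float)
        for c in covariates
    ]
    n = B.shape[0]
    rho_obs = partial_spearman(B, W, covs)
    iu = pair_index(n)
    if np.isnan(B[iu]).any() or any(np.isnan(c[iu]).any() for c in covs) or np.isnan(W[iu]).any():
        # missing pairs force the scalar listwise path per permutation
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Bp = B[np.ix_(perm, perm)]
            try:
                r = partial_spearman(Bp, W, covs)
            except UndefinedStatisticError:
                continue
            if r >= rho_obs:
                exceed += 1
        return rho_obs, (1 + exceed) / (n_perm + 1)

    # fast path: vectorise permutations through the fixed rank-space projector
    m = iu[0].size
    rw = rankdata(W[iu])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = _rank_design([c[iu] for c in covs], m)
    Q, _ = np.linalg.qr(X)
    w_res = rw - Q @ (Q.T @ rw)
    nw = np.linalg.norm(w_res)
    if nw == 0.0:
        raise UndefinedStatisticError("wellbeing ranks lie in the covariate span")
    w_unit = w_res / nw
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Bp = B[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, m)
    rb = rankdata(Bp, axis=1)
    rb_res = rb - (rb @ Q) @ Q.T
    nb = np.linalg.norm(rb_res, axis=1)
    ok = nb > 0.0
    rho_perm = np.full(n_perm, -np.inf)
    rho_perm[ok] = (rb_res[ok] @ w_unit) / nb[ok]
    p = (1 + int(np.sum(rho_perm >= rho_obs))) / (n_perm + 1)
    return rho_obs, p


def fdr_correct(
    p_values: Sequence[float], q: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment; flags = adjusted < q."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def screen_components(
    dec: ICDecomposition,
    exclude: Sequence[int] = (),
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> list[int]:
    """Retained component ids after artefact screening.

    Removes user-listed component ids (e.g. hand-labelled artefacts) and
    components whose positive-loading voxels leave no cluster after the
    size filter ("no activity after limiting to positive values").
    """
    exclude_set = set(int(i) for i in exclude)
    unknown = exclude_set - set(range(dec.n_components))
    if unknown:
        warnings.warn(f"unknown component ids in exclusion list: {sorted(unknown)}")
    retained = []
    for c in range(dec.n_components):
        if c in exclude_set:
            continue
        pos = dec.map_volume(c) > 0.0
        pos &= dec.mask
        if cluster_size_filter(pos, min_cluster, connectivity).n_voxels == 0:
            continue
        retained.append(c)
    return retained


def test_components(
    cohort: Cohort,
    dec: ICDecomposition,
    components: Sequence[int] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = DEFAULT_CONNECTIVITY,
    seed: int = 0,
) -> tuple[list[MantelResult], dict[int, ThresholdedMap]]:
    """Full Mantel stage over a set of components.

    For each component: normalise loadings, build the nine threshold masks,
    find the peak timepoint, select the best-rho threshold, run the Mantel
    permutation test, then BH-adjust over the tested family.  Returns the
    results (untestable components omitted) and the selected mask per
    tested component.
    """
    if components is None:
        components = screen_components(dec, min_cluster=min_cluster,
                                       connectivity=connectivity)
    wb = wellbeing_distance_matrix(cohort.profiles)
    age = age_distance_matrix(cohort.profiles)
    gen = gender_similarity_matrix(cohort.profiles)
    results: list[MantelResult] = []
    chosen: dict[int, ThresholdedMap] = {}
    ss = np.random.SeedSequence([int(seed), 17])
    comp_seeds = ss.generate_state(max(len(list(components)), 1))
    for idx, c in enumerate(components):
        vol = dec.map_volume(c)
        try:
            norm = normalize_loadings(vol)
        except ValueError:
            continue
        masks = multi_threshold_masks(
            norm, dec.mask, min_cluster, connectivity
        )
        if not masks:
            continue
        t_peak = peak_timepoint(dec.timecourses[:, c])
        try:
            best_mask, rho, D = select_threshold(cohort, masks, t_peak)
        except (ValueError, UndefinedStatisticError):
            continue
        _, p = mantel_test(
            D, wb, [age, gen], n_perm=n_perm, seed=int(comp_seeds[idx]) % (2 ** 31)
        )
        chosen[c] = best_mask
        results.append(
            MantelResult(
                component=int(c),
                threshold=float(best_mask.threshold),
                n_voxels=best_mask.n_voxels,
                peak_timepoint=t_peak,
                rho=float(rho),
                p=float(p),
            )
        )
    if results:
        p_adj, flags = fdr_correct([r.p for r in results], q=alpha)
        for r, pa, f in zip(results, p_adj, flags):
            r.p_fdr = float(pa)
            r.significant = bool(f)
    return results, chosen
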