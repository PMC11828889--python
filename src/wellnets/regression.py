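"""Regression of component timecourses on stimulus annotations.

Annotation channels sampled once per 3 s film segment are standardised
(mean 0, SD 1) and upsampled to the 1 s resolution of the component
timecourses by repeating each segment value three times.  The timecourse is
shifted by a fixed haemodynamic lag (default 4 s) so the response at second
t + lag is paired with the stimulus at second t, then regressed by ordinary
least squares (with intercept) on the four stimulus annotations plus the
two low-level controls (brightness, amplitude).

Because both sides of the regression are autocorrelated, parametric
p-values are not trusted; instead the target channel's 3 s series is
randomly shuffled, re-upsampled, and the model refit, building a two-tailed
permutation null for that channel's coefficient:

    p = (1 + #{|beta_perm| >= |beta_obs|}) / (n_perm + 1).

The family of component × annotation p-values is Benjamini–Hochberg
corrected at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mantel import fdr_correct
from .synthetic import (
    ANNOTATION_CHANNELS,
    AnnotationSet,
    CONTROL_CHANNELS,
    HAEMODYNAMIC_LAG_S,
)

__all__ = [
    "RegressionResult",
    "prepare_annotations",
    "align_timecourse",
    "fit_regression",
    "permute_annotation_test",
    "correct_regression",
    "regress_components",
]

#: Annotation channels tested for significance (controls are fitted but
#: not part of the permutation family).
TESTED_CHANNELS = tuple(c for c in ANNOTATION_CHANNELS if c not in CONTROL_CHANNELS)

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class RegressionResult:
    """Permutation-tested coefficient for one component × annotation."""

    component: int
    annotation: str
    beta: float
    p: float
    p_fdr: float = float("nan")
    significant: bool = False


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        raise ValueError(f"annotation channel {name!r} has zero variance")
    return (x - x.mean()) / sd


def prepare_annotations(ann: AnnotationSet) -> dict[str, np.ndarray]:
    """Standardise each channel at 3 s resolution, then upsample to 1 s.

    Upsampling repeats each segment value ``segment_duration_s`` times
    (the annotations are segment-constant by construction).
    """
    out: dict[str, np.ndarray] = {}
    for name, vals in ann.channels.items():
        z = _standardize(np.asarray(vals, dtype=np.float64), name)
        out[name] = np.repeat(z, ann.segment_duration_s)
    return out


def align_timecourse(
    tc: np.ndarray, design_len: int, lag_s: int = HAEMODYNAMIC_LAG_S
) -> tuple[np.ndarray, int]:
    """Lag-shift a 1 s timecourse against a design of ``design_len`` rows.

    The annotation at second t is paired with the timecourse at second
    t + lag; the usable overlap is ``min(design_len, len(tc) - lag)`` rows.
    Returns (aligned timecourse, usable length).
    """
    tc = np.asarray(tc, dtype=np.float64)
    if lag_s >= tc.size:
        raise ValueError("lag exceeds timecourse length")
    usable = min(design_len, tc.size - lag_s)
    return tc[lag_s : lag_s + usable], usable


def _design_matrix(
    channels: dict[str, np.ndarray], usable: int
) -> tuple[np.ndarray, list[str]]:
    names = [c for c in ANNOTATION_CHANNELS if c in channels]
    X = np.column_stack([np.ones(usable)] + [channels[c][:usable] for c in names])
    return X, names


def fit_regression(
    tc: np.ndarray, channels: dict[str, np.ndarray], lag_s: int = HAEMODYNAMIC_LAG_S
) -> dict[str, float]:
    """OLS coefficients of a timecourse on the prepared annotation channels.

    Returns a name -> beta mapping for all six regressors.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    design_len = len(next(iter(channels.values())))
    y, usable = align_timecourse(tc, design_len, lag_s)
    X, names = _design_matrix(channels, usable)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return dict(zip(names, beta[1:]))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
        else:
            bad.append(names[j - 1])
    return bad


def permute_annotation_test(
    tc: np.ndarray,
    ann: AnnotationSet,
    target: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    lag_s: int = HAEMODYNAMIC_LAG_S,
) -> tuple[float, float]:
    """Two-tailed permutation p for one annotation channel's coefficient.

    The target channel's standardised 3 s series is shuffled and
    re-upsampled per permutation while all other channels stay fixed.
    Returns (beta_obs, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if target not in ann.channels:
        raise KeyError(f"unknown annotation channel {target!r}")
    channels = prepare_annotations(ann)
    design_len = len(next(iter(channels.values())))
    y, usable = align_timecourse(tc, design_len, lag_s)
    X, names = _design_matrix(channels, usable)
    j = names.index(target) + 1  # + intercept column

    beta_obs = np.linalg.lstsq(X, y, rcond=None)[0][j]

    # Frisch–Waugh: the target coefficient equals the regression of the
    # residualised response on the residualised target column, so only the
    # target column needs reprojection per permutation.
    others = np.delete(X, j, axis=1)
    Q, _ = np.linalg.qr(others)
    y_res = y - Q @ (Q.T @ y)

    seg3 = _standardize(np.asarray(ann.channels[target], float), target)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(seg3) for _ in range(n_perm)])
    up = np.repeat(perms, ann.segment_duration_s, axis=1)[:, :usable]
    up_res = up - (up @ Q) @ Q.T
    denom = np.einsum("ij,ij->i", up_res, up_res)
    ok = denom > 0.0
    beta_perm = np.zeros(n_perm)
    beta_perm[ok] = (up_res[ok] @ y_res) / denom[ok]
    exceed = int(np.sum(np.abs(beta_perm) >= abs(beta_obs)))
    return float(beta_obs), (1 + exceed) / (n_perm + 1)


def correct_regression(
    results: list[RegressionResult], q: float = DEFAULT_ALPHA
) -> list[RegressionResult]:
    """BH correction over the flattened component × annotation family."""
    if not results:
        return results
    p_adj, flags = fdr_correct([r.p for r in results], q=q)
    for r, pa, f in zip(results, p_adj, flags):
        r.p_fdr = float(pa)
        r.significant = bool(f)
    return results


def regress_components(
    timecourses: np.ndarray,
    ann: AnnotationSet,
    components: list[int] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    lag_s: int = HAEMODYNAMIC_LAG_S,
    seed: int = 0,
) -> list[RegressionResult]:
    """Permutation-tested annotation coefficients for many components.

    ``timecourses`` is (timepoints × components); the tested family is the
    four stimulus annotations for every requested component, BH-corrected
    together.
    """
    if components is None:
        components = list(range(timecourses.shape[1]))
    results: list[RegressionResult] = []
    ss = np.random.SeedSequence([int(seed), 23])
    seeds = iter(ss.generate_state(len(components) * len(TESTED_CHANNELS)))
    for c in components:
        for channel in TESTED_CHANNELS:
            beta, p = permute_annotation_test(
                timecourses[:, c],
                ann,
                channel,
                n_perm=n_perm,
                seed=int(next(seeds)) % (2 ** 31),
                lag_s=lag_s,
            )
            results.append(RegressionResult(int(c), channel, beta, p))
    return correct_regression(results, q=alpha)
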