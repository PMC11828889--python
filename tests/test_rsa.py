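"""Unit tests for the searchlight inter-participant RSA building blocks.

Every numerical contract is checked against an independent brute-force
oracle: textbook Pearson/Spearman formulas, exhaustive sphere enumeration,
and a naive per-voxel searchlight loop.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wellnets import rsa
from wellnets.types import (
    Cohort,
    ParticipantRecording,
    SearchlightError,
    UndefinedStatisticError,
)

# ---------------------------------------------------------------------------
# correlation distance


def _pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    return num / den


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], 0.0),  # identity
        ([1.0, 2.0, 5.0], [-1.0, -2.0, -5.0], 2.0),  # perfect anticorrelation
    ],
)
def test_correlation_distance_limits(x, y, expected):
    assert rsa.correlation_distance(x, y) == pytest.approx(expected, abs=1e-12)


def test_correlation_distance_matches_textbook_pearson():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 4.0])
    assert rsa.correlation_distance(x, y) == pytest.approx(
        1.0 - _pearson_oracle(x, y), abs=1e-12
    )


def test_correlation_distance_constant_vector_is_nan():
    assert np.isnan(rsa.correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_correlation_distance_rejects_short_vectors():
    with pytest.raises(ValueError):
        rsa.correlation_distance([1.0, 2.0], [3.0, 4.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12),
    st.floats(0.1, 5.0),
    st.floats(-10, 10),
    st.floats(0.1, 5.0),
    st.floats(-10, 10),
)
def test_correlation_distance_affine_invariance(xs, a, b, c, d):
    x = np.asarray(xs)
    rng = np.random.default_rng(0)
    y = rng.standard_normal(x.size)
    if np.ptp(x) == 0:
        return
    d0 = rsa.correlation_distance(x, y)
    d1 = rsa.correlation_distance(a * x + b, c * y + d)
    assert d1 == pytest.approx(d0, abs=1e-8)


# ---------------------------------------------------------------------------
# sphere offsets


def test_sphere_radius_zero_is_centre_only():
    assert rsa.sphere_offsets(0.0).shape == (1, 3)


def test_sphere_radius_two_has_33_voxels():
    assert rsa.sphere_offsets(2.0).shape[0] == 33


@pytest.mark.parametrize("radius", [0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
def test_sphere_offsets_match_exhaustive_enumeration(radius):
    got = {tuple(o) for o in rsa.sphere_offsets(radius)}
    expected = {
        (dx, dy, dz)
        for dx in range(-4, 5)
        for dy in range(-4, 5)
        for dz in range(-4, 5)
        if dx * dx + dy * dy + dz * dz <= radius * radius
    }
    assert got == expected


def test_sphere_offsets_lexicographic_order():
    offs = rsa.sphere_offsets(2.0)
    assert sorted(map(tuple, offs)) == list(map(tuple, offs))


# ---------------------------------------------------------------------------
# distance matrices


def test_wellbeing_distance_duplicated_profile_is_zero(profiles6):
    profiles = list(profiles6)
    profiles[1] = type(profiles[0])(
        "dup", profiles[0].items.copy(), profiles[1].age, profiles[1].gender
    )
    m = rsa.wellbeing_distance_matrix(profiles)
    assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_wellbeing_distance_reflection_is_two(profiles6):
    profiles = list(profiles6)
    items = profiles[0].items
    reflected = 2 * items.mean() - items  # reflect about own mean
    profiles[1] = type(profiles[0])("refl", reflected, 30, "F")
    m = rsa.wellbeing_distance_matrix(profiles)
    assert m.values[0, 1] == pytest.approx(2.0, abs=1e-10)


def test_wellbeing_distance_matches_bruteforce(profiles6):
    m = rsa.wellbeing_distance_matrix(profiles6)
    for i in range(6):
        for j in range(i + 1, 6):
            expected = 1.0 - _pearson_oracle(profiles6[i].items, profiles6[j].items)
            assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_age_distance(profiles6):
    m = rsa.age_distance_matrix(profiles6)
    ages = [p.age for p in profiles6]
    assert m.values[0, 1] == abs(ages[0] - ages[1])
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)


def test_gender_similarity(profiles6):
    m = rsa.gender_similarity_matrix(profiles6)
    g = [p.gender for p in profiles6]
    assert m.values[0, 1] == (1.0 if g[0] == g[1] else 0.0)
    assert np.all(np.diag(m.values) == 1.0)


def test_gender_similarity_rejects_nonbinary_labels(profiles6):
    profiles = [
        type(p)(p.participant_id, p.items, p.age, lab)
        for p, lab in zip(profiles6, ["A", "B", "C", "A", "B", "C"])
    ]
    with pytest.raises(ValueError):
        rsa.gender_similarity_matrix(profiles)


# ---------------------------------------------------------------------------
# partial Spearman


def _partial_spearman_oracle(a, b, covs):
    """Explicit rank regression: rank, residualise on [1, ranked covs], correlate."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    X = np.column_stack([np.ones(len(a))] + [stats.rankdata(c) for c in covs])
    beta_a = np.linalg.lstsq(X, ra, rcond=None)[0]
    beta_b = np.linalg.lstsq(X, rb, rcond=None)[0]
    return _pearson_oracle(ra - X @ beta_a, rb - X @ beta_b)


def _square(v, n):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = v
    return m + m.T


def test_partial_spearman_monotone_transform_gives_one():
    n = 5
    rng = np.random.default_rng(1)
    a = rng.random(n * (n - 1) // 2)
    b = np.exp(3 * a)  # strictly increasing transform
    assert rsa.partial_spearman(_square(a, n), _square(b, n)) == pytest.approx(1.0)


def test_partial_spearman_constant_covariate_equals_plain():
    n = 6
    rng = np.random.default_rng(2)
    a = rng.random(n * (n - 1) // 2)
    b = rng.random(n * (n - 1) // 2)
    const = np.zeros((n, n))
    with pytest.warns(UserWarning, match="collinear"):
        partial = rsa.partial_spearman(_square(a, n), _square(b, n), [const])
    plain = stats.spearmanr(a, b).statistic
    assert partial == pytest.approx(plain, abs=1e-12)


def test_partial_spearman_matches_rank_regression_oracle():
    n = 4  # 6 pairs
    rng = np.random.default_rng(3)
    a = rng.random(6)
    b = rng.random(6)
    c = rng.random(6)
    got = rsa.partial_spearman(_square(a, n), _square(b, n), [_square(c, n)])
    assert got == pytest.approx(_partial_spearman_oracle(a, b, [c]), abs=1e-12)


def test_partial_spearman_covariate_recoding_invariance(profiles20):
    """Affine recoding of a covariate (e.g. 1/0 vs 0/1 gender) is immaterial."""
    rng = np.random.default_rng(4)
    n = 8
    a = _square(rng.random(28), n)
    b = _square(rng.random(28), n)
    gen = _square(rng.integers(0, 2, 28).astype(float), n)
    r1 = rsa.partial_spearman(a, b, [gen])
    r2 = rsa.partial_spearman(a, b, [1.0 - gen])  # flipped coding
    r3 = rsa.partial_spearman(a, b, [5.0 * gen - 2.0])
    assert r2 == pytest.approx(r1, abs=1e-12)
    assert r3 == pytest.approx(r1, abs=1e-12)


def test_partial_spearman_too_few_pairs_raises():
    n = 4
    a = np.full((n, n), np.nan)
    np.fill_diagonal(a, 0)
    with pytest.raises(UndefinedStatisticError):
        rsa.partial_spearman(a, np.zeros((n, n)))


def test_partial_spearman_missing_pairs_dropped_listwise():
    n = 6
    rng = np.random.default_rng(5)
    av = rng.random(15)
    bv = rng.random(15)
    a = _square(av, n)
    a[0, 1] = a[1, 0] = np.nan
    keep = np.ones(15, bool)
    keep[0] = False  # pair (0,1) is the first upper-triangle entry
    expected = _partial_spearman_oracle(av[keep], bv[keep], [])
    assert rsa.partial_spearman(a, _square(bv, n)) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# brain distance matrix + full searchlight vs naive oracle


def test_brain_distance_identical_volumes_zero(tiny_cohort):
    recs = [
        ParticipantRecording(p.participant_id, tiny_cohort.recordings[0].volume.copy())
        for p in tiny_cohort.profiles
    ]
    clone = Cohort(recordings=recs, profiles=tiny_cohort.profiles)
    mask = np.ones((6, 6, 6), bool)
    m = rsa.brain_distance_matrix(clone, (3, 3, 3), 0, mask, 2.0)
    off = m.values[np.triu_indices(6, 1)]
    assert np.allclose(off, 0.0, atol=1e-12)


def test_brain_distance_matches_bruteforce(tiny_cohort):
    mask = np.ones((6, 6, 6), bool)
    centre, t, radius = (2, 3, 2), 1, 1.5
    m = rsa.brain_distance_matrix(tiny_cohort, centre, t, mask, radius)
    offs = [
        (dx, dy, dz)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        for dz in range(-2, 3)
        if dx * dx + dy * dy + dz * dz <= radius ** 2
    ]
    vox = [
        (centre[0] + dx, centre[1] + dy, centre[2] + dz)
        for dx, dy, dz in offs
        if 0 <= centre[0] + dx < 6 and 0 <= centre[1] + dy < 6 and 0 <= centre[2] + dz < 6
    ]
    for i in range(6):
        for j in range(i + 1, 6):
            pi = [tiny_cohort.recordings[i].volume[x, y, z, t] for x, y, z in vox]
            pj = [tiny_cohort.recordings[j].volume[x, y, z, t] for x, y, z in vox]
            expected = 1.0 - _pearson_oracle(pi, pj)
            assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_brain_distance_small_sphere_raises(tiny_cohort):
    mask = np.zeros((6, 6, 6), bool)
    mask[0, 0, 0] = True
    with pytest.raises(SearchlightError):
        rsa.brain_distance_matrix(tiny_cohort, (0, 0, 0), 0, mask, 0.0)


def _naive_ssip(cohort, mask, radius):
    """Per-voxel loop oracle built from the scalar operations."""
    wb = rsa.wellbeing_distance_matrix(cohort.profiles)
    age = rsa.age_distance_matrix(cohort.profiles)
    gen = rsa.gender_similarity_matrix(cohort.profiles)
    T = cohort.n_timepoints
    out = np.full(cohort.grid_shape + (T,), np.nan)
    for centre in map(tuple, np.argwhere(mask)):
        for t in range(T):
            try:
                bd = rsa.brain_distance_matrix(cohort, centre, t, mask, radius)
                out[centre + (t,)] = rsa.partial_spearman(bd, wb, [age, gen])
            except (SearchlightError, UndefinedStatisticError):
                pass
    return out


def test_run_ssip_rsa_equals_naive_loop(tiny_cohort):
    mask = np.ones((6, 6, 6), bool)
    mask[0, :2, :2] = False  # exercise mask clipping
    fast = rsa.run_ssip_rsa(tiny_cohort, mask, 2.0)
    slow = _naive_ssip(tiny_cohort, mask, 2.0)
    assert np.allclose(
        np.nan_to_num(fast.rho, nan=-9), np.nan_to_num(slow, nan=-9), atol=1e-10
    )


def test_run_ssip_rsa_participant_order_invariance(tiny_cohort):
    mask = np.ones((6, 6, 6), bool)
    base = rsa.run_ssip_rsa(tiny_cohort, mask, 1.5, range(2))
    perm = [3, 1, 5, 0, 2, 4]
    shuffled = Cohort(
        recordings=[tiny_cohort.recordings[i] for i in perm],
        profiles=[tiny_cohort.profiles[i] for i in perm],
    )
    again = rsa.run_ssip_rsa(shuffled, mask, 1.5, range(2))
    assert np.allclose(
        np.nan_to_num(base.rho), np.nan_to_num(again.rho), atol=1e-10
    )


def test_run_ssip_rsa_tiny_mask_errors(tiny_cohort):
    mask = np.zeros((6, 6, 6), bool)
    mask[3, 3, 3] = True
    with pytest.raises(SearchlightError):
        rsa.run_ssip_rsa(tiny_cohort, mask, 0.0)
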