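"""Synthetic cohorts with planted co-active networks and known ground truth.

The generator emulates the statistical structure the searchlight
inter-participant analysis assumes: a cohort of participants with 7-item
wellbeing profiles on the T-score scale (population mean 50, SD 10), 4D
recordings in which a small number of disjoint spatial networks are planted,
and stimulus annotation channels coupled to the planted networks' activity
envelopes.

Inside a planted network's voxels, during its active windows, participant
p's spatial pattern is

    pattern_p = signature + coupling_strength * B @ v_p + noise

where ``signature`` is a voxel signature shared by all participants, ``B``
has orthonormal columns, and ``v_p`` is p's mean-centred, unit-norm
wellbeing item vector.  Because ``B`` is orthonormal, the inner product of
two participants' planted deviations equals the Pearson correlation of
their item profiles exactly, so pattern-pair correlation distance increases
monotonically with wellbeing-profile correlation distance — the coupling
the downstream searchlight statistic is designed to detect.  Outside
planted voxels and windows the recordings are pure i.i.d. Gaussian noise
around the scanner baseline (volumes scaled to a mean of 100).

Network activity envelopes are balanced binary block designs chosen to be
exactly orthogonal between networks, so annotation channels coupled to one
network carry no signal about another.  Annotation channels lead the
planted response by a fixed haemodynamic lag (default 4 s at 1 s per
timepoint), matching the shift applied by the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import (
    Cohort,
    InvalidCohortError,
    InvalidGeometryError,
    N_ITEMS,
    ParticipantRecording,
    WellbeingProfile,
)

__all__ = [
    "GroundTruth",
    "AnnotationSet",
    "SyntheticCohort",
    "generate_profiles",
    "generate_cohort",
    "generate_annotations",
    "generate_term_maps",
    "envelope_segments",
]

#: Annotation channels: four stimulus regressors + two low-level controls.
ANNOTATION_CHANNELS = (
    "valence",
    "arousal",
    "social",
    "speaking",
    "brightness",
    "amplitude",
)
BINARY_CHANNELS = ("social", "speaking")
CONTROL_CHANNELS = ("brightness", "amplitude")

#: Haemodynamic lag planted between annotations and network response, in
#: seconds (= timepoints; the recording is sampled at 1 s).
HAEMODYNAMIC_LAG_S = 4

#: Seconds per annotation segment.
SEGMENT_S = 3

# Desk-scale defaults: a 12^3 grid with a full-volume mask, 300 timepoints,
# 20 participants and 2 planted 75-voxel networks.  75 voxels comfortably
# clears the >50-voxel cluster filter used downstream.
DEFAULT_GRID = (12, 12, 12)
DEFAULT_N_TIMEPOINTS = 300
DEFAULT_N_PARTICIPANTS = 20
DEFAULT_N_NETWORKS = 2
DEFAULT_NETWORK_SIZE = 75
DEFAULT_COUPLING = 4.0
DEFAULT_NOISE_SD = 1.0
#: SD of the participant-shared voxel signature inside a planted network.
SIGNATURE_SD = 0.5
#: Baseline recording level (volumes scaled to a mean of 100).
BASELINE = 100.0
#: Length of one activity block in timepoints.
BLOCK_LEN = 25

#: Moderate positive correlation between wellbeing items (the items of the
#: questionnaire are moderately to highly correlated in practice).
ITEM_CORRELATION = 0.5

#: One annotation channel per network: coupling several channels to one
#: envelope would make them collinear regressors and split the recovered
#: coefficient between them.
_DEFAULT_ANNOTATION_COUPLING = (
    {"valence": +1},
    {"speaking": +1},
    {"arousal": +1},
    {"social": +1},
)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``planted_networks`` are disjoint sets of flat voxel indices inside the
    mask; ``active_windows[k]`` lists half-open timepoint intervals during
    which network k is active; ``annotation_coupling[k]`` maps annotation
    channel name -> coupling sign for network k.
    """

    planted_networks: list[np.ndarray]
    active_windows: list[list[tuple[int, int]]]
    coupling_strength: list[float]
    annotation_coupling: list[dict[str, int]]
    seed: int
    grid_shape: tuple[int, int, int]
    n_timepoints: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for net in self.planted_networks:
            s = set(int(v) for v in net)
            if seen & s:
                raise InvalidGeometryError("planted networks must be disjoint")
            seen |= s
        for wins in self.active_windows:
            for a, b in wins:
                if not (0 <= a < b <= self.n_timepoints):
                    raise ValueError("active window outside recording duration")
        if any(c < 0 for c in self.coupling_strength):
            raise ValueError("coupling_strength must be non-negative")

    def envelope(self, k: int) -> np.ndarray:
        """Binary activity envelope of network k at 1 s resolution."""
        env = np.zeros(self.n_timepoints)
        for a, b in self.active_windows[k]:
            env[a:b] = 1.0
        return env

    def network_mask(self, k: int) -> np.ndarray:
        """Boolean grid mask of network k's voxels."""
        m = np.zeros(self.grid_shape, dtype=bool)
        m.ravel()[self.planted_networks[k]] = True
        return m


@dataclass
class AnnotationSet:
    """Per-3-s-segment stimulus annotations (six named channels)."""

    channels: dict[str, np.ndarray]
    segment_duration_s: int = SEGMENT_S

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("annotation channels must have equal length")
        for name in BINARY_CHANNELS:
            if name in self.channels:
                vals = np.unique(self.channels[name])
                if not np.all(np.isin(vals, [0.0, 1.0])):
                    raise ValueError(f"channel {name!r} must be binary 0/1")

    @property
    def n_segments(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class SyntheticCohort(Cohort):
    """A generated cohort bundled with annotations and its ground truth."""

    annotations: AnnotationSet | None = None
    truth: GroundTruth | None = None


def generate_profiles(
    n_participants: int,
    seed: int,
    confound_demographics: bool = False,
) -> list[WellbeingProfile]:
    """Draw wellbeing profiles on the T-score scale (mean 50, SD 10).

    Items are multivariate normal with pairwise correlation
    ``ITEM_CORRELATION``.  Ages are integers in 19–55 and gender is a
    binary label, both independent of wellbeing by default; with
    ``confound_demographics`` age and gender are deliberately coupled to
    the profile mean so tests can verify that partialling removes them.
    """
    if n_participants < 4:
        raise InvalidCohortError(
            "pairwise statistics are undefined below 4 participants"
        )
    rng = np.random.default_rng(seed)
    cov = np.full((N_ITEMS, N_ITEMS), ITEM_CORRELATION * 100.0)
    np.fill_diagonal(cov, 100.0)
    items = rng.multivariate_normal(np.full(N_ITEMS, 50.0), cov, size=n_participants)
    ages = rng.integers(19, 56, size=n_participants)
    genders = rng.choice(["F", "M"], size=n_participants)
    if confound_demographics:
        # tie age and gender to the profile mean (rank-based, deterministic)
        order = np.argsort(items.mean(axis=1))
        ages = np.sort(ages)[np.argsort(order)]
        genders = np.where(items.mean(axis=1) > 50.0, "F", "M")
    return [
        WellbeingProfile(f"sub-{i + 1:02d}", items[i], int(ages[i]), str(genders[i]))
        for i in range(n_participants)
    ]


def _place_networks(
    grid_shape: tuple[int, int, int],
    n_networks: int,
    network_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Grow compact disjoint voxel blobs of the requested size."""
    total = int(np.prod(grid_shape))
    if n_networks * network_size > total:
        raise InvalidGeometryError(
            f"cannot place {n_networks} disjoint networks of {network_size} "
            f"voxels on a {grid_shape} grid"
        )
    taken = np.zeros(total, dtype=bool)
    grid = np.asarray(grid_shape)
    networks: list[np.ndarray] = []
    for _ in range(n_networks):
        placed = None
        for _attempt in range(200):
            seed_vox = rng.integers(0, total)
            if taken[seed_vox]:
                continue
            blob = _grow_blob(seed_vox, network_size, grid, taken)
            if blob is not None:
                placed = blob
                break
        if placed is None:
            raise InvalidGeometryError("could not place disjoint networks")
        taken[placed] = True
        networks.append(np.sort(placed))
    return networks


def _grow_blob(
    seed_vox: int, size: int, grid: np.ndarray, taken: np.ndarray
) -> np.ndarray | None:
    """Breadth-first growth over the 6-neighbourhood, avoiding taken voxels."""
    sx, sy, sz = grid
    blob = [seed_vox]
    inblob = {int(seed_vox)}
    frontier = [int(seed_vox)]
    while len(blob) < size and frontier:
        nxt: list[int] = []
        for v in frontier:
            x, y, z = v // (sy * sz), (v // sz) % sy, v % sz
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nx_, ny_, nz_ = x + dx, y + dy, z + dz
                if not (0 <= nx_ < sx and 0 <= ny_ < sy and 0 <= nz_ < sz):
                    continue
                w = nx_ * sy * sz + ny_ * sz + nz_
                if w in inblob or taken[w]:
                    continue
                inblob.add(w)
                blob.append(w)
                nxt.append(w)
                if len(blob) >= size:
                    return np.asarray(blob[:size], dtype=np.intp)
        frontier = nxt
    if len(blob) >= size:
        return np.asarray(blob[:size], dtype=np.intp)
    return None


def _active_windows(
    n_timepoints: int, n_networks: int
) -> list[list[tuple[int, int]]]:
    """Balanced block designs, exactly orthogonal across networks.

    Timepoints are divided into blocks of ``BLOCK_LEN``; network k is
    active in blocks whose index has bit k set.  With a block count that is
    a multiple of 2**n_networks the binary envelopes are orthogonal
    (correlation exactly zero) and each network is active half the time.
    """
    n_blocks = n_timepoints // BLOCK_LEN
    if n_blocks < 2 ** n_networks:
        raise InvalidGeometryError(
            f"{n_timepoints} timepoints give only {n_blocks} blocks; need "
            f"{2 ** n_networks} for {n_networks} orthogonal envelopes"
        )
    windows: list[list[tuple[int, int]]] = []
    for k in range(n_networks):
        wins = []
        for b in range(n_blocks):
            if (b >> k) & 1:
                wins.append((b * BLOCK_LEN, (b + 1) * BLOCK_LEN))
        windows.append(wins)
    return windows


def generate_cohort(
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    n_networks: int = DEFAULT_N_NETWORKS,
    coupling_strength: float = DEFAULT_COUPLING,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    network_size: int = DEFAULT_NETWORK_SIZE,
    confound_demographics: bool = False,
    ar1: float = 0.0,
) -> SyntheticCohort:
    """Generate a cohort with planted wellbeing-coupled networks.

    Parameters follow the module docstring.  ``ar1`` optionally adds AR(1)
    temporal autocorrelation to the noise (0 = white, the default).
    Deterministic given the seed; the returned cohort's ``truth`` records
    all planted structure.
    """
    if network_size < 60:
        raise InvalidGeometryError(
            "planted networks need >= 60 voxels so the downstream 50-voxel "
            "cluster filter can pass"
        )
    profiles = generate_profiles(n_participants, seed, confound_demographics)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    networks = _place_networks(grid_shape, n_networks, network_size, rng)
    windows = _active_windows(n_timepoints, n_networks)
    coupling = [
        _DEFAULT_ANNOTATION_COUPLING[k % len(_DEFAULT_ANNOTATION_COUPLING)]
        for k in range(n_networks)
    ]
    truth = GroundTruth(
        planted_networks=networks,
        active_windows=windows,
        coupling_strength=[float(coupling_strength)] * n_networks,
        annotation_coupling=[dict(c) for c in coupling],
        seed=seed,
        grid_shape=tuple(grid_shape),
        n_timepoints=n_timepoints,
    )

    # mean-centred unit-norm item vectors: pairwise inner products equal the
    # Pearson correlation between item profiles
    items = np.stack([p.items for p in profiles])
    v = items - items.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    v = v / norms

    total = int(np.prod(grid_shape))
    data = rng.standard_normal((n_participants, total, n_timepoints))
    if ar1 > 0.0:
        for t in range(1, n_timepoints):
            data[:, :, t] = ar1 * data[:, :, t - 1] + np.sqrt(1 - ar1 ** 2) * data[:, :, t]
    data *= noise_sd
    data += BASELINE

    for k, net in enumerate(networks):
        size = net.size
        signature = rng.standard_normal(size) * SIGNATURE_SD
        # orthonormal columns: preserves item-profile inner products exactly
        B = np.linalg.qr(rng.standard_normal((size, N_ITEMS)))[0]
        env = truth.envelope(k).astype(bool)
        planted = signature[None, :] + coupling_strength * (v @ B.T)  # (n, size)
        data[:, net[:, None], np.flatnonzero(env)[None, :]] += planted[:, :, None]

    recordings = [
        ParticipantRecording(
            profiles[i].participant_id,
            data[i].reshape(*grid_shape, n_timepoints),
        )
        for i in range(n_participants)
    ]
    n_segments = max(0, (n_timepoints - HAEMODYNAMIC_LAG_S) // SEGMENT_S)
    annotations = generate_annotations(n_segments, truth, seed)
    return SyntheticCohort(
        recordings=recordings,
        profiles=profiles,
        annotations=annotations,
        truth=truth,
    )


def envelope_segments(
    truth: GroundTruth, k: int, n_segments: int, lag_s: int = HAEMODYNAMIC_LAG_S
) -> np.ndarray:
    """Network k's activity envelope averaged over lag-shifted 3 s segments.

    Segment s covers stimulus seconds [3s, 3s+3); the planted neural
    response follows ``lag_s`` seconds later, so the segment is scored by
    the envelope over [3s+lag, 3s+3+lag), clipped to the recording.
    """
    env = truth.envelope(k)
    out = np.zeros(n_segments)
    for s in range(n_segments):
        a = s * SEGMENT_S + lag_s
        b = min(a + SEGMENT_S, env.size)
        if a >= env.size:
            break
        out[s] = env[a:b].mean()
    return out


def generate_annotations(
    n_segments: int, truth: GroundTruth, seed: int
) -> AnnotationSet:
    """Six annotation channels at 3 s resolution, coupled per ground truth.

    Channels named in ``truth.annotation_coupling`` track (with the stated
    sign) the lag-shifted activity envelope of their network; continuous
    channels get additive Gaussian noise, binary channels flip state with
    probability 0.1.  Unlisted channels (including the two low-level
    controls) are pure noise.
    """
    if n_segments * SEGMENT_S > truth.n_timepoints:
        raise ValueError("annotations longer than the recording")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    coupled: dict[str, tuple[int, int]] = {}
    for k, mapping in enumerate(truth.annotation_coupling):
        for name, sign in mapping.items():
            coupled[name] = (k, int(np.sign(sign)))
    channels: dict[str, np.ndarray] = {}
    for name in ANNOTATION_CHANNELS:
        if name in coupled:
            k, sign = coupled[name]
            env = envelope_segments(truth, k, n_segments)
            if name in BINARY_CHANNELS:
                on = env > 0.5 if sign > 0 else env <= 0.5
                flip = rng.random(n_segments) < 0.1
                channels[name] = (on ^ flip).astype(np.float64)
            else:
                channels[name] = sign * env + 0.7 * rng.standard_normal(n_segments)
        elif name in BINARY_CHANNELS:
            channels[name] = (rng.random(n_segments) < 0.5).astype(np.float64)
        else:
            channels[name] = rng.standard_normal(n_segments)
    return AnnotationSet(channels=channels)


def generate_term_maps(
    grid_shape: tuple[int, int, int],
    truth: GroundTruth,
    seed: int,
    n_distractors: int = 3,
    smooth_sigma: float = 1.0,
) -> dict[str, np.ndarray]:
    """Labelled term-association volumes for decoding tests.

    One map is concentrated on each planted network (label ``term_netK``)
    plus ``n_distractors`` maps concentrated on random blobs elsewhere
    (label ``distractorJ``).  All maps are lightly smoothed and carry weak
    background noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    total = int(np.prod(grid_shape))
    grid = np.asarray(grid_shape)
    maps: dict[str, np.ndarray] = {}
    taken = np.zeros(total, dtype=bool)
    for net in truth.planted_networks:
        taken[net] = True
    for k, net in enumerate(truth.planted_networks):
        vol = 0.05 * rng.standard_normal(total)
        vol[net] += 1.0
        maps[f"term_net{k}"] = gaussian_filter(
            vol.reshape(grid_shape), smooth_sigma
        )
    for j in range(n_distractors):
        blob = None
        for _ in range(100):
            seed_vox = rng.integers(0, total)
            if taken[seed_vox]:
                continue
            blob = _grow_blob(seed_vox, 60, grid, taken)
            if blob is not None:
                break
        vol = 0.05 * rng.standard_normal(total)
        if blob is not None:
            vol[blob] += 1.0
        maps[f"distractor{j}"] = gaussian_filter(vol.reshape(grid_shape), smooth_sigma)
    return maps
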