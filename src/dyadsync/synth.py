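"""Synthetic dyad studies with known ground truth.

The generator emulates the recording protocol of a two-group dyadic fNIRS
hyperscanning study: a 3-min rest, a 20-min collaborative navigation task
with a disruption at the 10-min mark (experimental group only), and a final
3-min rest, all sampled at 7.81 Hz over 16 channels mapped to six ROIs,
with 10 Hz behavioral streams (binary speech, cursor trajectory).

Signal model, per homotopic ROI pair: the O2Hb concentration dynamic is

    kappa(t) * s(t) + sqrt(1 - kappa(t)^2) * private(t)

where s and private are independent band-limited Gaussian processes in the
coupling band and kappa controls interbrain coupling (squared wavelet
coherence of such a pair is kappa^4 in expectation).  On top of the
dynamics each channel carries systemic cardiac / Mayer-wave / respiratory
oscillations (near-global across a participant's channels, which is what
makes the downstream PCA filter effective), white measurement noise,
optional motion artifacts, and an occasional dead channel that has no
cardiac component at all.  Concentrations are mapped to two-wavelength raw
intensities by inverting the same modified Beer-Lambert model the
preprocessing chain uses, so a generated study can be pushed through the
entire pipeline.

Coupling defaults are assumptions, not reproductions: the study this
emulates reported no disruption effect on synchrony, so ``coupling_post``
defaults to ``coupling_pre`` (kappa = 0.4, a real-minus-permuted coherence
excess of ~0.02, matching the scale the literature reports) and any
disruption-induced shift is an explicit scenario parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import config
from .behavior import ReferencePath, SpeechSeries, Trajectory
from .preprocess import PreprocessParams, RawIntensityRecording, extinction_matrix


class SimParameterError(ValueError):
    """Invalid simulation parameter; the message names the field."""


# Amplitudes of the concentration model, uM.  Systemic oscillations dominate
# the variance (as in real prefrontal fNIRS), which is what the 80% PCA
# filter relies on.  Each rhythm is a narrowband process shared across a
# participant's channels with a random per-channel phase (pulse-arrival and
# vasculature differences), making its spatial loadings signed and low-rank:
# the PCA filter removes that shared part while a small channel-local
# residual keeps the cardiac peak visible to the quality check.
HEMO_AMP = 0.15
CARDIAC_AMP = 1.05
MAYER_AMP = 0.3
RESP_AMP = 0.21
HHB_RATIO = -0.35  # neurovascular coupling: HHb dips when O2Hb rises
SYSTEMIC_HHB_RATIO = 0.3  # blood-volume rhythms raise O2Hb and HHb together
SYSTEMIC_SHARED_FRAC = 0.93  # variance fraction of a rhythm that is spatially shared


@dataclass
class SimParams:
    n_dyads: int = 49
    group_assignment: tuple | None = None  # per-dyad "control"|"experimental"
    fs_nirs: float = config.FS_NIRS
    fs_behavior: float = config.FS_BEHAVIOR
    rest_duration: float = config.REST_DURATION
    task_duration: float = config.TASK_DURATION
    disruption_offset: float = config.DISRUPTION_OFFSET
    coupling_pre: float = 0.4
    coupling_post: float = 0.4
    coupling_band: tuple = config.BAND
    ibs_trend: float = 0.0  # coherence-units per second within a period
    shared_per_roi: bool = False  # independent shared latent per homotopic ROI
    cardiac_freq: float = 1.0
    mayer_freq: float = 0.1
    resp_freq: float = 0.25
    noise_sd: float = 0.03
    artifact_spike_rate: float = 0.0  # events per minute
    artifact_shift_rate: float = 0.0
    bad_channel_prob: float = 0.0
    n_icons: int = 202
    icons_visible_after_disruption: int = 41
    # behavioral defaults (screen units / on-fractions); the experimental
    # group's post-disruption shifts emulate the published manipulation
    # checks (error roughly doubling, speech ratio shifting by ~1.33).
    skill_sd: float = 0.02
    post_skill_sd_experimental: float = 0.045
    guide_rate: float = 0.65
    drawer_rate: float = 0.08
    post_ratio_shift_experimental: float = 1.33
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("artifact_spike_rate", "artifact_shift_rate",
                     "bad_channel_prob", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimParameterError(f"{name} must be >= 0")
        for name in ("coupling_pre", "coupling_post"):
            v = np.atleast_1d(getattr(self, name))
            if (v < 0).any() or (v > 1).any():
                raise SimParameterError(f"{name} must lie in [0, 1]")
        if not self.disruption_offset < self.task_duration:
            raise SimParameterError("disruption_offset must be < task_duration")
        if self.icons_visible_after_disruption > self.n_icons:
            raise SimParameterError(
                "icons_visible_after_disruption must be <= n_icons")
        if not self.fs_nirs > 2 * self.coupling_band[1]:
            raise SimParameterError("fs_nirs must exceed 2x the coupling band")
        if self.n_dyads < 1:
            raise SimParameterError("n_dyads must be >= 1")
        if self.group_assignment is not None \
                and len(self.group_assignment) != self.n_dyads:
            raise SimParameterError("group_assignment length != n_dyads")

    def group_of(self, dyad_index: int) -> str:
        if self.group_assignment is not None:
            return self.group_assignment[dyad_index]
        return "experimental" if dyad_index % 2 else "control"

    @property
    def total_duration(self) -> float:
        return 2 * self.rest_duration + self.task_duration

    def coupling_for(self, dyad_index: int, when: str) -> float:
        v = getattr(self, f"coupling_{when}")
        v = np.atleast_1d(v)
        return float(v[dyad_index % len(v)])


@dataclass
class ArtifactEvent:
    onset_s: float
    kind: str  # "spike" | "shift"
    amplitude: float
    duration_s: float


@dataclass
class GroundTruth:
    dyad_id: str
    group: str
    coupling_pre: float
    coupling_post: float
    coupling_slope: float  # coherence-units per second
    artifacts: dict = field(default_factory=dict)  # (role, ch) -> [events]
    bad_channels: list = field(default_factory=list)  # (role, ch)
    speech_rates: dict = field(default_factory=dict)
    cursor_sd: tuple = (0.0, 0.0)
    roi_o2hb: dict = field(default_factory=dict)  # role -> (6, n) clean dynamics
    roi_hhb: dict = field(default_factory=dict)


@dataclass
class DyadRecording:
    dyad_id: str
    group: str
    guide: RawIntensityRecording
    drawer: RawIntensityRecording
    speech_guide: SpeechSeries
    speech_drawer: SpeechSeries
    trajectory: Trajectory
    reference_path: ReferencePath
    events: dict  # task_start, disruption, task_end (s on the record clock)
    difficulty: dict = field(default_factory=dict)  # (role, period) -> VAS score


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _narrowband_pair(rng: np.random.Generator, n: int, fs: float, f0: float,
                     rel_bw: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance narrowband process around ``f0`` plus its quadrature.

    Built in the frequency domain (white spectrum masked to f0*(1 +/- rel_bw)),
    so the pair (in-phase, quadrature) spans the rhythm's two-dimensional
    temporal subspace exactly.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spec[(freqs < f0 * (1 - rel_bw)) | (freqs > f0 * (1 + rel_bw))] = 0.0
    x = np.fft.irfft(spec, n)
    q = np.fft.irfft(spec * -1j, n)  # Hilbert quadrature
    sd = x.std()
    if sd > 0:
        x, q = x / sd, q / sd
    return x, q


def band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple = config.BAND) -> np.ndarray:
    """Unit-variance Gaussian process band-limited by a zero-phase filter."""
    b, a = sp_signal.butter(3, [band[0] / (fs / 2), band[1] / (fs / 2)],
                            btype="band")
    x = sp_signal.filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def inject_artifacts(signal_in: np.ndarray, spike_rate: float,
                     shift_rate: float, rng_seed, fs: float = config.FS_NIRS
                     ) -> tuple[np.ndarray, list[ArtifactEvent]]:
    """Add motion-like spikes (<= 2 s) and persistent baseline shifts.

    Rates are events per minute; amplitudes scale with the signal's robust
    SD.  Returns the corrupted signal and a log of injected events.
    """
    if spike_rate < 0 or shift_rate < 0:
        raise SimParameterError("artifact rates must be >= 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    x = np.asarray(signal_in, dtype=float).copy()
    n = x.size
    minutes = n / fs / 60.0
    sd = max(np.std(x), 1e-12)
    log: list[ArtifactEvent] = []
    for _ in range(rng.poisson(spike_rate * minutes)):
        dur = rng.uniform(0.2, 2.0)
        onset = rng.uniform(0, max(n / fs - dur, 0))
        amp = rng.choice([-1, 1]) * rng.uniform(6, 12) * sd
        i0 = int(onset * fs)
        i1 = min(n, i0 + max(1, int(dur * fs)))
        t = np.arange(i1 - i0) / fs
        x[i0:i1] += amp * np.exp(-t / max(dur / 4, 1e-3))
        log.append(ArtifactEvent(onset, "spike", float(amp), dur))
    for _ in range(rng.poisson(shift_rate * minutes)):
        onset = rng.uniform(0, n / fs)
        amp = rng.choice([-1, 1]) * rng.uniform(4, 8) * sd
        i0 = int(onset * fs)
        x[i0:] += amp
        log.append(ArtifactEvent(onset, "shift", float(amp), (n - i0) / fs))
    log.sort(key=lambda e: e.onset_s)
    return x, log


def generate_reference_path(params: SimParams, rng_seed) -> ReferencePath:
    """Axis-aligned polyline from Start to End; every turn sits on an icon.

    The path is a rectilinear staircase across the unit screen whose turn
    vertices double as icon positions; remaining icons are scattered
    uniformly.  With only two icons the path is a single segment.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    if params.n_icons < 2:
        raise SimParameterError("n_icons must be >= 2")
    start = np.array([0.05, 0.5])
    end = np.array([0.95, 0.5])
    if params.n_icons == 2:
        verts = np.array([start, end])
        return ReferencePath(vertices=verts, icons=verts.copy())
    n_turn = int(min(14, max(2, params.n_icons // 8)))
    xs = np.sort(rng.uniform(0.1, 0.9, n_turn))
    ys = rng.uniform(0.08, 0.92, n_turn)
    verts = [start]
    cur = start
    for x, y in zip(xs, ys):
        verts.append(np.array([x, cur[1]]))  # horizontal leg
        verts.append(np.array([x, y]))       # vertical leg; turn above an icon
        cur = np.array([x, y])
    verts.append(np.array([end[0], cur[1]]))
    verts.append(end)
    verts = np.array(verts)
    turn_icons = verts[1:-1]
    n_extra = params.n_icons - len(turn_icons)
    extra = rng.uniform(0.02, 0.98, size=(max(n_extra, 0), 2))
    icons = np.vstack([turn_icons, extra]) if n_extra > 0 else turn_icons
    return ReferencePath(vertices=verts, icons=icons)


def simulate_cursor(ref: ReferencePath, skill_sd: float,
                    disruption_time: float, post_skill_sd: float, fs: float,
                    rng_seed, duration: float = config.TASK_DURATION
                    ) -> Trajectory:
    """Cursor moving along the reference path with skill-dependent jitter.

    The cursor advances at constant speed (covering the path over the task)
    with smoothed Gaussian positional noise whose scale switches from
    ``skill_sd`` to ``post_skill_sd`` at the disruption.
    """
    if skill_sd < 0 or post_skill_sd < 0:
        raise SimParameterError("skill_sd must be >= 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n = int(round(duration * fs))
    seg = np.diff(ref.vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = np.linspace(0, cum[-1], n)
    xy = np.empty((n, 2))
    for dim in range(2):
        xy[:, dim] = np.interp(arc, cum, ref.vertices[:, dim])
    t = np.arange(n) / fs
    sd = np.where(t < disruption_time, skill_sd, post_skill_sd)
    if (sd > 0).any():
        noise = rng.standard_normal((n, 2))
        # smooth to ~0.5 s so the wobble looks like steering error, then
        # rescale so the per-sample SD matches the requested skill level
        noise = sp_signal.savgol_filter(noise, window_length=11, polyorder=2,
                                        axis=0)
        noise /= max(noise.std(), 1e-12)
        xy = xy + noise * sd[:, None]
    return Trajectory(xy=np.clip(xy, 0.0, 1.0), fs=fs)


def _markov_speech(rng, n, fs, rate, mean_on_s=1.5):
    if rate <= 0:
        return np.zeros(n, dtype=np.uint8)
    if rate >= 1:
        return np.ones(n, dtype=np.uint8)
    dt = 1.0 / fs
    p_off = min(1.0, dt / mean_on_s)            # on -> off
    mean_off = mean_on_s * (1 - rate) / rate
    p_on = min(1.0, dt / mean_off)              # off -> on
    u = rng.uniform(size=n)
    out = np.empty(n, dtype=np.uint8)
    state = 1 if rng.uniform() < rate else 0
    for i in range(n):
        state = (u[i] >= p_off) if state else (u[i] < p_on)
        out[i] = state
    return out


def simulate_speech(duration: float, fs: float, guide_rate: float,
                    drawer_rate: float, post_ratio_shift: float,
                    disruption_time: float, rng_seed
                    ) -> tuple[SpeechSeries, SpeechSeries]:
    """Two binary speech series with a post-disruption ratio shift.

    Pre-disruption on-fractions match the stated rates; afterwards the
    Guide/Drawer rate ratio is multiplied by ``post_ratio_shift`` (split
    symmetrically so total speaking time stays roughly constant, as the
    study's manipulation checks found).
    """
    for name, r in (("guide_rate", guide_rate), ("drawer_rate", drawer_rate)):
        if not 0 <= r <= 1:
            raise SimParameterError(f"{name} must lie in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n = int(round(duration * fs))
    n_pre = min(n, int(round(disruption_time * fs)))
    sqrt_shift = math.sqrt(max(post_ratio_shift, 0.0))
    g_post = min(1.0, guide_rate * sqrt_shift)
    d_post = drawer_rate / sqrt_shift if sqrt_shift > 0 else 0.0
    g = np.concatenate([_markov_speech(rng, n_pre, fs, guide_rate),
                        _markov_speech(rng, n - n_pre, fs, g_post)])
    d = np.concatenate([_markov_speech(rng, n_pre, fs, drawer_rate),
                        _markov_speech(rng, n - n_pre, fs, d_post)])
    return (SpeechSeries(g, fs, "Guide"), SpeechSeries(d, fs, "Drawer"))


# ---------------------------------------------------------------------------
# Full dyad generation
# ---------------------------------------------------------------------------

def _kappa_series(params: SimParams, group: str, dyad_index: int,
                  t: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Coupling amplitude kappa(t) over the whole record.

    The coupling lives in coherence units c = kappa^4; within each task
    period c drifts linearly at ``ibs_trend`` per second, and the
    experimental group switches from pre to post coupling at the disruption.
    """
    k_pre = params.coupling_for(dyad_index, "pre")
    k_post = params.coupling_for(dyad_index, "post") \
        if group == "experimental" else k_pre
    t_task = t - params.rest_duration
    t_disr = params.disruption_offset
    c = np.where(t_task < t_disr, k_pre ** 4, k_post ** 4).astype(float)
    if params.ibs_trend != 0.0:
        within = np.where(t_task < t_disr, np.maximum(t_task, 0.0),
                          t_task - t_disr)
        c = c + params.ibs_trend * within
    return np.clip(c, 0.0, 1.0) ** 0.25, k_pre, k_post


def _participant_channels(rng: np.random.Generator, params: SimParams,
                          roi_o2hb: np.ndarray, roi_hhb: np.ndarray,
                          t: np.ndarray):
    """16-channel O2Hb/HHb concentrations with systemic noise and faults."""
    n = t.size
    n_ch = len(config.DEFAULT_ROI_MAP)
    roi_index = {r: i for i, r in enumerate(config.ROI_NAMES)}
    o2hb = np.empty((n_ch, n))
    hhb = np.empty((n_ch, n))
    # Each systemic rhythm is a narrowband master process shared across the
    # participant's channels, entering each channel with its own random phase
    # (pulse-arrival and vasculature differences), plus a small channel-local
    # narrowband residual.  The shared part is spatially low-rank with signed
    # loadings -- the structure the PCA systemic filter removes -- while the
    # local residual keeps the cardiac peak visible in every good channel.
    freqs = (params.cardiac_freq, params.mayer_freq, params.resp_freq)
    amps = (CARDIAC_AMP, MAYER_AMP, RESP_AMP)
    masters = [_narrowband_pair(rng, n, params.fs_nirs, f) for f in freqs]
    c_shared = np.sqrt(SYSTEMIC_SHARED_FRAC)
    c_local = np.sqrt(1.0 - SYSTEMIC_SHARED_FRAC)
    bad_channels = []
    artifacts = {}
    for ch in range(1, n_ch + 1):
        roi = config.DEFAULT_ROI_MAP[ch]
        base_o = roi_o2hb[roi_index[roi]].copy()
        base_h = roi_hhb[roi_index[roi]].copy()
        if rng.uniform() < params.bad_channel_prob:
            # dead optode: white noise only, no cardiac component
            o2hb[ch - 1] = rng.standard_normal(n) * 2 * max(params.noise_sd, 0.05)
            hhb[ch - 1] = rng.standard_normal(n) * 2 * max(params.noise_sd, 0.05)
            bad_channels.append(ch)
            continue
        for (mi, mq), f, a in zip(masters, freqs, amps):
            theta = rng.uniform(0, 2 * np.pi)
            shared = np.cos(theta) * mi - np.sin(theta) * mq
            local, _ = _narrowband_pair(rng, n, params.fs_nirs, f)
            osc = (a * rng.uniform(0.8, 1.2) / np.sqrt(2.0)) * (
                c_shared * shared + c_local * local)
            base_o += osc
            base_h += SYSTEMIC_HHB_RATIO * osc
        base_o += rng.standard_normal(n) * params.noise_sd
        base_h += rng.standard_normal(n) * params.noise_sd * 0.5
        if params.artifact_spike_rate > 0 or params.artifact_shift_rate > 0:
            base_o, log = inject_artifacts(base_o, params.artifact_spike_rate,
                                           params.artifact_shift_rate, rng,
                                           fs=params.fs_nirs)
            for ev in log:
                i0 = int(ev.onset_s * params.fs_nirs)
                i1 = min(n, i0 + max(1, int(ev.duration_s * params.fs_nirs)))
                tt = np.arange(i1 - i0) / params.fs_nirs
                if ev.kind == "spike":
                    base_h[i0:i1] += 0.5 * ev.amplitude * np.exp(
                        -tt / max(ev.duration_s / 4, 1e-3))
                else:
                    base_h[i0:] += 0.5 * ev.amplitude
            artifacts[ch] = log
        o2hb[ch - 1] = base_o
        hhb[ch - 1] = base_h
    return o2hb, hhb, bad_channels, artifacts


def concentrations_to_intensity(o2hb: np.ndarray, hhb: np.ndarray,
                                rng: np.random.Generator,
                                params: PreprocessParams | None = None
                                ) -> np.ndarray:
    """Invert the modified Beer-Lambert model to two-wavelength intensities.

    I_lambda(t) = I0_lambda * exp(-OD_lambda(t)) with OD built from the same
    extinction matrix the preprocessing chain inverts; intensities are
    strictly positive by construction.
    """
    params = params or PreprocessParams()
    a = extinction_matrix(params)  # OD = A @ C_mM
    conc_mM = np.stack([o2hb, hhb], axis=1) / 1000.0  # (ch, 2, t)
    od = np.einsum("ij,cjt->cit", a, conc_mM)
    i0 = rng.uniform(0.5, 2.0, size=(od.shape[0], od.shape[1], 1))
    return i0 * np.exp(-od)


def _difficulty_scores(rng, group: str) -> dict:
    """Perceived-difficulty VAS scores, truncated normal on [0, 10].

    Means/SDs emulate the published manipulation check: the experimental
    group perceives the second half as far harder.
    """
    table = {
        ("control", "pre"): (4.0, 1.8), ("control", "post"): (4.2, 2.0),
        ("experimental", "pre"): (3.1, 1.7), ("experimental", "post"): (6.4, 1.7),
    }
    out = {}
    for role in ("Guide", "Drawer"):
        for period in ("pre", "post"):
            m, sd = table[(group, period)]
            out[(role, period)] = float(np.clip(rng.normal(m, sd), 0, 10))
    return out


def _roi_dynamics(params: SimParams, dyad_index: int, group: str,
                  rng: np.random.Generator):
    """Coupled ROI concentration dynamics for one dyad (both roles)."""
    n = int(round(params.fs_nirs * params.total_duration))
    t = np.arange(n) / params.fs_nirs
    kappa, k_pre, k_post = _kappa_series(params, group, dyad_index, t)

    n_roi = len(config.ROI_NAMES)
    if params.shared_per_roi:
        shared = [band_limited_noise(rng, n, params.fs_nirs,
                                     params.coupling_band)
                  for _ in range(n_roi)]
    else:
        shared = [band_limited_noise(rng, n, params.fs_nirs,
                                     params.coupling_band)] * n_roi
    mix = np.sqrt(np.clip(1.0 - kappa ** 2, 0.0, 1.0))
    roi_sets = {}
    for role in ("Guide", "Drawer"):
        o = np.empty((n_roi, n))
        h = np.empty((n_roi, n))
        for r in range(n_roi):
            private = band_limited_noise(rng, n, params.fs_nirs,
                                         params.coupling_band)
            o[r] = HEMO_AMP * (kappa * shared[r] + mix * private)
            extra = band_limited_noise(rng, n, params.fs_nirs,
                                       params.coupling_band)
            h[r] = HHB_RATIO * o[r] + 0.15 * HEMO_AMP * extra
        roi_sets[role] = (o, h)
    return t, k_pre, k_post, roi_sets


def generate_roi_dynamics(params: SimParams, dyad_index: int) -> GroundTruth:
    """Ground-truth ROI dynamics only, skipping channel/intensity synthesis.

    Uses the same seeding and draw order as :func:`generate_dyad`, so the
    returned ``roi_o2hb``/``roi_hhb`` match what that function would embed in
    its channels.  Useful when an experiment only needs the noiseless coupled
    dynamics (e.g. coherence studies at scale).
    """
    params.validate()
    if dyad_index >= params.n_dyads:
        raise SimParameterError("dyad_index must be < n_dyads")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.rng_seed), int(dyad_index)]))
    group = params.group_of(dyad_index)
    _, k_pre, k_post, roi_sets = _roi_dynamics(params, dyad_index, group, rng)
    return GroundTruth(
        dyad_id=f"dyad{dyad_index:03d}", group=group,
        coupling_pre=k_pre, coupling_post=k_post,
        coupling_slope=params.ibs_trend,
        roi_o2hb={r: roi_sets[r][0] for r in roi_sets},
        roi_hhb={r: roi_sets[r][1] for r in roi_sets})


def generate_dyad(params: SimParams, dyad_index: int
                  ) -> tuple[DyadRecording, GroundTruth]:
    """Generate one dyad's full recording plus its ground truth."""
    params.validate()
    if dyad_index >= params.n_dyads:
        raise SimParameterError("dyad_index must be < n_dyads")
    seed_seq = np.random.SeedSequence([int(params.rng_seed), int(dyad_index)])
    rng = np.random.default_rng(seed_seq)
    group = params.group_of(dyad_index)
    dyad_id = f"dyad{dyad_index:03d}"

    t, k_pre, k_post, roi_sets = _roi_dynamics(params, dyad_index, group, rng)

    recordings = {}
    truth_art, truth_bad = {}, []
    for role in ("Guide", "Drawer"):
        o, h = roi_sets[role]
        ch_o, ch_h, bad, art = _participant_channels(rng, params, o, h, t)
        intensity = concentrations_to_intensity(ch_o, ch_h, rng)
        recordings[role] = RawIntensityRecording(
            samples=intensity, fs=params.fs_nirs,
            participant_id=f"{dyad_id}_{role[0]}", role=role)
        truth_bad.extend((role, ch) for ch in bad)
        truth_art.update({(role, ch): log for ch, log in art.items()})

    ref = generate_reference_path(params, rng)
    post_sd = params.post_skill_sd_experimental \
        if group == "experimental" else params.skill_sd
    traj = simulate_cursor(ref, params.skill_sd, params.disruption_offset,
                           post_sd, params.fs_behavior, rng,
                           duration=params.task_duration)
    shift = params.post_ratio_shift_experimental \
        if group == "experimental" else 1.0
    g_rate = float(np.clip(rng.normal(params.guide_rate, 0.06), 0.05, 0.95))
    d_rate = float(np.clip(rng.lognormal(np.log(params.drawer_rate), 0.5),
                           0.01, 0.9))
    sp_g, sp_d = simulate_speech(params.task_duration, params.fs_behavior,
                                 g_rate, d_rate, shift,
                                 params.disruption_offset, rng)

    events = {"task_start": params.rest_duration,
              "disruption": params.rest_duration + params.disruption_offset,
              "task_end": params.rest_duration + params.task_duration}
    rec = DyadRecording(dyad_id=dyad_id, group=group,
                        guide=recordings["Guide"], drawer=recordings["Drawer"],
                        speech_guide=sp_g, speech_drawer=sp_d,
                        trajectory=traj, reference_path=ref, events=events,
                        difficulty=_difficulty_scores(rng, group))
    truth = GroundTruth(
        dyad_id=dyad_id, group=group, coupling_pre=k_pre, coupling_post=k_post,
        coupling_slope=params.ibs_trend, artifacts=truth_art,
        bad_channels=truth_bad,
        speech_rates={"Guide": g_rate, "Drawer": d_rate, "shift": shift},
        cursor_sd=(params.skill_sd, post_sd),
        roi_o2hb={r: roi_sets[r][0] for r in roi_sets},
        roi_hhb={r: roi_sets[r][1] for r in roi_sets})
    return rec, truth


def generate_study(params: SimParams):
    """Yield (DyadRecording, GroundTruth) for every dyad in the study."""
    for i in range(params.n_dyads):
        yield generate_dyad(params, i)


# ---------------------------------------------------------------------------
# Feature-level simulator (for statistical calibration and power analysis)
# ---------------------------------------------------------------------------

def simulate_feature_table(n_dyads: int = 40, n_rois: int = 6,
                           effect: float = 0.0, sd_dyad: float = 0.5,
                           sd_roi: float = 0.3, sd_resid: float = 1.0,
                           baseline: float = 0.0, time_effect: float = 0.0,
                           group_effect: float = 0.0,
                           rng=None) -> pd.DataFrame:
    """Long-format feature table from a known mixed-model generative process.

    Outcome = baseline + time_effect*Time + group_effect*Group +
    effect*Time*Group + dyad intercept + ROI-in-dyad intercept + noise,
    mirroring the nested design (ROIs within dyads, two periods).  Used to
    calibrate type-I error and power of the inferential machinery against a
    truth known by construction.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    rows = []
    for d in range(n_dyads):
        grp = d % 2  # 0 control, 1 experimental
        bd = rng.normal(0, sd_dyad)
        for r in range(n_rois):
            br = rng.normal(0, sd_roi)
            for time in (0, 1):
                y = (baseline + time_effect * time + group_effect * grp
                     + effect * time * grp + bd + br
                     + rng.normal(0, sd_resid))
                rows.append({"dyad_id": f"d{d:03d}",
                             "group": "experimental" if grp else "control",
                             "roi": config.ROI_NAMES[r % len(config.ROI_NAMES)],
                             "chromophore": "o2hb",
                             "period": "post" if time else "pre",
                             "value": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File interchange (CSV dialect)
# ---------------------------------------------------------------------------

def write_dyad(rec: DyadRecording, out_dir: str | Path) -> dict:
    """Write one dyad's streams as CSV files plus a metadata JSON.

    Intensity files are long format (time, channel, wavelength, intensity);
    behavioral streams are (time, x, y) and (time, speaking).  Returns the
    manifest row for the dyad.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role, raw in (("guide", rec.guide), ("drawer", rec.drawer)):
        n = raw.samples.shape[2]
        tt = np.arange(n) / raw.fs
        frames = []
        for ch in range(raw.n_channels):
            for wi, wl in enumerate(raw.wavelengths):
                frames.append(pd.DataFrame({
                    "time": tt, "channel": ch + 1, "wavelength": wl,
                    "intensity": raw.samples[ch, wi]}))
        path = out / f"{rec.dyad_id}_{role}_nirs.csv"
        pd.concat(frames).to_csv(path, index=False)
        paths[f"{role}_nirs"] = path.name
    for role, sp in (("guide", rec.speech_guide), ("drawer", rec.speech_drawer)):
        tt = np.arange(sp.values.size) / sp.fs
        path = out / f"{rec.dyad_id}_{role}_speech.csv"
        pd.DataFrame({"time": tt, "speaking": sp.values}).to_csv(path,
                                                                 index=False)
        paths[f"{role}_speech"] = path.name
    tt = np.arange(rec.trajectory.xy.shape[0]) / rec.trajectory.fs
    traj_path = out / f"{rec.dyad_id}_trajectory.csv"
    pd.DataFrame({"time": tt, "x": rec.trajectory.xy[:, 0],
                  "y": rec.trajectory.xy[:, 1]}).to_csv(traj_path, index=False)
    paths["trajectory"] = traj_path.name
    ref_path = out / f"{rec.dyad_id}_reference.csv"
    pd.DataFrame(rec.reference_path.vertices,
                 columns=["x", "y"]).to_csv(ref_path, index=False)
    paths["reference"] = ref_path.name
    meta = {"dyad_id": rec.dyad_id, "group": rec.group, "events": rec.events,
            "fs_nirs": rec.guide.fs, "fs_behavior": rec.trajectory.fs,
            "difficulty": {f"{k[0]}_{k[1]}": v
                           for k, v in rec.difficulty.items()}}
    meta_path = out / f"{rec.dyad_id}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths["meta"] = meta_path.name
    return {"dyad_id": rec.dyad_id, "group": rec.group, **paths}


def write_study(params: SimParams, out_dir: str | Path) -> Path:
    """Generate and write a whole study; returns the manifest path."""
    out = Path(out_dir)
    rows = [write_dyad(rec, out) for rec, _ in generate_study(params)]
    manifest = out / "study_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
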