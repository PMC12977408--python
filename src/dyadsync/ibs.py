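"""Interbrain synchrony: wavelet transform coherence and derived features.

The dyad-level quantity of interest is the magnitude-squared wavelet
coherence between homotopic ROI hemoglobin series of the two participants,

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) ),

where W_x, W_y are analytic Morlet continuous wavelet transforms
(center frequency omega0 = 6 rad/s, 12 voices per octave), W_xy = W_x
conj(W_y), and S denotes smoothing in time (Gaussian with standard
deviation matched to the scale) and across scale (boxcar spanning 0.6
octave).  Coherence values inside the cone of influence (COI) are excluded:
a frequency f is considered edge-contaminated within tau(f) = sqrt(2)/f
seconds of either record edge.

Three features summarize each (dyad, ROI, chromophore, period) cell:
``level`` (mean coherence over time and in-band frequencies), ``slope``
(OLS trend of the frequency-averaged coherence series, per second) and
``pct_det`` (recurrence-quantification determinism of that series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import config


class DataError(ValueError):
    """Raised when inputs violate an operation's data contract."""


# ---------------------------------------------------------------------------
# Cone of influence
# ---------------------------------------------------------------------------

def coi_duration(f: float, *, exact: bool = False) -> float:
    """One-sided edge-effect duration tau(f) of the analytic Morlet wavelet.

    ``tau(f) = sqrt(2) / f`` seconds; by default the value is rounded up to
    whole seconds (the convention in which the a-priori estimate at 0.01 Hz
    is 2 min 22 s).  ``exact=True`` returns the un-rounded value, which is
    what the masking geometry uses.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    tau = math.sqrt(2.0) / f
    return tau if exact else float(math.ceil(tau))


# ---------------------------------------------------------------------------
# Continuous wavelet transform and coherence
# ---------------------------------------------------------------------------

@dataclass
class WTCResult:
    """Time x frequency coherence with COI boundary and validity mask.

    ``coherence`` has shape (n_freqs, n_times); ``freqs`` is strictly
    decreasing (large scales last).  ``coi`` gives, per time sample, the
    lowest frequency not contaminated by edge effects; cells with
    ``freqs < coi[t]`` lie inside the cone.  ``valid`` is None until
    :func:`mask_and_band` is applied; ``times`` is in seconds relative to
    the start of the underlying record (after cropping, relative to the
    original record so period boundaries stay meaningful).
    """

    coherence: np.ndarray
    freqs: np.ndarray
    coi: np.ndarray
    fs: float
    times: np.ndarray
    valid: np.ndarray | None = None
    pair_id: tuple | None = None


def _wtc_freqs(fs: float, n: int, fmin: float | None, fmax: float | None,
               voices: int) -> np.ndarray:
    if fmax is None:
        fmax = fs / 2.0
    if fmin is None:
        fmin = 2.0 * fs / n  # at least two cycles in the record
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    n_oct = math.log2(fmax / fmin)
    k = int(math.ceil(n_oct * voices)) + 1
    return fmax * 2.0 ** (-np.arange(k) / voices)


def cwt_morlet(x: np.ndarray, fs: float, freqs: np.ndarray,
               omega0: float = config.MORLET_OMEGA0) -> np.ndarray:
    """Analytic Morlet CWT of ``x`` at the given frequencies (rows)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    dt = 1.0 / fs
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    xh = np.fft.fft(x - x.mean(), nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=dt)
    ff = 4.0 * np.pi / (omega0 + math.sqrt(2.0 + omega0 ** 2))
    scales = 1.0 / (ff * np.asarray(freqs))
    # psi_hat(s*w) for w > 0, with sqrt(2 pi s / dt) energy normalization
    arg = scales[:, None] * omega[None, :]
    psi = (np.pi ** -0.25) * np.exp(-0.5 * (arg - omega0) ** 2) * (omega > 0)
    psi *= np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    return np.fft.ifft(xh[None, :] * psi, axis=1)[:, :n]


def _gauss_kernels_fft(freqs: np.ndarray, fs: float, nfft: int,
                       omega0: float) -> np.ndarray:
    """FFTs of periodic Gaussian time-smoothing kernels, one per scale."""
    ff = 4.0 * np.pi / (omega0 + math.sqrt(2.0 + omega0 ** 2))
    scales_samples = fs / (ff * np.asarray(freqs))  # scale in samples
    t = np.arange(nfft)
    t = np.minimum(t, nfft - t).astype(float)  # circular distance
    kern = np.exp(-0.5 * (t[None, :] / scales_samples[:, None]) ** 2)
    kern /= kern.sum(axis=1, keepdims=True)
    return np.fft.fft(kern, axis=1)


def smooth_spectrum(p: np.ndarray, kern_fft: np.ndarray, n: int,
                    voices: int = config.VOICES_PER_OCTAVE) -> np.ndarray:
    """Time- then scale-smooth a (possibly complex) scale x time field."""
    nfft = kern_fft.shape[1]
    ph = np.fft.fft(p, nfft, axis=1)
    out = np.fft.ifft(ph * kern_fft, axis=1)[:, :n]
    if not np.iscomplexobj(p):
        out = out.real
    width = max(1, int(round(config.SCALE_SMOOTH_OCTAVES * voices)))
    if width > 1:
        if np.iscomplexobj(out):
            re = ndimage.uniform_filter1d(out.real, width, axis=0, mode="nearest")
            im = ndimage.uniform_filter1d(out.imag, width, axis=0, mode="nearest")
            out = re + 1j * im
        else:
            out = ndimage.uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


class CoherenceEngine:
    """Computes wavelet coherence with per-signal caching.

    The permuted-dyad control re-pairs every Guide with every non-partner
    Drawer, so each participant's CWT and smoothed auto-spectrum are reused
    across many pairings; caching them makes the all-pairs computation
    linear in participants plus one cross-smoothing per pair.
    """

    def __init__(self, fs: float, n: int, fmin: float | None = None,
                 fmax: float | None = None,
                 voices: int = config.VOICES_PER_OCTAVE,
                 omega0: float = config.MORLET_OMEGA0):
        self.fs = float(fs)
        self.n = int(n)
        self.voices = voices
        self.omega0 = omega0
        self.freqs = _wtc_freqs(fs, n, fmin, fmax, voices)
        self.nfft = 1 << int(np.ceil(np.log2(2 * n)))
        self._kern_fft = _gauss_kernels_fft(self.freqs, fs, self.nfft, omega0)
        ff = 4.0 * np.pi / (omega0 + math.sqrt(2.0 + omega0 ** 2))
        self._inv_scale = (ff * self.freqs)[:, None]
        self._cache: dict = {}
        dt = 1.0 / fs
        edge = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt
        with np.errstate(divide="ignore"):
            self.coi = np.where(edge > 0, math.sqrt(2.0) / np.maximum(edge, 1e-12),
                                np.inf)
        self.times = np.arange(n) * dt

    def add(self, key, x: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        if x.size != self.n:
            raise DataError(f"signal {key!r} has length {x.size}, expected {self.n}")
        w = cwt_morlet(x, self.fs, self.freqs, self.omega0)
        auto = smooth_spectrum(np.abs(w) ** 2 * self._inv_scale,
                               self._kern_fft, self.n, self.voices)
        self._cache[key] = (w, auto)

    def coherence(self, key_x, key_y, pair_id=None) -> WTCResult:
        wx, ax = self._cache[key_x]
        wy, ay = self._cache[key_y]
        cross = smooth_spectrum(wx * np.conj(wy) * self._inv_scale,
                                self._kern_fft, self.n, self.voices)
        denom = ax * ay
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.abs(cross) ** 2 / denom
        coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
        return WTCResult(coherence=coh, freqs=self.freqs.copy(),
                         coi=self.coi.copy(), fs=self.fs,
                         times=self.times.copy(), pair_id=pair_id)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                      fmin: float | None = None, fmax: float | None = None,
                      voices: int = config.VOICES_PER_OCTAVE,
                      omega0: float = config.MORLET_OMEGA0,
                      pair_id=None) -> WTCResult:
    """Magnitude-squared wavelet coherence of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    eng = CoherenceEngine(fs, x.size, fmin=fmin, fmax=fmax, voices=voices,
                          omega0=omega0)
    eng.add("x", x)
    eng.add("y", y)
    return eng.coherence("x", "y", pair_id=pair_id)


# ---------------------------------------------------------------------------
# Band/COI masking and the three features
# ---------------------------------------------------------------------------

@dataclass
class BandWindow:
    """Frequency band and analysis time window (seconds, record clock)."""

    f_lo: float = config.BAND[0]
    f_hi: float = config.BAND[1]
    t_start: float = 0.0
    t_end: float = np.inf

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")


def mask_and_band(w: WTCResult, win: BandWindow) -> WTCResult:
    """Apply COI exclusion and band selection, then crop the time window.

    Masking happens on the full record first, so rest periods on either side
    of the task absorb the edge effects; the returned result is cropped to
    ``[win.t_start, win.t_end]`` with times kept on the original clock.
    """
    if win.f_hi < w.freqs.min() or win.f_lo > w.freqs.max():
        raise DataError("band outside the computed frequency range")
    in_band = (w.freqs >= win.f_lo) & (w.freqs <= win.f_hi)
    valid = in_band[:, None] & (w.freqs[:, None] >= w.coi[None, :])
    keep = (w.times >= win.t_start) & (w.times <= win.t_end)
    if not keep.any() or not valid[:, keep].any():
        raise DataError("no valid coherence cells survive masking")
    return WTCResult(coherence=w.coherence[:, keep], freqs=w.freqs,
                     coi=w.coi[keep], fs=w.fs, times=w.times[keep],
                     valid=valid[:, keep], pair_id=w.pair_id)


def _period_columns(w: WTCResult, period: str, split: float) -> np.ndarray:
    if period not in ("pre", "post"):
        raise ValueError(f"period must be 'pre' or 'post', got {period!r}")
    return w.times < split if period == "pre" else w.times >= split


def ibs_level(w: WTCResult, period: str = "pre",
              split: float | None = None) -> float:
    """Mean coherence over valid (time, frequency) cells of one period."""
    if w.valid is None:
        raise DataError("ibs_level requires a masked WTCResult")
    if split is None:
        cols = np.ones(w.times.size, dtype=bool)
    else:
        cols = _period_columns(w, period, split)
    v = w.valid[:, cols]
    if not v.any():
        raise DataError("no valid cells in the requested period")
    return float(w.coherence[:, cols][v].mean())


@dataclass
class IBSSeries:
    """Frequency-averaged coherence as a function of time."""

    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True where no valid scale contributed
    fs: float


def ibs_timeseries(w: WTCResult) -> IBSSeries:
    """Average coherence across valid frequencies, per time sample."""
    if w.valid is None:
        raise DataError("ibs_timeseries requires a masked WTCResult")
    counts = w.valid.sum(axis=0)
    sums = np.where(w.valid, w.coherence, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return IBSSeries(times=w.times.copy(), values=vals, mask=counts == 0,
                     fs=w.fs)


MIN_SLOPE_SAMPLES = 10


def ibs_slope(s: IBSSeries, period: str = "pre",
              split: float | None = None) -> float:
    """OLS slope of the IBS series over one period, in coherence per second.

    Returns NaN (the missing-value flag) when fewer than
    ``MIN_SLOPE_SAMPLES`` unmasked samples are available.
    """
    if split is None:
        cols = np.ones(s.times.size, dtype=bool)
    else:
        cols = s.times < split if period == "pre" else s.times >= split
    ok = cols & ~s.mask & np.isfinite(s.values)
    if ok.sum() < MIN_SLOPE_SAMPLES:
        return float("nan")
    t = s.times[ok]
    y = s.values[ok]
    t = t - t.mean()
    return float((t @ (y - y.mean())) / (t @ t))


# ---------------------------------------------------------------------------
# Recurrence quantification
# ---------------------------------------------------------------------------

@dataclass
class RQAParams:
    embedding_dim: int = config.RQA_EMBEDDING_DIM
    radius: float | None = None  # chosen per signal when None
    target_rr: float = config.RQA_TARGET_RR
    lmin: int = config.RQA_LMIN
    theiler_window: int = config.RQA_THEILER

    def __post_init__(self):
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if not 0 < self.target_rr < 1:
            raise ValueError("target_rr must be in (0, 1)")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")


@dataclass
class RadiusSelection:
    epsilon: float
    achieved_rr: float
    degenerate: bool = False


@dataclass
class RecurrenceResult:
    rr: float
    pct_det: float
    line_hist: np.ndarray  # line_hist[L] = number of diagonal lines of length L
    epsilon: float
    degenerate: bool = False


def _embed(values: np.ndarray, m: int) -> np.ndarray:
    if m == 1:
        return values[:, None]
    n = values.size - m + 1
    return np.stack([values[i:i + n] for i in range(m)], axis=1)


def _distance_matrix(series: IBSSeries | np.ndarray, m: int,
                     theiler: int) -> np.ndarray:
    values = series.values if isinstance(series, IBSSeries) else np.asarray(series)
    values = values[np.isfinite(values)]
    emb = _embed(values.astype(np.float32), m)
    if m == 1:
        d = np.abs(emb[:, 0][:, None] - emb[:, 0][None, :])
    else:
        d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    n = d.shape[0]
    for k in range(theiler):  # Theiler window w excludes |i-j| < w
        np.fill_diagonal(d[k:, :n - k], np.inf)
        if k:
            np.fill_diagonal(d[:n - k, k:], np.inf)
    return d


def _rr_from_d(d: np.ndarray, eps: float, theiler: int) -> float:
    n = d.shape[0]
    excluded = n + 2 * sum(n - k for k in range(1, theiler))
    total = n * n - excluded
    return float((d <= eps).sum() / total)


def select_radius(s: IBSSeries | np.ndarray, params: RQAParams,
                  _d: np.ndarray | None = None) -> RadiusSelection:
    """Bisection for the recurrence radius achieving the target RR.

    Deterministic; a constant (or near-constant) series makes every pair
    recurrent at any positive radius, which is reported via the
    ``degenerate`` flag.
    """
    d = _distance_matrix(s, params.embedding_dim, params.theiler_window) \
        if _d is None else _d
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        return RadiusSelection(0.0, 1.0, degenerate=True)
    dmax = float(finite.max())
    if dmax <= 0:
        return RadiusSelection(0.0, 1.0, degenerate=True)
    lo, hi = 0.0, dmax
    eps = dmax / 2
    for _ in range(60):
        eps = 0.5 * (lo + hi)
        rr = _rr_from_d(d, eps, params.theiler_window)
        if abs(rr - params.target_rr) <= config.RQA_RR_TOL / 4:
            break
        if rr > params.target_rr:
            hi = eps
        else:
            lo = eps
    rr = _rr_from_d(d, eps, params.theiler_window)
    return RadiusSelection(float(eps), rr,
                           degenerate=abs(rr - params.target_rr) > config.RQA_RR_TOL)


def _diagonal_line_hist(rp: np.ndarray, theiler: int) -> np.ndarray:
    """Histogram of diagonal line lengths over off-Theiler diagonals."""
    n = rp.shape[0]
    parts = []
    sep = np.zeros(1, dtype=bool)
    for k in range(max(theiler, 1), n):
        parts.append(np.diagonal(rp, k))
        parts.append(sep)
    if not parts:
        return np.zeros(2, dtype=np.int64)
    long = np.concatenate(parts)
    padded = np.concatenate([[False], long, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    lengths = edges[1::2] - edges[::2]
    if lengths.size == 0:
        return np.zeros(2, dtype=np.int64)
    hist = np.bincount(lengths)
    return hist * 2  # lower triangle is the mirror image


def recurrence(s: IBSSeries | np.ndarray, params: RQAParams) -> RecurrenceResult:
    """Recurrence rate and %DET of a series at embedding dimension m.

    ``R(i, j) = 1`` iff the embedded states are within ``epsilon``
    (Chebyshev reduces to |s_i - s_j| at m = 1); pairs with
    ``|i - j| < theiler_window`` are excluded from all counts, so the
    always-recurrent main diagonal never inflates either statistic.  %DET is
    the fraction of recurrent points lying on diagonal lines of length at
    least ``lmin``.
    """
    values = s.values if isinstance(s, IBSSeries) else np.asarray(s)
    values = values[np.isfinite(values)]
    if values.size < params.lmin:
        return RecurrenceResult(float("nan"), float("nan"),
                                np.zeros(2, dtype=np.int64), float("nan"),
                                degenerate=True)
    d = _distance_matrix(values, params.embedding_dim, params.theiler_window)
    if params.radius is None:
        sel = select_radius(values, params, _d=d)
        eps = sel.epsilon
        degenerate = sel.degenerate
    else:
        eps = params.radius
        degenerate = False
    rp = d <= eps
    n_rec = int(rp.sum())
    rr = _rr_from_d(d, eps, params.theiler_window)
    hist = _diagonal_line_hist(rp, params.theiler_window)
    lengths = np.arange(hist.size)
    det_points = int((hist[params.lmin:] * lengths[params.lmin:]).sum()) \
        if hist.size > params.lmin else 0
    pct_det = det_points / n_rec if n_rec else float("nan")
    return RecurrenceResult(rr=rr, pct_det=float(pct_det), line_hist=hist,
                            epsilon=float(eps), degenerate=degenerate)


# ---------------------------------------------------------------------------
# Permuted dyads and the feature table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyadPairing:
    kind: str  # "real" | "permuted"
    guide_id: str
    drawer_id: str


def build_permuted_dyads(cohort: Sequence[DyadPairing]) -> list[DyadPairing]:
    """All Guide x Drawer pairings of participants who never interacted.

    For n real dyads this yields exactly n*(n-1) permuted pairs and never
    reproduces a real pairing.
    """
    real = [p for p in cohort]
    if len(real) < 2:
        raise DataError("need at least 2 real dyads to permute")
    taken = {(p.guide_id, p.drawer_id) for p in real}
    out = []
    for g in real:
        for d in real:
            pair = (g.guide_id, d.drawer_id)
            if pair not in taken:
                out.append(DyadPairing("permuted", *pair))
    return out


def feature_table(entries: Iterable[dict], split: float,
                  rqa_params: RQAParams | None = None,
                  periods: tuple[str, ...] = ("pre", "post"),
                  features: tuple[str, ...] = ("level", "slope", "pct_det")
                  ) -> pd.DataFrame:
    """Long-format IBS feature table, one row per (dyad, ROI, chromophore, period).

    ``entries`` yields dicts with keys ``dyad_id, group, roi, chromophore,
    wtc`` where ``wtc`` is a *masked* :class:`WTCResult`.  Missing ROIs are
    simply absent from ``entries`` and therefore produce no rows.
    ``features`` selects which of the three features to compute (the
    permuted-dyad control needs levels only, and RQA dominates runtime).
    """
    rqa_params = rqa_params or RQAParams()
    rows = []
    for e in entries:
        w = e["wtc"]
        series = ibs_timeseries(w)
        for period in periods:
            try:
                level = ibs_level(w, period, split)
            except DataError:
                continue
            row = {
                "dyad_id": e["dyad_id"], "group": e["group"], "roi": e["roi"],
                "chromophore": e["chromophore"], "period": period,
                "dyad_type": e.get("dyad_type", "real"),
                "level": level,
            }
            if "slope" in features:
                row["slope"] = ibs_slope(series, period, split)
            if "pct_det" in features:
                cols = series.times < split if period == "pre" \
                    else series.times >= split
                sub = IBSSeries(series.times[cols], series.values[cols],
                                series.mask[cols], series.fs)
                rec = recurrence(sub, rqa_params)
                row.update(pct_det=rec.pct_det, rr=rec.rr, epsilon=rec.epsilon)
            rows.append(row)
    return pd.DataFrame(rows)


def rr_dispersion_report(features: pd.DataFrame,
                         tol: float = config.RQA_RR_TOL) -> pd.DataFrame:
    """Per-ROI spread of achieved recurrence rates across dyads.

    %DET values are only comparable across dyads when the radius selection
    achieved similar recurrence rates everywhere; rows whose RR range exceeds
    ``2 * tol`` are flagged.
    """
    g = features.groupby("roi")["rr"]
    rep = pd.DataFrame({"rr_min": g.min(), "rr_max": g.max(),
                        "rr_mean": g.mean()})
    rep["flagged"] = (rep["rr_max"] - rep["rr_min"]) > 2 * tol
    return rep.reset_index()
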