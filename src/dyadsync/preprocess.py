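"""Raw two-wavelength intensity to quality-controlled ROI hemoglobin series.

The chain (applied in this order):

1. intensity -> optical density, OD(t) = -ln(I(t) / mean_t I);
2. channel-wise motion-artifact detection, spline correction of flagged
   segments, then wavelet-based despiking of the whole series;
3. PCA filter of spatially global (systemic) components per wavelength;
4. modified Beer-Lambert conversion to O2Hb / HHb concentrations (uM);
5. channel quality check: a cardiac (~1 Hz) peak in the O2Hb power spectrum
   indicates good optode-scalp contact;
6. (visual inspection step in the original workflow; the spectral criterion
   above operationalizes it);
7. averaging good channels into the six ROIs, discarding ROIs with no good
   channel and excluding participants missing more than one ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import interpolate, ndimage, signal

from . import config
from .config import ConfigurationError


class DataError(ValueError):
    pass


@dataclass
class RawIntensityRecording:
    """Channels x wavelengths x time raw intensity, arbitrary units."""

    samples: np.ndarray  # (n_channels, 2, n_times), > 0
    fs: float
    participant_id: str
    role: str  # "Guide" | "Drawer"
    wavelengths: tuple = config.WAVELENGTHS
    roi_map: dict = field(default_factory=lambda: dict(config.DEFAULT_ROI_MAP))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[2] / self.fs


@dataclass
class PreprocessParams:
    sd_thresh: float = 20.0
    amp_thresh: float = 0.5
    t_motion: float = 0.5
    t_mask: float = 2.0
    spline_p: float = 0.99
    wavelet_iqr: float = 1.5
    pca_variance_fraction: float = 0.80
    pca_mode: str = "remove"  # the conventional systemic filter; "keep" available
    ppf: tuple = config.PPF
    extinction: tuple = config.EXTINCTION_MM_CM
    cardiac_band: tuple = (0.8, 1.2)
    psd_peak_prominence_ratio: float = 2.0

    def __post_init__(self):
        if not 0 < self.pca_variance_fraction < 1:
            raise ConfigurationError("pca_variance_fraction must be in (0, 1)")
        if any(v <= 0 for v in self.ppf):
            raise ConfigurationError("ppf entries must be positive")
        if self.pca_mode not in ("remove", "keep"):
            raise ConfigurationError("pca_mode must be 'remove' or 'keep'")


@dataclass
class OpticalDensitySeries:
    values: np.ndarray  # (n_channels, 2, n_times)
    fs: float


@dataclass
class ConcentrationSeries:
    o2hb: np.ndarray  # (n_channels, n_times), uM
    hhb: np.ndarray
    fs: float


@dataclass
class ChannelQualityReport:
    """Per-channel cardiac-peak verdicts (1-based channel keys)."""

    peak_present: dict
    peak_freq: dict
    prominence_ratio: dict
    verdict: dict  # channel -> "good" | "bad"

    def bad_channels(self) -> list:
        return [ch for ch, v in self.verdict.items() if v == "bad"]


@dataclass
class ROITimeSeries:
    o2hb: np.ndarray  # (n_rois, n_times); NaN rows for discarded ROIs
    hhb: np.ndarray
    roi_names: tuple
    status: dict  # roi -> "ok" | "discarded"
    fs: float
    participant_id: str
    excluded: bool  # participant-level verdict (> 1 missing ROI)


# ---------------------------------------------------------------------------

def intensity_to_od(raw: RawIntensityRecording) -> OpticalDensitySeries:
    """OD(t) = -ln(I(t) / mean_t I), per channel and wavelength."""
    samples = np.asarray(raw.samples, dtype=float)
    bad = np.nonzero((samples <= 0).any(axis=(1, 2)))[0]
    if bad.size:
        raise DataError(
            f"non-positive intensity in channel(s) {[int(b) + 1 for b in bad]}")
    ref = samples.mean(axis=2, keepdims=True)
    return OpticalDensitySeries(values=-np.log(samples / ref), fs=raw.fs)


def detect_motion_artifacts(od: OpticalDensitySeries,
                            p: PreprocessParams) -> np.ndarray:
    """Boolean artifact mask per channel (n_channels, n_times).

    A channel is flagged wherever, within a sliding window of ``t_motion``
    seconds, the signal excursion of either wavelength exceeds
    ``sd_thresh`` times that wavelength's overall SD or exceeds
    ``amp_thresh`` in absolute OD.  Flags are extended by ``t_mask``
    seconds on both sides.
    """
    v = od.values
    n_ch, _, n = v.shape
    w = max(2, int(round(p.t_motion * od.fs)))
    mask = np.zeros((n_ch, n), dtype=bool)
    for ch in range(n_ch):
        for wl in range(v.shape[1]):
            x = v[ch, wl]
            exc = (ndimage.maximum_filter1d(x, w, mode="nearest")
                   - ndimage.minimum_filter1d(x, w, mode="nearest"))
            sd = x.std()
            hit = exc > p.amp_thresh
            if sd > 0:
                hit |= exc > p.sd_thresh * sd
            mask[ch] |= hit
    pad = int(round(p.t_mask * od.fs))
    if pad > 0:
        structure = np.ones(2 * pad + 1, dtype=bool)
        for ch in range(n_ch):
            mask[ch] = ndimage.binary_dilation(mask[ch], structure=structure)
    return mask


def _runs(mask_1d: np.ndarray):
    padded = np.concatenate([[False], mask_1d, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def correct_spline(od: OpticalDensitySeries, mask: np.ndarray,
                   spline_p: float = 0.99) -> OpticalDensitySeries:
    """Spline motion correction of masked segments.

    Within each flagged segment the slow artifact trajectory is estimated by
    a smoothing spline (``spline_p`` in the 0..1 convention where 1 is
    interpolating; 0 degenerates to a linear fit) and subtracted, and the
    segment is re-leveled to the mean of the adjacent clean signal.
    Unmasked samples are untouched.
    """
    out = od.values.copy()
    fs = od.fs
    anchor_w = max(1, int(round(2.0 * fs)))
    for ch in range(out.shape[0]):
        segs = _runs(mask[ch])
        for a, b in segs:
            if b - a < 3:
                warnings.warn("masked segment shorter than 3 samples; passthrough")
                continue
            t = np.arange(a, b) / fs
            for wl in range(out.shape[1]):
                y = out[ch, wl, a:b]
                if spline_p <= 0:
                    coef = np.polyfit(t, y, 1)
                    fit = np.polyval(coef, t)
                else:
                    lam = (1.0 - spline_p) / spline_p
                    fit = interpolate.make_smoothing_spline(t, y, lam=lam)(t)
                if a > 0:
                    lo = max(0, a - anchor_w)
                    anchor = out[ch, wl, lo:a][~mask[ch, lo:a]]
                else:
                    hi = min(out.shape[2], b + anchor_w)
                    anchor = out[ch, wl, b:hi][~mask[ch, b:hi]]
                level = anchor.mean() if anchor.size else y.mean()
                out[ch, wl, a:b] = y - fit + level
    return OpticalDensitySeries(values=out, fs=fs)


def correct_wavelet(od: OpticalDensitySeries,
                    wavelet_iqr: float = 1.5,
                    wavelet: str = "db2",
                    max_transient_s: float = 4.0) -> OpticalDensitySeries:
    """Wavelet despiking: zero outlying detail coefficients and reconstruct.

    Detail coefficients farther than ``wavelet_iqr`` interquartile ranges
    from their level's median are treated as motion transients and zeroed.
    Only detail levels with characteristic durations up to
    ``max_transient_s`` are despiked: motion transients are broadband and
    dominate the fine scales, while the slow hemodynamics of interest
    (< 0.1 Hz) live in the coarse levels, which are left untouched so that
    a clean signal passes through essentially unaltered.
    """
    v = od.values
    out = np.empty_like(v)
    n = v.shape[2]
    max_level = max(1, int(np.floor(np.log2(max(2.0, max_transient_s * od.fs)))))
    for ch in range(v.shape[0]):
        for wl in range(v.shape[1]):
            x = v[ch, wl]
            if not np.isfinite(wavelet_iqr):
                out[ch, wl] = x
                continue
            coeffs = pywt.wavedec(x, wavelet, mode="periodization")
            n_detail = len(coeffs) - 1
            for j in range(1, min(max_level, n_detail) + 1):
                c = coeffs[-j]  # level j = finest details at j = 1
                q1, med, q3 = np.percentile(c, [25, 50, 75])
                iqr = q3 - q1
                c[np.abs(c - med) > wavelet_iqr * iqr] = 0.0
            rec = pywt.waverec(coeffs, wavelet, mode="periodization")
            out[ch, wl] = rec[:n]
    return OpticalDensitySeries(values=out, fs=od.fs)


def remove_systemic_pca(od: OpticalDensitySeries,
                        pca_variance_fraction: float = 0.80,
                        mode: str = "remove") -> OpticalDensitySeries:
    """PCA filter of spatially global components, per wavelength.

    The leading principal components of the channels x time matrix whose
    cumulative variance first reaches ``pca_variance_fraction`` are taken as
    the systemic (global physiological) subspace.  ``mode='remove'``
    reconstructs the signal without them (the conventional systemic filter);
    ``mode='keep'`` retains only them.
    """
    v = od.values
    if v.shape[0] < 2:
        warnings.warn("single channel: PCA filter is a passthrough")
        return OpticalDensitySeries(values=v.copy(), fs=od.fs)
    out = np.empty_like(v)
    for wl in range(v.shape[1]):
        x = v[:, wl, :]
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        u, sv, _ = np.linalg.svd(xc, full_matrices=False)
        var = sv ** 2
        cum = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        k = 0 if pca_variance_fraction <= 0 else int(np.searchsorted(
            cum, pca_variance_fraction) + 1)
        k = min(k, len(sv))
        uk = u[:, :k]
        proj = uk @ (uk.T @ xc)
        out[:, wl, :] = (xc - proj if mode == "remove" else proj) + mu
    return OpticalDensitySeries(values=out, fs=od.fs)


def extinction_matrix(p: PreprocessParams,
                      distance_cm: float = config.SD_DISTANCE_CM) -> np.ndarray:
    """Effective 2x2 system matrix A with OD = A @ [C_o2hb, C_hhb] (mM)."""
    eps = np.asarray(p.extinction, dtype=float)
    a = np.diag([distance_cm * f for f in p.ppf]) @ eps
    if abs(np.linalg.det(a)) < 1e-12:
        raise ConfigurationError("extinction matrix is singular")
    return a


def od_to_concentration(od: OpticalDensitySeries, p: PreprocessParams,
                        source_detector_distance: float = config.SD_DISTANCE_CM
                        ) -> ConcentrationSeries:
    """Modified Beer-Lambert inversion to O2Hb/HHb concentrations (uM)."""
    a = extinction_matrix(p, source_detector_distance)
    a_inv = np.linalg.inv(a)
    v = od.values  # (ch, wl, t)
    conc_mM = np.einsum("ij,cjt->cit", a_inv, v)
    return ConcentrationSeries(o2hb=conc_mM[:, 0, :] * 1000.0,
                               hhb=conc_mM[:, 1, :] * 1000.0, fs=od.fs)


def assess_channel_quality(conc: ConcentrationSeries,
                           p: PreprocessParams) -> ChannelQualityReport:
    """Cardiac-peak criterion on the Welch PSD of each channel's O2Hb.

    A channel is good iff the maximum PSD inside ``cardiac_band`` is at
    least ``psd_peak_prominence_ratio`` times the median PSD of the
    surrounding high-frequency band.  Absence of the ~1 Hz heartbeat peak
    indicates poor optode-scalp contact.
    """
    lo, hi = p.cardiac_band
    if conc.fs <= 2 * hi:
        raise ConfigurationError(
            f"fs = {conc.fs} Hz cannot resolve the cardiac band up to {hi} Hz")
    n = conc.o2hb.shape[1]
    if n / conc.fs < 60:
        raise DataError("need at least 60 s of data for a stable PSD")
    nperseg = min(int(round(30 * conc.fs)), n)
    peak_present, peak_freq, ratio, verdict = {}, {}, {}, {}
    for ch in range(conc.o2hb.shape[0]):
        f, pxx = signal.welch(conc.o2hb[ch], fs=conc.fs, nperseg=nperseg,
                              window="hann")
        in_band = (f >= lo) & (f <= hi)
        surround = (f >= 0.5) & (f <= min(2.5, 0.98 * conc.fs / 2)) & ~in_band
        peak = pxx[in_band].max()
        base = np.median(pxx[surround]) if surround.any() else np.median(pxx)
        r = peak / base if base > 0 else np.inf
        good = r >= p.psd_peak_prominence_ratio
        key = ch + 1
        peak_present[key] = bool(good)
        peak_freq[key] = float(f[in_band][np.argmax(pxx[in_band])])
        ratio[key] = float(r)
        verdict[key] = "good" if good else "bad"
    return ChannelQualityReport(peak_present, peak_freq, ratio, verdict)


def average_rois(conc: ConcentrationSeries, quality: ChannelQualityReport,
                 roi_map: dict, fs: float | None = None,
                 participant_id: str = "", roi_names: tuple = config.ROI_NAMES
                 ) -> ROITimeSeries:
    """Average good channels into ROIs; apply the exclusion rules.

    ROIs whose channels are all bad are discarded (NaN rows); a participant
    missing more than one ROI is flagged excluded.
    """
    n_ch = conc.o2hb.shape[0]
    missing = set(range(1, n_ch + 1)) - set(roi_map)
    if missing:
        raise DataError(f"roi_map does not cover channels {sorted(missing)}")
    fs = fs or conc.fs
    n = conc.o2hb.shape[1]
    o2hb = np.full((len(roi_names), n), np.nan)
    hhb = np.full((len(roi_names), n), np.nan)
    status = {}
    for i, roi in enumerate(roi_names):
        chans = [ch for ch, r in roi_map.items() if r == roi]
        good = [ch for ch in chans if quality.verdict.get(ch) == "good"]
        if good:
            idx = [ch - 1 for ch in good]
            o2hb[i] = conc.o2hb[idx].mean(axis=0)
            hhb[i] = conc.hhb[idx].mean(axis=0)
            status[roi] = "ok"
        else:
            status[roi] = "discarded"
    n_missing = sum(1 for s in status.values() if s == "discarded")
    return ROITimeSeries(o2hb=o2hb, hhb=hhb, roi_names=tuple(roi_names),
                         status=status, fs=fs, participant_id=participant_id,
                         excluded=n_missing > 1)


def preprocess_recording(raw: RawIntensityRecording,
                         params: PreprocessParams | None = None
                         ) -> tuple[ROITimeSeries, ChannelQualityReport]:
    """Run the full chain (steps 1-7) on one participant's recording."""
    params = params or PreprocessParams()
    od = intensity_to_od(raw)
    mask = detect_motion_artifacts(od, params)
    od = correct_spline(od, mask, params.spline_p)
    od = correct_wavelet(od, params.wavelet_iqr)
    od = remove_systemic_pca(od, params.pca_variance_fraction, params.pca_mode)
    conc = od_to_concentration(od, params)
    quality = assess_channel_quality(conc, params)
    rois = average_rois(conc, quality, raw.roi_map,
                        participant_id=raw.participant_id)
    return rois, quality
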