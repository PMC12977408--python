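"""Unit and property tests for the preprocessing chain (steps 1-7)."""

import numpy as np
import pytest

from dyadsync import config, preprocess, synth
from dyadsync.config import ConfigurationError
from dyadsync.preprocess import (
    ChannelQualityReport, ConcentrationSeries, DataError,
    OpticalDensitySeries, PreprocessParams, RawIntensityRecording,
    assess_channel_quality, average_rois, correct_spline, correct_wavelet,
    detect_motion_artifacts, extinction_matrix, intensity_to_od,
    od_to_concentration, preprocess_recording, remove_systemic_pca)

from conftest import short_params

FS = config.FS_NIRS


def _od(values, fs=FS):
    return OpticalDensitySeries(values=np.asarray(values, dtype=float), fs=fs)


def _raw(samples, fs=FS, pid="p0"):
    return RawIntensityRecording(samples=np.asarray(samples, dtype=float),
                                 fs=fs, participant_id=pid, role="Guide")


# ---------------------------------------------------------------------------
# Step 1: optical density
# ---------------------------------------------------------------------------

def test_od_constant_intensity_is_zero(rng):
    x = np.full((2, 2, 500), 3.7)
    od = intensity_to_od(_raw(x))
    assert np.allclose(od.values, 0.0)


def test_od_closed_form():
    # I(t) = I_mean * exp(-1) at one sample -> OD = 1 there
    n = 1000
    x = np.ones((1, 2, n))
    # craft a series whose mean is exactly 1 while one sample is exp(-1)
    x[0, :, 0] = np.exp(-1.0)
    x[0, :, 1] = 2.0 - np.exp(-1.0)
    od = intensity_to_od(_raw(x))
    assert od.values[0, 0, 0] == pytest.approx(1.0)


def test_od_matches_elementwise_oracle(rng):
    x = rng.uniform(0.5, 2.0, size=(3, 2, 400))
    od = intensity_to_od(_raw(x))
    ref = -np.log(x / x.mean(axis=2, keepdims=True))
    assert np.allclose(od.values, ref)


def test_od_rejects_nonpositive_intensity(rng):
    x = rng.uniform(0.5, 2.0, size=(3, 2, 100))
    x[1, 0, 50] = 0.0
    with pytest.raises(DataError, match=r"\[2\]"):
        intensity_to_od(_raw(x))


# ---------------------------------------------------------------------------
# Step 2a: motion detection
# ---------------------------------------------------------------------------

def test_motion_clean_signal_unflagged(rng):
    p = PreprocessParams()
    x = 0.01 * rng.standard_normal((2, 2, 2000))
    mask = detect_motion_artifacts(_od(x), p)
    assert not mask.any()


def test_motion_step_flagged_with_tmask_padding(rng):
    p = PreprocessParams()
    n = 4000
    x = 0.005 * rng.standard_normal((1, 2, n))
    step_at = 2000
    x[0, :, step_at:] += 1.0  # far above amp_thresh = 0.5 OD
    mask = detect_motion_artifacts(_od(x), p)
    assert mask[0, step_at]
    pad = int(round(p.t_mask * FS))
    w = int(round(p.t_motion * FS))
    assert mask[0, step_at - pad + 1: step_at + pad].all()
    # flags stay local: well away from the step nothing is masked
    assert not mask[0, : step_at - pad - w - 2].any()
    assert not mask[0, step_at + pad + w + 2:].any()


def test_motion_sd_criterion(rng):
    # small absolute spike on an even smaller-SD signal: triggers only the
    # relative (sd_thresh) criterion
    p = PreprocessParams(sd_thresh=5.0, amp_thresh=10.0)
    x = 1e-4 * rng.standard_normal((1, 2, 3000))
    x[0, :, 1500] += 0.01
    mask = detect_motion_artifacts(_od(x), p)
    assert mask[0, 1500]


def test_motion_all_zero_signal(rng):
    mask = detect_motion_artifacts(_od(np.zeros((2, 2, 500))),
                                   PreprocessParams())
    assert not mask.any()


# ---------------------------------------------------------------------------
# Step 2b: spline correction
# ---------------------------------------------------------------------------

def test_spline_empty_mask_is_identity(rng):
    x = rng.standard_normal((2, 2, 1000))
    out = correct_spline(_od(x), np.zeros((2, 1000), dtype=bool))
    assert np.array_equal(out.values, x)


def test_spline_reduces_step_artifact(rng):
    n = 3000
    clean = 0.01 * np.sin(2 * np.pi * 0.05 * np.arange(n) / FS)
    x = np.tile(clean, (1, 2, 1)).reshape(1, 2, n).copy()
    a, b = 1400, 1700
    x[0, :, a:b] += 0.8
    mask = np.zeros((1, n), dtype=bool)
    mask[0, a:b] = True
    out = correct_spline(_od(x), mask)
    resid_before = np.abs(x[0, 0] - clean)[a:b].mean()
    resid_after = np.abs(out.values[0, 0] - clean)[a:b].mean()
    assert resid_after < 0.2 * resid_before  # >= 80% artifact reduction
    # untouched outside the mask
    assert np.array_equal(out.values[0, :, :a], x[0, :, :a])
    assert np.array_equal(out.values[0, :, b:], x[0, :, b:])


def test_spline_p_zero_removes_linear_trend_exactly():
    n = 2000
    x = np.zeros((1, 2, n))
    a, b = 800, 1200
    t = np.arange(b - a)
    x[0, :, a:b] = 0.5 + 0.001 * t  # purely linear artifact
    mask = np.zeros((1, n), dtype=bool)
    mask[0, a:b] = True
    out = correct_spline(_od(x), mask, spline_p=0.0)
    assert np.allclose(out.values[0, 0, a:b], 0.0, atol=1e-9)


def test_spline_short_segment_warns_and_passes_through():
    n = 500
    x = np.zeros((1, 2, n))
    x[0, :, 250:252] = 5.0
    mask = np.zeros((1, n), dtype=bool)
    mask[0, 250:252] = True
    with pytest.warns(UserWarning, match="shorter than 3"):
        out = correct_spline(_od(x), mask)
    assert np.array_equal(out.values, x)


# ---------------------------------------------------------------------------
# Step 2c: wavelet despiking
# ---------------------------------------------------------------------------

def test_wavelet_infinite_iqr_is_identity(rng):
    x = rng.standard_normal((2, 2, 1024))
    out = correct_wavelet(_od(x), wavelet_iqr=np.inf)
    assert np.array_equal(out.values, x)


def test_wavelet_reduces_isolated_spike(rng):
    # isolated spike 20x the noise SD -> amplitude reduced >= 5-fold
    n = 4096
    noise_sd = 0.01
    clean = noise_sd * rng.standard_normal(n)
    x = clean.reshape(1, 1, n).repeat(2, axis=1).copy()
    x[0, :, 2000] += 20 * noise_sd
    out = correct_wavelet(_od(x))
    spike_after = abs(out.values[0, 0, 2000] - clean[2000])
    assert spike_after < 20 * noise_sd / 5


def test_wavelet_constant_passthrough():
    x = np.full((1, 2, 1024), 0.3)
    out = correct_wavelet(_od(x))
    assert np.allclose(out.values, 0.3, atol=1e-10)


def test_wavelet_preserves_clean_slow_signal():
    # clean band-limited Gaussian hemodynamics: < 5% RMS alteration
    n = 8192
    r = np.random.default_rng(0)
    f = np.fft.rfftfreq(n, 1 / FS)
    spec = r.standard_normal(f.size) + 1j * r.standard_normal(f.size)
    spec[(f < 0.01) | (f > 0.08)] = 0.0
    slow = np.fft.irfft(spec, n)
    slow *= 0.05 / slow.std()
    x = slow.reshape(1, 1, n).repeat(2, axis=1).copy()
    out = correct_wavelet(_od(x))
    rms_change = np.sqrt(np.mean((out.values[0, 0] - slow) ** 2))
    assert rms_change < 0.05 * np.sqrt(np.mean(slow ** 2))


# ---------------------------------------------------------------------------
# Step 3: PCA systemic filter
# ---------------------------------------------------------------------------

def test_pca_zero_fraction_is_identity(rng):
    x = rng.standard_normal((4, 2, 600))
    out = remove_systemic_pca(_od(x), pca_variance_fraction=0.0)
    assert np.allclose(out.values, x)


def test_pca_removes_rank_one_common_component(rng):
    n = 3000
    common = np.sin(2 * np.pi * 1.0 * np.arange(n) / FS)
    gains = rng.uniform(0.5, 2.0, size=8)
    local = 0.05 * rng.standard_normal((8, n))
    x = (gains[:, None] * common[None, :] + local)
    od = _od(np.stack([x, x], axis=1))
    out = remove_systemic_pca(od, pca_variance_fraction=0.8)
    y = out.values[:, 0, :]
    # the common component is gone: channels are now nearly uncorrelated
    c = np.corrcoef(y)
    off = c[~np.eye(8, dtype=bool)]
    assert np.abs(off).mean() < 0.2
    assert np.abs(np.corrcoef(y[0], common)[0, 1]) < 0.2


def test_pca_removed_variance_tracks_fraction(rng):
    # orthonormal-ish white channels: removing the top components removes
    # close to the requested variance fraction
    x = rng.standard_normal((10, 1, 5000))
    out = remove_systemic_pca(_od(x), pca_variance_fraction=0.5)
    removed = 1 - out.values.var() / x.var()
    assert removed == pytest.approx(0.5, abs=0.07)


def test_pca_keep_mode_complements_remove(rng):
    x = rng.standard_normal((6, 2, 800))
    od = _od(x)
    rem = remove_systemic_pca(od, 0.6, "remove").values
    keep = remove_systemic_pca(od, 0.6, "keep").values
    mu = x.mean(axis=2, keepdims=True)
    assert np.allclose(rem + keep, x + mu, atol=1e-8)


def test_pca_single_channel_warns_passthrough(rng):
    x = rng.standard_normal((1, 2, 300))
    with pytest.warns(UserWarning, match="single channel"):
        out = remove_systemic_pca(_od(x), 0.8)
    assert np.array_equal(out.values, x)


# ---------------------------------------------------------------------------
# Step 4: modified Beer-Lambert
# ---------------------------------------------------------------------------

def test_mbll_zero_od_zero_concentration():
    od = _od(np.zeros((2, 2, 100)))
    conc = od_to_concentration(od, PreprocessParams())
    assert np.allclose(conc.o2hb, 0.0) and np.allclose(conc.hhb, 0.0)


def test_mbll_identity_system():
    # identity extinction, ppf 1, distance 1 cm -> conc (mM) = OD
    p = PreprocessParams(ppf=(1.0, 1.0), extinction=((1.0, 0.0), (0.0, 1.0)))
    od = _od(np.full((1, 2, 10), 0.002))
    conc = od_to_concentration(od, p, source_detector_distance=1.0)
    assert np.allclose(conc.o2hb, 2.0)  # 0.002 mM = 2 uM
    assert np.allclose(conc.hhb, 2.0)


def test_mbll_matches_linear_solve(rng):
    p = PreprocessParams()
    od_vals = rng.standard_normal((3, 2, 50)) * 0.01
    conc = od_to_concentration(_od(od_vals), p)
    a = extinction_matrix(p)
    for ch in range(3):
        ref = np.linalg.solve(a, od_vals[ch]) * 1000.0
        assert np.allclose(conc.o2hb[ch], ref[0])
        assert np.allclose(conc.hhb[ch], ref[1])


def test_mbll_linearity(rng):
    p = PreprocessParams()
    od_vals = rng.standard_normal((2, 2, 30)) * 0.01
    c1 = od_to_concentration(_od(od_vals), p)
    c2 = od_to_concentration(_od(3.0 * od_vals), p)
    assert np.allclose(c2.o2hb, 3.0 * c1.o2hb)


def test_mbll_roundtrip_with_generator(rng):
    # synthetic intensities invert back to the generating concentrations
    n = 400
    o2hb = rng.standard_normal((4, n))
    hhb = rng.standard_normal((4, n))
    inten = synth.concentrations_to_intensity(o2hb, hhb, rng)
    od = intensity_to_od(_raw(inten))
    conc = od_to_concentration(od, PreprocessParams())
    # OD referencing shifts each channel by a constant (the log of the mean
    # intensity), so the centered series must match exactly
    def _center(a):
        return a - a.mean(axis=1, keepdims=True)
    assert np.allclose(_center(conc.o2hb), _center(o2hb), atol=1e-8)
    assert np.allclose(_center(conc.hhb), _center(hhb), atol=1e-8)


def test_singular_extinction_rejected():
    with pytest.raises(ConfigurationError, match="singular"):
        extinction_matrix(PreprocessParams(
            extinction=((1.0, 2.0), (2.0, 4.0))))


# ---------------------------------------------------------------------------
# Step 5: channel quality
# ---------------------------------------------------------------------------

def _conc_with_cardiac(rng, n_ch=2, n=None, cardiac=True):
    n = n or int(300 * FS)
    t = np.arange(n) / FS
    out = np.empty((n_ch, n))
    for ch in range(n_ch):
        x = 0.05 * rng.standard_normal(n)
        if cardiac:
            x = x + np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 6))
        out[ch] = x
    return ConcentrationSeries(o2hb=out, hhb=0.3 * out, fs=FS)


def test_quality_cardiac_channel_good(rng):
    rep = assess_channel_quality(_conc_with_cardiac(rng), PreprocessParams())
    assert all(v == "good" for v in rep.verdict.values())
    assert all(0.8 <= f <= 1.2 for f in rep.peak_freq.values())


def test_quality_white_noise_bad_50_seeds():
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        rep = assess_channel_quality(
            _conc_with_cardiac(rng, n_ch=1, cardiac=False),
            PreprocessParams())
        hits += rep.verdict[1] == "bad"
    assert hits >= 48  # >= 95% specificity for flat-spectrum channels


def test_quality_needs_60_seconds(rng):
    conc = _conc_with_cardiac(rng, n=int(30 * FS))
    with pytest.raises(DataError, match="60 s"):
        assess_channel_quality(conc, PreprocessParams())


def test_quality_needs_adequate_fs(rng):
    conc = _conc_with_cardiac(rng)
    conc.fs = 2.0
    with pytest.raises(ConfigurationError, match="cardiac band"):
        assess_channel_quality(conc, PreprocessParams())


# ---------------------------------------------------------------------------
# Step 7: ROI averaging and exclusion rules
# ---------------------------------------------------------------------------

def _quality(verdicts):
    return ChannelQualityReport(
        peak_present={c: v == "good" for c, v in verdicts.items()},
        peak_freq={c: 1.0 for c in verdicts},
        prominence_ratio={c: 5.0 for c in verdicts}, verdict=dict(verdicts))


def test_average_rois_identical_channels(rng):
    n = 100
    base = rng.standard_normal(n)
    conc = ConcentrationSeries(o2hb=np.tile(base, (16, 1)),
                               hhb=np.tile(-base, (16, 1)), fs=FS)
    q = _quality({c: "good" for c in range(1, 17)})
    roi = average_rois(conc, q, dict(config.DEFAULT_ROI_MAP))
    for i in range(6):
        assert np.allclose(roi.o2hb[i], base)
    assert not roi.excluded
    assert all(v == "ok" for v in roi.status.values())


def test_average_uses_only_good_channels(rng):
    conc = ConcentrationSeries(o2hb=np.zeros((16, 50)),
                               hhb=np.zeros((16, 50)), fs=FS)
    conc.o2hb[1] = 1.0   # ch 2 (L_dlPFC), good
    conc.o2hb[2] = 99.0  # ch 3 (L_dlPFC), bad -> must not contribute
    verd = {c: "good" for c in range(1, 17)}
    verd[3] = "bad"
    roi = average_rois(conc, _quality(verd), dict(config.DEFAULT_ROI_MAP))
    i = config.ROI_NAMES.index("L_dlPFC")
    assert np.allclose(roi.o2hb[i], 1.0 / 3)  # mean of channels 2, 4, 5


def test_all_bad_roi_discarded_single_missing_not_excluded():
    conc = ConcentrationSeries(o2hb=np.zeros((16, 50)),
                               hhb=np.zeros((16, 50)), fs=FS)
    verd = {c: "good" for c in range(1, 17)}
    verd[1] = "bad"  # L_fpPFC is the single-channel ROI
    roi = average_rois(conc, _quality(verd), dict(config.DEFAULT_ROI_MAP))
    assert roi.status["L_fpPFC"] == "discarded"
    assert np.isnan(roi.o2hb[config.ROI_NAMES.index("L_fpPFC")]).all()
    assert not roi.excluded  # one missing ROI is tolerated


def test_two_missing_rois_exclude_participant():
    conc = ConcentrationSeries(o2hb=np.zeros((16, 50)),
                               hhb=np.zeros((16, 50)), fs=FS)
    verd = {c: "good" for c in range(1, 17)}
    verd[1] = verd[6] = "bad"  # both single-channel fpPFC ROIs
    roi = average_rois(conc, _quality(verd), dict(config.DEFAULT_ROI_MAP))
    assert roi.excluded


def test_roi_map_must_cover_channels():
    conc = ConcentrationSeries(o2hb=np.zeros((16, 50)),
                               hhb=np.zeros((16, 50)), fs=FS)
    bad_map = {c: r for c, r in config.DEFAULT_ROI_MAP.items() if c != 9}
    with pytest.raises(DataError, match=r"\[9\]"):
        average_rois(conc, _quality({c: "good" for c in range(1, 17)}),
                     bad_map)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def _brickwall_band(x, fs, lo=0.01, hi=0.08):
    f = np.fft.rfftfreq(x.size, 1 / fs)
    spec = np.fft.rfft(x - x.mean())
    spec[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(spec, x.size)


def test_full_chain_deterministic(short_dyad):
    rec, _ = short_dyad
    r1, q1 = preprocess_recording(rec.guide)
    r2, q2 = preprocess_recording(rec.guide)
    assert np.array_equal(r1.o2hb, r2.o2hb)
    assert q1.verdict == q2.verdict


def test_full_chain_recovers_dynamics(full_dyad):
    # End-to-end invariant at the real protocol durations: after the whole
    # chain, the in-band (brick-wall filtered) recovered ROI O2Hb correlates
    # with the planted dynamics at >= 0.9 on average across ROIs.
    rec, truth = full_dyad
    p = synth.SimParams(n_dyads=1, rng_seed=5)
    for raw, role in ((rec.guide, "Guide"), (rec.drawer, "Drawer")):
        roi, quality = preprocess_recording(raw)
        assert not roi.excluded
        assert quality.bad_channels() == []
        cors = []
        for i in range(6):
            got = _brickwall_band(roi.o2hb[i], p.fs_nirs)
            want = _brickwall_band(truth.roi_o2hb[role][i], p.fs_nirs)
            cors.append(np.corrcoef(got, want)[0, 1])
        assert np.mean(cors) >= 0.9, f"{role}: {np.round(cors, 3)}"


def test_full_chain_flags_planted_bad_channels():
    p = short_params(bad_channel_prob=0.25, rng_seed=33)
    rec, truth = synth.generate_dyad(p, 0)
    planted = {ch for role, ch in truth.bad_channels if role == "Guide"}
    assert planted
    _, quality = preprocess_recording(rec.guide)
    flagged = set(quality.bad_channels())
    assert planted <= flagged
    # no false alarms on this record
    assert flagged == planted
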