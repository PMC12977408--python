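"""End-to-end orchestration: load -> preprocess -> coherence features ->
behavior -> inference, with config validation, caching, and provenance.

The pipeline is deterministic given the input files and configuration; the
only randomness lives in the synthetic generator.  Per-participant
preprocessing results are cached keyed by a hash of the input file and the
preprocessing configuration, so interrupted runs resume without
recomputation.  A JSON-lines log records one entry per stage per dyad, and a
RunRecord ties every output file to a content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as config_mod
from . import behavior as behavior_mod
from . import ibs, preprocess, stats
from .config import ConfigurationError


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def validate_config(cfg=None) -> dict:
    """Merge over defaults and check cross-field consistency."""
    out = config_mod.load_config(cfg)
    lo, hi = out["band"]
    if not 0 < lo < hi:
        raise ConfigurationError(f"band must satisfy 0 < f_lo < f_hi, got {out['band']}")
    if out["fs_nirs"] <= 0 or out["fs_behavior"] <= 0:
        raise ConfigurationError("sampling rates must be positive")
    if hi >= out["fs_nirs"] / 2:
        raise ConfigurationError(
            f"band upper edge {hi} must be below the Nyquist frequency "
            f"{out['fs_nirs'] / 2}")
    if not 0 < out["split_time"] < out["task_duration"]:
        raise ConfigurationError(
            f"split_time {out['split_time']} must lie inside the task "
            f"(0, {out['task_duration']})")
    if out["chromophore"] not in ("o2hb", "hhb"):
        raise ConfigurationError("chromophore must be 'o2hb' or 'hhb'")
    r = out["rqa"]
    if r["lmin"] < 2:
        raise ConfigurationError("rqa.lmin must be >= 2")
    if not 0 < r["target_rr"] < 1:
        raise ConfigurationError("rqa.target_rr must be in (0, 1)")
    if r["theiler_window"] < 0:
        raise ConfigurationError("rqa.theiler_window must be >= 0")
    p = out["preprocess"]
    if p["pca_mode"] not in ("remove", "keep"):
        raise ConfigurationError("preprocess.pca_mode must be remove|keep")
    if not 0 <= p["pca_variance_fraction"] <= 1:
        raise ConfigurationError("preprocess.pca_variance_fraction in [0,1]")
    return out


def _preprocess_params(cfg: dict) -> preprocess.PreprocessParams:
    p = cfg["preprocess"]
    return preprocess.PreprocessParams(
        sd_thresh=p["sd_thresh"], amp_thresh=p["amp_thresh"],
        t_motion=p["t_motion"], t_mask=p["t_mask"], spline_p=p["spline_p"],
        wavelet_iqr=p["wavelet_iqr"],
        pca_variance_fraction=p["pca_variance_fraction"],
        pca_mode=p["pca_mode"], cardiac_band=tuple(p["cardiac_band"]),
        psd_peak_prominence_ratio=p["psd_peak_prominence_ratio"])


# ---------------------------------------------------------------------------
# Manifest and file loading
# ---------------------------------------------------------------------------

@dataclass
class StudyManifest:
    root: Path
    rows: list  # one dict per dyad (paths relative to root)

    def __post_init__(self):
        ids = [r["dyad_id"] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise PipelineError("dyad ids in the manifest are not unique")
        for r in self.rows:
            for key, val in r.items():
                if key.endswith(("_nirs", "_speech")) or key in (
                        "trajectory", "reference", "meta"):
                    path = self.root / str(val)
                    if not path.exists():
                        raise PipelineError(
                            f"manifest references missing file {path}")


def load_manifest(path: str | Path) -> StudyManifest:
    path = Path(path)
    rows = pd.read_csv(path).to_dict("records")
    return StudyManifest(root=path.parent, rows=rows)


def _read_intensity(path: Path, roi_map=None) -> preprocess.RawIntensityRecording:
    df = pd.read_csv(path)
    channels = np.sort(df["channel"].unique())
    wavelengths = np.sort(df["wavelength"].unique())
    t = np.sort(df["time"].unique())
    fs = 1.0 / float(np.median(np.diff(t)))
    cube = np.empty((channels.size, wavelengths.size, t.size))
    for ci, ch in enumerate(channels):
        for wi, wl in enumerate(wavelengths):
            sub = df[(df.channel == ch) & (df.wavelength == wl)]
            cube[ci, wi] = sub.sort_values("time")["intensity"].to_numpy()
    return preprocess.RawIntensityRecording(
        samples=cube, fs=fs, participant_id=path.stem, role="",
        wavelengths=tuple(int(w) for w in wavelengths),
        roi_map=roi_map or dict(config_mod.DEFAULT_ROI_MAP))


def load_dyad(row: dict, root: Path, cfg: dict) -> dict:
    """Read one dyad's files back into in-memory objects."""
    meta = json.loads((root / row["meta"]).read_text())
    out = {"dyad_id": row["dyad_id"], "group": row["group"], "meta": meta}
    for role in ("guide", "drawer"):
        rec = _read_intensity(root / row[f"{role}_nirs"])
        rec.role = role.capitalize()
        rec.participant_id = f"{row['dyad_id']}_{role}"
        out[role] = rec
        sp = pd.read_csv(root / row[f"{role}_speech"])
        out[f"speech_{role}"] = behavior_mod.SpeechSeries(
            values=sp["speaking"].to_numpy(), fs=cfg["fs_behavior"],
            role=role.capitalize())
    tr = pd.read_csv(root / row["trajectory"])
    out["trajectory"] = behavior_mod.Trajectory(
        xy=tr[["x", "y"]].to_numpy(), fs=cfg["fs_behavior"])
    rf = pd.read_csv(root / row["reference"])
    out["reference"] = behavior_mod.ReferencePath(
        vertices=rf[["x", "y"]].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def _sha(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _file_hash(path: Path) -> str:
    return _sha(path.read_bytes())


@dataclass
class RunRecord:
    config: dict
    version: str
    seeds: dict = field(default_factory=dict)
    stage_hashes: dict = field(default_factory=dict)  # stage -> {name: hash}
    warnings: list = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> hash

    def to_dict(self) -> dict:
        return asdict(self)


class _Log:
    """JSON-lines run log: one record per stage per dyad."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, stage: str, dyad_id: str, status: str, **detail):
        rec = {"stage": stage, "dyad_id": dyad_id, "status": status, **detail}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _preprocess_participant(raw, params, cache_dir: Path, input_hash: str,
                            resume: bool):
    """Preprocess one participant with on-disk caching keyed by input hash."""
    cache = cache_dir / f"{raw.participant_id}.npz"
    sidecar = cache_dir / f"{raw.participant_id}.json"
    if resume and cache.exists() and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("input_hash") == input_hash:
            z = np.load(cache, allow_pickle=False)
            roi = preprocess.ROITimeSeries(
                o2hb=z["o2hb"], hhb=z["hhb"], fs=float(z["fs"]),
                roi_names=tuple(meta["roi_names"]),
                status=dict(meta["status"]),
                participant_id=raw.participant_id,
                excluded=bool(meta["excluded"]))
            return roi, meta["bad_channels"], True
    roi, quality = preprocess.preprocess_recording(raw, params)
    bad = [int(c) for c in quality.bad_channels()]
    np.savez_compressed(cache, o2hb=roi.o2hb, hhb=roi.hhb, fs=roi.fs)
    sidecar.write_text(json.dumps({
        "input_hash": input_hash, "roi_names": list(roi.roi_names),
        "status": dict(roi.status), "excluded": bool(roi.excluded),
        "bad_channels": bad}, sort_keys=True))
    return roi, bad, False


def _roi_series(roi: preprocess.ROITimeSeries, chromophore: str) -> np.ndarray:
    return roi.o2hb if chromophore == "o2hb" else roi.hhb


def run_pipeline(manifest: StudyManifest | str | Path, cfg=None,
                 out_dir: str | Path = "results",
                 resume: bool = True) -> RunRecord:
    """Run the full analysis over a study; returns the provenance record.

    Writes ``features.csv``, ``permuted_features.csv``, ``behavior.csv``,
    ``difficulty.csv``, ``results.json``, ``run_record.json`` and
    ``run_log.jsonl`` under ``out_dir``.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = load_manifest(manifest)
    cfg = validate_config(cfg)
    out = Path(out_dir)
    (out / "cache").mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")
    from . import __version__
    record = RunRecord(config=cfg, version=__version__)
    params = _preprocess_params(cfg)
    params_hash = _sha(json.dumps(cfg["preprocess"], sort_keys=True).encode())
    chromo = cfg["chromophore"]

    # ---- load + preprocess, with the exclusion flow ----------------------
    processed = {}  # dyad_id -> dict
    excl = {"bad_channels": {}, "discarded_rois": {}, "excluded_participants": [],
            "excluded_dyads": []}
    for row in manifest.rows:
        did = row["dyad_id"]
        try:
            dyad = load_dyad(row, manifest.root, cfg)
        except Exception as exc:
            raise PipelineError(f"stage load, dyad {did}: {exc}") from exc
        log.write("load", did, "ok")
        rois = {}
        dyad_excluded = False
        for role in ("guide", "drawer"):
            raw = dyad[role]
            input_hash = _sha(
                (manifest.root / row[f"{role}_nirs"]).read_bytes()
                + params_hash.encode())
            try:
                roi, bad, cached = _preprocess_participant(
                    raw, params, out / "cache", input_hash, resume)
            except Exception as exc:
                raise PipelineError(
                    f"stage preprocess, dyad {did} ({role}): {exc}") from exc
            record.stage_hashes.setdefault("preprocess", {})[
                raw.participant_id] = input_hash
            pid = raw.participant_id
            if bad:
                excl["bad_channels"][pid] = bad
            missing = [r for r, v in zip(roi.roi_names,
                                         np.isnan(roi.o2hb).all(axis=1)) if v]
            if missing:
                excl["discarded_rois"][pid] = missing
            if roi.excluded:
                excl["excluded_participants"].append(pid)
                dyad_excluded = True
            rois[role] = roi
            log.write("preprocess", did, "ok", participant=pid,
                      cached=cached, bad_channels=bad, discarded_rois=missing,
                      excluded=bool(roi.excluded))
        if dyad_excluded:
            excl["excluded_dyads"].append(did)
            log.write("exclude", did, "excluded",
                      reason="participant with >1 missing ROI")
            continue
        processed[did] = {**dyad, "roi_guide": rois["guide"],
                          "roi_drawer": rois["drawer"]}
    record.exclusions = excl
    if not processed:
        raise PipelineError("all dyads excluded; nothing to analyze")

    # ---- coherence features ---------------------------------------------
    first = next(iter(processed.values()))
    n = first["roi_guide"].o2hb.shape[1]
    fs = first["roi_guide"].fs
    lo, hi = cfg["band"]
    engine = ibs.CoherenceEngine(fs=fs, n=n, fmin=lo * 0.8, fmax=hi * 1.5)
    roi_names = first["roi_guide"].roi_names
    for did, d in processed.items():
        for role in ("guide", "drawer"):
            series = _roi_series(d[f"roi_{role}"], chromo)
            for ri, roi_name in enumerate(roi_names):
                if not np.isnan(series[ri]).all():
                    engine.add((did, role, roi_name), series[ri])

    def entries_for(pairings):
        for p in pairings:
            gd = processed[p.guide_id]
            split = gd["meta"]["events"]["disruption"]
            t0, t1 = (gd["meta"]["events"]["task_start"],
                      gd["meta"]["events"]["task_end"])
            win = ibs.BandWindow(lo, hi, t0, t1)
            for roi_name in roi_names:
                kg = (p.guide_id, "guide", roi_name)
                kd = (p.drawer_id, "drawer", roi_name)
                if kg not in engine._cache or kd not in engine._cache:
                    continue
                w = engine.coherence(kg, kd, pair_id=f"{p.guide_id}|{p.drawer_id}")
                yield {"dyad_id": f"{p.guide_id}|{p.drawer_id}"
                       if p.kind == "permuted" else p.guide_id,
                       "group": gd["group"], "roi": roi_name,
                       "chromophore": chromo, "dyad_type": p.kind,
                       "wtc": ibs.mask_and_band(w, win), "split": split}

    real_pairs = [ibs.DyadPairing("real", did, did) for did in processed]
    permuted_pairs = ibs.build_permuted_dyads(real_pairs) \
        if len(real_pairs) >= 2 else []
    split = first["meta"]["events"]["disruption"]
    rqa = ibs.RQAParams(embedding_dim=cfg["rqa"]["embedding_dim"],
                        target_rr=cfg["rqa"]["target_rr"],
                        lmin=cfg["rqa"]["lmin"],
                        theiler_window=cfg["rqa"]["theiler_window"])
    try:
        features = ibs.feature_table(entries_for(real_pairs), split, rqa)
        permuted = ibs.feature_table(entries_for(permuted_pairs), split, rqa,
                                     periods=("pre",), features=("level",))
    except Exception as exc:
        raise PipelineError(f"stage coherence: {exc}") from exc
    for did in processed:
        log.write("coherence", did, "ok")

    # ---- behavior --------------------------------------------------------
    beh_rows, diff_rows = [], []
    for did, d in processed.items():
        split_task = d["meta"]["events"]["disruption"] - \
            d["meta"]["events"]["task_start"]
        try:
            comm = behavior_mod.comm_features(d["speech_guide"],
                                              d["speech_drawer"], split_task)
            perf = behavior_mod.path_error(d["trajectory"], d["reference"],
                                           split_task)
        except Exception as exc:
            raise PipelineError(f"stage behavior, dyad {did}: {exc}") from exc
        for c, p in zip(comm, perf):
            beh_rows.append({
                "dyad_id": did, "group": d["group"], "period": c.period,
                "total_speaking_time": c.total_speaking_time,
                "speech_ratio": c.speech_ratio,
                "speech_ratio_valid": c.valid,
                "sum_error": p.sum_error, "mean_error": p.mean_error})
        for key, score in d["meta"].get("difficulty", {}).items():
            role, period = key.rsplit("_", 1)
            diff_rows.append({"dyad_id": did, "group": d["group"],
                              "individual": f"{did}_{role}",
                              "period": period, "difficulty": score})
        log.write("behavior", did, "ok")
    behavior_df = pd.DataFrame(beh_rows)
    difficulty_df = pd.DataFrame(diff_rows)

    # ---- inference -------------------------------------------------------
    reml = bool(cfg["stats"]["reml_lrt"])
    results = {"config": cfg, "n_dyads_analyzed": len(processed),
               "exclusions": excl}
    try:
        results["control_analyses"] = stats.run_control_analyses(
            features, behavior=behavior_df,
            permuted_features=permuted if len(permuted) else None,
            difficulty=difficulty_df if len(diff_rows) else None,
            reml_lrt=reml)
        results["ibs_hypothesis_tests"] = stats.run_ibs_hypothesis_tests(
            features, reml_lrt=reml)
        wide = behavior_df.pivot_table(index="dyad_id",
                                       columns="period", aggfunc="first")
        deltas = pd.DataFrame({
            "dyad_id": wide.index,
            "delta_speaking_time": (wide["total_speaking_time"]["post"]
                                    - wide["total_speaking_time"]["pre"]),
            "delta_speech_ratio": (wide["speech_ratio"]["post"]
                                   - wide["speech_ratio"]["pre"]),
        }).reset_index(drop=True)
        try:
            results["moderation"] = stats.run_moderation(features, deltas,
                                                         reml_lrt=reml)
        except stats.StatsError as exc:
            # the three-way moderation design needs more dyads than the
            # primary models; on small studies record it as skipped
            if "rank deficient" not in str(exc):
                raise
            results["moderation"] = {"skipped": str(exc)}
            record.warnings.append(f"moderation skipped: {exc}")
    except stats.StatsError as exc:
        raise PipelineError(f"stage stats: {exc}") from exc
    for did in processed:
        log.write("stats", did, "ok")
    results["rr_dispersion"] = ibs.rr_dispersion_report(
        features).to_dict("records") if "rr" in features.columns else []

    # ---- outputs ---------------------------------------------------------
    def _write_csv(name, df):
        path = out / name
        df.to_csv(path, index=False)
        record.outputs[name] = _file_hash(path)

    _write_csv("features.csv", features)
    _write_csv("permuted_features.csv", permuted)
    _write_csv("behavior.csv", behavior_df)
    _write_csv("difficulty.csv", difficulty_df)
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=1, sort_keys=True,
                                       default=_jsonable))
    record.outputs["results.json"] = _file_hash(results_path)
    record.stage_hashes["outputs"] = dict(record.outputs)
    rec_path = out / "run_record.json"
    rec_path.write_text(json.dumps(record.to_dict(), indent=1, sort_keys=True,
                                   default=_jsonable))
    return record


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
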