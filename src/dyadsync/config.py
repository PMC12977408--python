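"""Study-level defaults and physical constants.

All tunable parameters of the pipeline live here as plain data so that a
configuration file can override any of them and the effective values can be
mirrored to the run log.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

#: Nominal fNIRS sampling rate (Hz).
FS_NIRS = 7.81
#: Behavioral stream sampling rate (Hz): speech series and cursor trajectory.
FS_BEHAVIOR = 10.0
#: Rest period before and after the task (s).
REST_DURATION = 180.0
#: Collaborative task duration (s).
TASK_DURATION = 1200.0
#: Time of the mid-task disruption, seconds from task start.
DISRUPTION_OFFSET = 600.0
#: Frequency band retained for interbrain coherence (Hz): below cardiac
#: (~1 Hz), Mayer (~0.1 Hz) and respiratory (~0.25 Hz) physiological noise.
BAND = (0.01, 0.08)

#: Source-detector separation (cm).
SD_DISTANCE_CM = 3.0
#: Partial pathlength factor, one per wavelength (760, 850 nm).
PPF = (6.0, 6.0)
#: Measurement wavelengths (nm).
WAVELENGTHS = (760, 850)

# Molar extinction coefficients, 1/(mM*cm), rows = wavelength (760, 850 nm),
# columns = chromophore (O2Hb, HHb).  Values from the standard compilation of
# hemoglobin spectra used throughout the fNIRS literature; shipped as explicit
# configuration data.
EXTINCTION_MM_CM = (
    (1.4866, 3.8437),  # 760 nm
    (2.5264, 1.7986),  # 850 nm
)

#: Channel -> region-of-interest map for the 16-channel montage.  Channels are
#: 1-based.  Six ROIs: left/right frontopolar PFC, left/right dorsolateral
#: PFC, left/right temporoparietal junction.
ROI_NAMES = ("L_fpPFC", "R_fpPFC", "L_dlPFC", "R_dlPFC", "L_TPJ", "R_TPJ")
DEFAULT_ROI_MAP = {
    1: "L_fpPFC",
    6: "R_fpPFC",
    2: "L_dlPFC", 3: "L_dlPFC", 4: "L_dlPFC", 5: "L_dlPFC",
    7: "R_dlPFC", 8: "R_dlPFC", 9: "R_dlPFC", 10: "R_dlPFC",
    11: "L_TPJ", 12: "L_TPJ", 13: "L_TPJ",
    14: "R_TPJ", 15: "R_TPJ", 16: "R_TPJ",
}

#: Homotopic pairing: each ROI of the Guide is compared with the same ROI of
#: the Drawer.
HOMOTOPIC_PAIRS = tuple((r, r) for r in ROI_NAMES)

# Wavelet-coherence conventions (pinned; the normative COI convention
# tau(f) = sqrt(2)/f reproduces the 2 min 22 s edge effect at 0.01 Hz).
MORLET_OMEGA0 = 6.0
VOICES_PER_OCTAVE = 12
SCALE_SMOOTH_OCTAVES = 0.6

# Recurrence quantification defaults.
RQA_EMBEDDING_DIM = 1
RQA_TARGET_RR = 0.10
RQA_LMIN = 40
RQA_THEILER = 1
RQA_RR_TOL = 0.02

#: Full default configuration tree for the pipeline, overridable via YAML.
DEFAULT_CONFIG: dict[str, Any] = {
    "band": list(BAND),
    "split_time": DISRUPTION_OFFSET,
    "fs_nirs": FS_NIRS,
    "fs_behavior": FS_BEHAVIOR,
    "rest_duration": REST_DURATION,
    "task_duration": TASK_DURATION,
    "chromophore": "o2hb",
    "preprocess": {
        "sd_thresh": 20.0,
        "amp_thresh": 0.5,
        "t_motion": 0.5,
        "t_mask": 2.0,
        "spline_p": 0.99,
        "wavelet_iqr": 1.5,
        "pca_variance_fraction": 0.80,
        "pca_mode": "remove",
        "cardiac_band": [0.8, 1.2],
        "psd_peak_prominence_ratio": 2.0,
    },
    "rqa": {
        "embedding_dim": RQA_EMBEDDING_DIM,
        "target_rr": RQA_TARGET_RR,
        "lmin": RQA_LMIN,
        "theiler_window": RQA_THEILER,
    },
    "wtc": {
        "omega0": MORLET_OMEGA0,
        "voices_per_octave": VOICES_PER_OCTAVE,
    },
    "stats": {
        "reml_lrt": False,
        "alpha": 0.05,
    },
}


class ConfigurationError(ValueError):
    """Raised for contradictory or unknown configuration settings."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(
                f"unknown configuration key {here!r}; accepted keys at this "
                f"level: {sorted(base)}"
            )
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{here!r} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path_or_dict: Any = None) -> dict[str, Any]:
    """Merge a YAML file (or dict) over :data:`DEFAULT_CONFIG`."""
    if path_or_dict is None:
        override: dict = {}
    elif isinstance(path_or_dict, dict):
        override = path_or_dict
    else:
        with open(path_or_dict) as fh:
            override = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, override)
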