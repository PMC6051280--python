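"""Shared I/O: WAV and CSV readers/writers, config files, JSON helpers.

Audio goes through :mod:`scipy.io.wavfile` (16/24/32-bit PCM and float),
resampling through polyphase filtering.  Flows and trajectories are plain
CSV; configs are YAML; fit results and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

from .model import SimulationConfig, StateVector
from .parameters import ModelParameters
from .waveform import GlottalWaveform, VoiceRecording

__all__ = [
    "read_wav", "write_wav", "resample", "read_flow_csv", "write_flow_csv",
    "load_config", "save_config", "write_json",
]

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): 2 ** 7}


def read_wav(path, target_fs: float | None = 25000.0) -> VoiceRecording:
    """Read a mono WAV file as floats in [-1, 1], optionally resampling.

    Stereo files are rejected rather than silently mixed down.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected a mono recording")
    if data.dtype in _PCM_SCALE:
        x = data.astype(float) / _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype("uint8"):
            x -= 1.0
    else:
        x = data.astype(float)
    rec = VoiceRecording(x, float(fs))
    if target_fs is not None and abs(fs - target_fs) > 1e-9:
        rec = resample(rec, target_fs)
    return rec


def write_wav(path, samples: np.ndarray, fs: int) -> None:
    """Write floats in [-1, 1] as 16-bit PCM."""
    x = np.clip(np.asarray(samples, float), -1.0, 1.0)
    wavfile.write(path, int(fs), (x * (2 ** 15 - 1)).astype(np.int16))


def resample(rec: VoiceRecording, target_fs: float) -> VoiceRecording:
    from fractions import Fraction
    frac = Fraction(int(round(target_fs)), int(round(rec.fs))).limit_denominator(1000)
    y = resample_poly(rec.samples, frac.numerator, frac.denominator)
    return VoiceRecording(y, target_fs)


def read_flow_csv(path) -> GlottalWaveform:
    """Read a flow CSV with columns (t [s or ms], ug) or a single column.

    The sample rate is inferred from the time column spacing; a bare
    single-column file requires a ``# fs=...`` header comment.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fs = float(first.split("fs=")[1])
        u = pd.read_csv(path, comment="#", header=None).iloc[:, 0].to_numpy()
        return GlottalWaveform(u, fs, source="measured")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("flow CSV needs (t, ug) columns or an fs header")
    t = df.iloc[:, 0].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    fs = 1.0 / dt
    if fs < 1000.0:       # time axis in milliseconds
        fs *= 1000.0
    return GlottalWaveform(df.iloc[:, 1].to_numpy(float), fs, source="measured")


def write_flow_csv(path, flow: GlottalWaveform) -> None:
    t = np.arange(flow.samples.size) / flow.fs
    pd.DataFrame({"t": t, "ug": flow.samples}).to_csv(path, index=False)


def load_config(path) -> tuple[ModelParameters, SimulationConfig]:
    """Load model parameters and simulation settings from YAML/JSON."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    pdoc = doc.get("parameters", {})
    cdoc = dict(doc.get("simulation", {}))
    if "initial_state" in cdoc:
        cdoc["initial_state"] = StateVector(**cdoc["initial_state"])
    return ModelParameters(**pdoc), SimulationConfig(**cdoc)


def save_config(path, params: ModelParameters,
                config: SimulationConfig | None = None) -> None:
    doc: dict = {"parameters": params.to_dict()}
    if config is not None:
        doc["simulation"] = {"dt": config.dt, "duration": config.duration,
                             "transient": config.transient,
                             "divergence_bound": config.divergence_bound,
                             "hard_switch": config.hard_switch}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
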