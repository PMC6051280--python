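"""Lightweight containers for voice recordings and glottal flows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoiceRecording", "GlottalWaveform"]


@dataclass
class VoiceRecording:
    """Mono voice signal (dimensionless amplitude) at sample rate fs (Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("recording must be mono (1-D)")
        if self.fs < 8000:
            raise ValueError("sample rate must be >= 8 kHz")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.fs


@dataclass
class GlottalWaveform:
    """Uniformly sampled glottal flow (arbitrary flow units).

    ``source`` records provenance: "measured" for flows estimated by
    inverse filtering, "simulated" for model output and synthetic pulses.
    """

    samples: np.ndarray
    fs: float
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("flow must be 1-D")

    def zero_mean(self) -> "GlottalWaveform":
        return GlottalWaveform(self.samples - self.samples.mean(),
                               self.fs, self.source)
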