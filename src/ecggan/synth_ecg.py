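"""Deterministic synthetic single-lead ECG-like signals.

The generator renders a PQRST-shaped cardiac cycle as a sum of five
Gaussian bumps on the cycle phase — a static analogue of the classic
dynamical ECG models — plus optional seeded white noise and baseline
wander.  Its purpose is to give every other module a realistic,
reproducible stand-in for clinical recordings such as the MIT-BIH
arrhythmia records; it makes no claim of physiological fidelity.

Amplitudes are in millivolts.  Default wave parameters follow the
commonly used morphological constants (R wave 1 mV, positions spread
over roughly half the cycle around the R peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ecg_io import (
    DEFAULT_ADC_GAIN,
    ECGRecord,
    SequenceWindow,
    segment_windows,
)
from .errors import ValidationError

__all__ = ["SynthConfig", "generate_ecg", "generate_dataset", "to_ecg_record"]

# (amplitude mV, width rad, phase position rad) per wave; R centred at pi so
# no peak sits on the cycle boundary.
_DEFAULT_WAVES: Dict[str, Tuple[float, float, float]] = {
    "P": (0.12, 0.25, np.pi - np.pi / 3),
    "Q": (-0.10, 0.10, np.pi - np.pi / 12),
    "R": (1.00, 0.10, np.pi),
    "S": (-0.17, 0.10, np.pi + np.pi / 12),
    "T": (0.25, 0.40, np.pi + np.pi / 2),
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic ECG generator."""

    heart_rate: float = 60.0  # beats per minute
    sampling_rate: float = 360.0  # Hz, the MIT-BIH rate
    duration: float = 30.0  # seconds
    wave_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES)
    )
    noise_sd: float = 0.05  # mV, additive white Gaussian noise
    baseline_amplitude: float = 0.0  # mV, optional low-frequency wander
    baseline_freq: float = 0.25  # Hz
    seed: int = 0

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ValidationError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.sampling_rate <= 0:
            raise ValidationError(
                f"sampling_rate must be > 0, got {self.sampling_rate}"
            )
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.wave_params) != 5:
            raise ValidationError(
                f"expected exactly 5 waves, got {len(self.wave_params)}"
            )
        positions = [p for (_, _, p) in self.wave_params.values()]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValidationError(
                "wave angular positions must be strictly increasing"
            )
        if any(w <= 0 for (_, w, _) in self.wave_params.values()):
            raise ValidationError("wave widths must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def generate_ecg(config: SynthConfig) -> np.ndarray:
    """Render one noisy PQRST signal; deterministic for a fixed seed.

    Each cardiac cycle spans phase [0, 2*pi); the signal value at phase
    theta is sum_i a_i * exp(-(theta - theta_i)^2 / (2 * w_i^2)).
    """
    config.validate()
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    phase = 2.0 * np.pi * np.mod(t * config.heart_rate / 60.0, 1.0)
    signal = np.zeros(n)
    for amp, width, pos in config.wave_params.values():
        # Include neighbouring cycle images so wide waves wrap smoothly.
        for offset in (-2.0 * np.pi, 0.0, 2.0 * np.pi):
            signal += amp * np.exp(-((phase - pos - offset) ** 2) / (2.0 * width ** 2))
    if config.baseline_amplitude:
        signal += config.baseline_amplitude * np.sin(
            2.0 * np.pi * config.baseline_freq * t
        )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)
    return signal


def generate_dataset(
    config: SynthConfig,
    n_records: int,
    window_length: int,
    hop: Optional[int] = None,
) -> List[SequenceWindow]:
    """Generate `n_records` independent signals and window each of them.

    Record ``r`` uses seed ``config.seed + r`` so records are distinct but
    the whole dataset is reproducible from one seed.
    """
    if n_records < 1:
        raise ValidationError(f"n_records must be >= 1, got {n_records}")
    windows: List[SequenceWindow] = []
    for r in range(n_records):
        cfg = SynthConfig(
            heart_rate=config.heart_rate,
            sampling_rate=config.sampling_rate,
            duration=config.duration,
            wave_params=dict(config.wave_params),
            noise_sd=config.noise_sd,
            baseline_amplitude=config.baseline_amplitude,
            baseline_freq=config.baseline_freq,
            seed=config.seed + r,
        )
        signal = generate_ecg(cfg)
        windows.extend(
            segment_windows(
                signal, window_length, hop, source_record=f"synth-{r:03d}"
            )
        )
    return windows


def to_ecg_record(
    signal: np.ndarray,
    config: SynthConfig,
    record_id: str,
    adc_gain: float = DEFAULT_ADC_GAIN,
) -> ECGRecord:
    """Quantize a physical-unit signal into an integer-sample ECGRecord,
    suitable for WFDB export and round-trip tests."""
    raw = np.clip(np.round(np.asarray(signal) * adc_gain), -2048, 2047).astype(
        np.int32
    )
    return ECGRecord(
        record_id=record_id, sampling_rate=config.sampling_rate, leads=[raw]
    )
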