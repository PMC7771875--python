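"""Saturation-protocol and asymmetry-analysis parameters.

The default protocol mirrors a clinical 3 T CEST acquisition: B1 = 2 uT,
21 saturation offsets evenly spaced from -610 to +610 Hz, a pulse train of
five 100 ms hyperbolic-secant pulses with 61 ms gaps, and an unsaturated
reference volume (S0) acquired with far off-resonant (-150 ppm)
pre-saturation.  Frequency offsets are expressed in ppm relative to water,
positive downfield (the amide resonance sits at +3.5 ppm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError

#: Proton gyromagnetic ratio in MHz/T, used for Hz <-> ppm conversion.
GAMMA_MHZ_PER_T = 42.576


def hz_to_ppm(offsets_hz, field_strength_t: float):
    """Convert frequency offsets in Hz to ppm at the given field strength."""
    return np.asarray(offsets_hz, dtype=float) / (GAMMA_MHZ_PER_T * field_strength_t)


def ppm_to_hz(offsets_ppm, field_strength_t: float):
    """Convert frequency offsets in ppm to Hz at the given field strength."""
    return np.asarray(offsets_ppm, dtype=float) * GAMMA_MHZ_PER_T * field_strength_t


@dataclass(frozen=True)
class SaturationProtocol:
    """Acquisition parameters of the saturation experiment.

    Parameters
    ----------
    field_strength : float
        Static field strength in tesla.
    b1_amplitude : float
        Saturation amplitude in microtesla.
    pulse_count : int
        Number of saturation pulses in the train.
    pulse_duration_ms : float
        Duration of each pulse in milliseconds.
    interpulse_delay_ms : float
        Gap between consecutive pulses in milliseconds.
    offsets_hz : tuple of float
        Strictly increasing saturation offsets in Hz relative to water.
    s0_offset_ppm : float
        Nominal offset (ppm) of the reference acquisition; far off-resonant
        so that the reference is effectively unsaturated.
    """

    field_strength: float = 3.0
    b1_amplitude: float = 2.0
    pulse_count: int = 5
    pulse_duration_ms: float = 100.0
    interpulse_delay_ms: float = 61.0
    offsets_hz: tuple = field(
        default_factory=lambda: tuple(np.linspace(-610.0, 610.0, 21))
    )
    s0_offset_ppm: float = -150.0

    def __post_init__(self):
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")
        offs = np.asarray(self.offsets_hz, dtype=float)
        if offs.ndim != 1 or offs.size < 2:
            raise ValueError("offsets_hz must be a 1-D list of >= 2 offsets")
        if not np.all(np.diff(offs) > 0):
            raise ValueError("offsets_hz must be strictly increasing")
        object.__setattr__(self, "offsets_hz", tuple(float(o) for o in offs))

    @property
    def offsets_ppm(self) -> np.ndarray:
        """Saturation offsets converted to ppm (positive downfield)."""
        return hz_to_ppm(self.offsets_hz, self.field_strength)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_hz)

    def to_dict(self) -> dict:
        return asdict(self) | {"offsets_hz": list(self.offsets_hz)}

    @classmethod
    def from_dict(cls, d: dict) -> "SaturationProtocol":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown protocol keys: {sorted(unknown)}")
        d = dict(d)
        if "offsets_hz" in d:
            d["offsets_hz"] = tuple(d["offsets_hz"])
        return cls(**d)


@dataclass(frozen=True)
class AsymParams:
    """Parameters of the asymmetry window MTRasym(center +/- halfwidth).

    ``center_ppm`` is the amide offset (3.5 ppm), ``halfwidth_ppm`` half the
    integration range (0.4 ppm, so the window spans 0.8 ppm), and
    ``fine_grid_step_ppm`` the spline-interpolation step used both for the
    window quadrature and the B0 minimum search.
    """

    center_ppm: float = 3.5
    halfwidth_ppm: float = 0.4
    fine_grid_step_ppm: float = 0.01

    def __post_init__(self):
        if not 0 < self.halfwidth_ppm < self.center_ppm:
            raise ValueError("require 0 < halfwidth_ppm < center_ppm")
        if self.fine_grid_step_ppm <= 0:
            raise ValueError("fine_grid_step_ppm must be positive")

    @property
    def window_width_ppm(self) -> float:
        """Full integration range (Deltafreq), 2 * halfwidth."""
        return 2.0 * self.halfwidth_ppm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AsymParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown asymmetry keys: {sorted(unknown)}")
        return cls(**d)


def load_protocol_json(path) -> tuple[SaturationProtocol, AsymParams]:
    """Load a ``{"protocol": {...}, "asym": {...}}`` JSON config file.

    Missing sections fall back to the defaults above.
    """
    with open(Path(path)) as fh:
        cfg = json.load(fh)
    unknown = set(cfg) - {"protocol", "asym"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    proto = SaturationProtocol.from_dict(cfg.get("protocol", {}))
    asym = AsymParams.from_dict(cfg.get("asym", {}))
    return proto, asym
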