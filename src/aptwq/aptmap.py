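"""APTw maps: the voxelwise pipeline and the stored-intensity codec.

Scanner-side APTw maps are stored as 12-bit integers with the linear codec

    aptw_fraction = (C - 2048) / (scalefactor * 2000),   scalefactor = 10

so code 2048 is 0 and one code step is 1/20000 of S0 (0.005 percentage
points).  ``compute_aptw_map`` runs normalize -> B0-correct -> MTRasym on
every voxel of a 4-D offset stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError, UncorrectableSpectrumError
from .protocol import AsymParams, SaturationProtocol
from .zspectrum import correct_b0, mtr_asym_integral, normalize_zspectrum

#: Stored-integer zero point and scale of the intensity codec.
CODEC_OFFSET = 2048
CODEC_SCALEFACTOR = 10
CODEC_DENOM = CODEC_SCALEFACTOR * 2000  # codes per unit APTw fraction
CODE_MIN, CODE_MAX = 0, 4095


def encode_intensity(aptw_fraction):
    """Encode APTw fractions to stored integer codes.

    ``round(aptw * 20000) + 2048``, clamped to the 12-bit range [0, 4095]
    with a saturation warning.  Accepts scalars or arrays; NaN maps to the
    zero code with a warning (missing voxels carry no signal).
    """
    a = np.asarray(aptw_fraction, dtype=float)
    scalar = a.ndim == 0
    nan_mask = ~np.isfinite(a)
    if np.any(nan_mask):
        warnings.warn(
            f"{int(nan_mask.sum())} non-finite value(s) encoded as code {CODEC_OFFSET}",
            stacklevel=2,
        )
        a = np.where(nan_mask, 0.0, a)
    codes = np.round(a * CODEC_DENOM) + CODEC_OFFSET
    out_of_range = (codes < CODE_MIN) | (codes > CODE_MAX)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} value(s) outside the codec range clamped",
            stacklevel=2,
        )
        codes = np.clip(codes, CODE_MIN, CODE_MAX)
    codes = codes.astype(np.int64)
    return int(codes) if scalar else codes


def decode_intensity(stored):
    """Decode stored integer codes back to APTw fractions: (C - 2048)/20000."""
    c = np.asarray(stored)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("stored codes must be integers")
        c = np.round(c).astype(np.int64)
    if c.size and (c.min() < CODE_MIN or c.max() > CODE_MAX):
        raise ValueError(f"stored codes must lie in [{CODE_MIN}, {CODE_MAX}]")
    out = (c.astype(float) - CODEC_OFFSET) / CODEC_DENOM
    return float(out) if out.ndim == 0 else out


@dataclass
class APTwMap:
    """A voxel grid of APTw values as fractions of S0 (NaN = missing).

    ``qc`` summarizes voxels the pipeline could not quantify (invalid S0,
    no interior Z-spectrum minimum, clamped signals).
    """

    values: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 4.0)
    stored_dtype_offset: int = CODEC_OFFSET
    scalefactor: int = CODEC_SCALEFACTOR
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeMismatchError("APTwMap values must be a 3-D voxel grid")

    @property
    def percent(self) -> np.ndarray:
        """Map values in percent of S0."""
        return self.values * 100.0

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def encoded(self) -> np.ndarray:
        """The map as stored integer codes (missing voxels -> zero code)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return encode_intensity(self.values)


def compute_aptw_map(
    offset_stack: np.ndarray,
    s0_volume: np.ndarray,
    protocol: SaturationProtocol,
    params: AsymParams | None = None,
    *,
    voxel_size: tuple = (2.0, 2.0, 4.0),
) -> APTwMap:
    """Run the full per-voxel pipeline over a 4-D saturation-offset stack.

    ``offset_stack`` has shape ``(nx, ny, nz, n_offsets)`` and shares its
    voxel grid with ``s0_volume``.  Voxels with non-positive S0 or without a
    correctable Z-spectrum become NaN and are counted in ``qc``.
    """
    params = params or AsymParams()
    stack = np.asarray(offset_stack, dtype=float)
    s0 = np.asarray(s0_volume, dtype=float)
    if stack.ndim != 4 or stack.shape[-1] != protocol.n_offsets:
        raise ShapeMismatchError(
            f"offset stack must be (nx, ny, nz, {protocol.n_offsets}), got {stack.shape}"
        )
    if s0.shape != stack.shape[:3]:
        raise ShapeMismatchError(
            f"S0 grid {s0.shape} does not match stack grid {stack.shape[:3]}"
        )
    values = np.full(s0.shape, np.nan)
    n_s0_invalid = n_uncorrectable = 0
    for idx in np.ndindex(*s0.shape):
        if not (np.isfinite(s0[idx]) and s0[idx] > 0):
            n_s0_invalid += 1
            continue
        z = normalize_zspectrum(stack[idx], s0[idx], protocol, warn=False)
        try:
            zc = correct_b0(z, params)
        except UncorrectableSpectrumError:
            n_uncorrectable += 1
            continue
        values[idx] = mtr_asym_integral(zc, params)
    qc = {
        "n_voxels": int(s0.size),
        "n_s0_invalid": n_s0_invalid,
        "n_uncorrectable": n_uncorrectable,
        "n_missing": n_s0_invalid + n_uncorrectable,
    }
    return APTwMap(values=values, voxel_size=voxel_size, qc=qc)
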