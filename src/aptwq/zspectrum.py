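"""Z-spectrum normalization, B0 correction, and the MTRasym window integral.

A Z-spectrum is the water signal during off-resonance saturation, normalized
by the unsaturated reference S0, as a function of the saturation offset from
water.  The APTw score is the asymmetry of the spectrum about 0 ppm averaged
over a window centred on the amide resonance:

    APTw = { integral of S/S0 over [-c-h, -c+h]
             - integral of S/S0 over [+c-h, +c+h] } / (2 h)

with c = 3.5 ppm and h = 0.4 ppm by default, i.e. a window average of
P(-dw) - P(+dw) in units of S0.  Because the acquired offset grid is coarse
(~0.48 ppm spacing), the spectrum is interpolated with a cubic spline on a
fine grid (default 0.01 ppm) before both the B0 minimum search and the
window quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    CoverageError,
    InvalidReferenceError,
    ShapeMismatchError,
    UncorrectableSpectrumError,
)
from .protocol import AsymParams, SaturationProtocol

#: Upper bound accepted for normalized signals (slack for noise above S0).
SIGNAL_CEILING = 1.1


@dataclass(frozen=True)
class ZSpectrum:
    """A sampled, normalized saturation spectrum.

    ``offsets_ppm`` are strictly increasing, positive downfield of water;
    ``signals`` are S/S0 values in [0, 1.1].  ``b0_shift_ppm`` records the
    water-centre displacement removed by :func:`correct_b0` (0 until then).
    """

    offsets_ppm: np.ndarray
    signals: np.ndarray
    b0_shift_ppm: float = 0.0
    corrected: bool = False

    def __post_init__(self):
        offs = np.asarray(self.offsets_ppm, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if offs.ndim != 1 or offs.shape != sig.shape:
            raise ShapeMismatchError(
                f"offsets {offs.shape} and signals {sig.shape} must be equal-length 1-D"
            )
        if not np.all(np.diff(offs) > 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if np.any(~np.isfinite(sig)):
            raise ValueError("signals must be finite")
        if sig.min() < -1e-9 or sig.max() > SIGNAL_CEILING + 1e-9:
            raise ValueError(
                f"signals outside [0, {SIGNAL_CEILING}]: "
                f"min={sig.min():.4g}, max={sig.max():.4g}"
            )
        object.__setattr__(self, "offsets_ppm", offs)
        object.__setattr__(self, "signals", sig)

    def __len__(self) -> int:
        return self.offsets_ppm.size

    def mirrored(self) -> "ZSpectrum":
        """The spectrum reflected about 0 ppm (used in symmetry tests)."""
        return replace(
            self,
            offsets_ppm=-self.offsets_ppm[::-1],
            signals=self.signals[::-1],
        )


def normalize_zspectrum(
    raw_signals,
    s0: float,
    protocol: SaturationProtocol,
    *,
    warn: bool = True,
) -> ZSpectrum:
    """Normalize raw saturated intensities by the reference S0.

    Offsets are taken from ``protocol`` and converted Hz -> ppm.  Normalized
    signals above the noise ceiling (1.1) are clamped with a warning;
    negative raw intensities are rejected.

    Raises
    ------
    InvalidReferenceError
        If ``s0 <= 0``.
    ShapeMismatchError
        If the signal count differs from the protocol's offset count.
    """
    if not np.isfinite(s0) or s0 <= 0:
        raise InvalidReferenceError(f"reference signal S0 must be positive, got {s0!r}")
    raw = np.asarray(raw_signals, dtype=float)
    if raw.ndim != 1 or raw.size != protocol.n_offsets:
        raise ShapeMismatchError(
            f"expected {protocol.n_offsets} signals, got shape {raw.shape}"
        )
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    sig = raw / float(s0)
    n_clamped = int(np.count_nonzero(sig > SIGNAL_CEILING))
    if n_clamped:
        if warn:
            warnings.warn(
                f"{n_clamped} normalized signal(s) above {SIGNAL_CEILING} clamped",
                stacklevel=2,
            )
        sig = np.minimum(sig, SIGNAL_CEILING)
    return ZSpectrum(offsets_ppm=protocol.offsets_ppm, signals=sig)


def _fine_spline(z: ZSpectrum) -> CubicSpline:
    return CubicSpline(z.offsets_ppm, z.signals)


def _max_symmetry_center(
    z: ZSpectrum,
    spline: CubicSpline,
    d0_argmin: float,
    step: float,
    sym_halfwidth: float,
    refine_halfwidth: float = 0.3,
) -> float:
    """Refine the dip centre as the point of maximum flank symmetry.

    Candidate centres span ``d0_argmin +/- refine_halfwidth``; for each, the
    squared difference between the dip's two flanks is summed over offsets
    up to ``sym_halfwidth`` (shrunk if the sampled range is narrower).
    """
    cand = np.arange(d0_argmin - refine_halfwidth, d0_argmin + refine_halfwidth + step / 2, step)
    xmax = min(
        sym_halfwidth,
        z.offsets_ppm[-1] - cand.max(),
        cand.min() - z.offsets_ppm[0],
    )
    if xmax < 3 * step:  # dip too close to the edge: keep the argmin estimate
        return d0_argmin
    xs = np.arange(step, xmax + step / 2, step)
    flanks = spline(cand[:, None] + xs) - spline(cand[:, None] - xs)
    cost = np.einsum("ij,ij->i", flanks, flanks)
    return float(cand[int(np.argmin(cost))])


def correct_b0(
    z: ZSpectrum,
    params: AsymParams | None = None,
    *,
    search_halfwidth_ppm: float = 1.5,
    symmetry_halfwidth_ppm: float = 1.2,
) -> ZSpectrum:
    """Re-centre the spectrum so its direct-saturation minimum sits at 0 ppm.

    The spectrum is interpolated on a fine grid over
    ``[-search_halfwidth_ppm, +search_halfwidth_ppm]`` and the bottom of the
    dip is located by grid argmin.  Because the argmin of an interpolated
    coarse grid carries a sampling-phase-dependent bias, the water-centre
    displacement ``d0`` is then refined as the point of maximum local
    symmetry of the dip (the centre minimizing the summed squared
    difference between the two flanks out to ``symmetry_halfwidth_ppm``),
    evaluated on the same fine grid.  The spectrum is finally resampled at
    the nominal offsets shifted by ``+d0`` (the dip moves back to 0).

    Raises
    ------
    UncorrectableSpectrumError
        If the minimum lies on the search boundary (no interior dip).
    ValueError
        If ``z`` is already corrected.
    """
    if z.corrected:
        raise ValueError("spectrum is already B0-corrected")
    params = params or AsymParams()
    step = params.fine_grid_step_ppm
    lo = max(z.offsets_ppm[0], -search_halfwidth_ppm)
    hi = min(z.offsets_ppm[-1], search_halfwidth_ppm)
    if hi - lo < 2 * step:
        raise UncorrectableSpectrumError("search window does not cover the spectrum")
    n = int(round((hi - lo) / step)) + 1
    grid = np.linspace(lo, hi, n)
    spline = _fine_spline(z)
    values = spline(grid)
    imin = int(np.argmin(values))
    if imin in (0, n - 1):
        raise UncorrectableSpectrumError(
            "Z-spectrum minimum on the search boundary; no interior water dip"
        )
    d0 = _max_symmetry_center(z, spline, float(grid[imin]), step, symmetry_halfwidth_ppm)
    shifted = np.clip(spline(z.offsets_ppm + d0), 0.0, SIGNAL_CEILING)
    return ZSpectrum(
        offsets_ppm=z.offsets_ppm,
        signals=shifted,
        b0_shift_ppm=d0,
        corrected=True,
    )


def mtr_asym_integral(
    z: ZSpectrum,
    params: AsymParams | None = None,
    *,
    allow_uncorrected: bool = False,
) -> float:
    """The MTRasym window average: APTw as a dimensionless fraction of S0.

    Trapezoidal quadrature of the spline-interpolated spectrum over the
    downfield window ``[-c-h, -c+h]`` minus the upfield window
    ``[c-h, c+h]``, divided by the window width ``2 h``.  Multiply by 100
    for percent.

    Raises
    ------
    CoverageError
        If either window extends beyond the sampled offsets.
    ValueError
        If ``z`` is uncorrected and ``allow_uncorrected`` is False.
    """
    params = params or AsymParams()
    if not z.corrected and not allow_uncorrected:
        raise ValueError(
            "spectrum is not B0-corrected; pass allow_uncorrected=True to override"
        )
    c, h = params.center_ppm, params.halfwidth_ppm
    if -(c + h) < z.offsets_ppm[0] - 1e-12 or (c + h) > z.offsets_ppm[-1] + 1e-12:
        raise CoverageError(
            f"asymmetry window +/-[{c - h}, {c + h}] ppm outside sampled range "
            f"[{z.offsets_ppm[0]:.3f}, {z.offsets_ppm[-1]:.3f}] ppm"
        )
    n = int(round(params.window_width_ppm / params.fine_grid_step_ppm)) + 1
    pos_grid = np.linspace(c - h, c + h, n)
    neg_grid = -pos_grid[::-1]  # exact mirror so symmetric spectra cancel exactly
    spline = _fine_spline(z)
    i_pos = np.trapezoid(spline(pos_grid), pos_grid)
    i_neg = np.trapezoid(spline(neg_grid), neg_grid)
    return float((i_neg - i_pos) / params.window_width_ppm)
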