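"""Synthetic multi-pool Z-spectra and digital lesion phantoms.

The generator models each tissue class as a sum of Lorentzian saturation
lines — direct water saturation at 0 ppm, a broad semisolid
magnetization-transfer (MT) pool centred at -2.4 ppm, a relayed NOE pool at
-3.5 ppm, and the amide pool at +3.5 ppm:

    Z(d) = 1 - sum_i  A_i * (w_i/2)^2 / ((w_i/2)^2 + (d - c_i)^2)

Per-voxel B0 offsets shift the whole spectrum; Gaussian (optionally Rician)
noise is added on the normalized scale.  The amide amplitude of each shipped
tissue class is calibrated, by root-finding through the actual quantification
pipeline, so that the engine recovers that class's nominal APTw percentage
(generator/engine closure).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import PhantomSpecError
from .protocol import AsymParams, SaturationProtocol
from .zspectrum import correct_b0, mtr_asym_integral, normalize_zspectrum


@dataclass(frozen=True)
class LorentzianPool:
    """One saturation line: centre (ppm), amplitude (fraction of S0), FWHM (ppm)."""

    center_ppm: float
    amplitude: float
    fwhm_ppm: float

    def __post_init__(self):
        if not 0 <= self.amplitude < 1:
            raise ValueError("pool amplitude must lie in [0, 1)")
        if self.fwhm_ppm <= 0:
            raise ValueError("pool FWHM must be positive")

    def __call__(self, offsets_ppm) -> np.ndarray:
        hw2 = (self.fwhm_ppm / 2.0) ** 2
        d = np.asarray(offsets_ppm, dtype=float) - self.center_ppm
        return self.amplitude * hw2 / (hw2 + d * d)


@dataclass(frozen=True)
class TissuePoolSet:
    """A labelled set of Lorentzian pools describing one tissue class."""

    label: str
    pools: tuple

    def saturation(self, offsets_ppm) -> np.ndarray:
        """Total saturation fraction at the given offsets."""
        offs = np.asarray(offsets_ppm, dtype=float)
        total = np.zeros_like(offs)
        for p in self.pools:
            total += p(offs)
        return total

    def with_amide_amplitude(self, amplitude: float) -> "TissuePoolSet":
        """A copy with the +3.5 ppm pool's amplitude replaced."""
        pools = tuple(
            replace(p, amplitude=amplitude) if p.center_ppm == AMIDE_PPM else p
            for p in self.pools
        )
        return replace(self, pools=pools)

    @property
    def amide_amplitude(self) -> float:
        for p in self.pools:
            if p.center_ppm == AMIDE_PPM:
                return p.amplitude
        return 0.0


AMIDE_PPM = 3.5

#: Nominal engine output per tissue class (percent of S0).  Tumour classes
#: carry the cohort group averages the generator is meant to emulate;
#: normal-appearing white matter and fluid are centred at zero asymmetry.
CLASS_TARGET_PERCENT: dict[str, float] = {
    "NAWM": 0.0,
    "LGG": 1.49,
    "HGG": 2.60,
    "MET": 2.49,
    "CSF": 0.0,
}

#: Non-amide pool geometry per class (centre ppm, amplitude, FWHM ppm) plus
#: the amide FWHM; the amide amplitude is filled in by calibration.  Line
#: widths reflect saturation broadening at B1 = 2 uT (gamma*B1 ~ 85 Hz ~
#: 0.7 ppm at 3 T), which dominates the effective width of the exchanging
#: pools: the amide and NOE lines are ~2 and ~3.5 ppm wide, not their
#: intrinsic chemical-shift widths.
_BASE_POOLS: dict[str, dict] = {
    # water / MT / NOE triples, amide FWHM
    "NAWM": {
        "water": (0.0, 0.85, 2.0),
        "mt": (-2.4, 0.10, 50.0),
        "noe": (-3.5, 0.020, 3.5),
        "amide_fwhm": 2.0,
    },
    "LGG": {
        "water": (0.0, 0.86, 2.1),
        "mt": (-2.4, 0.09, 50.0),
        "noe": (-3.5, 0.018, 3.5),
        "amide_fwhm": 2.0,
    },
    "HGG": {
        "water": (0.0, 0.88, 2.2),
        "mt": (-2.4, 0.08, 50.0),
        "noe": (-3.5, 0.016, 3.5),
        "amide_fwhm": 2.0,
    },
    "MET": {
        "water": (0.0, 0.87, 2.2),
        "mt": (-2.4, 0.08, 50.0),
        "noe": (-3.5, 0.016, 3.5),
        "amide_fwhm": 2.0,
    },
    "CSF": {
        "water": (0.0, 0.95, 1.2),
        "mt": (-2.4, 0.005, 50.0),
        "noe": (-3.5, 0.002, 3.5),
        "amide_fwhm": 2.0,
    },
}


def _uncalibrated_pool_set(label: str, amide_amplitude: float) -> TissuePoolSet:
    try:
        base = _BASE_POOLS[label]
    except KeyError:
        raise ValueError(
            f"unknown tissue class {label!r}; known: {sorted(_BASE_POOLS)}"
        ) from None
    pools = tuple(
        [LorentzianPool(*base[k]) for k in ("water", "mt", "noe")]
        + [LorentzianPool(AMIDE_PPM, amide_amplitude, base["amide_fwhm"])]
    )
    return TissuePoolSet(label=label, pools=pools)


def _engine_aptw_percent(
    pools: TissuePoolSet, protocol: SaturationProtocol, params: AsymParams
) -> float:
    """Noiseless closed loop: simulate -> normalize -> B0-correct -> MTRasym."""
    raw, s0 = simulate_zspectrum(pools, protocol, noise_sd=0.0)
    z = normalize_zspectrum(raw, s0, protocol, warn=False)
    return 100.0 * mtr_asym_integral(correct_b0(z, params), params)


@functools.lru_cache(maxsize=None)
def _calibrated_amide_amplitude(label: str) -> float:
    """Amide amplitude for which the default engine recovers the class target."""
    protocol, params = SaturationProtocol(), AsymParams()
    target = CLASS_TARGET_PERCENT[label]

    def gap(a: float) -> float:
        return _engine_aptw_percent(_uncalibrated_pool_set(label, a), protocol, params) - target

    return float(brentq(gap, 0.0, 0.30, xtol=1e-10))


def make_pool_set(label: str) -> TissuePoolSet:
    """Return the calibrated pool set for a shipped tissue class.

    The amide amplitude is solved so that the quantification pipeline at its
    default protocol reproduces :data:`CLASS_TARGET_PERCENT` for the class.
    """
    if label not in _BASE_POOLS:
        raise ValueError(f"unknown tissue class {label!r}; known: {sorted(_BASE_POOLS)}")
    return _uncalibrated_pool_set(label, _calibrated_amide_amplitude(label))


def simulate_zspectrum(
    pools: TissuePoolSet,
    protocol: SaturationProtocol,
    *,
    b0_shift_ppm: float = 0.0,
    noise_sd: float = 0.0,
    rng=None,
    noise_model: str = "gaussian",
    s0_value: float = 1000.0,
    s0_mode: str = "ideal",
) -> tuple[np.ndarray, float]:
    """Simulate raw saturated intensities and the S0 reference.

    ``b0_shift_ppm`` displaces the spectrum (the water dip appears at
    ``+b0_shift_ppm``).  ``noise_sd`` is the noise standard deviation as a
    fraction of S0; ``noise_model`` is ``"gaussian"`` or ``"rician"``.
    ``s0_mode="presaturated"`` applies the tissue's residual saturation at
    the far off-resonant reference offset instead of an ideal reference.
    Deterministic for a fixed ``rng`` seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    offs = protocol.offsets_ppm - b0_shift_ppm
    sat = pools.saturation(offs)
    if np.any(sat >= 1.0):
        raise PhantomSpecError(
            f"pool set {pools.label!r} saturates >= 100% of S0 at some offset"
        )
    signals = s0_value * (1.0 - sat)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        sd = noise_sd * s0_value
        if noise_model == "gaussian":
            signals = signals + rng.normal(0.0, sd, size=signals.shape)
        elif noise_model == "rician":
            re = signals + rng.normal(0.0, sd, size=signals.shape)
            im = rng.normal(0.0, sd, size=signals.shape)
            signals = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")
        signals = np.maximum(signals, 0.0)
    if s0_mode == "ideal":
        s0 = s0_value
    elif s0_mode == "presaturated":
        s0 = float(s0_value * (1.0 - pools.saturation(protocol.s0_offset_ppm - b0_shift_ppm)))
    else:
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    return signals, s0


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: centre in voxel indices, radius in millimetres
    (so anisotropic voxels are handled), tissue class, and an optional
    concentric necrotic (fluid-like, excluded) core.

    Lesions must fit in-plane; through-plane clipping by a thin slab is
    allowed (as for real acquisitions with few slices).
    """

    center: tuple
    radius_mm: float
    tissue: str = "HGG"
    necrotic_core_radius_mm: float = 0.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if not 0 <= self.necrotic_core_radius_mm < self.radius_mm:
            raise ValueError("necrotic core must be smaller than the lesion")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a digital lesion phantom."""

    grid_shape: tuple = (32, 32, 4)
    voxel_size: tuple = (2.0, 2.0, 4.0)
    background: str = "NAWM"
    lesions: tuple = ()
    b0_coeffs: tuple = (0.0, 0.0, 0.0, 0.0)  # ppm: const + x, y, z linear terms
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass
class PhantomBundle:
    """Everything a downstream stage needs: the 4-D offset stack, the S0
    volume, lesion/exclusion masks, and a per-lesion truth table."""

    offset_stack: np.ndarray
    s0_volume: np.ndarray
    lesion_mask: np.ndarray
    exclusion_mask: np.ndarray
    truth: pd.DataFrame
    spec: PhantomSpec


def _sphere_mask(shape, center, radius_mm, voxel_size) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) * vs) ** 2 for g, c, vs in zip(grids, center, voxel_size))
    return d2 <= radius_mm**2


def b0_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth per-voxel B0 offset map (ppm) from the polynomial coefficients,
    over coordinates normalized to [-1, 1] along each axis."""
    nx, ny, nz = spec.grid_shape
    ax = [np.linspace(-1, 1, n) if n > 1 else np.zeros(1) for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c0, cx, cy, cz = spec.b0_coeffs
    return c0 + cx * X + cy * Y + cz * Z


def build_lesion_phantom(
    spec: PhantomSpec, protocol: SaturationProtocol | None = None
) -> PhantomBundle:
    """Render a lesion phantom: per-voxel class -> simulated Z-spectrum with
    the voxel's B0 offset, plus masks and a truth table.

    Necrotic cores are rendered as fluid (CSF-like) tissue and marked in the
    exclusion mask.  Overlapping lesions or lesions crossing the grid
    boundary raise :class:`PhantomSpecError`.
    """
    protocol = protocol or SaturationProtocol()
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size
    for les in spec.lesions:
        if les.tissue not in _BASE_POOLS:
            raise PhantomSpecError(f"unknown lesion tissue {les.tissue!r}")
        for c, n, v in zip(les.center[:2], shape[:2], vs[:2]):  # in-plane only
            if c * v - les.radius_mm < 0 or c * v + les.radius_mm > (n - 1) * v:
                raise PhantomSpecError(
                    f"lesion at {les.center} extends outside the grid in-plane"
                )
    for i, a in enumerate(spec.lesions):
        for b in spec.lesions[i + 1 :]:
            dist = np.sqrt(
                sum(((p - q) * v) ** 2 for p, q, v in zip(a.center, b.center, vs))
            )
            if dist < a.radius_mm + b.radius_mm:
                raise PhantomSpecError(f"lesions at {a.center} and {b.center} overlap")

    class_map = np.full(shape, spec.background, dtype=object)
    lesion_mask = np.zeros(shape, dtype=bool)
    exclusion_mask = np.zeros(shape, dtype=bool)
    truth_rows = []
    for i, les in enumerate(spec.lesions):
        sphere = _sphere_mask(shape, les.center, les.radius_mm, vs)
        class_map[sphere] = les.tissue
        lesion_mask |= sphere
        if les.necrotic_core_radius_mm > 0:
            core = _sphere_mask(shape, les.center, les.necrotic_core_radius_mm, vs)
            class_map[core] = "CSF"
            exclusion_mask |= core
        truth_rows.append(
            {
                "lesion_id": i,
                "tissue": les.tissue,
                "center": les.center,
                "radius_mm": les.radius_mm,
                "expected_aptw_percent": CLASS_TARGET_PERCENT[les.tissue],
            }
        )

    b0 = b0_field(spec)
    offs = protocol.offsets_ppm
    s0_value = 1000.0
    stack = np.empty(shape + (offs.size,), dtype=float)
    flat_classes = class_map.ravel()
    flat_b0 = b0.ravel()
    flat_stack = stack.reshape(-1, offs.size)
    for label in np.unique(flat_classes):
        pools = make_pool_set(str(label))
        sel = np.flatnonzero(flat_classes == label)
        # (n_voxels, n_offsets) offsets seen by each voxel after its B0 shift
        local = offs[None, :] - flat_b0[sel, None]
        sat = pools.saturation(local)
        if np.any(sat >= 1.0):
            raise PhantomSpecError(f"pool set {label!r} saturates >= 100% of S0")
        flat_stack[sel] = s0_value * (1.0 - sat)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stack += rng.normal(0.0, spec.noise_sd * s0_value, size=stack.shape)
        np.maximum(stack, 0.0, out=stack)
    s0_volume = np.full(shape, s0_value)
    truth = pd.DataFrame(
        truth_rows,
        columns=["lesion_id", "tissue", "center", "radius_mm", "expected_aptw_percent"],
    )
    return PhantomBundle(
        offset_stack=stack,
        s0_volume=s0_volume,
        lesion_mask=lesion_mask,
        exclusion_mask=exclusion_mask,
        truth=truth,
        spec=spec,
    )
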