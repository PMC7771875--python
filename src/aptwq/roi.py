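"""Maximal-signal ROI search and ROI statistics on APTw maps.

The clinical reading places one circular 10-pixel ROI at the location of
highest APTw signal within lesional tissue, avoiding hemorrhagic, cystic
and necrotic areas; mean, max, min and range (max - min) are extracted in
percent.  Here the "circular ROI of size n pixels" is an n-member digital
disc (the n in-plane voxels nearest the centre), and the manual placement is
replaced by an exhaustive per-slice search for the admissible centre whose
disc mean is maximal — a deterministic, reproducible surrogate for the
radiologist's placement, and labelled as such in outputs.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .aptmap import APTwMap
from .errors import PlacementError


@functools.lru_cache(maxsize=None)
def disc_offsets(n_pixels: int) -> tuple:
    """The n-member digital disc: (row, col) offsets of the ``n`` voxels
    nearest the origin by Euclidean distance, ties broken by (row, col)
    ascending.  Deterministic and cached.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    r = int(np.ceil(np.sqrt(n_pixels))) + 1
    candidates = [
        (dr * dr + dc * dc, dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
    ]
    candidates.sort()
    return tuple((dr, dc) for _, dr, dc in candidates[:n_pixels])


@dataclass(frozen=True)
class RoiPlacement:
    """A placed disc: slice index, centre voxel, and its member offsets."""

    slice_index: int
    center: tuple
    offsets: tuple
    method: str = "automated maximal-mean search"

    @property
    def n_pixels(self) -> int:
        return len(self.offsets)

    def member_voxels(self) -> list:
        """(row, col, slice) triples of the disc members."""
        r0, c0 = self.center
        return [(r0 + dr, c0 + dc, self.slice_index) for dr, dc in self.offsets]


@dataclass(frozen=True)
class ROIStats:
    """Mean / max / min / range APTw over an ROI, in percent."""

    mean: float
    max: float
    min: float

    def __post_init__(self):
        if not (self.min <= self.mean + 1e-12 and self.mean <= self.max + 1e-12):
            raise ValueError("ROI statistics must satisfy min <= mean <= max")

    @property
    def range(self) -> float:
        return self.max - self.min

    def as_dict(self) -> dict:
        return {"mean": self.mean, "max": self.max, "min": self.min, "range": self.range}


def _admissible_value_grid(aptw: APTwMap, lesion_mask, exclusion_mask):
    lesion = np.asarray(lesion_mask, dtype=bool)
    if lesion.shape != aptw.values.shape:
        raise ValueError("lesion mask grid does not match the map grid")
    if exclusion_mask is None:
        excl = np.zeros_like(lesion)
    else:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != lesion.shape:
            raise ValueError("exclusion mask grid does not match the map grid")
    admissible = lesion & ~excl & np.isfinite(aptw.values)
    return admissible


def find_max_roi(
    aptw: APTwMap,
    lesion_mask,
    exclusion_mask=None,
    n_pixels: int = 10,
) -> RoiPlacement:
    """Exhaustively search all slices for the admissible disc of ``n_pixels``
    voxels with the highest mean APTw.

    A centre is admissible when every disc member lies inside the image,
    inside the lesion mask, outside the exclusion mask, and carries a finite
    value.  Ties are broken by lowest slice, then row, then column.

    Raises
    ------
    PlacementError
        If no admissible placement exists (mask too small for the disc).
    """
    admissible = _admissible_value_grid(aptw, lesion_mask, exclusion_mask)
    offsets = disc_offsets(n_pixels)
    nr, nc, ns = aptw.values.shape
    best = None  # (mean, slice, row, col)
    values = np.where(admissible, aptw.values, np.nan)
    for s in range(ns):
        vs = values[:, :, s]
        # stack of disc-member views; NaN marks inadmissible members
        acc = np.full((nr, nc), 0.0)
        ok = np.ones((nr, nc), dtype=bool)
        for dr, dc in offsets:
            shifted = np.full((nr, nc), np.nan)
            r_lo, r_hi = max(0, -dr), min(nr, nr - dr)
            c_lo, c_hi = max(0, -dc), min(nc, nc - dc)
            shifted[r_lo:r_hi, c_lo:c_hi] = vs[
                r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc
            ]
            ok &= np.isfinite(shifted)
            acc += np.where(np.isfinite(shifted), shifted, 0.0)
        if not ok.any():
            continue
        means = np.where(ok, acc / n_pixels, -np.inf)
        idx = np.unravel_index(np.argmax(means), means.shape)
        cand = (means[idx], s, int(idx[0]), int(idx[1]))
        # strict ">" keeps the earliest (lowest slice, row, col) maximum
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        raise PlacementError(
            f"no admissible placement for a {n_pixels}-pixel disc in the lesion mask"
        )
    _, s, r, c = best
    return RoiPlacement(slice_index=s, center=(r, c), offsets=offsets)


def roi_stats(aptw: APTwMap, placement: RoiPlacement) -> ROIStats:
    """Mean/max/min (percent) over exactly the placed disc members.

    Raises
    ------
    ValueError
        If any member voxel is outside the grid or missing-valued; the
        offending voxels are listed.
    """
    vals = []
    bad = []
    shape = aptw.values.shape
    for r, c, s in placement.member_voxels():
        if not (0 <= r < shape[0] and 0 <= c < shape[1] and 0 <= s < shape[2]):
            bad.append((r, c, s))
            continue
        v = aptw.values[r, c, s]
        if not np.isfinite(v):
            bad.append((r, c, s))
        else:
            vals.append(v)
    if bad:
        raise ValueError(f"ROI member voxels missing or out of grid: {bad}")
    arr = 100.0 * np.asarray(vals)
    return ROIStats(mean=float(arr.mean()), max=float(arr.max()), min=float(arr.min()))


def whole_lesion_stats(
    aptw: APTwMap,
    lesion_mask,
    slice_index: int,
    exclusion_mask=None,
) -> ROIStats:
    """Single-slice whole-lesion variant: statistics over all admissible
    lesion voxels on one slice (exclusion mask subtracted)."""
    admissible = _admissible_value_grid(aptw, lesion_mask, exclusion_mask)
    sel = admissible[:, :, slice_index]
    if not sel.any():
        raise PlacementError(f"no admissible lesion voxels on slice {slice_index}")
    arr = 100.0 * aptw.values[:, :, slice_index][sel]
    return ROIStats(mean=float(arr.mean()), max=float(arr.max()), min=float(arr.min()))
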