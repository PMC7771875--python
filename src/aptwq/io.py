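"""NIfTI-1 input/output for volumes, masks, and APTw maps (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .aptmap import APTwMap, decode_intensity, encode_intensity

_CODEC_TAG = "APTw int16 codec offset=2048 scale=10"


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(data: np.ndarray, path, voxel_size=(2.0, 2.0, 4.0)) -> None:
    """Write a 3-D or 4-D float volume (or mask) as NIfTI-1."""
    data = np.asarray(data)
    dtype = np.uint8 if data.dtype == bool else np.float32
    img = nib.Nifti1Image(data.astype(dtype), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    """Read a NIfTI volume as a float array."""
    return np.asarray(nib.load(str(path)).get_fdata())


def save_aptw_nifti(aptw: APTwMap, path, *, codec: bool = False) -> None:
    """Write an APTw map as NIfTI: float32, or int16 via the stored-intensity
    codec (flagged in the header description)."""
    aff = _affine(aptw.voxel_size)
    if codec:
        img = nib.Nifti1Image(aptw.encoded().astype(np.int16), aff)
        img.header["descrip"] = _CODEC_TAG.encode()
    else:
        img = nib.Nifti1Image(aptw.values.astype(np.float32), aff)
        img.header["descrip"] = b"APTw fraction of S0"
    nib.save(img, str(path))


def load_aptw_nifti(path) -> APTwMap:
    """Read an APTw map, transparently decoding the int16 codec variant."""
    img = nib.load(str(Path(path)))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.get_fdata())
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    if descrip == _CODEC_TAG:
        values = decode_intensity(np.round(data).astype(np.int64))
    else:
        values = data
    return APTwMap(values=values, voxel_size=voxel_size)


__all__ = [
    "save_volume",
    "load_volume",
    "save_aptw_nifti",
    "load_aptw_nifti",
    "encode_intensity",
]
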