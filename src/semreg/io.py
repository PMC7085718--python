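"""File formats: greyscale PNG images, indexed-PNG label maps, NIfTI
displacement fields (with a JSON sidecar recording units/axis conventions)
and self-describing ``.npz`` checkpoints embedding the full configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "save_image",
    "load_image",
    "save_labels",
    "load_labels",
    "save_field",
    "load_field",
    "save_checkpoint",
    "load_checkpoint",
]


def save_image(path, image: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit greyscale PNG (or float NIfTI)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.eye(4)), path)
    else:
        iio.imwrite(path, np.clip(np.asarray(image) * 255.0, 0, 255).astype(np.uint8))


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        return np.asarray(nib.load(path).get_fdata(), dtype=np.float32)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr.astype(np.float32) / 255.0)


def save_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("label ids must fit in uint8 for indexed PNG")
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(labels.astype(np.int16), np.eye(4)), path)
    else:
        iio.imwrite(path, labels.astype(np.uint8))


def load_labels(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        return np.asarray(nib.load(path).get_fdata()).astype(np.int64)
    return iio.imread(path).astype(np.int64)


_FIELD_HEADER = {
    "channels": ["dx (columns)", "dy (rows)"],
    "units": "pixels of the full-resolution image",
    "convention": "backward warping: output(x) = source(x + D(x)); 0-based, origin top-left",
}


def save_field(path, field: np.ndarray) -> None:
    """(2, H, W) float32 field -> NIfTI with channels as the 4th dim + sidecar."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError("field must be (2, H, W)")
    vol = field.transpose(1, 2, 0)[:, :, None, :]  # H, W, 1, 2
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    Path(str(sidecar) + ".json").write_text(json.dumps(_FIELD_HEADER, indent=1))


def load_field(path) -> np.ndarray:
    vol = np.asarray(nib.load(path).get_fdata(), dtype=np.float32)
    return vol[:, :, 0, :].transpose(2, 0, 1)


def save_checkpoint(path, arrays_by_group: dict[str, list[np.ndarray]], config: dict) -> None:
    """Store network weights grouped by module plus the full config."""
    payload = {"__config__": np.frombuffer(json.dumps(config).encode(), dtype=np.uint8)}
    for group, arrays in arrays_by_group.items():
        for i, arr in enumerate(arrays):
            payload[f"{group}:{i:03d}"] = arr
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[dict[str, list[np.ndarray]], dict]:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        groups: dict[str, list[np.ndarray]] = {}
        for key in sorted(k for k in data.files if k != "__config__"):
            group, _ = key.rsplit(":", 1)
            groups.setdefault(group, []).append(data[key])
    return groups, config
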