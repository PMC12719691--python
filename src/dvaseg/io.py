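"""File formats and run configuration.

Volumes and masks travel as NIfTI (.nii/.nii.gz) with voxel spacing taken
from the header; manifests, metric tables and grade/rank records as CSV;
search results and analysis reports as JSON.  A run configuration is a
single YAML file with one section per pipeline stage and a global seed that
is fanned out into named per-module substreams.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .metrics import BinaryMask, VolumeImage


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def read_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(values, spacing)


def write_volume(vol: VolumeImage, path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32),
                             _affine(vol.spacing)), str(path))


def read_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    uniq = np.unique(values)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError(
            f"{path}: mask files must be binary (values in {{0,1}}); "
            f"found values {uniq[:8]}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(values.astype(np.uint8), spacing)


def write_mask(mask: BinaryMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8),
                             _affine(mask.spacing)), str(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTIONS = ("metric", "model", "search", "synthesis", "analysis")
_GLOBAL_KEYS = ("seed", "output_dir")


def default_config() -> dict:
    return {"seed": 0, "output_dir": "runs/default",
            **{s: {} for s in _SECTIONS}}


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - set(_SECTIONS) - set(_GLOBAL_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = default_config()
    for key, value in cfg.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            out[key] = dict(value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(validate_config(cfg), fh, sort_keys=True)


def substream_seed(global_seed: int, name: str) -> int:
    """Derive a named, reproducible per-module seed from the global seed."""
    key = zlib.crc32(name.encode())
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def write_search_result(result, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "assignment": result.best_partition.assignment.tolist(),
        "K": result.best_partition.K,
        "score": result.best_score,
        "n_evaluations": result.n_evaluations,
        "history": [list(h) for h in result.history],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
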