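"""Standard-format I/O: NIfTI volumes, CSV tables, JSON results.

NIfTI round-trips preserve grid, spacing and values; CSV round-trips
preserve feature names, order and values to 1e-12.  Result JSON files are
checked against a minimal shipped schema before writing and after reading.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import NoduleParams, SyntheticVolume


class FormatError(ValueError):
    pass


def write_volume(vol: SyntheticVolume, path) -> None:
    """Write HU grid and spacing as .nii/.nii.gz (spacing in the affine)."""
    affine = np.diag([*vol.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.hu_grid.astype(np.float32), affine), str(path))


def write_mask(vol: SyntheticVolume, path) -> None:
    affine = np.diag([*vol.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(path))


def read_volume(vol_path, mask_path) -> SyntheticVolume:
    """Read a volume+mask pair back into a SyntheticVolume container."""
    try:
        img = nib.load(str(vol_path))
        msk = nib.load(str(mask_path))
    except Exception as exc:  # nibabel raises various per-format errors
        raise FormatError(f"cannot read NIfTI pair {vol_path}, {mask_path}: "
                          f"{exc}") from exc
    hu = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.asarray(msk.dataobj) > 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    params = NoduleParams(class_label="benign", equiv_diameter=10.0)
    return SyntheticVolume(hu, spacing, mask, params)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0)
    if table.isna().any().any():
        rows = table.index[table.isna().any(axis=1)].tolist()
        cols = table.columns[table.isna().any()].tolist()
        raise FormatError(
            f"{path}: missing values at rows {rows[:5]}, columns {cols[:5]}")
    return table


RESULTS_SCHEMA = {
    "required": {
        "seed": int,
        "counts": dict,
        "models": list,
    },
    "model_required": {
        "features": list,
        "weights": list,
        "cutoff": (int, float),
        "train_auc": (int, float),
        "j_index": (int, float),
    },
}


def validate_results(results: dict) -> None:
    """Check a results payload against the shipped minimal schema."""
    for key, typ in RESULTS_SCHEMA["required"].items():
        if key not in results:
            raise FormatError(f"results missing required key {key!r}")
        if not isinstance(results[key], typ):
            raise FormatError(f"results key {key!r} has wrong type")
    for model in results["models"]:
        for key, typ in RESULTS_SCHEMA["model_required"].items():
            if key not in model or not isinstance(model[key], typ):
                raise FormatError(f"model entry missing/invalid key {key!r}")


def write_results(results: dict, path) -> None:
    validate_results(results)
    Path(path).write_text(json.dumps(results, indent=2, default=_jsonable))


def read_results(path) -> dict:
    results = json.loads(Path(path).read_text())
    validate_results(results)
    return results


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
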