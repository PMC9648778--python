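"""NIfTI and CSV round-trips for phantom scans and attenuation tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import S1_COLUMNS, AortaScan, PhantomParams
from .plaque import make_plaque_law

__all__ = [
    "save_scan_nifti",
    "load_volume_nifti",
    "write_s1_table",
    "read_s1_table",
    "load_params",
]


def _affine(pixel_spacing_mm: float, slice_thickness_mm: float) -> np.ndarray:
    return np.diag([pixel_spacing_mm, pixel_spacing_mm, slice_thickness_mm, 1.0])


def save_scan_nifti(scan: AortaScan, out_dir, pixel_spacing_mm: float = 0.7) -> dict[str, Path]:
    """Write image / aorta mask / plaque truth as NIfTI-1 volumes.

    Slice axis becomes the NIfTI third axis; spacing is carried in the
    affine.  Returns the written paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(pixel_spacing_mm, scan.meta.slice_thickness)
    paths = {}
    stacks = {
        "image": scan.image.astype(np.int16),
        "aorta_mask": scan.aorta_mask.astype(np.uint8),
        "plaque_truth": scan.plaque_truth_mask.astype(np.uint8),
    }
    for role, arr in stacks.items():
        vol = np.moveaxis(arr, 0, -1)  # (ny, nx, n_slices)
        path = out_dir / f"{scan.meta.scan_id}_{role}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), str(path))
        paths[role] = path
    levels = pd.DataFrame(
        {"slice_index": range(len(scan.vertebral_labels)), "vertebral_level": scan.vertebral_labels}
    )
    lv_path = out_dir / f"{scan.meta.scan_id}_levels.csv"
    levels.to_csv(lv_path, index=False)
    paths["levels"] = lv_path
    return paths


def load_volume_nifti(path) -> np.ndarray:
    """Read a NIfTI volume back into slice-first (n_slices, ny, nx) order."""
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    return np.moveaxis(vol, -1, 0)


def write_s1_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in S1_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing canonical columns: {missing}")
    table.to_csv(path, index=False)


def read_s1_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in S1_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing canonical columns: {missing}")
    return table


def load_params(path) -> PhantomParams:
    """Build PhantomParams from a flat YAML mapping.

    Keys mirror the dataclass fields; ``plaque_law`` is given as a
    three-element mapping (offset_HU, median_HU, p99_HU).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "plaque_law" in raw:
        law = raw.pop("plaque_law")
        raw["plaque_law"] = make_plaque_law(
            law.get("offset_HU", 130.0), law.get("median_HU", 256.0), law.get("p99_HU", 1400.0)
        )
    for key in ("lesions_per_scan", "lesion_arc_deg", "lesion_radial_band",
                "vessel_radius_px", "slice_shape", "levels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomParams(**raw)
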