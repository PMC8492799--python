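"""Readers/writers (NIfTI + JSON sidecars, CSV, YAML) and volume summaries.

All images are NIfTI-1 (.nii.gz) with per-volume acquisition times in a
JSON sidecar ``{"times_s": [...], "sequence": "fast|slow", "baseline_count": n}``;
affines are carried through untouched (voxel-index space, pre-registered
masks). Tables are UTF-8 CSV with '.' decimal and units embedded in column
headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .quantify import DynamicSeries


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def save_series(path, series: DynamicSeries, affine: np.ndarray | None = None
                ) -> None:
    """Write a dynamic series as 4D NIfTI (4th dim = time) + JSON sidecar."""
    save_nifti(path, series.data, affine)
    sidecar = {"times_s": [float(t) for t in series.times],
               "sequence": series.sequence_tag,
               "baseline_count": int(series.baseline_count)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_series(path) -> DynamicSeries:
    data, _ = load_nifti(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return DynamicSeries(data=data, times=np.asarray(meta["times_s"]),
                         sequence_tag=meta["sequence"],
                         baseline_count=int(meta["baseline_count"]))


def save_labels(path, labels: np.ndarray, affine: np.ndarray | None = None
                ) -> None:
    save_nifti(path, np.asarray(labels, dtype=np.int16), affine)


def load_labels(path) -> np.ndarray:
    data, _ = load_nifti(path)
    return np.asarray(np.rint(data), dtype=np.int16)


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def save_yaml(path, payload: Mapping[str, Any]) -> None:
    Path(path).write_text(yaml.safe_dump(dict(payload), sort_keys=False))


def load_yaml(path) -> dict[str, Any]:
    return yaml.safe_load(Path(path).read_text()) or {}


@dataclass
class VolumeSummary:
    """Region volumes and intracranial-volume-normalized ratios."""

    voxel_counts: dict[str, int]
    volumes_mm3: dict[str, float]
    icv_voxels: int
    icv_mm3: float
    relative_brain_volume: float
    relative_wmh_volume: float
    relative_volumes: dict[str, float]
    icv_covers_all: bool


def compute_relative_volumes(masks: Mapping[str, np.ndarray],
                             icv_mask: np.ndarray,
                             voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
                             brain_regions: tuple[str, ...] = ("NAWM", "WMH",
                                                              "CGM", "DGM"),
                             wmh_region: str = "WMH") -> VolumeSummary:
    """Normalize structure volumes to the intracranial volume (ICV).

    relative volume = structure volume / ICV; relative brain volume uses
    the union of the tissue regions, relative WMH volume the WMH mask.
    Whether the ICV mask covers every structure voxel is reported, not
    enforced.
    """
    icv_mask = np.asarray(icv_mask, dtype=bool)
    icv_voxels = int(icv_mask.sum())
    if icv_voxels == 0:
        raise ValueError("ICV mask is empty")
    voxel_mm3 = float(np.prod(voxel_dims))

    counts = {name: int(np.asarray(m, dtype=bool).sum())
              for name, m in masks.items()}
    volumes = {name: c * voxel_mm3 for name, c in counts.items()}
    relative = {name: c / icv_voxels for name, c in counts.items()}

    brain = np.zeros_like(icv_mask)
    for name in brain_regions:
        if name in masks:
            brain |= np.asarray(masks[name], dtype=bool)
    covered = all(np.all(icv_mask | ~np.asarray(m, dtype=bool))
                  for m in masks.values())
    rel_wmh = counts.get(wmh_region, 0) / icv_voxels
    return VolumeSummary(
        voxel_counts=counts, volumes_mm3=volumes, icv_voxels=icv_voxels,
        icv_mm3=icv_voxels * voxel_mm3,
        relative_brain_volume=int(brain.sum()) / icv_voxels,
        relative_wmh_volume=rel_wmh, relative_volumes=relative,
        icv_covers_all=covered)
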