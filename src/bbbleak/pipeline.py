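"""End-to-end pipeline: simulate -> quantify -> leakage -> cognition -> associate.

Runs the full chain on a digital phantom and synthetic cohort, writes every
intermediate product to the output directory, and records a manifest with
the seed, configuration and a SHA-256 checksum per output file so reruns
are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as bio
from .associate import run_association_grid
from .cognition import compute_compounds
from .cohort import CohortConfig, generate_cohort, sample_leakage_table
from .leakage import DEFAULT_BIN_WIDTH, region_leakage
from .phantom import (REGION_LABELS, SINUS, TISSUE_REGIONS, PhantomConfig,
                      simulate_acquisition)
from .protocol import AcquisitionProtocol
from .quantify import (DynamicSeries, concentration_from_signal, extract_vif,
                       merge_dual_sequences, patlak_fit)


@dataclass
class PipelineConfig:
    """Configuration of a full phantom-plus-cohort run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_width: float = DEFAULT_BIN_WIDTH
    fit_window: tuple[float, float] | None = None
    seed: int = 0
    out_dir: str = "bbbleak_out"


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all five stages and return the output manifest.

    Stage failures abort with the stage named; outputs written so far are
    preserved. Reruns with the same config and seed are bit-identical
    (checksummed in the manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": [],
                                "files": {}, "qc": {}}
    phantom_cfg = PhantomConfig(**{**config.phantom.to_dict(),
                                   "seed": config.seed})
    stage = "simulate"
    try:
        fast_sim, slow_sim, t1_map, masks, truth = simulate_acquisition(
            phantom_cfg, config.protocol)
        fast = DynamicSeries(fast_sim.data, fast_sim.times, "fast",
                             fast_sim.baseline_count)
        slow = DynamicSeries(slow_sim.data, slow_sim.times, "slow",
                             slow_sim.baseline_count)
        bio.save_series(out / "dynamic_fast.nii.gz", fast)
        bio.save_series(out / "dynamic_slow.nii.gz", slow)
        bio.save_nifti(out / "t1_map.nii.gz", t1_map)
        bio.save_labels(out / "labels.nii.gz", truth.labels)
        bio.save_nifti(out / "ki_true.nii.gz", truth.ki_map)
        manifest["stages"].append(stage)

        stage = "quantify"
        tissue_mask = np.isin(truth.labels,
                              [REGION_LABELS[r] for r in TISSUE_REGIONS])
        conc_fast, qc_fast = concentration_from_signal(
            fast, t1_map, config.protocol, mask=tissue_mask | masks[SINUS])
        conc_slow, qc_slow = concentration_from_signal(
            slow, t1_map, config.protocol, mask=tissue_mask | masks[SINUS])
        merged = merge_dual_sequences(conc_fast, conc_slow)
        vif = extract_vif(merged, masks[SINUS], config.protocol.hematocrit)
        ki_map = patlak_fit(merged, vif, tissue_mask,
                            fit_window=config.fit_window)
        bio.save_nifti(out / "ki.nii.gz", ki_map.ki)
        bio.save_nifti(out / "vp.nii.gz", ki_map.vp)
        bio.save_nifti(out / "r2.nii.gz", ki_map.r2)
        manifest["qc"]["quantify"] = {
            "fast_invalid_s0": qc_fast["n_invalid_s0"],
            "slow_invalid_s0": qc_slow["n_invalid_s0"],
            "fast_clamped_samples": qc_fast["n_clamped_samples"],
            "slow_clamped_samples": qc_slow["n_clamped_samples"],
            "invalid_fits": int((~ki_map.valid & tissue_mask).sum()),
        }
        (out / "qc.json").write_text(json.dumps(manifest["qc"]["quantify"],
                                                indent=1))
        manifest["stages"].append(stage)

        stage = "leakage"
        region_masks = {r: masks[r] for r in TISSUE_REGIONS}
        leak = region_leakage(ki_map.ki, region_masks, config.bin_width)
        bio.save_table(out / "leakage.csv", leak)
        manifest["stages"].append(stage)

        stage = "cognition"
        cohort_cfg = CohortConfig(**{
            **{k: v for k, v in config.cohort.__dict__.items()},
            "seed": config.seed + 1})
        leakage_table = sample_leakage_table(cohort_cfg.n_patients,
                                             seed=config.seed + 2)
        cohort = generate_cohort(cohort_cfg, leakage_table)
        compounds = compute_compounds(cohort, cohort_cfg.test_battery)
        bio.save_table(out / "cohort.csv", cohort)
        merged_table = pd.concat([cohort, compounds], axis=1)
        bio.save_table(out / "compounds.csv",
                       compounds.reset_index(names="patient_id"))
        manifest["stages"].append(stage)

        stage = "associate"
        grid = run_association_grid(merged_table)
        bio.save_table(out / "associations.csv", grid)
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
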