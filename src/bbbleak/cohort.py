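"""Synthetic patient cohort with leakage-dependent cognitive decline.

Stands in for the private longitudinal cohort: per-patient baseline
leakage measures (mean Ki and leakage volume per brain region), covariates
(age, sex, education, relative WMH and brain volumes), and a
neuropsychological battery measured at baseline and two-year follow-up.
The latent decline of each cognitive domain is a linear function of
z-scored leakage measures and covariates plus Gaussian noise, so the
downstream compound-score and regression stages have a known ground truth
to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .cognition import DEFAULT_BATTERY, DOMAINS, TestSpec

REGIONS = ("NAWM", "WMH", "CGM", "DGM")
MEASURES = ("vl", "ki")
COVARIATES = ("age", "sex", "education", "rel_wmh_volume", "rel_brain_volume")

#: cohort-scale leakage distributions per region: mean (SD); v_l in %,
#: Ki in 1e-4 min^-1
LEAKAGE_DISTRIBUTIONS = {
    ("vl", "NAWM"): (32.0, 16.0), ("vl", "WMH"): (39.0, 19.0),
    ("vl", "CGM"): (18.0, 11.0), ("vl", "DGM"): (30.0, 19.0),
    ("ki", "NAWM"): (3.1, 1.6), ("ki", "WMH"): (3.4, 2.0),
    ("ki", "CGM"): (2.3, 1.2), ("ki", "DGM"): (3.1, 2.0),
}

#: plausible baseline score scales per default-battery test (mean, SD)
_SCORE_SCALES = {
    "ravlt_immediate": (42.0, 9.0),
    "ravlt_delayed_recall": (8.0, 3.0),
    "ravlt_delayed_recognition": (28.0, 2.5),
    "digit_span_forward": (8.5, 2.0),
    "scwt_interference": (60.0, 25.0),
    "tmt_interference": (55.0, 30.0),
    "category_fluency_animals": (21.0, 5.5),
    "category_fluency_professions": (16.0, 4.5),
    "letter_fluency": (34.0, 11.0),
    "letter_number_sequencing": (9.0, 2.5),
    "digit_span_backward": (6.5, 2.0),
    "symbol_substitution": (45.0, 12.0),
    "tmt_a": (45.0, 18.0),
    "scwt_part1": (48.0, 9.0),
    "scwt_part2": (62.0, 13.0),
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    ``effect_beta`` maps (region, measure, domain) to the slope of that
    domain's latent decline (z-units) per SD of the leakage measure; the
    domain entry may be ``"all"``. ``covariate_effects`` are slopes per SD
    of the (z-scored) covariate, applied to every domain.
    ``noise_sd_cognition`` is the SD of the domain-level latent noise;
    ``test_noise_sd`` adds independent test-level noise on top.
    """

    n_patients: int = 51
    effect_beta: dict[tuple[str, str, str], float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.2, "sex": 0.0, "education": -0.1,
                                 "rel_wmh_volume": 0.15,
                                 "rel_brain_volume": -0.15})
    noise_sd_cognition: float = 0.5
    test_noise_sd: float = 0.5
    test_battery: Sequence[TestSpec] = DEFAULT_BATTERY
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd_cognition < 0 or self.test_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for key in self.effect_beta:
            region, measure, domain = key
            if measure not in MEASURES:
                raise ValueError(f"unknown measure {measure!r} in effect_beta")
            if domain not in DOMAINS + ("all",):
                raise ValueError(f"unknown domain {domain!r} in effect_beta")


def sample_leakage_table(n_patients: int, seed: int = 0) -> pd.DataFrame:
    """Draw per-patient baseline leakage measures from the cohort-scale
    region distributions (clipped at 0)."""
    rng = np.random.default_rng(seed)
    out = {"patient_id": np.arange(n_patients)}
    for (measure, region), (mean, sd) in LEAKAGE_DISTRIBUTIONS.items():
        out[f"{measure}_{region}"] = np.clip(
            rng.normal(mean, sd, n_patients), 0.0, None)
    return pd.DataFrame(out)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig,
                    leakage_table: pd.DataFrame) -> pd.DataFrame:
    """Generate the cohort table: covariates, raw baseline/follow-up test
    scores, leakage measures, and latent ground-truth decline columns.

    The latent decline of domain d is
    sum_beta beta_(r,m,d) * z(measure_rm) + sum_c gamma_c * z(cov_c) + eps_d,
    eps_d ~ N(0, noise_sd_cognition). Each test realizes the latent decline
    of its domain (plus test-level noise) in oriented units; inverted-scale
    tests (Stroop/TMT times) worsen by *increasing* at follow-up.
    Follow-up scores are set missing independently at ``missing_rate``.
    """
    n = config.n_patients
    if len(leakage_table) != n:
        raise ValueError("leakage table must have one row per patient")
    # distinct stream from sample_leakage_table even under an equal seed,
    # so covariates are independent of the leakage draws
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(1,)))

    for region, measure, _ in config.effect_beta:
        col = f"{measure}_{region}"
        if col not in leakage_table.columns:
            raise KeyError(
                f"effect_beta references {col!r} absent from the leakage table")

    cov = pd.DataFrame({
        "patient_id": np.asarray(leakage_table.get(
            "patient_id", np.arange(n))),
        "age": rng.normal(67.0, 12.0, n),
        "sex": (rng.random(n) < 0.59).astype(int),
        "education": rng.choice([1, 2, 3], size=n, p=[0.47, 0.35, 0.18]),
        "rel_wmh_volume": np.clip(rng.normal(0.014, 0.006, n), 0.0, None),
        "rel_brain_volume": np.clip(rng.normal(0.675, 0.05, n), 0.3, 1.0),
    })

    cov_term = np.zeros(n)
    for name, gamma in config.covariate_effects.items():
        if gamma != 0.0:
            cov_term = cov_term + gamma * _zscore(cov[name].to_numpy(dtype=float))

    latent = {}
    for domain in DOMAINS:
        lin = cov_term.copy()
        for (region, measure, dom), beta in config.effect_beta.items():
            if dom in (domain, "all") and beta != 0.0:
                x = leakage_table[f"{measure}_{region}"].to_numpy(dtype=float)
                lin = lin + beta * _zscore(x)
        latent[domain] = lin + rng.normal(0.0, config.noise_sd_cognition, n)

    scores = pd.DataFrame(index=np.arange(n))
    for spec in config.test_battery:
        mean, sd = _SCORE_SCALES.get(spec.name, (50.0, 10.0))
        baseline = rng.normal(mean, sd, n)
        oriented = latent[spec.domain] + (
            rng.normal(0.0, config.test_noise_sd, n)
            if config.test_noise_sd > 0 else 0.0)
        # oriented decline is in z-like units; map to the test's raw scale
        raw_decline = oriented * sd * 0.1
        if spec.higher_is_worse:
            followup = baseline + raw_decline
        else:
            followup = baseline - raw_decline
        if config.missing_rate > 0:
            followup = np.where(rng.random(n) < config.missing_rate,
                                np.nan, followup)
        scores[f"{spec.name}_baseline"] = baseline
        scores[f"{spec.name}_followup"] = followup

    out = pd.concat([cov, scores,
                     leakage_table.drop(columns=["patient_id"],
                                        errors="ignore").reset_index(drop=True)],
                    axis=1)
    for domain in DOMAINS:
        out[f"latent_{domain}_decline"] = latent[domain]
    return out


def cohort_config_to_dict(config: CohortConfig) -> dict[str, Any]:
    d = asdict(config)
    d["effect_beta"] = [
        {"region": r, "measure": m, "domain": dom, "beta": b}
        for (r, m, dom), b in config.effect_beta.items()]
    d["test_battery"] = [asdict(t) for t in config.test_battery]
    return d


def cohort_config_from_dict(d: Mapping[str, Any]) -> CohortConfig:
    d = dict(d)
    if "effect_beta" in d and isinstance(d["effect_beta"], list):
        d["effect_beta"] = {
            (e["region"], e["measure"], e["domain"]): e["beta"]
            for e in d["effect_beta"]}
    if "test_battery" in d:
        d["test_battery"] = tuple(
            t if isinstance(t, TestSpec) else TestSpec(**t)
            for t in d["test_battery"])
    return CohortConfig(**d)
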