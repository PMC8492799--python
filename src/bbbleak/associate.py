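"""Linear association between baseline leakage and cognitive decline.

Fits ordinary least squares models with a cognitive-decline compound as
outcome and one leakage measure (mean Ki or leakage volume of one region)
as predictor — univariable, and adjusted for age, sex, education level,
baseline relative WMH volume and baseline relative brain volume. The
reported coefficient B is standardized: outcome and leakage predictor are
z-scored (sample SD) before the fit, covariates stay on their native scale
by default; in the single-predictor case B then equals the Pearson
correlation. Complete-case analysis throughout; significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_COVARIATES = ("age", "sex", "education", "rel_wmh_volume",
                      "rel_brain_volume")
OUTCOMES = ("overall", "executive", "speed", "memory")


@dataclass(frozen=True)
class AssociationSpec:
    """One model: outcome compound ~ (region, measure) [+ covariates]."""

    outcome: str
    region: str
    measure: str              # 'vl' | 'ki'
    covariates: tuple[str, ...] = ()
    alpha: float = 0.05
    standardize: str = "outcome_predictor"  # | 'all' | 'none'

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError("predictor and covariates must be disjoint")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.standardize not in ("outcome_predictor", "all", "none"):
            raise ValueError("standardize must be 'outcome_predictor', 'all' or 'none'")

    @property
    def predictor(self) -> str:
        return f"{self.measure}_{self.region}"


@dataclass
class AssociationResult:
    """Standardized coefficient of the leakage predictor with 95% CI."""

    b_standardized: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model: str                # 'univariable' | 'adjusted'
    outcome: str = ""
    region: str = ""
    measure: str = ""
    significant: bool = False
    raw_coefficient: float = float("nan")


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in column {name!r}")
    return (x - x.mean()) / sd


def fit_association(data: pd.DataFrame, spec: AssociationSpec
                    ) -> AssociationResult:
    """Fit one (un)adjusted linear model and report the standardized B.

    Complete cases only; requires at least (number of covariates + 3)
    complete cases and nonzero predictor variance. The confidence interval
    and two-sided p-value come from the t-distribution of the OLS
    coefficient.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    sub = data[cols].dropna()
    n = len(sub)
    if n < len(spec.covariates) + 3:
        raise ValueError(
            f"only {n} complete cases for outcome {spec.outcome!r}; need "
            f">= {len(spec.covariates) + 3}")

    y_raw = sub[spec.outcome].to_numpy(dtype=float)
    x_raw = sub[spec.predictor].to_numpy(dtype=float)
    if x_raw.std(ddof=1) == 0:
        raise ValueError(f"zero predictor variance: {spec.predictor}")

    if spec.standardize == "none":
        y, x = y_raw, x_raw
    else:
        y = _zscore(y_raw, spec.outcome)
        x = _zscore(x_raw, spec.predictor)
    design = pd.DataFrame({spec.predictor: x}, index=sub.index)
    for c in spec.covariates:
        v = sub[c].to_numpy(dtype=float)
        design[c] = _zscore(v, c) if spec.standardize == "all" else v
    design = sm.add_constant(design, prepend=True)

    # rank check on unit-norm columns so covariate scale cannot mask or
    # fake collinearity
    mat = design.to_numpy()
    norms = np.linalg.norm(mat, axis=0)
    rank = np.linalg.matrix_rank(mat / np.where(norms > 0, norms, 1.0))
    if rank < design.shape[1]:
        corr = design.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"rank-deficient design matrix (collinear columns, e.g. {worst})")

    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=spec.alpha).loc[spec.predictor]
    b = float(fit.params[spec.predictor])
    p = float(fit.pvalues[spec.predictor])
    # raw-scale coefficient for reference (decline units per measure unit)
    scale = (y_raw.std(ddof=1) / x_raw.std(ddof=1)
             if spec.standardize != "none" else 1.0)
    return AssociationResult(
        b_standardized=b, ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=p, n_used=n,
        model="adjusted" if spec.covariates else "univariable",
        outcome=spec.outcome, region=spec.region, measure=spec.measure,
        significant=p < spec.alpha, raw_coefficient=b * scale)


def run_association_grid(data: pd.DataFrame,
                         regions: Sequence[str] = ("NAWM", "WMH", "CGM", "DGM"),
                         measures: Sequence[str] = ("vl", "ki"),
                         outcomes: Sequence[str] = OUTCOMES,
                         covariates: Sequence[str] = DEFAULT_COVARIATES,
                         alpha: float = 0.05,
                         fdr: bool = False) -> pd.DataFrame:
    """Fit the full grid: every (region, measure, outcome), univariable and
    covariate-adjusted. Cell failures are recorded in-table (error column)
    and the run continues. Optional Benjamini-Hochberg correction across
    the grid (off by default) adds a q-value column.
    """
    rows = []
    for model_covs, model in ((tuple(), "univariable"),
                              (tuple(covariates), "adjusted")):
        for region, measure, outcome in product(regions, measures, outcomes):
            base = {"model": model, "region": region, "measure": measure,
                    "outcome": outcome}
            try:
                res = fit_association(data, AssociationSpec(
                    outcome=outcome, region=region, measure=measure,
                    covariates=model_covs, alpha=alpha))
                base.update(B=res.b_standardized, ci_low=res.ci_low,
                            ci_high=res.ci_high, p=res.p_value, n=res.n_used,
                            error="")
            except (ValueError, KeyError) as exc:
                base.update(B=np.nan, ci_low=np.nan, ci_high=np.nan,
                            p=np.nan, n=0, error=str(exc))
            rows.append(base)
    table = pd.DataFrame(rows, columns=["model", "region", "measure",
                                        "outcome", "B", "ci_low", "ci_high",
                                        "p", "n", "error"])
    if fdr:
        from statsmodels.stats.multitest import multipletests
        ok = table["p"].notna()
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(table.loc[ok, "p"],
                                             method="fdr_bh")[1]
        table["q_fdr_bh"] = q
    return table
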