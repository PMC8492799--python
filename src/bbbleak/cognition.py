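"""Cognitive-decline compound scores.

Raw decline = baseline score - follow-up score per test, with tests where a
higher score means worse performance (Stroop and Trail Making times)
inverted so that a positive decline always means worsening. Declines are
z-standardized over the analysis cohort (sample SD, n-1), averaged within
each of the three domains (memory, executive function, information
processing speed) to domain compounds, and the three domains averaged to
the overall compound. A domain compound is computed from the remaining
tests when exactly one test is missing and is absent when more than one is
missing; a missing domain makes the overall compound missing too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("memory", "executive", "speed")


@dataclass(frozen=True)
class TestSpec:
    """One neuropsychological test: its domain and score orientation."""

    __test__ = False  # despite the name, not a pytest case

    name: str
    domain: str
    higher_is_worse: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}")


#: Battery covering the three domains: Rey Auditory Verbal Learning Test
#: (RAVLT), WAIS-III subtests, Stroop Color-Word Test (SCWT) and Trail
#: Making Test (TMT). Time-based SCWT/TMT scores are higher-is-worse.
DEFAULT_BATTERY: tuple[TestSpec, ...] = (
    TestSpec("ravlt_immediate", "memory"),
    TestSpec("ravlt_delayed_recall", "memory"),
    TestSpec("ravlt_delayed_recognition", "memory"),
    TestSpec("digit_span_forward", "memory"),
    TestSpec("scwt_interference", "executive", higher_is_worse=True),
    TestSpec("tmt_interference", "executive", higher_is_worse=True),
    TestSpec("category_fluency_animals", "executive"),
    TestSpec("category_fluency_professions", "executive"),
    TestSpec("letter_fluency", "executive"),
    TestSpec("letter_number_sequencing", "executive"),
    TestSpec("digit_span_backward", "executive"),
    TestSpec("symbol_substitution", "speed"),
    TestSpec("tmt_a", "speed", higher_is_worse=True),
    TestSpec("scwt_part1", "speed", higher_is_worse=True),
    TestSpec("scwt_part2", "speed", higher_is_worse=True),
)


def battery_by_domain(battery: Sequence[TestSpec]) -> dict[str, list[TestSpec]]:
    out: dict[str, list[TestSpec]] = {d: [] for d in DOMAINS}
    for spec in battery:
        out[spec.domain].append(spec)
    return out


def raw_decline(baseline, followup, spec: TestSpec):
    """Oriented raw decline score; NaN propagates from either time point.

    decline = baseline - followup, negated for higher-is-worse tests so a
    positive value always means worsening.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    d = baseline - followup
    return -d if spec.higher_is_worse else d


def decline_table(scores: pd.DataFrame, battery: Sequence[TestSpec]
                  ) -> pd.DataFrame:
    """Per-patient oriented decline per test from <test>_baseline/_followup
    columns; a missing score at either time point makes the decline NaN."""
    out = pd.DataFrame(index=scores.index)
    for spec in battery:
        b, f = f"{spec.name}_baseline", f"{spec.name}_followup"
        if b not in scores.columns or f not in scores.columns:
            raise KeyError(f"missing score columns for test {spec.name!r}")
        out[spec.name] = raw_decline(scores[b].to_numpy(),
                                     scores[f].to_numpy(), spec)
    return out


def zscore_cohort(declines: pd.Series) -> pd.Series:
    """Standardize one test's declines over the cohort: (d - mean)/SD.

    Sample SD (n-1 denominator) over present values; absent values stay
    absent. At least two present values with nonzero SD are required.
    """
    present = declines.dropna()
    if len(present) < 2:
        raise ValueError(
            f"test {declines.name!r}: need >= 2 present decline scores")
    sd = present.std(ddof=1)
    if sd == 0:
        raise ValueError(f"test {declines.name!r}: zero standard deviation")
    return (declines - present.mean()) / sd


def domain_compound(z_by_test: pd.DataFrame, battery: Sequence[TestSpec],
                    domain: str, max_missing: int = 1) -> pd.Series:
    """Average the domain's z-scores per patient; absent when more than
    ``max_missing`` of the domain's tests are missing."""
    tests = [s.name for s in battery if s.domain == domain]
    if not tests:
        raise ValueError(f"no tests registered for domain {domain!r}")
    block = z_by_test[tests]
    n_missing = block.isna().sum(axis=1)
    compound = block.mean(axis=1)
    compound[n_missing > max_missing] = np.nan
    return compound


def overall_compound(domain_compounds: pd.DataFrame) -> pd.Series:
    """Mean of the three domain compounds; absent if any domain is absent."""
    block = domain_compounds[list(DOMAINS)]
    out = block.mean(axis=1)
    out[block.isna().any(axis=1)] = np.nan
    return out


def compute_compounds(scores: pd.DataFrame,
                      battery: Sequence[TestSpec] = DEFAULT_BATTERY,
                      max_missing: int = 1) -> pd.DataFrame:
    """Full chain: raw declines -> cohort z-scores -> domain and overall
    compounds, with per-domain validity flags.

    Returns a frame indexed like ``scores`` with columns memory, executive,
    speed, overall and <domain>_valid flags.
    """
    declines = decline_table(scores, battery)
    z = pd.DataFrame({name: zscore_cohort(declines[name])
                      for name in declines.columns}, index=declines.index)
    out = pd.DataFrame(index=scores.index)
    for domain in DOMAINS:
        out[domain] = domain_compound(z, battery, domain, max_missing)
    out["overall"] = overall_compound(out)
    for domain in DOMAINS:
        out[f"{domain}_valid"] = out[domain].notna()
    out["overall_valid"] = out["overall"].notna()
    return out
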