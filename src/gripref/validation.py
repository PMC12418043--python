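"""Back-generation cross-validation of the reference standards.

The reference model is validated internally: a stratified random holdout
subset is drawn (by age and sex), the LMS model is refitted on it, and the
holdout-fitted medians ("fitted") are compared with the full-sample medians
("actual") per age and sex.  Agreement is scored with a *signed* mean
relative error — called MAPE in the forecasting tradition even though the
sign is retained — and banded by the usual interpretation scale:
100·|MAPE| < 10 "highly accurate", 10–20 "good", 20–50 "reasonable",
above 50 "inaccurate".

The default relative-error denominator is the fitted value,
(actual − fitted)/fitted, so a model that over-predicts gives a negative
row error; the actual-denominator variant is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .fit import FitConfig, fit_lms, predict_lms
from .hbz import round_half_up

__all__ = [
    "BackgenRow",
    "SexValidation",
    "ValidationReport",
    "stratified_holdout",
    "backgen_test",
    "mape_interpret",
    "run_backgeneration",
]

BANDS = ("highly accurate", "good", "reasonable", "inaccurate")


@dataclass
class BackgenRow:
    age: float
    actual_p50: float
    fitted_p50: float
    row_mape: float  # signed fraction, full precision

    @property
    def row_mape_display(self) -> float:
        """Row error rounded to 2 decimals for table display."""
        return round_half_up(self.row_mape, 2)


@dataclass
class SexValidation:
    rows: list[BackgenRow]
    average_mape: float  # signed fraction, full precision
    accuracy_band: str
    sex: str = ""

    @property
    def average_mape_display(self) -> float:
        return round_half_up(self.average_mape, 3)


@dataclass
class ValidationReport:
    blocks: dict[str, SexValidation]
    holdout_fraction: float
    seed: int
    convention: str = "fitted"
    p50_mode: str = "refit"
    extra: dict = field(default_factory=dict)


def stratified_holdout(
    cohort: Iterable, fraction: float, seed: int
) -> tuple[list, list]:
    """Split a cohort into (full set, holdout subset), stratified by age x sex.

    Each stratum contributes round-half-up(fraction * stratum size) records,
    so holdout proportions are within one record of the target per stratum.
    Fully reproducible for a given seed.  Strata yielding fewer than 10
    holdout records trigger a warning.
    """
    records = list(cohort)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"holdout fraction must be in (0, 1), got {fraction}")
    if not records:
        raise ValueError("empty cohort")
    strata: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault((rec.sex, float(rec.age)), []).append(i)
    rng = np.random.default_rng(seed)
    holdout_idx: list[int] = []
    for key in sorted(strata):
        members = strata[key]
        if not members:
            raise ValueError(f"empty stratum {key}")
        k = int(np.floor(fraction * len(members) + 0.5))
        if k < 10:
            warnings.warn(
                f"stratum {key} contributes only {k} holdout record(s); "
                "holdout medians there will be noisy"
            )
        chosen = rng.choice(len(members), size=k, replace=False)
        holdout_idx.extend(members[j] for j in chosen)
    holdout = [records[i] for i in sorted(holdout_idx)]
    return records, holdout


def backgen_test(
    actual_p50: Mapping[float, float],
    fitted_p50: Mapping[float, float],
    convention: str = "fitted",
    sex: str = "",
) -> SexValidation:
    """Score fitted against actual medians with the signed relative error.

    ``convention`` chooses the denominator: ``"fitted"`` (default, the
    published convention) or ``"actual"``.  Values are stored at full
    precision; display rounding (2 dp rows, 3 dp average) is a property of
    the rows, never the stored value.
    """
    if convention not in ("fitted", "actual"):
        raise ValueError(f"unknown MAPE convention {convention!r}")
    if set(actual_p50) != set(fitted_p50):
        raise ValueError(
            f"age keys differ: actual {sorted(actual_p50)} vs fitted {sorted(fitted_p50)}"
        )
    rows = []
    for age in sorted(actual_p50):
        a, f = float(actual_p50[age]), float(fitted_p50[age])
        if a <= 0 or f <= 0:
            raise ValueError(f"median values must be > 0 (age {age}: actual={a}, fitted={f})")
        denom = f if convention == "fitted" else a
        rows.append(BackgenRow(age=float(age), actual_p50=a, fitted_p50=f,
                               row_mape=(a - f) / denom))
    avg = float(np.mean([r.row_mape for r in rows]))
    return SexValidation(rows=rows, average_mape=avg,
                         accuracy_band=mape_interpret(avg), sex=sex)


def mape_interpret(average_mape: float) -> str:
    """Accuracy band for a signed average MAPE (fraction).

    Banded on 100·|MAPE|: < 10 highly accurate, [10, 20) good, [20, 50]
    reasonable, > 50 inaccurate (boundaries go to the better band).
    """
    m = 100.0 * abs(float(average_mape))
    if not np.isfinite(m):
        raise ValueError("average MAPE must be finite")
    if m < 10.0:
        return "highly accurate"
    if m < 20.0:
        return "good"
    if m <= 50.0:
        return "reasonable"
    return "inaccurate"


def _p50_by_age(records: list, ages: list[float], config: FitConfig,
                mode: str) -> dict[float, float]:
    if mode == "raw":
        arr_ages = np.array([float(r.age) for r in records])
        vals = np.array([float(r.hgs_abs) for r in records])
        return {a: float(np.median(vals[arr_ages == a])) for a in ages}
    model = fit_lms(records, config)
    return {a: predict_lms(model, a).mu for a in ages}


def run_backgeneration(
    cohort: Iterable,
    fit_configs: "FitConfig | Mapping[str, FitConfig] | None" = None,
    fraction: float = 0.2,
    seed: int = 0,
    convention: str = "fitted",
    p50_mode: str = "refit",
) -> ValidationReport:
    """Full back-generation pipeline on a two-sex cohort.

    Draws the stratified holdout, obtains the P50 per age from the full
    sample ("actual") and from the holdout ("fitted") — by refitting the LMS
    model on each (default) or from raw medians (``p50_mode="raw"``) — and
    scores each sex block.  Reproducible under ``seed``.
    """
    if p50_mode not in ("refit", "raw"):
        raise ValueError(f"unknown p50 mode {p50_mode!r}")
    records = list(cohort)
    full, holdout = stratified_holdout(records, fraction, seed)
    sexes = sorted({r.sex for r in records})
    if len(sexes) < 1:
        raise ValueError("cohort has no sex labels")
    blocks: dict[str, SexValidation] = {}
    for sex in sexes:
        full_sex = [r for r in full if r.sex == sex]
        hold_sex = [r for r in holdout if r.sex == sex]
        ages = sorted({float(r.age) for r in full_sex})
        config = (
            fit_configs.get(sex, FitConfig()) if isinstance(fit_configs, Mapping)
            else (fit_configs or FitConfig())
        )
        try:
            actual = _p50_by_age(full_sex, ages, config, p50_mode)
            fitted = _p50_by_age(hold_sex, ages, config, p50_mode)
        except Exception as err:
            raise RuntimeError(f"back-generation failed for sex {sex!r}: {err}") from err
        blocks[sex] = backgen_test(actual, fitted, convention=convention, sex=sex)
    return ValidationReport(
        blocks=blocks, holdout_fraction=fraction, seed=seed,
        convention=convention, p50_mode=p50_mode,
    )
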