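"""Percentile reference tables and smoothed centile curves.

Turns LMS triples — fitted by :mod:`gripref.fit` or supplied from a printed
table — into the age × percentile matrices used as normative reference
standards, and into dense centile curves for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bccg import LMSTriple, Percentile, bccg_quantile
from .fit import LMSCurveModel

__all__ = [
    "DEFAULT_PERCENTILES",
    "ReferenceRow",
    "ReferenceTable",
    "build_reference_table",
    "reconstruct_and_diff",
    "centile_curves",
    "interpolate_triples",
]

#: The percentile set the reference tables tabulate.
DEFAULT_PERCENTILES: tuple[float, ...] = (3.0, 10.0, 35.0, 50.0, 65.0, 90.0)


@dataclass
class ReferenceRow:
    age: float
    lms: LMSTriple
    percentile_values: dict[float, float]


@dataclass
class ReferenceTable:
    """Age grid x LMS triple x percentile matrix for one sex.

    ``percentile_values`` are stored at full precision; 2-decimal rounding is
    applied only when serializing for display.
    """

    sex: str
    rows: list[ReferenceRow]
    percentile_set: tuple[float, ...] = field(default=DEFAULT_PERCENTILES)

    def __post_init__(self) -> None:
        ages = [r.age for r in self.rows]
        if sorted(set(ages)) != ages:
            raise ValueError("reference rows must have strictly increasing, unique ages")

    def row(self, age: float) -> ReferenceRow:
        for r in self.rows:
            if r.age == age:
                return r
        raise KeyError(f"no reference row for age {age} ({self.sex})")

    @property
    def ages(self) -> list[float]:
        return [r.age for r in self.rows]

    def value(self, age: float, rank: float) -> float:
        return self.row(age).percentile_values[rank]


def build_reference_table(
    triples: Mapping[float, LMSTriple],
    percentile_set: Sequence[float] = DEFAULT_PERCENTILES,
    sex: str = "unspecified",
) -> ReferenceTable:
    """Evaluate the BCCG quantile at every (age, rank) cell.

    ``triples`` maps age to its LMS triple; ``percentile_set`` must be sorted
    ranks inside (0, 100).  A triple for which a requested centile does not
    exist raises with the age and sex in the message.
    """
    ranks = [float(p) for p in percentile_set]
    if ranks != sorted(ranks) or any(not 0 < p < 100 for p in ranks):
        raise ValueError("percentile_set must be sorted ranks inside (0, 100)")
    pcts = [Percentile.from_rank(p) for p in ranks]
    rows = []
    for age in sorted(triples):
        lms = triples[age]
        cells: dict[float, float] = {}
        for pct in pcts:
            try:
                cells[pct.p] = bccg_quantile(lms, pct)
            except ValueError as err:
                raise ValueError(f"sex={sex}, age={age}: {err}") from err
        rows.append(ReferenceRow(age=float(age), lms=lms, percentile_values=cells))
    return ReferenceTable(sex=sex, rows=rows, percentile_set=tuple(ranks))


def reconstruct_and_diff(printed_table: ReferenceTable) -> dict:
    """Recompute every cell from the stored triples and report discrepancies.

    Regression harness for printed tables: with 3-decimal-rounded L and S a
    per-cell drift of ±0.01–0.02 kg is legitimate.  Returns per-row maximum
    absolute differences, the flagged cells above 0.02 kg, and the overall
    maximum.
    """
    per_row: dict[float, float] = {}
    flagged: list[tuple[float, float, float]] = []  # (age, rank, |diff|)
    overall = 0.0
    for row in printed_table.rows:
        row_max = 0.0
        for rank, printed in row.percentile_values.items():
            recomputed = bccg_quantile(row.lms, rank)
            diff = abs(recomputed - printed)
            row_max = max(row_max, diff)
            if diff > 0.02:
                flagged.append((row.age, rank, diff))
        per_row[row.age] = row_max
        overall = max(overall, row_max)
    return {"per_row_max": per_row, "max_discrepancy": overall, "flagged": flagged}


def interpolate_triples(
    triples: Mapping[float, LMSTriple], ages: Sequence[float]
) -> list[LMSTriple]:
    """Interpolate LMS triples between tabulated ages.

    lam, ln mu and ln sigma are taken linear in age between knots, which
    keeps every interpolated triple valid (mu, sigma > 0).
    """
    knots = np.array(sorted(triples))
    lam = np.array([triples[a].lam for a in knots])
    lmu = np.log([triples[a].mu for a in knots])
    lsig = np.log([triples[a].sigma for a in knots])
    a = np.asarray(ages, dtype=float)
    if a.min() < knots[0] or a.max() > knots[-1]:
        raise ValueError("interpolation ages must lie inside the tabulated age range")
    return [
        LMSTriple(
            lam=float(np.interp(x, knots, lam)),
            mu=float(np.exp(np.interp(x, knots, lmu))),
            sigma=float(np.exp(np.interp(x, knots, lsig))),
        )
        for x in a
    ]


def centile_curves(
    source: "LMSCurveModel | Mapping[float, LMSTriple]",
    age_grid: Sequence[float],
    percentile_set: Sequence[float] = DEFAULT_PERCENTILES,
) -> dict[float, np.ndarray]:
    """Centile curve coordinates over an age grid, one array per rank.

    ``source`` is either a fitted :class:`LMSCurveModel` (evaluated through
    its smooth curves) or a map of tabulated triples (interpolated with
    lam, ln mu, ln sigma linear in age).  The returned curves are strictly
    ordered (non-crossing) at every grid point by construction of the
    quantile; this is verified and enforced.
    """
    ages = np.asarray(age_grid, dtype=float)
    if isinstance(source, LMSCurveModel):
        lo, hi = source.age_domain
        if ages.min() < lo or ages.max() > hi:
            raise ValueError(f"age grid must lie inside the fitted domain [{lo}, {hi}]")
        triples = source.predict_many(ages)
    else:
        triples = interpolate_triples(source, ages)
    ranks = [float(p) for p in percentile_set]
    curves = {
        rank: np.array([bccg_quantile(t, rank) for t in triples]) for rank in ranks
    }
    stacked = np.vstack([curves[r] for r in sorted(ranks)])
    if not np.all(np.diff(stacked, axis=0) > 0):
        raise RuntimeError("centile curves cross; invalid parameter curves")
    return curves
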