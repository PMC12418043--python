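"""Health Benefit Zones: percentile-band cut-offs and population classification.

Five ordered zones — Very Poor, Poor, Medium, Good, Excellent — partition the
strength scale at designated reference percentiles, per age and sex.  Two
banding schemes are supported:

``table6`` (default)
    Band edges at P3/P10/P35/P65/P90, the edges the published cut-off table
    realizes.  Nominal zone masses under the generating model are
    10/25/30/25/10 % (the Very Poor zone absorbs the open sub-P3 tail, so its
    mass is 3 + 7 = 10 %).
``section27``
    The verbal scheme — Very Poor < P3, Poor P3–P10, Medium P10–P50, Good
    P50–P90, Excellent >= P90 — with nominal masses 3/7/40/40/10 %.  The two
    schemes genuinely differ; published population shares (~32.7 % Medium)
    match ``table6``.

Classification is closed-below / open-above at full precision: a value equal
to an edge belongs to the zone above it, and values beyond the outer edges
fall in the open tails (Very Poor below, Excellent above).  Display strings
use the published 2-decimal convention in which each band's printed lower
bound is the previous band's upper bound + 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .reference import ReferenceTable

__all__ = [
    "ZONES",
    "SCHEMES",
    "HBZRow",
    "HBZTable",
    "ZoneDistribution",
    "build_hbz_table",
    "classify",
    "population_distribution",
]

ZONES: tuple[str, ...] = ("Very Poor", "Poor", "Medium", "Good", "Excellent")

#: scheme -> (display floor rank for the lowest band, classification edge ranks)
SCHEMES: dict[str, tuple[float, tuple[float, ...]]] = {
    "table6": (3.0, (10.0, 35.0, 65.0, 90.0)),
    "section27": (3.0, (3.0, 10.0, 50.0, 90.0)),
}


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt2(x: float) -> str:
    return f"{Decimal(repr(x)).quantize(Decimal('0.01'), rounding=ROUND_HALF_UP):.2f}"


@dataclass
class HBZRow:
    age: float
    #: classification edges, closed below: [Poor, Medium, Good, Excellent) starts
    edges: tuple[float, float, float, float]
    #: full-precision display floor of the lowest band (P3 in the table6 scheme)
    display_floor: float

    def zone_of(self, value: float) -> str:
        if not value > 0:
            raise ValueError(f"strength value must be > 0, got {value}")
        k = sum(value >= e for e in self.edges)
        return ZONES[k]

    def band_strings(self) -> dict[str, str]:
        """Published-style range strings (2 dp, +0.01 lower-bound offset)."""
        out: dict[str, str] = {}
        uppers = [Decimal(_fmt2(e)) for e in self.edges]
        if self.edges[0] == self.display_floor:
            # section27-style: the lowest band is the open tail below its edge
            out[ZONES[0]] = f"<{uppers[0]}"
            out[ZONES[1]] = f"{uppers[0]}–{uppers[1]}"
            for i, zone in enumerate(ZONES[2:4], start=2):
                out[zone] = f"{uppers[i - 1] + Decimal('0.01')}–{uppers[i]}"
        else:
            # table6-style: lowest band printed from the display floor (P3);
            # each later band's printed lower bound = previous upper + 0.01
            out[ZONES[0]] = f"{Decimal(_fmt2(self.display_floor))}–{uppers[0]}"
            for i, zone in enumerate(ZONES[1:4], start=1):
                out[zone] = f"{uppers[i - 1] + Decimal('0.01')}–{uppers[i]}"
        out[ZONES[4]] = f"≥{uppers[3] + Decimal('0.01')}"
        return out


@dataclass
class HBZTable:
    """Zone cut-off intervals for one sex, one row per age."""

    sex: str
    rows: dict[float, HBZRow]
    scheme: str = "table6"

    def row(self, age: float) -> HBZRow:
        try:
            return self.rows[float(age)]
        except KeyError:
            raise KeyError(f"no HBZ row for age {age} ({self.sex})") from None


@dataclass
class ZoneDistribution:
    """Zone counts and percentages for a classified cohort."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n: int
    by_sex: dict[str, "ZoneDistribution"] | None = None
    excluded: list = None  # records not covered by the tables

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], **kw) -> "ZoneDistribution":
        n = sum(counts.values())
        if n == 0:
            raise ValueError("cannot summarize an empty cohort")
        pct = {z: round_half_up(100.0 * counts.get(z, 0) / n, 1) for z in ZONES}
        return cls(counts={z: counts.get(z, 0) for z in ZONES},
                   percentages=pct, n=n, **kw)


def build_hbz_table(ref: ReferenceTable, scheme: str = "table6") -> HBZTable:
    """Derive zone cut-offs from a reference table's percentile columns.

    Edges are taken at full precision from the table; a missing percentile
    rank raises with the rank named.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown banding scheme {scheme!r}; options: {sorted(SCHEMES)}")
    floor_rank, edge_ranks = SCHEMES[scheme]
    rows: dict[float, HBZRow] = {}
    for row in ref.rows:
        vals = row.percentile_values
        for rank in {floor_rank, *edge_ranks}:
            if rank not in vals:
                raise ValueError(
                    f"scheme {scheme!r} needs percentile rank {rank:g}, "
                    f"missing from reference table ({ref.sex}, age {row.age:g})"
                )
        rows[row.age] = HBZRow(
            age=row.age,
            edges=tuple(vals[r] for r in edge_ranks),
            display_floor=vals[floor_rank],
        )
    return HBZTable(sex=ref.sex, rows=rows, scheme=scheme)


def classify(value: float, age: float, sex: str,
             hbz: "HBZTable | Mapping[str, HBZTable]") -> str:
    """Zone label for one measurement; errors on uncovered age/sex."""
    table = hbz if isinstance(hbz, HBZTable) else hbz.get(sex)
    if table is None or (isinstance(hbz, HBZTable) and table.sex != sex):
        raise KeyError(f"no HBZ table for sex {sex!r}")
    return table.row(age).zone_of(value)


def population_distribution(
    cohort: Iterable, hbz: "HBZTable | Mapping[str, HBZTable]"
) -> ZoneDistribution:
    """Classify a cohort and summarize its zone distribution.

    Records whose age x sex is not covered by the tables are excluded with a
    warning and listed in ``excluded`` — never silently dropped.
    Percentages are 100*count/n, rounded half-up to one decimal.
    """
    tables: Mapping[str, HBZTable]
    if isinstance(hbz, HBZTable):
        tables = {hbz.sex: hbz}
    else:
        tables = hbz
    counts: dict[str, int] = {z: 0 for z in ZONES}
    by_sex_counts: dict[str, dict[str, int]] = {}
    excluded = []
    total = 0
    for rec in cohort:
        sex, age, value = rec.sex, float(rec.age), float(rec.hgs_abs)
        table = tables.get(sex)
        if table is None or age not in table.rows:
            excluded.append(rec)
            continue
        zone = table.row(age).zone_of(value)
        counts[zone] += 1
        by_sex_counts.setdefault(sex, {z: 0 for z in ZONES})[zone] += 1
        total += 1
    if excluded:
        warnings.warn(
            f"{len(excluded)} record(s) not covered by the HBZ tables were excluded"
        )
    if total == 0:
        raise ValueError("cannot summarize an empty (or fully uncovered) cohort")
    by_sex = {
        s: ZoneDistribution.from_counts(c) for s, c in sorted(by_sex_counts.items())
    }
    return ZoneDistribution.from_counts(counts, by_sex=by_sex, excluded=excluded)
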