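"""Cohort ingest, derived fields, descriptive summaries, study planning, CSV IO.

All tabular artifacts are CSV with decimal points and UTF-8; Unicode minus
signs (as printed in journal tables) are normalized to ASCII on ingest.
Quartiles use linear interpolation between order statistics (the "type 7"
convention), recorded in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bccg import LMSTriple
from .cohort import CohortRecord
from .hbz import ZONES, HBZTable
from .reference import ReferenceRow, ReferenceTable
from .validation import ValidationReport

__all__ = [
    "required_sample_size",
    "derive_fields",
    "describe",
    "cohort_to_csv",
    "read_cohort_csv",
    "reference_to_csv",
    "read_reference_csv",
    "hbz_to_csv",
    "hbz_band_strings_frame",
    "validation_to_csv",
]

COHORT_COLUMNS = ["id", "sex", "age", "height_cm", "weight_kg", "bmi",
                  "hgs_left_kg", "hgs_right_kg", "hgs_abs_kg"]


# ---------------------------------------------------------------------------
# study planning


def required_sample_size(p: float, e: float, z: float = 1.96,
                         d: float = 1.0) -> int:
    """Minimum sample size n = ceil((z^2 * p * q / e^2) * d), q = 1 - p.

    ``p`` is the anticipated population proportion, ``e`` the margin of
    error, ``z`` the normal deviate of the confidence level and ``d`` the
    design effect.  Sample sizes round up by convention.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"proportion p must be in (0, 1), got {p}")
    if not 0.0 < e < 1.0:
        raise ValueError(f"margin of error e must be in (0, 1), got {e}")
    if z <= 0 or d <= 0:
        raise ValueError("z and design effect d must be > 0")
    q = 1.0 - p
    return math.ceil((z * z * p * q / (e * e)) * d)


# ---------------------------------------------------------------------------
# cohort ingest


def _normalize_minus(obj):
    if isinstance(obj, str):
        return obj.replace("−", "-")
    return obj


def derive_fields(rows: "pd.DataFrame | Iterable[Mapping]") -> tuple[list[CohortRecord], list[dict]]:
    """Validate raw rows and compute the derived fields (BMI, absolute HGS).

    Each row needs sex, age, height_cm, weight_kg and either ``hgs_abs_kg``
    or both ``hgs_left_kg`` and ``hgs_right_kg``.  Absolute HGS is the mean
    of the two hand maxima; BMI is weight / (height in m)^2.  Invalid rows
    are returned in a reject report with reasons — never silently dropped.
    Idempotent on already-derived records.
    """
    if isinstance(rows, pd.DataFrame):
        iterator = (row._asdict() if hasattr(row, "_asdict") else dict(row)
                    for row in rows.to_dict("records"))
    else:
        iterator = (dict(r) for r in rows)
    records: list[CohortRecord] = []
    rejects: list[dict] = []
    for i, raw in enumerate(iterator):
        row = {k: _normalize_minus(v) for k, v in raw.items()}
        try:
            sex = str(row["sex"])
            age = int(float(row["age"]))
            height = float(row["height_cm"])
            weight = float(row["weight_kg"])
        except (KeyError, TypeError, ValueError) as err:
            rejects.append({"row": i, "reason": f"missing/invalid mandatory column: {err}",
                            "data": raw})
            continue
        if height <= 0 or weight <= 0:
            rejects.append({"row": i, "reason": "height and weight must be > 0",
                            "data": raw})
            continue
        left = row.get("hgs_left_kg")
        right = row.get("hgs_right_kg")
        abs_given = row.get("hgs_abs_kg")
        try:
            if left is not None and right is not None and not _isnan(left) and not _isnan(right):
                left, right = float(left), float(right)
                hgs_abs = (left + right) / 2.0
            elif abs_given is not None and not _isnan(abs_given):
                hgs_abs = float(abs_given)
                left = float(left) if left is not None and not _isnan(left) else hgs_abs
                right = float(right) if right is not None and not _isnan(right) else hgs_abs
            else:
                raise ValueError("need hgs_abs_kg or both hand maxima")
        except (TypeError, ValueError) as err:
            rejects.append({"row": i, "reason": str(err), "data": raw})
            continue
        if hgs_abs <= 0 or left <= 0 or right <= 0:
            rejects.append({"row": i, "reason": "strength values must be > 0",
                            "data": raw})
            continue
        records.append(CohortRecord(
            id=str(row.get("id", f"r{i:05d}")), sex=sex, age=age,
            height=height, weight=weight,
            bmi=weight / (height / 100.0) ** 2,
            hgs_left=left, hgs_right=right, hgs_abs=hgs_abs,
        ))
    return records, rejects


def _isnan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# descriptive summaries


def describe(cohort: Iterable[CohortRecord],
             by: Sequence[str] = ("sex",)) -> pd.DataFrame:
    """Median and IQR (Q3 - Q1, type-7 quartiles) per group and variable."""
    df = cohort_frame(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    variables = ["height_cm", "weight_kg", "bmi", "hgs_abs_kg"]
    out = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        if grp.empty:
            continue
        entry = dict(zip(by, key))
        entry["n"] = len(grp)
        for var in variables:
            q1, med, q3 = np.percentile(grp[var], [25, 50, 75])  # type 7
            entry[f"{var}_median"] = med
            entry[f"{var}_iqr"] = q3 - q1
        out.append(entry)
    result = pd.DataFrame(out)
    result.attrs["quartile_rule"] = "type 7 (linear interpolation)"
    return result


# ---------------------------------------------------------------------------
# CSV serialization


def cohort_frame(cohort: Iterable[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        d = asdict(r)
        rows.append({
            "id": d["id"], "sex": d["sex"], "age": d["age"],
            "height_cm": d["height"], "weight_kg": d["weight"], "bmi": d["bmi"],
            "hgs_left_kg": d["hgs_left"], "hgs_right_kg": d["hgs_right"],
            "hgs_abs_kg": d["hgs_abs"],
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_to_csv(cohort: Iterable[CohortRecord], path) -> None:
    cohort_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ("sex", "age", "height_cm", "weight_kg") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing mandatory column(s): {missing}")
    records, rejects = derive_fields(df)
    if rejects:
        raise ValueError(f"{len(rejects)} invalid row(s); first: {rejects[0]['reason']}")
    return records


def reference_to_csv(table: ReferenceTable, path) -> None:
    """Columns sex, age, L, M, S then P<rank>; 2-dp kg, 3-dp L and S."""
    rows = []
    for r in table.rows:
        row = {"sex": table.sex, "age": r.age,
               "L": f"{r.lms.lam:.3f}", "M": f"{r.lms.mu:.2f}",
               "S": f"{r.lms.sigma:.3f}"}
        for rank in table.percentile_set:
            row[f"P{rank:g}"] = f"{r.percentile_values[rank]:.2f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reference_csv(path) -> dict[str, ReferenceTable]:
    df = pd.read_csv(path)
    ranks = [float(c[1:]) for c in df.columns if c.startswith("P")]
    tables: dict[str, ReferenceTable] = {}
    for sex, grp in df.groupby("sex"):
        rows = []
        for _, r in grp.sort_values("age").iterrows():
            lms = LMSTriple(lam=float(r["L"]), mu=float(r["M"]), sigma=float(r["S"]))
            cells = {rank: float(r[f"P{rank:g}"]) for rank in ranks}
            rows.append(ReferenceRow(age=float(r["age"]), lms=lms,
                                     percentile_values=cells))
        tables[str(sex)] = ReferenceTable(sex=str(sex), rows=rows,
                                          percentile_set=tuple(sorted(ranks)))
    return tables


def hbz_to_csv(tables: "HBZTable | Mapping[str, HBZTable]", path) -> None:
    """Columns sex, age, zone, lower, upper (upper empty for Excellent)."""
    if isinstance(tables, HBZTable):
        tables = {tables.sex: tables}
    rows = []
    for sex in sorted(tables):
        t = tables[sex]
        for age in sorted(t.rows):
            r = t.rows[age]
            # classification intervals: Very Poor open below, Excellent open above
            bounds = ["", *r.edges, ""]
            for k, zone in enumerate(ZONES):
                rows.append({"sex": sex, "age": age, "zone": zone,
                             "scheme": t.scheme,
                             "lower": bounds[k], "upper": bounds[k + 1]})
    pd.DataFrame(rows).to_csv(path, index=False)


def hbz_band_strings_frame(tables: "HBZTable | Mapping[str, HBZTable]") -> pd.DataFrame:
    """Published-style display table: one row per sex x age, one column per zone."""
    if isinstance(tables, HBZTable):
        tables = {tables.sex: tables}
    rows = []
    for sex in sorted(tables):
        t = tables[sex]
        for age in sorted(t.rows):
            rows.append({"sex": sex, "age": age, **t.rows[age].band_strings()})
    return pd.DataFrame(rows)


def validation_to_csv(report: ValidationReport, path) -> None:
    """Published-layout validation table with a metadata header."""
    lines = [
        f"# holdout_fraction={report.holdout_fraction}",
        f"# seed={report.seed}",
        f"# convention={report.convention}",
        f"# p50_mode={report.p50_mode}",
    ]
    frames = []
    for sex, block in sorted(report.blocks.items()):
        rows = [{"sex": sex, "age": r.age, "actual": r.actual_p50,
                 "fitted": r.fitted_p50, "mape": f"{r.row_mape_display:.2f}"}
                for r in block.rows]
        rows.append({"sex": sex, "age": "average", "actual": "", "fitted": "",
                     "mape": f"{block.average_mape_display:.3f}"})
        frames.append(pd.DataFrame(rows))
    body = pd.concat(frames, ignore_index=True).to_csv(index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n" + body)
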