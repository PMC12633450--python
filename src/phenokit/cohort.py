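"""Diagnostic-status coding and cohort descriptive summaries.

DSM-5 ADHD *presentations* (Inattentive, Hyperactive-Impulsive, Combined) are
re-coded into two binary *status* flags: a Combined presentation is positive
on both the inattentive and hyperactive flags, so that each flag captures the
presence of that symptom domain regardless of presentation.  ADHD
other/unspecified cases do not meet full criteria for any presentation and
are excluded from every downstream model.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosisStatus",
    "PRESENTATION_LABELS",
    "code_diagnosis_status",
    "load_participants",
    "summarize_cohort",
    "format_cohort_table",
    "sex_ratio",
    "default_groups",
]


class DiagnosisStatus(NamedTuple):
    adhd_inatt: int
    adhd_hyper: int
    excluded: int


#: presentation label -> (adhd_inatt, adhd_hyper, excluded)
PRESENTATION_LABELS: dict[str, DiagnosisStatus] = {
    "Inattentive": DiagnosisStatus(1, 0, 0),
    "Hyperactive": DiagnosisStatus(0, 1, 0),
    "Combined": DiagnosisStatus(1, 1, 0),
    "OtherUnspecified": DiagnosisStatus(0, 0, 1),
    "None": DiagnosisStatus(0, 0, 0),
}


def code_diagnosis_status(presentation_label: str) -> DiagnosisStatus:
    """Map a DSM-5 ADHD presentation label to binary status flags.

    Combined sets both flags; OtherUnspecified sets ``excluded=1`` (the
    record is dropped from all fits).  Unknown labels are a hard error.
    """
    try:
        return PRESENTATION_LABELS[presentation_label]
    except KeyError:
        raise ValueError(
            f"unknown ADHD presentation label: {presentation_label!r}; "
            f"expected one of {sorted(PRESENTATION_LABELS)}"
        ) from None


#: continuous fields summarized as mean (SD), in display order
DEFAULT_CONTINUOUS = [
    "age", "swan_inatt", "swan_hyper", "assq", "mfq", "scared",
    "cbcl_ext", "cbcl_int", "iq_full", "iq_verbal", "interview_minutes",
]

#: binary fields summarized as count (%)
DEFAULT_BINARY = ["sex", "adhd_inatt", "adhd_hyper", "asd"]


def default_groups() -> dict[str, Callable[[pd.DataFrame], pd.Series]]:
    """Diagnostic group predicates over the coded status flags.

    Inattentive and Hyperactive groups overlap (Combined members belong to
    both).  "Typically Developing" means all diagnostic flags negative, plus
    the explicit ``td`` indicator when present (a negative consensus decision
    in every diagnostic category, not merely the absence of these three).
    """

    def td(df: pd.DataFrame) -> pd.Series:
        base = (df["asd"] == 0) & (df["adhd_inatt"] == 0) & (df["adhd_hyper"] == 0)
        if "td" in df.columns:
            base &= df["td"] == 1
        return base

    return {
        "ADHD-Inattentive": lambda d: d["adhd_inatt"] == 1,
        "ADHD-Hyperactive": lambda d: d["adhd_hyper"] == 1,
        "ASD": lambda d: d["asd"] == 1,
        "Typically Developing": td,
        "Full Sample": lambda d: pd.Series(True, index=d.index),
    }


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 17.5 -> 18)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def load_participants(path) -> pd.DataFrame:
    """Read a participants CSV and code the diagnostic status flags.

    Expects at least ``participant_id``, ``age``, ``sex``, ``presentation``
    and ``asd`` columns; empty cells are missing.  Adds ``adhd_inatt``,
    ``adhd_hyper`` and ``excluded`` columns from the presentation label.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    labels = df["presentation"].fillna("None")
    coded = [code_diagnosis_status(lab) for lab in labels]
    df["adhd_inatt"] = [c.adhd_inatt for c in coded]
    df["adhd_hyper"] = [c.adhd_hyper for c in coded]
    df["excluded"] = [c.excluded for c in coded]
    return df


def summarize_cohort(
    records: pd.DataFrame,
    groups: Mapping[str, Callable[[pd.DataFrame], pd.Series]] | None = None,
    continuous: Sequence[str] | None = None,
    binary: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Descriptive summary per diagnostic group.

    Returns a tidy frame with one row per (group, field): for continuous
    fields the mean and SD over non-missing values (pairwise, not listwise);
    for binary fields the positive count and integer-rounded percentage of
    the group.  Empty groups yield ``n=0`` with missing statistics.
    """
    if groups is None:
        groups = default_groups()
    if continuous is None:
        continuous = [c for c in DEFAULT_CONTINUOUS if c in records.columns]
    if binary is None:
        binary = [c for c in DEFAULT_BINARY if c in records.columns]

    rows = []
    total_n = len(records)
    for gname, predicate in groups.items():
        member = records[predicate(records).astype(bool)]
        n = len(member)
        if n > total_n:  # pragma: no cover - predicate misuse guard
            raise ValueError(f"group {gname!r} larger than cohort")
        for field in continuous:
            vals = member[field].dropna() if n else pd.Series(dtype=float)
            rows.append({
                "group": gname, "field": field, "kind": "continuous",
                "group_n": n, "n_nonmissing": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
            })
        for field in binary:
            if n:
                count = int((member[field] == 1).sum())
                pct = _round_half_away(100.0 * count / n)
            else:
                count, pct = np.nan, np.nan
            rows.append({
                "group": gname, "field": field, "kind": "binary",
                "group_n": n, "count": count, "percent": pct,
            })
    return pd.DataFrame(rows)


def format_cohort_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a :func:`summarize_cohort` frame as printable cells.

    Continuous cells read ``"mean (sd)"``, binary cells ``"count (pct)"``,
    mirroring the conventional clinical Table-1 layout (fields x groups).
    """
    def cell(row) -> str:
        if row["kind"] == "continuous":
            if row["n_nonmissing"] == 0:
                return ""
            return f"{row['mean']:.1f} ({row['sd']:.2f})"
        if not np.isfinite(row.get("count", np.nan)):
            return ""
        return f"{int(row['count'])} ({int(row['percent'])})"

    out = summary.copy()
    out["cell"] = out.apply(cell, axis=1)
    table = out.pivot(index="field", columns="group", values="cell")
    order = [f for f in out["field"].unique()]
    return table.loc[order]


def sex_ratio(records: pd.DataFrame) -> float:
    """Male-to-female ratio (sex coded female=1, male=0), two decimals."""
    males = int((records["sex"] == 0).sum())
    females = int((records["sex"] == 1).sum())
    if females == 0:
        raise ValueError("undefined ratio: no female participants")
    return round(males / females, 2)
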