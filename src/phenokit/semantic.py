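"""Semantic typicality scoring of interview answers.

Each answer to one of the 23 scripted interview questions is represented by a
D-dimensional text embedding.  A normative reference is built per question as
the component-wise median embedding over answers from older typically
developing participants (ages 14-22 by default).  An answer's *typicality* is
its cosine similarity to that reference; per-question scores are averaged
into conceptual domains (narrative detail, factual memory, thematic
understanding, self/character emotion description, preferences), and the
Fisher-Z transform (artanh) of the domain mean is the variable entering
regression, to approximate normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._assets import DEFAULT_DOMAIN_MAP, N_QUESTIONS

__all__ = [
    "ReferenceSet",
    "embedding_columns",
    "build_reference",
    "typicality",
    "cosine_similarity",
    "fisher_z",
    "domain_score",
    "select_typical_answer",
    "semantic_table",
]

ARTANH_EPS = 1e-7  # keeps |z| <= artanh(1 - 1e-7) ~ 8.4: bounded leverage


def embedding_columns(df: pd.DataFrame) -> list[str]:
    """The ``v0..v{D-1}`` vector columns of an embedding table, in order."""
    cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


@dataclass
class ReferenceSet:
    """Per-question normative embeddings (component-wise medians)."""

    medians: pd.DataFrame          # index question_id, columns v0..v{D-1}
    n_contributors: pd.Series      # index question_id

    def vector(self, question_id: int) -> np.ndarray:
        return self.medians.loc[question_id].to_numpy(float)


def build_reference(
    embeddings: pd.DataFrame,
    participants: pd.DataFrame,
    age_band: tuple[float, float] = (14.0, 22.0),
) -> ReferenceSet:
    """Build the typically-developing reference set.

    Contributors are participants with every diagnostic flag negative (and a
    positive ``td`` indicator when the table carries one) whose age falls
    within ``age_band`` (inclusive).  For each question, the reference is the
    component-wise median of the contributors' non-missing answer vectors.
    Questions with zero contributors are a hard error.
    """
    lo, hi = age_band
    td = (participants["asd"] == 0) & (participants["adhd_inatt"] == 0) \
        & (participants["adhd_hyper"] == 0)
    if "excluded" in participants.columns:
        td &= participants["excluded"] == 0
    if "td" in participants.columns:
        td &= participants["td"] == 1
    td &= participants["age"].between(lo, hi)
    td_ids = set(participants.loc[td, "participant_id"])

    vcols = embedding_columns(embeddings)
    contrib = embeddings[
        embeddings["participant_id"].isin(td_ids) & (embeddings["missing"] == 0)
    ]
    counts = contrib.groupby("question_id").size()
    questions = sorted(embeddings["question_id"].unique())
    empty = [int(q) for q in questions if counts.get(q, 0) == 0]
    if empty:
        raise ValueError(f"no typically-developing contributors for question(s) {empty}")
    med = contrib.groupby("question_id")[vcols].median()
    return ReferenceSet(medians=med, n_contributors=counts)


def cosine_similarity(a: np.ndarray, r: np.ndarray) -> float:
    """cos(a, r); NaN (with warning) when either vector has zero norm."""
    na = np.linalg.norm(a)
    nr = np.linalg.norm(r)
    if na == 0 or nr == 0:
        warnings.warn("zero-norm vector in cosine similarity; score is missing",
                      stacklevel=2)
        return float("nan")
    return float(np.dot(a, r) / (na * nr))


def typicality(embeddings: pd.DataFrame, reference: ReferenceSet) -> pd.DataFrame:
    """Cosine similarity of every answer to its question's reference.

    Returns a long frame (participant_id, question_id, similarity); missing
    answers get a missing (NaN) similarity.
    """
    vcols = embedding_columns(embeddings)
    parts = []
    for qid, sub in embeddings.groupby("question_id"):
        r = reference.vector(qid)
        nr = np.linalg.norm(r)
        if nr == 0:
            raise ValueError(f"reference for question {qid} has zero norm")
        V = sub[vcols].to_numpy(float)
        norms = np.linalg.norm(V, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (V @ r) / (norms * nr)
        sim[norms == 0] = np.nan
        sim = np.where(sub["missing"].to_numpy() == 1, np.nan, sim)
        parts.append(pd.DataFrame({
            "participant_id": sub["participant_id"].to_numpy(),
            "question_id": qid,
            "similarity": sim,
        }))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["participant_id", "question_id"], ignore_index=True)


def fisher_z(s, eps: float = ARTANH_EPS):
    """Fisher-Z (artanh) of a similarity in [-1, 1], clipped to stay finite.

    Values outside [-1, 1] beyond a 1e-9 numerical tolerance are an error;
    NaN passes through as NaN.
    """
    arr = np.asarray(s, dtype=float)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) > 1 + 1e-9):
        raise ValueError("similarity outside [-1, 1]")
    clipped = np.clip(arr, -1 + eps, 1 - eps)
    out = np.arctanh(clipped)
    out = np.where(finite, out, np.nan)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def domain_score(
    per_question: pd.DataFrame,
    domain_map: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Average per-question similarities into conceptual domains.

    ``per_question`` is the long (participant_id, question_id, similarity)
    frame from :func:`typicality`.  Each domain score is the mean of the
    participant's non-missing similarities over the domain's questions;
    all-missing propagates missing.  ``<domain>_z`` columns hold the Fisher-Z
    of the domain mean (the regression variable).
    """
    domain_map = domain_map or DEFAULT_DOMAIN_MAP
    known = set(per_question["question_id"].unique())
    for dom, qs in domain_map.items():
        if not qs:
            raise ValueError(f"domain {dom!r} has an empty question set")
        bad = [q for q in qs if not (1 <= q <= N_QUESTIONS)]
        if bad:
            raise ValueError(f"domain {dom!r} references invalid question ids {bad}")
        unknown = [q for q in qs if q not in known]
        if unknown:
            raise ValueError(f"domain {dom!r} references unknown question(s) {unknown}")

    wide = per_question.pivot(index="participant_id", columns="question_id",
                              values="similarity")
    out = pd.DataFrame(index=wide.index)
    for dom, qs in domain_map.items():
        mean = wide[list(qs)].mean(axis=1)  # skips NaN; all-NaN -> NaN
        out[dom] = mean
        out[f"{dom}_z"] = fisher_z(mean.to_numpy())
    out.index.name = "participant_id"
    return out.reset_index()


def select_typical_answer(
    answers_for_question: pd.DataFrame, reference_vector: np.ndarray
) -> str:
    """Participant whose answer is semantically closest to the reference.

    Argmax of cosine similarity over non-missing answers; ties break to the
    lexicographically smallest participant_id.  No usable answer is an error.
    """
    vcols = embedding_columns(answers_for_question)
    sub = answers_for_question[answers_for_question["missing"] == 0]
    if len(sub) == 0:
        raise ValueError("no non-missing answers for this question")
    sub = sub.sort_values("participant_id", kind="stable")
    V = sub[vcols].to_numpy(float)
    norms = np.linalg.norm(V, axis=1)
    nr = np.linalg.norm(reference_vector)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (V @ np.asarray(reference_vector, float)) / (norms * nr)
    sim[norms == 0] = -np.inf
    if not np.isfinite(sim).any():
        raise ValueError("no usable (nonzero-norm) answers for this question")
    best = int(np.argmax(sim))  # first occurrence wins -> smallest id after sort
    return str(sub["participant_id"].iloc[best])


def semantic_table(
    embeddings: pd.DataFrame,
    participants: pd.DataFrame,
    domain_map: Mapping[str, Sequence[int]] | None = None,
    age_band: tuple[float, float] = (14.0, 22.0),
) -> pd.DataFrame:
    """End-to-end semantic scoring: reference -> typicality -> domains.

    Returns one row per participant with ``sim_q<id>`` per-question
    similarities plus per-domain means and their Fisher-Z.
    """
    ref = build_reference(embeddings, participants, age_band)
    sims = typicality(embeddings, ref)
    doms = domain_score(sims, domain_map)
    wide = sims.pivot(index="participant_id", columns="question_id", values="similarity")
    wide.columns = [f"sim_q{int(q)}" for q in wide.columns]
    return wide.reset_index().merge(doms, on="participant_id", how="left")
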