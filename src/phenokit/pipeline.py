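"""End-to-end orchestration: inputs -> scoring -> effect-size matrices.

A run assembles one participant-level table (demographics and diagnostic
flags joined with behavioral features, movement log-displacements and
semantic Fisher-Z domain scores), fits the robust multivariate model to every
outcome in each analysis block, applies Bonferroni control within the block,
and writes per-block effect-size matrices alongside a machine-readable run
report.  Cells failing the significance cut-off are flagged, never dropped.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import movement as mv
from . import semantic as se
from . import stats as st
from . import synth

__all__ = ["RunConfig", "RunResult", "assemble_table", "fit_block", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Either provide input CSV paths (``participants_csv`` etc.) or a
    simulation setup (``simulate=True`` with the generator configs); blocks
    map an analysis-block name to its outcome columns in the assembled
    table.  ``family_sizes`` defaults to the number of outcomes per block.
    """

    outdir: str = "phenokit_run"
    seed: int = 0
    alpha: float = 0.01
    blocks: dict[str, list[str]] = field(default_factory=dict)
    family_sizes: dict[str, int] = field(default_factory=dict)
    # file inputs
    participants_csv: str | None = None
    features_csv: str | None = None
    landmarks_csv: str | None = None
    embeddings_csv: str | None = None
    # or simulation
    simulate: bool = False
    cohort_config: synth.CohortConfig | None = None
    feature_effects: Mapping[str, synth.FeatureEffect] | None = None
    landmark_config: synth.LandmarkSimConfig | None = None
    embedding_config: synth.EmbeddingSimConfig | None = None
    include_landmarks: bool = True
    include_embeddings: bool = True
    semantic_age_band: tuple[float, float] = (14.0, 22.0)
    domain_map: Mapping[str, Sequence[int]] | None = None


@dataclass
class RunResult:
    table: pd.DataFrame
    fits: dict[str, st.FitResult]
    matrices: dict[str, pd.DataFrame]
    report: dict


def assemble_table(config: RunConfig) -> pd.DataFrame:
    """Build the participant-level analysis table from files or simulation."""
    if config.simulate:
        bundle = synth.simulate_dataset(
            config.cohort_config, config.feature_effects, config.landmark_config,
            config.embedding_config, seed=config.seed,
            include_landmarks=config.include_landmarks)
        participants = bundle["participants"]
        table = participants.merge(bundle["features"], on="participant_id", how="left")
        if config.include_landmarks:
            mt = mv.movement_table(bundle["landmark_series"])
            table = table.merge(mt, on="participant_id", how="left")
        if config.include_embeddings:
            sem = se.semantic_table(bundle["embeddings"], participants,
                                    config.domain_map, config.semantic_age_band)
            table = table.merge(sem, on="participant_id", how="left")
        return table

    from .cohort import load_participants
    if config.participants_csv is None:
        raise ValueError("either simulate=True or participants_csv is required")
    table = load_participants(config.participants_csv)
    if config.features_csv:
        table = table.merge(pd.read_csv(config.features_csv,
                                        dtype={"participant_id": str}),
                            on="participant_id", how="left")
    if config.landmarks_csv:
        series = mv.read_landmarks_csv(config.landmarks_csv)
        table = table.merge(mv.movement_table(list(series.values())),
                            on="participant_id", how="left")
    if config.embeddings_csv:
        emb = pd.read_csv(config.embeddings_csv, dtype={"participant_id": str})
        table = table.merge(
            se.semantic_table(emb, table, config.domain_map,
                              config.semantic_age_band),
            on="participant_id", how="left")
    return table


def fit_block(
    table: pd.DataFrame,
    outcomes: Sequence[str],
    family_size: int | None = None,
    alpha: float = 0.01,
) -> tuple[dict[str, st.FitResult], pd.DataFrame]:
    """Fit the multivariate model to each outcome of one analysis block.

    Returns the per-outcome fits and the block's effect-size matrix
    (outcome x predictor) with Bonferroni-adjusted p-values and significance
    flags; non-significant cells carry ``sig=False`` but keep their ES.
    """
    m = family_size if family_size is not None else len(outcomes)
    fits: dict[str, st.FitResult] = {}
    rows = []
    for outcome in outcomes:
        try:
            y, X, n_used = st.build_design(table, outcome)
            fit = st.fit_robust_linear(y, X, outcome=outcome)
        except Exception as exc:
            logger.warning("model for %r failed: %s", outcome, exc)
            rows.append({"outcome": outcome, "error": str(exc)})
            continue
        fits[outcome] = fit
        row: dict[str, object] = {"outcome": outcome, "n_used": n_used,
                                  "dfe": fit.dfe, "converged": fit.converged}
        for term in st.PREDICTORS:
            flag, p_adj = st.bonferroni_flag(fit.table.loc[term, "p"], m, alpha)
            row[f"{term}_es"] = fit.table.loc[term, "es"]
            row[f"{term}_p_adj"] = float(p_adj[0])
            row[f"{term}_sig"] = bool(flag[0])
        rows.append(row)
    return fits, pd.DataFrame(rows)


def run(config: RunConfig) -> RunResult:
    """Execute a full run and write matrices plus a report to ``outdir``."""
    logger.info("assembling analysis table (seed=%d)", config.seed)
    table = assemble_table(config)

    blocks = config.blocks
    if not blocks:
        blocks = _default_blocks(table)
    matrices: dict[str, pd.DataFrame] = {}
    all_fits: dict[str, st.FitResult] = {}
    effects_rows = []
    report: dict = {"seed": config.seed, "alpha": config.alpha,
                    "n_participants": int(len(table)), "blocks": {}, "errors": {}}
    os.makedirs(config.outdir, exist_ok=True)

    for block, outcomes in blocks.items():
        missing = [o for o in outcomes if o not in table.columns]
        if missing:
            raise ValueError(f"block {block!r} outcomes missing from table: {missing}")
        m = config.family_sizes.get(block, len(outcomes))
        fits, matrix = fit_block(table, outcomes, m, config.alpha)
        matrices[block] = matrix
        matrix.to_csv(os.path.join(config.outdir, f"effects_matrix_{block}.csv"),
                      index=False)
        report["blocks"][block] = {
            "family_size": m,
            "outcomes": list(outcomes),
            "n_used": {o: int(f.n_used) for o, f in fits.items()},
            "converged": {o: bool(f.converged) for o, f in fits.items()},
        }
        if "error" in matrix.columns:
            errs = matrix.dropna(subset=["error"]) if matrix["error"].notna().any() else None
            if errs is not None:
                report["errors"][block] = dict(zip(errs["outcome"], errs["error"]))
        for outcome, fit in fits.items():
            all_fits[outcome] = fit
            tab = fit.table.reset_index(names="predictor")
            tab.insert(0, "outcome", outcome)
            tab["block"] = block
            tab["n_used"] = fit.n_used
            tab["dfe"] = fit.dfe
            tab["converged"] = fit.converged
            # the Bonferroni family runs across the block's outcomes, so each
            # term's p is adjusted by the block family size m
            tab["p_adj"] = np.minimum(1.0, m * tab["p"].to_numpy())
            effects_rows.append(tab)

    effects = pd.concat(effects_rows, ignore_index=True) if effects_rows else pd.DataFrame()
    effects.to_csv(os.path.join(config.outdir, "effects.csv"), index=False)

    try:
        from importlib.metadata import version
        pkg_version = version("phenokit")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    report["version"] = pkg_version
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return RunResult(table=table, fits=all_fits, matrices=matrices, report=report)


def _default_blocks(table: pd.DataFrame) -> dict[str, list[str]]:
    """Infer analysis blocks from assembled column naming conventions."""
    blocks: dict[str, list[str]] = {}
    feats = [c for c in table.columns if c.startswith("feature_")]
    if feats:
        blocks["language"] = feats
    movement = [c for c in table.columns
                if c.startswith("movement_") and c.endswith("_log")]
    if movement:
        blocks["movement"] = movement
    semantic = [c for c in table.columns
                if c.endswith("_z") and not c.startswith("movement_")]
    if semantic:
        blocks["semantic"] = semantic
    return blocks
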