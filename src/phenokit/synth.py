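"""Synthetic cohort, feature, landmark and embedding generators.

The restricted source recordings cannot be redistributed, so this module
generates inputs with exactly the statistical structure the analysis chain
assumes, together with the ground truth needed for recovery tests:

* **Cohort** — ages from a truncated normal (mean 10.1, SD 3.39, bounds
  5-22), ~2:1 male-to-female ratio, ADHD-Inattentive / ADHD-Hyperactive /
  ASD status flags with a configurable comorbidity odds-ratio structure
  (defaults: Inattentive->ASD OR 2.3, Hyperactive->ASD OR 1.6, age->
  Hyperactive OR 0.83 per year).  Status flags are drawn sequentially: ADHD
  flags first, then ASD through a logistic link, so the configured odds
  ratios are exact in the generative model.  Logistic intercepts are solved
  numerically so realized marginal prevalences match the configured ones.
* **Features** — linear-in-standardized-predictors outcomes
  ``y = sum(es_k * z_k) * 1 + eps`` with unit-variance Gaussian noise, the
  generative inverse of the effect-size model, so a refit should recover the
  configured ES vector.
* **Landmarks** — random-walk motion whose per-frame step SD scales as
  ``base * exp(age_slope * (age - 10) + hyper_step * adhd_hyper)``, plus
  injected missing runs and high-variance jitter bursts at known locations.
* **Embeddings** — per-question unit prototypes plus isotropic noise whose
  scale decreases with age and increases with ASD on narrative-type
  questions; missing answers injected at a configurable rate.

Everything is deterministic given (config, seed); sub-streams are split with
``numpy.random.SeedSequence`` so modules can be re-run independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import _assets
from .movement import LandmarkSeries

__all__ = [
    "CohortConfig",
    "FeatureEffect",
    "LandmarkSimConfig",
    "EmbeddingSimConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_feature_table",
    "simulate_landmarks",
    "simulate_embeddings",
    "simulate_dataset",
]


@dataclass
class CohortConfig:
    """Generative parameters for the participant table.

    Prevalences are target marginals; comorbidity is parameterized by odds
    ratios on the logistic scale.  Defaults mirror the developmental cohort
    the analysis is designed for (N≈2341, ages 5-22, ~2:1 male:female,
    ADHD-Inattentive 55%, ADHD-Hyperactive 31%, ASD 15%).
    """

    n_participants: int = 2341
    age_mean: float = 10.1
    age_sd: float = 3.39
    age_range: tuple[float, float] = (5.0, 22.0)
    male_fraction: float = 0.665
    p_inatt: float = 0.546
    p_hyper: float = 0.307
    p_asd: float = 0.149
    p_other_unspecified: float = 0.036  # excluded from every downstream fit
    or_inatt_asd: float = 2.3
    or_hyper_asd: float = 1.6
    or_age_hyper: float = 0.83          # per year
    iq_mean_td: float = 106.5
    iq_drop_diagnosed: float = 8.0
    iq_sd: float = 16.0
    iq_missing_rate: float = 0.067
    interview_minutes_mean: float = 4.5
    interview_minutes_sd: float = 1.5

    def validate(self) -> None:
        for name in ("p_inatt", "p_hyper", "p_asd", "p_other_unspecified",
                     "male_fraction", "iq_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("or_inatt_asd", "or_hyper_asd", "or_age_hyper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive odds ratio")
        if self.age_sd <= 0 or self.iq_sd <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass
class GroundTruth:
    """Generative parameters actually used, for recovery tests."""

    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _solve_intercept(lin_pred: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + lin_pred)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def f(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + lin_pred)))) - target

    return brentq(f, -40.0, 40.0, xtol=1e-10)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a participant table with the configured comorbidity structure.

    Returns the records frame (with coded status flags and a DSM-5
    presentation label consistent with them) and the ground truth holding the
    solved logistic intercepts and configured odds ratios.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n = config.n_participants

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng)
    sex = (rng.random(n) >= config.male_fraction).astype(int)  # female=1

    inatt = (rng.random(n) < config.p_inatt).astype(int)

    age_term = np.log(config.or_age_hyper) * (age - config.age_mean)
    b0_hyper = _solve_intercept(age_term, config.p_hyper) if config.p_hyper > 0 else -np.inf
    p_hyper = 1.0 / (1.0 + np.exp(-(b0_hyper + age_term))) if np.isfinite(b0_hyper) else np.zeros(n)
    hyper = (rng.random(n) < p_hyper).astype(int)

    asd_term = np.log(config.or_inatt_asd) * inatt + np.log(config.or_hyper_asd) * hyper
    b0_asd = _solve_intercept(asd_term, config.p_asd) if config.p_asd > 0 else -np.inf
    p_asd = 1.0 / (1.0 + np.exp(-(b0_asd + asd_term))) if np.isfinite(b0_asd) else np.zeros(n)
    asd = (rng.random(n) < p_asd).astype(int)

    # ADHD other/unspecified overrides the drawn flags and is excluded downstream
    other = (rng.random(n) < config.p_other_unspecified).astype(int)
    inatt = np.where(other == 1, 0, inatt)
    hyper = np.where(other == 1, 0, hyper)
    excluded = other

    presentation = np.select(
        [other == 1, (inatt == 1) & (hyper == 1), inatt == 1, hyper == 1],
        ["OtherUnspecified", "Combined", "Inattentive", "Hyperactive"],
        default="None",
    )

    any_diag = ((inatt == 1) | (hyper == 1) | (asd == 1)).astype(int)
    iq_full = (config.iq_mean_td - config.iq_drop_diagnosed * any_diag
               + rng.normal(0.0, config.iq_sd, n))
    iq_verbal = iq_full + 3.0 + rng.normal(0.0, 5.0, n)
    iq_missing = rng.random(n) < config.iq_missing_rate
    iq_full = np.where(iq_missing, np.nan, iq_full)
    iq_verbal = np.where(iq_missing, np.nan, iq_verbal)

    # clinical scale scores: simple linear-in-flags emulations with noise
    swan_inatt = -0.3 + 1.4 * inatt + rng.normal(0, 0.9, n)
    swan_hyper = -0.4 + 1.2 * hyper - 0.05 * (age - config.age_mean) + rng.normal(0, 0.9, n)
    assq = 2.3 + 15.0 * asd + 4.0 * ((inatt | hyper) & ~asd.astype(bool)) + rng.normal(0, 5.0, n)
    mfq = np.maximum(0, 4.7 + 5.0 * any_diag + rng.normal(0, 6.0, n))
    scared = np.maximum(0, 9.4 + 5.5 * any_diag + rng.normal(0, 9.0, n))
    cbcl_ext = np.maximum(0, 5.6 + 9.0 * hyper + 3.0 * inatt + rng.normal(0, 7.0, n))
    cbcl_int = np.maximum(0, 5.3 + 6.0 * asd + 4.0 * inatt + rng.normal(0, 6.0, n))

    df = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "iq_full": iq_full,
        "iq_verbal": iq_verbal,
        "presentation": presentation,
        "asd": asd,
        "adhd_inatt": inatt,
        "adhd_hyper": hyper,
        "excluded": excluded,
        "td": ((any_diag == 0) & (other == 0)).astype(int),
        "swan_inatt": swan_inatt,
        "swan_hyper": swan_hyper,
        "assq": assq,
        "mfq": mfq,
        "scared": scared,
        "cbcl_ext": cbcl_ext,
        "cbcl_int": cbcl_int,
        "interview_minutes": np.maximum(
            1.0, rng.normal(config.interview_minutes_mean,
                            config.interview_minutes_sd, n)),
    })
    gt = GroundTruth({
        "seed": seed,
        "intercept_hyper": b0_hyper,
        "intercept_asd": b0_asd,
        "or_inatt_asd": config.or_inatt_asd,
        "or_hyper_asd": config.or_hyper_asd,
        "or_age_hyper": config.or_age_hyper,
    })
    return df, gt


@dataclass
class FeatureEffect:
    """Standardized effect sizes of the six predictors on one feature."""

    es: dict[str, float]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        known = {"age", "iq_full", "sex", "adhd_inatt", "adhd_hyper", "asd"}
        bad = set(self.es) - known
        if bad:
            raise ValueError(f"unknown predictor name(s) in effect spec: {sorted(bad)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Default effect structure for a language-like feature: strong age effect,
#: reliable IQ effect, small sex and diagnostic effects, inattention null.
DEFAULT_FEATURE_EFFECTS: dict[str, FeatureEffect] = {
    "feature_language": FeatureEffect(
        es={"age": 0.40, "iq_full": 0.27, "sex": 0.08,
            "adhd_inatt": 0.00, "adhd_hyper": 0.12, "asd": 0.13},
        noise_sd=1.0),
}


def simulate_feature_table(
    records: pd.DataFrame,
    effects: Mapping[str, FeatureEffect] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate behavioral features as the generative inverse of the ES model.

    Each feature is ``y = sum_k es_k * z_k + eps`` with z the predictor
    standardized over the analyzable sample (excluded rows and rows with
    missing predictors drop out as missing features) and
    ``eps ~ N(0, noise_sd^2)``.  Standardization constants are stored in the
    ground truth.
    """
    effects = dict(effects) if effects is not None else dict(DEFAULT_FEATURE_EFFECTS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    preds = ["age", "iq_full", "sex", "adhd_inatt", "adhd_hyper", "asd"]
    usable = (records.get("excluded", pd.Series(0, index=records.index)) != 1)
    usable &= records[preds].notna().all(axis=1)

    Z = pd.DataFrame(index=records.index, dtype=float)
    standardization = {}
    sub = records.loc[usable, preds].astype(float)
    for pcol in preds:
        mu = sub[pcol].mean()
        sd = sub[pcol].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {pcol!r} is constant; cannot standardize")
        Z[pcol] = (records[pcol].astype(float) - mu) / sd
        standardization[pcol] = {"mean": float(mu), "sd": float(sd)}

    out = pd.DataFrame({"participant_id": records["participant_id"]})
    truth = {"seed": seed, "standardization": standardization, "effects": {}}
    for fname, eff in effects.items():
        y = np.zeros(len(records))
        for pcol, es in eff.es.items():
            y = y + es * Z[pcol].to_numpy()
        y = y + rng.normal(0.0, eff.noise_sd, len(records)) if eff.noise_sd > 0 else y
        y = np.where(usable.to_numpy(), y, np.nan)
        out[fname] = y
        truth["effects"][fname] = {"es": dict(eff.es), "noise_sd": eff.noise_sd}
    return out, GroundTruth(truth)


@dataclass
class LandmarkSimConfig:
    """Generative parameters for one participant's landmark series.

    Step SDs are in image-normalized coordinate units per frame.  The
    hyperactivity increment acts on the log of the step SD, so group contrasts
    in log mean displacement are additive.
    """

    fps: float = 30.0
    duration_s: float = 20.0
    base_step_body: float = 0.004
    base_step_face: float = 0.002
    age_slope: float = -0.04          # per year, on log step SD
    hyper_step: float = 0.35          # log-scale increment for ADHD-Hyperactive
    age_ref: float = 10.0
    head_wobble_deg: float = 2.0      # global rigid wobble, removed by alignment
    missing_runs_per_min: float = 2.0
    missing_run_frames: tuple[int, int] = (15, 60)
    jitter_bursts_per_min: float = 1.0
    jitter_x_sd_face: float = 0.5
    jitter_x_sd_pose: float = 0.05
    measurement_noise: float = 0.0


def simulate_landmarks(
    record: Mapping, config: LandmarkSimConfig | None = None, seed: int = 0
) -> tuple[LandmarkSeries, GroundTruth]:
    """Random-walk landmark series for one participant.

    Per-frame step SD is ``base * exp(age_slope*(age-age_ref) +
    hyper_step*adhd_hyper)``.  Face landmarks additionally ride a global
    rigid head wobble (rotation about z plus translation) that affine
    alignment is expected to remove.  Missing runs and x-jitter bursts are
    injected at the configured rates; their locations are recorded in the
    ground truth.
    """
    config = config or LandmarkSimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    T = int(round(config.fps * config.duration_s))
    lm_ids = list(_assets.ALL_LANDMARKS)
    L = len(lm_ids)
    classes = np.array([_assets.LANDMARK_CLASS[l] for l in lm_ids])
    face = classes == "face"

    age = float(record["age"])
    hyper = int(record["adhd_hyper"])
    log_scale = config.age_slope * (age - config.age_ref) + config.hyper_step * hyper
    step_sd = np.where(face, config.base_step_face, config.base_step_body) * np.exp(log_scale)

    anchors = np.array([
        _assets.CANONICAL_FACE.get(l, None) or {
            "left_shoulder": (0.35, 0.75, 0.0), "right_shoulder": (0.65, 0.75, 0.0),
            "left_elbow": (0.28, 0.92, 0.0), "right_elbow": (0.72, 0.92, 0.0),
            "left_wrist": (0.25, 1.05, 0.0), "right_wrist": (0.75, 1.05, 0.0),
        }[l] for l in lm_ids
    ], dtype=float)

    steps = rng.normal(0.0, 1.0, (T, L, 3)) * step_sd[None, :, None]
    local = np.cumsum(steps, axis=0)
    coords = anchors[None, :, :] + local

    # global rigid head wobble on the face landmarks (slow sinusoid + noise)
    theta = np.deg2rad(config.head_wobble_deg) * np.sin(
        2 * np.pi * 0.2 * np.arange(T) / config.fps + rng.uniform(0, 2 * np.pi))
    shift = 0.005 * config.head_wobble_deg * np.stack([
        np.sin(2 * np.pi * 0.1 * np.arange(T) / config.fps + rng.uniform(0, 2 * np.pi)),
        np.cos(2 * np.pi * 0.13 * np.arange(T) / config.fps + rng.uniform(0, 2 * np.pi)),
        np.zeros(T)], axis=1)
    centroid = anchors[face].mean(axis=0)
    rel = coords[:, face, :] - centroid
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rx = cos_t[:, None] * rel[:, :, 0] - sin_t[:, None] * rel[:, :, 1]
    ry = sin_t[:, None] * rel[:, :, 0] + cos_t[:, None] * rel[:, :, 1]
    rel = np.stack([rx, ry, rel[:, :, 2]], axis=2)
    coords[:, face, :] = rel + centroid + shift[:, None, :]

    if config.measurement_noise > 0:
        coords = coords + rng.normal(0, config.measurement_noise, coords.shape)

    present = np.ones((T, L), dtype=bool)
    minutes = T / config.fps / 60.0
    missing_runs = []
    n_runs = rng.poisson(config.missing_runs_per_min * minutes)
    for _ in range(n_runs):
        lm = int(rng.integers(L))
        length = int(rng.integers(config.missing_run_frames[0],
                                  config.missing_run_frames[1] + 1))
        start = int(rng.integers(0, max(1, T - length)))
        present[start:start + length, lm] = False
        missing_runs.append({"landmark": lm_ids[lm], "start": start, "length": length})

    jitter_bursts = []
    n_bursts = rng.poisson(config.jitter_bursts_per_min * minutes)
    for _ in range(n_bursts):
        lm = int(rng.integers(L))
        start = int(rng.integers(0, max(1, T - 10)))
        sd = config.jitter_x_sd_face if classes[lm] == "face" else config.jitter_x_sd_pose
        coords[start:start + 10, lm, 0] += rng.normal(0, sd, min(10, T - start))
        jitter_bursts.append({"landmark": lm_ids[lm], "start": start, "length": 10})

    series = LandmarkSeries(str(record["participant_id"]), config.fps, coords,
                            present, lm_ids)
    gt = GroundTruth({
        "seed": seed, "step_sd": step_sd, "log_scale": log_scale,
        "missing_runs": missing_runs, "jitter_bursts": jitter_bursts,
    })
    return series, gt


@dataclass
class EmbeddingSimConfig:
    """Generative parameters for the answer-embedding table.

    Answers are ``prototype_q + sigma * z / sqrt(D)`` with unit prototypes,
    so the expected noise norm is ``sigma`` and cosine typicality decreases
    monotonically in sigma.  Sigma shrinks with age and grows with ASD on the
    configured narrative-type questions.
    """

    dim: int = 32                    # study embeddings are 768-d; configurable
    n_questions: int = _assets.N_QUESTIONS
    sigma0: float = 0.8
    age_coef: float = 0.04           # per year, on log sigma
    asd_extra: float = 0.30          # log-scale sigma increase for ASD
    narrative_questions: tuple[int, ...] = (1, 2, 3, 4, 9, 10, 11, 14, 17, 20, 23)
    age_ref: float = 10.0
    missing_rate: float = 0.10

    def validate(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")


def simulate_embeddings(
    records: pd.DataFrame,
    config: EmbeddingSimConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Answer embeddings for every participant x question."""
    config = config or EmbeddingSimConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    D, Q = config.dim, config.n_questions

    protos = rng.normal(0, 1, (Q, D))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)

    n = len(records)
    age = records["age"].to_numpy(float)
    asd = records["asd"].to_numpy(int)
    narrative = np.zeros(Q, dtype=bool)
    narrative[[q - 1 for q in config.narrative_questions]] = True

    rows = []
    vecs = []
    sigmas = np.empty((n, Q))
    for qi in range(Q):
        log_sigma = (np.log(config.sigma0 if config.sigma0 > 0 else 1.0)
                     - config.age_coef * (age - config.age_ref)
                     + (config.asd_extra * asd if narrative[qi] else 0.0))
        sigma = np.exp(log_sigma) if config.sigma0 > 0 else np.zeros(n)
        sigmas[:, qi] = sigma
        noise = rng.normal(0, 1, (n, D)) / np.sqrt(D)
        V = protos[qi][None, :] + sigma[:, None] * noise
        missing = rng.random(n) < config.missing_rate
        rows.append(pd.DataFrame({
            "participant_id": records["participant_id"].to_numpy(),
            "question_id": qi + 1,
            "missing": missing.astype(int),
        }))
        V = np.where(missing[:, None], np.nan, V)
        vecs.append(V)
    table = pd.concat(rows, ignore_index=True)
    vmat = np.vstack(vecs)
    for d in range(D):
        table[f"v{d}"] = vmat[:, d]
    gt = GroundTruth({
        "seed": seed, "dim": D, "sigma0": config.sigma0,
        "age_coef": config.age_coef, "asd_extra": config.asd_extra,
        "narrative_questions": list(config.narrative_questions),
        "mean_sigma_per_question": sigmas.mean(axis=0),
    })
    return table, gt


def simulate_dataset(
    cohort: CohortConfig | None = None,
    effects: Mapping[str, FeatureEffect] | None = None,
    landmarks: LandmarkSimConfig | None = None,
    embeddings: EmbeddingSimConfig | None = None,
    seed: int = 0,
    outdir=None,
    include_landmarks: bool = True,
) -> dict:
    """Generate the full four-table input bundle (optionally written to disk).

    Returns a dict with keys ``participants``, ``features``, ``embeddings``,
    ``landmark_series`` (list of LandmarkSeries) and ``groundtruth``.
    """
    records, gt_cohort = simulate_cohort(cohort, seed)
    features, gt_feat = simulate_feature_table(records, effects, seed)
    emb, gt_emb = simulate_embeddings(records, embeddings, seed)
    series_list = []
    gt_lm = []
    if include_landmarks:
        ss = np.random.SeedSequence([seed, 505]).generate_state(len(records))
        for (_, rec), s in zip(records.iterrows(), ss):
            series, g = simulate_landmarks(rec, landmarks, int(s) % (2**31))
            series_list.append(series)
            gt_lm.append(g.params)
    truth = GroundTruth({
        "cohort": gt_cohort.params,
        "features": gt_feat.params,
        "embeddings": {k: v for k, v in gt_emb.params.items()},
        "landmarks_n": len(gt_lm),
    })
    bundle = {
        "participants": records,
        "features": features,
        "embeddings": emb,
        "landmark_series": series_list,
        "groundtruth": truth,
    }
    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        records.to_csv(os.path.join(outdir, "participants.csv"), index=False)
        features.to_csv(os.path.join(outdir, "features.csv"), index=False)
        emb.to_csv(os.path.join(outdir, "embeddings.csv"), index=False)
        if include_landmarks:
            pd.concat([s.to_frame() for s in series_list], ignore_index=True
                      ).to_csv(os.path.join(outdir, "landmarks.csv"), index=False)
        truth.to_json(os.path.join(outdir, "groundtruth.json"))
    return bundle
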