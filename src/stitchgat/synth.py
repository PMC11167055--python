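"""Synthetic multi-institution cohort generator.

Emulates the statistical structure of the study population so every
downstream stage is testable without the restricted clinical dataset:

* five institutions with surgeons nested in institutions;
* a six-dimensional latent ability per surgeon whose correlation structure
  follows the prior sub-skill graph (correlation ``edge_corr`` exactly on
  graph edges, zero elsewhere);
* per-stitch latent factors = surgeon ability + stitch-level jitter;
* six correlated binary labels: sub-skill *k* is rated ideal when
  ``own_signal * f_k + sum_{j in N(k)} beta_kj * f_j + noise`` exceeds a
  threshold chosen to hit the configured prevalence (the cross-signal terms
  make neighbour information genuinely useful for assessment — the property
  the joint model is designed to exploit);
* per-sub-skill feature vectors informative about their own latent factor
  only, plus a per-institution affine shift (institution heterogeneity);
* smooth random-walk kinematic streams with unit quaternions whose motion
  amplitude carries a weak trace of the latent factor;
* a patient outcome table whose 3-month continence probability is driven by
  surgeon skill through a logistic model with age/BMI/PSA/prostate-volume
  covariate terms.

Identical seeds produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import (
    ClipRef,
    Cohort,
    FeatureStore,
    KinematicFrame,
    StitchRecord,
    SUBSKILL_ORDER,
    SubSkill,
)
from .gat import DEFAULT_PAIRS, PriorGraph, build_prior_graph

__all__ = ["SynthConfig", "LatentTruth", "generate_cohort",
           "generate_kinematics", "generate_outcomes"]


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Cohort-generator parameters.

    ``cross_signal`` may be a single float applied to every prior-graph edge
    (both directions) or a mapping ``{(target_code, source_code): beta}`` for
    planted asymmetric structure.
    """

    n_institutions: int = 5
    surgeons_per_institution: int = 8
    stitches_per_surgeon: int = 25
    feature_dim: int = 128
    edge_corr: float = 0.4          # latent correlation on prior-graph edges
    cross_signal: float | Mapping[tuple[str, str], float] = 0.5
    own_signal: float = 1.0
    noise_sd: float = 0.5           # label-threshold noise
    stitch_sd: float = 0.5          # stitch-level latent jitter
    feature_noise_sd: float = 1.0
    institution_scale_jitter: float = 0.3
    kinematic_len: tuple[int, int] = (16, 40)  # inclusive frame-count range per clip
    kinematic_signal: float = 0.3
    prevalence: float = 0.5
    prior_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    # outcome model
    cases_per_surgeon: int = 10
    outcome_intercept: float = 0.4
    outcome_skill_coefs: Mapping[str, float] = field(default_factory=dict)
    outcome_covariate_coefs: tuple[float, float, float, float] = (
        -0.03, -0.05, -0.04, -0.01)  # age, BMI, PSA, prostate volume (centered)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_institutions", "surgeons_per_institution",
                     "stitches_per_surgeon", "feature_dim", "cases_per_surgeon"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not (0 <= self.edge_corr < 1):
            raise ConfigError("edge_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 < self.prevalence < 1):
            raise ConfigError("prevalence must be in (0, 1)")
        lo, hi = self.kinematic_len
        if lo < 1 or hi < lo:
            raise ConfigError("kinematic_len must satisfy 1 <= lo <= hi")
        # latent covariance must be positive definite
        sigma = self.latent_cov()
        if np.linalg.eigvalsh(sigma).min() <= 1e-10:
            raise ConfigError("implied latent covariance is not positive definite")

    def graph(self) -> PriorGraph:
        return build_prior_graph(self.prior_pairs)

    def latent_cov(self) -> np.ndarray:
        adj = build_prior_graph(self.prior_pairs).adjacency
        sigma = np.where(adj.astype(bool), self.edge_corr, 0.0)
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def beta_matrix(self) -> np.ndarray:
        """(6, 6) cross-signal matrix B with B[k, j] = beta for j in N(k)."""
        adj = self.graph().adjacency.copy()
        np.fill_diagonal(adj, 0)
        if isinstance(self.cross_signal, Mapping):
            B = np.zeros((6, 6))
            for (tgt, src), beta in self.cross_signal.items():
                k, j = SubSkill.from_code(tgt).index, SubSkill.from_code(src).index
                if not adj[k, j]:
                    raise ConfigError(f"cross_signal on non-edge {tgt}<-{src}")
                B[k, j] = float(beta)
        else:
            B = adj * float(self.cross_signal)
        return B


@dataclass
class LatentTruth:
    """Ground truth used by parameter-recovery tests."""

    surgeon_ability: dict[str, np.ndarray]           # surgeon -> z in R^6
    stitch_factors: dict[str, np.ndarray]            # stitch -> f in R^6
    beta_matrix: np.ndarray                          # planted edge strengths
    feature_directions: np.ndarray                   # (6, feature_dim)
    institution_shift: dict[str, np.ndarray]         # institution -> (6, feature_dim)
    institution_beta_scale: dict[str, float]
    label_thresholds: np.ndarray                     # (6,)
    outcome_coefs: dict | None = None


def _label_threshold(config: SynthConfig) -> np.ndarray:
    """Per-sub-skill threshold achieving the configured prevalence.

    The linear index ``c_k^T f + eps`` is Gaussian; its variance follows from
    the latent covariance of f (= Sigma + stitch_sd^2 I) and the noise.
    """
    sigma_f = config.latent_cov() + config.stitch_sd**2 * np.eye(6)
    B = config.beta_matrix()
    C = config.own_signal * np.eye(6) + B          # rows are c_k
    var = np.einsum("ki,ij,kj->k", C, sigma_f, C) + config.noise_sd**2
    return norm.ppf(1.0 - config.prevalence) * np.sqrt(var)


def generate_kinematics(
    rng: np.random.Generator,
    config: SynthConfig,
    latent: np.ndarray,
    start_frame: int = 0,
) -> tuple[list[KinematicFrame], dict[SubSkill, list[int]]]:
    """One per-stitch kinematic log: six consecutive sub-phase windows.

    Positions follow a smooth random walk whose step amplitude carries a weak
    monotone trace of the sub-skill's latent factor; quaternions are random
    walks on the unit sphere (always unit norm); each frame includes a camera
    pose.
    """
    lo, hi = config.kinematic_len
    lengths = rng.integers(lo, hi + 1, size=6)
    frames: list[KinematicFrame] = []
    clip_ids: dict[SubSkill, list[int]] = {}
    fid = start_frame
    pos = rng.normal(0, 0.2, size=(10, 3))
    quat = rng.normal(size=(10, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    cam_pos = rng.normal(0, 0.1, size=3)
    cam_quat = rng.normal(size=4)
    cam_quat /= np.linalg.norm(cam_quat)
    for s, T in zip(SUBSKILL_ORDER, lengths):
        amp = 0.05 * np.exp(config.kinematic_signal * np.tanh(latent[s.index]))
        ids = []
        for _ in range(int(T)):
            pos = pos + rng.normal(0, amp, size=(10, 3))
            quat = quat + rng.normal(0, 0.05, size=(10, 4))
            quat /= np.linalg.norm(quat, axis=1, keepdims=True)
            cam = np.concatenate([cam_pos, cam_quat])
            frames.append(
                KinematicFrame(
                    frame_id=fid,
                    poses=np.concatenate([pos, quat], axis=1),
                    camera=cam.copy(),
                )
            )
            ids.append(fid)
            fid += 1
        clip_ids[s] = ids
    return frames, clip_ids


def generate_cohort(
    config: SynthConfig,
) -> tuple[Cohort, FeatureStore, LatentTruth]:
    """Draw a full synthetic cohort, its stage-1-like features and the truth."""
    rng = np.random.default_rng(config.seed)
    sigma = config.latent_cov()
    chol = np.linalg.cholesky(sigma)
    B = config.beta_matrix()
    thresholds = _label_threshold(config)

    w = rng.normal(size=(6, config.feature_dim))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    w *= config.own_signal

    institutions = [f"inst_{chr(65 + i)}" for i in range(config.n_institutions)]
    shift = {
        inst: rng.normal(0, config.institution_scale_jitter, size=(6, config.feature_dim))
        for inst in institutions
    }
    beta_scale = {
        inst: float(np.clip(1.0 + rng.normal(0, config.institution_scale_jitter), 0.1, None))
        for inst in institutions
    }

    records: list[StitchRecord] = []
    store = FeatureStore(encoder_id="synthetic", dim=config.feature_dim)
    ability: dict[str, np.ndarray] = {}
    factors: dict[str, np.ndarray] = {}

    for inst in institutions:
        for si in range(config.surgeons_per_institution):
            surgeon = f"{inst}_s{si:02d}"
            z = chol @ rng.normal(size=6)
            ability[surgeon] = z
            for ti in range(config.stitches_per_surgeon):
                sid = f"{surgeon}_t{ti:03d}"
                f = z + config.stitch_sd * rng.normal(size=6)
                factors[sid] = f
                index = (
                    config.own_signal * f
                    + beta_scale[inst] * (B @ f)
                    + config.noise_sd * rng.normal(size=6)
                )
                labels = {
                    s: int(index[s.index] > thresholds[s.index]) for s in SUBSKILL_ORDER
                }
                log, clip_ids = generate_kinematics(rng, config, f)
                clips = {
                    s: ClipRef(stitch_id=sid, subskill=s, frame_ids=clip_ids[s])
                    for s in SUBSKILL_ORDER
                }
                for s in SUBSKILL_ORDER:
                    x = (
                        f[s.index] * w[s.index]
                        + shift[inst][s.index]
                        + config.feature_noise_sd * rng.normal(size=config.feature_dim)
                    )
                    store.put(sid, s, x)
                records.append(
                    StitchRecord(
                        stitch_id=sid,
                        surgeon_id=surgeon,
                        institution_id=inst,
                        clips=clips,
                        kinematics={s: log for s in SUBSKILL_ORDER},
                        labels=labels,
                    )
                )

    truth = LatentTruth(
        surgeon_ability=ability,
        stitch_factors=factors,
        beta_matrix=B,
        feature_directions=w,
        institution_shift=shift,
        institution_beta_scale=beta_scale,
        label_thresholds=thresholds,
    )
    return Cohort(records=records, institutions=institutions), store, truth


def generate_outcomes(
    cohort: Cohort, truth: LatentTruth, config: SynthConfig
) -> pd.DataFrame:
    """Patient outcome table: one row per prostatectomy case.

    Continence recovery at 3 months follows
    ``logit(P) = a0 + sum_k a_k * mean_skill_k + covariate terms`` where
    ``mean_skill_k`` is the surgeon's mean ideal rate for sub-skill k over
    their stitches, and the covariates (age, BMI, PSA, prostate volume) enter
    mean-centered.  Coefficients are recorded in ``truth.outcome_coefs``.
    """
    rng = np.random.default_rng(config.seed + 1)
    alpha = np.array(
        [float(config.outcome_skill_coefs.get(s.code, 0.0)) for s in SUBSKILL_ORDER]
    )
    cov_coefs = np.asarray(config.outcome_covariate_coefs, dtype=float)
    cov_means = np.array([64.0, 27.5, 8.0, 45.0])

    labels = cohort.labels_matrix()
    surgeons = np.array([r.surgeon_id for r in cohort.records])
    rows = []
    for surgeon in dict.fromkeys(surgeons):  # insertion order, deterministic
        mask = surgeons == surgeon
        mean_skill = labels[mask].mean(axis=0)
        inst = next(r.institution_id for r in cohort.records if r.surgeon_id == surgeon)
        for ci in range(config.cases_per_surgeon):
            age = rng.normal(64, 7)
            bmi = rng.normal(27.5, 4)
            psa = np.exp(rng.normal(np.log(7.0), 0.5))
            vol = rng.normal(45, 12)
            covs = np.array([age, bmi, psa, vol]) - cov_means
            logit = config.outcome_intercept + alpha @ mean_skill + cov_coefs @ covs
            p = 1.0 / (1.0 + np.exp(-logit))
            rows.append(
                {
                    "case_id": f"{surgeon}_c{ci:03d}",
                    "surgeon_id": surgeon,
                    "institution_id": inst,
                    "age": age,
                    "bmi": bmi,
                    "psa": psa,
                    "prostate_volume": vol,
                    **{f"skill_{s.code}": mean_skill[s.index] for s in SUBSKILL_ORDER},
                    "continence_3mo": int(rng.random() < p),
                }
            )
    truth.outcome_coefs = {
        "intercept": config.outcome_intercept,
        "skill": {s.code: alpha[s.index] for s in SUBSKILL_ORDER},
        "covariates": dict(zip(("age", "bmi", "psa", "prostate_volume"), cov_coefs)),
    }
    return pd.DataFrame(rows)
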