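"""End-to-end experiment orchestration.

Reproduces the shape of the study's main experiment on synthetic data:
simulate a multi-institution cohort, build per-node inputs (stage-1 features
concatenated with flattened aligned kinematics), run leave-one-institution-out
cross-validation for the four arms (independent, joint, w/o attention,
w/o kinematics), average attention maps, and — when configured — associate
skill scores with the synthetic continence outcome.

All randomness derives from a single integer seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Cohort, FeatureStore, SUBSKILL_ORDER, SubSkill
from .evaluate import ARM_ORDER, FoldResult, compute_auc, loio_splits, summarize
from .gat import (
    JointConfig,
    PriorGraph,
    build_prior_graph,
    extract_attention,
    predict_joint,
    train_stage2,
)
from .kinematics import flatten, prepare_clip_kinematics
from .outcomes import attach_case_scores, fit_multivariable, fit_univariable, roc_from_predictions
from .stage1 import Stage1Config, predict_independent, train_stage1
from .synth import LatentTruth, SynthConfig, generate_cohort, generate_outcomes

__all__ = [
    "RunConfig",
    "seed_everything",
    "substream",
    "substream_seed",
    "assemble_node_inputs",
    "run_fold_arms",
    "run_experiment",
]


def substream_seed(seed: int, name: str) -> int:
    """Stable, named derived seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))


_SEED_STATE: dict[str, int] = {}


def seed_everything(seed: int | None = None) -> int:
    """Fix the root seed for subsequent configs; returns the seed used."""
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31 - 1))
    _SEED_STATE["seed"] = int(seed)
    return int(seed)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str | None = None
    arms: tuple[str, ...] = ARM_ORDER
    target_len: int = 24
    include_outcomes: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    joint: JointConfig = field(default_factory=JointConfig)

    def __post_init__(self):
        unknown = [a for a in self.arms if a not in ARM_ORDER]
        if unknown:
            raise ValueError(f"unknown arms: {unknown}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Strict construction: unknown keys anywhere are rejected."""
        def build(dc, section: dict, where: str):
            names = {f.name for f in dataclasses.fields(dc)}
            unknown = set(section) - names
            if unknown:
                raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
            fixed = dict(section)
            for k, v in fixed.items():
                if isinstance(v, list):
                    fixed[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            return dc(**fixed)

        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for section, dc in (("synth", SynthConfig), ("stage1", Stage1Config),
                            ("joint", JointConfig)):
            if section in kwargs:
                kwargs[section] = build(dc, kwargs[section], section)
        if "arms" in kwargs:
            kwargs["arms"] = tuple(kwargs["arms"])
        return cls(**kwargs)

    def hash(self) -> str:
        # output_dir is deployment detail, not part of the experiment identity
        blob = dataclasses.asdict(self)
        blob.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(_jsonable(blob), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def quickstart_config(seed: int = 0, output_dir: str | None = None) -> RunConfig:
    """Small four-arm experiment: 5 institutions x 5 surgeons x 8 stitches
    (200 stitches), compact model widths and a 10-epoch override, so the full
    pipeline runs end to end in well under a minute on one CPU."""
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        target_len=4,
        include_outcomes=True,
        synth=SynthConfig(
            n_institutions=5,
            surgeons_per_institution=5,
            stitches_per_surgeon=8,
            feature_dim=16,
            kinematic_len=(4, 10),
            cases_per_surgeon=8,
            outcome_skill_coefs={"RP": 2.0},
        ),
        stage1=Stage1Config(feature_dim=16, epochs=30),
        joint=JointConfig(feature_dim=16, target_len=4, hidden=32, att_hidden=16,
                          out_dim=16, epochs=30),
    )


# ---------------------------------------------------------------------------
# Node input assembly
# ---------------------------------------------------------------------------


def assemble_node_inputs(
    cohort: Cohort,
    store: FeatureStore,
    target_len: int,
    include_kinematics: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 6, feature_dim + 70*target_len) node inputs and (n, 6) labels.

    The kinematics block is the flattened camera-relative, normalized,
    length-``target_len`` sequence for the sub-skill's clip; with
    ``include_kinematics=False`` it is zero (same dimensionality).
    """
    feat_dim = store.dim
    kin_dim = 70 * target_len
    n = len(cohort.records)
    X = np.zeros((n, 6, feat_dim + kin_dim))
    Y = np.zeros((n, 6), dtype=int)
    for i, r in enumerate(cohort.records):
        for s in SUBSKILL_ORDER:
            k = s.index
            X[i, k, :feat_dim] = store.get(r.stitch_id, s)
            if include_kinematics:
                ak = prepare_clip_kinematics(r.kinematics[s], r.clips[s], target_len)
                X[i, k, feat_dim:] = flatten(ak)
            Y[i, k] = r.labels[s]
    return X, Y


# ---------------------------------------------------------------------------
# Arms
# ---------------------------------------------------------------------------


def _train_independent_arm(
    cohort: Cohort,
    store: FeatureStore,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    stage1_cfg: Stage1Config,
) -> np.ndarray:
    """(n_test, 6) independent-arm probabilities from per-sub-skill heads."""
    records = cohort.records
    train_cohort = Cohort(
        records=[records[i] for i in train_idx], institutions=cohort.institutions
    )
    probs = np.zeros((len(test_idx), 6))
    for s in SUBSKILL_ORDER:
        model, _, _ = train_stage1(train_cohort, s, stage1_cfg, features=store)
        Xt = np.stack([store.get(records[i].stitch_id, s) for i in test_idx])
        probs[:, s.index] = predict_independent(model, features_matrix=Xt)
    return probs


def _joint_cfg_for_arm(base: JointConfig, arm: str) -> JointConfig:
    if arm == "joint":
        return replace(base, use_attention=True, use_kinematics=True)
    if arm == "no_attention":
        return replace(base, use_attention=False, use_kinematics=True)
    if arm == "no_kinematics":
        return replace(base, use_attention=True, use_kinematics=False)
    raise ValueError(f"unknown joint arm {arm!r}")


def run_fold_arms(
    cohort: Cohort,
    store: FeatureStore,
    X: np.ndarray,
    Y: np.ndarray,
    graph: PriorGraph,
    config: RunConfig,
) -> dict[str, list[FoldResult]]:
    """Train and score every requested arm on every LOIO fold."""
    results: dict[str, list[FoldResult]] = {a: [] for a in config.arms}
    for fold_i, (train_idx, test_idx, inst) in enumerate(loio_splits(cohort)):
        y_test = Y[test_idx]
        for arm in config.arms:
            attention = None
            if arm == "independent":
                s1cfg = replace(
                    config.stage1,
                    feature_dim=store.dim,
                    seed=substream_seed(config.seed, f"stage1/{inst}"),
                )
                probs = _train_independent_arm(cohort, store, train_idx, test_idx, s1cfg)
            else:
                jcfg = _joint_cfg_for_arm(config.joint, arm)
                jcfg = replace(
                    jcfg,
                    feature_dim=store.dim,
                    target_len=config.target_len,
                    seed=substream_seed(config.seed, f"stage2/{arm}/{inst}"),
                )
                params = train_stage2(X[train_idx], Y[train_idx], graph, jcfg)
                probs = predict_joint(params, X[test_idx], graph)
                if jcfg.use_attention:
                    attention = extract_attention(params, X[test_idx], graph)
            auc = {}
            for s in SUBSKILL_ORDER:
                k = s.index
                if len(np.unique(y_test[:, k])) < 2:
                    auc[s.code] = float("nan")
                else:
                    auc[s.code] = compute_auc(probs[:, k], y_test[:, k])
            results[arm].append(
                FoldResult(
                    held_out_institution=inst,
                    auc=auc,
                    n_test=len(test_idx),
                    attention=attention,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------


def _out_of_fold_scores(
    cohort: Cohort,
    store: FeatureStore,
    X: np.ndarray,
    graph: PriorGraph,
    config: RunConfig,
    Y: np.ndarray,
) -> pd.DataFrame:
    """Held-out joint-model ideal-probabilities for every stitch."""
    n = len(cohort.records)
    scores = np.zeros((n, 6))
    for train_idx, test_idx, inst in loio_splits(cohort):
        jcfg = replace(
            _joint_cfg_for_arm(config.joint, "joint"),
            feature_dim=store.dim,
            target_len=config.target_len,
            seed=substream_seed(config.seed, f"stage2/joint/{inst}"),
        )
        params = train_stage2(X[train_idx], Y[train_idx], graph, jcfg)
        scores[test_idx] = predict_joint(params, X[test_idx], graph)
    return pd.DataFrame(
        {
            "stitch_id": [r.stitch_id for r in cohort.records],
            "surgeon_id": [r.surgeon_id for r in cohort.records],
            **{f"score_{s.code}": scores[:, s.index] for s in SUBSKILL_ORDER},
        }
    )


def run_experiment(config: RunConfig) -> dict:
    """Simulate, train all arms under LOIO CV, summarize; optionally run the
    skill-outcome association.  Returns a JSON-able report bundle and, when
    ``config.output_dir`` is set, writes tables alongside a manifest with the
    config hash and seed."""
    synth_cfg = replace(config.synth, seed=substream_seed(config.seed, "synth"))
    cohort, store, truth = generate_cohort(synth_cfg)
    graph = synth_cfg.graph()
    X, Y = assemble_node_inputs(
        cohort, store, config.target_len,
        include_kinematics=any(a in ("joint", "no_attention") for a in config.arms)
        or "no_kinematics" in config.arms,
    )
    fold_results = run_fold_arms(cohort, store, X, Y, graph, config)
    table = summarize(fold_results)

    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_stitches": len(cohort.records),
        "institutions": cohort.institutions,
        "summary": {
            arm: {
                row: {
                    "mean": round(float(table.loc[row, (arm, "mean")]), 10),
                    "std": round(float(table.loc[row, (arm, "std")]), 10),
                }
                for row in table.index
            }
            for arm in config.arms
        },
    }
    attention_maps = {
        f.held_out_institution: f.attention
        for f in fold_results.get("joint", [])
        if f.attention is not None
    }
    report["attention"] = {k: np.round(v, 10).tolist() for k, v in attention_maps.items()}

    if config.include_outcomes:
        stitch_scores = _out_of_fold_scores(cohort, store, X, graph, config, Y)
        outcome_table = generate_outcomes(cohort, truth, synth_cfg)
        cases = attach_case_scores(outcome_table, stitch_scores)
        uni = [
            fit_univariable(cases[f"skill_{s.code}"], cases["continence_3mo"], s.code)
            for s in SUBSKILL_ORDER
        ]
        _, preds, rows = fit_multivariable(cases)
        _, auc = roc_from_predictions(preds, cases["continence_3mo"].to_numpy())
        report["outcome_association"] = {
            "univariable": [
                {k: (round(v, 10) if isinstance(v, float) else v)
                 for k, v in r.as_dict().items()}
                for r in uni
            ],
            "multivariable": [
                {k: (round(v, 10) if isinstance(v, float) else v)
                 for k, v in r.as_dict().items()}
                for r in rows
            ],
            "multivariable_auc": round(float(auc), 10),
            "n_cases": int(len(cases)),
        }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = table.copy()
        flat.columns = [f"{a}_{s}" for a, s in flat.columns]
        flat.to_csv(out / "summary_auc.csv")
        for inst, amap in attention_maps.items():
            pd.DataFrame(
                np.round(amap, 10),
                index=[s.code for s in SUBSKILL_ORDER],
                columns=[s.code for s in SUBSKILL_ORDER],
            ).to_csv(out / f"attention_{inst}.csv")
        with open(out / "metrics.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config_hash": config.hash(), "seed": config.seed}, fh, indent=2)
    return report
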