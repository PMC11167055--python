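"""Cohort data model and on-disk formats.

A *stitch* (one needle pass) is the unit of assessment.  Each stitch is
segmented into six sub-phase clips, one per assessed sub-skill, and carries
six binary skill labels (1 = ideal performance, 0 = non-ideal), a surgeon id
and the id of the contributing institution.  Instrument kinematics are logged
per frame as ten tracked poses (position + quaternion, 70 scalars) plus the
camera pose.

On-disk layout of a cohort directory::

    manifest.csv          one row per stitch: ids, labels, sidecar paths
    kin/<stitch>.csv      kinematic log, one row per frame
    clips/<stitch>_<skill>.txt   frame ids of the sub-phase clip, one per line

Frame ids are 0-based and join against the kinematic log's ``frame_id``
column; they are not positional indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

N_POSES = 10
POSE_SCALARS = 70  # 10 poses x (3 position + 4 quaternion)
CAMERA_SCALARS = 7

__all__ = [
    "SubSkill",
    "SUBSKILL_ORDER",
    "ClipRef",
    "KinematicFrame",
    "StitchRecord",
    "Cohort",
    "FeatureStore",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "load_cohort",
    "save_cohort",
    "validate_cohort",
    "save_features",
    "load_features",
]


class SchemaError(ValueError):
    """Manifest or sidecar file does not follow the expected schema."""


class ValidationError(ValueError):
    """Parsed data violates a cohort invariant."""


class SubSkill(Enum):
    """The six assessed suturing sub-skills and their parent domains."""

    RP = ("RP", "needle_handling", "needle repositioning")
    HR = ("HR", "needle_handling", "needle hold ratio")
    HA = ("HA", "needle_handling", "needle hold angle")
    DS = ("DS", "needle_driving", "needle driving smoothness")
    WR = ("WR", "needle_driving", "wrist rotation")
    WRnw = ("WRnw", "needle_withdrawal", "wrist rotation needle withdrawal")

    def __init__(self, code: str, domain: str, description: str):
        self.code = code
        self.domain = domain
        self.description = description

    @classmethod
    def from_code(cls, code: str) -> "SubSkill":
        for s in cls:
            if s.code == code:
                return s
        raise ValueError(f"unknown sub-skill code {code!r}")

    @property
    def index(self) -> int:
        return SUBSKILL_ORDER.index(self)


#: Canonical node/report ordering used everywhere (rows of attention maps,
#: columns of tables).
SUBSKILL_ORDER: tuple[SubSkill, ...] = (
    SubSkill.RP,
    SubSkill.HR,
    SubSkill.HA,
    SubSkill.DS,
    SubSkill.WR,
    SubSkill.WRnw,
)


@dataclass
class ClipRef:
    """Reference to one sub-phase clip of a stitch."""

    stitch_id: str
    subskill: SubSkill
    frame_ids: list[int]
    media_path: str | None = None

    def violations(self) -> list[str]:
        out = []
        if len(self.frame_ids) == 0:
            out.append(f"{self.stitch_id}/{self.subskill.code}: empty frame_ids")
        else:
            arr = np.asarray(self.frame_ids)
            if (arr < 0).any():
                out.append(f"{self.stitch_id}/{self.subskill.code}: negative frame id")
            if not (np.diff(arr) > 0).all():
                out.append(
                    f"{self.stitch_id}/{self.subskill.code}: frame_ids not strictly increasing"
                )
        return out


@dataclass
class KinematicFrame:
    """One frame of the motion-tracking log: 10 poses plus the camera."""

    frame_id: int
    poses: np.ndarray  # (10, 7): x, y, z, qw, qx, qy, qz
    camera: np.ndarray  # (7,)

    def violations(self, where: str = "") -> list[str]:
        out = []
        if np.asarray(self.poses).shape != (N_POSES, 7):
            out.append(f"{where}frame {self.frame_id}: expected {N_POSES} poses x 7 scalars")
        elif not np.isfinite(self.poses).all():
            out.append(f"{where}frame {self.frame_id}: non-finite pose entries")
        if np.asarray(self.camera).shape != (7,) or not np.isfinite(self.camera).all():
            out.append(f"{where}frame {self.frame_id}: bad camera pose")
        return out


@dataclass
class StitchRecord:
    stitch_id: str
    surgeon_id: str
    institution_id: str
    clips: dict[SubSkill, ClipRef]
    kinematics: dict[SubSkill, list[KinematicFrame]]
    labels: dict[SubSkill, int]

    def violations(self) -> list[str]:
        out = []
        for s in SUBSKILL_ORDER:
            if s not in self.clips:
                out.append(f"{self.stitch_id}: missing clip for {s.code}")
            else:
                out.extend(self.clips[s].violations())
            if s not in self.labels:
                out.append(f"{self.stitch_id}: missing label for {s.code}")
            elif self.labels[s] not in (0, 1):
                out.append(f"{self.stitch_id}: non-binary label {self.labels[s]!r} for {s.code}")
            for fr in self.kinematics.get(s, []):
                out.extend(fr.violations(f"{self.stitch_id}/{s.code}: "))
                if out and len(out) > 50:
                    return out  # cap noise on massively corrupt records
        return out


@dataclass
class Cohort:
    records: list[StitchRecord]
    institutions: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def violations(self) -> list[str]:
        out = []
        if not self.institutions:
            out.append("cohort: empty institution list")
        known = set(self.institutions)
        for r in self.records:
            if r.institution_id not in known:
                out.append(f"{r.stitch_id}: unknown institution {r.institution_id!r}")
            out.extend(r.violations())
        return out

    def labels_matrix(self) -> np.ndarray:
        """(n_stitches, 6) int array in canonical sub-skill order."""
        return np.array(
            [[r.labels[s] for s in SUBSKILL_ORDER] for r in self.records], dtype=int
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every type invariant; empty report iff the cohort is clean."""
    return ValidationReport(cohort.violations())


# ---------------------------------------------------------------------------
# Feature store
# ---------------------------------------------------------------------------


@dataclass
class FeatureStore:
    """Fixed-dimension feature vectors keyed by (stitch_id, sub-skill)."""

    vectors: dict[tuple[str, SubSkill], np.ndarray] = field(default_factory=dict)
    encoder_id: str = "unknown"
    dim: int | None = None

    def put(self, stitch_id: str, subskill: SubSkill, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64).ravel()
        if self.dim is None:
            self.dim = vec.shape[0]
        elif vec.shape[0] != self.dim:
            raise ValidationError(
                f"feature dimension mismatch: store has {self.dim}, got {vec.shape[0]} "
                f"for {stitch_id}/{subskill.code}"
            )
        self.vectors[(stitch_id, subskill)] = vec

    def get(self, stitch_id: str, subskill: SubSkill) -> np.ndarray:
        return self.vectors[(stitch_id, subskill)]

    def merge(self, other: "FeatureStore") -> "FeatureStore":
        if self.dim is not None and other.dim is not None and self.dim != other.dim:
            raise ValidationError(
                f"cannot merge feature stores of dimension {self.dim} and {other.dim}"
            )
        for (sid, s), v in other.vectors.items():
            self.put(sid, s, v)
        return self

    def __len__(self) -> int:
        return len(self.vectors)


def save_features(store: FeatureStore, path: str | Path) -> Path:
    """Write a store as an .npz archive keyed ``stitch_id/subskill``."""
    if len(store) == 0:
        raise ValidationError("refusing to save an empty feature store")
    path = Path(path)
    arrays = {f"{sid}/{s.code}": v for (sid, s), v in store.vectors.items()}
    meta = json.dumps({"encoder_id": store.encoder_id, "dim": store.dim})
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def load_features(path: str | Path) -> FeatureStore:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        store = FeatureStore(encoder_id=meta["encoder_id"], dim=None)
        for key in npz.files:
            if key == "__meta__":
                continue
            sid, code = key.rsplit("/", 1)
            store.put(sid, SubSkill.from_code(code), npz[key])
    if store.dim != meta["dim"]:
        raise ValidationError("stored dimension metadata disagrees with arrays")
    return store


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

_KIN_COLUMNS = (
    ["frame_id"]
    + [f"p{i}_{c}" for i in range(N_POSES) for c in ("x", "y", "z", "qw", "qx", "qy", "qz")]
    + [f"cam_{c}" for c in ("x", "y", "z", "qw", "qx", "qy", "qz")]
)


def _kin_to_frame(row: np.ndarray) -> KinematicFrame:
    return KinematicFrame(
        frame_id=int(row[0]),
        poses=row[1 : 1 + POSE_SCALARS].reshape(N_POSES, 7),
        camera=row[1 + POSE_SCALARS :],
    )


def kinematics_to_frame_list(table: pd.DataFrame) -> list[KinematicFrame]:
    arr = table[_KIN_COLUMNS].to_numpy(dtype=np.float64)
    return [_kin_to_frame(row) for row in arr]


def frames_to_table(frames: Iterable[KinematicFrame]) -> pd.DataFrame:
    rows = [
        np.concatenate([[f.frame_id], np.asarray(f.poses).ravel(), np.asarray(f.camera)])
        for f in frames
    ]
    return pd.DataFrame(rows, columns=_KIN_COLUMNS)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "kin").mkdir(parents=True, exist_ok=True)
    (out_dir / "clips").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort.records:
        row: dict[str, object] = {
            "stitch_id": r.stitch_id,
            "surgeon_id": r.surgeon_id,
            "institution_id": r.institution_id,
            "kin_path": f"kin/{r.stitch_id}.csv",
        }
        # every sub-skill shares one per-stitch log; write it once
        frames_to_table(r.kinematics[SubSkill.RP]).to_csv(
            out_dir / "kin" / f"{r.stitch_id}.csv", index=False
        )
        for s in SUBSKILL_ORDER:
            row[f"label_{s.code}"] = r.labels[s]
            clip_path = f"clips/{r.stitch_id}_{s.code}.txt"
            with open(out_dir / clip_path, "w") as fh:
                fh.write("\n".join(str(i) for i in r.clips[s].frame_ids))
            row[f"clip_{s.code}"] = clip_path
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "institutions.json", "w") as fh:
        json.dump(cohort.institutions, fh)
    return out_dir / "manifest.csv"


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort directory; raises on schema or invariant violations."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    if not manifest_path.exists():
        raise SchemaError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, dtype={"stitch_id": str, "surgeon_id": str,
                                              "institution_id": str})
    required = {"stitch_id", "surgeon_id", "institution_id", "kin_path"}
    for s in SUBSKILL_ORDER:
        required |= {f"label_{s.code}", f"clip_{s.code}"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")

    records = []
    for _, row in table.iterrows():
        sid = str(row["stitch_id"])
        log = kinematics_to_frame_list(pd.read_csv(base / row["kin_path"]))
        clips, kin, labels = {}, {}, {}
        for s in SUBSKILL_ORDER:
            lab = row[f"label_{s.code}"]
            if lab not in (0, 1):
                raise ValidationError(f"stitch {sid}: non-binary label {lab!r} for {s.code}")
            labels[s] = int(lab)
            clip_file = base / str(row[f"clip_{s.code}"])
            if not clip_file.exists():
                raise SchemaError(f"stitch {sid}: missing clip frame-id file for {s.code}")
            frame_ids = [int(x) for x in clip_file.read_text().split()]
            clips[s] = ClipRef(stitch_id=sid, subskill=s, frame_ids=frame_ids)
            kin[s] = log
        records.append(
            StitchRecord(
                stitch_id=sid,
                surgeon_id=str(row["surgeon_id"]),
                institution_id=str(row["institution_id"]),
                clips=clips,
                kinematics=kin,
                labels=labels,
            )
        )
    inst_file = base / "institutions.json"
    if inst_file.exists():
        institutions = json.load(open(inst_file))
    else:
        institutions = sorted({r.institution_id for r in records})
    cohort = Cohort(records=records, institutions=institutions)
    report = validate_cohort(cohort)
    if not report.ok:
        raise ValidationError(
            "cohort failed validation:\n" + "\n".join(report.violations[:20])
        )
    return cohort
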