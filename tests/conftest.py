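import numpy as np
import pytest

from stitchgat.datamodel import (
    ClipRef,
    Cohort,
    KinematicFrame,
    StitchRecord,
    SUBSKILL_ORDER,
)


def make_frame(frame_id: int, rng: np.random.Generator) -> KinematicFrame:
    quat = rng.normal(size=(10, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    cam_q = rng.normal(size=4)
    cam_q /= np.linalg.norm(cam_q)
    return KinematicFrame(
        frame_id=frame_id,
        poses=np.concatenate([rng.normal(size=(10, 3)), quat], axis=1),
        camera=np.concatenate([rng.normal(size=3), cam_q]),
    )


def make_record(
    stitch_id: str,
    surgeon_id: str,
    institution_id: str,
    rng: np.random.Generator,
    frames_per_clip: int = 6,
) -> StitchRecord:
    n = frames_per_clip * 6
    log = [make_frame(i, rng) for i in range(n)]
    clips, labels = {}, {}
    for k, s in enumerate(SUBSKILL_ORDER):
        ids = list(range(k * frames_per_clip, (k + 1) * frames_per_clip))
        clips[s] = ClipRef(stitch_id=stitch_id, subskill=s, frame_ids=ids)
        labels[s] = int(rng.integers(0, 2))
    return StitchRecord(
        stitch_id=stitch_id,
        surgeon_id=surgeon_id,
        institution_id=institution_id,
        clips=clips,
        kinematics={s: log for s in SUBSKILL_ORDER},
        labels=labels,
    )


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three stitches, two surgeons, two institutions."""
    rng = np.random.default_rng(42)
    records = [
        make_record("s1_t0", "s1", "inst_A", rng),
        make_record("s1_t1", "s1", "inst_A", rng),
        make_record("s2_t0", "s2", "inst_B", rng),
    ]
    return Cohort(records=records, institutions=["inst_A", "inst_B"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
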