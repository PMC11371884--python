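"""Multi-reader seating votes and majority-rule label fusion.

Each joint is assessed independently by an odd number of readers (five in
the reference protocol: four maxillofacial surgeons and a 3D medical
engineer).  A vote of True marks the condyle as incorrectly seated.  The
final label is decided by strict majority; "incorrectly seated" is the
positive class throughout the package, so sensitivity downstream measures
the detection of seating problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CORRECT = "correct"
INCORRECT = "incorrect"


@dataclass(frozen=True)
class AnnotationRecord:
    joint_id: str
    votes: tuple  # booleans, True = marked incorrectly seated
    final_label: str
    unanimous: bool

    @property
    def n_incorrect_votes(self) -> int:
        return sum(self.votes)

    @classmethod
    def from_votes(cls, joint_id: str, votes: Sequence[bool]) -> "AnnotationRecord":
        label, unanimous = majority_label(votes)
        return cls(joint_id, tuple(bool(v) for v in votes), label, unanimous)


def majority_label(votes: Sequence[bool]) -> tuple[str, bool]:
    """Fuse reader votes: incorrect iff a strict majority marked incorrect.

    Requires an odd reader count so the majority is always defined.
    Returns (final_label, unanimous).
    """
    votes = [bool(v) for v in votes]
    k = len(votes)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"reader count must be odd and >= 1, got {k}")
    n_inc = sum(votes)
    label = INCORRECT if n_inc > k / 2 else CORRECT
    return label, n_inc in (0, k)


def vote_histogram(records: Sequence[AnnotationRecord]) -> np.ndarray:
    """Histogram of joints by number of incorrect votes (0..n_readers)."""
    if not records:
        return np.zeros(1, dtype=int)
    n_readers = {len(r.votes) for r in records}
    if len(n_readers) != 1:
        raise ValueError(f"inconsistent reader counts: {sorted(n_readers)}")
    k = n_readers.pop()
    hist = np.zeros(k + 1, dtype=int)
    for r in records:
        hist[r.n_incorrect_votes] += 1
    return hist


def fuse_histogram(hist: Sequence[int]) -> dict:
    """Summarise a vote histogram (index = number of incorrect votes).

    Returns counts of majority-correct, majority-incorrect, unanimous and
    majority-rule-needed joints.  The reader count is ``len(hist) - 1`` and
    must be odd.
    """
    hist = np.asarray(hist, dtype=int)
    k = len(hist) - 1
    if k < 1 or k % 2 == 0:
        raise ValueError(f"reader count must be odd and >= 1, got {k}")
    bins = np.arange(k + 1)
    incorrect = int(hist[bins > k / 2].sum())
    correct = int(hist[bins <= k / 2].sum())
    unanimous = int(hist[0] + hist[k])
    return {
        "n_joints": int(hist.sum()),
        "majority_correct": correct,
        "majority_incorrect": incorrect,
        "unanimous": unanimous,
        "majority_rule_needed": int(hist.sum()) - unanimous,
    }


def read_votes(path) -> list:
    """Votes CSV: joint_id, reader_1..reader_k with 0/1 entries."""
    df = pd.read_csv(path)
    reader_cols = [c for c in df.columns if c.startswith("reader_")]
    if not reader_cols:
        raise ValueError("votes CSV has no reader_* columns")
    records = []
    for _, row in df.iterrows():
        votes = [bool(int(row[c])) for c in reader_cols]
        records.append(AnnotationRecord.from_votes(str(row["joint_id"]), votes))
    return records


def write_fused_labels(records: Sequence[AnnotationRecord], path) -> None:
    pd.DataFrame(
        {
            "joint_id": [r.joint_id for r in records],
            "final_label": [r.final_label for r in records],
            "unanimous": [int(r.unanimous) for r in records],
        }
    ).to_csv(path, index=False)
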