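"""Trial-level containers shared by the simulators, fitters and IO layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusSet", "ChoiceDataset"]


def _as_array(x, dtype) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=dtype))


@dataclass
class StimulusSet:
    """An ordered list of two-option choice pairs shared by a cohort."""

    m1: np.ndarray
    c1: np.ndarray
    m2: np.ndarray
    c2: np.ndarray
    block: np.ndarray
    cost_type: str = "effort"

    def __post_init__(self) -> None:
        self.m1 = _as_array(self.m1, float)
        self.c1 = _as_array(self.c1, float)
        self.m2 = _as_array(self.m2, float)
        self.c2 = _as_array(self.c2, float)
        self.block = _as_array(self.block, int)
        n = len(self.m1)
        if not all(len(a) == n for a in (self.c1, self.m2, self.c2, self.block)):
            raise ValueError("stimulus columns must have equal length")
        for name, m in (("m1", self.m1), ("m2", self.m2)):
            if np.any(m < 0) or np.any(m > 75):
                raise ValueError(f"{name}: magnitudes must lie in [0, 75]")
        for name, c in (("c1", self.c1), ("c2", self.c2)):
            if np.any(c < 0) or np.any(c > 1):
                raise ValueError(f"{name}: costs must lie in [0, 1]")
        pairs = set(zip(self.m1, self.c1, self.m2, self.c2))
        if len(pairs) != n:
            raise ValueError("stimulus set contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.m1)


@dataclass
class ChoiceDataset:
    """All trials of one subject in one task.

    ``chosen`` holds 1 or 2 (the index of the chosen option); ``realized``
    flags trials on which the cost was actually incurred.  For sessions with a
    constant no-cost default, ``default_option`` names which option (1 or 2)
    is the default; it is ``None`` for symmetric two-offer designs.
    """

    subject: str
    cost_type: str
    m1: np.ndarray
    c1: np.ndarray
    m2: np.ndarray
    c2: np.ndarray
    chosen: np.ndarray
    realized: np.ndarray
    block: np.ndarray
    trial: np.ndarray
    default_option: int | None = None

    def __post_init__(self) -> None:
        self.m1 = _as_array(self.m1, float)
        self.c1 = _as_array(self.c1, float)
        self.m2 = _as_array(self.m2, float)
        self.c2 = _as_array(self.c2, float)
        self.chosen = _as_array(self.chosen, int)
        self.realized = _as_array(self.realized, bool)
        self.block = _as_array(self.block, int)
        self.trial = _as_array(self.trial, int)
        n = len(self.m1)
        cols = (self.c1, self.m2, self.c2, self.chosen, self.realized, self.block, self.trial)
        if not all(len(a) == n for a in cols):
            raise ValueError("dataset columns must have equal length")
        if n and not np.isin(self.chosen, (1, 2)).all():
            raise ValueError("chosen must be 1 or 2 for every trial")
        if self.default_option not in (None, 1, 2):
            raise ValueError("default_option must be None, 1 or 2")

    def __len__(self) -> int:
        return len(self.m1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "block": self.block,
                "trial": self.trial,
                "cost_type": self.cost_type,
                "m1": self.m1,
                "c1": self.c1,
                "m2": self.m2,
                "c2": self.c2,
                "chosen": self.chosen,
                "realized": self.realized.astype(int),
                "default_option": 0 if self.default_option is None else self.default_option,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChoiceDataset":
        subjects = frame["subject"].unique()
        if len(subjects) != 1:
            raise ValueError("frame must contain exactly one subject")
        cost_types = frame["cost_type"].unique()
        if len(cost_types) != 1:
            raise ValueError("frame must contain exactly one cost type")
        default = int(frame["default_option"].iloc[0])
        return cls(
            subject=str(subjects[0]),
            cost_type=str(cost_types[0]),
            m1=frame["m1"].to_numpy(),
            c1=frame["c1"].to_numpy(),
            m2=frame["m2"].to_numpy(),
            c2=frame["c2"].to_numpy(),
            chosen=frame["chosen"].to_numpy(),
            realized=frame["realized"].to_numpy().astype(bool),
            block=frame["block"].to_numpy(),
            trial=frame["trial"].to_numpy(),
            default_option=None if default == 0 else default,
        )

    def equals(self, other: "ChoiceDataset") -> bool:
        if self.subject != other.subject or self.cost_type != other.cost_type:
            return False
        if self.default_option != other.default_option or len(self) != len(other):
            return False
        return all(
            np.array_equal(getattr(self, a), getattr(other, a))
            for a in ("m1", "c1", "m2", "c2", "chosen", "realized", "block", "trial")
        )
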