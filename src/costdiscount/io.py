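"""Reading and writing of trial tables and fit tables (CSV, UTF-8).

Column order is fixed; magnitudes are stored in display units, costs as
decimals on [0, 1].  Numbers round-trip at full precision (Python repr).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import ChoiceDataset

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "write_fit_table"]

TRIAL_COLUMNS = (
    "subject",
    "block",
    "trial",
    "cost_type",
    "m1",
    "c1",
    "m2",
    "c2",
    "chosen",
    "realized",
    "default_option",
)


def write_trials(datasets: Iterable[ChoiceDataset], path) -> None:
    """Write one or more subjects' trials to a delimited text file."""
    frames = [d.to_frame() for d in datasets]
    if not frames:
        raise ValueError("nothing to write")
    out = pd.concat(frames, ignore_index=True)[list(TRIAL_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


class TrialParseError(ValueError):
    """Malformed trial table; the message names the offending line and column."""


def _check(frame: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    # +2: header line plus 1-based numbering
    for col in ("m1", "c1", "m2", "c2"):
        bad = ~np.isfinite(frame[col].to_numpy(dtype=float))
        if bad.any():
            raise TrialParseError(f"{path}: line {bad.argmax() + 2}, column {col!r}: not a number")
    for col in ("c1", "c2"):
        c = frame[col].to_numpy(dtype=float)
        bad = (c < 0) | (c > 1)
        if bad.any():
            raise TrialParseError(
                f"{path}: line {bad.argmax() + 2}, column {col!r}: cost {c[bad.argmax()]} outside [0, 1]"
            )
    chosen = frame["chosen"].to_numpy()
    bad = ~np.isin(chosen, (1, 2))
    if bad.any():
        raise TrialParseError(
            f"{path}: line {bad.argmax() + 2}, column 'chosen': value {chosen[bad.argmax()]} not in {{1, 2}}"
        )
    realized = frame["realized"].to_numpy()
    bad = ~np.isin(realized, (0, 1))
    if bad.any():
        raise TrialParseError(
            f"{path}: line {bad.argmax() + 2}, column 'realized': value {realized[bad.argmax()]} not 0/1"
        )


def read_trials(path) -> list[ChoiceDataset]:
    """Parse a trial table into per-subject datasets (input order preserved)."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialParseError(f"{path}: {exc}") from exc
    _check(frame, path)
    datasets = []
    for subject in frame["subject"].astype(str).unique():
        sub = frame[frame["subject"].astype(str) == subject]
        for cost_type in sub["cost_type"].unique():
            datasets.append(ChoiceDataset.from_frame(sub[sub["cost_type"] == cost_type]))
    return datasets


def write_fit_table(fits: Sequence[dict], path) -> pd.DataFrame:
    """Persist per-(subject, model) fit summaries; returns the written frame."""
    frame = pd.DataFrame(list(fits))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return frame
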