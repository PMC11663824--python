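"""CSV readers/writers for the trial and questionnaire formats.

Trial CSV columns (UTF-8, comma-separated, header required):
participant_id, group, task, block, trial_index, digit, response_side,
correct, rt_ms.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from snarcpipe.simulate import DIGITS, TRIAL_COLUMNS

_REQUIRED_CDPQ = ["participant_id", "group"] + [f"item{i}" for i in range(1, 8)]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_digit = ~df["digit"].isin(DIGITS)
    if bad_digit.any():
        line = int(df.index[bad_digit][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: line {line}: invalid digit {df.loc[bad_digit, 'digit'].iloc[0]}")
    bad_side = ~df["response_side"].isin(["left", "right"])
    if bad_side.any():
        line = int(df.index[bad_side][0]) + 2
        raise ValueError(f"{path}: line {line}: response_side must be left or right")
    if (df["rt_ms"] <= 0).any():
        line = int(df.index[df["rt_ms"] <= 0][0]) + 2
        raise ValueError(f"{path}: line {line}: rt_ms must be positive")
    df["correct"] = df["correct"].astype(bool)
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def write_cdpq(cdpq: pd.DataFrame, path: str | Path) -> None:
    cdpq.to_csv(path, index=False)


def read_cdpq(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in _REQUIRED_CDPQ if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
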