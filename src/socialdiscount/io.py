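"""Trial-log file format: schema-validated tidy CSV.

One row per decision. Canonical columns:

    subject_id, group, block (1-5), block_label, trial (1-50),
    design_tag (generative|adaptive), agent (self|other_A|other_B),
    ss_amount, ll_amount, delay_days, choice (SS|LL),
    feedback_correct (blank outside other blocks), rng_stream_id

Files are UTF-8, comma-separated, with a header row. ``read_trial_log``
validates on read and reports malformed rows with their line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import pandas as pd

from .core import AMOUNT_MAX, AMOUNT_MIN, DELAY_MAX, LL, SS
from .design import BLOCK_LABELS

__all__ = ["TRIAL_LOG_COLUMNS", "TrialLogError", "read_trial_log", "write_trial_log"]

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "block_label",
    "trial",
    "design_tag",
    "agent",
    "ss_amount",
    "ll_amount",
    "delay_days",
    "choice",
    "feedback_correct",
    "rng_stream_id",
]

_SELF_BLOCKS = {1, 3, 5}


class TrialLogError(ValueError):
    """Raised when a trial-log file violates the schema."""


def _fail(messages: List[str]):
    raise TrialLogError("; ".join(messages))


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Returns the validated DataFrame with typed columns. Schema
    violations raise :class:`TrialLogError` naming the offending columns
    and 1-based data line numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "rng_stream_id": str})
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"missing required column(s): {', '.join(missing)}")

    problems: List[str] = []

    def lines(mask) -> str:
        idx = df.index[mask][:10] + 2  # +1 header, +1 zero-based
        return ", ".join(map(str, idx))

    for col, lo, hi in (
        ("block", 1, 5),
        ("trial", 1, 50),
        ("ss_amount", AMOUNT_MIN, AMOUNT_MAX),
        ("ll_amount", AMOUNT_MIN, AMOUNT_MAX),
        ("delay_days", 1, DELAY_MAX),
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < lo) | (vals > hi)
        if bad.any():
            problems.append(
                f"column '{col}' must be an integer in [{lo}, {hi}] "
                f"(lines {lines(bad)})"
            )
        else:
            df[col] = vals.astype(int)
    if not problems:
        bad = df["ll_amount"] <= df["ss_amount"]
        if bad.any():
            problems.append(f"ll_amount must exceed ss_amount (lines {lines(bad)})")
        bad = df["block_label"] != df["block"].map(
            lambda b: BLOCK_LABELS[b - 1]
        )
        if bad.any():
            problems.append(
                f"block_label inconsistent with block index (lines {lines(bad)})"
            )
    bad = ~df["choice"].isin([SS, LL])
    if bad.any():
        problems.append(f"choice must be SS or LL (lines {lines(bad)})")
    bad = ~df["design_tag"].isin(["generative", "adaptive"])
    if bad.any():
        problems.append(f"invalid design_tag (lines {lines(bad)})")
    bad = ~df["agent"].isin(["self", "other_A", "other_B"])
    if bad.any():
        problems.append(f"invalid agent (lines {lines(bad)})")
    if problems:
        _fail(problems)

    fb = df["feedback_correct"]
    df["feedback_correct"] = fb.map(
        lambda v: pd.NA if pd.isna(v) or v == "" else bool(v in (True, "True", "true", 1, "1", 1.0))
    ).astype("boolean")
    is_self = df["block"].isin(_SELF_BLOCKS)
    bad = (is_self & df["feedback_correct"].notna()) | (
        ~is_self & df["feedback_correct"].isna()
    )
    if bad.any():
        _fail([f"feedback_correct present exactly in blocks 2 and 4 (lines {lines(bad)})"])
    return df[TRIAL_LOG_COLUMNS]


def write_trial_log(dataset: pd.DataFrame, path) -> Path:
    """Write a trial log in canonical column order; round-trips with
    :func:`read_trial_log`."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in dataset.columns]
    if missing:
        raise TrialLogError(f"dataset missing column(s): {', '.join(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset[TRIAL_LOG_COLUMNS].to_csv(path, index=False)
    return path
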