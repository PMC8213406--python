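"""Segment tables: onset/offset intervals in seconds, tagged by recording.

A segment table is a plain :class:`pandas.DataFrame` with at least the
columns ``recording``, ``onset_s``, ``offset_s`` and optionally ``label``
plus any extra annotation columns (``truth``, ``condition``, ``motif`` ...).
Intervals are half-open ``[onset_s, offset_s)`` in seconds.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("recording", "onset_s", "offset_s")


def make_segment_table(rows, extra_columns=()) -> pd.DataFrame:
    """Build a segment table from an iterable of (recording, onset, offset, ...)."""
    columns = list(REQUIRED_COLUMNS) + list(extra_columns)
    df = pd.DataFrame(rows, columns=columns)
    validate_segment_table(df)
    return df


def validate_segment_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *df* is not a valid segment table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    if len(df) and not (df["offset_s"] > df["onset_s"]).all():
        bad = df.index[df["offset_s"] <= df["onset_s"]].tolist()
        raise ValueError(f"segments with offset_s <= onset_s at rows {bad}")


def read_segments(path) -> pd.DataFrame:
    """Read a segment table from CSV (header row, seconds as decimals)."""
    df = pd.read_csv(path)
    validate_segment_table(df)
    return df


def write_segments(df: pd.DataFrame, path) -> None:
    validate_segment_table(df)
    df.to_csv(path, index=False)


def durations(df: pd.DataFrame):
    """Segment durations in seconds, as a Series aligned with *df*."""
    return df["offset_s"] - df["onset_s"]
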