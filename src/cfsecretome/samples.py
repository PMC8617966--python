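"""Sample-label conventions: columns are named ``P<patient>_<condition>``."""

from __future__ import annotations

from typing import Iterable


def patient_of(column: str) -> int:
    return int(column.split("_", 1)[0][1:])


def condition_of(column: str) -> str:
    return column.split("_", 1)[1]


def condition_columns(columns: Iterable[str], condition: str) -> list[str]:
    """Columns belonging to one condition, ordered by patient number, so
    lists for two conditions align pairwise by patient."""
    cols = [c for c in columns if condition_of(c) == condition]
    return sorted(cols, key=patient_of)
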