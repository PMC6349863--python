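"""Small formatting helpers for summary tables."""

from __future__ import annotations

from .errors import DataError


def format_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage as printed in demographic tables: 100*count/total, rounded.

    ``decimals=1`` gives e.g. 16/117 -> 13.7; ``decimals=0`` gives 2/15 -> 13.
    """
    if total <= 0:
        raise DataError("total must be > 0")
    if count < 0 or count > total:
        raise DataError("count must be in [0, total]")
    pct = 100.0 * count / total
    return float(round(pct, decimals)) if decimals > 0 else float(round(pct))
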