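"""Published per-class sample counts of the four evaluation datasets, and
class-share arithmetic over them.

The moving-modes collection (HMM; with and without barometer), the static
behaviour set (HSBD) and the postural-transition set (HDBD) are summarised
here by their published window counts per activity; the share of each
activity is that count over the dataset total.  Published share tables
appear to truncate rather than round the third decimal (e.g. stilling
1325/10663 = 12.426% listed as 12.42%), so recomputed shares can differ from
listed ones by up to one unit in the last printed digit.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_CLASS_COUNTS", "class_shares", "summary_table"]

#: published number of windowed samples per activity class, by dataset
PUBLISHED_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "HMM": {
        "STILLING": 1325,
        "WALKING": 2216,
        "ELEVATOR_UP": 685,
        "ELEVATOR_DOWN": 730,
        "ESCALATOR_UP": 2216,
        "ESCALATOR_DOWN": 1598,
        "WALKING_UP": 864,
        "WALKING_DOWN": 1029,
    },
    "HSBD": {
        "WALKING": 1772,
        "WALKING_UP": 1544,
        "WALKING_DOWN": 1406,
        "STANDING": 1777,
        "SITTING": 1906,
        "LAYING": 1944,
    },
    "HDBD": {
        "STAND_TO_SIT": 697,
        "SIT_TO_STAND": 192,
        "SIT_TO_LIE": 1193,
        "LIE_TO_SIT": 879,
        "STAND_TO_LIE": 1753,
        "LIE_TO_STAND": 870,
    },
}


def class_shares(counts: dict[str, int], ndigits: int | None = None) -> dict[str, float]:
    """Percentage share of each class; round-half-even when ``ndigits`` set."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    shares = {k: 100.0 * v / total for k, v in counts.items()}
    if ndigits is not None:
        shares = {k: round(v, ndigits) for k, v in shares.items()}
    return shares


def summary_table(dataset: str | None = None) -> pd.DataFrame:
    """Counts and recomputed percentage shares, one row per class."""
    names = [dataset] if dataset else list(PUBLISHED_CLASS_COUNTS)
    rows = []
    for name in names:
        counts = PUBLISHED_CLASS_COUNTS[name]
        shares = class_shares(counts)
        for cls, cnt in counts.items():
            rows.append(
                {"dataset": name, "class": cls, "count": cnt, "share_pct": shares[cls]}
            )
    return pd.DataFrame(rows)
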