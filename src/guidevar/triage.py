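"""Three-class sgRNA prioritization and library-level effect-size evaluation.

Guides are triaged on their predicted on-target score (calibrated [0, 1])
and aggregate off-target score:

* ``high_on_low_off`` -- on > on_thr and off < off_thr: select with priority;
* ``high_on_high_off`` -- on > on_thr but off >= off_thr: usable, less
  preferred;
* ``low_on`` -- on <= on_thr: recommended to discard.

Boundary values fall in the less-preferred class (strict inequalities gate
the preferred outcomes).  Selection quality is evaluated as the SSMD between
essential- and non-essential-gene LFC distributions within each category.
"""

from __future__ import annotations

import pandas as pd

from .errors import InsufficientGroupError, MissingIdError
from .screenstats import ssmd

HIGH_ON_LOW_OFF = "high_on_low_off"
HIGH_ON_HIGH_OFF = "high_on_high_off"
LOW_ON = "low_on"

CATEGORIES = (HIGH_ON_LOW_OFF, HIGH_ON_HIGH_OFF, LOW_ON)


def classify(
    on_scores: pd.Series,
    off_scores: pd.Series,
    on_thr: float = 0.5,
    off_thr: float = 1.0,
) -> pd.DataFrame:
    """Triage guides into the three categories.

    Returns a DataFrame indexed by guide id with columns ``on_score``,
    ``off_score`` and ``category``.
    """
    on_scores = pd.Series(on_scores, dtype=float)
    off_scores = pd.Series(off_scores, dtype=float)
    if not on_scores.index.equals(off_scores.index):
        raise MissingIdError("on and off score tables must share an index")
    category = pd.Series(LOW_ON, index=on_scores.index, dtype=object)
    high_on = on_scores > on_thr
    category[high_on & (off_scores < off_thr)] = HIGH_ON_LOW_OFF
    category[high_on & (off_scores >= off_thr)] = HIGH_ON_HIGH_OFF
    return pd.DataFrame(
        {"on_score": on_scores, "off_score": off_scores, "category": category}
    )


def evaluate_selection(
    triage: pd.DataFrame, screen: pd.DataFrame, strict: bool = True
) -> dict:
    """SSMD per triage category and for the full library.

    ``screen`` must be indexed by guide id with ``lfc`` and boolean
    ``essential`` columns.  For each category (and the whole library) the
    SSMD separates essential-gene LFCs (positive arm) from non-essential
    LFCs (negative arm).  A category absent from the triage table is
    omitted; a category present with fewer than 2 guides in either arm
    raises :class:`InsufficientGroupError` (or is reported as NaN with
    ``strict=False``).
    """
    for col in ("lfc", "essential"):
        if col not in screen.columns:
            raise MissingIdError(f"screen table missing column {col!r}")
    joined = triage.join(screen[["lfc", "essential"]], how="inner")
    if joined.empty:
        raise MissingIdError("no overlap between triage table and screen table")

    def arm_ssmd(df: pd.DataFrame, label: str) -> float:
        ess = df.loc[df["essential"].astype(bool), "lfc"]
        non = df.loc[~df["essential"].astype(bool), "lfc"]
        if len(ess) < 2 or len(non) < 2:
            raise InsufficientGroupError(
                f"{label}: needs >= 2 essential and >= 2 non-essential guides"
            )
        return ssmd(ess.to_numpy(), non.to_numpy())

    out = {"full_library": arm_ssmd(joined, "full_library")}
    for cat, df in joined.groupby("category"):
        try:
            out[str(cat)] = arm_ssmd(df, str(cat))
        except InsufficientGroupError:
            if strict:
                raise
            out[str(cat)] = float("nan")
    return out
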