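"""Dual-target off-target quantification.

A synthetic paired sgRNA-target construct carries an sgRNA cassette together
with its on-target sequence and one designed off-target sequence in tandem,
so that indel read counts can be partitioned into C1 (indel at the off-target
site only), C2 (on-target only) and C3 (both).  From these counts this module
computes:

* the off-on ratio ``r = (C1 + C3) / (C2 + C3)`` -- the relative activity at
  the off-target versus the on-target site;
* the variant/wild-type reduction ratio
  ``VT/WT = (r_hifi + r_lz3) / (2 * r_wt)`` -- how much a pair of
  high-fidelity variants suppresses the off-target relative to WT SpCas9;
* the individual mismatch effect (IME) matrix -- the mean off-on ratio for a
  mismatch of a given type at a given spacer position, estimated from
  single-mismatch pairs;
* the pairwise combinatorial-effect table delta_ij -- the multiplicative
  deviation of double-mismatch activity from the product of the two
  single-mismatch effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CompositionError,
    EmptyInputError,
    MismatchCountError,
    RangeError,
    ZeroDenominatorError,
)
from .seqfeat import MT_ORDER, GuideTargetPair, Spacer, annotate_mismatches

ENZYMES = ("WT", "HiFi", "LZ3")

#: Default mismatch panel: three 1-MM, three 2-MM, one 3-MM target per guide.
DEFAULT_PANEL = {1: 3, 2: 3, 3: 1}

#: PAM-proximal positions interacting with the REC3 domain.
REC3_POSITIONS = (15, 16, 17, 18)


@dataclass(frozen=True)
class DualTargetCounts:
    """Indel read counts for one pair and one enzyme."""

    pair_id: str
    enzyme: str
    c1: int  # off-target only
    c2: int  # on-target only
    c3: int  # both sites

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise RangeError(f"unknown enzyme {self.enzyme!r}")
        if min(self.c1, self.c2, self.c3) < 0:
            raise RangeError("counts must be non-negative")


@dataclass
class OffOnRecord:
    """Per-pair off-on ratios across enzymes and the derived VT/WT ratio."""

    pair_id: str
    r_wt: float
    r_hf: float
    r_lz: float

    @property
    def r_vt(self) -> float:
        return (self.r_hf + self.r_lz) / 2.0

    @property
    def vtwt(self) -> float:
        return vt_wt_ratio(self.r_hf, self.r_lz, self.r_wt)


def off_on_ratio(c: DualTargetCounts, eps: float = 0.0) -> float:
    """Off-on ratio ``r = (C1 + C3 + eps) / (C2 + C3 + eps)``.

    ``eps`` defaults to 0 so that pairs with no on-target editing surface as
    :class:`ZeroDenominatorError` rather than being silently smoothed.
    """
    denom = c.c2 + c.c3 + eps
    if denom == 0:
        raise ZeroDenominatorError(f"pair {c.pair_id}: C2 + C3 = 0 and eps = 0")
    return (c.c1 + c.c3 + eps) / denom


def vt_wt_ratio(r_hf: float, r_lz: float, r_wt: float) -> float:
    """Variant/WT off-target reduction ratio ``(r_hf + r_lz) / (2 * r_wt)``."""
    if r_wt <= 0:
        raise ZeroDenominatorError("r_wt must be > 0")
    return (r_hf + r_lz) / (2.0 * r_wt)


def design_panel(
    spacer: Spacer,
    composition: Mapping[int, int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[GuideTargetPair]:
    """Design a mismatch panel of off-target sequences for one spacer.

    ``composition`` maps mismatch count -> number of targets (default 3/3/1
    for 1/2/3 mismatches).  Mismatch positions are drawn without replacement
    per target and the substituted protospacer base uniformly from the three
    non-matching bases.  Deterministic under a fixed seed/generator.
    """
    composition = dict(DEFAULT_PANEL if composition is None else composition)
    rng = np.random.default_rng(rng)
    L = len(spacer)
    for k in composition:
        if not 1 <= k <= L:
            raise CompositionError(f"cannot place {k} mismatches in {L} positions")
    pairs = []
    alphabet = "ACGT"
    for k in sorted(composition):
        for _ in range(composition[k]):
            positions = rng.choice(np.arange(1, L + 1), size=k, replace=False)
            target = list(spacer.sequence)
            for pos in positions:
                idx = L - int(pos)
                choices = [b for b in alphabet if b != spacer.sequence[idx]]
                target[idx] = choices[int(rng.integers(3))]
            pairs.append(annotate_mismatches(spacer, "".join(target)))
    return pairs


class IMEMatrix:
    """Individual mismatch effect: 20 positions x 12 mismatch types.

    ``values`` is a DataFrame indexed by position 1..20 with columns in
    :data:`~guidevar.seqfeat.MT_ORDER`; ``provenance`` marks each cell as
    ``observed``, ``type_mean`` or ``global_mean`` fill.
    """

    def __init__(self, values: pd.DataFrame, provenance: pd.DataFrame | None = None):
        self.values = values.astype(float)
        if provenance is None:
            provenance = pd.DataFrame(
                "observed", index=values.index, columns=values.columns
            )
        self.provenance = provenance

    def __getitem__(self, key: tuple[int, str]) -> float:
        pos, code = key
        return float(self.values.loc[pos, code])

    @classmethod
    def from_constant(cls, value: float) -> "IMEMatrix":
        df = pd.DataFrame(value, index=range(1, 21), columns=list(MT_ORDER))
        return cls(df, df.copy().map(lambda _: "constant"))

    def to_tsv(self, path) -> None:
        self.values.rename_axis("position").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "IMEMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(df)


def estimate_ime(
    pairs_1mm: Sequence[tuple[GuideTargetPair, float]],
) -> IMEMatrix:
    """Estimate the IME matrix from single-mismatch (pair, off-on ratio) data.

    Each cell (position, type) is the mean ratio over all pairs carrying that
    single mismatch.  Cells never observed are filled by the mean over the
    same mismatch type, then by the global mean, with the fill recorded in
    ``provenance``.
    """
    if not pairs_1mm:
        raise EmptyInputError("no single-mismatch pairs supplied")
    sums = pd.DataFrame(0.0, index=range(1, 21), columns=list(MT_ORDER))
    ns = sums.copy()
    for pair, r in pairs_1mm:
        if pair.n_mismatches != 1:
            raise MismatchCountError(
                f"pair with {pair.n_mismatches} mismatches in 1-MM input"
            )
        mm = pair.mismatches[0]
        sums.loc[mm.position, mm.type_code] += r
        ns.loc[mm.position, mm.type_code] += 1
    observed = ns > 0
    values = sums.where(~observed, sums / ns.where(observed))
    values[~observed] = np.nan
    provenance = pd.DataFrame("observed", index=values.index, columns=values.columns)
    type_means = values.mean(axis=0)  # per mismatch type
    global_mean = float(np.nanmean(values.values))
    for code in values.columns:
        col_missing = values[code].isna()
        fill = type_means[code]
        if np.isnan(fill):
            fill, tag = global_mean, "global_mean"
        else:
            tag = "type_mean"
        values.loc[col_missing, code] = fill
        provenance.loc[col_missing, code] = tag
    return IMEMatrix(values, provenance)


class DeltaTable:
    """Symmetric pairwise combinatorial-effect table over positions 1..20."""

    def __init__(self, values: np.ndarray, observed: np.ndarray | None = None):
        values = np.asarray(values, dtype=float)
        if values.shape != (20, 20):
            raise RangeError("delta table must be 20 x 20")
        if not np.allclose(values, values.T, equal_nan=True):
            raise RangeError("delta table must be symmetric")
        self.values = values
        self.observed = (
            np.ones((20, 20), dtype=bool) if observed is None else observed
        )

    def __getitem__(self, key: tuple[int, int]) -> float:
        i, j = key
        if i == j:
            raise RangeError("delta is defined for distinct positions only")
        return float(self.values[i - 1, j - 1])

    @classmethod
    def from_constant(cls, value: float = 1.0) -> "DeltaTable":
        v = np.full((20, 20), value)
        np.fill_diagonal(v, np.nan)
        return cls(v, observed=np.zeros((20, 20), dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        """Long format: i, j (i < j), delta, observed."""
        rows = []
        for i in range(1, 21):
            for j in range(i + 1, 21):
                rows.append(
                    {
                        "i": i,
                        "j": j,
                        "delta": self.values[i - 1, j - 1],
                        "observed": bool(self.observed[i - 1, j - 1]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DeltaTable":
        df = pd.read_csv(path, sep="\t")
        v = np.full((20, 20), np.nan)
        obs = np.zeros((20, 20), dtype=bool)
        for _, row in df.iterrows():
            i, j = int(row["i"]) - 1, int(row["j"]) - 1
            v[i, j] = v[j, i] = row["delta"]
            obs[i, j] = obs[j, i] = bool(row.get("observed", True))
        return cls(v, obs)


def estimate_delta(
    pairs_2mm: Sequence[tuple[GuideTargetPair, float]],
    ime: IMEMatrix,
) -> DeltaTable:
    """Estimate pairwise combinatorial effects from double-mismatch data.

    For each position pair (i, j), ``delta_ij`` is the median over pairs of
    ``r_observed / (m_i * m_j)`` where ``m`` are the IME values of the two
    constituent single mismatches.  Unobserved position pairs default to 1
    (multiplicative independence) with ``observed=False``.
    """
    if not pairs_2mm:
        raise EmptyInputError("no double-mismatch pairs supplied")
    ratios: dict[tuple[int, int], list[float]] = {}
    for pair, r in pairs_2mm:
        if pair.n_mismatches != 2:
            raise MismatchCountError(
                f"pair with {pair.n_mismatches} mismatches in 2-MM input"
            )
        a, b = pair.mismatches
        m = ime[a.position, a.type_code] * ime[b.position, b.type_code]
        if m > 0:
            key = (min(a.position, b.position), max(a.position, b.position))
            ratios.setdefault(key, []).append(r / m)
    values = np.ones((20, 20), dtype=float)
    np.fill_diagonal(values, np.nan)
    observed = np.zeros((20, 20), dtype=bool)
    for (i, j), rs in ratios.items():
        med = float(np.median(rs))
        values[i - 1, j - 1] = values[j - 1, i - 1] = med
        observed[i - 1, j - 1] = observed[j - 1, i - 1] = True
    return DeltaTable(values, observed)


def position_vtwt_summary(
    records: Sequence[tuple[GuideTargetPair, OffOnRecord]],
    min_r_wt: float = 0.5,
    rec3_positions: Sequence[int] = REC3_POSITIONS,
) -> dict:
    """Summarize variant-mediated off-target reduction for 1-MM pairs.

    Keeps pairs with a strong WT off-target effect (``r_wt > min_r_wt``),
    then reports the median VT/WT ratio grouped by mismatch position and by
    mismatch type, together with group sizes and a two-sided Mann-Whitney U
    test comparing VT/WT at the REC3-interacting positions (15-18 by default)
    against all other positions.
    """
    rows = []
    for pair, rec in records:
        if pair.n_mismatches != 1:
            raise MismatchCountError("position summary expects 1-MM records")
        if rec.r_wt > min_r_wt:
            mm = pair.mismatches[0]
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "position": mm.position,
                    "type_code": mm.type_code,
                    "vtwt": rec.vtwt,
                }
            )
    df = pd.DataFrame(rows, columns=["pair_id", "position", "type_code", "vtwt"])
    by_pos = df.groupby("position")["vtwt"].agg(["median", "size"])
    by_type = df.groupby("type_code")["vtwt"].agg(["median", "size"])
    in_rec3 = df["position"].isin(rec3_positions)
    if in_rec3.any() and (~in_rec3).any():
        pval = float(
            stats.mannwhitneyu(
                df.loc[in_rec3, "vtwt"], df.loc[~in_rec3, "vtwt"],
                alternative="two-sided",
            ).pvalue
        )
    else:
        pval = float("nan")
    return {
        "records": df,
        "by_position": by_pos,
        "by_type": by_type,
        "rec3_vs_rest_pvalue": pval,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def counts_table_to_records(df: pd.DataFrame, eps: float = 0.0) -> pd.DataFrame:
    """Pivot a long counts table (pair_id, enzyme, c1, c2, c3) to per-pair ratios.

    Returns a DataFrame indexed by pair_id with columns r_wt, r_hf, r_lz,
    r_vt and vtwt.  Pairs missing any enzyme are dropped.
    """
    ratios = {}
    for row in df.itertuples(index=False):
        c = DualTargetCounts(str(row.pair_id), row.enzyme, int(row.c1), int(row.c2), int(row.c3))
        ratios.setdefault(c.pair_id, {})[c.enzyme] = off_on_ratio(c, eps=eps)
    rows = []
    for pid, r in ratios.items():
        if set(ENZYMES) <= set(r):
            rec = OffOnRecord(pid, r_wt=r["WT"], r_hf=r["HiFi"], r_lz=r["LZ3"])
            rows.append(
                {
                    "pair_id": pid,
                    "r_wt": rec.r_wt,
                    "r_hf": rec.r_hf,
                    "r_lz": rec.r_lz,
                    "r_vt": rec.r_vt,
                    "vtwt": rec.vtwt if rec.r_wt > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("pair_id")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a dual-target counts TSV (pair_id, spacer, target, enzyme, c1, c2, c3)."""
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str})
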