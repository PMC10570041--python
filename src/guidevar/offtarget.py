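"""Off-target effect prediction and candidate-site scoring ("GuideVar-off").

Single-mismatch effects are predicted by a regressor (gradient-boosted trees
by default) over a 34-long feature vector: the IME matrix value for the
mismatch (1), the guide-intrinsic mismatch tolerance GMT (1), the one-hot
mismatch type MT (12) and mismatch position MP (20).  Multi-mismatch sites
combine the per-mismatch predictions ``m_i`` with a pairwise
combinatorial-effect term:

``delta_all = (2/n) * sum_{i<j} delta_ij``   (printed-formula mode, default)

``score = delta_all * prod_i m_i``;  a single mismatch bypasses ``delta_all``.

A per-guide aggregate off-target score is the log2 of the summed predicted
effects over all candidate genomic sites, found here by an exhaustive
Hamming scan against NGG-adjacent windows on both strands (suited to toy
genomes; genome-scale indexed search is out of scope).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from .dualtarget import DeltaTable, IMEMatrix
from .errors import (
    EmptyInputError,
    LengthMismatchError,
    MismatchCountError,
    SchemaError,
    UncalibratedModelError,
    UnknownKindError,
)
from .seqfeat import (
    GuideTargetPair,
    Spacer,
    annotate_mismatches,
    encode_mismatch,
    reverse_complement,
)

AGGREGATE_EPS = 1e-6

DELTA_MODES = ("as_printed", "pair_mean", "geometric")


# ---------------------------------------------------------------------------
# GMT scorers
# ---------------------------------------------------------------------------

class ConstantGMT:
    """Guide-intrinsic mismatch tolerance fixed at one value for all guides."""

    def __init__(self, value: float = 1.0):
        self.value = float(value)

    def score(self, spacer: Spacer) -> float:
        return self.value


class LookupGMT:
    """GMT from a per-guide lookup (keyed by spacer sequence), with default."""

    def __init__(self, table: dict, default: float = 1.0):
        self.table = {str(k): float(v) for k, v in table.items()}
        self.default = float(default)

    def score(self, spacer: Spacer) -> float:
        return self.table.get(spacer.sequence, self.default)


# ---------------------------------------------------------------------------
# Single-mismatch model
# ---------------------------------------------------------------------------

def mismatch_features(
    pairs: Sequence[GuideTargetPair], ime: IMEMatrix, gmt
) -> np.ndarray:
    """Feature matrix for 1-MM pairs: [IME, GMT, MT(12), MP(20)], shape (n, 34)."""
    rows = []
    for pair in pairs:
        if pair.n_mismatches != 1:
            raise MismatchCountError(
                f"expected exactly 1 mismatch, got {pair.n_mismatches}"
            )
        mm = pair.mismatches[0]
        mt, mp = encode_mismatch(mm)
        rows.append(
            np.concatenate(
                [
                    [ime[mm.position, mm.type_code]],
                    [gmt.score(pair.spacer)],
                    mt,
                    mp,
                ]
            )
        )
    return np.asarray(rows, dtype=float)


_KINDS = {
    "linear": lambda seed: LinearRegression(),
    "svr_rbf": lambda seed: SVR(kernel="rbf"),
    "random_forest": lambda seed: RandomForestRegressor(n_estimators=200, random_state=seed),
    "gbt": lambda seed: GradientBoostingRegressor(random_state=seed),
}


class SingleMismatchRegressor(BaseEstimator, RegressorMixin):
    """Regressor for the off-on ratio of a single-mismatch guide-target pair.

    ``kind`` selects the underlying model (default gradient-boosted trees,
    the best performer among linear/SVR/RF/GBT panels).  Predictions are
    clipped to be non-negative.  ``fit``/``predict`` operate on the frozen
    34-feature layout of :func:`mismatch_features`.
    """

    def __init__(self, kind: str = "gbt", random_state: int = 0):
        self.kind = kind
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[float]) -> "SingleMismatchRegressor":
        if self.kind not in _KINDS:
            raise UnknownKindError(f"kind {self.kind!r} not in {sorted(_KINDS)}")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != 34:
            raise LengthMismatchError(f"expected 34 features, got {X.shape[1]}")
        self.model_ = _KINDS[self.kind](self.random_state)
        self.model_.fit(X, np.asarray(y, dtype=float))
        self.n_features_in_ = 34
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise UncalibratedModelError("model is not fitted")
        return np.clip(self.model_.predict(np.asarray(X, dtype=float)), 0.0, None)


def predict_single(
    model: SingleMismatchRegressor, ime: IMEMatrix, gmt, pair: GuideTargetPair
) -> float:
    """Predicted off-on effect for one single-mismatch pair (clipped >= 0)."""
    return float(model.predict(mismatch_features([pair], ime, gmt))[0])


def combine_multi(
    m: Sequence[float],
    positions: Sequence[int],
    delta: DeltaTable,
    mode: str = "as_printed",
) -> float:
    """Combine per-mismatch effects into an overall multi-mismatch score.

    ``m`` are the predicted single-mismatch effects and ``positions`` their
    spacer positions.  For n = 1 the single effect is returned unchanged
    (the combinatorial term is only defined for n > 1).  For n >= 2 the
    pairwise combinatorial effects are pooled per ``mode``:

    * ``as_printed``: ``delta_all = (2/n) * sum_{i<j} delta_ij``
    * ``pair_mean``: arithmetic mean of the ``delta_ij``
    * ``geometric``: geometric mean of the ``delta_ij``

    and the score is ``delta_all * prod(m)``.  The two non-default modes
    coincide with ``as_printed`` at n = 2.
    """
    if len(m) != len(positions):
        raise LengthMismatchError("m and positions must have equal length")
    if len(m) == 0:
        raise EmptyInputError("at least one mismatch effect required")
    if mode not in DELTA_MODES:
        raise UnknownKindError(f"mode {mode!r} not in {DELTA_MODES}")
    prod_m = float(np.prod(np.asarray(m, dtype=float)))
    n = len(m)
    if n == 1:
        return prod_m
    deltas = [delta[i, j] for i, j in itertools.combinations(positions, 2)]
    if mode == "as_printed":
        d_all = (2.0 / n) * float(np.sum(deltas))
    elif mode == "pair_mean":
        d_all = float(np.mean(deltas))
    else:
        d_all = float(np.exp(np.mean(np.log(deltas))))
    return d_all * prod_m


# ---------------------------------------------------------------------------
# Candidate-site enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSite:
    """A candidate genomic off-target site (0-based half-open, forward coords)."""

    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    n_mismatches: int


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode_seq(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE.get(b, 4) for b in seq.upper()), dtype=np.int8,
                       count=len(seq))


def _scan_one_strand(
    seq_arr: np.ndarray, spacer_arr: np.ndarray, max_mm: int, pam: str
) -> list[tuple[int, int]]:
    """Return (window_start, n_mismatches) hits on one already-oriented strand."""
    L = len(spacer_arr)
    P = len(pam)
    n = len(seq_arr)
    if n < L + P:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, L)[: n - L - P + 1]
    # Genome N never matches any spacer base.
    mm = (windows != spacer_arr).sum(axis=1)
    pam_ok = np.ones(len(windows), dtype=bool)
    for k, p in enumerate(pam.upper()):
        col = seq_arr[L + k : L + k + len(windows)]
        if p == "N":
            pam_ok &= col < 4  # wildcard matches concrete bases only
        else:
            pam_ok &= col == _BASE_CODE[p]
    hits = np.nonzero((mm <= max_mm) & pam_ok)[0]
    return [(int(i), int(mm[i])) for i in hits]


def enumerate_sites(
    spacer: Spacer,
    genome: dict[str, str],
    max_mm: int = 5,
    pam: str = "NGG",
) -> list[CandidateSite]:
    """Exhaustively enumerate PAM-adjacent candidate sites on both strands.

    ``genome`` maps contig name to sequence (A/C/G/T/N).  A window qualifies
    when its 3'-adjacent triplet matches ``pam`` and the protospacer is
    within Hamming distance ``max_mm`` of the spacer; N never matches.
    Coordinates are 0-based half-open over the protospacer on the forward
    strand.
    """
    L = len(spacer)
    spacer_arr = _encode_seq(spacer.sequence)
    sites = []
    for contig, seq in genome.items():
        seq = seq.upper()
        fwd_arr = _encode_seq(seq)
        for win_start, n_mm in _scan_one_strand(fwd_arr, spacer_arr, max_mm, pam):
            sites.append(
                CandidateSite(
                    contig=contig,
                    start=win_start,
                    end=win_start + L,
                    strand="+",
                    protospacer=seq[win_start : win_start + L],
                    pam=seq[win_start + L : win_start + L + len(pam)],
                    n_mismatches=n_mm,
                )
            )
        rc = reverse_complement(seq)
        rc_arr = _encode_seq(rc)
        for win_start, n_mm in _scan_one_strand(rc_arr, spacer_arr, max_mm, pam):
            sites.append(
                CandidateSite(
                    contig=contig,
                    start=len(seq) - (win_start + L),
                    end=len(seq) - win_start,
                    strand="-",
                    protospacer=rc[win_start : win_start + L],
                    pam=rc[win_start + L : win_start + L + len(pam)],
                    n_mismatches=n_mm,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# Scoring bundle
# ---------------------------------------------------------------------------

@dataclass
class OffTargetScorer:
    """Bundle of fitted components used to score sites and guides."""

    model: SingleMismatchRegressor
    ime: IMEMatrix
    gmt: object
    delta: DeltaTable
    mode: str = "as_printed"

    def site_effect(self, spacer: Spacer, target: str) -> float:
        """Predicted off-target effect of one site (any mismatch count >= 1)."""
        pair = annotate_mismatches(spacer, target)
        if pair.n_mismatches == 0:
            raise MismatchCountError("perfect-match site has no off-target effect")
        ms, positions = [], []
        for mm in pair.mismatches:
            # Rebuild the single-mismatch version of this site.
            single = list(spacer.sequence)
            idx = len(spacer) - mm.position
            single[idx] = pair.target[idx]
            sub_pair = annotate_mismatches(spacer, "".join(single))
            ms.append(predict_single(self.model, self.ime, self.gmt, sub_pair))
            positions.append(mm.position)
        return combine_multi(ms, positions, self.delta, mode=self.mode)

    def aggregate_score(
        self,
        spacer: Spacer,
        sites: Sequence[CandidateSite],
        include_perfect: bool = False,
        eps: float = AGGREGATE_EPS,
    ) -> float:
        """Per-guide aggregate: log2(eps + sum of predicted site effects).

        Perfect-match sites (the intended locus) are excluded unless
        ``include_perfect``; a perfect match then contributes effect 1.
        With no qualifying site the score is the documented floor
        ``log2(eps)``.
        """
        total = 0.0
        for site in sites:
            if site.n_mismatches == 0:
                if include_perfect:
                    total += 1.0
                continue
            total += self.site_effect(spacer, site.protospacer)
        return float(np.log2(eps + total))


def aggregate_off_score(
    scorer: OffTargetScorer,
    spacer: Spacer,
    sites: Sequence[CandidateSite],
    include_perfect: bool = False,
) -> float:
    return scorer.aggregate_score(spacer, sites, include_perfect=include_perfect)


# ---------------------------------------------------------------------------
# Site-list I/O
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "guide_id", "contig", "start", "end", "strand", "protospacer", "pam",
    "n_mismatches",
]


def write_site_list(path, guide_id: str, sites: Sequence[CandidateSite]) -> None:
    df = pd.DataFrame(
        [
            {
                "guide_id": guide_id,
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "protospacer": s.protospacer,
                "pam": s.pam,
                "n_mismatches": s.n_mismatches,
            }
            for s in sites
        ],
        columns=_SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_site_list(path) -> list[tuple[str, CandidateSite]]:
    """Read a validated candidate-site TSV; raises SchemaError with line number."""
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "contig": str})
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"site list missing columns {sorted(missing)}")
    out = []
    for k, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.strand not in ("+", "-"):
            raise SchemaError(f"line {k}: invalid strand {row.strand!r}")
        start, end = int(row.start), int(row.end)
        proto = str(row.protospacer).upper()
        if end - start != len(proto):
            raise SchemaError(f"line {k}: start/end span != protospacer length")
        if end <= start:
            raise SchemaError(f"line {k}: empty or inverted interval")
        out.append(
            (
                row.guide_id,
                CandidateSite(
                    contig=row.contig,
                    start=start,
                    end=end,
                    strand=row.strand,
                    protospacer=proto,
                    pam=str(row.pam).upper(),
                    n_mismatches=int(row.n_mismatches),
                ),
            )
        )
    return out
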