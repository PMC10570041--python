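"""Sequence types, coordinate conventions and feature encodings.

Conventions frozen here and used everywhere else in the package:

* Spacer sequences are stored 5'->3' over {A,C,G,T} (RNA U normalized to T),
  length 19 or 20 nt.
* Spacer *positions* are 1-based counted from the PAM-proximal end: position 1
  is the nucleotide adjacent to the NGG PAM (the last character of the 5'->3'
  string), position L is the 5' terminus.  This matches the convention in
  which the seed region is positions ~1-10 and the REC3-interacting region is
  positions 15-18.
* 19-nt spacers are padded at the PAM-distal end: feature matrices always
  span 20 positions, with the position-20 column all-zero.
* Mismatches are written rXdY, where X is the guide (RNA) base and Y is the
  *template-strand* DNA base the guide hybridizes to -- i.e. the complement
  of the protospacer-strand base.  Watson-Crick pairs (rAdT, rCdG, rGdC,
  rUdA) are not representable, leaving 12 mismatch types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlphabetError, LengthError, LengthMismatchError, RangeError

#: Row order of the mononucleotide (4 x 20) encoding.
MONO_ORDER = "ATCG"

#: Row order of the dinucleotide (16 x 19) encoding.
DI_ORDER = (
    "AT", "AC", "AG", "AA", "TT", "TA", "TG", "TC",
    "CC", "CA", "CG", "CT", "GG", "GA", "GT", "GC",
)

#: The 12 representable guide:template mismatch types, in the frozen bit order
#: of the MT vector.
MT_ORDER = (
    "rAdA", "rAdC", "rAdG", "rCdA", "rCdC", "rCdT",
    "rGdA", "rGdG", "rGdT", "rUdC", "rUdG", "rUdT",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DNA = set("ACGT")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T; ambiguous N maps to N."""
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


@dataclass(frozen=True)
class Spacer:
    """A validated 19-20 nt guide spacer (5'->3', DNA alphabet)."""

    sequence: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) not in (19, 20):
            raise LengthError(
                f"spacer {self.id!r}: length {len(self.sequence)} not in (19, 20)"
            )
        bad = set(self.sequence) - _DNA
        if bad:
            raise AlphabetError(
                f"spacer {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based PAM-proximal position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[len(self) - position]


def validate_spacer(raw: str, id: str = "") -> Spacer:
    """Normalize and validate a raw spacer string.

    Input is case-insensitive; RNA U is stored as T.  Raises
    :class:`AlphabetError` for characters outside ACGTU and
    :class:`LengthError` for lengths other than 19 or 20.
    """
    if not raw:
        raise LengthError(f"spacer {id!r}: empty sequence")
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _DNA
    if bad:
        raise AlphabetError(f"spacer {id!r}: invalid characters {sorted(bad)}")
    return Spacer(seq, id)


@dataclass(frozen=True)
class Mismatch:
    """A single guide:template mismatch.

    ``rna_base`` is the guide base (U for T), ``dna_base`` the template-strand
    base it faces (complement of the protospacer base), ``type_code`` the
    rXdY label, and ``position`` the 1-based PAM-proximal position.
    """

    position: int
    rna_base: str
    dna_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 20:
            raise RangeError(f"mismatch position {self.position} outside 1..20")
        if self.rna_base not in set("ACGU"):
            raise AlphabetError(f"invalid RNA base {self.rna_base!r}")
        if self.dna_base not in _DNA:
            raise AlphabetError(f"invalid DNA base {self.dna_base!r}")
        if self.type_code not in MT_ORDER:
            raise AlphabetError(
                f"{self.type_code} is a Watson-Crick pairing, not a mismatch"
            )

    @property
    def type_code(self) -> str:
        return f"r{self.rna_base}d{self.dna_base}"


@dataclass(frozen=True)
class GuideTargetPair:
    """A spacer aligned to a same-length protospacer-strand target."""

    spacer: Spacer
    target: str
    mismatches: tuple = field(default_factory=tuple)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def annotate_mismatches(spacer: Spacer, target: str) -> GuideTargetPair:
    """Annotate guide:template mismatches between a spacer and a target.

    ``target`` is the protospacer-strand sequence (same orientation as the
    spacer).  At each differing position the guide base faces the complement
    of the protospacer base on the template strand, which is the base entering
    the rXdY code.
    """
    target = target.upper()
    if len(target) != len(spacer):
        raise LengthMismatchError(
            f"target length {len(target)} != spacer length {len(spacer)}"
        )
    bad = set(target) - _DNA
    if bad:
        raise AlphabetError(f"target contains invalid characters {sorted(bad)}")
    mms = []
    for pos in range(1, len(spacer) + 1):
        s = spacer.base_at(pos)
        t = target[len(target) - pos]
        if s != t:
            rna = "U" if s == "T" else s
            mms.append(Mismatch(position=pos, rna_base=rna, dna_base=complement(t)))
    mms.sort(key=lambda m: m.position)
    return GuideTargetPair(spacer=spacer, target=target, mismatches=tuple(mms))


def encode_mono(spacer: Spacer) -> np.ndarray:
    """One-hot mononucleotide encoding, shape (4, 20).

    Rows follow :data:`MONO_ORDER` (A, T, C, G); column ``j`` (0-based) is
    PAM-proximal position ``j + 1``.  For 19-nt spacers the PAM-distal
    column (position 20) is all-zero padding.
    """
    m = np.zeros((4, 20), dtype=np.int8)
    for pos in range(1, len(spacer) + 1):
        m[MONO_ORDER.index(spacer.base_at(pos)), pos - 1] = 1
    return m


def decode_mono(m: np.ndarray) -> str:
    """Invert :func:`encode_mono` (round-trip check helper)."""
    bases = []
    for j in range(20):
        col = m[:, j]
        if col.sum() == 0:
            continue
        bases.append(MONO_ORDER[int(np.argmax(col))])
    return "".join(reversed(bases))


_DI_INDEX = {d: i for i, d in enumerate(DI_ORDER)}


def encode_di(spacer: Spacer) -> np.ndarray:
    """One-hot dinucleotide encoding, shape (16, 19).

    Rows follow :data:`DI_ORDER`.  Column ``j`` (0-based) encodes the base
    pair at PAM-proximal positions (j+1, j+2), read as
    ``base_at(j+1) + base_at(j+2)``.  19-nt spacers populate columns 0..17
    and leave the PAM-distal column 18 zero.
    """
    m = np.zeros((16, 19), dtype=np.int8)
    for pos in range(1, len(spacer)):
        di = spacer.base_at(pos) + spacer.base_at(pos + 1)
        m[_DI_INDEX[di], pos - 1] = 1
    return m


def decode_di(m: np.ndarray) -> str:
    """Invert :func:`encode_di` for a fully populated encoding."""
    pairs = []
    for j in range(19):
        col = m[:, j]
        if col.sum() == 0:
            continue
        pairs.append(DI_ORDER[int(np.argmax(col))])
    # pairs[j] = base(pos j+1) + base(pos j+2); reconstruct proximal->distal
    bases = [pairs[0][0]]
    for p in pairs:
        bases.append(p[1])
    return "".join(reversed(bases))


_MT_INDEX = {c: i for i, c in enumerate(MT_ORDER)}


def encode_mismatch(mm: Mismatch) -> tuple[np.ndarray, np.ndarray]:
    """Encode one mismatch as its (MT, MP) one-hot vectors.

    MT is a 12-bit vector over :data:`MT_ORDER`; MP is a 20-bit vector whose
    set bit is the 1-based PAM-proximal position.
    """
    mt = np.zeros(12, dtype=np.int8)
    mt[_MT_INDEX[mm.type_code]] = 1
    mp = np.zeros(20, dtype=np.int8)
    mp[mm.position - 1] = 1
    return mt, mp


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise LengthMismatchError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spacers_fasta(path) -> list[Spacer]:
    """Read spacers from FASTA; the record id becomes the spacer id."""
    from Bio import SeqIO

    return [validate_spacer(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def read_spacers_tsv(path) -> pd.DataFrame:
    """Read a spacer table (columns: id, sequence[, gene, essential]).

    Sequences are validated/normalized in place; returns a DataFrame with at
    least ``id`` and ``sequence`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise LengthMismatchError(f"spacer TSV missing required column {col!r}")
    df = df.copy()
    df["sequence"] = [
        validate_spacer(s, i).sequence for s, i in zip(df["sequence"], df["id"])
    ]
    return df


def spacers_from_frame(df: pd.DataFrame) -> list[Spacer]:
    return [Spacer(s, i) for s, i in zip(df["sequence"], df["id"])]
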