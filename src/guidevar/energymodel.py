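"""Mismatch-associated energy barriers from nearest-neighbor stacking terms.

During R-loop formation the guide RNA displaces the protospacer strand and
hybridizes to the template strand.  A guide:template mismatch replaces two
fully paired DNA-DNA dinucleotide stacking steps with two perturbed RNA-DNA
hybrid steps, and the free-energy difference

``barrier = E_stack(DNA-DNA duplex) - E_stack(RNA-DNA hybrid)``

summed over the (at most two) dinucleotide steps spanning the three
nucleotides centered at the mismatch position is used as the energy barrier
the mismatch imposes.  At the duplex ends (positions 1 or L) the window
truncates to the single available step.

Parameter tables are keyed by ``(duplex_kind, template-strand step
dinucleotide 5'->3', central pairing state)`` where the pairing state is
``WC`` for a Watson-Crick step or the rXdY mismatch code when the step
contains the mismatched base.  Both duplex kinds share the same key space,
so exchanging the two kinds in a table negates every barrier exactly.

The package does not embed any published thermodynamic parameter set; it
ships a synthetic, reproducible fixture table (:func:`synthetic_stacking_table`)
for tests and demonstrations, and a TSV loader for user-supplied parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MissingParameterError, RangeError
from .seqfeat import MT_ORDER, GuideTargetPair, Mismatch, complement

DUPLEX_KINDS = ("DNA-DNA", "RNA-DNA")
WATSON_CRICK = "WC"

_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class StackingTable:
    """Nearest-neighbor stacking free energies in kcal/mol.

    ``params`` maps ``(duplex_kind, step_5to3, pairing_state)`` to a free
    energy.  ``pairing_state`` is ``"WC"`` or an rXdY mismatch code.  Both
    duplex kinds are looked up with identical (step, state) keys; since the
    protospacer:template DNA duplex is fully paired regardless of the guide,
    a physically derived table would replicate its WC value across the
    mismatch states of the DNA-DNA kind.
    """

    params: dict = field(default_factory=dict)
    units: str = "kcal/mol"

    def energy(self, duplex_kind: str, step: str, pairing_state: str) -> float:
        key = (duplex_kind, step, pairing_state)
        if key not in self.params:
            raise MissingParameterError(f"no stacking parameter for {key}")
        return self.params[key]

    def swapped(self) -> "StackingTable":
        """Table with the DNA-DNA and RNA-DNA entries exchanged."""
        dd, rd = DUPLEX_KINDS
        swapped = {
            (rd if k == dd else dd, s, p): v for (k, s, p), v in self.params.items()
        }
        return StackingTable(swapped, self.units)

    def to_tsv(self, path) -> None:
        rows = [
            {"duplex_kind": k, "step_5to3": s, "pairing_state": p,
             "energy_kcal_per_mol": v}
            for (k, s, p), v in sorted(self.params.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StackingTable":
        df = pd.read_csv(path, sep="\t")
        required = {"duplex_kind", "step_5to3", "pairing_state", "energy_kcal_per_mol"}
        missing = required - set(df.columns)
        if missing:
            raise RangeError(f"stacking TSV missing columns {sorted(missing)}")
        params = {
            (r.duplex_kind, r.step_5to3, r.pairing_state): float(r.energy_kcal_per_mol)
            for r in df.itertuples(index=False)
        }
        return cls(params)


def synthetic_stacking_table(seed: int = 20230824) -> StackingTable:
    """A complete synthetic stacking-parameter fixture.

    Values are reproducible draws in a physically plausible range
    (-2.5 .. -0.3 kcal/mol for paired steps, destabilized by +0.5 .. +2.0
    for mismatched steps) and carry no relation to any measured parameter
    set.  Intended for tests and synthetic-data demonstrations.
    """
    rng = np.random.default_rng(seed)
    params: dict = {}
    for kind in DUPLEX_KINDS:
        for step in _DINUCS:
            base = float(-2.5 + 2.2 * rng.random())
            params[(kind, step, WATSON_CRICK)] = round(base, 3)
            for code in MT_ORDER:
                penalty = float(0.5 + 1.5 * rng.random())
                params[(kind, step, code)] = round(base + penalty, 3)
    return StackingTable(params)


def _template_step(pair: GuideTargetPair, pos_low: int) -> str:
    """Template-strand dinucleotide (5'->3') over positions (pos_low, pos_low+1).

    The template strand is the reverse complement of the protospacer strand
    and runs 5'->3' from PAM-proximal to PAM-distal positions, so the step
    reads ``complement(protospacer[pos_low]) + complement(protospacer[pos_low+1])``.
    """
    L = len(pair.target)
    b1 = complement(pair.target[L - pos_low])
    b2 = complement(pair.target[L - (pos_low + 1)])
    return b1 + b2


def energy_barrier(
    pair: GuideTargetPair, mm: Mismatch, table: StackingTable
) -> float:
    """Energy barrier (kcal/mol) for one mismatch in a guide-target pair.

    Sums the DNA-DNA minus RNA-DNA stacking energies over the dinucleotide
    steps covering the three nucleotides centered at the mismatch position,
    truncating to one step at the duplex ends.
    """
    if mm not in pair.mismatches:
        raise RangeError("mismatch is not an annotation of this pair")
    L = len(pair.target)
    p = mm.position
    steps = [q for q in (p - 1, p) if 1 <= q and q + 1 <= L]
    barrier = 0.0
    for q in steps:
        step = _template_step(pair, q)
        barrier += table.energy("DNA-DNA", step, mm.type_code)
        barrier -= table.energy("RNA-DNA", step, mm.type_code)
    return barrier


def expected_type_barrier(table: StackingTable, type_code: str) -> float:
    """Expected barrier of a mismatch type over uniform sequence contexts.

    The template base of the mismatch (the dY of rXdY) sits in both window
    steps, so the realizable steps are ``X + dY`` (PAM-proximal neighbor)
    and ``dY + X`` (PAM-distal neighbor); the expectation averages the
    DNA-DNA minus RNA-DNA difference over the four choices of each neighbor
    and sums the two steps, matching the two-step window of
    :func:`energy_barrier` at interior positions.
    """
    d = type_code[3]
    total = 0.0
    for steps in ([x + d for x in "ACGT"], [d + x for x in "ACGT"]):
        diffs = [
            table.energy("DNA-DNA", s, type_code) - table.energy("RNA-DNA", s, type_code)
            for s in steps
        ]
        total += float(np.mean(diffs))
    return total


@dataclass(frozen=True)
class BarrierRecord:
    """Energy barrier joined to the variant/WT reduction for one pair."""

    pair_id: str
    type_code: str
    position: int
    barrier: float
    vtwt: float


def barrier_vtwt_correlation(records) -> dict:
    """Correlate energy barriers with variant-mediated off-target reduction.

    Returns per-pair Pearson r/p over (barrier, VT/WT), and per-type Pearson
    r/p between the mean barrier of each mismatch type and its median VT/WT
    ratio.  Requires at least 3 pairs and 3 distinct types with non-zero
    variance on both axes.
    """
    df = pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "type_code": r.type_code,
                "barrier": r.barrier,
                "vtwt": r.vtwt,
            }
            for r in records
        ]
    )
    if len(df) < 3:
        raise InsufficientDataError("need >= 3 records for per-pair correlation")
    if df["barrier"].nunique() < 2 or df["vtwt"].nunique() < 2:
        raise InsufficientDataError("constant barrier or VT/WT: correlation undefined")
    per_pair = stats.pearsonr(df["barrier"], df["vtwt"])
    by_type = df.groupby("type_code").agg(
        barrier=("barrier", "mean"), vtwt=("vtwt", "median")
    )
    if len(by_type) < 3:
        raise InsufficientDataError("need >= 3 mismatch types for per-type correlation")
    if by_type["barrier"].nunique() < 2 or by_type["vtwt"].nunique() < 2:
        raise InsufficientDataError("constant per-type values: correlation undefined")
    per_type = stats.pearsonr(by_type["barrier"], by_type["vtwt"])
    return {
        "per_pair_r": float(per_pair.statistic),
        "per_pair_p": float(per_pair.pvalue),
        "per_type_r": float(per_type.statistic),
        "per_type_p": float(per_type.pvalue),
        "by_type": by_type,
    }
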