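"""Synthetic data generation with planted ground truth.

Every generator is a pure function of (configuration, seed) and emulates the
statistical structure the analysis modules assume:

* a pooled viability screen: sgRNAs target essential or non-essential genes;
  knockout efficiency is a logistic function of spacer sequence; a
  high-fidelity variant suffers an additional guide-specific efficiency
  penalty planted on the T content of the REC3-interacting positions 15-18;
  a small fraction of promiscuous guides carries off-target dropout that the
  variants largely rescue; read counts are negative-binomial;
* a dual-target library: each guide gets a 3/3/1 panel of 1/2/3-mismatch
  targets; the true off-on ratio follows the multiplicative model
  GMT x prod(IME) x pairwise-delta, attenuated per enzyme with stronger
  attenuation for mismatches at positions 15-18; indel counts arise from
  independent per-molecule on/off editing events;
* a toy genome: random background with planted NGG-adjacent off-target
  sites at recorded coordinates.

The :class:`TruthBundle` carries every planted parameter so recovery tests
can compare estimates against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dualtarget import (
    DEFAULT_PANEL,
    DeltaTable,
    ENZYMES,
    IMEMatrix,
    REC3_POSITIONS,
    design_panel,
)
from .errors import CapacityError, RangeError
from .screenstats import compute_lfc, dropout_zscore
from .seqfeat import MT_ORDER, GuideTargetPair, Spacer, reverse_complement

ALPHABET = "ACGT"


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TruthBundle:
    """All planted parameters behind one synthetic study.

    The defaults chosen by :func:`make_truth` are the package's reference
    study conditions; see the methods note for the rationale behind each.
    """

    seed: int
    bias: float
    pos_weights: np.ndarray  # (4, 20), rows A/T/C/G, cols positions 1..20
    penalty_factor: float
    essential_effect: dict  # gene -> dropout effect size (log2 units)
    gmt: dict  # spacer sequence -> guide-intrinsic mismatch tolerance
    ime: IMEMatrix
    delta: DeltaTable
    attenuation: dict  # enzyme -> per-position off-target attenuation (20,)
    off_burden: dict  # guide id -> extra WT off-target dropout (log2 units)
    variant_off_residual: float = 0.3
    type_attenuation: dict = field(default_factory=dict)  # rXdY -> variant factor

    # -- on-target truth ----------------------------------------------------
    def wt_efficiency(self, spacer: Spacer) -> float:
        """WT knockout efficiency in (0, 1): logistic positional model."""
        from .seqfeat import MONO_ORDER

        s = 0.0
        for pos in range(1, len(spacer) + 1):
            s += self.pos_weights[MONO_ORDER.index(spacer.base_at(pos)), pos - 1]
        return float(_logistic(self.bias + s))

    def penalized(self, spacer: Spacer) -> bool:
        """Planted variant-specific penalty rule on positions 15-18.

        A guide loses efficiency with the high-fidelity variants when
        position 16 is T and an adjacent T occurs at position 15 or 17
        (inside the REC3-interacting window); this marks ~11% of random
        guides.  Keeping the penalized fraction well below ~15% matters:
        the 2-SD classification rule measures dispersion over the mixture,
        so a denser planted effect would mask itself.
        """
        if spacer.base_at(16) != "T":
            return False
        return any(spacer.base_at(p) == "T" for p in (15, 17))

    def variant_efficiency(self, spacer: Spacer) -> float:
        e = self.wt_efficiency(spacer)
        return e * self.penalty_factor if self.penalized(spacer) else e

    def efficiency(self, spacer: Spacer, enzyme: str) -> float:
        return self.wt_efficiency(spacer) if enzyme == "WT" else self.variant_efficiency(spacer)

    # -- off-target truth ---------------------------------------------------
    def _delta_term(self, positions) -> float:
        import itertools

        if len(positions) < 2:
            return 1.0
        ds = [self.delta[i, j] for i, j in itertools.combinations(positions, 2)]
        return float(np.mean(ds))

    def true_r(self, pair: GuideTargetPair, enzyme: str = "WT") -> float:
        """True off-on ratio under the multiplicative IME x GMT x delta model."""
        g = self.gmt[pair.spacer.sequence]
        m = np.prod([self.ime[mm.position, mm.type_code] for mm in pair.mismatches])
        r = g * float(m) * self._delta_term([mm.position for mm in pair.mismatches])
        att = self.attenuation[enzyme]
        for mm in pair.mismatches:
            r *= float(att[mm.position - 1])
            if enzyme != "WT" and self.type_attenuation:
                r *= float(self.type_attenuation[mm.type_code])
        return r

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "bias": self.bias,
            "pos_weights": self.pos_weights.tolist(),
            "penalty_factor": self.penalty_factor,
            "essential_effect": self.essential_effect,
            "gmt": self.gmt,
            "ime": self.ime.values.values.tolist(),
            "delta": np.where(np.isnan(self.delta.values), None, self.delta.values).tolist(),
            "attenuation": {k: np.asarray(v).tolist() for k, v in self.attenuation.items()},
            "off_burden": self.off_burden,
            "variant_off_residual": self.variant_off_residual,
            "type_attenuation": self.type_attenuation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        with open(path) as fh:
            p = json.load(fh)
        ime = IMEMatrix(
            pd.DataFrame(p["ime"], index=range(1, 21), columns=list(MT_ORDER))
        )
        delta_vals = np.array(
            [[np.nan if v is None else v for v in row] for row in p["delta"]]
        )
        return cls(
            seed=p["seed"],
            bias=p["bias"],
            pos_weights=np.asarray(p["pos_weights"]),
            penalty_factor=p["penalty_factor"],
            essential_effect=p["essential_effect"],
            gmt=p["gmt"],
            ime=ime,
            delta=DeltaTable(delta_vals),
            attenuation={k: np.asarray(v) for k, v in p["attenuation"].items()},
            off_burden=p["off_burden"],
            variant_off_residual=p["variant_off_residual"],
            type_attenuation=p.get("type_attenuation", {}),
        )


def gen_library(
    n_guides: int,
    length: int = 20,
    essential_fraction: float = 0.33,
    control_fraction: float = 0.05,
    guides_per_gene: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Random spacer library with round-robin gene assignment.

    Returns a DataFrame (id, sequence, gene, essential, control).  The
    essential fraction mirrors the makeup of a viability-screen library with
    core essential controls; ``control`` marks intergenic-style negative
    controls (non-essential, no off-target burden) that serve as the
    Z-score reference population.
    """
    if n_guides < 1:
        raise RangeError("n_guides must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list(ALPHABET), size=length)) for _ in range(n_guides)]
    n_ctrl = int(round(n_guides * control_fraction))
    n_rest = n_guides - n_ctrl
    n_genes = max(1, n_rest // guides_per_gene)
    n_ess_genes = int(round(n_genes * essential_fraction))
    genes, essential, control = [], [], []
    for i in range(n_rest):
        g = i % n_genes
        genes.append(f"gene{g:05d}")
        essential.append(g < n_ess_genes)
        control.append(False)
    for i in range(n_ctrl):
        genes.append(f"ctrl{i % max(1, n_ctrl // guides_per_gene):05d}")
        essential.append(False)
        control.append(True)
    return pd.DataFrame(
        {
            "id": [f"sg{i:05d}" for i in range(n_guides)],
            "sequence": seqs,
            "gene": genes,
            "essential": essential,
            "control": control,
        }
    )


def make_truth(
    library: pd.DataFrame,
    seed: int = 0,
    bias: float = 1.2,
    pos_weight_scale: float = 0.03,
    penalty_factor: float = 0.25,
    essential_effect_mean: float = 4.5,
    essential_effect_sd: float = 0.3,
    gmt_sigma: float = 0.3,
    delta_sigma: float = 0.25,
    promiscuous_fraction: float = 0.04,
    off_burden_mean: float = 1.5,
    variant_off_residual: float = 0.3,
    energy_coupling: float = 0.5,
) -> TruthBundle:
    """Plant the full generative truth for a library.

    IME values rise from the PAM-proximal seed toward PAM-distal positions
    (mismatch tolerance grows with distance from the PAM), modulated by a
    per-type factor and lognormal jitter.  Variant attenuation of off-target
    activity is strongest at the REC3-interacting positions 15-18, and is
    additionally coupled to the per-type mean stacking energy barrier of the
    synthetic parameter fixture (``energy_coupling`` scales how much a
    high-barrier mismatch type deepens the variant's off-target reduction).
    """
    rng = np.random.default_rng(seed)
    pos_weights = rng.normal(0.0, pos_weight_scale, size=(4, 20))

    effects = {}
    for gene, ess in library.groupby("gene")["essential"].first().items():
        effects[gene] = (
            float(rng.normal(essential_effect_mean, essential_effect_sd)) if ess else 0.0
        )

    # GMT is a tolerance multiplier centered at 1 (lognormal, clipped).
    gmt = {
        seq: float(np.clip(rng.lognormal(0.0, gmt_sigma), 0.4, 2.2))
        for seq in library["sequence"]
    }

    positions = np.arange(1, 21)
    pos_factor = 0.08 + 0.9 * ((positions - 1) / 19.0) ** 1.5
    type_factor = rng.uniform(0.4, 1.0, size=12)
    jitter = rng.lognormal(0.0, 0.15, size=(20, 12))
    ime_vals = np.clip(pos_factor[:, None] * type_factor[None, :] * jitter, 0.01, 1.2)
    ime = IMEMatrix(pd.DataFrame(ime_vals, index=range(1, 21), columns=list(MT_ORDER)))

    dvals = np.clip(rng.lognormal(0.0, delta_sigma, size=(20, 20)), 0.4, 2.2)
    dvals = (dvals + dvals.T) / 2.0
    np.fill_diagonal(dvals, np.nan)
    delta = DeltaTable(dvals)

    att = {"WT": np.ones(20)}
    for enzyme in ("HiFi", "LZ3"):
        base = np.full(20, 0.45) + rng.normal(0, 0.02, size=20)
        for p in REC3_POSITIONS:
            base[p - 1] = 0.28 + rng.normal(0, 0.01)
        att[enzyme] = np.clip(base, 0.05, 1.0)

    # Per-type variant attenuation tied to the synthetic stacking barriers:
    # mismatch types with a larger expected energy barrier are suppressed more.
    from .energymodel import expected_type_barrier, synthetic_stacking_table

    stacking = synthetic_stacking_table()
    type_barrier = {
        code: expected_type_barrier(stacking, code) for code in MT_ORDER
    }
    bvals = np.array(list(type_barrier.values()))
    lo, hi = bvals.min(), bvals.max()
    type_att = {
        code: float(1.0 - energy_coupling * (b - lo) / (hi - lo))
        for code, b in type_barrier.items()
    }

    burden = {}
    controls = (
        library.set_index("id")["control"].astype(bool)
        if "control" in library.columns
        else pd.Series(False, index=library["id"])
    )
    for gid in library["id"]:
        promiscuous = (not controls[gid]) and rng.random() < promiscuous_fraction
        burden[gid] = float(rng.normal(off_burden_mean, 0.3)) if promiscuous else 0.0

    return TruthBundle(
        seed=seed,
        bias=bias,
        pos_weights=pos_weights,
        penalty_factor=penalty_factor,
        essential_effect=effects,
        gmt=gmt,
        ime=ime,
        delta=delta,
        attenuation=att,
        off_burden=burden,
        variant_off_residual=variant_off_residual,
        type_attenuation=type_att,
    )


def gen_screen(
    library: pd.DataFrame,
    truth: TruthBundle,
    enzyme: str = "WT",
    depth: float = 700.0,
    n_reps: int = 3,
    nb_size: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one viability screen for one enzyme.

    The expected LFC of a guide is ``-(gene effect) x (enzyme-specific
    efficiency) - (off-target dropout)``; counts are negative-binomial around
    the expected abundances.  Returns a per-guide table with counts, the
    realized ``lfc`` (replicate-averaged) and ``z`` (standardized against
    non-essential guides), plus the planted truth columns.
    """
    if enzyme not in ENZYMES:
        raise RangeError(f"unknown enzyme {enzyme!r}")
    rng = np.random.default_rng(seed)
    spacers = [Spacer(s, i) for s, i in zip(library["sequence"], library["id"])]
    eff = np.array([truth.efficiency(s, enzyme) for s in spacers])
    gene_eff = np.array([truth.essential_effect[g] for g in library["gene"]])
    off = np.array([truth.off_burden[i] for i in library["id"]])
    if enzyme != "WT":
        off = off * truth.variant_off_residual
    lfc_true = -gene_eff * eff - off

    def nb(mean: np.ndarray) -> np.ndarray:
        p = nb_size / (nb_size + mean)
        return rng.negative_binomial(nb_size, p)

    initial = nb(np.full(len(library), float(depth)))
    finals = {
        f"final_{r + 1}": nb(depth * np.power(2.0, lfc_true)) for r in range(n_reps)
    }
    df = library.set_index("id").copy()
    df["initial"] = initial
    for k, v in finals.items():
        df[k] = v
    lfc = compute_lfc(df["initial"], df[list(finals)], pseudocount=0.5)
    if "control" in df.columns and df["control"].astype(bool).any():
        reference = df.index[df["control"].astype(bool)]
    else:
        reference = df.index[~df["essential"].astype(bool)]
    z = dropout_zscore(lfc, reference)
    df["lfc"] = lfc
    df["z"] = z
    df["true_efficiency"] = eff
    df["true_lfc"] = lfc_true
    df["penalized"] = [truth.penalized(s) for s in spacers]
    df["promiscuous"] = off > 0 if enzyme == "WT" else off > 0
    return df


def gen_dualtarget(
    library: pd.DataFrame,
    truth: TruthBundle,
    enzymes=ENZYMES,
    depth: int = 2000,
    composition=None,
    p_on_scale: float = 0.5,
    p_on_floor: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Simulate a dual-target panel for every guide in the library.

    Per guide, :func:`~guidevar.dualtarget.design_panel` draws the 3/3/1
    mismatch panel; for each (pair, enzyme) a per-molecule model edits the
    on-target site with probability ``p_on`` and the off-target site with
    probability ``p_off = min(0.98, r_true * p_on)``, independently, over
    ``depth`` molecules.  Returns ``(counts, pairs, truth_table)`` where
    ``counts`` is a long table (pair_id, enzyme, c1, c2, c3), ``pairs`` maps
    pair_id to its :class:`~guidevar.seqfeat.GuideTargetPair` and
    ``truth_table`` records the exact per-enzyme event probabilities
    (``true_r = p_off / p_on``).
    """
    composition = DEFAULT_PANEL if composition is None else composition
    rng = np.random.default_rng(seed)
    count_rows, truth_rows = [], []
    pairs: dict[str, GuideTargetPair] = {}
    for gid, seq in zip(library["id"], library["sequence"]):
        spacer = Spacer(seq, gid)
        panel = design_panel(spacer, composition, rng)
        for k, pair in enumerate(panel):
            pid = f"{gid}:t{k}"
            pairs[pid] = pair
            for enzyme in enzymes:
                p_on = p_on_floor + p_on_scale * truth.efficiency(spacer, enzyme)
                r = truth.true_r(pair, enzyme)
                p_off = min(0.98, r * p_on)
                c3 = int(rng.binomial(depth, p_on * p_off))
                c1 = int(rng.binomial(depth, p_off * (1 - p_on)))
                c2 = int(rng.binomial(depth, p_on * (1 - p_off)))
                count_rows.append(
                    {"pair_id": pid, "enzyme": enzyme, "c1": c1, "c2": c2, "c3": c3}
                )
                truth_rows.append(
                    {
                        "pair_id": pid,
                        "enzyme": enzyme,
                        "n_mismatches": pair.n_mismatches,
                        "p_on": p_on,
                        "p_off": p_off,
                        "true_r": p_off / p_on,
                    }
                )
    return pd.DataFrame(count_rows), pairs, pd.DataFrame(truth_rows)


def gen_toy_genome(
    spacers,
    n_planted: int = 2,
    mm_counts=(1, 2, 3),
    size_bp: int = 10000,
    contig: str = "toy1",
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Random genome with planted NGG-adjacent off-target sites.

    Plants ``n_planted`` sites per spacer, drawing each site's mismatch count
    from ``mm_counts``; slots are disjoint and recorded in the manifest
    (contig, start, end, strand, protospacer, pam, n_mm, guide_id).
    """
    rng = np.random.default_rng(seed)
    spacers = list(spacers)
    L = max(len(s) for s in spacers)
    slot = L + 3 + 4  # site + PAM + spacer gap
    n_sites = n_planted * len(spacers)
    if n_sites * slot > size_bp:
        raise CapacityError(
            f"{n_sites} sites need {n_sites * slot} bp, genome has {size_bp}"
        )
    background = rng.choice(list(ALPHABET), size=size_bp)
    starts = (np.arange(n_sites) * (size_bp // n_sites))[:n_sites]
    starts = starts + rng.integers(0, max(1, size_bp // n_sites - slot), size=n_sites)
    manifest = []
    order = rng.permutation(n_sites)
    idx = 0
    for spacer in spacers:
        for _ in range(n_planted):
            start0 = int(starts[order[idx]])
            idx += 1
            n_mm = int(rng.choice(mm_counts))
            # mutate n_mm random positions of the protospacer
            proto = list(spacer.sequence)
            for pos in rng.choice(np.arange(len(proto)), size=n_mm, replace=False):
                proto[pos] = rng.choice([b for b in ALPHABET if b != proto[pos]])
            proto = "".join(proto)
            pam = rng.choice(list(ALPHABET)) + "GG"
            piece = proto + pam
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                background[start0 : start0 + len(piece)] = list(piece)
                p_start = start0
            else:
                rc = reverse_complement(piece)
                background[start0 : start0 + len(piece)] = list(rc)
                p_start = start0 + 3
            manifest.append(
                {
                    "guide_id": spacer.id,
                    "contig": contig,
                    "start": p_start,
                    "end": p_start + len(spacer),
                    "strand": strand,
                    "protospacer": proto,
                    "pam": pam,
                    "n_mismatches": n_mm,
                }
            )
    genome = {contig: "".join(background)}
    return genome, pd.DataFrame(manifest)


def write_fasta(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
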