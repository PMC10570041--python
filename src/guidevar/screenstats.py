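"""Pooled viability-screen dropout statistics.

Implements the per-sgRNA quantities used throughout the package: log2
fold changes (LFC) of sgRNA abundance between timepoints, dropout Z-scores
standardized against a negative-control population, three-way efficiency /
depletion group classifications comparing wild-type SpCas9 with a
high-fidelity variant, positional nucleotide log-odds and Kullback-Leibler
divergence between sgRNA groups, and the strictly standardized mean
difference (SSMD) effect size.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateError,
    DegenerateReferenceError,
    MissingIdError,
    RangeError,
)
from .seqfeat import MONO_ORDER, Spacer

#: Efficiency-group labels (Z-score / indel-rate based classification).
INEFFICIENT = "Inefficient"
WT_EFFICIENT_ONLY = "WT_efficient_only"
BOTH_EFFICIENT = "Both_efficient"

#: Depletion-group labels (LFC based classification).
NO_DEPLETION = "No_depletion"
BOTH_DEPLETION = "Both_depletion"
WT_DEPLETION_ONLY = "WT_depletion_only"


def compute_lfc(
    initial: pd.Series | np.ndarray,
    final: pd.DataFrame | pd.Series | np.ndarray,
    pseudocount: float = 0.5,
    mode: str = "counts",
) -> pd.Series:
    """Per-sgRNA log2 fold change of relative abundance.

    Parameters
    ----------
    initial
        Read counts at the initial timepoint (plasmid pool), indexed by
        sgRNA id.
    final
        Read counts at the final timepoint.  A DataFrame is treated as one
        column per replicate; the LFC is computed per replicate and then
        averaged.
    pseudocount
        In ``mode="counts"`` (default), added to every raw count before
        normalization.  In ``mode="fraction"``, added to the normalized
        fractions instead.
    """
    if pseudocount <= 0:
        raise RangeError("pseudocount must be > 0")
    initial = pd.Series(initial, dtype=float)
    if isinstance(final, np.ndarray) and final.ndim == 1:
        final = pd.Series(final, index=initial.index)
    final = pd.DataFrame(final)
    if not final.index.equals(initial.index):
        missing = final.index.symmetric_difference(initial.index)
        raise MissingIdError(f"unmatched sgRNA ids: {list(missing)[:5]}")

    def one_rep(f: pd.Series) -> pd.Series:
        if mode == "counts":
            fi = (initial + pseudocount) / (initial + pseudocount).sum()
            ff = (f + pseudocount) / (f + pseudocount).sum()
            return np.log2(ff / fi)
        if mode == "fraction":
            fi = initial / initial.sum() + pseudocount
            ff = f / f.sum() + pseudocount
            return np.log2(ff / fi)
        raise RangeError(f"unknown mode {mode!r}")

    lfcs = pd.DataFrame({c: one_rep(final[c].astype(float)) for c in final.columns})
    return lfcs.mean(axis=1)


def dropout_zscore(lfc: pd.Series, reference_ids: Sequence) -> pd.Series:
    """Standardize LFCs against a reference (non-essential/control) population.

    ``z = (lfc - mean_ref) / sd_ref`` with the reference moments computed
    over ``reference_ids``.  Raises :class:`DegenerateReferenceError` if the
    reference LFCs are constant.
    """
    lfc = pd.Series(lfc, dtype=float)
    ref_ids = [i for i in reference_ids if i in lfc.index]
    if not ref_ids:
        raise MissingIdError("no reference ids present in the LFC table")
    ref = lfc.loc[ref_ids]
    sd = float(ref.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateReferenceError("reference population has zero variance")
    return (lfc - float(ref.mean())) / sd


def _three_way_split(
    primary: pd.Series,
    diff: pd.Series,
    efficient_mask: pd.Series,
    sd_mult: float,
    sd_over: str,
) -> pd.Series:
    """Shared three-way classification: inefficient / WT-only / both."""
    if sd_over == "efficient":
        sd = float(diff[efficient_mask].std(ddof=1))
    elif sd_over == "all":
        sd = float(diff.std(ddof=1))
    else:
        raise RangeError(f"sd_over must be 'efficient' or 'all', got {sd_over!r}")
    labels = pd.Series(INEFFICIENT, index=primary.index, dtype=object)
    wt_only = efficient_mask & (diff > sd_mult * sd)
    labels[efficient_mask] = BOTH_EFFICIENT
    labels[wt_only] = WT_EFFICIENT_ONLY
    return labels


def classify_efficiency_groups(
    z_wt: pd.Series,
    z_variant: pd.Series,
    z_thr: float = -3.0,
    sd_mult: float = 2.0,
    sd_over: str = "efficient",
) -> pd.Series:
    """Three-way efficiency classification of essential-gene sgRNAs.

    * ``Inefficient`` -- Z-score > ``z_thr`` in the wild-type screen.
    * ``WT_efficient_only`` -- efficient in WT and the variant-minus-WT
      Z-score difference exceeds ``sd_mult`` standard deviations of that
      difference (computed over the sgRNAs passing the WT threshold by
      default; ``sd_over="all"`` uses every input sgRNA).
    * ``Both_efficient`` -- efficient in WT with no large difference.
    """
    z_wt = pd.Series(z_wt, dtype=float)
    z_variant = pd.Series(z_variant, dtype=float)
    if not z_wt.index.equals(z_variant.index):
        raise MissingIdError("z_wt and z_variant must share an index")
    return _three_way_split(
        z_wt, z_variant - z_wt, z_wt <= z_thr, sd_mult, sd_over
    )


def classify_efficiency_groups_indel(
    indel_wt: pd.Series,
    indel_var: pd.Series,
    rate_thr: float = 0.6,
    sd_mult: float = 2.0,
    sd_over: str = "efficient",
) -> pd.Series:
    """Efficiency classification from measured indel rates (HF1-style data).

    ``Inefficient`` if the WT indel rate is below ``rate_thr``; otherwise the
    WT-minus-variant rate difference is compared against ``sd_mult`` SDs.
    """
    indel_wt = pd.Series(indel_wt, dtype=float)
    indel_var = pd.Series(indel_var, dtype=float)
    for name, v in (("indel_wt", indel_wt), ("indel_var", indel_var)):
        if ((v < 0) | (v > 1)).any():
            raise RangeError(f"{name} contains rates outside [0, 1]")
    if not indel_wt.index.equals(indel_var.index):
        raise MissingIdError("indel_wt and indel_var must share an index")
    return _three_way_split(
        indel_wt, indel_wt - indel_var, indel_wt >= rate_thr, sd_mult, sd_over
    )


def classify_depletion_groups(
    lfc_wt: pd.Series,
    lfc_vt: pd.Series,
    lfc_thr: float = -1.0,
    fold_diff: float = 2.0,
) -> pd.Series:
    """Depletion classification used for non-essential/essential scatter views.

    ``No_depletion`` if the WT LFC is above ``lfc_thr``; otherwise
    ``WT_depletion_only`` when the variant abundance exceeds the WT abundance
    by more than ``fold_diff``-fold (LFC difference > log2(fold_diff)), else
    ``Both_depletion``.
    """
    lfc_wt = pd.Series(lfc_wt, dtype=float)
    lfc_vt = pd.Series(lfc_vt, dtype=float)
    if not lfc_wt.index.equals(lfc_vt.index):
        raise MissingIdError("lfc_wt and lfc_vt must share an index")
    labels = pd.Series(NO_DEPLETION, index=lfc_wt.index, dtype=object)
    depleted = lfc_wt <= lfc_thr
    wt_only = depleted & ((lfc_vt - lfc_wt) > np.log2(fold_diff))
    labels[depleted] = BOTH_DEPLETION
    labels[wt_only] = WT_DEPLETION_ONLY
    return labels


def _position_freqs(spacers: Sequence[Spacer], pseudo: float, L: int) -> tuple[np.ndarray, np.ndarray]:
    """(smoothed, raw) per-position nucleotide frequencies, each (4, L)."""
    counts = np.zeros((4, L), dtype=float)
    n_at = np.zeros(L, dtype=float)
    for s in spacers:
        for pos in range(1, len(s) + 1):
            counts[MONO_ORDER.index(s.base_at(pos)), pos - 1] += 1
            n_at[pos - 1] += 1
    f = counts / np.maximum(n_at, 1)
    f = f + pseudo
    return f / f.sum(axis=0, keepdims=True), counts / np.maximum(n_at, 1)


def position_log_odds(
    group_a: Sequence[Spacer],
    group_b: Sequence[Spacer],
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Positional nucleotide log2 odds ratios between two sgRNA groups.

    For nucleotide ``n`` at position ``i``:
    ``LOR = log2(odds_a / odds_b)`` with ``odds = (f + pseudo)/(1 - f + pseudo)``
    and ``f`` the within-group frequency.  Rows A/T/C/G, columns positions
    1..L (PAM-proximal first).  Positive values mark enrichment in group a.
    """
    L = max(max(len(s) for s in group_a), max(len(s) for s in group_b))
    _, fa = _position_freqs(group_a, pseudo, L)
    _, fb = _position_freqs(group_b, pseudo, L)
    odds_a = (fa + pseudo) / (1 - fa + pseudo)
    odds_b = (fb + pseudo) / (1 - fb + pseudo)
    lor = np.log2(odds_a / odds_b)
    return pd.DataFrame(lor, index=list(MONO_ORDER), columns=range(1, L + 1))


def position_kl(
    group_a: Sequence[Spacer],
    group_b: Sequence[Spacer],
    pseudo: float = 0.01,
) -> pd.Series:
    """Per-position KL divergence (natural log) of group a from group b.

    ``KL_i = sum_n N_i^n * ln(N_i^n / M_i^n)`` where N and M are the smoothed,
    renormalized nucleotide frequencies at position i in groups a and b.
    Larger values mark positions whose nucleotide composition most separates
    the two groups.
    """
    L = max(max(len(s) for s in group_a), max(len(s) for s in group_b))
    na, _ = _position_freqs(group_a, pseudo, L)
    mb, _ = _position_freqs(group_b, pseudo, L)
    kl = (na * np.log(na / mb)).sum(axis=0)
    return pd.Series(kl, index=range(1, len(kl) + 1))


def ssmd(values_pos: Sequence[float], values_neg: Sequence[float]) -> float:
    """Strictly standardized mean difference between two sgRNA populations.

    ``SSMD = (mean(neg) - mean(pos)) / sqrt(var(neg) + var(pos))``.
    With ``values_pos`` the essential-gene (dropout) LFCs and ``values_neg``
    the non-essential LFCs, stronger essential dropout gives a larger
    positive SSMD.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateError("both groups need at least 2 values")
    denom = np.sqrt(neg.var(ddof=1) + pos.var(ddof=1))
    if denom == 0:
        raise DegenerateError("both group variances are zero")
    return float((neg.mean() - pos.mean()) / denom)
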