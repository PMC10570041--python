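# Methods

This note documents the models implemented in `guidevar`, the conventions
they rely on, the synthetic study conditions used throughout the tests and
the acceptance script, and the design decisions taken where the design was
genuinely open.

## Coordinates and sequence conventions

Spacers are 19–20 nt DNA-alphabet strings stored 5'→3' (RNA U normalized to
T). Positions are 1-based from the **PAM-proximal** end: position 1 abuts
the NGG PAM, the seed region is roughly positions 1–10, and the
REC3-interacting window is positions 15–18. 19-nt spacers are padded at the
PAM-distal end, so every feature matrix spans 20 positions with the
position-20 column zero. Mismatches are written rXdY with X the guide base
and Y the **template-strand** base (the complement of the protospacer base);
this convention is forced by the 12-type alphabet, which contains rUdT but
no rUdA. The row orders of the mono (A,T,C,G) and di encodings and the MT
bit order are frozen constants in `seqfeat`; no canonical ordering exists
for them, so the orders are arbitrary but documented and stable.

## Screen statistics

LFC is computed per replicate as log2 of the ratio of count fractions, with
a 0.5 read-count pseudocount added before normalization (a fraction-space
pseudocount mode is available), then averaged over replicates. Z-scores
standardize LFC against a reference population — by default designated
negative-control guides, otherwise all non-essential guides. Using clean
controls matters: guides whose dropout is off-target-driven would otherwise
inflate the reference SD differently in WT and variant screens and corrupt
the variant-minus-WT difference scale.

The three-way efficiency classification declares a guide *Inefficient* if
its WT Z-score exceeds −3; among the rest, *WT efficient only* requires the
variant−WT Z difference to exceed 2 SD of that difference. The SD is
computed over the guides that passed the WT threshold (configurable to all
essentials); nothing in the classification uses the planted truth. Note a
structural property of this rule: the planted (or real) effect is part of
the dispersion it is compared against, so if much more than ~15% of guides
carry a large penalty the rule partially masks itself. KL divergence uses
the natural-log four-term sum over smoothed (pseudo = 0.01), renormalized
frequencies; log-odds use log2 with odds (f+0.01)/(1−f+0.01). SSMD is
(μ_neg − μ_pos)/√(σ²_neg + σ²_pos) with sample variances.

## Dual-target quantification

The off–on ratio r = (C1+C3)/(C2+C3) has a zero-denominator error by
default (eps = 0) so that uncovered pairs surface instead of being smoothed.
The IME matrix is the per-cell mean of single-mismatch ratios; cells never
observed are filled by the same-type mean, then the global mean, with
provenance flags. δᵢⱼ is the median over double-mismatch pairs of
r/(mᵢ·mⱼ); the median resists the heavy right tail of ratio noise. The δ
estimator is exact on noise-free multiplicative data (closed-loop test) but
carries a small multiplicative bias ≈ median(GMT)/E[GMT]² when guides have
heterogeneous mismatch tolerance; with the lognormal(σ=0.3) GMT used in the
synthetic study this bias is ~9%. Position pairs without data default to
δ = 1 (multiplicative independence), flagged `observed=False`.

The VT/WT ratio (r_HiFi + r_LZ3)/(2·r_WT) is summarized per position and per
mismatch type after keeping pairs with a strong WT effect (r_WT > 0.5);
the position contrast (15–18 vs others) is a two-sided Mann–Whitney U test.

## Energy model

The barrier of a mismatch is the DNA–DNA minus RNA–DNA stacking energy
summed over the one or two dinucleotide steps covering the three nucleotides
centered at the mismatch (truncated at the duplex ends — no physical
neighbor exists there; summation rather than averaging was chosen so the
truncated window is directly comparable step-for-step). Steps are keyed by
the template-strand dinucleotide and the central pairing state (WC or the
rXdY code); both duplex kinds share the key space, which makes
"swap the two tables" an exact sign flip and lets a user table express (or
ignore) state dependence per kind. **No published thermodynamic parameters
are embedded**: `synthetic_stacking_table()` generates a reproducible,
physically plausible but synthetic fixture, and `StackingTable.from_tsv`
loads user-supplied values. All numeric results involving energies in this
repository are therefore statements about the synthetic fixture, not about
measured chemistry.

## GuideVar-on (transfer learning)

The source encoders are bidirectional LSTMs (hidden size 24–32 in the
reference configurations, input = 4×20 one-hot, embedding = the two final
hidden states concatenated) trained with a temporary linear head by
full-batch Adam on mean-squared error; the head is discarded and the
recurrent parameters frozen, with a SHA-256 digest over the parameter bytes
asserting the freezing contract before and after fine-tuning. The LSTM and
its backpropagation-through-time are implemented in numpy (gradient-checked
in the test suite); at these sizes full-batch training takes seconds and is
bit-reproducible under a fixed seed.

Fine-tuning trains a small dense head (sklearn `MLPRegressor`, default
(128, 32), L2 α = 1e-4) on the concatenated embeddings plus, per
configuration, flattened mono (80) and/or di (304) features. The target is
the negated mean of the HiFi and LZ3 dropout Z-scores so that higher =
more efficient; predictions are min–max calibrated to [0, 1] on the
training targets and clipped. The calibrated scale anchors the triage
threshold 0.5. Baselines (linear, RBF-SVR, random forest, GBT) run on the
same flattened features with the same calibration. Cross-validation is
repeated k-fold (default k = 5, 10 repeats — published accounts of this
architecture mention both 5- and 10-fold CV, so k is configurable) with
held-out Spearman as the metric.

## GuideVar-off

The single-mismatch regressor (GBT default; linear/SVR/RF selectable) maps
the frozen 34-feature layout [IME(1), GMT(1), MT(12), MP(20)] to the off–on
ratio, clipped non-negative. For N-mismatch sites each constituent single
mismatch is predicted separately and combined as δ_all · Π mᵢ. The printed
combiner δ_all = (2/n)Σ_{i<j}δᵢⱼ is the default (`as_printed`); because the
accompanying prose describes a *mean* while this expression is not one for
n > 2, `pair_mean` and `geometric` modes are provided, and all three
coincide at n = 2. A single mismatch bypasses δ_all entirely (the printed
expression would be 0 and annihilate the score). δ indexing uses positions
1..20. GMT is pluggable (constant, lookup; a learned scorer can be dropped
in) — note that multiplying per-mismatch predictions counts the guide's GMT
once per mismatch, a property inherited from the model family rather than
corrected here.

Candidate sites come from an exhaustive vectorized Hamming scan of both
strands for NGG-adjacent windows (N in the genome never matches; wildcard
PAM positions require a concrete base). Coordinates are 0-based half-open on
the forward strand. The per-guide aggregate is log2(ε + Σ effects) with
ε = 1e-6, perfect-match sites excluded by default (the intended locus is
not an off-target); the triage off-threshold 1.0 is defined against this
log2/ε convention. The enumerator targets toy genomes (tests use ≤ 25 kb);
indexed genome-scale search is explicitly out of scope.

## Triage

Classes: low_on (on ≤ 0.5), high_on_low_off (on > 0.5, off < 1.0),
high_on_high_off (otherwise). Boundaries fall into the less-preferred class
since the thresholds were stated as open inequalities. Selection quality is
the SSMD between essential and non-essential LFC distributions within each
class versus the full library.

## Synthetic study conditions

The generator defaults define the reference study used by the tests and the
acceptance script:

* **Library**: uniform random 20-nt spacers; 4 guides/gene; 33% of genes
  essential (the approximate essential-targeting fraction of a viability
  screen library with core-essential controls); 5% clean negative-control
  guides used as the Z reference.
* **On-target truth**: WT efficiency = logistic(1.2 + Σ positional weights),
  weights N(0, 0.03) — most guides 0.65–0.85 efficient. Variant penalty:
  guides with T at position 16 and T at 15 or 17 (≈11% of random guides)
  keep only 25% of their efficiency with HiFi/LZ3. The penalized fraction is
  deliberately kept near 10% so the 2-SD classification rule can recover it
  (see the self-masking caveat above).
* **Screens**: gene effect ≈ N(4.5, 0.3) log2 units for essential genes;
  4% of non-control guides carry off-target dropout N(1.5, 0.3) log2 units,
  reduced to 30% under the variants; negative-binomial counts (size 100)
  at depth 700 (deep-coverage tests use 2000/size 300); 3 replicates.
* **Off-target truth**: r = GMT · Π IME · δ̄. IME rises from ~0.08 at the
  seed to ~1 PAM-distally, times a per-type factor U(0.4, 1) and lognormal
  jitter; GMT lognormal(0, 0.3) centered at 1; δ lognormal(0, 0.25) clipped
  to [0.4, 2.2]. Variant attenuation per mismatch: 0.45 per position
  (0.28 at 15–18) times a per-type factor that decreases linearly in the
  type's expected synthetic stacking barrier (range 0.5–1.0) — so both the
  positional and the energetic structure of variant off-target reduction
  are planted and recoverable. 3-mismatch truth pools δ pairs by their
  arithmetic mean.
* **Dual-target counts**: per molecule, on- and off-target edits are
  independent Bernoulli events with p_off = min(0.98, r · p_on), aggregated
  over `depth` molecules (reference depth 5000); C3 counts joint events.
  This reproduces r = p_off/p_on in expectation.

What the generator does **not** emulate: PCR/sequencing error, overdispersed
indel spectra, guide-position effects within genes, copy-number artifacts,
correlated off-target sites, bulges, or non-NGG PAMs. Passing recovery
tests therefore demonstrates the correctness and statistical soundness of
the estimators and models under the stated generative assumptions — not
their real-data accuracy, which requires real screens and pretrained
source weights.

## Numerical choices and degenerate inputs

Zero denominators raise typed errors rather than returning sentinels
(off–on ratio, VT/WT, Z-scores with constant reference, SSMD with two
zero-variance arms). Frequency smoothing constants: 0.01 for log-odds/KL,
configurable. The aggregate off score floor is log2(1e-6) ≈ −19.9 for
guides with no qualifying site. Ties in GBT/RF are handled by fixed
`random_state`; all generators draw from `numpy.random.default_rng` seeded
per call, so every artifact is a pure function of (config, seed).

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to make the
statistical guarantees comfortably testable: 1500-guide dual-target panels
(≈19 single-mismatch pairs per IME cell, ≈24 double-mismatch pairs per
position pair), 1200-guide screens at depth 2000 for group recovery,
900-guide screens across 10 seeds for triage, 2000 guides for the
fine-tuning freezing contract, and 10-kb genomes for enumerator equivalence.

## Known limitations

* The BiLSTM encoders are pretrained on synthetic tasks; importing real
  pretrained embeddings is supported by constructing `SourceEncoder` from
  saved parameters, but no real weights ship with the package.
* The on-target score scale is a min–max calibration of the training
  target; scores are comparable within one trained model only.
* δ estimation assumes the IME product model holds up to a pairwise
  correction; higher-order interactions are not modeled.
* The stacking-energy fixture is synthetic; conclusions about real
  mismatch thermodynamics require a user-supplied parameter table.
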