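"""Off-target prediction: features, multi-mismatch combination, site search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from guidevar import offtarget as ot
from guidevar.dualtarget import DeltaTable, IMEMatrix
from guidevar.errors import (
    LengthMismatchError,
    MismatchCountError,
    SchemaError,
    UnknownKindError,
)
from guidevar.seqfeat import MT_ORDER, Spacer, annotate_mismatches, reverse_complement

from conftest import random_spacer


class TestMismatchFeatures:
    def test_layout(self):
        ime = IMEMatrix.from_constant(0.33)
        gmt = ot.ConstantGMT(0.8)
        sp = Spacer("A" * 20)
        target = list(sp.sequence)
        target[20 - 7] = "G"  # rAdC at position 7
        X = ot.mismatch_features([annotate_mismatches(sp, "".join(target))], ime, gmt)
        assert X.shape == (1, 34)
        assert X[0, 0] == pytest.approx(0.33)  # IME value
        assert X[0, 1] == pytest.approx(0.8)  # GMT
        assert X[0, 2 + MT_ORDER.index("rAdC")] == 1 and X[0, 2:14].sum() == 1
        assert X[0, 14 + 6] == 1 and X[0, 14:34].sum() == 1

    def test_multi_mismatch_rejected(self):
        sp = Spacer("A" * 20)
        pair = annotate_mismatches(sp, "GG" + sp.sequence[2:])
        with pytest.raises(MismatchCountError):
            ot.mismatch_features([pair], IMEMatrix.from_constant(1), ot.ConstantGMT())


class TestSingleMismatchRegressor:
    def test_constant_zero_regressor(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 34))
        model = ot.SingleMismatchRegressor(kind="linear").fit(X, np.zeros(50))
        assert np.allclose(model.predict(X), 0.0, atol=1e-9)

    def test_predictions_clipped_nonnegative(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 34))
        y = rng.normal(size=100)  # includes negatives
        model = ot.SingleMismatchRegressor(kind="linear").fit(X, y)
        assert (model.predict(X) >= 0).all()

    def test_unknown_kind(self):
        with pytest.raises(UnknownKindError):
            ot.SingleMismatchRegressor(kind="cnn").fit(np.zeros((5, 34)), np.zeros(5))

    def test_wrong_feature_width(self):
        with pytest.raises(LengthMismatchError):
            ot.SingleMismatchRegressor().fit(np.zeros((5, 10)), np.zeros(5))

    def test_closed_loop_ime_gmt_product(self, dual_study):
        """Model trained on r = IME x GMT data ranks pairs like the truth."""
        pairs, ratios = dual_study["pairs"], dual_study["ratios"]
        ime = IMEMatrix(dual_study["truth"].ime.values)
        gmt = dual_study["gmt"]
        ids = dual_study["one_ids"]
        X = ot.mismatch_features([pairs[p] for p in ids], ime, gmt)
        y = ratios.loc[ids, "r_wt"].to_numpy()
        model = ot.SingleMismatchRegressor(kind="gbt", random_state=0).fit(
            X[:3000], y[:3000]
        )
        truth_r = (
            dual_study["dt_truth"]
            .query("enzyme == 'WT'")
            .set_index("pair_id")
            .loc[ids[3000:], "true_r"]
            .to_numpy()
        )
        rho = spearmanr(model.predict(X[3000:]), truth_r).statistic
        assert rho >= 0.9


class TestCombineMulti:
    def test_single_mismatch_passthrough(self):
        delta = DeltaTable.from_constant(5.0)
        assert ot.combine_multi([0.3], [4], delta) == pytest.approx(0.3)

    def test_two_mismatches_modes_coincide(self):
        v = np.full((20, 20), 1.0)
        v[0, 4] = v[4, 0] = 0.8
        np.fill_diagonal(v, np.nan)
        delta = DeltaTable(v)
        for mode in ("as_printed", "pair_mean", "geometric"):
            assert ot.combine_multi([0.5, 0.4], [1, 5], delta, mode) == pytest.approx(0.16)

    def test_three_mismatch_mode_divergence(self):
        delta = DeltaTable.from_constant(1.0)
        m = [0.5, 0.4, 0.3]
        prod = float(np.prod(m))
        assert ot.combine_multi(m, [1, 5, 9], delta, "as_printed") == pytest.approx(2 * prod)
        assert ot.combine_multi(m, [1, 5, 9], delta, "pair_mean") == pytest.approx(prod)
        assert ot.combine_multi(m, [1, 5, 9], delta, "geometric") == pytest.approx(prod)

    def test_permutation_invariance_and_homogeneity(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.5, 1.5, (20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        delta = DeltaTable(v)
        m = [0.7, 0.2, 0.9]
        pos = [2, 11, 17]
        ref = ot.combine_multi(m, pos, delta)
        for perm in itertools.permutations(range(3)):
            assert ot.combine_multi(
                [m[i] for i in perm], [pos[i] for i in perm], delta
            ) == pytest.approx(ref)
        # degree-1 homogeneity in each m_i
        scaled = ot.combine_multi([3 * m[0], m[1], m[2]], pos, delta)
        assert scaled == pytest.approx(3 * ref)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            ot.combine_multi([0.1, 0.2], [1], DeltaTable.from_constant())


class TestEnumerateSites:
    def test_exact_match_with_pam_found(self):
        sp = Spacer("ACGTACGTACGTACGTACGT", "g")
        genome = {"chr": "TTTT" + sp.sequence + "AGG" + "TTTT"}
        sites = ot.enumerate_sites(sp, genome, max_mm=0)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.strand, s.n_mismatches) == (4, 24, "+", 0)
        assert s.pam == "AGG"

    def test_non_ngg_pam_rejected(self):
        sp = Spacer("ACGTACGTACGTACGTACGT", "g")
        genome = {"chr": "TTTT" + sp.sequence + "ACG" + "TTTT"}
        assert ot.enumerate_sites(sp, genome, max_mm=5) == []

    def test_minus_strand_coordinates(self):
        sp = Spacer("ACGTACGTACGTACGTACGT", "g")
        piece = sp.sequence + "TGG"
        genome = {"chr": "AAAA" + reverse_complement(piece) + "AAAA"}
        sites = ot.enumerate_sites(sp, genome, max_mm=0)
        assert len(sites) == 1
        s = sites[0]
        assert (s.strand, s.start, s.end) == ("-", 7, 27)
        assert s.protospacer == sp.sequence

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            sp = random_spacer(rng, id="g")
            genome = {
                "c": "".join(
                    rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=3000)
                )
            }
            mine = sorted(
                (s.contig, s.start, s.end, s.strand, s.protospacer, s.pam, s.n_mismatches)
                for s in ot.enumerate_sites(sp, genome, max_mm=4)
            )
            assert mine == brute_force_sites(sp, genome, max_mm=4)


def brute_force_sites(spacer, genome, max_mm=5):
    """Independent Hamming-scan oracle (plain string loops, no shared helpers)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    out = []
    L = len(spacer.sequence)
    for contig, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else "".join(comp[b] for b in reversed(seq))
            for i in range(n - L - 2):
                win, pam = s[i : i + L], s[i + L : i + L + 3]
                if pam[0] == "N" or pam[1] != "G" or pam[2] != "G":
                    continue
                mm = sum(a != b for a, b in zip(win, spacer.sequence))
                if mm <= max_mm:
                    if strand == "+":
                        out.append((contig, i, i + L, "+", win, pam, mm))
                    else:
                        out.append((contig, n - (i + L), n - i, "-", win, pam, mm))
    return sorted(out)


class _StubModel:
    """Duck-typed single-mismatch model returning a fixed effect."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _stub_scorer(value, delta_value=1.0):
    return ot.OffTargetScorer(
        model=_StubModel(value),
        ime=IMEMatrix.from_constant(0.5),
        gmt=ot.ConstantGMT(1.0),
        delta=DeltaTable.from_constant(delta_value),
    )


class TestAggregateScore:
    def _site(self, sp, n_mm, seed=0):
        rng = np.random.default_rng(seed)
        target = list(sp.sequence)
        for pos in rng.choice(20, size=n_mm, replace=False):
            target[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[target[pos]]
        return ot.CandidateSite("c", 0, 20, "+", "".join(target), "AGG", n_mm)

    def test_no_sites_gives_floor(self):
        sp = Spacer("A" * 20)
        assert _stub_scorer(1.0).aggregate_score(sp, []) == pytest.approx(
            np.log2(1e-6)
        )

    def test_single_site_effect_two(self):
        sp = Spacer("ACGT" * 5)
        score = _stub_scorer(2.0).aggregate_score(sp, [self._site(sp, 1)])
        assert score == pytest.approx(1.0, abs=1e-5)

    def test_adding_sites_strictly_increases(self):
        sp = Spacer("ACGT" * 5)
        scorer = _stub_scorer(0.5)
        sites = [self._site(sp, 1, seed=s) for s in range(4)]
        scores = [scorer.aggregate_score(sp, sites[:k]) for k in range(5)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_perfect_match_excluded_by_default(self):
        sp = Spacer("ACGT" * 5)
        perfect = ot.CandidateSite("c", 0, 20, "+", sp.sequence, "AGG", 0)
        scorer = _stub_scorer(1.0)
        floor = scorer.aggregate_score(sp, [perfect])
        assert floor == pytest.approx(np.log2(1e-6))
        assert scorer.aggregate_score(sp, [perfect], include_perfect=True) > floor

    def test_multi_mismatch_site_uses_delta(self):
        sp = Spacer("ACGT" * 5)
        scorer = _stub_scorer(0.5, delta_value=0.8)
        site = self._site(sp, 2)
        # two mismatches: delta_all * m1 * m2 = 0.8 * 0.25
        assert scorer.site_effect(sp, site.protospacer) == pytest.approx(0.2)


class TestSiteListIO:
    def _sites(self, sp):
        return [
            ot.CandidateSite("chr1", 10, 30, "+", sp.sequence, "AGG", 0),
            ot.CandidateSite("chr1", 50, 70, "-", sp.sequence, "TGG", 2),
        ]

    def test_round_trip(self, tmp_path):
        sp = Spacer("ACGT" * 5)
        path = tmp_path / "sites.tsv"
        ot.write_site_list(path, "g1", self._sites(sp))
        loaded = ot.load_site_list(path)
        assert [s for _, s in loaded] == self._sites(sp)
        assert all(g == "g1" for g, _ in loaded)

    def test_malformed_strand(self, tmp_path):
        sp = Spacer("ACGT" * 5)
        path = tmp_path / "sites.tsv"
        ot.write_site_list(path, "g1", self._sites(sp))
        df = pd.read_csv(path, sep="\t")
        df.loc[1, "strand"] = "x"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="line 3"):
            ot.load_site_list(path)

    def test_span_mismatch(self, tmp_path):
        sp = Spacer("ACGT" * 5)
        path = tmp_path / "sites.tsv"
        ot.write_site_list(path, "g1", self._sites(sp))
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "end"] = 25
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="line 2"):
            ot.load_site_list(path)


def test_predict_single_requires_one_mismatch():
    sp = Spacer("A" * 20)
    pair = annotate_mismatches(sp, "GG" + sp.sequence[2:])
    model = _StubModel(1.0)
    with pytest.raises(MismatchCountError):
        ot.predict_single(model, IMEMatrix.from_constant(1), ot.ConstantGMT(), pair)
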