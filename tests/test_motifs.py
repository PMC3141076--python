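"""PWM scoring, exact p-value thresholds, scanning, ChoRE pairs and ZOOPS-EM
discovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from choreseq.motifs import (
    PWM,
    consensus_to_pwm,
    discover_motif_em,
    exceedance_probability,
    find_chore_pairs,
    log_odds_score,
    normalized_score,
    pvalue_threshold,
    reverse_complement,
    scan_sequences,
    score_distribution,
)

CHORE_ELEMENT = "CACGTGGCCGGCGCGTG"  # perfect E-box, 5-nt spacer, imperfect E-box


class TestConsensusToPwm:
    def test_literal_consensus(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        assert pwm.width == 6
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0)
        assert pwm.consensus() == "CACGTG"

    def test_iupac_b_column(self):
        pwm = consensus_to_pwm("CABGTG")
        np.testing.assert_allclose(pwm.matrix[:, 2], [0, 1 / 3, 1 / 3, 1 / 3])

    def test_n_uniform(self):
        pwm = consensus_to_pwm("N")
        np.testing.assert_allclose(pwm.matrix[:, 0], [0.25] * 4)

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            consensus_to_pwm("CAXGTG")


class TestNormalizedScore:
    def test_consensus_scores_one(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        assert normalized_score(pwm, "CACGTG") == 1.0

    def test_no_matching_position_scores_zero(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        # TGTACA matches CACGTG at no position
        assert normalized_score(pwm, "TGTACA") == 0.0

    def test_tied_columns_still_score_one(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5], [0, 0], [0, 0]])
        pwm = PWM(m)
        assert normalized_score(pwm, "AA") == 1.0
        assert normalized_score(pwm, "CC") == 1.0

    def test_window_with_n_skipped(self):
        pwm = consensus_to_pwm("CACGTG")
        assert normalized_score(pwm, "CACGTN") is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations(range(4)), st.text(alphabet="ACGT", min_size=5, max_size=5))
    def test_invariant_under_base_permutation(self, perm, window):
        """Permuting PWM rows together with the window's bases keeps the score."""
        rng = np.random.default_rng(5)
        m = rng.dirichlet(np.ones(4), size=5).T
        pwm = PWM(m)
        perm = list(perm)
        pwm_p = PWM(m[perm, :])
        trans = {"ACGT"[perm[i]]: "ACGT"[i] for i in range(4)}
        window_p = "".join(trans[c] for c in window)
        assert normalized_score(pwm, window) == pytest.approx(
            normalized_score(pwm_p, window_p)
        )


class TestPvalueThreshold:
    def test_consensus_only_threshold(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        t = pvalue_threshold(pwm, 1 / 4096)
        v, p = score_distribution(pwm)
        assert exceedance_probability(v, p, t) == pytest.approx(4.0 ** -6)
        # only the consensus window passes
        assert normalized_score(pwm, "CACGTG") >= t - 1e-12
        assert normalized_score(pwm, "AACGTG") < t - 1e-12

    def test_alpha_one_gives_minimum(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        v, _ = score_distribution(pwm)
        assert pvalue_threshold(pwm, 1.0) == pytest.approx(float(v.min()))

    def test_alpha_out_of_range(self):
        pwm = consensus_to_pwm("CACGTG")
        for alpha in (0.0, -1, 1.5):
            with pytest.raises(ValueError):
                pvalue_threshold(pwm, alpha)

    @pytest.mark.parametrize("width", [4, 6, 8])
    def test_dp_matches_enumeration(self, width):
        """DP-convolution threshold equals enumeration to the grid resolution."""
        rng = np.random.default_rng(width)
        for _ in range(10):
            m = rng.dirichlet(np.full(4, 0.5), size=width).T
            pwm = PWM(m)
            alpha = float(rng.uniform(0.001, 0.2))
            te = pvalue_threshold(pwm, alpha, method="enumerate")
            td = pvalue_threshold(pwm, alpha, method="dp", grid_size=20_000)
            cols = pwm.matrix / pwm.max_normalizer()
            delta = (cols.max(0).sum() - cols.min(0).sum()) / (20_000 - 1)
            assert abs(te - td) <= pwm.width * delta


class TestScan:
    def test_minus_strand_hit(self):
        pwm = consensus_to_pwm("CACGTT", pseudocount=0)  # not palindromic
        seq = "AAAA" + reverse_complement("CACGTT") + "AAAA"
        hits, counts = scan_sequences({"s": seq}, pwm, alpha=1 / 4096)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].offset == 4
        assert counts["s"] == 1

    def test_all_a_no_hits(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        hits, counts = scan_sequences({"s": "A" * 100}, pwm, alpha=1 / 4096)
        assert hits == [] and counts["s"] == 0

    def test_revcomp_mirror_property(self):
        """Scanning the reverse complement swaps strands and mirrors offsets."""
        rng = np.random.default_rng(8)
        pwm = PWM(rng.dirichlet(np.ones(4) * 0.3, size=6).T)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        fwd_hits, _ = scan_sequences({"s": seq}, pwm, alpha=0.01)
        rc_hits, _ = scan_sequences({"s": reverse_complement(seq)}, pwm, alpha=0.01)
        L, w = len(seq), 6
        mirrored = sorted(
            (L - w - h.offset, "-" if h.strand == "+" else "+", round(h.score, 9))
            for h in fwd_hits
        )
        got = sorted((h.offset, h.strand, round(h.score, 9)) for h in rc_hits)
        assert mirrored == got

    def test_background_calibration(self):
        """Hit counts on iid sequence match the binomial expectation of the
        threshold's exact exceedance probability (both strands)."""
        rng = np.random.default_rng(123)
        pwm = PWM(rng.dirichlet(np.full(4, 0.7), size=8).T)
        alpha = 0.001
        t = pvalue_threshold(pwm, alpha)
        v, p = score_distribution(pwm)
        q = exceedance_probability(v, p, t)
        seqs = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
            for i in range(100)
        }
        _, counts = scan_sequences(seqs, pwm, alpha)
        total = sum(counts.values())
        n_windows = 2 * (400 - 8 + 1) * 100
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], n_windows, q)
        assert lo <= total <= hi


class TestChorePairs:
    def test_canonical_element(self):
        ebox = consensus_to_pwm("CAYGNG")
        pairs = find_chore_pairs(CHORE_ELEMENT, ebox)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.start == 0 and p.spacer == 5 and p.orientation == "+"

    @pytest.mark.parametrize(
        "element",
        [
            "CACGTGGCCGCGCGTG",    # 4-nt spacer
            "CACGTGGCCGGGCGCGTG",  # 6-nt spacer
        ],
    )
    def test_wrong_spacing_rejected(self, element):
        ebox = consensus_to_pwm("CAYGNG")
        assert find_chore_pairs(element, ebox) == []

    def test_reverse_complement_minus_orientation(self):
        ebox = consensus_to_pwm("CAYGNG")
        pairs = find_chore_pairs(reverse_complement(CHORE_ELEMENT), ebox)
        assert len(pairs) == 1
        assert pairs[0].orientation == "-"


class TestDiscovery:
    def make_planted(self, n=50, length=100, seed=42):
        rng = np.random.default_rng(seed)
        seqs = []
        for _ in range(n):
            flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
            pos = int(rng.integers(0, length - len(CHORE_ELEMENT)))
            seqs.append(
                flank[:pos] + CHORE_ELEMENT + flank[pos + len(CHORE_ELEMENT):]
            )
        return seqs

    def test_planted_motif_recovered(self):
        seqs = self.make_planted()
        res = discover_motif_em(seqs, 17, n_starts=3, seed=1)
        cons = res.pwm.consensus()
        fwd = sum(a == b for a, b in zip(cons, CHORE_ELEMENT))
        rev = sum(
            a == b for a, b in zip(reverse_complement(cons), CHORE_ELEMENT)
        )
        assert max(fwd, rev) >= 15

    def test_loglik_monotone(self):
        seqs = self.make_planted(seed=7)
        res = discover_motif_em(seqs, 17, n_starts=2, seed=3)
        assert np.all(np.diff(res.loglik_history) >= -1e-6)

    def test_seed_determinism(self):
        seqs = self.make_planted(seed=11)
        r1 = discover_motif_em(seqs, 17, n_starts=2, seed=5)
        r2 = discover_motif_em(seqs, 17, n_starts=2, seed=5)
        np.testing.assert_array_equal(r1.pwm.matrix, r2.pwm.matrix)
        assert r1.log_likelihood == r2.log_likelihood

    def test_null_relative_entropy_lower(self):
        rng = np.random.default_rng(99)
        nulls = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
            for _ in range(50)
        ]
        planted = self.make_planted(seed=13)
        re_null = discover_motif_em(nulls, 17, n_starts=2, seed=1).relative_entropy
        re_planted = discover_motif_em(planted, 17, n_starts=2, seed=1).relative_entropy
        assert re_planted > re_null

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match="at least 5"):
            discover_motif_em(["ACGTACGTACGT"] * 3, 6)


class TestMemeRoundTrip:
    def test_write_read(self, tmp_path):
        rng = np.random.default_rng(2)
        pwm = PWM(rng.dirichlet(np.ones(4), size=9).T, np.array([0.3, 0.2, 0.2, 0.3]))
        path = tmp_path / "m.meme"
        pwm.to_meme(path, "test")
        again = PWM.from_meme(path)
        np.testing.assert_allclose(again.matrix, pwm.matrix, atol=1e-6)
        np.testing.assert_allclose(again.background, pwm.background, atol=1e-6)


class TestLogOdds:
    def test_uniform_background_consensus(self):
        pwm = consensus_to_pwm("CACGTG", pseudocount=0)
        assert log_odds_score(pwm, "CACGTG") == pytest.approx(6 * np.log2(4))
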