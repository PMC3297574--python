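"""PWM parsing, scoring, scanning and enrichment statistics, each checked
against an independent brute-force oracle wherever the operation's contract
is nontrivial."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cisclassify as cc
from cisclassify.motifs import (
    IUPAC_CODES,
    ScoreDistribution,
    composition_background,
    log_odds,
    parse_motif_library,
    reverse_complement_table,
    score_distribution,
    uniform_background,
    write_meme,
    write_transfac,
)
from cisclassify.records import SequenceRecord, reverse_complement

from .conftest import point_mass_pwm
from .oracles import (
    bh_stepup,
    brute_force_scan,
    enumerate_score_pvalue,
    hypergeom_fisher_greater,
)


def random_pwm(rng, width):
    probs = rng.dirichlet(np.ones(4) * 2, size=width)
    probs = np.maximum(probs, 1e-3)
    probs /= probs.sum(axis=1, keepdims=True)
    return cc.Pwm("rand", probs)


# ---------------------------------------------------------------------------
# Parsing


class TestMotifFiles:
    def test_meme_two_motifs(self, tmp_path, signal_pwms):
        path = tmp_path / "lib.meme"
        write_meme(signal_pwms[:2], path)
        back = parse_motif_library(path, "meme_minimal")
        assert len(back) == 2
        assert [p.width for p in back] == [p.width for p in signal_pwms[:2]]

    def test_transfac_pseudocount_arithmetic(self, tmp_path):
        path = tmp_path / "lib.transfac"
        path.write_text(
            "ID TEST_01\nP0      A      C      G      T\n"
            "01      4      0      0      0      A\n"
            "02      0      4      0      0      C\n"
            "03      0      0      4      0      G\n"
            "04      0      0      0      4      T\nXX\n//\n"
        )
        (pwm,) = parse_motif_library(path, "transfac_matrix")
        assert pwm.probs[0, 0] == pytest.approx(4.01 / 4.04)
        assert pwm.probs[0, 1] == pytest.approx(0.01 / 4.04)

    def test_meme_roundtrip_field_for_field(self, tmp_path, signal_pwms):
        p1 = tmp_path / "a.meme"
        p2 = tmp_path / "b.meme"
        write_meme(signal_pwms, p1)
        first = parse_motif_library(p1, "meme_minimal")
        write_meme(first, p2)
        second = parse_motif_library(p2, "meme_minimal")
        for a, b in zip(first, second):
            assert a.id == b.id and a.name == b.name
            assert np.allclose(a.probs, b.probs, atol=1e-8)

    def test_transfac_roundtrip(self, tmp_path, signal_pwms):
        path = tmp_path / "lib.transfac"
        write_transfac(signal_pwms, path)
        back = parse_motif_library(path, "transfac_matrix")
        for a, b in zip(signal_pwms, back):
            assert a.id == b.id
            assert np.allclose(a.probs, b.probs, atol=1e-3)

    def test_malformed_block_names_offender(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text("MEME version 4\n\nMOTIF broken\n\nMOTIF other\n")
        with pytest.raises(ValueError, match="broken"):
            parse_motif_library(path, "meme_minimal")


# ---------------------------------------------------------------------------
# Scoring


class TestLogOdds:
    def test_uniform_rows_vs_uniform_background_are_zero(self):
        pwm = cc.Pwm("u", np.full((5, 4), 0.25))
        assert np.allclose(log_odds(pwm, uniform_background()), 0.0)

    def test_pointish_row_value(self):
        pwm = cc.Pwm("p", np.array([[0.97, 0.01, 0.01, 0.01]] * 4))
        table = log_odds(pwm, uniform_background())
        assert table[0, 0] == pytest.approx(math.log2(0.97 / 0.25), abs=1e-9)

    def test_zero_background_rejected(self):
        pwm = cc.Pwm("u", np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            log_odds(pwm, np.array([0.5, 0.5, 0.0, 0.0]))

    def test_reverse_complement_table_equivalence(self):
        """Score of a word under the RC table equals the score of its
        reverse complement under the forward table (100 random cases)."""
        rng = np.random.default_rng(0)
        idx = {c: i for i, c in enumerate("ACGT")}
        for _ in range(100):
            w = int(rng.integers(4, 9))
            pwm = random_pwm(rng, w)
            table = log_odds(pwm, uniform_background())
            rc = reverse_complement_table(table)
            word = "".join(rng.choice(list("ACGT"), size=w))
            s_rc = sum(rc[j, idx[c]] for j, c in enumerate(word))
            s_fwd = sum(
                table[j, idx[c]] for j, c in enumerate(reverse_complement(word))
            )
            assert s_rc == pytest.approx(s_fwd, abs=1e-9)


class TestScorePvalue:
    def test_minimum_score_has_p_one(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 5)
        bg = uniform_background()
        dist = score_distribution(pwm, bg)
        assert cc.score_pvalue(pwm, dist.min_score, bg) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [3, 5, 8])
    def test_convolution_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = random_pwm(rng, width)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        table = log_odds(pwm, bg)
        for q in (0.1, 0.5, 0.9):
            score = float(np.quantile(table.sum(axis=0), q)) * q
            assert cc.score_pvalue(pwm, score, bg) == pytest.approx(
                enumerate_score_pvalue(table, bg, score), abs=1e-6
            )

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 6)
        bg = uniform_background()
        grid = np.linspace(-20, 12, 50)
        ps = [cc.score_pvalue(pwm, s, bg) for s in grid]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# Scanning


class TestScanSequence:
    def test_point_mass_forward_match(self):
        # p gate set so that only the exact consensus word passes (1/256)
        seq = SequenceRecord("s", "TTACGGTT")
        matches = cc.scan_sequence(
            seq, point_mass_pwm("ACGG"), p_threshold=0.004,
            background=uniform_background(),
        )
        assert [(m.offset, m.strand) for m in matches] == [(2, "+")]

    def test_point_mass_reverse_match(self):
        seq = SequenceRecord("s", "TTCCGTTT")
        matches = cc.scan_sequence(
            seq, point_mass_pwm("ACGG"), p_threshold=0.004,
            background=uniform_background(),
        )
        assert [(m.offset, m.strand) for m in matches] == [(2, "-")]

    def test_short_sequence_returns_empty(self):
        seq = SequenceRecord("s", "ACG")
        assert cc.scan_sequence(seq, point_mass_pwm("ACGTACGT")) == []

    def test_n_windows_skipped(self):
        seq = SequenceRecord("s", "TTANGGTT")
        assert cc.scan_sequence(
            seq, point_mass_pwm("ACGG"), p_threshold=0.004,
            background=uniform_background(),
        ) == []

    def test_matches_equal_brute_force(self):
        """Scanner agrees with direct per-offset evaluation for widths <= 6,
        lengths <= 30."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            w = int(rng.integers(3, 7))
            L = int(rng.integers(w, 31))
            pwm = random_pwm(rng, w)
            seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=L)))
            bg = composition_background(seq)
            dist = score_distribution(pwm, bg)
            threshold = 0.05
            cutoff = dist.score_threshold(threshold)
            got = {
                (m.offset, m.strand)
                for m in cc.scan_sequence(seq, pwm, threshold)
            }
            table = log_odds(pwm, bg)
            expected = {
                (off, strand)
                for off, strand, _ in brute_force_scan(
                    seq.residues, table, reverse_complement_table(table), cutoff
                )
            }
            assert got == expected

    def test_strand_symmetry_of_match_sets(self):
        """Scanning the reverse complement yields the mirror-image set."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            w = int(rng.integers(4, 7))
            L = int(rng.integers(15, 30))
            pwm = random_pwm(rng, w)
            seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=L)))
            bg = uniform_background()
            fwd = cc.scan_sequence(seq, pwm, 0.05, background=bg)
            rev = cc.scan_sequence(seq.reverse_complement(), pwm, 0.05, background=bg)
            mirror = {(L - w - m.offset, "+-"[m.strand == "+"]) for m in rev}
            assert {(m.offset, m.strand) for m in fwd} == mirror

    def test_forward_only_flag(self):
        seq = SequenceRecord("s", "TTCCGTTT")
        assert (
            cc.scan_sequence(
                seq, point_mass_pwm("ACGG"), 0.004, both_strands=False,
                background=uniform_background(),
            )
            == []
        )


@pytest.mark.parametrize(
    "n_matches,length,expected", [(5, 1000, 0.005), (0, 700, 0.0), (2, 500, 0.004)]
)
def test_count_per_bp(n_matches, length, expected):
    seq = SequenceRecord("s", "A" * length)
    matches = [
        cc.MotifMatch("m", "s", offset=i, strand="+") for i in range(n_matches)
    ]
    assert cc.count_per_bp(matches, seq) == pytest.approx(expected)


def test_count_per_bp_rejects_foreign_matches():
    seq = SequenceRecord("s", "ACGT")
    with pytest.raises(ValueError):
        cc.count_per_bp([cc.MotifMatch("m", "other", 0, "+")], seq)


# ---------------------------------------------------------------------------
# IUPAC consensus matching


class TestConsensusMatch:
    def test_ebox_family_pattern(self):
        matches = cc.consensus_match(SequenceRecord("s", "TTCACGTGTT"), "CAYRTG")
        assert (2, "+") in {(m.offset, m.strand) for m in matches}

    def test_no_match(self):
        assert cc.consensus_match(SequenceRecord("s", "AAAAAAA"), "CCCC") == []

    def test_invalid_letter(self):
        with pytest.raises(ValueError):
            cc.consensus_match(SequenceRecord("s", "ACGT"), "ACXG")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        pattern=st.text(alphabet=list(IUPAC_CODES), min_size=2, max_size=5),
        residues=st.text(alphabet="ACGT", min_size=5, max_size=20),
    )
    def test_equals_brute_force(self, pattern, residues):
        seq = SequenceRecord("s", residues)
        got = {(m.offset, m.strand) for m in cc.consensus_match(seq, pattern)}
        comp = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))
        rc_pat = "".join(comp[c] for c in reversed(pattern.upper()))
        expected = set()
        for off in range(len(residues) - len(pattern) + 1):
            word = residues[off : off + len(pattern)]
            for strand, pat in (("+", pattern.upper()), ("-", rc_pat)):
                if all(c in IUPAC_CODES[p] for c, p in zip(word, pat)):
                    expected.add((off, strand))
        assert got == expected


# ---------------------------------------------------------------------------
# Over-representation statistics


class TestFisher:
    def test_all_query_hit_closed_form(self):
        assert hypergeom_fisher_greater(10, 0, 0, 10) == pytest.approx(
            1 / math.comb(20, 10)
        )
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[10, 0], [0, 10]], alternative="greater")
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_identical_proportions_not_significant(self):
        # equal proportions carry no enrichment signal: p equals the full
        # upper hypergeometric tail at the observed cell, far from 0.05
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[1, 9], [1, 9]], alternative="greater")
        assert p == pytest.approx(hypergeom_fisher_greater(1, 9, 1, 9), rel=1e-9)
        assert p > 0.5

    def test_random_tables_match_enumeration(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(
                hypergeom_fisher_greater(a, b, c, d), rel=1e-9, abs=1e-12
            )

    def test_overrepresentation_pipeline(self, signal_pwms):
        query, _ = cc.make_positives(12, signal_pwms[:1], seed=61, min_copies=2, max_copies=3)
        background = [cc.sample_background(1000, 0.43, seed=62 + i) for i in range(12)]
        for i, b in enumerate(background):
            b.id = f"bg_{i}"
        results = cc.fisher_overrepresentation(query, background, signal_pwms[:1])
        (res,) = results
        assert res.count_query > res.count_background
        assert 0 < res.p_value < 0.05
        assert res.q_value >= res.p_value

    def test_depletion_is_complementary_tail(self):
        """Relabeling query/background turns enrichment into depletion: the
        one-sided p-values of the table and its row-swap overlap-sum to
        1 + P(observed)."""
        from scipy.stats import fisher_exact
        from scipy.stats import hypergeom

        a, b, c, d = 7, 3, 2, 8
        _, p_enrich = fisher_exact([[a, b], [c, d]], alternative="greater")
        _, p_swap = fisher_exact([[c, d], [a, b]], alternative="greater")
        pmf_obs = hypergeom.pmf(a, a + b + c + d, a + c, a + b)
        assert p_enrich + (1 - p_swap) == pytest.approx(pmf_obs, abs=1e-9) or (
            p_enrich + p_swap
        ) == pytest.approx(1 + pmf_obs, abs=1e-9)


class TestBhAdjust:
    def test_single_p(self):
        assert cc.bh_adjust([0.04]) == [pytest.approx(0.04)]

    def test_stepup_example(self):
        assert cc.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert cc.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        assert np.allclose(cc.bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cc.bh_adjust([0.5, 1.2])
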