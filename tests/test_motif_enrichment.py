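"""Promoter extraction, motif scanning and the resampling null."""

import math

import numpy as np
import pytest
from scipy import stats

from bsakit import (
    Locus,
    MotifModel,
    carrier_proportion,
    extract_promoters,
    random_gene_test,
    scan_motif,
    simulate_promoter_set,
)

MOTIF = MotifModel(consensus="TGACGT")


def one_hot_pwm(consensus, p_max=0.97):
    rows = []
    for c in consensus:
        row = [(1 - p_max) / 3] * 4
        row["ACGT".index(c)] = p_max
        rows.append(row)
    return np.array(rows)


class TestMotifModel:
    def test_requires_exactly_one_representation(self):
        with pytest.raises(ValueError):
            MotifModel()
        with pytest.raises(ValueError):
            MotifModel(consensus="ACGT", pwm=one_hot_pwm("ACGT"))

    def test_pwm_rows_must_sum_to_one(self):
        bad = one_hot_pwm("ACGT")
        bad[0, 0] += 0.1
        with pytest.raises(ValueError):
            MotifModel(pwm=bad)

    def test_consensus_sequence_from_pwm_is_argmax(self):
        m = MotifModel(pwm=one_hot_pwm("TGACGT"))
        assert m.consensus_sequence() == "TGACGT"

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            MotifModel(consensus="")

    def test_meme_minimal_round_trip(self, tmp_path):
        path = tmp_path / "motif.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF test\nletter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0\n"
            " 0.97 0.01 0.01 0.01\n 0.01 0.01 0.97 0.01\n"
            " 0.01 0.97 0.01 0.01\n 0.01 0.01 0.01 0.97\n"
        )
        m = MotifModel.from_meme(str(path))
        assert m.consensus_sequence() == "AGCT"


class TestExtractPromoters:
    CHROM = {"Chr1": "".join("ACGT"[i % 4] for i in range(60))}

    def test_plus_strand_window(self):
        gene = Locus("g1", "Chr1", 21, 40, "gene", "+")
        prom = extract_promoters([gene], self.CHROM, length=10)["g1"]
        assert prom == self.CHROM["Chr1"][10:20]  # positions 11..20

    def test_minus_strand_reverse_complement(self):
        gene = Locus("g1", "Chr1", 21, 40, "gene", "-")
        prom = extract_promoters([gene], self.CHROM, length=10)["g1"]
        import bsakit.motif_enrichment as me
        assert prom == me._revcomp(self.CHROM["Chr1"][40:50])

    def test_truncated_at_chromosome_start(self, caplog):
        gene = Locus("g1", "Chr1", 5, 20, "gene", "+")
        with caplog.at_level("WARNING"):
            prom = extract_promoters([gene], self.CHROM, length=10)["g1"]
        assert prom == self.CHROM["Chr1"][:4]  # only 4 bp upstream exist
        assert any("truncated" in r.message for r in caplog.records)

    def test_missing_strand_is_error(self):
        gene = Locus("g1", "Chr1", 21, 40, "gene", ".")
        with pytest.raises(ValueError, match="strand"):
            extract_promoters([gene], self.CHROM)


class TestScanMotif:
    def test_planted_forward_hit(self):
        seq = "A" * 20 + "TGACGT" + "A" * 20
        hits = scan_motif(seq, MOTIF)
        assert [(h.position, h.strand) for h in hits] == [(21, "+")]

    def test_planted_reverse_hit(self):
        rc = "ACGTCA"  # reverse complement of TGACGT
        seq = "A" * 10 + rc + "A" * 10
        hits = scan_motif(seq, MOTIF)
        assert [(h.position, h.strand) for h in hits] == [(11, "-")]

    def test_forward_only_flag(self):
        seq = "A" * 10 + "ACGTCA" + "A" * 10
        assert scan_motif(seq, MOTIF, both_strands=False) == []

    def test_n_never_matches(self):
        assert scan_motif("TGANGT", MOTIF) == []

    def test_iupac_degeneracy(self):
        m = MotifModel(consensus="TGACGY")  # Y = C or T
        assert len(scan_motif("TGACGC", m, both_strands=False)) == 1
        assert len(scan_motif("TGACGT", m, both_strands=False)) == 1
        assert len(scan_motif("TGACGA", m, both_strands=False)) == 0

    def test_overlapping_matches_found(self):
        m = MotifModel(consensus="AAA")
        hits = scan_motif("AAAAA", m, both_strands=False)
        assert [h.position for h in hits] == [1, 2, 3]

    def test_pwm_threshold_one_equals_consensus_mode(self):
        """PWM mode at threshold 1.0 hits exactly where the argmax
        consensus occurs."""
        rng = np.random.default_rng(0)
        pwm_motif = MotifModel(pwm=one_hot_pwm("TGACGT"), threshold=1.0)
        for _ in range(100):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
            expect = [(h.position, h.strand) for h in scan_motif(seq, MOTIF)]
            got = [(h.position, h.strand) for h in scan_motif(seq, pwm_motif)]
            assert got == expect

    def test_pwm_partial_threshold_accepts_near_matches(self):
        # a mismatch against a sharp column costs log2(0.01/0.97) ~ -6.6
        # bits, so near-matches need a permissive threshold
        pwm_motif = MotifModel(pwm=one_hot_pwm("TGACGT"), threshold=0.4)
        assert scan_motif("TGACGA", pwm_motif, both_strands=False)
        assert not scan_motif("TGAAAA", pwm_motif, both_strands=False)


class TestCarrierProportion:
    def test_twenty_five_of_twenty_six(self):
        """25 carriers of 26 genes is a 96% carrier proportion."""
        proms = {f"g{i}": ("A" * 30 + "TGACGT" + "A" * 30 if i < 25 else "A" * 66)
                 for i in range(26)}
        rep = carrier_proportion(list(proms), proms, MOTIF, "down_common")
        assert (rep.n_carriers, rep.n_genes) == (25, 26)
        assert rep.proportion == pytest.approx(25 / 26)
        assert f"{rep.proportion:.0%}" == "96%"

    def test_missing_promoter_named(self):
        with pytest.raises(ValueError, match="g2"):
            carrier_proportion(["g1", "g2"], {"g1": "ACGT"}, MOTIF)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            carrier_proportion([], {}, MOTIF)

    def test_all_carriers(self):
        proms = {f"g{i}": "C" * 5 + "TGACGT" + "C" * 5 for i in range(4)}
        assert carrier_proportion(list(proms), proms, MOTIF).proportion == 1.0


@pytest.fixture(scope="module")
def universe():
    motif12 = MotifModel(consensus="TGACGTCATGCA")
    seqs, truth = simulate_promoter_set(
        n_background=2000, n_target=0, motif=motif12,
        background_rate=0.1246, target_rate=0.0, seed=13)
    return motif12, seqs, truth


class TestRandomGeneTest:
    def test_null_mean_matches_background_rate(self, universe):
        """Mean of resampled carrier proportions converges to the
        genome-wide carrier rate."""
        motif12, seqs, truth = universe
        proms = {f"g{i}": "A" * 40 for i in range(26)}  # 0 carriers observed
        obs = carrier_proportion(list(proms), proms, motif12)
        res = random_gene_test(obs, seqs, motif12, n_draws=4000, seed=0)
        realized = truth["carrier"].mean()
        se = res.null_sd / math.sqrt(res.n_draws)
        assert abs(res.null_mean - realized) <= 4 * se

    def test_strong_enrichment_hits_floor(self, universe):
        motif12, seqs, _ = universe
        proms = {f"g{i}": ("A" * 20 + "TGACGTCATGCA" + "A" * 20 if i < 25
                           else "A" * 52) for i in range(26)}
        obs = carrier_proportion(list(proms), proms, motif12)
        res = random_gene_test(obs, seqs, motif12, n_draws=2000, seed=1)
        assert res.p == pytest.approx(1 / 2001)
        # independent binomial-tail oracle confirms the truth is far below
        # anything the empirical floor could resolve
        oracle = stats.binom.sf(24, 26, 0.1246)
        assert oracle < 1e-18

    def test_zero_carriers_gives_p_near_one(self, universe):
        motif12, seqs, _ = universe
        proms = {f"g{i}": "A" * 40 for i in range(26)}
        obs = carrier_proportion(list(proms), proms, motif12)
        res = random_gene_test(obs, seqs, motif12, n_draws=500, seed=2)
        assert res.p == pytest.approx(1.0)

    def test_monotone_in_observed_count(self, universe):
        """Empirical p is non-increasing in the observed carrier count."""
        motif12, seqs, _ = universe
        last = 1.1
        for k in (0, 3, 6, 13, 26):
            proms = {f"g{i}": ("G" * 10 + "TGACGTCATGCA" + "G" * 10 if i < k
                               else "G" * 32) for i in range(26)}
            obs = carrier_proportion(list(proms), proms, motif12)
            res = random_gene_test(obs, seqs, motif12, n_draws=1000, seed=3)
            assert res.p <= last + 1e-12
            last = res.p

    def test_deterministic_for_seed(self, universe):
        motif12, seqs, _ = universe
        proms = {f"g{i}": "A" * 40 for i in range(10)}
        obs = carrier_proportion(list(proms), proms, motif12)
        a = random_gene_test(obs, seqs, motif12, n_draws=200, seed=5)
        b = random_gene_test(obs, seqs, motif12, n_draws=200, seed=5)
        assert a == b

    def test_bad_draws(self, universe):
        motif12, seqs, _ = universe
        proms = {"g": "A" * 40}
        obs = carrier_proportion(["g"], proms, motif12)
        with pytest.raises(ValueError):
            random_gene_test(obs, seqs, motif12, n_draws=0)
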