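"""Arm conservation, conservation/expression concordance and copy counting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from mirfate.catalog import HairpinLocus
from mirfate.fates import (
    arm_conservation,
    consensus_hairpin,
    conserved_vs_dominant,
    count_genomic_loci,
    infer_rounds_from_copies,
    merge_hits,
    supported_rounds,
)
from mirfate.preference import OapRecord
from mirfate.simulate import random_seq, revcomp


LOOP = "TTTTTGGGGGTTTTT"


def _locus(lid, arm5, arm3, family="fam", species="A"):
    seq = arm5 + LOOP + arm3
    return HairpinLocus(
        lid, species, "chr1", 1, len(seq), "+", seq,
        (0, len(arm5)), (len(arm5) + len(LOOP), len(seq)), family,
    )


ARM_A = "ACGTACGTACGTACGTACGTAC"
ARM_A_4MM = "TCGTACGTTCGTACGTTCGTAT"  # 4 substitutions vs ARM_A
ARM_B = "CATGCATGCATGCATGCATGCA"


class TestArmConservation:
    def test_identical_3p_divergent_5p(self):
        # identical 3p arms score 1.0; 5p arms differing at 4 of 22
        # positions score 18/22
        p1 = _locus("p1", ARM_A, ARM_B)
        p2 = _locus("p2", ARM_A_4MM, ARM_B)
        res = arm_conservation([p1, p2], "fam", "A")
        assert res.score_3p == pytest.approx(1.0)
        assert res.score_5p == pytest.approx(18 / 22)
        assert res.conserved_arm == "3p"
        assert res.n_paralogues == 2

    def test_tie_when_scores_equal(self):
        p1 = _locus("p1", ARM_A, ARM_B)
        p2 = _locus("p2", ARM_A, ARM_B)
        res = arm_conservation([p1, p2])
        assert res.score_5p == res.score_3p == pytest.approx(1.0)
        assert res.conserved_arm == "tie"

    def test_order_invariance(self):
        rng = np.random.default_rng(21)
        loci = [
            _locus(
                f"p{i}",
                "".join(rng.choice(list("ACGT"), size=22)),
                "".join(rng.choice(list("ACGT"), size=22)),
            )
            for i in range(4)
        ]
        fwd = arm_conservation(loci)
        rev = arm_conservation(loci[::-1])
        assert fwd.score_5p == pytest.approx(rev.score_5p)
        assert fwd.score_3p == pytest.approx(rev.score_3p)
        assert fwd.conserved_arm == rev.conserved_arm

    def test_single_paralogue_returns_none(self):
        assert arm_conservation([_locus("p1", ARM_A, ARM_B)]) is None

    def test_missing_arm_paralogues_excluded(self):
        seq = ARM_A + LOOP + ARM_B
        one_arm = HairpinLocus(
            "p3", "A", "chr1", 1, len(seq), "+", seq, (0, 22), None, "fam"
        )
        res = arm_conservation(
            [_locus("p1", ARM_A, ARM_B), _locus("p2", ARM_A, ARM_B), one_arm]
        )
        assert res.n_paralogues == 2


def _cons(family, arm, species="A"):
    from mirfate.fates import ArmConservationResult

    s5, s3 = (0.99, 0.8) if arm == "5p" else (0.8, 0.99)
    if arm == "tie":
        s5 = s3 = 0.9
    return ArmConservationResult(family, species, 3, s5, s3, arm)


def _oap(arm, locus="l1"):
    return OapRecord(locus, arm, 1.0 if arm in ("5p", "3p") else 0.0, 5)


class TestConcordance:
    def test_perfect_concordance_binomial_oracle(self):
        cons = [_cons(f"fam{i}", "5p") for i in range(10)]
        oaps = {f"fam{i}": {"A": {"l1": _oap("5p")}} for i in range(10)}
        summary = conserved_vs_dominant(cons, oaps)
        assert summary.n_assessed == 10
        assert summary.n_concordant == 10
        assert summary.fraction == pytest.approx(1.0)
        # exact two-sided binomial: P = 2 * 0.5^10
        assert summary.p_value == pytest.approx(2 * 0.5**10)
        assert summary.p_value == pytest.approx(binomtest(10, 10, 0.5).pvalue)

    def test_discordant_family_counted_but_not_concordant(self):
        cons = [_cons("famX", "5p")]
        oaps = {"famX": {"A": {"l1": _oap("3p")}}}
        summary = conserved_vs_dominant(cons, oaps)
        assert summary.n_assessed == 1 and summary.n_concordant == 0

    def test_elimination_rules(self):
        cons = [
            _cons("switchy", "5p"),
            _cons("tied", "tie"),
            _cons("split_cons", "5p", species="A"),
            _cons("split_cons", "3p", species="B"),
            _cons("silent", "5p"),
            _cons("keep", "3p"),
        ]
        oaps = {
            # defined but opposite OAPs across species: eliminated
            "switchy": {"A": {"l1": _oap("5p")}, "B": {"l1": _oap("3p")}},
            "tied": {"A": {"l1": _oap("5p")}},
            "split_cons": {"A": {"l1": _oap("5p")}, "B": {"l1": _oap("5p")}},
            # only undefined OAPs: eliminated
            "silent": {"A": {"l1": _oap("undefined")}},
            "keep": {"A": {"l1": _oap("3p"), "l2": _oap("3p")}},
        }
        summary = conserved_vs_dominant(cons, oaps)
        assert summary.assessed_families == ["keep"]
        assert summary.n_concordant == 1

    def test_paralogue_disagreement_eliminated(self):
        cons = [_cons("fam", "5p")]
        oaps = {"fam": {"A": {"l1": _oap("5p"), "l2": _oap("3p")}}}
        assert conserved_vs_dominant(cons, oaps).n_assessed == 0

    def test_empty_input(self):
        summary = conserved_vs_dominant([], {})
        assert summary.n_assessed == 0
        assert summary.p_value is None
        assert math.isnan(summary.fraction)


class TestGenomeSearch:
    HAIRPIN = ARM_A + LOOP + ARM_B  # 59 nt

    def _genome_with_copies(self, n, seed=5, spacing=400, mutate_idx=None,
                            n_mut=0, revcomp_idx=()):
        rng = np.random.default_rng(seed)
        background = random_seq(spacing * (n + 1), rng)
        chars = list(background)
        copies = []
        for i in range(n):
            hp = self.HAIRPIN
            if mutate_idx is not None and i == mutate_idx:
                pos = rng.choice(len(hp), size=n_mut, replace=False)
                hp = list(hp)
                for p in pos:
                    hp[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hp[p]]
                hp = "".join(hp)
            if i in revcomp_idx:
                hp = revcomp(hp)
            start = spacing * i + 50
            chars[start : start + len(hp)] = list(hp)
            copies.append(start)
        return {"chr1": "".join(chars)}

    def test_eight_exact_copies_found(self):
        genome = self._genome_with_copies(8)
        assert count_genomic_loci(self.HAIRPIN, genome) == 8

    def test_reverse_strand_copy_found(self):
        genome = self._genome_with_copies(2, revcomp_idx=(1,))
        assert count_genomic_loci(self.HAIRPIN, genome) == 2

    def test_heavily_mutated_copy_rejected(self):
        # one of three copies carries 25 substitutions in 59 nt
        # (identity < 0.6), well below the 0.8 acceptance threshold
        genome = self._genome_with_copies(3, mutate_idx=2, n_mut=25)
        assert count_genomic_loci(self.HAIRPIN, genome) == 2

    def test_lightly_mutated_copy_accepted(self):
        # 5 substitutions in 59 nt keeps identity ~0.915 >= 0.8
        genome = self._genome_with_copies(3, mutate_idx=2, n_mut=5)
        assert count_genomic_loci(self.HAIRPIN, genome) == 3

    def test_no_copies_in_random_background(self):
        rng = np.random.default_rng(17)
        genome = {"chr1": random_seq(3000, rng)}
        assert count_genomic_loci(self.HAIRPIN, genome) == 0


class TestMergeHits:
    def test_minor_overlap_stays_separate(self):
        # overlap 30 nt, shorter hit 80 nt: 30 <= 40, two loci
        hits = [("c", 100, 180, "+", 1.0), ("c", 150, 230, "+", 1.0)]
        assert len(merge_hits(hits)) == 2

    def test_major_overlap_merges(self):
        # overlap 60 nt of an 80 nt hit: merged into one locus
        hits = [("c", 100, 180, "+", 1.0), ("c", 120, 200, "+", 1.0)]
        merged = merge_hits(hits)
        assert len(merged) == 1
        assert merged[0][1] == 100 and merged[0][2] == 200

    def test_different_chromosomes_never_merge(self):
        hits = [("c1", 0, 80, "+", 1.0), ("c2", 0, 80, "+", 1.0)]
        assert len(merge_hits(hits)) == 2


class TestConsensus:
    def test_majority_vote(self):
        seqs = ["AAAA", "AAAA", "ACAA"]
        loci = [_locus_like(s, i) for i, s in enumerate(seqs)]
        assert consensus_hairpin(loci) == "AAAA"

    def test_unequal_lengths_fall_back_to_first(self):
        loci = [_locus_like("AAAAA", 0), _locus_like("AAAA", 1)]
        assert consensus_hairpin(loci) == "AAAAA"


def _locus_like(seq, i):
    return HairpinLocus(f"x{i}", "A", "chr1", 1, len(seq), "+", seq, None, None, "f")


class TestRoundsFromCopies:
    @pytest.mark.parametrize(
        "n,r", [(0, 0), (1, 0), (2, 1), (3, 2), (4, 2), (5, 3), (8, 3), (9, 4)]
    )
    def test_supported_rounds(self, n, r):
        assert supported_rounds(n) == r

    def test_genome_estimate_from_copy_table(self):
        df = pd.DataFrame(
            {
                "family_id": [f"f{i}" for i in range(8)],
                "species_id": ["A"] * 8,
                "n_loci": [8, 8, 8, 5, 2, 1, 1, 1],
            }
        )
        # fractions with n_loci > 2^(r-1): r=1: 5/8, r=2: 4/8, r=3: 3/8,
        # r=4: 0 -> estimate 3
        out = infer_rounds_from_copies(df, family_fraction=0.25)
        assert out["per_species"]["A"]["estimate"] == 3
        assert out["per_species"]["A"]["families_gt4_copies"] == 4
        assert out["estimate"] == 3

    def test_conserved_family_filter(self):
        df = pd.DataFrame(
            {
                "family_id": ["f0", "f1", "f2", "f3"],
                "species_id": ["A"] * 4,
                "n_loci": [8, 1, 1, 1],
            }
        )
        # unrestricted: 1/4 = 0.25 of families exceed each threshold -> 3
        assert infer_rounds_from_copies(df)["estimate"] == 3
        # restricted to single-copy families -> no duplication signal
        out = infer_rounds_from_copies(df, conserved_families=["f1", "f2", "f3"])
        assert out["estimate"] == 0

    def test_empty_table(self):
        df = pd.DataFrame(columns=["family_id", "species_id", "n_loci"])
        assert infer_rounds_from_copies(df)["estimate"] == 0
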