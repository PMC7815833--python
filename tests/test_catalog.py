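"""Catalog loading, validation, strand handling and family bookkeeping."""

import pytest

from mirfate.catalog import (
    CatalogError,
    HairpinLocus,
    copies_per_family,
    classify_conservation,
    load_catalog,
    write_catalog,
)
from mirfate.simulate import SimConfig, revcomp, simulate_genome


def _chrom(n=200, motif="ACGT"):
    return (motif * (n // len(motif) + 1))[:n]


class TestLoadCatalog:
    def test_consistent_toy_annotation(self, toy_files):
        seq = _chrom(200)
        fasta, gff, fam = toy_files(
            seq,
            [
                {
                    "locus_id": "hp1",
                    "start": 21,
                    "end": 100,
                    "strand": "+",
                    "arms": [(31, 52), (71, 92)],
                }
            ],
        )
        catalog = load_catalog(fasta, gff, fam, species_id="A")
        locus = catalog.loci["hp1"]
        assert len(locus.hairpin_seq) == 80
        assert locus.hairpin_seq == seq[20:100]
        assert locus.arm5p == (10, 32) and locus.arm3p == (50, 72)
        assert locus.arm5p[1] - locus.arm5p[0] == 22
        assert locus.arm3p[1] - locus.arm3p[0] == 22
        assert locus.family_id == "hp1_fam"

    def test_out_of_bounds_arm_is_fatal(self, toy_files):
        fasta, gff, fam = toy_files(
            _chrom(200),
            [
                {
                    "locus_id": "hp1",
                    "start": 21,
                    "end": 100,
                    "strand": "+",
                    # arm runs past the hairpin end (genomic 91..115 > 100)
                    "arms": [(31, 52), (91, 115)],
                }
            ],
        )
        with pytest.raises(CatalogError, match="hp1"):
            load_catalog(fasta, gff, fam)

    def test_coordinates_outside_sequence_fatal(self, toy_files):
        fasta, gff, fam = toy_files(
            _chrom(90),
            [
                {
                    "locus_id": "hp1",
                    "start": 41,
                    "end": 120,
                    "strand": "+",
                    "arms": [(45, 60)],
                }
            ],
        )
        with pytest.raises(CatalogError, match="hp1"):
            load_catalog(fasta, gff, fam)

    def test_minus_strand_reverse_complement(self, toy_files):
        # 20 nt toy hairpin on the minus strand: hairpin_seq must be the
        # reverse complement of genome[100:180] restricted here to a 20 nt
        # locus, and arms re-expressed in hairpin coordinates.
        seq = _chrom(200)
        fasta, gff, fam = toy_files(
            seq,
            [
                {
                    "locus_id": "hpm",
                    "start": 101,
                    "end": 120,
                    "strand": "-",
                    # genomic arm intervals: 101-106 and 113-120
                    "arms": [(101, 106), (113, 120)],
                }
            ],
        )
        catalog = load_catalog(fasta, gff, fam)
        locus = catalog.loci["hpm"]
        expected = revcomp(seq[100:120])
        assert locus.hairpin_seq == expected
        # genomic 113-120 is nearest the hairpin 5' end on the minus strand
        assert locus.arm5p == (0, 8)
        assert locus.arm3p == (14, 20)
        assert locus.arm_seq("5p") == expected[0:8]

    def test_duplicate_locus_id_fatal(self, toy_files):
        feats = [
            {"locus_id": "hp1", "start": 1, "end": 40, "strand": "+", "arms": [(1, 18)]},
            {"locus_id": "hp1", "start": 61, "end": 100, "strand": "+", "arms": [(61, 78)]},
        ]
        fasta, gff, fam = toy_files(_chrom(120), feats)
        with pytest.raises(Exception):
            load_catalog(fasta, gff, fam)


class TestHairpinLocusInvariants:
    def test_span_must_match_sequence_length(self):
        with pytest.raises(CatalogError):
            HairpinLocus("x", "A", "chr1", 1, 50, "+", "ACGT" * 10, (0, 10), (20, 30), "f")

    def test_arms_must_be_ordered_and_disjoint(self):
        with pytest.raises(CatalogError):
            HairpinLocus("x", "A", "chr1", 1, 40, "+", "ACGT" * 10, (15, 30), (5, 14), "f")


class TestRoundTripAndStrand:
    def test_write_load_fixpoint(self, small_sim, tmp_path):
        cat1 = small_sim.catalog
        p = tmp_path
        write_catalog(cat1, p / "h.fa", p / "h.gff3", p / "fam.tsv")
        cat2 = load_catalog(p / "h.fa", p / "h.gff3", p / "fam.tsv", species_id="A")
        assert set(cat2.loci) == set(cat1.loci)
        for lid, l1 in cat1.loci.items():
            l2 = cat2.loci[lid]
            assert l2.hairpin_seq == l1.hairpin_seq
            assert l2.arm5p == l1.arm5p and l2.arm3p == l1.arm3p
            assert l2.strand == l1.strand
            assert l2.family_id == l1.family_id
        # second write is byte-identical: a true fixpoint
        write_catalog(cat2, p / "h2.fa", p / "h2.gff3", p / "fam2.tsv")
        assert (p / "h.fa").read_bytes() == (p / "h2.fa").read_bytes()
        assert (p / "h.gff3").read_bytes() == (p / "h2.gff3").read_bytes()

    def test_reverse_complemented_genome_gives_same_hairpins(self, toy_files, tmp_path):
        # flipping the chromosome and all strands leaves the strand-resolved
        # hairpin sequence and arm intervals unchanged
        seq = "ACCGTTAGCATGCCGATTACGGATCCGATTGCACCAGTTGACA" + _chrom(60)
        n = len(seq)
        feats = [
            {"locus_id": "hp", "start": 5, "end": 34, "strand": "+",
             "arms": [(5, 14), (25, 34)]}
        ]
        fasta, gff, fam = toy_files(seq, feats)
        cat_fwd = load_catalog(fasta, gff, fam)

        flipped = tmp_path / "flipped"
        flipped.mkdir()
        (flipped / "genome.fa").write_text(f">chr1\n{revcomp(seq)}\n")
        gs, ge = n - 34 + 1, n - 5 + 1
        a1s, a1e = n - 14 + 1, n - 5 + 1
        a2s, a2e = n - 34 + 1, n - 25 + 1
        (flipped / "mirna.gff3").write_text(
            "##gff-version 3\n"
            f"chr1\ttoy\tmiRNA_primary_transcript\t{gs}\t{ge}\t.\t-\t.\tID=hp\n"
            f"chr1\ttoy\tmiRNA\t{a1s}\t{a1e}\t.\t-\t.\tID=hp-a;Derives_from=hp\n"
            f"chr1\ttoy\tmiRNA\t{a2s}\t{a2e}\t.\t-\t.\tID=hp-b;Derives_from=hp\n"
        )
        cat_rev = load_catalog(flipped / "genome.fa", flipped / "mirna.gff3", None)
        assert cat_rev.loci["hp"].hairpin_seq == cat_fwd.loci["hp"].hairpin_seq
        assert cat_rev.loci["hp"].arm5p == cat_fwd.loci["hp"].arm5p
        assert cat_rev.loci["hp"].arm3p == cat_fwd.loci["hp"].arm3p


class TestConservationClassAndCopies:
    def _two_species_catalog(self, shared=True):
        from mirfate.catalog import MirnaCatalog

        cat = MirnaCatalog()
        hp = "ACGT" * 15
        for sp in ("A", "B") if shared else ("A",):
            cat.add_locus(
                HairpinLocus(
                    f"{sp}_bantam_1", sp, "chr1", 1, 60, "+", hp, (0, 22), (38, 60),
                    "bantam",
                )
            )
        cat.add_locus(
            HairpinLocus("A_novel_1", "A", "chr2", 1, 60, "+", hp, (0, 22), (38, 60),
                         "novelfam")
        )
        return cat

    def test_reference_listed_family_gets_reference_class(self, tmp_path):
        cat = self._two_species_catalog()
        ref = tmp_path / "ref.tsv"
        ref.write_text("bantam\tbilaterian_conserved\n")
        classify_conservation(cat, ref)
        assert cat.loci["A_bantam_1"].conservation_class == "bilaterian_conserved"

    def test_single_species_unlisted_family_is_unknown(self, tmp_path):
        cat = self._two_species_catalog()
        ref = tmp_path / "ref.tsv"
        ref.write_text("bantam\tbilaterian_conserved\n")
        classify_conservation(cat, ref)
        assert cat.loci["A_novel_1"].conservation_class == "unknown"

    def test_shared_unlisted_family_is_lineage_novel(self, tmp_path):
        cat = self._two_species_catalog()
        ref = tmp_path / "ref.tsv"
        ref.write_text("othermir\tbilaterian_conserved\n")
        classify_conservation(cat, ref)
        # bantam present in both species but absent from the reference
        assert cat.loci["B_bantam_1"].conservation_class == "lineage_novel"

    def test_copies_per_family_counts(self):
        cat = self._two_species_catalog()
        df = copies_per_family(cat)
        assert df.loc["bantam", "A"] == 1
        assert df.loc["bantam", "B"] == 1
        assert df.loc["novelfam", "B"] == 0

    def test_full_retention_three_rounds_gives_eight_copies(self):
        cfg = SimConfig(
            seed=3, n_chromosomes=1, genes_per_chromosome=4, n_mirna_families=3,
            rounds=3, retention_prob=1.0, species_split=False,
            n_samples_per_species=2, gene_len=60,
        )
        sim = simulate_genome(cfg)
        df = copies_per_family(sim.catalog)
        assert (df["A"] == 8).all()
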