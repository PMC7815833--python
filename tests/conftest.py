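"""Shared fixtures: tiny hand-written annotation sets and small simulations."""

from __future__ import annotations

from pathlib import Path

import pytest

from mirfate.simulate import SimConfig, simulate_genome


def write_toy_annotation(
    tmpdir: Path,
    chrom_seq: str,
    features: list[dict],
    family_rows: list[tuple[str, str, str]] | None = None,
):
    """Write a single-chromosome FASTA + miRBase-style GFF3 + family TSV.

    Each feature dict: locus_id, start, end (1-based inclusive), strand,
    arms = list of (gstart, gend) genomic arm intervals.
    """
    fasta = tmpdir / "genome.fa"
    fasta.write_text(f">chr1\n{chrom_seq}\n")
    gff = tmpdir / "mirna.gff3"
    lines = ["##gff-version 3"]
    for ft in features:
        lines.append(
            f"chr1\ttoy\tmiRNA_primary_transcript\t{ft['start']}\t{ft['end']}\t.\t"
            f"{ft['strand']}\t.\tID={ft['locus_id']}"
        )
        for i, (gs, ge) in enumerate(ft["arms"]):
            lines.append(
                f"chr1\ttoy\tmiRNA\t{gs}\t{ge}\t.\t{ft['strand']}\t.\t"
                f"ID={ft['locus_id']}-arm{i};Derives_from={ft['locus_id']}"
            )
    gff.write_text("\n".join(lines) + "\n")
    fam = tmpdir / "families.tsv"
    rows = family_rows or [
        (ft["locus_id"] + "_fam", ft["locus_id"], "unknown") for ft in features
    ]
    fam.write_text(
        "#family_id\tlocus_id\tclass\n"
        + "\n".join("\t".join(r) for r in rows)
        + "\n"
    )
    return fasta, gff, fam


@pytest.fixture
def toy_files(tmp_path):
    return lambda *a, **k: write_toy_annotation(tmp_path, *a, **k)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic two-species 2R simulation shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_chromosomes=1,
        genes_per_chromosome=40,
        n_mirna_families=8,
        rounds=2,
        retention_prob=0.8,
        species_split=True,
        switch_fraction=0.25,
        n_samples_per_species=3,
        reads_per_locus_mean=60,
        gene_len=80,
    )
    return simulate_genome(cfg)
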