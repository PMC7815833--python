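"""Catalog of miRNA hairpin loci, mature-arm annotations and families.

Coordinate conventions: GFF3 is 1-based inclusive on disk; every in-memory
interval is 0-based half-open.  Hairpin sequences are stored strand-resolved
(5'->3'), so minus-strand loci hold the reverse complement of the genomic
segment and their arm intervals are expressed in hairpin coordinates.

Arm polarity (5p vs 3p) is assigned purely by position within the hairpin:
the arm nearer the hairpin 5' end is the 5p arm.  Annotation names are never
trusted for polarity, which keeps simulated and real annotations consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

CONSERVATION_CLASSES = (
    "bilaterian_conserved",
    "chelicerate_specific",
    "lineage_novel",
    "unknown",
)


class CatalogError(ValueError):
    """Fatal catalog validation error (bad coordinates, duplicate IDs...)."""


@dataclass
class HairpinLocus:
    """A genomic miRNA hairpin with annotated mature-arm intervals.

    ``start``/``end`` are 1-based inclusive genomic coordinates; ``arm5p``
    and ``arm3p`` are 0-based half-open intervals in hairpin coordinates.
    A locus with only one annotated arm keeps ``None`` for the missing arm
    and is excluded from arm-usage statistics downstream.
    """

    locus_id: str
    species_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    hairpin_seq: str
    arm5p: tuple[int, int] | None
    arm3p: tuple[int, int] | None
    family_id: str
    conservation_class: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.hairpin_seq)
        if self.strand not in "+-":
            raise CatalogError(f"{self.locus_id}: bad strand {self.strand!r}")
        if self.end - self.start + 1 != n:
            raise CatalogError(
                f"{self.locus_id}: span {self.start}-{self.end} does not match "
                f"hairpin length {n}"
            )
        for name, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if arm is None:
                continue
            s, e = arm
            if not (0 <= s < e <= n):
                raise CatalogError(
                    f"{self.locus_id}: {name} interval {arm} outside hairpin "
                    f"of length {n}"
                )
        if self.arm5p is not None and self.arm3p is not None:
            if not self.arm5p[1] <= self.arm3p[0]:
                raise CatalogError(
                    f"{self.locus_id}: arms {self.arm5p} and {self.arm3p} "
                    "overlap or are misordered (5p must precede 3p)"
                )

    @property
    def has_both_arms(self) -> bool:
        return self.arm5p is not None and self.arm3p is not None

    def arm_seq(self, arm: str) -> str | None:
        iv = self.arm5p if arm == "5p" else self.arm3p
        if iv is None:
            return None
        return self.hairpin_seq[iv[0] : iv[1]]


@dataclass
class MirnaFamily:
    family_id: str
    members: dict[str, list[str]] = field(default_factory=dict)  # species -> locus ids
    is_ancestral_single_copy: bool = True

    def loci(self) -> list[str]:
        return [lid for ids in self.members.values() for lid in ids]


@dataclass
class SampleMeta:
    sample_id: str
    species_id: str
    tissue_or_stage: str


@dataclass
class MirnaCatalog:
    """Validated collection of hairpin loci grouped into families."""

    loci: dict[str, HairpinLocus] = field(default_factory=dict)
    families: dict[str, MirnaFamily] = field(default_factory=dict)

    def add_locus(self, locus: HairpinLocus) -> None:
        if locus.locus_id in self.loci:
            raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
        self.loci[locus.locus_id] = locus
        fam = self.families.setdefault(locus.family_id, MirnaFamily(locus.family_id))
        fam.members.setdefault(locus.species_id, []).append(locus.locus_id)

    def merge(self, other: "MirnaCatalog") -> "MirnaCatalog":
        merged = MirnaCatalog()
        for cat in (self, other):
            for locus in cat.loci.values():
                merged.add_locus(replace(locus))
        return merged

    @property
    def species(self) -> list[str]:
        return sorted({l.species_id for l in self.loci.values()})

    def subset_species(self, species_id: str) -> "MirnaCatalog":
        sub = MirnaCatalog()
        for locus in self.loci.values():
            if locus.species_id == species_id:
                sub.add_locus(replace(locus))
        return sub

    def family_loci(self, family_id: str, species_id: str | None = None):
        fam = self.families[family_id]
        ids = (
            fam.members.get(species_id, [])
            if species_id is not None
            else fam.loci()
        )
        return [self.loci[i] for i in ids]


def _to_hairpin_interval(locus_start: int, locus_end: int, strand: str,
                         feat_start: int, feat_end: int) -> tuple[int, int]:
    """Map a 1-based inclusive genomic sub-interval into 0-based half-open
    hairpin coordinates, honouring the strand."""
    if strand == "+":
        return feat_start - locus_start, feat_end - locus_start + 1
    return locus_end - feat_end, locus_end - feat_start + 1


def load_catalog(
    fasta: str | Path,
    gff: str | Path,
    family_table: str | Path | None = None,
    species_id: str = "unknown",
) -> MirnaCatalog:
    """Read hairpin loci and arm annotations into a validated catalog.

    ``fasta`` holds the sequences the GFF3 seqids refer to (chromosomes or
    per-locus records).  ``gff`` follows the miRBase dialect: features of
    type ``miRNA_primary_transcript`` are hairpins; ``miRNA`` features carry
    ``Derives_from=<hairpin ID>`` and are the mature arms.  ``family_table``
    is a TSV with columns family_id, locus_id and optionally class; without
    it every locus founds a singleton family named after itself.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    db = gffutils.create_db(
        str(gff),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )

    family_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    if family_table is not None:
        for line in Path(family_table).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            fam, lid = parts[0], parts[1]
            family_of[lid] = fam
            if len(parts) > 2 and parts[2]:
                class_of[fam] = parts[2]

    arms_by_parent: dict[str, list] = {}
    for feat in db.features_of_type("miRNA"):
        parent = feat.attributes.get("Derives_from", [None])[0]
        if parent is None:
            raise CatalogError(
                f"miRNA feature {feat.id!r} lacks a Derives_from attribute"
            )
        arms_by_parent.setdefault(parent, []).append(feat)

    catalog = MirnaCatalog()
    for hp in db.features_of_type("miRNA_primary_transcript"):
        locus_id = hp.id
        if hp.seqid not in seqs:
            raise CatalogError(
                f"{locus_id}: seqid {hp.seqid!r} not present in FASTA"
            )
        chrom = seqs[hp.seqid]
        if not (1 <= hp.start <= hp.end <= len(chrom)):
            raise CatalogError(
                f"{locus_id}: coordinates {hp.start}-{hp.end} outside "
                f"sequence {hp.seqid} of length {len(chrom)}"
            )
        segment = chrom[hp.start - 1 : hp.end]
        strand = hp.strand if hp.strand in "+-" else "+"
        hairpin_seq = (
            segment if strand == "+" else str(Seq(segment).reverse_complement())
        )

        arm_ivs: list[tuple[int, int]] = []
        for feat in arms_by_parent.get(locus_id, []):
            if not (hp.start <= feat.start <= feat.end <= hp.end):
                raise CatalogError(
                    f"arm feature {feat.id!r} at {feat.start}-{feat.end} "
                    f"outside hairpin {locus_id} ({hp.start}-{hp.end})"
                )
            arm_ivs.append(
                _to_hairpin_interval(hp.start, hp.end, strand, feat.start, feat.end)
            )
        if not arm_ivs:
            raise CatalogError(f"{locus_id}: hairpin has no annotated arm")
        arm_ivs.sort()
        arm5p: tuple[int, int] | None
        arm3p: tuple[int, int] | None
        if len(arm_ivs) >= 2:
            # positional polarity: first arm along the hairpin is 5p
            arm5p, arm3p = arm_ivs[0], arm_ivs[-1]
        else:
            (iv,) = arm_ivs
            mid = (iv[0] + iv[1]) / 2
            if mid < len(hairpin_seq) / 2:
                arm5p, arm3p = iv, None
            else:
                arm5p, arm3p = None, iv

        fam = family_of.get(locus_id, locus_id)
        catalog.add_locus(
            HairpinLocus(
                locus_id=locus_id,
                species_id=species_id,
                seq_id=hp.seqid,
                start=hp.start,
                end=hp.end,
                strand=strand,
                hairpin_seq=hairpin_seq,
                arm5p=arm5p,
                arm3p=arm3p,
                family_id=fam,
                conservation_class=class_of.get(fam, "unknown"),
            )
        )
    return catalog


def write_catalog(catalog: MirnaCatalog, fasta: str | Path, gff: str | Path,
                  family_table: str | Path) -> None:
    """Write the catalog back to FASTA + GFF3 + family TSV.

    Each locus is emitted against its own source record (named
    ``<locus_id>_src`` holding the forward-strand genomic segment), so a
    reload reproduces hairpin sequence, arm intervals, strand and family
    exactly; the original chromosome-level coordinates are not recoverable
    from a per-locus FASTA and are re-based to the segment.
    """
    fasta, gff, family_table = Path(fasta), Path(gff), Path(family_table)
    loci = sorted(catalog.loci.values(), key=lambda l: l.locus_id)
    with fasta.open("w") as fh:
        for locus in loci:
            seg = (
                locus.hairpin_seq
                if locus.strand == "+"
                else str(Seq(locus.hairpin_seq).reverse_complement())
            )
            fh.write(f">{locus.locus_id}_src\n{seg}\n")
    with gff.open("w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            n = len(locus.hairpin_seq)
            fh.write(
                f"{locus.locus_id}_src\tmirfate\tmiRNA_primary_transcript\t1\t{n}\t.\t"
                f"{locus.strand}\t.\tID={locus.locus_id};Name={locus.locus_id}\n"
            )
            for tag, iv in (("5p", locus.arm5p), ("3p", locus.arm3p)):
                if iv is None:
                    continue
                if locus.strand == "+":
                    g_start, g_end = iv[0] + 1, iv[1]
                else:
                    g_start, g_end = n - iv[1] + 1, n - iv[0]
                fh.write(
                    f"{locus.locus_id}_src\tmirfate\tmiRNA\t{g_start}\t{g_end}\t.\t"
                    f"{locus.strand}\t.\tID={locus.locus_id}-{tag};"
                    f"Derives_from={locus.locus_id}\n"
                )
    with family_table.open("w") as fh:
        fh.write("#family_id\tlocus_id\tclass\n")
        for locus in loci:
            fh.write(
                f"{locus.family_id}\t{locus.locus_id}\t{locus.conservation_class}\n"
            )


def classify_conservation(
    catalog: MirnaCatalog, reference_family_list: str | Path
) -> MirnaCatalog:
    """Fill ``conservation_class`` from a reference family->class table.

    Families absent from the reference are called ``lineage_novel`` when
    annotated in at least two species of the input set (shared novelties),
    otherwise ``unknown``.
    """
    ref: dict[str, str] = {}
    for line in Path(reference_family_list).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fam, cls = line.rstrip("\n").split("\t")[:2]
        if cls not in CONSERVATION_CLASSES:
            raise CatalogError(f"unknown conservation class {cls!r} for {fam!r}")
        ref[fam] = cls
    for fam_id, fam in catalog.families.items():
        if fam_id in ref:
            cls = ref[fam_id]
        elif sum(1 for ids in fam.members.values() if ids) >= 2:
            cls = "lineage_novel"
        else:
            cls = "unknown"
        for lid in fam.loci():
            catalog.loci[lid].conservation_class = cls
    return catalog


def copies_per_family(catalog: MirnaCatalog):
    """Annotated locus count per family per species as a DataFrame
    (families x species, missing combinations 0)."""
    import pandas as pd

    species = catalog.species
    rows = {}
    for fam_id, fam in sorted(catalog.families.items()):
        rows[fam_id] = {sp: len(fam.members.get(sp, [])) for sp in species}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species).fillna(0)
    df.index.name = "family_id"
    return df.astype(int)


def load_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV sample sheet (sample_id, species_id, tissue_or_stage)."""
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sid, sp, tissue = line.rstrip("\n").split("\t")[:3]
        if sid in seen:
            raise CatalogError(f"duplicate sample_id {sid!r} in sample sheet")
        seen.add(sid)
        samples.append(SampleMeta(sid, sp, tissue))
    return samples
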