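"""Synthetic WGD genomes, miRNA families, arm expression and small RNA reads.

The generator emulates the study design this package analyses: an ancestral
genome with ordered genes and embedded miRNA hairpins passes through R
rounds of whole-genome duplication.  Each round duplicates every
chromosome; on the new copy each gene or hairpin survives with
``retention_prob`` while one copy always persists, which keeps expected
copy numbers analytic (E[n after R rounds] = (1 + p)^R).  After the WGD
rounds the genome may split into two descendant species with identical
structure.  Sequences then diverge from the ancestor by per-site
substitution only (no indels, so arm identities have a clean oracle): one
mature arm per family is designated conserved and evolves at
``mu_conserved_arm`` while the other arm and the loop evolve at
``mu_free_arm``.

Expression: per family one arm is dominant, coupled to the conserved arm
with probability ``conserved_dominant_prob``; the dominant arm carries
``true_arm_fraction`` of the family's reads.  A ``switch_fraction`` of
families is planted with a species arm switch (dominance flipped in the
second species) and optionally with a tissue switch (flipped in one
designated tissue).  Reads are 18-27 nt mature-arm sequences with +-2 nt
end offsets and high Phred qualities; per-locus totals are Poisson.

All randomness flows from ``SimConfig.seed`` through one generator, so
identical configs give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirfate.catalog import HairpinLocus, MirnaCatalog, SampleMeta
from mirfate.synteny import Anchor, write_anchors

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def random_seq(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate(seq: str, mu: float, rng: np.random.Generator) -> str:
    """Per-site substitution at rate mu; substituted sites get one of the
    three other bases uniformly."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < mu
    idx = np.nonzero(mask)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        arr[idx] = _BASES[(_BASE_INDEX[arr[idx]] + shift) % 4]
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT).decode()[::-1]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset (defaults mirror the
    two-species, 3R, multi-tissue design the analyses assume)."""

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 120
    n_mirna_families: int = 50
    rounds: int = 3
    retention_prob: float = 0.7
    mu_conserved_arm: float = 0.01
    mu_free_arm: float = 0.15
    species_split: bool = True
    switch_fraction: float = 0.1
    tissue_switch_fraction: float = 0.0
    conserved_dominant_prob: float = 0.9
    true_arm_fraction: float = 0.9
    n_samples_per_species: int = 5
    reads_per_locus_mean: int = 200
    read_len_range: tuple[int, int] = (18, 27)
    arm_len: int = 22
    loop_len: int = 15
    gene_len: int = 200
    spacer_len: int = 30
    mu_gene: float = 0.02

    def validate(self) -> None:
        checks = {
            "rounds": 0 <= self.rounds <= 3,
            "retention_prob": 0 < self.retention_prob <= 1,
            "mu_conserved_arm": 0 <= self.mu_conserved_arm <= 1,
            "mu_free_arm": 0 <= self.mu_free_arm <= 1,
            "switch_fraction": 0 <= self.switch_fraction <= 1,
            "tissue_switch_fraction": 0 <= self.tissue_switch_fraction <= 1,
            "conserved_dominant_prob": 0 <= self.conserved_dominant_prob <= 1,
            "true_arm_fraction": 0.5 < self.true_arm_fraction <= 1,
            "n_chromosomes": self.n_chromosomes >= 1,
            "genes_per_chromosome": self.genes_per_chromosome >= 1,
            "n_mirna_families": self.n_mirna_families >= 1,
            "n_samples_per_species": self.n_samples_per_species >= 1,
            "read_len_range": 0 < self.read_len_range[0] <= self.read_len_range[1],
            "arm_len": self.read_len_range[0] <= self.arm_len,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SimConfig field: {name}")


@dataclass
class TruthManifest:
    """Simulator ground truth for parameter-recovery tests."""

    rounds: int
    species: list[str]
    chromosomes: list[str]
    paralogy_groups: dict[str, dict[str, list[str]]]  # family -> species -> loci
    conserved_arm: dict[str, str]  # family -> '5p' | '3p'
    dominant_arm: dict[str, dict[str, str]]  # family -> species -> arm
    switched_families: list[str]
    tissue_switched: dict[str, str]  # family -> sample tissue flipped
    samples: list[dict]  # sample_id, species_id, tissue_or_stage
    arm_fraction_5p: dict[str, float]  # "locus|sample" -> true 5p fraction
    true_counts: dict[str, list[int]] = field(default_factory=dict)
    # "locus|sample" -> [n_5p, n_3p], filled by simulate_reads
    read_source: dict[str, list[str]] = field(default_factory=dict)
    # read_id -> [locus_id, arm]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        return cls(**d)


def write_truth(truth: TruthManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def load_truth(path: str | Path) -> TruthManifest:
    return TruthManifest.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Simulation:
    """In-memory simulated dataset plus writers for standard formats."""

    cfg: SimConfig
    genomes: dict[str, dict[str, str]]  # species -> chrom -> sequence
    gene_features: dict[str, list[tuple]]  # species -> (chrom, gene_id, s0, e0, strand, rank)
    catalog: MirnaCatalog
    anchors: dict[str, list[Anchor]]
    truth: TruthManifest
    reads: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # sample -> [(read_id, seq, qual_string)]

    @property
    def samples(self) -> list[SampleMeta]:
        return [SampleMeta(**s) for s in self.truth.samples]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA/GFF3/TSV/FASTQ/JSON files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sp in sorted(self.genomes):
            gfa = outdir / f"{sp}.genome.fa"
            with gfa.open("w") as fh:
                for chrom in sorted(self.genomes[sp]):
                    fh.write(f">{chrom}\n{self.genomes[sp][chrom]}\n")
            paths[f"genome_{sp}"] = gfa

            ggff = outdir / f"{sp}.genes.gff3"
            with ggff.open("w") as fh:
                fh.write("##gff-version 3\n")
                for chrom, gid, s0, e0, strand, rank in self.gene_features[sp]:
                    fh.write(
                        f"{chrom}\tmirfate_sim\tgene\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t"
                        f"ID={gid};rank={rank}\n"
                    )
            paths[f"genes_{sp}"] = ggff

            mgff = outdir / f"{sp}.mirna.gff3"
            hfa = outdir / f"{sp}.hairpins.fa"
            loci = sorted(
                (l for l in self.catalog.loci.values() if l.species_id == sp),
                key=lambda l: l.locus_id,
            )
            with mgff.open("w") as gh, hfa.open("w") as hh:
                gh.write("##gff-version 3\n")
                for locus in loci:
                    gh.write(
                        f"{locus.seq_id}\tmirfate_sim\tmiRNA_primary_transcript\t"
                        f"{locus.start}\t{locus.end}\t.\t{locus.strand}\t.\t"
                        f"ID={locus.locus_id};Name={locus.family_id}\n"
                    )
                    for tag, iv in (("5p", locus.arm5p), ("3p", locus.arm3p)):
                        if iv is None:
                            continue
                        if locus.strand == "+":
                            gs, ge = locus.start + iv[0], locus.start + iv[1] - 1
                        else:
                            gs, ge = locus.end - iv[1] + 1, locus.end - iv[0]
                        gh.write(
                            f"{locus.seq_id}\tmirfate_sim\tmiRNA\t{gs}\t{ge}\t.\t"
                            f"{locus.strand}\t.\tID={locus.locus_id}-{tag};"
                            f"Derives_from={locus.locus_id}\n"
                        )
                    hh.write(f">{locus.locus_id}\n{locus.hairpin_seq}\n")
            paths[f"mirna_{sp}"] = mgff
            paths[f"hairpins_{sp}"] = hfa

            afile = outdir / f"{sp}.anchors.tsv"
            write_anchors(self.anchors[sp], afile)
            paths[f"anchors_{sp}"] = afile

        fam = outdir / "families.tsv"
        with fam.open("w") as fh:
            fh.write("#family_id\tlocus_id\tclass\n")
            for locus in sorted(self.catalog.loci.values(), key=lambda l: l.locus_id):
                fh.write(
                    f"{locus.family_id}\t{locus.locus_id}\t{locus.conservation_class}\n"
                )
        paths["families"] = fam

        sheet = outdir / "samples.tsv"
        with sheet.open("w") as fh:
            fh.write("#sample_id\tspecies_id\ttissue_or_stage\n")
            for s in self.truth.samples:
                fh.write(
                    f"{s['sample_id']}\t{s['species_id']}\t{s['tissue_or_stage']}\n"
                )
        paths["samples"] = sheet

        for sample_id in sorted(self.reads):
            fq = outdir / f"reads_{sample_id}.fastq"
            with fq.open("w") as fh:
                for rid, seq, qual in self.reads[sample_id]:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            paths[f"reads_{sample_id}"] = fq

        tpath = outdir / "truth.json"
        write_truth(self.truth, tpath)
        paths["truth"] = tpath
        return paths


def _wgd_copies(n_elements: int, cfg: SimConfig, rng: np.random.Generator):
    """Chromosome copy suffixes with retained element index sets after the
    configured WGD rounds; the '0' child of each duplication keeps its
    parent's content, the '1' child loses each element independently."""
    copies: list[tuple[str, frozenset[int]]] = [("", frozenset(range(n_elements)))]
    for _ in range(cfg.rounds):
        nxt = []
        for suffix, kept in copies:
            nxt.append((suffix + "0", kept))
            retained = frozenset(
                e for e in sorted(kept) if rng.random() < cfg.retention_prob
            )
            nxt.append((suffix + "1", retained))
        copies = nxt
    return copies


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> Simulation:
    """Build the full simulated dataset (genomes, catalog, anchors, truth).

    Reads are not generated here; see :func:`simulate_reads` and the
    count-level shortcut :func:`simulate_arm_counts`.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    species = ["A", "B"] if cfg.species_split else ["A"]
    hairpin_len = 2 * cfg.arm_len + cfg.loop_len

    # --- ancestral layout -------------------------------------------------
    # Per ancestral chromosome: ordered elements, each ('gene', id) or
    # ('mirna', family).  Families are distributed round-robin and inserted
    # at random inter-gene slots.
    fam_ids = [f"fam{k:03d}" for k in range(cfg.n_mirna_families)]
    layouts: list[list[tuple[str, str]]] = []
    anc_gene_seq: dict[str, str] = {}
    anc_hairpin: dict[str, str] = {}
    strand_of: dict[str, str] = {}
    conserved_arm = {}
    for c in range(cfg.n_chromosomes):
        elements = [("gene", f"g{c}_{i}") for i in range(cfg.genes_per_chromosome)]
        fams_here = [f for k, f in enumerate(fam_ids) if k % cfg.n_chromosomes == c]
        slots = sorted(
            rng.integers(0, cfg.genes_per_chromosome + 1, size=len(fams_here)).tolist(),
            reverse=True,
        )
        for fam, slot in zip(fams_here, slots):
            elements.insert(slot, ("mirna", fam))
        layouts.append(elements)
        for kind, name in elements:
            strand_of[name] = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                anc_gene_seq[name] = random_seq(cfg.gene_len, rng)
            else:
                anc_hairpin[name] = random_seq(hairpin_len, rng)
                conserved_arm[name] = "5p" if rng.random() < 0.5 else "3p"

    # --- WGD structure (shared by both species: duplications precede the
    # species split) -------------------------------------------------------
    chrom_copies = []  # (anc_chrom_idx, chrom_name, kept element indices)
    for c, elements in enumerate(layouts):
        for suffix, kept in _wgd_copies(len(elements), cfg, rng):
            name = f"chr{c}" + (f"_{suffix}" if suffix else "")
            chrom_copies.append((c, name, kept))
    chrom_names = [name for _, name, _ in chrom_copies]

    # --- expression truth -------------------------------------------------
    dominant_base = {
        fam: (
            conserved_arm[fam]
            if rng.random() < cfg.conserved_dominant_prob
            else ("3p" if conserved_arm[fam] == "5p" else "5p")
        )
        for fam in fam_ids
    }
    n_switch = int(round(cfg.switch_fraction * cfg.n_mirna_families))
    switched = sorted(
        rng.choice(fam_ids, size=n_switch, replace=False).tolist()
    ) if (n_switch and len(species) == 2) else []
    n_tissue_switch = int(round(cfg.tissue_switch_fraction * cfg.n_mirna_families))
    eligible = [f for f in fam_ids if f not in switched]
    tissue_switched = {
        fam: f"tissue{cfg.n_samples_per_species - 1}"
        for fam in sorted(
            rng.choice(eligible, size=min(n_tissue_switch, len(eligible)), replace=False).tolist()
        )
    } if n_tissue_switch else {}

    dominant_arm = {
        fam: {
            sp: (
                ("3p" if dominant_base[fam] == "5p" else "5p")
                if (fam in switched and sp == "B")
                else dominant_base[fam]
            )
            for sp in species
        }
        for fam in fam_ids
    }

    samples = [
        {"sample_id": f"{sp}_t{t}", "species_id": sp, "tissue_or_stage": f"tissue{t}"}
        for sp in species
        for t in range(cfg.n_samples_per_species)
    ]

    # --- per-species genomes, catalog, anchors ----------------------------
    catalog = MirnaCatalog()
    genomes: dict[str, dict[str, str]] = {}
    gene_features: dict[str, list[tuple]] = {}
    anchors: dict[str, list[Anchor]] = {}
    paralogy: dict[str, dict[str, list[str]]] = {
        fam: {sp: [] for sp in species} for fam in fam_ids
    }

    for sp in species:
        genomes[sp] = {}
        gene_features[sp] = []
        anchors[sp] = []
        gene_ranks: dict[str, dict[str, int]] = {}  # chrom -> gene_id -> rank
        for c, chrom_name, kept in chrom_copies:
            elements = layouts[c]
            parts = []
            pos = 0
            rank = 0
            ranks_here: dict[str, int] = {}
            spacer = "N" * cfg.spacer_len
            parts.append(spacer)
            pos += cfg.spacer_len
            for e_idx, (kind, name) in enumerate(elements):
                if e_idx not in kept:
                    continue
                if kind == "gene":
                    seq = mutate(anc_gene_seq[name], cfg.mu_gene, rng)
                    start0 = pos
                    occ = seq if strand_of[name] == "+" else revcomp(seq)
                    parts.append(occ)
                    pos += len(seq)
                    gene_features[sp].append(
                        (chrom_name, name, start0, pos, strand_of[name], rank)
                    )
                    ranks_here[name] = rank
                    rank += 1
                else:
                    fam = name
                    anc = anc_hairpin[fam]
                    a5 = (0, cfg.arm_len)
                    loop = (cfg.arm_len, cfg.arm_len + cfg.loop_len)
                    a3 = (cfg.arm_len + cfg.loop_len, hairpin_len)
                    mu5 = (
                        cfg.mu_conserved_arm
                        if conserved_arm[fam] == "5p"
                        else cfg.mu_free_arm
                    )
                    mu3 = (
                        cfg.mu_conserved_arm
                        if conserved_arm[fam] == "3p"
                        else cfg.mu_free_arm
                    )
                    hp = (
                        mutate(anc[a5[0] : a5[1]], mu5, rng)
                        + mutate(anc[loop[0] : loop[1]], cfg.mu_free_arm, rng)
                        + mutate(anc[a3[0] : a3[1]], mu3, rng)
                    )
                    start0 = pos
                    occ = hp if strand_of[fam] == "+" else revcomp(hp)
                    parts.append(occ)
                    pos += len(hp)
                    locus_id = f"{sp}_{fam}_{chrom_name}"
                    catalog.add_locus(
                        HairpinLocus(
                            locus_id=locus_id,
                            species_id=sp,
                            seq_id=chrom_name,
                            start=start0 + 1,
                            end=pos,
                            strand=strand_of[fam],
                            hairpin_seq=hp,
                            arm5p=a5,
                            arm3p=a3,
                            family_id=fam,
                            conservation_class="bilaterian_conserved",
                        )
                    )
                    paralogy[fam][sp].append(locus_id)
                parts.append(spacer)
                pos += cfg.spacer_len
            genomes[sp][chrom_name] = "".join(parts)
            gene_ranks[chrom_name] = ranks_here

        # anchors: retained paralogous gene pairs between chromosome copies
        by_anc: dict[int, list[tuple[str, dict[str, int]]]] = {}
        for c, chrom_name, _ in chrom_copies:
            by_anc.setdefault(c, []).append((chrom_name, gene_ranks[chrom_name]))
        for c in sorted(by_anc):
            group = by_anc[c]
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    name_i, ranks_i = group[i]
                    name_j, ranks_j = group[j]
                    for gid in ranks_i:
                        if gid in ranks_j:
                            anchors[sp].append(
                                Anchor(name_i, ranks_i[gid], name_j, ranks_j[gid])
                            )

    arm_fraction: dict[str, float] = {}
    for s in samples:
        sp = s["species_id"]
        for fam in fam_ids:
            dom = dominant_arm[fam][sp]
            if fam in tissue_switched and s["tissue_or_stage"] == tissue_switched[fam]:
                dom = "3p" if dom == "5p" else "5p"
            frac = cfg.true_arm_fraction if dom == "5p" else 1.0 - cfg.true_arm_fraction
            for locus_id in paralogy[fam][sp]:
                arm_fraction[f"{locus_id}|{s['sample_id']}"] = frac

    truth = TruthManifest(
        rounds=cfg.rounds,
        species=species,
        chromosomes=chrom_names,
        paralogy_groups=paralogy,
        conserved_arm=conserved_arm,
        dominant_arm=dominant_arm,
        switched_families=switched,
        tissue_switched=tissue_switched,
        samples=samples,
        arm_fraction_5p=arm_fraction,
    )
    return Simulation(
        cfg=cfg,
        genomes=genomes,
        gene_features=gene_features,
        catalog=catalog,
        anchors=anchors,
        truth=truth,
    )


def simulate_reads(
    sim: Simulation, rng: np.random.Generator | None = None
) -> Simulation:
    """Draw small RNA reads per locus per sample from the truth fractions.

    Totals are Poisson(``reads_per_locus_mean``); each read comes from the
    5p arm with the locus's true 5p fraction, as the mature arm sequence
    with up to +-2 nt end offsets (clamped to the hairpin and to the read
    length window) and Phred qualities of 30-40.
    """
    cfg = sim.cfg
    rng = rng or np.random.default_rng(cfg.seed + 1)
    min_len, max_len = cfg.read_len_range
    sim.reads = {}
    sim.truth.true_counts = {}
    sim.truth.read_source = {}
    loci_by_species: dict[str, list] = {}
    for locus in sorted(sim.catalog.loci.values(), key=lambda l: l.locus_id):
        loci_by_species.setdefault(locus.species_id, []).append(locus)
    for s in sim.truth.samples:
        sample_id, sp = s["sample_id"], s["species_id"]
        out: list[tuple[str, str, str]] = []
        for locus in loci_by_species.get(sp, []):
            frac = sim.truth.arm_fraction_5p[f"{locus.locus_id}|{sample_id}"]
            total = int(rng.poisson(cfg.reads_per_locus_mean))
            n5 = int(rng.binomial(total, frac)) if total else 0
            sim.truth.true_counts[f"{locus.locus_id}|{sample_id}"] = [n5, total - n5]
            hp = locus.hairpin_seq
            for arm, count in (("5p", n5), ("3p", total - n5)):
                iv = locus.arm5p if arm == "5p" else locus.arm3p
                for k in range(count):
                    ds, de = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
                    s0 = max(0, iv[0] + ds)
                    e0 = min(len(hp), iv[1] + de)
                    if e0 - s0 > max_len:
                        e0 = s0 + max_len
                    if e0 - s0 < min_len:
                        s0 = max(0, e0 - min_len)
                    seq = hp[s0:e0]
                    quals = rng.integers(30, 41, size=len(seq))
                    qual = "".join(chr(33 + q) for q in quals)
                    rid = f"{sample_id}|{locus.locus_id}|{arm}|{k}"
                    out.append((rid, seq, qual))
                    sim.truth.read_source[rid] = [locus.locus_id, arm]
        sim.reads[sample_id] = out
    return sim


def simulate_arm_counts(
    sim: Simulation, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Count-level shortcut: draw the per-(locus, sample) arm counts that
    read simulation plus exact quantification would produce (Poisson total,
    binomial 5p split), without materialising reads.  Used for large
    replicate studies of the downstream statistics."""
    cfg = sim.cfg
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rows = []
    loci = sorted(sim.catalog.loci.values(), key=lambda l: l.locus_id)
    for s in sim.truth.samples:
        sample_id, sp = s["sample_id"], s["species_id"]
        for locus in loci:
            if locus.species_id != sp:
                continue
            frac = sim.truth.arm_fraction_5p[f"{locus.locus_id}|{sample_id}"]
            total = int(rng.poisson(cfg.reads_per_locus_mean))
            n5 = int(rng.binomial(total, frac)) if total else 0
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "sample_id": sample_id,
                    "count_5p": float(n5),
                    "count_3p": float(total - n5),
                    "count_ambiguous": 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "sample_id", "count_5p", "count_3p", "count_ambiguous"],
    )
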