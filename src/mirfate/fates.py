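"""Paralogue arm conservation, conservation-vs-expression concordance,
genomic copy counting and WGD-round inference from copy numbers.

After WGD, paralogue families typically keep one mature arm under stronger
constraint: per arm, the mean pairwise identity across paralogues scores
conservation, and the higher-scoring arm is the conserved arm.  Families
whose conserved arm is also their expression-dominant arm (by overall arm
preference) are 'concordant'; an exact binomial test against 0.5 asks
whether concordance exceeds chance.  Copy numbers come from searching a
family consensus hairpin against the genome; n copies is evidence for the
smallest r with 2^r >= n duplication rounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import binomtest

from mirfate.alignment import pairwise_identity
from mirfate.catalog import HairpinLocus, MirnaCatalog
from mirfate.preference import OapRecord


@dataclass
class ArmConservationResult:
    family_id: str
    species_id: str
    n_paralogues: int
    score_5p: float
    score_3p: float
    conserved_arm: str  # '5p', '3p' or 'tie'


@dataclass
class ConcordanceSummary:
    n_assessed: int
    n_concordant: int
    fraction: float
    p_value: float | None
    assessed_families: list[str]


def _mean_pairwise_identity(seqs: list[str]) -> float:
    pairs = [
        pairwise_identity(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return sum(pairs) / len(pairs)


def arm_conservation(
    paralogues: list[HairpinLocus],
    family_id: str | None = None,
    species_id: str = "",
) -> ArmConservationResult | None:
    """Per-arm mean pairwise identity over a family's paralogues.

    Only paralogues with both arms annotated contribute; fewer than two
    such paralogues -> ``None`` (family skipped).  ``conserved_arm`` is
    order-invariant because mean pairwise identity is.
    """
    usable = [p for p in paralogues if p.has_both_arms]
    if len(usable) < 2:
        return None
    fam = family_id or usable[0].family_id
    score_5p = _mean_pairwise_identity([p.arm_seq("5p") for p in usable])
    score_3p = _mean_pairwise_identity([p.arm_seq("3p") for p in usable])
    if score_5p > score_3p:
        arm = "5p"
    elif score_3p > score_5p:
        arm = "3p"
    else:
        arm = "tie"
    return ArmConservationResult(fam, species_id, len(usable), score_5p, score_3p, arm)


def conservation_by_family(
    catalog: MirnaCatalog, per_species: bool = True
) -> list[ArmConservationResult]:
    """arm_conservation for every family (per species by default)."""
    results = []
    for family_id in sorted(catalog.families):
        if per_species:
            for sp in catalog.species:
                res = arm_conservation(
                    catalog.family_loci(family_id, sp), family_id, sp
                )
                if res is not None:
                    results.append(res)
        else:
            res = arm_conservation(catalog.family_loci(family_id), family_id, "all")
            if res is not None:
                results.append(res)
    return results


def conserved_vs_dominant(
    conservation: list[ArmConservationResult],
    oaps: dict[str, dict[str, dict[str, OapRecord]]],
) -> ConcordanceSummary:
    """Concordance between the sequence-conserved arm and expression OAP.

    ``oaps``: family -> species -> paralogue locus -> OapRecord.  The
    assessed set keeps families whose conserved-arm calls agree (and are
    not ties) across species, and whose defined per-paralogue OAPs agree
    within and across species (the elimination of paralogue- and
    species-switching cases); at least one defined OAP is required.  The
    p-value is an exact two-sided binomial test of the concordant count
    against 0.5.
    """
    cons_by_family: dict[str, set[str]] = {}
    for res in conservation:
        cons_by_family.setdefault(res.family_id, set()).add(res.conserved_arm)

    assessed: list[str] = []
    concordant = 0
    for family_id in sorted(cons_by_family):
        arms = cons_by_family[family_id]
        if len(arms) != 1 or "tie" in arms:
            continue
        conserved_arm = next(iter(arms))
        fam_oaps = [
            rec.oap
            for by_locus in oaps.get(family_id, {}).values()
            for rec in by_locus.values()
            if rec.oap in ("5p", "3p")
        ]
        if not fam_oaps or len(set(fam_oaps)) != 1:
            continue  # unexpressed, or paralogue/species arm usage differs
        assessed.append(family_id)
        if fam_oaps[0] == conserved_arm:
            concordant += 1

    n = len(assessed)
    p_value = binomtest(concordant, n, 0.5).pvalue if n else None
    fraction = concordant / n if n else float("nan")
    return ConcordanceSummary(n, concordant, fraction, p_value, assessed)


class GenomeSearcher:
    """Seeded approximate search of a query against one genome.

    Exact k-mer seeds nominate candidate windows; each window is verified
    by infix (edlib HW) alignment, which aligns the full query against a
    substring of the window, so query coverage is complete by construction.
    Hits are accepted at edit distance <= (1 - min_identity) * query length
    and merged when overlapping by more than half the shorter hit.
    """

    def __init__(self, genome: dict[str, str], seed_len: int = 12):
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for pos in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[pos : pos + seed_len], []).append((name, pos))

    @classmethod
    def from_fasta(cls, path: str | Path, seed_len: int = 12) -> "GenomeSearcher":
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(genome, seed_len)

    def _candidate_windows(self, query: str):
        """Cluster seed diagonals into windows (chrom, start, end)."""
        L, k = len(query), self.seed_len
        diags: dict[str, set[int]] = {}
        for qpos in range(L - k + 1):
            for chrom, gpos in self._index.get(query[qpos : qpos + k], ()):
                diags.setdefault(chrom, set()).add(gpos - qpos)
        pad = max(4, L // 4)
        for chrom in sorted(diags):
            ds = sorted(diags[chrom])
            cluster = [ds[0]]
            for d in ds[1:]:
                if d - cluster[-1] <= pad:
                    cluster.append(d)
                else:
                    yield chrom, max(0, cluster[0] - pad), min(
                        len(self.genome[chrom]), cluster[-1] + L + pad
                    )
                    cluster = [d]
            yield chrom, max(0, cluster[0] - pad), min(
                len(self.genome[chrom]), cluster[-1] + L + pad
            )

    def find_hits(self, query: str, min_identity: float = 0.8):
        """All accepted hit intervals: list of (chrom, start, end, strand,
        identity), 0-based half-open genomic coordinates."""
        hits = []
        for strand in "+-":
            q = query.upper() if strand == "+" else str(
                Seq(query.upper()).reverse_complement()
            )
            max_dist = int(math.floor((1.0 - min_identity) * len(q)))
            for chrom, w0, w1 in self._candidate_windows(q):
                window = self.genome[chrom][w0:w1]
                res = edlib.align(q, window, mode="HW", task="locations", k=max_dist)
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / len(q)
                for s, e in res["locations"]:
                    hits.append((chrom, w0 + s, w0 + e + 1, strand, identity))
        return hits


def merge_hits(hits: list[tuple]) -> list[tuple]:
    """Merge hits overlapping by more than 50% of the shorter hit."""
    merged: list[list] = []
    for hit in sorted(hits, key=lambda h: (h[0], h[1], h[2])):
        chrom, s, e = hit[0], hit[1], hit[2]
        if merged:
            mc, ms, me = merged[-1][0], merged[-1][1], merged[-1][2]
            if mc == chrom:
                overlap = min(e, me) - max(s, ms)
                shorter = min(e - s, me - ms)
                if shorter > 0 and overlap > 0.5 * shorter:
                    merged[-1][1] = min(s, ms)
                    merged[-1][2] = max(e, me)
                    continue
        merged.append([chrom, s, e, hit[3], hit[4]])
    return [tuple(m) for m in merged]


def count_genomic_loci(
    hairpin_consensus: str,
    genome: "dict[str, str] | str | Path | GenomeSearcher",
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    seed_len: int = 12,
) -> int:
    """Number of genomic loci matching a hairpin consensus on either strand.

    Infix alignment keeps query coverage at 1.0 except at sequence ends,
    so ``min_coverage`` is effectively guaranteed; it is retained for
    interface stability.  Overlapping hits are merged (>50% of the shorter).
    """
    if isinstance(genome, GenomeSearcher):
        searcher = genome
    elif isinstance(genome, dict):
        searcher = GenomeSearcher(genome, seed_len)
    else:
        searcher = GenomeSearcher.from_fasta(genome, seed_len)
    hits = searcher.find_hits(hairpin_consensus, min_identity)
    hits = [
        h for h in hits if (h[2] - h[1]) >= min_coverage * len(hairpin_consensus)
    ]
    return len(merge_hits(hits))


def consensus_hairpin(loci: list[HairpinLocus]) -> str:
    """Majority-vote consensus of equal-length hairpins (arms evolve by
    substitution only, so a columnwise vote is well defined); falls back to
    the first sequence when lengths differ."""
    seqs = [l.hairpin_seq.upper() for l in loci]
    if len({len(s) for s in seqs}) != 1:
        return seqs[0]
    cols = zip(*seqs)
    return "".join(max(sorted(set(col)), key=col.count) for col in cols)


def copy_number_table(
    catalog: MirnaCatalog,
    genomes: dict[str, "dict[str, str] | GenomeSearcher"],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    seed_len: int = 12,
) -> pd.DataFrame:
    """Genomic copy counts per family per species by consensus search.

    Returns columns family_id, species_id, n_loci, supported_rounds.
    """
    searchers = {
        sp: g if isinstance(g, GenomeSearcher) else GenomeSearcher(g, seed_len)
        for sp, g in genomes.items()
    }
    rows = []
    for family_id in sorted(catalog.families):
        loci = catalog.family_loci(family_id)
        if not loci:
            continue
        query = consensus_hairpin(loci)
        for sp in sorted(searchers):
            n = count_genomic_loci(
                query, searchers[sp], min_identity, min_coverage, seed_len
            )
            rows.append(
                {
                    "family_id": family_id,
                    "species_id": sp,
                    "n_loci": n,
                    "supported_rounds": supported_rounds(n),
                }
            )
    return pd.DataFrame(
        rows, columns=["family_id", "species_id", "n_loci", "supported_rounds"]
    )


def supported_rounds(n_loci: int) -> int:
    """Smallest r with 2^r >= n_loci (0 for n_loci <= 1)."""
    if n_loci <= 1:
        return 0
    return math.ceil(math.log2(n_loci))


def infer_rounds_from_copies(
    copies: pd.DataFrame,
    family_fraction: float = 0.25,
    conserved_families: list[str] | None = None,
) -> dict:
    """Genome-level WGD-round estimate from per-family copy counts.

    Per species, the estimate is the largest r >= 1 such that at least
    ``family_fraction`` of (conserved) families have n_loci > 2^(r-1),
    else 0.  Also reports the count of families with more than 4 copies,
    the copy-count evidence used for a third round.
    """
    df = copies
    if conserved_families is not None:
        df = df[df["family_id"].isin(conserved_families)]
    out: dict = {"per_species": {}, "family_fraction": family_fraction}
    estimates = []
    for sp, grp in df.groupby("species_id"):
        n_fam = len(grp)
        est = 0
        r = 1
        while n_fam and (grp["n_loci"] > 2 ** (r - 1)).sum() / n_fam >= family_fraction:
            est = r
            r += 1
        gt4 = int((grp["n_loci"] > 4).sum())
        out["per_species"][sp] = {
            "estimate": est,
            "n_families": int(n_fam),
            "families_gt4_copies": gt4,
        }
        estimates.append(est)
    out["estimate"] = max(estimates) if estimates else 0
    return out
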