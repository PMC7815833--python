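"""Small RNA read filtering, hairpin mapping and per-arm counting.

Reads are quality- and length-filtered (mean Phred >= 20, 18-27 nt by
default), then matched against every hairpin in the catalog as exact
substrings with up to ``max_mismatches`` substitutions (no indels).  A
placement is credited to the 5p or 3p arm when at least half the read
length overlaps that arm interval; everything else is ambiguous
(loop-spanning or 50/50 ties).  Multi-mapping reads, which are common among
WGD paralogues sharing an arm, are handled by one of three policies:
``fractional`` (1/n per hit locus, the default -- winner-takes-all would
bias arm-usage ratios), ``all``, or ``unique``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from mirfate.catalog import MirnaCatalog

POLICIES = ("fractional", "all", "unique")


@dataclass
class SmallRnaRead:
    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class Placement:
    read_id: str
    locus_id: str
    hairpin_offset: int
    read_len: int
    mismatches: int
    n_loci_hit: int


@dataclass
class FilterStats:
    n_input: int = 0
    n_kept: int = 0
    n_quality_fail: int = 0
    n_length_fail: int = 0


def trim_adapter(sequence: str, qualities: list[int], adapter: str | None):
    """Clip at the first occurrence of (a prefix of) the 3' adapter.

    Simulated libraries are adapter-free, so this is a pass-through hook by
    default; with an adapter string, the read is cut at the earliest match
    of the full adapter or of an adapter prefix (>= 5 nt) reaching the read
    end, the usual situation for short inserts.
    """
    if not adapter:
        return sequence, qualities
    idx = sequence.find(adapter)
    if idx < 0:
        for k in range(len(adapter) - 1, 4, -1):
            if sequence.endswith(adapter[:k]):
                idx = len(sequence) - k
                break
    if idx < 0:
        return sequence, qualities
    return sequence[:idx], qualities[:idx]


def preprocess_reads(
    fastq: str | Path,
    min_mean_phred: float = 20.0,
    min_len: int = 18,
    max_len: int = 27,
    adapter: str | None = None,
) -> tuple[list[SmallRnaRead], FilterStats]:
    """Parse a Phred+33 FASTQ and drop low-quality / off-length reads.

    A read is removed when its mean Phred score is below ``min_mean_phred``
    or its (post-trim) length falls outside [min_len, max_len].
    """
    stats = FilterStats()
    kept: list[SmallRnaRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(fastq), "fastq")):
            stats.n_input += 1
            seq = str(rec.seq).upper()
            quals = rec.letter_annotations["phred_quality"]
            seq, quals = trim_adapter(seq, quals, adapter)
            if not quals or sum(quals) / len(quals) < min_mean_phred:
                stats.n_quality_fail += 1
                continue
            if not (min_len <= len(seq) <= max_len):
                stats.n_length_fail += 1
                continue
            kept.append(SmallRnaRead(rec.id, seq, list(quals)))
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record around index {stats.n_input} in {fastq}: {exc}"
        ) from exc
    stats.n_kept = len(kept)
    return kept, stats


class HairpinIndex:
    """Exact-substring index over all hairpin windows of the read-length
    range, queried with the read itself plus all single-substitution
    variants (mismatch tolerance without indels)."""

    def __init__(self, catalog: MirnaCatalog, min_len: int = 18, max_len: int = 27):
        self.min_len = min_len
        self.max_len = max_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for locus in catalog.loci.values():
            seq = locus.hairpin_seq.upper().replace("U", "T")
            for L in range(min_len, min(max_len, len(seq)) + 1):
                for off in range(len(seq) - L + 1):
                    self._index.setdefault(seq[off : off + L], []).append(
                        (locus.locus_id, off)
                    )

    def lookup(self, read_seq: str, max_mismatches: int = 1):
        """Best placement per locus: list of (locus_id, offset, mismatches)."""
        seq = read_seq.upper().replace("U", "T")
        best: dict[str, tuple[int, int]] = {}  # locus -> (mismatches, offset)

        def _consider(query: str, nm: int) -> None:
            for locus_id, off in self._index.get(query, ()):  # exact hits
                cur = best.get(locus_id)
                if cur is None or (nm, off) < cur:
                    best[locus_id] = (nm, off)

        _consider(seq, 0)
        if max_mismatches >= 1:
            for pos, base in enumerate(seq):
                for alt in "ACGT":
                    if alt != base:
                        _consider(seq[:pos] + alt + seq[pos + 1 :], 1)
        if max_mismatches >= 2:
            raise NotImplementedError(
                "substitution index supports at most 1 mismatch"
            )
        # a 0-mismatch hit at a locus supersedes any 1-mismatch variant hit
        return [
            (locus_id, off, nm)
            for locus_id, (nm, off) in sorted(best.items())
            if nm <= max_mismatches
        ]


def map_reads(
    reads: list[SmallRnaRead],
    catalog: MirnaCatalog,
    max_mismatches: int = 1,
    index: HairpinIndex | None = None,
) -> list[Placement]:
    """Place every read on every hairpin it matches with <= max_mismatches
    substitutions.  One placement per (read, locus): ties resolved by fewest
    mismatches, then smallest offset, so n_loci_hit equals the number of
    placements of the read."""
    if index is None:
        lens = [len(r.sequence) for r in reads] or [18]
        index = HairpinIndex(catalog, min(lens), max(lens))
    placements: list[Placement] = []
    for read in reads:
        hits = index.lookup(read.sequence, max_mismatches=max_mismatches)
        n = len(hits)
        for locus_id, off, nm in hits:
            placements.append(
                Placement(read.read_id, locus_id, off, len(read.sequence), nm, n)
            )
    return placements


def _assign_arm(locus, offset: int, read_len: int) -> str:
    """'5p', '3p' or 'ambiguous' by the >=50%-of-read-length overlap rule."""
    r0, r1 = offset, offset + read_len

    def overlap(iv):
        if iv is None:
            return 0
        return max(0, min(r1, iv[1]) - max(r0, iv[0]))

    o5, o3 = overlap(locus.arm5p), overlap(locus.arm3p)
    half = read_len / 2
    if o5 >= half and o5 > o3:
        return "5p"
    if o3 >= half and o3 > o5:
        return "3p"
    return "ambiguous"


def count_arms(
    placements: list[Placement],
    catalog: MirnaCatalog,
    sample_id: str,
    policy: str = "fractional",
) -> pd.DataFrame:
    """Aggregate placements into an arm-count table for one sample.

    Returns a DataFrame with columns locus_id, sample_id, count_5p,
    count_3p, count_ambiguous.  Under the fractional policy the total
    assigned weight equals the number of placed reads (conservation).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown multi-mapping policy {policy!r}; use one of {POLICIES}")
    counts: dict[str, dict[str, float]] = {
        lid: {"count_5p": 0.0, "count_3p": 0.0, "count_ambiguous": 0.0}
        for lid in catalog.loci
    }
    for pl in placements:
        if policy == "unique" and pl.n_loci_hit != 1:
            continue
        weight = 1.0 / pl.n_loci_hit if policy == "fractional" else 1.0
        arm = _assign_arm(catalog.loci[pl.locus_id], pl.hairpin_offset, pl.read_len)
        key = {"5p": "count_5p", "3p": "count_3p", "ambiguous": "count_ambiguous"}[arm]
        counts[pl.locus_id][key] += weight
    rows = [
        {"locus_id": lid, "sample_id": sample_id, **vals}
        for lid, vals in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["locus_id", "sample_id", "count_5p", "count_3p", "count_ambiguous"]
    )


def quantify_samples(
    fastqs: dict[str, str | Path],
    catalog: MirnaCatalog,
    policy: str = "fractional",
    max_mismatches: int = 1,
    min_mean_phred: float = 20.0,
    min_len: int = 18,
    max_len: int = 27,
    adapter: str | None = None,
) -> tuple[pd.DataFrame, dict[str, FilterStats]]:
    """Run filter -> map -> count for several samples; one shared index."""
    index = HairpinIndex(catalog, min_len, max_len)
    tables = []
    stats: dict[str, FilterStats] = {}
    for sample_id in sorted(fastqs):
        reads, st = preprocess_reads(
            fastqs[sample_id], min_mean_phred, min_len, max_len, adapter
        )
        stats[sample_id] = st
        placements = map_reads(reads, catalog, max_mismatches, index=index)
        tables.append(count_arms(placements, catalog, sample_id, policy))
    if not tables:
        return (
            pd.DataFrame(
                columns=["locus_id", "sample_id", "count_5p", "count_3p", "count_ambiguous"]
            ),
            stats,
        )
    return pd.concat(tables, ignore_index=True), stats
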