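"""Collinear synteny-block detection over gene-rank anchors and WGD-round
inference from syntenic partner counts.

Anchors are homologous gene pairs given by per-chromosome gene ranks
(non-genic sequence is ignored, as with gene masking).  Blocks are maximal
monotone chains: within a chromosome pair and orientation, anchors are
chained with strictly increasing ranks on chromosome A and strictly
monotone ranks on B (increasing = forward, decreasing = reverse), with
per-step rank gaps bounded by ``max_gap`` on both chromosomes.  Chains are
extracted iteratively: the longest chain (ties broken toward the
lexicographically smallest anchor sequence) is removed first, so each
anchor joins at most one block per orientation and the block set at a
higher ``min_dots`` threshold is a subset of the set at a lower one.

After R rounds of WGD with decent retention, each chromosome shares blocks
with about 2^R - 1 paralogous chromosomes; counting the chromosome's own
copy as well, the partner count is about 2^R, so rounds are inferred as
ceil(log2(partner count)).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True, order=True)
class Anchor:
    chrom_a: str
    index_a: int
    chrom_b: str
    index_b: int

    def __post_init__(self) -> None:
        if self.index_a < 0 or self.index_b < 0:
            raise ValueError("gene ranks must be >= 0")


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor]
    orientation: str  # 'forward' or 'reverse'

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class PartnerCountSummary:
    n_partners: dict[str, int] = field(default_factory=dict)
    partners: dict[str, set] = field(default_factory=dict)


def _canonical(anchor: Anchor) -> Anchor:
    """Orient each anchor so chrom_a <= chrom_b (self pairs: index_a <=
    index_b); drop happens upstream for trivial self matches."""
    if anchor.chrom_a > anchor.chrom_b or (
        anchor.chrom_a == anchor.chrom_b and anchor.index_a > anchor.index_b
    ):
        return Anchor(anchor.chrom_b, anchor.index_b, anchor.chrom_a, anchor.index_a)
    return anchor


def _step_ok(prev: Anchor, nxt: Anchor, orientation: str, max_gap: int) -> bool:
    da = nxt.index_a - prev.index_a
    if not (1 <= da <= max_gap):
        return False
    db = nxt.index_b - prev.index_b
    if orientation == "forward":
        return 1 <= db <= max_gap
    return 1 <= -db <= max_gap


def best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> list[Anchor]:
    """Longest valid chain; among equally long chains, the one whose
    (index_a, index_b) sequence is lexicographically smallest.

    Quadratic DP on anchors sorted by (index_a, index_b); the chain is
    reconstructed start-first, always taking the smallest optimal successor,
    which realises the lexicographic tie-break exactly.
    """
    if not anchors:
        return []
    order = sorted(anchors, key=lambda x: (x.index_a, x.index_b))
    n = len(order)
    length = [1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _step_ok(order[i], order[j], orientation, max_gap):
                if 1 + length[j] > length[i]:
                    length[i] = 1 + length[j]
    lmax = max(length)
    start = min(i for i in range(n) if length[i] == lmax)
    chain = [order[start]]
    cur, remaining = start, lmax - 1
    while remaining:
        nxt = min(
            j
            for j in range(cur + 1, n)
            if length[j] == remaining and _step_ok(order[cur], order[j], orientation, max_gap)
        )
        chain.append(order[nxt])
        cur, remaining = nxt, remaining - 1
    return chain


def find_synteny_blocks(
    anchors: list[Anchor], min_dots: int, max_gap: int = 15
) -> list[SyntenyBlock]:
    """Detect collinear blocks per chromosome pair and orientation.

    Anchors are de-duplicated and canonically oriented; trivial self
    matches (same chromosome, same rank) are dropped.  Chains are extracted
    longest-first down to length 2, independently of ``min_dots``; only
    chains with >= min_dots anchors are reported as blocks, which makes the
    reported block set nested across thresholds.
    """
    if min_dots < 2:
        raise ValueError(f"min_dots must be >= 2, got {min_dots}")
    by_pair: dict[tuple[str, str], set[Anchor]] = {}
    for anchor in anchors:
        if anchor.chrom_a == anchor.chrom_b and anchor.index_a == anchor.index_b:
            continue
        canon = _canonical(anchor)
        by_pair.setdefault((canon.chrom_a, canon.chrom_b), set()).add(canon)

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        for orientation in ("forward", "reverse"):
            avail = set(by_pair[(ca, cb)])
            while True:
                chain = best_chain(sorted(avail), orientation, max_gap)
                if len(chain) < 2:
                    break
                avail.difference_update(chain)
                if len(chain) >= min_dots:
                    blocks.append(SyntenyBlock(ca, cb, chain, orientation))
    return blocks


def partner_counts(
    blocks: list[SyntenyBlock],
    chromosomes: list[str],
    include_self: str = "always",
) -> PartnerCountSummary:
    """Distinct syntenic partner chromosomes per chromosome.

    ``include_self='always'`` counts the chromosome's own copy whenever it
    participates in any block (the convention behind partner counts of
    2^R); ``'self_block'`` adds the chromosome itself only when a
    self-block (block with chrom_a == chrom_b) exists.
    """
    if include_self not in ("always", "self_block"):
        raise ValueError(f"unknown include_self mode {include_self!r}")
    partners: dict[str, set] = {c: set() for c in chromosomes}
    for blk in blocks:
        partners.setdefault(blk.chrom_a, set())
        partners.setdefault(blk.chrom_b, set())
        if blk.chrom_a == blk.chrom_b:
            partners[blk.chrom_a].add(blk.chrom_a)
        else:
            partners[blk.chrom_a].add(blk.chrom_b)
            partners[blk.chrom_b].add(blk.chrom_a)
    if include_self == "always":
        for chrom, ps in partners.items():
            if ps:
                ps.add(chrom)
    return PartnerCountSummary(
        n_partners={c: len(ps) for c, ps in sorted(partners.items())},
        partners=dict(sorted(partners.items())),
    )


def rounds_from_partners(n_partners: int) -> int:
    """ceil(log2(n_partners)) for n_partners >= 1; 0 for n_partners <= 1."""
    if n_partners <= 1:
        return 0
    return math.ceil(math.log2(n_partners))


def infer_rounds_from_synteny(summary: PartnerCountSummary) -> dict:
    """Genome-level round estimate: mode of per-chromosome inferred rounds
    over chromosomes with at least one partner; ties broken toward the
    larger value, with all tied values reported."""
    table = pd.DataFrame(
        [
            {
                "chromosome": c,
                "n_partners": n,
                "inferred_rounds": rounds_from_partners(n),
            }
            for c, n in summary.n_partners.items()
        ],
        columns=["chromosome", "n_partners", "inferred_rounds"],
    )
    active = table[table["n_partners"] >= 1]
    if active.empty:
        return {"estimate": 0, "tied_estimates": [], "per_chromosome": table}
    counts = Counter(active["inferred_rounds"])
    top = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == top)
    return {
        "estimate": int(tied[-1]),
        "tied_estimates": [int(t) for t in tied],
        "per_chromosome": table,
    }


def read_anchors(path) -> list[Anchor]:
    """Read a TSV anchor list (chrom_a, gene_a_rank, chrom_b, gene_b_rank)."""
    anchors = []
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        ca, ia, cb, ib = line.rstrip("\n").split("\t")[:4]
        anchors.append(Anchor(ca, int(ia), cb, int(ib)))
    return anchors


def write_anchors(anchors: list[Anchor], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#chrom_a\tgene_a_rank\tchrom_b\tgene_b_rank\n")
        for a in anchors:
            fh.write(f"{a.chrom_a}\t{a.index_a}\t{a.chrom_b}\t{a.index_b}\n")
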