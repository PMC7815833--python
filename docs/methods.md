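# Methods

This note defines every statistic `mirfate` computes, the defaults it
uses, and the reasoning behind the numerical choices. All coordinates are
0-based half-open within hairpins and 1-based inclusive on genomes (GFF3
convention); minus-strand hairpins are reverse-complemented so that arm
intervals are always in hairpin (5'→3') coordinates.

## 1. Catalogue

Inputs are a genome FASTA, a miRBase-dialect GFF3
(`miRNA_primary_transcript` features with `miRNA` children linked by
`Derives_from`) and an optional family table (TSV:
family_id, locus_id, conservation class). Mature arms are assigned
positionally: the arm nearer the hairpin 5' end is 5p, the other 3p; a
single annotated arm is assigned by its midpoint relative to the hairpin
midpoint. Validation is strict and fatal: arm intervals must lie inside
the hairpin, hairpins inside their chromosome, locus IDs must be unique.
`write_catalog`/`load_catalog` form a fixpoint: writing a loaded catalogue
and reloading reproduces it exactly, and a second write is byte-identical.

Conservation classes: families listed in a reference table take the
listed class; unlisted families present in ≥ 2 species are
`lineage_novel`; otherwise `unknown`.

## 2. Arm quantification

Read filtering removes reads with mean Phred < 20 (a mean of exactly 20
is kept) or length outside 18–27 nt. FASTQ parsing is strict; a malformed
record aborts with the record index. An optional 3' adapter is trimmed
when the full adapter, or a terminal prefix of ≥ 5 nt of it, is found.

Mapping is substring matching of the read (T and U equivalent) against
the hairpin set with at most one substitution and no indels, implemented
as an exact dictionary over all hairpin substrings of length 18–27 plus
lookup of all 1-substitution variants of the read. Each read keeps its
best placement per hairpin (fewest mismatches, then smallest offset);
`n_loci_hit` is the number of hairpins hit.

Arm assignment: a placement is counted for an arm when the read overlaps
that arm by at least 50% of the read length and strictly more than the
other arm; exact ties and loop-dominated reads are `ambiguous`.
Multi-mapping policies: `fractional` (default) gives each placement
weight 1 / n_loci_hit so total assigned weight equals the number of
placed reads exactly; `all` counts every placement with weight 1;
`unique` drops multi-mapping reads. Reads are only mapped against
hairpins of their own species, so near-identical orthologues do not
absorb weight.

## 3. Arm preference and switching

AUR = count_5p / (count_5p + count_3p), defined only when
count_5p + count_3p ≥ `min_reads` (default 10; below it the call is
`no_expression`). Dominance: AUR > 0.7 → `dominant_5p`, AUR < 0.3 →
`dominant_3p`, the closed interval [0.3, 0.7] → `no_preference`.

The overall arm preference (OAP) of a miRNA is `5p` or `3p` when that
dominance type is shown by **strictly more than** `oap_fraction` = 70% of
informative samples (8 of 10 qualifies, 7 of 10 does not); with fewer
than 2 informative samples the OAP is `undefined`. By default
`no_expression` samples are excluded from the denominator
(`count_no_expression = False`).

Switching: a `species_switch` is an opposite pair of defined OAPs for the
same family in two species; a `paralogue_switch` is an opposite pair of
defined OAPs between paralogues within a species; a `tissue_switch` is a
5p-dominant and a 3p-dominant sample call for the same locus. A defined
OAP paired with an undefined one is reported as uncallable, never as a
switch. Family-level OAPs pool the arm counts of all paralogues per
sample before calling.

## 4. Paralogue fates

**Arm conservation.** For each family (per species), each arm's score is
the mean pairwise identity over all paralogue pairs with both arms
annotated (≥ 2 required). Identity uses overlap (free-end-gap) alignment
with match +1, mismatch 0, internal gap −1; terminal gaps in one sequence
per end are free and excluded from the column count. Because co-optimal
alignments can have different identities, the implementation fixes a
deterministic optimum: lexicographically maximise (score, matches,
−columns) by an additive tuple DP (the order is translation-invariant, so
the DP is exact without traceback). Identity = matches / columns. The
higher-scoring arm is the conserved arm; equal scores are a `tie`.

**Concordance.** A family is assessed when (i) its conserved-arm calls
agree and are not ties across species, and (ii) all defined per-paralogue
OAPs agree within and across species (families showing paralogue or
species switching, or no defined OAP, are eliminated). Concordant =
conserved arm equals that OAP. Significance: exact two-sided binomial
test of the concordant count against p = 0.5 (`scipy.stats.binomtest`).

**Copy counting.** The family consensus hairpin (column-wise majority
vote; sequences evolve by substitution only in the simulator, so lengths
match) is searched against each genome on both strands: exact 12-mer
seeds nominate candidate windows by diagonal clustering, each window is
verified by infix (edlib HW) alignment with edit distance ≤
(1 − `min_identity`) × query length (`min_identity` = 0.8). Infix mode
aligns the whole query, so coverage is complete by construction. Hits
overlapping by more than 50% of the shorter hit are merged. n copies
supports r rounds where 2^r ≥ n (`supported_rounds`). The genome-level
estimate is the largest r ≥ 1 such that at least `family_fraction` = 25%
of families have more than 2^(r−1) copies.

## 5. Synteny and WGD rounds

Anchors are homologous gene pairs expressed as gene ranks per chromosome
(rank-space removes length effects, as with gene masking). Within one
chromosome pair and orientation, a chain has strictly increasing ranks on
A, strictly monotone ranks on B (increasing = forward, decreasing =
reverse), and per-step rank gaps ≤ `max_gap` = 15 on both axes. Chains
are extracted iteratively: the longest chain — ties broken toward the
lexicographically smallest (rank_a, rank_b) sequence, realised exactly by
the DP reconstruction — is removed first, down to length 2. Chains with
≥ `min_dots` anchors (default 7) are reported as blocks; because
extraction does not depend on `min_dots`, block sets are nested across
thresholds. Trivial self matches (a gene against itself) are dropped;
mirrored duplicate anchors are canonicalised.

Partner counts: the number of distinct chromosomes a chromosome shares a
block with, counting its own copy whenever it participates in any block
(`include_self = "always"`; the alternative `"self_block"` counts self
only when an intra-chromosome block exists). After R rounds each
chromosome has ≈ 2^R − 1 paralogous partners plus itself, so
per-chromosome rounds = ceil(log2(n_partners)) and the genome estimate is
the mode over chromosomes with ≥ 1 partner, ties broken toward the larger
value (later rounds lose signal first, so under-counting is the common
failure mode).

## 6. Simulator

An ancestral genome of `n_chromosomes` × `genes_per_chromosome` genes
(`gene_len` = 200 nt) with `n_mirna_families` hairpins (22 nt arms, 15 nt
loop) inserted at random inter-gene slots passes through `rounds` WGD
rounds. Each round duplicates every chromosome; the "0" child keeps its
parent's content and the "1" child retains each element independently
with `retention_prob` = 0.7, so E[copies after R rounds] = (1 + p)^R
(≈ 4.9 for p = 0.7, R = 3) and chromosome names record the duplication
path (`chr0_101` etc.). An optional species split yields two species with
identical structure that diverge independently from the ancestor.

Sequence divergence is per-site substitution only (no indels): the
designated conserved arm of each family mutates at `mu_conserved_arm` =
0.01, the free arm and loop at `mu_free_arm` = 0.15, genes at `mu_gene` =
0.02. The dominant arm coincides with the conserved arm with probability
`conserved_dominant_prob` = 0.9; it carries `true_arm_fraction` = 0.9 of
each locus's reads. `switch_fraction` = 0.1 of families have dominance
flipped in species B (species switch); `tissue_switch_fraction` families
are flipped in one designated tissue. Reads are mature-arm sequences with
±2 nt end offsets clamped to 18–27 nt, Phred 30–40, Poisson totals
(`reads_per_locus_mean` = 200 by default); a count-level shortcut
(`simulate_arm_counts`) draws the same Poisson/binomial counts without
materialising reads for large replicate studies. All randomness flows
from a single `numpy` generator seeded by `SimConfig.seed`, so outputs
are byte-identical across runs. A truth manifest records rounds,
paralogy groups, conserved and dominant arms, switched families,
per-locus arm fractions and per-read sources.

Anchors are emitted from the simulator's own gene ranks (retained
paralogous gene pairs between chromosome copies), i.e. the simulator
plays the role of the orthology caller.

## 7. Pipeline

Stages: simulate → quantify → arm_prefs → switch → conserve → copies →
synteny → report. Every stage reads and writes plain files (TSV with one
`#` header line; JSON with sorted keys and no timestamps) under one
output directory, records a SHA-256 key over its parameters and input
file digests, and is skipped when the key and outputs are unchanged —
stages are therefore individually re-runnable and the whole run is
resumable and deterministic.

## Design decisions

- **Substitution-only divergence** keeps equal arm lengths, which gives
  exact brute-force oracles for identity and consensus; real indel
  dynamics are out of scope.
- **Deterministic alignment tie-break** ((score, matches, −columns)
  lexicographic) removes co-optimal ambiguity from conserved-arm calls at
  zero cost.
- **Rank-space synteny** with iterative longest-chain extraction is a
  deliberately simple, fully testable stand-in for dot-plot chaining
  tools; it is quadratic per chromosome pair and not intended for
  megascale anchor sets.
- **Per-species read mapping** prevents cross-species weight splitting
  between near-identical orthologous hairpins under the fractional
  policy.
- **Mode with larger-value tie-break** for the synteny round estimate,
  and the 25% family fraction for the copy-number estimate, reflect that
  duplicate loss erodes evidence downward, never upward.

## Limitations

- Read mapping allows substitutions only (≤ 1) and no indels; there is no
  seed-based mapper for genome-scale read sets.
- Copy counting assumes hairpins are recognisably similar (≥ 80%
  identity); ancient, heavily diverged duplicates are undercounted.
- The simulator does not model expression noise beyond Poisson/binomial
  sampling, nor arm-length heterogeneity, RNA editing or isomiR
  structure.
- The concordance test treats families as independent observations.
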