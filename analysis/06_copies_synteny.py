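#!/usr/bin/env python
"""Count genomic hairpin copies per family, chain synteny blocks and
infer the number of WGD rounds from both signals.  Writes
copy_number.tsv, blocks.tsv, partner_counts.tsv and the rounds JSONs."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["copies", "synteny"], __doc__)
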