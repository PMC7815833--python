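#!/usr/bin/env python
"""Simulate the study dataset: two species, three WGD rounds, small RNA
reads for five tissues per species.  Writes FASTA/GFF3/FASTQ plus the
truth manifest under <outdir>/sim/."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["simulate"], __doc__)
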