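#!/usr/bin/env python
"""Filter the small RNA reads, map them to their species' hairpins and
count per-arm placements (fractional multi-mapping).  Writes
arm_counts.tsv."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["quantify"], __doc__)
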