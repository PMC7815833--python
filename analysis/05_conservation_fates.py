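#!/usr/bin/env python
"""Score per-arm sequence conservation across paralogues and test the
concordance between the conserved arm and the expression-dominant arm.
Writes arm_conservation.tsv and concordance.json."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["conserve"], __doc__)
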