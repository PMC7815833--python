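#!/usr/bin/env python
"""Compute per-sample arm usage ratios (AUR), dominance calls and
per-locus overall arm preferences.  Writes arm_calls.tsv and oap.tsv."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["arm_prefs"], __doc__)
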