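#!/usr/bin/env python
"""Detect species, tissue and paralogue arm switches from the arm calls
and family-level preferences.  Writes switches.tsv and the per-family
preference matrix."""

from _common import run_stages

if __name__ == "__main__":
    run_stages(["switch"], __doc__)
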