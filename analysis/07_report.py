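#!/usr/bin/env python
"""Aggregate all stage outputs into the final report.json."""

import json

from _common import run_stages

if __name__ == "__main__":
    report = run_stages(["report"], __doc__)
    print(json.dumps(json.loads(report.read_text()), indent=1, sort_keys=True))
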