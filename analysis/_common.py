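"""Shared defaults for the numbered analysis scripts.

Every script drives one or two stages of the resumable pipeline against
the same output directory, so the scripts can be run in order (01..07) or
individually after their upstream outputs exist.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mirfate.pipeline import run_pipeline

HERE = Path(__file__).resolve().parent
CONFIG = HERE / "config.yaml"
DEFAULT_OUTDIR = HERE.parent / "results" / "wgd_run"
DEFAULT_SEED = 1


def run_stages(stages: list[str], description: str) -> Path:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", type=Path, default=DEFAULT_OUTDIR)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()
    import logging

    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    return run_pipeline(CONFIG, args.outdir, seed=args.seed, only=stages)
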