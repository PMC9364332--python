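#!/usr/bin/env python
"""Extract the kinematic outcomes from the simulated cohort's trial files.

Re-reads results/cohort/trials via the manifest, brings each pair onto the
common 200 Hz grid, synchronizes, removes baseline offsets, fragments the
movement phases and computes ROM/TROM/PAV/MAV per trial and system.
Writes results/cohort/summaries.csv (long format: one row per outcome).
"""

import argparse
from pathlib import Path

from shoulderval.config import load_config
from shoulderval.pipeline import extract_stage, _write_df

BASE = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=BASE,
                    help="directory written by 01_simulate_cohort.py")
    args = ap.parse_args()

    cfg = load_config(args.cohort / "config.yaml")
    summaries = extract_stage(args.cohort / "manifest.csv", cfg)
    out = args.cohort / "summaries.csv"
    _write_df(summaries, out)
    per_outcome = summaries.groupby("outcome").size().to_dict()
    print(f"wrote {len(summaries)} outcome rows to {out} ({per_outcome})")


if __name__ == "__main__":
    main()
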