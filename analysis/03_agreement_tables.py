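#!/usr/bin/env python
"""Between-system agreement tables for the simulated cohort.

Computes per movement x outcome: per-system mean +- SD, RMSE, two-way
mixed single-measures ICC (consistency) with interpretation band,
Bland-Altman bias and 95% limits of agreement, and the Kendall-tau
heteroscedasticity check.  Writes results/tables/agreement_report.csv,
a readable .txt rendering split into the ROM/TROM and PAV/MAV tables,
and prints the ROM table.
"""

import argparse
from pathlib import Path

import pandas as pd

from shoulderval.agreement import format_report_text
from shoulderval.config import load_config
from shoulderval.pipeline import validate_stage, _write_df

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=BASE / "cohort")
    ap.add_argument("--out", type=Path, default=BASE / "tables")
    args = ap.parse_args()

    cfg = load_config(args.cohort / "config.yaml")
    summaries = pd.read_csv(args.cohort / "summaries.csv")
    report = validate_stage(summaries, cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    _write_df(report, args.out / "agreement_report.csv")

    rom = report[report.outcome.isin(["ROM", "TROM"])]
    vel = report[report.outcome.isin(["PAV", "MAV"])]
    text = (
        "ROM and TROM agreement\n" + format_report_text(rom)
        + "\nPAV and MAV agreement\n" + format_report_text(vel)
    )
    (args.out / "agreement_report.txt").write_text(text)
    print(format_report_text(rom))
    worst = report.loc[report.icc.idxmin()]
    best = report.loc[report.icc.idxmax()]
    print(f"ICC range: {worst.icc:.3f} ({worst.movement} {worst.outcome}) "
          f"to {best.icc:.3f} ({best.movement} {best.outcome}); "
          f"largest |bias|: "
          f"{report.bias.abs().max():.1f} "
          f"({report.loc[report.bias.abs().idxmax()].movement} "
          f"{report.loc[report.bias.abs().idxmax()].outcome})")


if __name__ == "__main__":
    main()
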