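#!/usr/bin/env python
"""Summarize the panel into the triangulation table.

Per exposure x outcome: direction concordance across strategies; per exposure:
efficacy/safety profile (significant & protective on efficacy outcomes, null
on safety outcomes -> "favourable") and colocalization support. Reads
results/panel_out/report.tsv, writes results/triangulation.tsv.
"""

from pathlib import Path

import pandas as pd

from coagmr.pipeline import summarize_triangulation

ROOT = Path(__file__).resolve().parent.parent
REPORT = ROOT / "results" / "panel_out" / "report.tsv"
OUT = ROOT / "results" / "triangulation.tsv"


def main():
    report = pd.read_csv(REPORT, sep="\t")
    summary = summarize_triangulation(report)
    summary.to_csv(OUT, sep="\t", index=False)
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    favourable = summary.groupby("exposure")["profile"].first()
    for exposure, profile in favourable.items():
        print(f"{exposure}: {profile}")


if __name__ == "__main__":
    main()
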