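#!/usr/bin/env python
"""Generate the synthetic exposure/outcome panel.

Writes a 2-exposure x 3-outcome summary-statistics panel to results/panel_data/:
TARGET1 is a favourable anticoagulant-style target (protects against the
thrombotic outcomes, null on bleeding, one dominant cis pQTL shared with the
outcomes), TARGET2 a harmful control. The directory also receives the LD
matrix, gene table and a ready-to-run pipeline config.
"""

from pathlib import Path

from coagmr.simulate import PANEL_SEED, PANEL_TRUTH, simulate_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panel_data"


def main():
    paths = simulate_panel(OUT, seed=PANEL_SEED)
    print(f"panel written to {OUT} (seed {PANEL_SEED})")
    print("true log-odds effects per 1 SD higher exposure:")
    for target, effects in PANEL_TRUTH.items():
        print(f"  {target}: {effects}")
    print(f"pipeline config: {paths['config']}")


if __name__ == "__main__":
    main()
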