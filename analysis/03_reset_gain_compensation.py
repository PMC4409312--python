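#!/usr/bin/env python
"""Separate intrinsic gain from fluctuation sensitivity via the reset.

A smaller spike slope factor raises the deterministic f-I gain, which by
itself could explain stronger fluctuation modulation. Lowering the reset
voltage V_r divisively reduces gain, so sweeping V_r provides the control:
even with gain matched through a more negative reset, sharper thresholds
remain more strongly modulated, and the spike-probability metrics (which
the reset cannot touch) grade smoothly with the slope factor.
"""

import argparse
from pathlib import Path

from fluctmod import figures
from fluctmod.io import read_json


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/03_reset_gain_compensation")
    args = ap.parse_args()
    out = Path(args.out)
    figures.fig5(out, seed=args.seed)
    sweep = read_json(out / "vr_gain_sweep.json")
    for name, rows in sweep.items():
        gains = [r["gain"] for r in rows]
        print(f"{name}: gain falls from {max(gains):.3f} to "
              f"{min(gains):.3f} spikes/(pA s) as V_r is lowered")
    shifts = read_json(out / "probability_metrics.json")
    print("Boltzmann k by slope factor:",
          {k: round(v["k"], 1) for k, v in shifts.items()})
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
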