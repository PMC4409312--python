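#!/usr/bin/env python
"""Mechanism: how the slope factor shapes the approach to threshold.

Phase-plane (dV/dt vs V) curves show that a 15 mV slope factor keeps the
voltage derivative small across a wide sub-threshold band, slowing the
trajectory everywhere; a 2 mV slope factor lets the trajectory plateau
just below threshold. The interval-fraction analysis quantifies the
consequence: with calibrated fluctuations, the probability that noise
fires a spike within 50 ms is substantially higher through most of the
~4 Hz firing cycle when the threshold is sharp.
"""

import argparse
from pathlib import Path

import numpy as np

from fluctmod import figures
from fluctmod.io import read_curve


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/05_threshold_approach")
    args = ap.parse_args()
    out = Path(args.out)
    figures.fig7(out, seed=args.seed)
    p2 = read_curve(out / "interval_probability_DT2.csv")
    p15 = read_curve(out / "interval_probability_DT15.csv")
    mid = (p2.x >= 0.2) & (p2.x <= 0.7)
    print(f"mean spike probability over cycle fractions 0.2-0.7: "
          f"sharp threshold {p2.y[mid].mean():.2f} vs "
          f"shallow {p15.y[mid].mean():.2f}")
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
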