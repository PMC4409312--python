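#!/usr/bin/env python
"""Measure fluctuation-based modulation of the eLIF input-output curves.

Calibrates the filtered-noise stimulus to the target voltage SD at −75 mV
and measures how much the fluctuations raise the initial firing rate of
the f-I curve (at the deterministic rheobase) and smooth the spike-
probability curve, for spike slope factors 2 vs 15 mV, with and without a
15 nS shunt (the shunt rows receive the same current fluctuations as
their baseline). Expected pattern: a sharp threshold (2 mV) is modulated
roughly five-fold more strongly than the shallow one (15 mV).
"""

import argparse
import json
from pathlib import Path

from fluctmod import figures
from fluctmod.models import ELIFParams
from fluctmod.noise import calibrate_noise_coefficient
from fluctmod.studies import low_region_delta_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--repeats", type=int, default=60)
    ap.add_argument("--out", default="results/02_fluctuation_modulation")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    deltas = {}
    for DT in (2.0, 15.0):
        base = ELIFParams(Delta_T=DT)
        coeff = calibrate_noise_coefficient(base, seed=args.seed + 11)
        for gsh in (0.0, 15.0):
            p = ELIFParams(Delta_T=DT, g_shunt=gsh)
            st = low_region_delta_study(p, coeff, seed=args.seed,
                                        n_repeats=args.repeats)
            key = f"DT{DT:g}_gsh{gsh:g}"
            deltas[key] = {k: st[k] for k in
                           ("rheobase_amp", "det_rate", "noisy_rate",
                            "delta", "delta_sem")}
            print(f"{key}: low-region delta = {st['delta']:.1f} "
                  f"± {st['delta_sem']:.1f} spikes/s "
                  f"(rheobase {st['rheobase_amp']:.0f} pA)")
    (out / "low_region_deltas.json").write_text(
        json.dumps(deltas, indent=2))
    figures.fig4(out, seed=args.seed)
    print(f"curves and panels -> {out}")


if __name__ == "__main__":
    main()
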