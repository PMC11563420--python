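"""Estimate intervention effect sizes for the screening scenarios.

Two complementary views: (1) the published area-level participation rates
give the deterministic incremental effects (proxy area minus control
state); (2) synthetic register-style monthly kit series verify that the
interrupted-time-series machinery recovers a known rate ratio, with an
advisory negative-binomial confidence interval.
"""

import argparse
import pathlib

import numpy as np

import crcscreen as cs
from crcscreen.effectiveness import incremental_effects_table

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    table = incremental_effects_table()
    table.to_csv(OUT / "effectiveness.csv", index=False)
    print("Area-level participation increases and incremental effects (pp):")
    print(table[["area", "increase_pp", "incremental_pp"]].to_string(index=False))
    print("\nScenario effect sizes fed to the model: Arabic +0.2 (minimum "
          "IRR-implied) and +1.3 pp; Mandarin +1.1 (Whitehorse minus SA) "
          "and +2.4 pp.")

    truth = 1.18
    irrs = []
    for rep in range(50):
        ctl, interv = cs.gen_monthly_kit_series(cs.GeneratorSpec(
            seed=args.seed + rep, group="mandarin", true_rate_ratio=truth))
        irrs.append(cs.rate_ratio(interv, ctl))
    ctl, interv = cs.gen_monthly_kit_series(cs.GeneratorSpec(
        seed=args.seed, group="mandarin", true_rate_ratio=truth))
    irr, lo, hi = cs.rate_ratio_nb(interv, ctl)
    print(f"\nSynthetic series (true IRR {truth}): mean point IRR over 50 "
          f"replicates {np.mean(irrs):.3f}; NB regression on one series "
          f"{irr:.3f} (95% CI {lo:.3f}-{hi:.3f})")


if __name__ == "__main__":
    main()
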