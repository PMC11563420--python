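"""Base-case cost-utility analysis of the four published scenarios.

Paired common-random-number runs of 10,000 individuals over 50 years,
replicated and pooled because a sub-percentage-point one-year uplift
changes only a handful of screening decisions per cohort.  Writes a
summary table (per-person costs and QALYs, increments, ICER, detected
cases at population scale) under results/.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

import crcscreen as cs

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SCENARIOS = [("arabic", 0.2), ("arabic", 1.3), ("mandarin", 1.1), ("mandarin", 2.4)]


def pooled_cua(group, uplift, params, costs, utilities, pop, reps, seed_rng):
    base = cs.base_scenario(group, params)
    intv = cs.uplift_scenario(group, uplift, params, costs=costs)
    rows = []
    for _ in range(reps):
        rs = cs.RunSpec(group=group, n_patients=10_000, horizon_years=50,
                        seed=int(seed_rng.integers(2 ** 31)))
        cua, det = cs.run_cua(rs, base, intv, params, costs, utilities, pop)
        b, i = det["base"], det["intervention"]
        rows.append({
            "base_cost": b.cost_per_person, "base_qaly": b.qalys_per_person,
            "int_cost": i.cost_per_person, "int_qaly": i.qalys_per_person,
            "d_cost": cua.incremental_cost, "d_qaly": cua.incremental_qalys,
            "d_detected_pop": det["delta_cases_detected_population"],
            "base_detected_pop": b.cases_detected * det["population"] / b.n_patients,
        })
    df = pd.DataFrame(rows)
    m = df.mean()
    icer = m.d_cost / m.d_qaly if m.d_qaly != 0 else np.nan
    return {
        "group": group, "uplift_pp": uplift, "reps": reps,
        "base_cost_pp": m.base_cost, "base_qaly_pp": m.base_qaly,
        "d_cost_pp": m.d_cost, "d_qaly_pp": m.d_qaly,
        "d_qaly_se": df.d_qaly.std() / np.sqrt(reps),
        "icer": icer,
        "detected_base_pop": m.base_detected_pop,
        "d_detected_pop": m.d_detected_pop,
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=40)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    params, costs, utilities = cs.load_parameters()
    seed_rng = np.random.default_rng(args.seed)
    rows = []
    for group, uplift in SCENARIOS:
        pop = cs.default_population(group)
        row = pooled_cua(group, uplift, params, costs, utilities, pop,
                         args.reps, seed_rng)
        row["intervention_cost_pp"] = cs.intervention_cost_per_person(
            costs.intervention_total_by_group[group], pop.total)
        rows.append(row)
        icer_txt = "n/a" if np.isnan(row["icer"]) else f"${row['icer']:,.0f}"
        print(f"{group} +{uplift}pp: base QALY/pp {row['base_qaly_pp']:.3f}, "
              f"dC ${row['d_cost_pp']:.2f}, dQ {row['d_qaly_pp']:.2e} "
              f"(se {row['d_qaly_se']:.1e}), ICER {icer_txt}")
    pd.DataFrame(rows).to_csv(OUT / "base_case_cua.csv", index=False)
    print("\nNote: QALY differences of one-year sub-percentage-point uplifts "
          "sit at or below Monte Carlo resolution even pooled; the ICER "
          "point estimates are correspondingly unstable (see docs/methods.md).")


if __name__ == "__main__":
    main()
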