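#!/usr/bin/env python
"""Error and coverage of extrapolated estimands, true family specified.

With the generating exponential family fitted to every dataset, the
remaining error is pure finite-sample noise — this isolates how sample
size and follow-up limit what any model-selection procedure could
achieve.  Reports the MAPE surface of median survival, the probability a
single trial misses the truth by more than 20%, and interval coverage
(including the under-coverage of RMST evaluated at the model-estimated
horizon).

Writes: results/error_surface.csv, results/coverage.csv
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from parsurvsim.study import coverage_study, error_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    err = error_study(seed=20211218, n_sim=500)
    perf = err["performance"]
    med = perf[perf["estimand"] == "median"]
    med.to_csv(OUT / "error_surface.csv", index=False)

    print(f"truth (population fit): median {err['truth']['median']:.1f} d")
    print("\nMAPE (%) of median survival, exponential correctly specified:")
    print(
        med.pivot_table(index="n_obs", columns="pe", values="mape")
        .round(1)
        .to_string()
    )
    print("\nP(>20% error) (%):")
    print(
        (100 * med.pivot_table(index="n_obs", columns="pe",
                               values="prob_20pct_error"))
        .round(0)
        .to_string()
    )
    print(
        f"\nanchors: MAPE {err['mape_smallest_shortest_pct']:.1f}% at "
        f"(n=30, 10% events), {err['mape_smallest_full_pct']:.1f}% at "
        f"(n=30, complete), {err['mape_largest_shortest_pct']:.1f}% at "
        f"(n=500, 10% events)"
    )

    cov = coverage_study(seed=20211218, n_sim=400)
    cov["performance"].to_csv(OUT / "coverage.csv", index=False)
    pooled = cov["pooled_coverage"]
    print("\npooled 95% CI coverage by estimand:")
    for name, val in sorted(pooled.items()):
        print(f"  {name:>15}: {val:.3f}")
    print(
        "note the under-coverage of rmst_sample_th relative to "
        "rmst_pop_th: fixing the horizon at the sample's own estimate "
        "understates uncertainty."
    )


if __name__ == "__main__":
    main()
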