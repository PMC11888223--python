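#!/usr/bin/env python
"""Color-naming analysis of the seen trials.

Expected-response matrices over intensity x proportion-L bins,
heterogeneity tertile curves, and the logistic mixed-effects model
(random intercepts for subject and wavelength) with the likelihood-ratio
test of the heterogeneity term.

Reads results/study/ + threshold_measurements.tsv; writes tertiles.tsv,
glmm_odds_factors.tsv, and response_matrix_<wavelength>.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from smallspot.io import read_table, write_table
from smallspot.pipeline import color_analysis, fit_study_thresholds, trials_with_fitted_multiples
from smallspot.synthesize import read_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = read_study(args.outdir / "study")
    measurements, included, _ = fit_study_thresholds(study)
    trials = trials_with_fitted_multiples(included, measurements)
    out = color_analysis(trials)

    seen = trials[trials["seen"].astype(bool)]
    for wl, g in seen.groupby("wavelength"):
        rates = g["color_response"].value_counts(normalize=True) * 100
        print(f"{wl:.0f} nm: " + ", ".join(f"{k} {v:.1f}%" for k, v in rates.items()))

    for wl, m in out["matrices"].items():
        df = pd.DataFrame(m.rate)
        df[np.asarray(m.suppressed)] = np.nan
        write_table(
            df, args.outdir / f"response_matrix_{wl:.0f}.tsv", {"master_seed": args.seed}
        )
    write_table(out["tertiles"], args.outdir / "tertiles.tsv", {"master_seed": args.seed})

    glmm = out["glmm"]
    write_table(
        glmm.odds_factors.reset_index(names="term"),
        args.outdir / "glmm_odds_factors.tsv",
        {"master_seed": args.seed},
    )
    print(f"\nGLMM on {glmm.n_trials} seen trials ({glmm.result.method}):")
    of = glmm.odds_factors
    for term in ("log2_intensity", "heterogeneity", "s_cone_distance"):
        row = of.loc[term]
        print(
            f"    {term}: odds factor {row['odds_factor']:.2f} "
            f"(95% CI [{row['lower']:.2f}, {row['upper']:.2f}])"
        )
    print(f"    random-intercept SDs: {glmm.result.sigmas}")
    print(f"    adjusted pseudo-R2: {glmm.adjusted_r2:.3f}")
    lr = out["lr_test"]
    print(
        f"    LR test of heterogeneity: stat {lr['lr_stat']:.2f}, "
        f"delta df {lr['delta_df']}, delta AIC {lr['delta_aic']:.2f}, p = {lr['p']:.2g}"
    )


if __name__ == "__main__":
    main()
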