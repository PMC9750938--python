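#!/usr/bin/env python
"""Two-sample Mendelian randomization of a quantitative exposure on a
binary outcome.

Simulates 784 independent instruments (exposure GWAS n = 428,525, outcome
GWAS n = 893,130) with a true causal effect of 0.1 per exposure SD, 5%
reverse-causal instruments and mild balanced pleiotropy; harmonizes the
two summary-stat tables to the exposure-increasing allele; applies Steiger
and radial filtering; and runs IVW (primary), Egger, weighted median and
penalised weighted median, plus a multivariable model adjusting for a
correlated co-exposure.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from burdenmr import mr, simcohort as sc
from burdenmr import io as bio

OUT = Path("results/mr")
SEED = 17


def main() -> None:
    cfg = sc.MRSimConfig(n_instruments=784, theta=0.1, pleiotropy_sd=0.02,
                         reverse_causal_fraction=0.05, seed=SEED)
    instruments = sc.simulate_mr_instruments(cfg)
    exposure, outcome = sc.as_two_tables(instruments, seed=SEED + 1)
    OUT.mkdir(parents=True, exist_ok=True)
    bio.write_table(exposure, OUT / "exposure.tsv")
    bio.write_table(outcome, OUT / "outcome.tsv")

    harmonized, dropped = mr.harmonize(exposure, outcome)
    print(f"harmonized {len(harmonized)}/{cfg.n_instruments} instruments "
          f"({(dropped['reason'] == 'palindromic_ambiguous').sum()} ambiguous "
          f"palindromic dropped)")

    def show(suite, label):
        print(label)
        for _, row in suite.iterrows():
            line = (f"  {row['method']}: theta = {row['theta']:.3f} "
                    f"(OR per SD = {row['odds_ratio']:.3f}), p = {row['p']:.2e}")
            if np.isfinite(row["i2"]):
                line += f", I2 = {row['i2']:.1f}%"
            if row["method"] == "Egger":
                line += f", intercept p = {row['intercept_p']:.2f}"
            print(line)

    # naive estimators on the contaminated set: the reverse-causal
    # instruments carry large outcome effects and drag IVW/Egger upward,
    # while the weighted median stays near the truth
    suite_all = mr.mr_suite(harmonized, seed=SEED + 2).assign(
        instrument_set="harmonized"
    )
    show(suite_all, f"estimates on all {len(harmonized)} harmonized "
                    f"instruments (true theta = 0.1/SD):")

    # Steiger removes every reverse-causal instrument, but the raw r2
    # comparison also trims valid instruments with noisy outcome effects,
    # truncating |beta_y| and deflating IVW: reported as sensitivity only
    retained, reverse_ids, _ = mr.steiger_filter(harmonized)
    print(f"Steiger removed {len(reverse_ids)} instruments with stronger "
          f"outcome than exposure association "
          f"(simulated reverse-causal: {int(instruments['reverse'].sum())}); "
          f"IVW after Steiger: theta = {mr.ivw(retained).theta:.3f} "
          f"(over-trims noisy valid instruments)")

    # radial outlier exclusion removes the contaminants by their Q
    # contribution without truncating the noise distribution
    radial_kept, radial_ids = mr.radial_filter(harmonized)
    suite_radial = mr.mr_suite(radial_kept, seed=SEED + 2).assign(
        instrument_set="radial_filtered"
    )
    show(suite_radial, f"after radial exclusion of {len(radial_ids)} outliers:")
    suite = pd.concat([suite_all, suite_radial], ignore_index=True)
    bio.write_table(suite, OUT / "mr_results.tsv")

    # multivariable MR against a correlated co-exposure (height-like)
    rng = np.random.default_rng(SEED + 3)
    mv = radial_kept.copy()
    mv["beta_height"] = 0.4 * mv["beta_x"] + rng.normal(0, 0.02, len(mv))
    res = mr.mvmr(mv, exposure_cols=("beta_x", "beta_height"))
    print(f"  MVMR direct effect (adjusting the co-exposure): "
          f"theta = {res.theta:.3f}, p = {res.p:.2e}")
    print(f"wrote {OUT}/mr_results.tsv")


if __name__ == "__main__":
    sys.exit(main())
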