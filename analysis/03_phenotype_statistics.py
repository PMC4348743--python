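#!/usr/bin/env python
"""Descriptive phenotype statistics: geometric group summaries, two-way
ANOVA (cohort x exposure, log2 scale), Tukey HSD between exposure groups,
and pre/post-exposure Pearson correlations."""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dotox import io, phenostats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = parser.parse_args()
    out = args.outdir
    ph = io.read_phenotypes(out / "phenotypes.csv")

    gs = phenostats.group_summaries(ph["post_bm_mnret"], ph["exposure_ppm"])
    gs.to_csv(out / "group_summaries.csv", index=False)
    print("bone-marrow MN-RET per 1,000 (geometric mean, +/-2 log-SD interval):")
    for _, r in gs.iterrows():
        print(
            f"  {r['group']:>6.1f} ppm: {r['geometric_mean']:.2f} "
            f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), n={int(r['n'])}"
        )

    anova = phenostats.two_way_anova_log(
        ph["post_bm_mnret"], ph["cohort"], ph["exposure_ppm"]
    )
    print(
        f"two-way ANOVA (log2): exposure p = {anova['p_exposure']:.2e}, "
        f"cohort p = {anova['p_cohort']:.2f}, "
        f"interaction p = {anova['p_interaction']:.2f}"
    )

    tukey = phenostats.tukey_hsd(
        np.log(ph["post_bm_mnret"].to_numpy()), ph["exposure_ppm"]
    )
    tukey.to_csv(out / "tukey.csv", index=False)
    print("Tukey HSD (selected):")
    for _, r in tukey.iterrows():
        print(f"  {r['group1']} vs {r['group2']} ppm: p_adj = {r['p_adj']:.3g}")

    corr = phenostats.correlate_pre_post(
        ph["pre_pb_mnret"], ph["post_pb_mnret"], ph["exposure_ppm"]
    )
    corr.to_csv(out / "pre_post_correlation.csv", index=False)
    print("pre/post blood MN-RET Pearson r by exposure group:")
    print("  " + ", ".join(f"{g:.0f} ppm: {r:.2f}" for g, r in zip(corr["group"], corr["r"])))


if __name__ == "__main__":
    main()
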