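"""Demographic and genotyping statistics of the cohort.

Hardy-Weinberg equilibrium chi-square on the genotype counts, Fisher's
exact test on the gender split, and a Wilcoxon-Mann-Whitney test on age.
"""

import argparse
import json
from pathlib import Path

from scnet import io as scio
from scnet.pipeline import cohort_statistics

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort_stats.json"))
    args = ap.parse_args()

    cohort = scio.read_thickness_table(args.cohort)
    stats = cohort_statistics(cohort)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(stats, indent=2))

    print(f"HWE chi2 = {stats['hwe_chi2']:.2f} "
          f"(p = {stats['hwe_p_df1']:.3f} at df=1, {stats['hwe_p_df2']:.3f} at df=2)")
    print(f"Val/Val fraction = {stats['valval_percent']:.1f}%")
    print(f"gender Fisher p = {stats['gender_fisher_p']}")
    print(f"age rank-sum p = {stats['age_ranksum_p']:.3f}")
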