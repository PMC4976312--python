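"""Case-control association of low vs high CNV copy number.

Part 1 re-analyzes the published low/high copy contingency counts of the
discovery, replication and pooled cohorts (Fisher two-tailed, sample and
conditional-MLE odds ratios, Woolf 95% CI).  Part 2 runs the same battery,
plus the five-category exact test, age-adjusted logistic regression and the
onset analyses, on the simulated cohort from step 01.
"""

import argparse
import json
from pathlib import Path

from nsfcnv import defaults, io
from nsfcnv.association import (
    copy_category_table,
    dichotomize,
    fisher_exact_2x2,
    fisher_exact_2xK,
    logistic_adjust,
    onset_analysis,
)


def published_reanalysis() -> dict:
    out = {}
    for arm, counts in defaults.COHORT_COUNTS.items():
        table = [list(counts["cases"]), list(counts["controls"])]
        res = fisher_exact_2x2(table)
        case_pct = 100 * counts["cases"][0] / sum(counts["cases"])
        ctrl_pct = 100 * counts["controls"][0] / sum(counts["controls"])
        out[arm] = {
            "case_low_pct": round(case_pct, 1),
            "control_low_pct": round(ctrl_pct, 1),
            "p_two_tailed": res.p_value,
            "or_sample": res.or_sample,
            "or_cmle": res.or_cmle,
            "ci_95": [res.ci_low, res.ci_high],
        }
        print(f"{arm:12s} low-copy {case_pct:.0f}% cases vs {ctrl_pct:.0f}% controls; "
              f"OR {res.or_sample:.2f} [{res.ci_low:.2f}-{res.ci_high:.2f}], "
              f"CMLE {res.or_cmle:.3f}, P = {res.p_value:.2g}")
    return out


def simulated_analysis(cohort_dir: Path, seed: int) -> dict:
    subjects = io.read_subject_tsv(cohort_dir / "genotypes.tsv")
    table = dichotomize(subjects)
    res = fisher_exact_2x2(table)
    import numpy as np

    exact_k = fisher_exact_2xK(copy_category_table(subjects),
                               rng=np.random.default_rng([seed, 97]))
    adjusted = logistic_adjust(subjects, covariates=("age",))
    onset = onset_analysis(subjects)
    print(f"\nsimulated     OR {res.or_sample:.2f} "
          f"[{res.ci_low:.2f}-{res.ci_high:.2f}], P = {res.p_value:.2g}; "
          f"5-category exact P = {exact_k.p_value:.2g} ({exact_k.method})")
    print(f"age-adjusted OR {adjusted['or_adjusted']:.2f}, P = {adjusted['p_value']:.2g}")
    print(f"onset: median lapse low {onset['median_onset_low']:.2f} y vs "
          f"high {onset['median_onset_high']:.2f} y, MW P = {onset['mann_whitney_p']:.2g}; "
          f"early-onset one-tailed P = {onset['one_tailed_fisher'].p_value:.2g}")
    return {
        "table_low_high": table.counts.tolist(),
        "p_two_tailed": res.p_value,
        "or_sample": res.or_sample,
        "ci_95": [res.ci_low, res.ci_high],
        "p_five_categories": exact_k.p_value,
        "age_adjusted": adjusted,
        "onset": {
            "mann_whitney_p": onset["mann_whitney_p"],
            "one_tailed_p": float(onset["one_tailed_fisher"].p_value),
            "early_late_table": onset["early_late_table"].counts.tolist(),
        },
    }


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/association.json"))
    args = parser.parse_args()

    report = {"published_counts": published_reanalysis()}
    if (args.cohort_dir / "genotypes.tsv").exists():
        report["simulated_cohort"] = simulated_analysis(args.cohort_dir, args.seed)
    else:
        print("(no simulated cohort found; run analysis/01_simulate_cohort.py first)")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2))
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
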