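"""Relate transcript expression to CNV copy number (dosage trend).

Simulates the expression study (45 donors) and, per transcript, computes
the Kruskal-Wallis test across copy groups 2-6, the low-vs-high
Mann-Whitney test, the high/low fold change, the Spearman rank correlation
with copies, and the OLS slope.  CNV-internal transcripts are generated
with positive dosage slopes (calibrated to 2.1- and 1.5-fold contrasts);
CNV-external transcripts are flat.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from nsfcnv.expression import dosage_trend
from nsfcnv.synthetic import load_scenario_config, simulate_expression, simulate_population


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-donors", type=int, default=45)
    parser.add_argument("--out", type=Path, default=Path("results/expression_trends.json"))
    args = parser.parse_args()

    cfg = load_scenario_config(seed=args.seed, n_individuals=args.n_donors)
    individuals = simulate_population(cfg)
    samples = simulate_expression(individuals, cfg)

    report = {}
    print(f"{'transcript':>18s} {'fold':>6s} {'rho':>6s} {'KW P':>9s} {'MW P':>9s}")
    for transcript in sorted(cfg.dosage_slope):
        res = dosage_trend(samples, transcript_id=transcript)
        report[transcript] = asdict(res)
        print(f"{transcript:>18s} {res.fold_change:6.2f} {res.spearman_rho:6.2f} "
              f"{res.kruskal_p:9.2g} {res.mw_low_high_p:9.2g}")
    print("(internal transcripts should show fold > 1 and positive rho; "
          "external ones fold ~ 1 and rho ~ 0)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
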