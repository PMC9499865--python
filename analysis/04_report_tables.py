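#!/usr/bin/env python
"""Emit the summary report tables.

Baseline characteristics (counts and percentages per group), early adverse
events (any grade / grade >= 3 from dose 1 until 28 d after the last dose)
and immune-related adverse events per term, each with exact binomial 95%
confidence intervals, formatted "k (percent, lower-upper)".

Writes results/analysis/report/report_tables.json.
"""

import argparse
import json
from pathlib import Path

from cytovax.pipeline import RunConfig, run_pipeline


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--cohort", default="results/analysis/cohort")
    parser.add_argument("--out", default="results/analysis")
    args = parser.parse_args()

    cfg = RunConfig(
        seed=args.seed, out_dir=args.out, input_dir=args.cohort,
        stages=("simulate", "report"),
    )
    run_pipeline(cfg)

    tables = json.loads(
        (Path(args.out) / "report" / "report_tables.json").read_text()
    )
    print("early adverse events (vaccinated):")
    for k, v in tables["early_adverse_events"].items():
        print(f"  {k}: {v}")
    print("immune-related adverse events, k (percent, 95% CI):")
    for term, row in tables["immune_related_adverse_events"].items():
        cells = "  ".join(f"{g}={v}" for g, v in row.items())
        print(f"  {term}: {cells}")


if __name__ == "__main__":
    main()
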