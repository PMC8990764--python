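#!/usr/bin/env python
"""Assemble the multifunctional evaluation.

Groups the fitted relative mixture effects into the four service classes
(yield, resource-use efficiency, crop protection, quality), appends lodging
as absolute per-system means, classifies each entry by the 4C pLER quadrants
against the sowing-density thresholds, and tabulates protein-based quality
promotions.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mixtrial import inference, report  # noqa: E402
from mixtrial.indices import (  # noqa: E402
    build_index_table, lodging_frame, rme_long_table,
)
from mixtrial.io import read_plot_table  # noqa: E402
from mixtrial.model import default_design  # noqa: E402


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=pathlib.Path,
                        default=pathlib.Path("results/plot_table.tsv"))
    parser.add_argument("--out-dir", type=pathlib.Path,
                        default=pathlib.Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    design = default_design()
    records = read_plot_table(args.table, design)
    index_table = build_index_table(records, design)
    rme_long = rme_long_table(records, design)

    for season in design.seasons:
        tag = season.replace("/", "-")
        rme_means = inference.fit_rme_model(rme_long, season=season)
        lodging = lodging_frame(records, season)
        lodging_means = (lodging.groupby("system")["value"].mean()
                         .rename("estimate").reset_index())
        service = report.service_report(rme_means, design,
                                        lodging_means=lodging_means)
        service.to_csv(args.out_dir / f"service_report_{tag}.tsv", sep="\t",
                       index=False)
        by_class = service[service.kind == "rme"].groupby("service_class")
        summary = ", ".join(f"{k}: {int(g.effect_present.sum())}/{len(g)}"
                            for k, g in by_class)
        print(f"{season} service classes with CI-backed effects — {summary}")

        verdicts = report.classify_4c(index_table, design, season=season)
        pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(
            args.out_dir / f"four_c_{tag}.tsv", sep="\t", index=False)
        quads = pd.Series([v.quadrant for v in verdicts]).value_counts()
        print(f"{season} 4C quadrants: {quads.to_dict()}")

        promo = report.quality_promotion_table(index_table, season=season)
        promo.to_csv(args.out_dir / f"quality_promotion_{tag}.tsv", sep="\t",
                     index=False)
        print(f"{season}: {int(promo.promoted.sum())}/{len(promo)} entries "
              "promoted to a higher baking-quality class in mixture")


if __name__ == "__main__":
    main()
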