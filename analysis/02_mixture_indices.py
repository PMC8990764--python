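#!/usr/bin/env python
"""Derive the mixture-performance indices.

Reads the plot table from results/ (run 01_simulate_trial.py first, or point
--table at your own data), computes the per-block index table (yield gain,
LER/pLER, AUNGLA, foot-disease index, harvest index, days to heading,
quality classes) and the per-plot relative-mixture-effect table, and prints
the season summaries.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mixtrial.indices import (  # noqa: E402
    build_index_table, mixture_density_summary, rme_long_table,
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
    total, pct_w, pct_p = mixture_density_summary(design)
    print(f"mixture sowing density: {total:.0f} seeds/m2 "
          f"({pct_w}% of the wheat, {pct_p}% of the pea pure stand)")

    index_table = build_index_table(records, design)
    index_path = args.out_dir / "index_table.tsv"
    index_table.to_csv(index_path, sep="\t", index=False)
    for season, grp in index_table.groupby("season"):
        print(f"{season}: mean YG {grp.yg_abs.mean():+.2f} t/ha "
              f"({grp.yg_rel.mean():+.1f}%), mean LER {grp.ler.mean():.2f} "
              f"(pLER wheat {grp.pler_wheat.mean():.2f}, "
              f"pea {grp.pler_pea.mean():.2f})")
    print(f"index table ({len(index_table)} block x entry rows) "
          f"-> {index_path}")

    rme_long = rme_long_table(records, design)
    rme_path = args.out_dir / "rme_long.tsv"
    rme_long.to_csv(rme_path, sep="\t", index=False)
    print(f"per-plot RMEs ({len(rme_long)} rows, "
          f"{rme_long.response.nunique()} responses) -> {rme_path}")


if __name__ == "__main__":
    main()
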