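#!/usr/bin/env python
"""GGE and genotype-by-trait biplot coordinates.

Builds entry x environment tables (environment = season:system) for wheat
yield and protein, decomposes them (environment-centered SVD, symmetric
singular-value partitioning), exports scores, explained variances and
mean-vs-stability rankings, and runs the genotype-by-trait analysis per
season.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mixtrial import gge  # noqa: E402
from mixtrial.indices import build_index_table  # noqa: E402
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

    for response in ("wheat_yield", "protein"):
        table = gge.default_environment_table(records, response)
        result = gge.gge_decompose(table)
        stability = gge.mean_vs_stability(result)
        result.genotype_scores.reset_index().to_csv(
            args.out_dir / f"gge_{response}_genotypes.tsv", sep="\t",
            index=False)
        result.environment_scores.reset_index().to_csv(
            args.out_dir / f"gge_{response}_environments.tsv", sep="\t",
            index=False)
        stability.reset_index().to_csv(
            args.out_dir / f"gge_{response}_stability.tsv", sep="\t",
            index=False)
        top = stability.sort_values("mean_rank").index[0]
        steadiest = stability.sort_values("stability_rank").index[0]
        print(f"{response}: first two components explain "
              f"{result.explained[:2].sum():.0f}% of G+GE variation; "
              f"best mean performance {top!r}, most stable {steadiest!r}")

    index_table = build_index_table(records, design)
    for season in design.seasons:
        tag = season.replace("/", "-")
        trait_table = gge.genotype_trait_table(index_table, season)
        result = gge.gt_decompose(trait_table)
        cos = gge.trait_cosines(result)
        cos.to_csv(args.out_dir / f"gt_trait_cosines_{tag}.tsv", sep="\t")
        print(f"{season} genotype-by-trait: {trait_table.shape[1]} traits, "
              f"first two components {result.explained[:2].sum():.0f}%; "
              f"cos(pLER_pea, protein) = "
              f"{cos.loc['pler_pea', 'protein_mix']:.2f}")


if __name__ == "__main__":
    main()
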