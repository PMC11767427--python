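#!/usr/bin/env python
"""Co-expression modules and their correlation with clinical covariates.

WGCNA-style soft-threshold/TOM clustering assigns module colors; each
module's eigen-metabolite and each RF-style biomarker is correlated with
the numeric clinical covariates (Pearson, p < 0.05 flagged).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import osteowarn as ow
from osteowarn.module_trait import eigen_metabolite, trait_correlations, wgcna_modules


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/module_trait"))
    args = parser.parse_args()

    cohort, truth = ow.generate_cohort(ow.SimConfig(seed=args.seed))
    cohort, _ = ow.filter_missing(cohort)
    colors = wgcna_modules(cohort.abundance)
    traits = cohort.metadata.select_dtypes(include=[np.number])

    args.out.mkdir(parents=True, exist_ok=True)
    colors.rename("module_color").rename_axis("metabolite").reset_index().to_csv(
        args.out / "modules.tsv", sep="\t", index=False)

    eigens = {}
    for color in sorted(set(colors) - {"grey"}):
        members = colors.index[colors == color].tolist()
        eigens[color] = eigen_metabolite(cohort.abundance, members)
    if eigens:
        table = trait_correlations(pd.DataFrame(eigens), traits)
        table.to_csv(args.out / "module_trait.tsv", sep="\t", index=False)
        sig = table[table["significant"]]
        print(f"modules found: {sorted(set(colors) - {'grey'})} "
              f"(grey pool: {(colors == 'grey').sum()})")
        for color in eigens:
            members = set(colors.index[colors == color])
            overlap = members & set(truth.domain_members)
            print(f"  {color}: {len(members)} metabolites, "
                  f"{len(overlap)} in the planted domain")
        print(f"significant module-trait cells: {len(sig)}/{len(table)}")
    else:
        print("no module above min_size; all metabolites grey")


if __name__ == "__main__":
    main()
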