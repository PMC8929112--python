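#!/usr/bin/env python
"""Occurrence rate of SNPs (ORS) for each NLR, group and region.

Reports per-group SNP totals, the fraction of NLRs with no SNPs in genic
versus 2 kb-promoter regions, and the genes whose variation is private to
one group.
"""

import pandas as pd
from common import RUN_DIR, stage_config

from nlr_atlas.pipeline import run
from nlr_atlas.popdiv import no_snp_fraction, private_group_fraction


def main():
    run(stage_config("ors"))
    table = pd.read_csv(RUN_DIR / "ors.tsv", sep="\t", comment="#")
    totals = pd.read_csv(RUN_DIR / "group_snp_totals.tsv", sep="\t",
                         comment="#")
    print(f"ors -> {RUN_DIR / 'ors.tsv'}")
    print("  group SNP totals per chromosome:")
    print(totals.to_string(index=False))
    for group in table.group.unique():
        sub = table[table.group == group]
        print(f"  {group}: no-SNP NLR fraction genic "
              f"{no_snp_fraction(sub, [group], 'genic'):.2f}% / promoter "
              f"{no_snp_fraction(sub, [group], 'promoter'):.2f}%; "
              f"mean genic ORS "
              f"{sub[sub.region == 'genic'].ors.mean():.4f}")
    groups = list(table.group.unique())
    if len(groups) >= 2:
        pct = private_group_fraction(table, groups[0], groups[1:])
        print(f"  NLRs with SNPs private to {groups[0]}: {pct:.2f}%")


if __name__ == "__main__":
    main()
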