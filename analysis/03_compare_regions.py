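#!/usr/bin/env python
"""Cross-region comparison of flagged proteins against the ground truth.

Reads the per-region protein summaries from results/plf/, reports every
Venn partition, the region-exclusive sets and the proteins unique to
fingerprinting (vs the abundance-significant stand-in list), and checks
them against the implanted effects. Writes results/region_comparison.csv.
"""

from pathlib import Path

import pandas as pd

import plf

ROOT = Path(__file__).resolve().parent.parent / "results"
REGIONS = ("posterior", "left_lateral", "anterior")


def main() -> None:
    flagged = {}
    for region in REGIONS:
        df = pd.read_csv(ROOT / "plf" / f"{region}_proteins.csv")
        flagged[region] = set(df.loc[df["flagged"], "accession"])
    sets = plf.intersect_regions(flagged)

    truth = pd.read_csv(ROOT / "data" / "true_effects.csv")
    tissue_wide = set(
        truth.loc[(truth["fold_change"] < 1) & (truth["regions"] == "all"),
                  "accession"])
    rows = []
    for cell, members in sorted(sets.venn_cells().items(),
                                key=lambda kv: tuple(sorted(kv[0]))):
        label = "&".join(sorted(cell))
        rows.append({"regions": label, "count": len(members),
                     "accessions": ";".join(sorted(members))})
        print(f"{label}: {len(members)}")
    print(f"\nshared in all regions: {sorted(sets.intersection)}")
    print(f"implanted tissue-wide suppressions recovered there: "
          f"{len(sets.intersection & tissue_wide)}/{len(tissue_wide)}")
    for region in REGIONS:
        print(f"exclusive to {region}: {sorted(sets.exclusive(region))}")

    abundance = set((ROOT / "data" / "abundance_significant.txt")
                    .read_text().split())
    unique = plf.plf_unique(sets.union, abundance)
    shift_only = set(truth.loc[truth["fold_change"] > 1, "accession"])
    print(f"\nflagged union {len(sets.union)}, unique to fingerprinting "
          f"{len(unique)}; pure abundance-shift proteins correctly unflagged: "
          f"{len(shift_only - sets.union)}/{len(shift_only)}")

    out = ROOT / "region_comparison.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
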