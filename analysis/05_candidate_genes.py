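#!/usr/bin/env python
"""Candidate genes inside the mango fruit-weight QTL regions.

Queries the packaged mango reference (gene table plus the LG4/LG7 fruit-weight
region bounds) with the 1-based closed-interval start-in-region rule and
writes one candidate list per region under results/.
"""

import argparse
from pathlib import Path

from crosshap import annotation


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    genes, regions = annotation.load_mango_fruit_weight_tables()
    for region in regions:
        hits = annotation.genes_in_region(genes, region)
        safe = region.region_id.replace(":", "_")
        path = args.results / f"candidate_genes_{safe}.tsv"
        hits.to_csv(path, sep="\t", index=False)
        print(f"{region.lg} [{region.start_bp:,}-{region.end_bp:,}]: "
              f"{len(hits)} candidate genes -> {path}")
        print("  first:", hits["annotation"].iloc[0])
        print("  last: ", hits["annotation"].iloc[-1])


if __name__ == "__main__":
    main()
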