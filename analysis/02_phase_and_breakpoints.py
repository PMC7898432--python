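#!/usr/bin/env python
"""Classify SNP informativeness, phase both parents, call breakpoints.

Reads results/run/genotypes.vcf, classifies each SNP from the parental calls,
phases the one-parent-heterozygous SNPs by progeny co-segregation and writes
per-parent transmission matrices plus recombination-breakpoint intervals.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosshap import markers, phasing


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/run"))
    ap.add_argument("--min-run", type=int, default=3)
    args = ap.parse_args()
    out = args.results

    gm = markers.read_genotypes(out / "genotypes.vcf")
    classes = markers.classify_markers(gm)
    counts = pd.Series([c.value for c in classes]).value_counts()
    print("marker classes:")
    print(counts.to_string())

    frames = []
    for parent in ("maternal", "paternal"):
        tm = phasing.phase_parent(phasing.raw_transmission(gm, classes, parent))
        phasing.write_transmissions_tsv(tm, out / f"transmissions_{parent}.tsv")
        frames.append(phasing.detect_breakpoints(tm, args.min_run))
        print(f"{parent}: {len(tm.markers)} informative SNPs phased, "
              f"{int(tm.low_confidence.sum())} low-confidence")
    bps = pd.concat(frames, ignore_index=True)
    bps.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
    per_ind = bps.groupby("individual").size()
    print(f"{len(bps)} breakpoints called "
          f"(median {per_ind.median():.0f} per individual) -> {out}")


if __name__ == "__main__":
    main()
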