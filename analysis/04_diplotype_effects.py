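#!/usr/bin/env python
"""Region diplotypes, recombinant exclusion, and ANOVA/Tukey effect tests.

For each QTL region, assigns every individual the pair of parental haplotypes
it carries across the region (TA1KP1 ... TA2KP2 with the default prefixes),
reports in-region recombinants, and tests fruit-weight differences among
diplotype groups with one-way ANOVA and Tukey HSD.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosshap import association, diplotypes, markers, phasing


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/run"))
    ap.add_argument("--prefixes", default="TA,KP")
    args = ap.parse_args()
    out = args.results
    prefixes = tuple(args.prefixes.split(","))

    tms = {p: phasing.read_transmissions_tsv(out / f"transmissions_{p}.tsv", p)
           for p in ("maternal", "paternal")}
    pheno = markers.read_phenotypes(out / "phenotypes.tsv", tms["maternal"].progeny)
    reg_df = pd.read_csv(out / "regions.tsv", sep="\t", dtype={"lg": str})

    for row in reg_df.itertuples():
        region = association.QTLRegion(row.region_id, row.lg, int(row.start_bp),
                                       int(row.end_bp), [], float(row.min_p))
        calls = diplotypes.call_region_diplotypes(tms, region)
        calls["rendered"] = [diplotypes.render_call(c, prefixes)
                             for c in calls["call"]]
        safe = region.region_id.replace(":", "_")
        calls.to_csv(out / f"diplotypes_{safe}.tsv", sep="\t", index=False,
                     float_format="%.4g")
        report = diplotypes.diplotype_effect_test(calls, pheno, prefixes)
        (out / f"effects_{safe}.json").write_text(report.to_json() + "\n")

        print(f"\n== {region.region_id} ==")
        print(f"{report.n_recombinant} in-region recombinants excluded, "
              f"{report.n_unknown} unknown")
        print(report.groups.to_string(index=False))
        if report.f_stat is not None:
            print(f"ANOVA F({report.df_between},{report.df_within}) = "
                  f"{report.f_stat:.2f}, p = {report.p_value:.3g}")
            print(report.tukey.to_string(index=False))
        else:
            print(f"no test: {report.reason}")
    print(f"\n-> {out}")


if __name__ == "__main__":
    main()
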