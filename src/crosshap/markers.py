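"""Genotype containers, marker informativeness classes, and genotype/phenotype I/O.

In a pseudo-testcross design the mapping information lives in markers that are
heterozygous in exactly one parent and homozygous in the other: such a marker
segregates 1:1 in the F1 and identifies which of the informative parent's two
haplotypes each progeny inherited.  This module loads unphased diploid calls
(VCF or TSV), holds them in a :class:`GenotypeMatrix`, and classifies every SNP
into one of the five :class:`MarkerClass` states from the two parental calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = "."

__all__ = [
    "MISSING",
    "MarkerClass",
    "GenotypeMatrix",
    "classify_markers",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "write_phenotypes_tsv",
]


class MarkerClass(Enum):
    """Pseudo-testcross informativeness class of a SNP, from the parents only."""

    MATERNAL_INFORMATIVE = "maternal_informative"  # mother het, father hom
    PATERNAL_INFORMATIVE = "paternal_informative"  # father het, mother hom
    BOTH_HET = "both_het"                          # ambiguous transmission
    UNINFORMATIVE = "uninformative"                # both parents homozygous
    UNUSABLE = "unusable"                          # parent call missing / >2 alleles


@dataclass
class GenotypeMatrix:
    """Unphased diploid calls for two parents and their F1 progeny.

    Parameters
    ----------
    markers : DataFrame indexed by marker id with columns ``lg`` (str) and
        ``bp`` (int, 1-based); rows sorted by (lg, bp) with bp strictly
        increasing within each linkage group.
    individuals : ids in column order of ``calls``; must contain the two
        parent ids.
    calls : array of shape (n_markers, n_individuals, 2), single-character
        alleles with ``"."`` for missing.  Both alleles of a call are missing
        together.
    mother_id, father_id : ids of the two parents within ``individuals``.
    """

    markers: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray
    mother_id: str
    father_id: str
    _col: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for pid in (self.mother_id, self.father_id):
            if pid not in self.individuals:
                raise ValueError(f"parent {pid!r} not among individuals")
        if self.calls.shape != (len(self.markers), len(self.individuals), 2):
            raise ValueError("calls shape does not match markers x individuals")
        for lg, sub in self.markers.groupby("lg", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise ValueError(f"bp positions not strictly increasing in {lg}")
        self._col = {ind: j for j, ind in enumerate(self.individuals)}

    @property
    def progeny(self) -> list[str]:
        return [i for i in self.individuals if i not in (self.mother_id, self.father_id)]

    def column(self, individual: str) -> np.ndarray:
        """Calls for one individual, shape (n_markers, 2)."""
        return self.calls[:, self._col[individual], :]

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality of metadata and calls; unphased calls are unordered pairs."""
        return (
            self.markers.equals(other.markers)
            and self.individuals == other.individuals
            and self.mother_id == other.mother_id
            and self.father_id == other.father_id
            and np.array_equal(np.sort(self.calls, axis=2),
                               np.sort(other.calls, axis=2))
        )


def _is_missing(call: np.ndarray) -> bool:
    return call[0] == MISSING or call[1] == MISSING


def classify_markers(gm: GenotypeMatrix) -> pd.Series:
    """Classify every marker from the two parental calls alone.

    Returns a Series of :class:`MarkerClass` indexed like ``gm.markers``.
    Markers with more than two distinct alleles across the two parents are
    UNUSABLE (SNP assumption violated) and counted in a single warning.
    """
    mother = gm.column(gm.mother_id)
    father = gm.column(gm.father_id)
    out = np.empty(len(gm.markers), dtype=object)
    n_multi = 0
    for i in range(len(gm.markers)):
        m, f = mother[i], father[i]
        if _is_missing(m) or _is_missing(f):
            out[i] = MarkerClass.UNUSABLE
            continue
        alleles = {m[0], m[1], f[0], f[1]}
        if len(alleles) > 2:
            out[i] = MarkerClass.UNUSABLE
            n_multi += 1
            continue
        m_het = m[0] != m[1]
        f_het = f[0] != f[1]
        if m_het and not f_het:
            out[i] = MarkerClass.MATERNAL_INFORMATIVE
        elif f_het and not m_het:
            out[i] = MarkerClass.PATERNAL_INFORMATIVE
        elif m_het and f_het:
            out[i] = MarkerClass.BOTH_HET
        else:
            out[i] = MarkerClass.UNINFORMATIVE
    if n_multi:
        warnings.warn(f"{n_multi} markers with >2 parental alleles set UNUSABLE")
    return pd.Series(out, index=gm.markers.index, name="marker_class")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal unphased VCF (GT only), CHROM = linkage group, POS = bp."""
    path = Path(path)
    mk = gm.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for lg in mk["lg"].unique():
            fh.write(f"##contig=<ID={lg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##crosshap_mother={gm.mother_id}\n")
        fh.write(f"##crosshap_father={gm.father_id}\n")
        cols = "\t".join(gm.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for i, (mid, row) in enumerate(mk.iterrows()):
            site = gm.calls[i]
            observed = [a for a in site.ravel() if a != MISSING]
            if not observed:
                ref, alts = "N", ["."]
            else:
                ref = observed[0]
                alts = sorted({a for a in observed if a != ref}) or ["."]
            index = {ref: 0, **{a: j + 1 for j, a in enumerate(alts) if a != "."}}
            gts = []
            for call in site:
                if call[0] == MISSING:
                    gts.append("./.")
                else:
                    a, b = sorted(index[c] for c in call)
                    gts.append(f"{a}/{b}")
            fh.write(
                f"{row['lg']}\t{row['bp']}\t{mid}\t{ref}\t{','.join(alts)}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path: Path, mother_id: str | None, father_id: str | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    if mother_id is None or father_id is None:
        header = vcf.raw_header
        for line in header.splitlines():
            if line.startswith("##crosshap_mother=") and mother_id is None:
                mother_id = line.split("=", 1)[1]
            if line.startswith("##crosshap_father=") and father_id is None:
                father_id = line.split("=", 1)[1]
    if mother_id is None or father_id is None:
        raise ValueError("mother/father ids must be given or recorded in the VCF header")
    ids, lgs, bps, rows = [], [], [], []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        row = np.full((len(individuals), 2), MISSING, dtype="<U1")
        for j, (a1, a2, *_ ) in enumerate(var.genotypes):
            if a1 >= 0 and a2 >= 0:
                row[j, 0] = alleles[a1]
                row[j, 1] = alleles[a2]
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        lgs.append(var.CHROM)
        bps.append(var.POS)
        rows.append(row)
    markers = pd.DataFrame({"lg": lgs, "bp": bps}, index=pd.Index(ids, name="marker"))
    calls = np.stack(rows) if rows else np.empty((0, len(individuals), 2), dtype="<U1")
    return GenotypeMatrix(markers, individuals, calls, mother_id, father_id)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """TSV dialect: marker, lg, bp, then one ``A/G`` (or ``./.``) column per individual."""
    mk = gm.markers
    data = {"marker": mk.index, "lg": mk["lg"].to_numpy(), "bp": mk["bp"].to_numpy()}
    for j, ind in enumerate(gm.individuals):
        col = gm.calls[:, j, :]
        data[ind] = [f"{a}/{b}" for a, b in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path, mother_id: str | None, father_id: str | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"lg": str})
    meta_cols = ["marker", "lg", "bp"]
    individuals = [c for c in df.columns if c not in meta_cols]
    if mother_id is None or father_id is None:
        raise ValueError("mother/father ids are required for TSV input")
    calls = np.full((len(df), len(individuals), 2), MISSING, dtype="<U1")
    for j, ind in enumerate(individuals):
        pairs = df[ind].astype(str).str.split("/", expand=True)
        a = pairs[0].to_numpy(dtype="<U1")
        b = pairs[1].to_numpy(dtype="<U1")
        ok = (a != MISSING) & (b != MISSING)
        calls[ok, j, 0] = a[ok]
        calls[ok, j, 1] = b[ok]
    markers = pd.DataFrame(
        {"lg": df["lg"].to_numpy(), "bp": df["bp"].astype(int).to_numpy()},
        index=pd.Index(df["marker"], name="marker"),
    )
    return GenotypeMatrix(markers, individuals, calls, mother_id, father_id)


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    mother_id: str | None = None,
    father_id: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dialect written by this package.

    ``fmt`` is inferred from the suffix when omitted (``.vcf`` vs ``.tsv``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, mother_id, father_id)
    if fmt == "tsv":
        return _read_tsv(path, mother_id, father_id)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno[["individual", "trait"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, known_individuals=None) -> pd.DataFrame:
    """Read ``individual<TAB>trait``; rows whose id is unknown are dropped and counted.

    Returns a DataFrame with columns ``individual`` (str) and ``trait`` (float).
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    if df["individual"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    df["trait"] = df["trait"].astype(float)
    if known_individuals is not None:
        known = set(known_individuals)
        keep = df["individual"].isin(known)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.warning("dropped %d phenotype rows with unknown ids", n_dropped)
        df = df[keep].reset_index(drop=True)
        df.attrs["n_dropped"] = n_dropped
    return df
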