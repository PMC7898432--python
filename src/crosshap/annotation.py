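"""Candidate-gene extraction: which annotated genes lie inside a QTL region.

Gene records come either from a GFF3 annotation (via gffutils) or from a
3-column TSV (lg, bp, annotation) of the kind produced when a published gene
table lists one representative position per gene.  Membership uses 1-based
closed intervals.  Because single-position tables carry no gene extent, the
default rule is *start-in-region*; for full GFF3 input an *overlap* rule is
also available.

The package ships the curated gene table and region bounds for the mango
fruit-weight QTLs on LG4 and LG7 of the 'Tommy Atkins' x 'Kensington Pride'
population as a worked reference dataset.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .association import QTLRegion

__all__ = [
    "load_gene_table",
    "load_genes_gff3",
    "genes_in_region",
    "load_mango_fruit_weight_tables",
]

_COLUMNS = ["gene_id", "lg", "start", "end", "annotation"]


def load_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV (lg, bp, annotation) into the gene-record frame.

    ``end`` is set equal to ``start`` (point records); ``gene_id`` is derived
    from the annotation's leading symbol when present, else lg:bp.
    """
    df = pd.read_csv(path, sep="\t", dtype={"lg": str})
    if (df["bp"] < 1).any():
        raise ValueError("gene positions must be >= 1 (1-based)")
    sym = df["annotation"].str.extract(r"^([^:]{1,20}):", expand=False)
    gene_id = sym.fillna(df["lg"] + ":" + df["bp"].astype(str))
    out = pd.DataFrame({
        "gene_id": gene_id,
        "lg": df["lg"],
        "start": df["bp"].astype(int),
        "end": df["bp"].astype(int),
        "annotation": df["annotation"],
    })
    return out[_COLUMNS]


def load_genes_gff3(path: str | Path, seqid_to_lg: dict[str, str] | None = None,
                    feature_type: str = "gene") -> pd.DataFrame:
    """Load gene features from a GFF3 file into the gene-record frame.

    ``seqid_to_lg`` maps GFF seqids onto linkage-group names (identity by
    default).  The annotation string is taken from the ``Name`` or ``product``
    attribute, falling back to the feature ID.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type(feature_type):
        lg = feat.seqid if seqid_to_lg is None else seqid_to_lg.get(feat.seqid, feat.seqid)
        ann = (feat.attributes.get("Name") or feat.attributes.get("product")
               or [feat.id])[0]
        rows.append((feat.id, lg, feat.start, feat.end, ann))
    return pd.DataFrame(rows, columns=_COLUMNS)


def genes_in_region(genes: pd.DataFrame, region: QTLRegion,
                    rule: str = "start-in-region") -> pd.DataFrame:
    """Genes of ``genes`` inside ``region``, sorted by start position.

    rule="start-in-region": region.start_bp <= gene.start <= region.end_bp.
    rule="overlap": any overlap of [gene.start, gene.end] with the region.
    Both use 1-based closed intervals.  An unknown linkage group returns an
    empty frame with a warning.
    """
    on_lg = genes[genes["lg"] == region.lg]
    if on_lg.empty:
        warnings.warn(f"no gene records on {region.lg}")
        return on_lg.copy()
    if rule == "start-in-region":
        hit = (on_lg["start"] >= region.start_bp) & (on_lg["start"] <= region.end_bp)
    elif rule == "overlap":
        hit = (on_lg["end"] >= region.start_bp) & (on_lg["start"] <= region.end_bp)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return on_lg[hit].sort_values("start", kind="stable").reset_index(drop=True)


def load_mango_fruit_weight_tables() -> tuple[pd.DataFrame, list[QTLRegion]]:
    """The packaged mango fruit-weight reference: gene table + QTL region bounds."""
    data = resources.files("crosshap") / "data"
    genes = load_gene_table(data / "mango_fruit_weight_qtl_genes.tsv")
    reg_df = pd.read_csv(data / "mango_fruit_weight_qtl_regions.tsv", sep="\t",
                         dtype={"lg": str})
    regions = [
        QTLRegion(region_id=r.region_id, lg=r.lg, start_bp=int(r.start_bp),
                  end_bp=int(r.end_bp), markers=[], min_p=float("nan"))
        for r in reg_df.itertuples()
    ]
    return genes, regions
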