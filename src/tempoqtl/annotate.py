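"""Candidate-gene window scan around significant SNPs.

A gene is a candidate for a marker when its body [start, end] intersects the
closed interval [pos - window, pos + window] on the same chromosome (default
window 15 kb each side).  Distance is 0 when the marker lies inside the gene
body, otherwise the gap to the nearest gene edge; strand is reported for
context but ignored for inclusion (the scan is a symmetric physical window).
GFF3 coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["GeneAnnotation", "scan_window", "write_gff3", "read_gff3"]


GFF_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclasses.dataclass
class GeneAnnotation:
    """Gene-level annotation records (id, chrom, start, end, strand)."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        missing = set(GFF_COLUMNS) - set(g.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if (g["start"] > g["end"]).any():
            raise ValueError("gene with start > end")
        if (g["start"] < 1).any():
            raise ValueError("gene with start < 1 (GFF3 is 1-based)")
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        self.genes = g

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        return cls(read_gff3(path))

    def to_gff3(self, path) -> None:
        write_gff3(self.genes, path)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over gene bodies (closed intervals)."""
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.genes.groupby("chrom", sort=False):
            tree = IntervalTree()
            for row in grp.itertuples():
                # intervaltree is half-open; +1 closes the right edge
                tree.addi(int(row.start), int(row.end) + 1, row.Index)
            out[str(chrom)] = tree
        return out


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Emit gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, grp in genes.groupby("chrom", sort=False):
            fh.write(f"##sequence-region {chrom} 1 {int(grp['end'].max()) + 1000}\n")
        for row in genes.itertuples():
            fh.write(
                f"{row.chrom}\ttempoqtl\tgene\t{int(row.start)}\t{int(row.end)}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene-level features from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": str(feat.seqid),
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows, columns=GFF_COLUMNS)


def scan_window(
    markers: pd.DataFrame,
    annotation: GeneAnnotation | pd.DataFrame,
    window: int = 15_000,
) -> pd.DataFrame:
    """All genes within `window` bp of each marker.

    `markers` needs columns (marker, chrom, pos).  Returns one row per
    (marker, gene) pair: marker, chrom, pos, gene_id, distance_bp, relation
    (contains / upstream / downstream; upstream = gene entirely before the
    marker position).  Markers on chromosomes absent from the annotation get
    no rows (with a warning).
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = GeneAnnotation(annotation)
    trees = annotation.trees()
    genes = annotation.genes
    rows = []
    missing_chroms = set()
    for m in markers.itertuples():
        chrom = str(m.chrom)
        pos = int(m.pos)
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            continue
        lo = max(1, pos - window)
        hi = pos + window
        for iv in sorted(tree.overlap(lo, hi + 1)):
            g = genes.iloc[iv.data]
            if g.start <= pos <= g.end:
                dist, rel = 0, "contains"
            elif g.end < pos:
                dist, rel = pos - int(g.end), "upstream"
            else:
                dist, rel = int(g.start) - pos, "downstream"
            rows.append(
                {
                    "marker": m.marker,
                    "chrom": chrom,
                    "pos": pos,
                    "gene_id": g.gene_id,
                    "distance_bp": dist,
                    "relation": rel,
                    "strand": g.strand,
                }
            )
    if missing_chroms:
        warnings.warn(
            f"markers on chromosomes absent from annotation: {sorted(missing_chroms)}"
        )
    return pd.DataFrame(
        rows,
        columns=["marker", "chrom", "pos", "gene_id", "distance_bp", "relation", "strand"],
    )
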