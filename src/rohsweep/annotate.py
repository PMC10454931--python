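"""Positional candidate-gene lookup around selected regions.

Genes are read from a local BED or TSV table (never fetched from a
remote database).  A gene hits a region when its body overlaps the
region extended by ``flank_bp`` on each side; the reported distance is
the signed difference gene start minus region start, with "Upstream N" /
"Downstream N" labels derived from the sign alone.

No default flank exists: typical analyses use 50 kb around ROH-island
SNPs and 500 kb around selection-scan hits, and the caller must choose.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GENE_COLUMNS = ("gene", "chrom", "start_bp", "end_bp", "strand")
HIT_COLUMNS = (
    "region_chrom", "region_start_bp", "region_end_bp",
    "gene", "gene_start_bp", "gene_end_bp", "distance_bp", "direction",
)


def bed_to_1based(start: int, end: int) -> tuple[int, int]:
    """Convert one 0-based half-open BED interval to 1-based closed."""
    if end <= start:
        raise ValueError("BED interval must satisfy end > start")
    return start + 1, end


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene table from BED (chrom start end name [score strand],
    0-based half-open) or a 5-column TSV with a header row containing
    gene, chrom, start_bp, end_bp, strand (1-based closed)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        rows = []
        for r in df.itertuples(index=False):
            s, e = bed_to_1based(int(r[1]), int(r[2]))
            name = str(r[3]) if len(r) > 3 else f"{r[0]}:{s}-{e}"
            strand = str(r[5]) if len(r) > 5 else "."
            rows.append((name, str(r[0]), s, e, strand))
        return pd.DataFrame(rows, columns=GENE_COLUMNS)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    return df[list(GENE_COLUMNS)]


def direction_label(distance_bp: int) -> str:
    """"Upstream N" for positive signed distances, "Downstream N" for
    negative, "Within 0" at zero — and back again via the sign."""
    if distance_bp > 0:
        return f"Upstream {distance_bp:,}"
    if distance_bp < 0:
        return f"Downstream {-distance_bp:,}"
    return "Within 0"


def parse_direction_label(label: str) -> int:
    word, _, num = label.partition(" ")
    value = int(num.replace(",", ""))
    if word == "Downstream":
        return -value
    return value


def genes_in_flank(
    regions: pd.DataFrame, genes: pd.DataFrame, flank_bp: int
) -> pd.DataFrame:
    """Genes overlapping each region extended by ``flank_bp`` per side.

    ``regions`` needs columns chrom, start_bp, end_bp (1-based closed);
    ``genes`` the :data:`GENE_COLUMNS`.  Intervals are closed on both
    ends; strand is carried through but ignored for overlap.  Genes on a
    different chromosome are silently excluded.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    rows = []
    for region in regions.itertuples(index=False):
        lo = region.start_bp - flank_bp
        hi = region.end_bp + flank_bp
        g = genes[
            (genes["chrom"].astype(str) == str(region.chrom))
            & (genes["start_bp"] <= hi)
            & (genes["end_bp"] >= lo)
        ]
        for gene in g.itertuples(index=False):
            dist = int(gene.start_bp - region.start_bp)
            rows.append(
                (
                    region.chrom, region.start_bp, region.end_bp,
                    gene.gene, gene.start_bp, gene.end_bp,
                    dist, direction_label(dist),
                )
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
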