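"""ROH islands: per-SNP incidence, top-1% selection, shared regions.

An island is a genomic region where an unusually high fraction of a
population's individuals carry overlapping ROH — a footprint of drift
or directional selection.  Here islands are built by ranking every SNP
by the fraction of individuals whose ROH cover it, taking the top
fraction (default 1%), and merging runs of selected SNPs into regions.
Regions can then be intersected across populations to find intervals
autozygous in all of them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .popdiff import top_fraction

REGION_COLUMNS = ("population", "chrom", "start_bp", "end_bp", "length_bp", "n_snps")


def _merged_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts, kind="mergesort")
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def snp_incidence(
    segments: pd.DataFrame, markers: pd.DataFrame, n_individuals: int
) -> pd.DataFrame:
    """Fraction of individuals whose ROH cover each marker.

    ``segments`` holds one population's ROH table (columns as produced by
    :func:`rohsweep.roh.detect_roh_population`); both segment bounds are
    inclusive.  Overlapping segments of the same individual are unioned
    first so each individual is counted once per marker.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    counts = np.zeros(len(markers), dtype=np.int64)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos_bp"].to_numpy()
    for (_, chrom), grp in segments.groupby(["sample_id", "chrom"]):
        sel = np.flatnonzero(chrom_arr == chrom)
        if sel.size == 0:
            continue
        pos = pos_arr[sel]
        order = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[order]
        for s, e in _merged_intervals(
            grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()
        ):
            lo = np.searchsorted(pos_sorted, s, side="left")
            hi = np.searchsorted(pos_sorted, e, side="right")
            counts[sel[order[lo:hi]]] += 1
    out = markers[["chrom", "pos_bp", "snp_id"]].copy()
    out["count"] = counts
    out["freq"] = counts / n_individuals
    return out


def call_islands(
    incidence: pd.DataFrame,
    fraction: float = 0.01,
    merge_gap_bp: int = 1_000_000,
    population: str = "",
) -> pd.DataFrame:
    """Merge the top-``fraction`` incidence SNPs into island regions.

    Selected SNPs on one chromosome are grouped left to right; a new
    region starts whenever the gap to the previous selected SNP exceeds
    ``merge_gap_bp``.  Region bounds are the first/last member SNP
    positions, so ``length_bp = end_bp - start_bp``.
    """
    if incidence.empty:
        raise ValueError("call_islands: empty incidence table")
    mask, _tied = top_fraction(incidence["freq"].to_numpy(), fraction)
    sel = incidence[mask]
    rows = []
    for chrom, grp in sel.groupby("chrom", sort=False):
        pos = np.sort(grp["pos_bp"].to_numpy())
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        for piece in np.split(pos, breaks + 1):
            rows.append(
                (
                    population,
                    chrom,
                    int(piece[0]),
                    int(piece[-1]),
                    int(piece[-1] - piece[0]),
                    int(piece.size),
                )
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def region_length(start_bp: int, end_bp: int) -> int:
    """Region length as last minus first member SNP position (no +1)."""
    if end_bp < start_bp:
        raise ValueError("end_bp < start_bp")
    return int(end_bp) - int(start_bp)


def shared_regions(regions_by_pop: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Intervals carried as islands by every population.

    For each chromosome, the k population interval sets are intersected:
    an output interval is [max of the overlapping starts, min of the
    ends], reported only when non-empty in every population.  The result
    is independent of the order populations are supplied in.
    """
    pops = sorted(regions_by_pop)
    if len(pops) < 2:
        raise ValueError("shared_regions needs >= 2 populations")

    def intervals(df: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
        g = df[df["chrom"] == chrom]
        return sorted(zip(g["start_bp"].astype(int), g["end_bp"].astype(int)))

    chroms = sorted(
        {c for df in regions_by_pop.values() for c in df["chrom"].unique()}
    )
    rows = []
    for chrom in chroms:
        current = intervals(regions_by_pop[pops[0]], chrom)
        for pop in pops[1:]:
            nxt = []
            for s1, e1 in current:
                for s2, e2 in intervals(regions_by_pop[pop], chrom):
                    s, e = max(s1, s2), min(e1, e2)
                    if s <= e:
                        nxt.append((s, e))
            current = nxt
            if not current:
                break
        for s, e in current:
            rows.append((chrom, s, e, ",".join(pops)))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "populations"])


def island_table(
    regions_by_pop: dict[str, pd.DataFrame], qtl_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the multi-population island report.

    One row per region: population, chrom, start, end, length, member SNP
    count — plus, when a user-supplied ``qtl_table`` (columns chrom,
    start_bp, end_bp, name) is given, the names of QTL intervals
    overlapping each region.
    """
    frames = [regions_by_pop[p].assign(population=p) for p in regions_by_pop]
    table = pd.concat(frames, ignore_index=True)[list(REGION_COLUMNS)]
    if qtl_table is not None:
        notes = []
        for row in table.itertuples(index=False):
            q = qtl_table[
                (qtl_table["chrom"].astype(str) == str(row.chrom))
                & (qtl_table["start_bp"] <= row.end_bp)
                & (qtl_table["end_bp"] >= row.start_bp)
            ]
            notes.append(";".join(q["name"]) if len(q) else "-")
        table["qtl"] = notes
    return table


def load_published_island_table() -> pd.DataFrame:
    """The published top-1% ROH island table for the three Large White
    pig lines (American, Canadian, Danish; Sus scrofa 11.1 coordinates),
    bundled with the package as a worked reference input."""
    with resources.files("rohsweep").joinpath(
        "data/largewhite_roh_islands.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df
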