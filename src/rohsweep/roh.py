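"""Sliding-window detection of runs of homozygosity (ROH).

A ROH is a contiguous stretch of one individual's genome where both
inherited haplotypes are identical, seen on a SNP array as a run of
homozygous calls.  Detection follows the sliding-window scheme used by
PLINK and detectRUNS:

1. slide a ``window_snps``-marker window one SNP at a time along each
   chromosome; a window passes if it contains at most ``max_het_per_window``
   heterozygous and ``max_missing_per_window`` missing calls;
2. a SNP is a run member if at least ``window_hit_threshold`` of the
   full windows covering it pass;
3. maximal stretches of member SNPs become candidate runs, split
   wherever the gap between consecutive member SNPs exceeds
   ``max_gap_bp``;
4. candidates are kept if they span at least ``min_length_bp``, keep a
   density of at least one SNP per ``max_bp_per_snp`` and contain at
   least ``min_snps_in_run`` markers.

``min_snps_in_run`` guards against chance runs of homozygosity; it is
normally set from :func:`min_snp_count`, which bounds the genome-wide
false-positive rate at ``alpha`` given the number of SNPs scanned, the
number of individuals, and the mean heterozygosity of the array.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, markers_sorted

log = logging.getLogger(__name__)

SEGMENT_COLUMNS = ("sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp")

#: ROH length classes in Mb: short (1-5), medium (5-10), long (>10).
LENGTH_CLASSES = ((1, 5), (5, 10), (10, math.inf))


@dataclass(frozen=True)
class RohParams:
    """Detection thresholds; defaults follow standard 50K-chip practice."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 2
    min_length_bp: int = 1_000_000
    max_bp_per_snp: int = 500_000  # density: >= 1 SNP per this many bp
    max_gap_bp: int = 1_000_000
    window_hit_threshold: float = 0.05
    min_snps_in_run: int = 0  # set from min_snp_count for the cohort

    def __post_init__(self):
        if self.window_snps < 1 or self.min_length_bp <= 0:
            raise ValueError("window_snps >= 1 and min_length_bp > 0 required")
        if not (0.0 < self.window_hit_threshold <= 1.0):
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if min(self.max_het_per_window, self.max_missing_per_window,
               self.min_snps_in_run) < 0:
            raise ValueError("count thresholds must be >= 0")

    def with_min_snps(self, alpha: float, ns: int, ni: int, het: float) -> "RohParams":
        return replace(self, min_snps_in_run=min_snp_count(alpha, ns, ni, het))


def min_snp_count(alpha: float, ns: int, ni: int, het: float) -> int:
    """Minimum run length in SNPs that keeps chance runs below ``alpha``.

    l = ceil( ln(alpha / (ns * ni)) / ln(1 - het) )

    where ``ns`` is the number of SNPs scanned per individual, ``ni`` the
    number of individuals and ``het`` the mean heterozygosity across SNPs:
    a run of l homozygous calls arises by chance with probability
    (1-het)^l, and ns*ni Bonferroni-corrects over every tested position.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if ns < 1 or ni < 1:
        raise ValueError("ns and ni must be >= 1")
    if not (0.0 < het < 1.0):
        raise ValueError("het must be strictly inside (0, 1)")
    return math.ceil(math.log(alpha / (ns * ni)) / math.log(1.0 - het))


def _chromosome_runs(
    calls: np.ndarray, pos: np.ndarray, p: RohParams
) -> list[tuple[int, int, int, int]]:
    """Runs on one chromosome for one individual.

    Returns (start_bp, end_bp, n_snps, length_bp) tuples; ``calls`` and
    ``pos`` are aligned and position-sorted.
    """
    m = calls.size
    w = p.window_snps
    if m < w:
        return []
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    ok = ((chet[starts + w] - chet[starts]) <= p.max_het_per_window) & (
        (cmis[starts + w] - cmis[starts]) <= p.max_missing_per_window
    )
    cok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])

    # windows covering SNP j have start indices in [j-w+1, j] ∩ [0, n_win-1]
    j = np.arange(m)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, n_win - 1)
    n_cov = hi - lo + 1
    n_pass = cok[hi + 1] - cok[lo]
    member = (n_pass / n_cov) >= p.window_hit_threshold

    segs: list[tuple[int, int, int, int]] = []
    idx = np.flatnonzero(member)
    if idx.size == 0:
        return segs
    # maximal member stretches, split at large physical gaps
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > p.max_gap_bp)
    )
    pieces = np.split(idx, breaks + 1)
    for piece in pieces:
        start_bp = int(pos[piece[0]])
        end_bp = int(pos[piece[-1]])
        n_snps = int(piece.size)
        length = end_bp - start_bp
        if length < p.min_length_bp:
            continue
        if n_snps < p.min_snps_in_run:
            continue
        if length > 0 and n_snps / length < 1.0 / p.max_bp_per_snp:
            continue
        segs.append((start_bp, end_bp, n_snps, length))
    return segs


def detect_roh(
    g: GenotypeMatrix, sample_id: str, params: RohParams | None = None
) -> pd.DataFrame:
    """ROH segments for one individual, as a DataFrame with
    :data:`SEGMENT_COLUMNS`.  Markers must be sorted by (chrom, pos)."""
    params = params or RohParams()
    if not markers_sorted(g.markers):
        raise ValueError("markers must be sorted by (chrom, pos); use sort_markers()")
    try:
        i = g.samples.index(sample_id)
    except ValueError:
        raise KeyError(f"sample {sample_id!r} not present") from None
    rows = []
    chrom_arr = g.markers["chrom"].to_numpy()
    pos_arr = g.markers["pos_bp"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        calls = g.calls[i, sel]
        if calls.size < params.window_snps:
            log.debug("chromosome %s: %d SNPs < window, skipped", chrom, calls.size)
            continue
        for start, end, n_snps, length in _chromosome_runs(
            calls, pos_arr[sel], params
        ):
            rows.append((sample_id, chrom, start, end, n_snps, length))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def detect_roh_population(
    g: GenotypeMatrix, params: RohParams | None = None
) -> pd.DataFrame:
    """ROH segments for every individual in ``g`` (concatenated)."""
    frames = [detect_roh(g, s, params) for s in g.samples]
    if not frames:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class RohSummary:
    per_individual: pd.DataFrame  # sample_id, n_roh, total_length_mb
    per_chromosome: pd.DataFrame  # chrom, n_roh, coverage
    length_classes: pd.DataFrame  # class label, count

    n_segments: int = field(default=0)


def summarize_roh(
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_individuals: int | None = None,
) -> RohSummary:
    """Population summaries of a segment table.

    Per-chromosome coverage is the summed segment length across
    individuals divided by (number of individuals x chromosome length),
    i.e. the mean fraction of that chromosome inside a ROH.
    """
    for chrom, grp in segments.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom} missing from chrom_lengths")
        if (grp["end_bp"] > chrom_lengths[chrom]).any():
            raise ValueError(f"segment beyond length of chromosome {chrom}")
    if n_individuals is None:
        n_individuals = segments["sample_id"].nunique()
    per_ind = (
        segments.groupby("sample_id")
        .agg(n_roh=("chrom", "size"), total_length_bp=("length_bp", "sum"))
        .reset_index()
    )
    per_ind["total_length_mb"] = per_ind["total_length_bp"] / 1e6
    per_chrom_rows = []
    for chrom, grp in segments.groupby("chrom"):
        cov = grp["length_bp"].sum() / (n_individuals * chrom_lengths[chrom])
        per_chrom_rows.append((chrom, len(grp), cov))
    per_chrom = pd.DataFrame(per_chrom_rows, columns=["chrom", "n_roh", "coverage"])
    mb = segments["length_bp"] / 1e6
    class_rows = []
    for lo, hi in LENGTH_CLASSES:
        label = f">{lo} Mb" if math.isinf(hi) else f"{lo}-{hi} Mb"
        class_rows.append((label, int(((mb >= lo) & (mb < hi)).sum())))
    length_classes = pd.DataFrame(class_rows, columns=["length_class", "count"])
    return RohSummary(per_ind, per_chrom, length_classes, n_segments=len(segments))


def audit_segments(segments: pd.DataFrame, params: RohParams) -> None:
    """Raise if any reported segment violates the length, density or
    minimum-SNP constraint (post-hoc consistency check)."""
    if segments.empty:
        return
    if (segments["length_bp"] != segments["end_bp"] - segments["start_bp"]).any():
        raise AssertionError("length_bp != end_bp - start_bp")
    if (segments["length_bp"] < params.min_length_bp).any():
        raise AssertionError("segment below min_length_bp")
    if (segments["n_snps"] < params.min_snps_in_run).any():
        raise AssertionError("segment below min_snps_in_run")
    dens = segments["n_snps"] / segments["length_bp"]
    if (dens < 1.0 / params.max_bp_per_snp).any():
        raise AssertionError("segment below minimum SNP density")
    for (_, _), grp in segments.groupby(["sample_id", "chrom"]):
        srt = grp.sort_values("start_bp")
        if (srt["start_bp"].to_numpy()[1:] <= srt["end_bp"].to_numpy()[:-1]).any():
            raise AssertionError("overlapping segments within one individual")


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED rows (start-1, end) from 1-based closed segments."""
    return pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start_bp"] - 1,
            "end": segments["end_bp"],
            "name": segments["sample_id"],
        }
    )
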