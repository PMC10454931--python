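"""Population differentiation: Weir-Cockerham F_ST, sliding windows, LSBL.

Per-SNP F_ST uses the Weir & Cockerham (1984) two-population diploid
estimator with variance components a (among populations), b (among
individuals within populations) and c (within individuals), the same
estimator VCFtools reports.  Windowed values use the ratio-of-sums
("weighted") form sum(a) / sum(a+b+c) over the SNPs in each window;
the mean of per-SNP ratios is carried alongside.

Locus-specific branch lengths (LSBL) decompose three pairwise F_ST
values into one branch per population:

    L_a = (F_ab + F_ac - F_bc) / 2   (and cyclic permutations)

so that L_a + L_b = F_ab identically and the three branches sum to half
the sum of the pairwise values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


def _pop_summaries(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (n genotyped, alt freq, het fraction) for one population."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
        h = np.where(obs, calls == 1, False).sum(axis=0) / n
    return n, p, h


def wc_fst_per_snp(g: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham F_ST between two populations.

    Returns a DataFrame aligned with ``g.markers`` holding the variance
    component numerator ``num`` (= a), denominator ``den`` (= a+b+c),
    the ratio ``fst`` and a ``defined`` flag.  A marker is undefined when
    either population has fewer than 2 genotyped individuals or the
    denominator is zero (monomorphic in the pooled pair); undefined
    markers carry num = den = 0 and fst = NaN.  Negative estimates are
    retained.
    """
    calls_a = g.calls[g.pop_indices(pop_a), :]
    calls_b = g.calls[g.pop_indices(pop_b), :]
    n1, p1, h1 = _pop_summaries(calls_a)
    n2, p2, h2 = _pop_summaries(calls_b)

    r = 2.0
    defined = (n1 >= 2) & (n2 >= 2)
    # avoid warnings on undefined markers; values overwritten below
    n1s, n2s = np.where(defined, n1, 2.0), np.where(defined, n2, 2.0)
    p1s, p2s = np.nan_to_num(p1), np.nan_to_num(p2)
    h1s, h2s = np.nan_to_num(h1), np.nan_to_num(h2)

    n_bar = (n1s + n2s) / r
    n_c = (r * n_bar - (n1s**2 + n2s**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1s * p1s + n2s * p2s) / (r * n_bar)
    s2 = (n1s * (p1s - p_bar) ** 2 + n2s * (p2s - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1s * h1s + n2s * h2s) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0

    num = a
    den = a + b + c
    defined = defined & (den != 0.0)
    num = np.where(defined, num, 0.0)
    den = np.where(defined, den, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(defined, num / np.where(den != 0, den, 1.0), np.nan)
    return pd.DataFrame(
        {
            "chrom": g.markers["chrom"],
            "pos_bp": g.markers["pos_bp"],
            "snp_id": g.markers["snp_id"],
            "num": num,
            "den": den,
            "fst": fst,
            "defined": defined,
        }
    )


def genome_weighted_fst(snp_fst: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums F_ST over defined markers."""
    d = snp_fst[snp_fst["defined"]]
    den = d["den"].sum()
    if den == 0:
        raise ValueError("no defined markers with nonzero denominator")
    return float(d["num"].sum() / den)


def windowed_fst(
    snp_fst: pd.DataFrame,
    size_bp: int = 50_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Aggregate per-SNP components into sliding genomic windows.

    Windows are 1-based inclusive ``[start, start + size_bp - 1]``; the
    first window of each chromosome starts at bp 1 and starts advance by
    ``step_bp`` (VCFtools convention).  A SNP contributes to every window
    containing its position.  Windows without any defined SNP are dropped.
    """
    if not (size_bp >= step_bp > 0):
        raise ValueError("require size_bp >= step_bp > 0")
    out = []
    for chrom, grp in snp_fst.groupby("chrom", sort=False):
        grp = grp[grp["defined"]]
        if grp.empty:
            continue
        pos = grp["pos_bp"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        num = grp["num"].to_numpy()[order]
        den = grp["den"].to_numpy()[order]
        fst = grp["fst"].to_numpy()[order]
        cnum = np.concatenate([[0.0], np.cumsum(num)])
        cden = np.concatenate([[0.0], np.cumsum(den)])
        cfst = np.concatenate([[0.0], np.cumsum(fst)])
        last_start = int(pos[-1])  # windows beyond the last SNP are empty
        starts = np.arange(1, last_start + 1, step_bp, dtype=np.int64)
        ends = starts + size_bp - 1
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        nz = hi > lo
        starts, ends, lo, hi = starts[nz], ends[nz], lo[nz], hi[nz]
        wden = cden[hi] - cden[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            weighted = np.where(wden != 0, (cnum[hi] - cnum[lo]) / wden, np.nan)
        mean = (cfst[hi] - cfst[lo]) / (hi - lo)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start_bp": starts,
                    "end_bp": ends,
                    "n_snps": hi - lo,
                    "weighted_fst": weighted,
                    "mean_fst": mean,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "n_snps", "weighted_fst", "mean_fst"]
        )
    return pd.concat(out, ignore_index=True)


def lsbl(fst_ab, fst_ac, fst_bc) -> pd.DataFrame:
    """Branch lengths for populations a, b, c from the three pairwise series.

    Inputs must be aligned (same SNPs or windows, same order).  Negative
    branch lengths are preserved and flagged in ``any_negative``.
    """
    fst_ab = np.asarray(fst_ab, dtype=float)
    fst_ac = np.asarray(fst_ac, dtype=float)
    fst_bc = np.asarray(fst_bc, dtype=float)
    if not (fst_ab.shape == fst_ac.shape == fst_bc.shape):
        raise ValueError("pairwise F_ST series are misaligned")
    l_a = (fst_ab + fst_ac - fst_bc) / 2.0
    l_b = (fst_ab + fst_bc - fst_ac) / 2.0
    l_c = (fst_ac + fst_bc - fst_ab) / 2.0
    return pd.DataFrame(
        {
            "l_a": l_a,
            "l_b": l_b,
            "l_c": l_c,
            "any_negative": (l_a < 0) | (l_b < 0) | (l_c < 0),
        }
    )


def windowed_lsbl(
    snp_fst_ab: pd.DataFrame,
    snp_fst_ac: pd.DataFrame,
    snp_fst_bc: pd.DataFrame,
    size_bp: int = 50_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Windowed F_ST for the three pairs merged on window identity, with
    per-window branch lengths appended.  Only windows present for all
    three pairs are kept (a window can be SNP-empty for one pair when its
    markers are undefined there)."""
    keys = ["chrom", "start_bp", "end_bp"]
    w = None
    for tag, snp_fst in (("ab", snp_fst_ab), ("ac", snp_fst_ac), ("bc", snp_fst_bc)):
        wi = windowed_fst(snp_fst, size_bp, step_bp)
        wi = wi.rename(
            columns={
                "weighted_fst": f"fst_{tag}",
                "mean_fst": f"mean_fst_{tag}",
                "n_snps": f"n_snps_{tag}",
            }
        )
        w = wi if w is None else w.merge(wi, on=keys, how="inner")
    branches = lsbl(w["fst_ab"], w["fst_ac"], w["fst_bc"])
    return pd.concat([w.reset_index(drop=True), branches], axis=1)


def top_fraction(scores, fraction: float = 0.01) -> tuple[np.ndarray, bool]:
    """Select the top ``fraction`` of entries by score.

    ``ceil(fraction * n)`` entries are taken before tie expansion; every
    entry tied with the cut-off score is then included.  Returns a boolean
    selection mask and a flag that is True when ties expanded the set.
    NaN scores are never selected.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("top_fraction: empty input")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    finite = ~np.isnan(scores)
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("top_fraction: all scores are NaN")
    k = min(int(np.ceil(fraction * n)), n_finite)
    ranked = np.sort(scores[finite])[::-1]
    threshold = ranked[k - 1]
    mask = finite & (scores >= threshold)
    return mask, bool(mask.sum() > k)


def intersect_selected(
    a: pd.DataFrame, b: pd.DataFrame, mode: str = "exact"
) -> pd.DataFrame:
    """Windows selected by both of two scans.

    ``mode="exact"`` matches on identical (chrom, start_bp, end_bp);
    ``mode="overlap"`` keeps rows of ``a`` whose interval overlaps any
    selected interval of ``b`` on the same chromosome.
    """
    keys = ["chrom", "start_bp", "end_bp"]
    if mode == "exact":
        return a.merge(b[keys].drop_duplicates(), on=keys, how="inner")
    if mode != "overlap":
        raise ValueError("mode must be 'exact' or 'overlap'")
    rows = []
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        bs = gb["start_bp"].to_numpy()
        be = gb["end_bp"].to_numpy()
        for _, row in ga.iterrows():
            if np.any((row["start_bp"] <= be) & (row["end_bp"] >= bs)):
                rows.append(row)
    return pd.DataFrame(rows, columns=a.columns).reset_index(drop=True)
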