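"""Independent reference implementations used only by the tests.

These are deliberately written as plain scalar loops, separately from
the vectorized package code, so that agreement between the two is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import math

MISSING = -1


def wc_fst_components_oracle(genos_a, genos_b):
    """Weir & Cockerham (1984) variance components for one biallelic SNP
    and two populations, from first principles.

    ``genos_a``/``genos_b`` are iterables of alt-allele dosages (0/1/2),
    missing calls already excluded.  Returns (a, a+b+c) or None when the
    estimate is undefined (<2 genotyped in either sample, or zero
    denominator).
    """
    sample_sizes = [len(list(genos_a)), len(list(genos_b))]
    if min(sample_sizes) < 2:
        return None
    pops = [list(genos_a), list(genos_b)]
    r = 2
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    if a + b + c == 0:
        return None
    return a, a + b + c


def roh_oracle(calls, pos, *, window_snps=50, max_het=1, max_missing=2,
               min_length_bp=1_000_000, max_bp_per_snp=500_000,
               max_gap_bp=1_000_000, hit_threshold=0.05, min_snps_in_run=0):
    """Brute-force enumeration of sliding-window ROH for one individual
    on one chromosome.  Returns (start_bp, end_bp, n_snps, length_bp)
    tuples."""
    calls = list(int(c) for c in calls)
    pos = list(int(p) for p in pos)
    m = len(calls)
    w = window_snps
    if m < w:
        return []
    passes = []
    for s in range(m - w + 1):
        win = calls[s : s + w]
        n_het = sum(1 for x in win if x == 1)
        n_mis = sum(1 for x in win if x == MISSING)
        passes.append(n_het <= max_het and n_mis <= max_missing)

    member = []
    for j in range(m):
        covering = [passes[s] for s in range(max(0, j - w + 1), min(j, m - w) + 1)]
        member.append(sum(covering) / len(covering) >= hit_threshold)

    # maximal member stretches, split at big physical gaps
    runs = []
    current = []
    for j in range(m):
        if member[j]:
            if current and pos[j] - pos[current[-1]] > max_gap_bp:
                runs.append(current)
                current = []
            current.append(j)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    out = []
    for run in runs:
        start, end = pos[run[0]], pos[run[-1]]
        length = end - start
        n_snps = len(run)
        if length < min_length_bp:
            continue
        if n_snps < min_snps_in_run:
            continue
        if length > 0 and n_snps / length < 1.0 / max_bp_per_snp:
            continue
        out.append((start, end, n_snps, length))
    return out


def min_snp_count_oracle(alpha, ns, ni, het):
    return math.ceil(math.log(alpha / (ns * ni)) / math.log(1 - het))


def incidence_oracle(segments, markers, samples):
    """Double loop over (individual, marker): count individuals with at
    least one covering segment.  ``segments`` is an iterable of dicts
    with sample_id/chrom/start_bp/end_bp; ``markers`` of (chrom, pos)."""
    counts = []
    for chrom, pos in markers:
        n = 0
        for sample in samples:
            covered = any(
                seg["sample_id"] == sample
                and seg["chrom"] == chrom
                and seg["start_bp"] <= pos <= seg["end_bp"]
                for seg in segments
            )
            n += covered
        counts.append(n)
    return counts
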