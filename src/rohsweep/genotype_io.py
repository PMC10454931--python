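"""Genotype input/output and array quality control.

Supports the two text formats the pipeline consumes: PLINK .ped/.map
(whitespace-delimited, "0" = missing allele, family ID carries the
population label) and VCF 4.x with GT.  QC applies the standard chip
filters: SNP call rate, known autosomal position, minor allele
frequency, then sample call rate — in that order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AUTOSOMES, MISSING, GenotypeMatrix, QCReport, make_marker_map

log = logging.getLogger(__name__)

# alleles the writer emits; .ped has no ref/alt notion so the pair is a
# fixed convention (ref, alt)
_WRITE_ALLELES = ("A", "C")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, alt_allele: str | None = None) -> GenotypeMatrix:
    """Read a PLINK .ped/.map pair into a :class:`GenotypeMatrix`.

    Genotypes are recoded to alt-allele dosage.  By default the minor
    allele of each marker is taken as alt (ties broken toward the
    lexicographically larger allele); pass ``alt_allele`` to force a
    specific allele letter instead, which makes reading invertible for
    files produced by :func:`write_plink_text` (``alt_allele="C"``).

    The family-ID column is used as the population label.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns")
            map_rows.append((fields[0], fields[1], int(fields[3])))
    if not map_rows:
        raise ParseError(f"{map_path}: no markers")
    n_markers = len(map_rows)

    samples: list[str] = []
    populations: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise ParseError(f"{ped_path}: line {lineno}: expected >=6 columns")
            alleles = fields[6:]
            if len(alleles) != 2 * n_markers:
                raise ParseError(
                    f"{ped_path}: line {lineno}: {len(alleles)} allele fields, "
                    f"expected {2 * n_markers} for {n_markers} markers"
                )
            populations.append(fields[0])
            samples.append(fields[1])
            allele_rows.append(np.array(alleles, dtype="U8"))
    if not samples:
        raise ParseError(f"{ped_path}: no samples")

    alleles = np.stack(allele_rows)  # (n, 2m)
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        cj1, cj2 = a1[:, j], a2[:, j]
        obs = (cj1 != "0") & (cj2 != "0")
        letters, counts = np.unique(
            np.concatenate([cj1[obs], cj2[obs]]), return_counts=True
        )
        if letters.size > 2:
            raise ParseError(f"marker {map_rows[j][1]}: more than 2 alleles")
        if letters.size == 0:
            continue  # fully missing marker
        if alt_allele is not None:
            alt = alt_allele
        elif letters.size == 1:
            alt = None  # monomorphic: dosage 0 for the single observed allele
        else:
            # minor allele = alt; tie -> lexicographically larger
            if counts[0] != counts[1]:
                alt = letters[int(np.argmin(counts))]
            else:
                alt = max(letters)
        if alt is None:
            calls[obs, j] = 0
        else:
            calls[obs, j] = (cj1[obs] == alt).astype(np.int8) + (
                cj2[obs] == alt
            ).astype(np.int8)
    markers = make_marker_map(
        [r[0] for r in map_rows], [r[2] for r in map_rows], [r[1] for r in map_rows]
    )
    return GenotypeMatrix(calls, markers, samples, populations)


def write_plink_text(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``.

    Alleles are emitted as ref='A', alt='C' for every marker; read back
    with ``read_plink_text(..., alt_allele="C")`` for an exact round trip.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in g.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
    ref, alt = _WRITE_ALLELES
    pair = {0: f"{ref} {ref}", 1: f"{ref} {alt}", 2: f"{alt} {alt}", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, (sid, pop) in enumerate(zip(g.samples, g.populations)):
            geno = " ".join(pair[int(c)] for c in g.calls[i])
            fh.write(f"{pop} {sid} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, pop_map: dict[str, str], on_unknown_sample: str = "error"
             ) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF with GT into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged).  ``./.``
    becomes the missing call.  ``pop_map`` maps sample id -> population;
    samples absent from it either raise (``on_unknown_sample="error"``)
    or are dropped (``"drop"``).
    """
    from cyvcf2 import VCF

    if on_unknown_sample not in ("error", "drop"):
        raise ValueError("on_unknown_sample must be 'error' or 'drop'")
    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in pop_map]
    if unknown and on_unknown_sample == "error":
        raise KeyError(f"samples missing from pop_map: {unknown[:5]}...")
    keep = np.array([s in pop_map for s in vcf_samples])
    samples = [s for s in vcf_samples if s in pop_map]

    chroms, poss, ids, rows = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(rec.gt_types)[keep].astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ParseError(f"{vcf_path}: no biallelic SNP records")
    calls = np.stack(rows).T  # records x samples -> samples x markers
    markers = make_marker_map(chroms, poss, ids)
    populations = [pop_map[s] for s in samples]
    return GenotypeMatrix(calls, markers, samples, populations)


def write_vcf(g: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF 4.2 with GT only (ref='A', alt='C')."""
    path = Path(path)
    ref, alt = _WRITE_ALLELES
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, row in enumerate(g.markers.itertuples(index=False)):
            gts = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.snp_id}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def pop_map_of(g: GenotypeMatrix) -> dict[str, str]:
    return dict(zip(g.samples, g.populations))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def allele_frequencies(calls: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per marker over non-missing calls (nan if none)."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)


def qc_filter(
    g: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    maf: float = 0.05,
    sample_call_rate: float = 0.95,
    autosomes: tuple[str, ...] = AUTOSOMES,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply chip QC: SNP filters first, then the sample filter.

    SNPs are removed for (a) unknown position — chromosome outside
    ``autosomes`` or position <= 0, (b) call rate below ``snp_call_rate``,
    (c) MAF below ``maf`` computed on pooled non-missing allele counts.
    Markers exactly at a threshold are kept ("less than" is removed).
    Samples are then removed if their call rate over the surviving SNPs
    is below ``sample_call_rate``.
    """
    if g.n_markers == 0 or g.n_samples == 0:
        raise ValueError("qc_filter: empty input matrix")
    calls = g.calls
    obs = calls != MISSING

    pos_ok = g.markers["chrom"].isin(autosomes).to_numpy() & (
        g.markers["pos_bp"].to_numpy() > 0
    )
    call_rate = obs.mean(axis=0)
    freq = allele_frequencies(calls)
    maf_val = np.fmin(freq, 1.0 - freq)

    removed_snps: list[tuple[str, str]] = []
    snp_keep = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        sid = g.markers["snp_id"].iat[j]
        if not pos_ok[j]:
            removed_snps.append((sid, "unknown_position"))
            snp_keep[j] = False
        elif call_rate[j] < snp_call_rate:
            removed_snps.append((sid, "low_call_rate"))
            snp_keep[j] = False
        elif np.isnan(maf_val[j]) or maf_val[j] < maf:
            removed_snps.append((sid, "low_maf"))
            snp_keep[j] = False
    if not snp_keep.any():
        raise ValueError("qc_filter: no SNPs remain after QC")

    sample_rate = obs[:, snp_keep].mean(axis=1)
    sample_keep = sample_rate >= sample_call_rate
    removed_samples = [
        (g.samples[i], "low_call_rate") for i in np.flatnonzero(~sample_keep)
    ]
    if not sample_keep.any():
        raise ValueError("qc_filter: no samples remain after QC")

    out = g.take_markers(np.flatnonzero(snp_keep)).take_samples(
        np.flatnonzero(sample_keep)
    )
    report = QCReport(
        n_snps_in=g.n_markers,
        n_snps_out=out.n_markers,
        n_samples_in=g.n_samples,
        n_samples_out=out.n_samples,
        removed_snps=removed_snps,
        removed_samples=removed_samples,
    )
    return out, report
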