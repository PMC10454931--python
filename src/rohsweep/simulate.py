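"""Synthetic multi-population SNP-array cohorts with known truth.

Emulates the structure of a three-line breeding study: populations that
diverged from a common ancestral gene pool, genotyped on a mapped
autosomal SNP array, with per-call missingness and — for ROH work —
planted autozygous segments whose coordinates are recorded.

Allele frequencies follow the Balding-Nichols model: each population's
frequency at a SNP is Beta-distributed around the ancestral frequency
p with parameters p(1-c)/c and (1-p)(1-c)/c, where the drift parameter
c equals the expected pairwise F_ST between populations drifted at c.
That closed form is what makes parameter-recovery tests possible.
Genotypes are binomial(2, p_pop) draws — sites are unlinked, so the
simulator deliberately has no LD; see the package docs for what that
does and does not exercise.

Planted segments overwrite carrier genotypes with one shared homozygous
haplotype per segment (drawn from the population's frequencies), so
both per-individual ROH detection and cross-individual island incidence
see the same footprint.  Missingness is applied last.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, make_marker_map
from .genotype_io import write_plink_text, write_vcf


@dataclass(frozen=True)
class PlantedSegment:
    """One autozygous interval to plant: which population, what fraction
    of its individuals carry it, and where it sits."""

    population: str
    carrier_fraction: float
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults mirror the cohort scale the pipeline targets: three Large
    White-style lines of 500/295/1500 individuals genotyped at ~45k
    autosomal SNPs spread over 18 chromosomes.  Tests use much smaller
    instances of the same configuration.
    """

    pop_names: tuple[str, ...] = ("Canadian", "Danish", "American")
    pop_sizes: tuple[int, ...] = (500, 295, 1500)
    n_snps: int = 45_000
    n_chroms: int = 18
    chrom_length_bp: int = 150_000_000
    target_fst: float = 0.1  # Balding-Nichols drift parameter c, per population
    missing_rate: float = 0.01
    planted_segments: tuple[PlantedSegment, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if len(self.pop_names) != len(self.pop_sizes):
            raise ValueError("pop_names and pop_sizes must align")
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        for seg in self.planted_segments:
            if seg.population not in self.pop_names:
                raise ValueError(f"planted segment in unknown population {seg.population}")
            if not (0.0 < seg.carrier_fraction <= 1.0):
                raise ValueError("carrier_fraction must be in (0, 1]")
            if not (1 <= seg.start_bp <= seg.end_bp <= self.chrom_length_bp):
                raise ValueError("planted segment outside chromosome bounds")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    ancestral_freq: np.ndarray  # per SNP
    pop_freq: dict[str, np.ndarray]  # per population, per SNP
    planted: list[dict]  # one record per planted segment, with carriers
    expected_pairwise_fst: float  # closed-form target for any population pair

    def to_json(self) -> dict:
        return {
            "expected_pairwise_fst": self.expected_pairwise_fst,
            "planted": self.planted,
        }


def _positions(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chroms, cfg.n_snps // cfg.n_chroms)
    per_chrom[: cfg.n_snps % cfg.n_chroms] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chroms):
        m = int(per_chrom[c])
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chrom_length_bp + 1, dtype=np.int64),
                size=m,
                replace=False,
            )
            if cfg.chrom_length_bp >= m
            else np.arange(1, m + 1)
        )
        chroms.extend([str(c + 1)] * m)
        positions.extend(pos.tolist())
    return make_marker_map(chroms, positions)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a cohort under ``cfg``; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    markers = _positions(rng, cfg)
    m = len(markers)
    anc = rng.uniform(0.05, 0.95, size=m)
    c = cfg.target_fst
    pop_freq: dict[str, np.ndarray] = {}
    for pop in cfg.pop_names:
        if c == 0.0:
            pop_freq[pop] = anc.copy()
        else:
            ratio = (1.0 - c) / c
            pop_freq[pop] = rng.beta(anc * ratio, (1.0 - anc) * ratio)

    n_total = int(sum(cfg.pop_sizes))
    calls = np.empty((n_total, m), dtype=np.int8)
    samples: list[str] = []
    populations: list[str] = []
    offsets: dict[str, tuple[int, int]] = {}
    row = 0
    for pop, size in zip(cfg.pop_names, cfg.pop_sizes):
        calls[row : row + size] = rng.binomial(
            2, pop_freq[pop][None, :], size=(size, m)
        ).astype(np.int8)
        samples.extend(f"{pop}_{i:04d}" for i in range(size))
        populations.extend([pop] * size)
        offsets[pop] = (row, row + size)
        row += size

    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos_bp"].to_numpy()
    planted_records: list[dict] = []
    for seg in cfg.planted_segments:
        in_seg = np.flatnonzero(
            (chrom_arr == seg.chrom)
            & (pos_arr >= seg.start_bp)
            & (pos_arr <= seg.end_bp)
        )
        if in_seg.size == 0:
            raise ValueError(
                f"planted segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} "
                "contains no SNPs"
            )
        lo, hi = offsets[seg.population]
        size = hi - lo
        n_carriers = max(1, int(round(seg.carrier_fraction * size)))
        carriers = lo + rng.choice(size, size=n_carriers, replace=False)
        haplotype = rng.binomial(1, pop_freq[seg.population][in_seg]).astype(np.int8)
        calls[np.ix_(carriers, in_seg)] = 2 * haplotype[None, :]
        planted_records.append(
            {
                "population": seg.population,
                "chrom": seg.chrom,
                "start_bp": int(seg.start_bp),
                "end_bp": int(seg.end_bp),
                "n_snps": int(in_seg.size),
                "carriers": [samples[i] for i in carriers],
            }
        )

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    g = GenotypeMatrix(calls, markers, samples, populations)
    truth = SimTruth(
        ancestral_freq=anc,
        pop_freq=pop_freq,
        planted=planted_records,
        expected_pairwise_fst=c,
    )
    return g, truth


def simulate_gene_table(
    cfg: SimConfig, n_genes: int = 100, gene_length_bp: int = 50_000, seed: int = 1
) -> pd.DataFrame:
    """A synthetic gene table (for annotation tests) spread uniformly
    over the simulated genome; columns match annotate.GENE_COLUMNS."""
    rng = np.random.default_rng(seed)
    chroms = rng.integers(1, cfg.n_chroms + 1, size=n_genes)
    starts = rng.integers(1, max(2, cfg.chrom_length_bp - gene_length_bp), size=n_genes)
    return pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in range(n_genes)],
            "chrom": chroms.astype(str),
            "start_bp": starts,
            "end_bp": starts + gene_length_bp,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
        }
    ).sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def write_fixture(
    g: GenotypeMatrix,
    truth: SimTruth,
    out_dir,
    cfg: SimConfig | None = None,
    formats: tuple[str, ...] = ("plink", "vcf", "genes"),
) -> dict[str, str]:
    """Write a simulated cohort to ``out_dir`` as PLINK text, VCF, a
    synthetic gene BED and a truth JSON.  Returns a name -> path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if "plink" in formats:
        ped, mp = write_plink_text(g, out_dir / "cohort")
        written["ped"], written["map"] = str(ped), str(mp)
    if "vcf" in formats:
        written["vcf"] = str(write_vcf(g, out_dir / "cohort.vcf"))
    if "genes" in formats and cfg is not None:
        genes = simulate_gene_table(cfg)
        bed = out_dir / "genes.bed"
        pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["start_bp"] - 1,
                "end": genes["end_bp"],
                "name": genes["gene"],
                "score": 0,
                "strand": genes["strand"],
            }
        ).to_csv(bed, sep="\t", header=False, index=False)
        written["genes"] = str(bed)
    truth_path = out_dir / "truth.json"
    payload = truth.to_json()
    if cfg is not None:
        payload["config"] = asdict(cfg)
        payload["config"]["planted_segments"] = [
            asdict(s) for s in cfg.planted_segments
        ]
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    written["truth"] = str(truth_path)
    return written
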