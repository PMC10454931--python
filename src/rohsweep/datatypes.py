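"""Core in-memory containers shared by every stage of the pipeline.

Genotypes are held as a dense int8 matrix of alt-allele dosages
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) with a pandas marker
map alongside.  This mirrors how SNP-array cohorts of tens of thousands
of markers and a few thousand individuals are handled in practice: the
full matrix for the study scale (~2300 x ~50k) is ~115 MB as int8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: Autosome labels of the Sus scrofa 11.1 assembly used throughout.
AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 19))

MARKER_COLUMNS = ("chrom", "pos_bp", "snp_id")


def make_marker_map(chrom, pos_bp, snp_id=None) -> pd.DataFrame:
    """Build and validate a marker map DataFrame.

    Parameters
    ----------
    chrom : sequence of str
        Chromosome label per marker.
    pos_bp : sequence of int
        1-based physical position in base pairs.
    snp_id : sequence of str, optional
        Marker identifiers; generated as ``chrom:pos`` when omitted.
    """
    chrom = np.asarray(chrom, dtype=object).astype(str)
    pos_bp = np.asarray(pos_bp, dtype=np.int64)
    if snp_id is None:
        snp_id = np.array([f"{c}:{p}" for c, p in zip(chrom, pos_bp)], dtype=object)
    else:
        snp_id = np.asarray(snp_id, dtype=object).astype(str)
    m = pd.DataFrame({"chrom": chrom, "pos_bp": pos_bp, "snp_id": snp_id})
    validate_marker_map(m)
    return m


def validate_marker_map(markers: pd.DataFrame) -> None:
    missing_cols = set(MARKER_COLUMNS) - set(markers.columns)
    if missing_cols:
        raise ValueError(f"marker map lacks columns {sorted(missing_cols)}")
    dup = markers.duplicated(subset=["chrom", "pos_bp"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate chrom/pos pairs in marker map "
            f"(first: {markers.loc[dup.idxmax(), ['chrom', 'pos_bp']].tolist()})"
        )


def markers_sorted(markers: pd.DataFrame) -> bool:
    """True when positions are strictly increasing within each chromosome
    and chromosomes form contiguous blocks."""
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    if np.any(same & (np.diff(pos) <= 0)):
        return False
    # each chromosome must appear as one contiguous block
    boundary_chroms = [chrom[0]] + list(chrom[1:][~same])
    return len(boundary_chroms) == len(set(boundary_chroms))


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a multi-population SNP-array cohort.

    Attributes
    ----------
    calls : np.ndarray
        int8 array of shape (n_samples, n_markers); alt-allele dosage
        0/1/2, ``MISSING`` (-1) for a failed call.
    markers : pd.DataFrame
        Columns ``chrom`` (str), ``pos_bp`` (int, 1-based), ``snp_id``.
    samples : list[str]
        Sample identifiers.
    populations : list[str]
        Population label per sample, aligned with ``samples``.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    populations: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x markers)")
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} call rows")
        if len(self.populations) != n:
            raise ValueError("populations must align with samples")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} markers for {m} call columns")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls outside the {0,1,2,missing} alphabet")
        validate_marker_map(self.markers)
        self.markers = self.markers.reset_index(drop=True)

    # -- shape / bookkeeping -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def population_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    # -- subsetting ----------------------------------------------------------
    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            calls=self.calls[idx, :].copy(),
            markers=self.markers.copy(),
            samples=[self.samples[i] for i in idx],
            populations=[self.populations[i] for i in idx],
        )

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            calls=self.calls[:, idx].copy(),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            populations=list(self.populations),
        )

    def subset_population(self, population: str) -> "GenotypeMatrix":
        return self.take_samples(self.pop_indices(population))

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy sorted by (chromosome, position).

        Chromosomes sort numerically when their labels are integers.
        """
        key = self.markers.assign(
            _ck=pd.to_numeric(self.markers["chrom"], errors="coerce")
        )
        order = key.sort_values(
            ["_ck", "chrom", "pos_bp"], kind="mergesort"
        ).index.to_numpy()
        return self.take_markers(order)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.samples == other.samples
            and self.populations == other.populations
            and self.markers[list(MARKER_COLUMNS)].equals(
                other.markers[list(MARKER_COLUMNS)]
            )
        )


@dataclass
class QCReport:
    """Itemized record of what a QC pass removed and why."""

    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_snps_in - self.n_snps_out != len(self.removed_snps):
            raise ValueError("SNP counts inconsistent with removal list")
        if self.n_samples_in - self.n_samples_out != len(self.removed_samples):
            raise ValueError("sample counts inconsistent with removal list")

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", i, r) for i, r in self.removed_snps] + [
            ("sample", i, r) for i, r in self.removed_samples
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
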