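"""End-to-end orchestration: QC -> (PCA | F_ST+LSBL | ROH -> islands ->
shared regions) -> annotation, with every stage output written as TSV
and a JSON manifest recording per-stage counts.

QC runs jointly (one pooled pass) for the PCA and differentiation
stages, and separately per population for ROH detection, so each line's
marker set reflects its own call rates — the convention for
multi-line array studies.  Any stage can be skipped by name.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import genotype_io, islands, popdiff, roh, structure

log = logging.getLogger(__name__)

STAGES = ("qc", "pca", "fst", "lsbl", "roh", "islands", "annotate")


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    out_dir: str
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    pop_map: str | None = None  # TSV sample<TAB>population, required for VCF
    genes: str | None = None  # BED/TSV gene table for the annotate stage
    flank_bp: int = 50_000
    snp_call_rate: float = 0.95
    maf: float = 0.05
    sample_call_rate: float = 0.95
    window_size_bp: int = 50_000
    window_step_bp: int = 10_000
    top_fraction: float = 0.01
    pca_k: int = 10
    alpha: float = 0.05
    merge_gap_bp: int = 1_000_000
    roh_params: roh.RohParams = field(default_factory=roh.RohParams)
    skip: tuple[str, ...] = ()

    def __post_init__(self):
        if (self.ped is None) == (self.vcf is None):
            raise ValueError("provide exactly one of ped/map or vcf input")
        if self.ped is not None and self.map is None:
            raise ValueError("ped input requires a map file")
        if self.vcf is not None and self.pop_map is None:
            raise ValueError("vcf input requires a pop_map file")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "roh_params" in raw:
            raw["roh_params"] = roh.RohParams(**raw["roh_params"])
        if "skip" in raw:
            raw["skip"] = tuple(raw["skip"])
        return cls(**raw)


def _read_pop_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, default=str)
    manifest: dict = {"stages": {}, "outputs": {}, "skipped": list(cfg.skip)}
    t0 = time.time()

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        log.info("stage %-8s %s", stage, info)

    def emit(name: str, df: pd.DataFrame) -> str:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = str(path)
        return str(path)

    try:
        # ---- load ---------------------------------------------------------
        if cfg.ped is not None:
            g_raw = genotype_io.read_plink_text(cfg.ped, cfg.map)
        else:
            g_raw = genotype_io.read_vcf(cfg.vcf, _read_pop_map(cfg.pop_map))
        g_raw = g_raw.sort_markers()
        record("load", n_samples=g_raw.n_samples, n_snps=g_raw.n_markers,
               populations=g_raw.population_set)

        # ---- joint QC -----------------------------------------------------
        if "qc" not in cfg.skip:
            g, qc_report = genotype_io.qc_filter(
                g_raw, cfg.snp_call_rate, cfg.maf, cfg.sample_call_rate
            )
            emit("qc_report", qc_report.to_frame())
            record("qc", n_snps_in=qc_report.n_snps_in, n_snps_out=qc_report.n_snps_out,
                   n_samples_in=qc_report.n_samples_in,
                   n_samples_out=qc_report.n_samples_out)
        else:
            g = g_raw

        pops = g.population_set

        # ---- PCA ----------------------------------------------------------
        if "pca" not in cfg.skip:
            k = min(cfg.pca_k, g.n_samples - 1, g.n_markers)
            pca = structure.genotype_pca(g, k=k)
            path = out / "pca.eigenvec.tsv"
            structure.write_eigenvec(pca, path)
            manifest["outputs"]["pca_eigenvec"] = str(path)
            record("pca", k=k,
                   explained=[round(float(v), 4) for v in pca.explained_variance])

        # ---- pairwise F_ST + windows -------------------------------------
        windows_by_pair: dict[tuple[str, str], pd.DataFrame] = {}
        if "fst" not in cfg.skip:
            for pa, pb in itertools.combinations(pops, 2):
                snp_fst = popdiff.wc_fst_per_snp(g, pa, pb)
                emit(f"fst_snp_{pa}_{pb}", snp_fst)
                w = popdiff.windowed_fst(
                    snp_fst, cfg.window_size_bp, cfg.window_step_bp
                )
                windows_by_pair[(pa, pb)] = w
                emit(f"fst_windows_{pa}_{pb}", w)
            record("fst", pairs=len(windows_by_pair),
                   windows={f"{a}-{b}": len(w)
                            for (a, b), w in windows_by_pair.items()})

        # ---- LSBL + top windows ------------------------------------------
        if "lsbl" not in cfg.skip and len(pops) == 3 and "fst" not in cfg.skip:
            a, b, c = pops
            wl = popdiff.windowed_lsbl(
                popdiff.wc_fst_per_snp(g, a, b),
                popdiff.wc_fst_per_snp(g, a, c),
                popdiff.wc_fst_per_snp(g, b, c),
                cfg.window_size_bp,
                cfg.window_step_bp,
            )
            emit("lsbl_windows", wl)
            sel_rows = {}
            for col, tag in (("fst_ab", "fst"), ("l_a", "lsbl")):
                mask, tied = popdiff.top_fraction(
                    wl[col].to_numpy(), cfg.top_fraction
                )
                sel = wl[mask]
                emit(f"top_windows_{tag}", sel)
                sel_rows[tag] = sel
            overlap = popdiff.intersect_selected(
                sel_rows["fst"], sel_rows["lsbl"]
            )
            emit("top_windows_overlap", overlap)
            record("lsbl", n_windows=len(wl),
                   n_top_fst=len(sel_rows["fst"]),
                   n_top_lsbl=len(sel_rows["lsbl"]),
                   n_overlap=len(overlap))

        # ---- ROH per population (per-population QC) ----------------------
        regions_by_pop: dict[str, pd.DataFrame] = {}
        pop_sizes: dict[str, int] = {}
        pop_matrices: dict[str, "genotype_io.GenotypeMatrix"] = {}
        if "roh" not in cfg.skip:
            seg_frames = []
            roh_counts = {}
            for pop in pops:
                gp = g_raw.subset_population(pop)
                if "qc" not in cfg.skip:
                    gp, _ = genotype_io.qc_filter(
                        gp, cfg.snp_call_rate, cfg.maf, cfg.sample_call_rate
                    )
                het = float(
                    (gp.calls == 1).sum() / (gp.calls != -1).sum()
                )
                params = cfg.roh_params.with_min_snps(
                    cfg.alpha, gp.n_markers, gp.n_samples, het
                )
                segs = roh.detect_roh_population(gp, params)
                roh.audit_segments(segs, params)
                segs = segs.assign(population=pop)
                seg_frames.append(segs)
                pop_sizes[pop] = gp.n_samples
                pop_matrices[pop] = gp
                roh_counts[pop] = {
                    "n_samples": gp.n_samples, "n_snps": gp.n_markers,
                    "min_snps_in_run": params.min_snps_in_run,
                    "n_segments": len(segs),
                }
            all_segs = pd.concat(seg_frames, ignore_index=True)
            emit("roh_segments", all_segs)
            record("roh", **roh_counts)

            # ---- islands --------------------------------------------------
            if "islands" not in cfg.skip:
                inc_frames = []
                for pop in pops:
                    gp = pop_matrices[pop]
                    segs = all_segs[all_segs["population"] == pop]
                    inc = islands.snp_incidence(segs, gp.markers, pop_sizes[pop])
                    inc_frames.append(inc.assign(population=pop))
                    if (inc["count"] > 0).any():
                        regions_by_pop[pop] = islands.call_islands(
                            inc, cfg.top_fraction, cfg.merge_gap_bp, population=pop
                        )
                emit("roh_incidence", pd.concat(inc_frames, ignore_index=True))
                if regions_by_pop:
                    table = islands.island_table(regions_by_pop)
                    emit("roh_islands", table)
                    if len(regions_by_pop) >= 2:
                        shared = islands.shared_regions(regions_by_pop)
                        emit("roh_islands_shared", shared)
                    record("islands",
                           regions={p: len(r) for p, r in regions_by_pop.items()})

        # ---- annotation ---------------------------------------------------
        if "annotate" not in cfg.skip and cfg.genes is not None and regions_by_pop:
            genes = annotate_mod.read_gene_table(cfg.genes)
            hits = annotate_mod.genes_in_flank(
                islands.island_table(regions_by_pop), genes, cfg.flank_bp
            )
            emit("island_gene_hits", hits)
            record("annotate", n_genes=len(genes), n_hits=len(hits))

    except Exception as exc:  # mark partial outputs, then re-raise
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
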