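import numpy as np
import pandas as pd
import pytest

from oracles import min_snp_count_oracle, roh_oracle
from rohsweep.datatypes import MISSING
from rohsweep.roh import (
    RohParams,
    audit_segments,
    detect_roh,
    detect_roh_population,
    min_snp_count,
    segments_to_bed,
    summarize_roh,
)
from rohsweep.simulate import PlantedSegment, SimConfig, simulate_genotypes


def oracle_params(p: RohParams) -> dict:
    return dict(
        window_snps=p.window_snps, max_het=p.max_het_per_window,
        max_missing=p.max_missing_per_window, min_length_bp=p.min_length_bp,
        max_bp_per_snp=p.max_bp_per_snp, max_gap_bp=p.max_gap_bp,
        hit_threshold=p.window_hit_threshold,
        min_snps_in_run=p.min_snps_in_run,
    )


class TestMinSnpCount:
    def test_worked_examples(self):
        assert min_snp_count(0.05, 1000, 100, 0.5) == 21
        assert min_snp_count(0.05, 34_497, 1500, 0.25) == 73

    @pytest.mark.parametrize(
        "alpha,ns,ni,het",
        [(a, ns, ni, h) for a in (0.01, 0.05, 0.2) for ns in (500, 40_000)
         for ni in (10, 2000) for h in (0.1, 0.3, 0.6)],
    )
    def test_grid_matches_direct_arithmetic(self, alpha, ns, ni, het):
        assert min_snp_count(alpha, ns, ni, het) == min_snp_count_oracle(
            alpha, ns, ni, het
        )

    def test_monotone_in_each_argument(self):
        base = (0.05, 10_000, 500, 0.3)
        l0 = min_snp_count(*base)
        # stricter alpha, more SNPs or individuals -> never fewer SNPs needed
        assert min_snp_count(0.025, *base[1:]) >= l0
        assert min_snp_count(base[0], 20_000, *base[2:]) >= l0
        assert min_snp_count(base[0], base[1], 1000, base[3]) >= l0
        # higher heterozygosity -> chance runs rarer -> never more needed
        assert min_snp_count(base[0], base[1], base[2], 0.5) <= l0

    def test_domain_errors(self):
        for bad in [(0.0, 10, 10, 0.5), (0.05, 0, 10, 0.5), (0.05, 10, 10, 0.0),
                    (0.05, 10, 10, 1.0)]:
            with pytest.raises(ValueError):
                min_snp_count(*bad)


class TestDetect:
    def test_all_heterozygous_yields_nothing(self, make_g):
        g = make_g(np.ones((1, 300), dtype=np.int8))
        assert detect_roh(g, "s0", RohParams()).empty

    def test_planted_homozygous_block_recovered(self, make_g):
        # 3 Mb homozygous block (SNP every 10 kb) inside het-rich flanks
        rng = np.random.default_rng(4)
        m = 900
        pos = np.arange(1, m + 1) * 10_000
        calls = rng.choice([0, 1, 2], size=(1, m), p=[0.3, 0.4, 0.3]).astype(np.int8)
        calls[0, 300:601] = np.where(rng.random(301) < 0.5, 0, 2)
        g = make_g(calls, pos=pos)
        params = RohParams()
        segs = detect_roh(g, "s0", params)
        assert len(segs) == 1
        window_span = pos[params.window_snps] - pos[0]
        assert abs(segs["start_bp"].iloc[0] - pos[300]) <= window_span
        assert abs(segs["end_bp"].iloc[0] - pos[600]) <= window_span
        expected = roh_oracle(calls[0], pos, **oracle_params(params))
        assert list(segs[["start_bp", "end_bp", "n_snps", "length_bp"]]
                    .itertuples(index=False, name=None)) == expected

    def test_sub_minimum_length_block_rejected(self, make_g):
        rng = np.random.default_rng(5)
        m = 400
        pos = np.arange(1, m + 1) * 10_000  # 0.8 Mb block = 80 SNPs
        calls = rng.choice([0, 1, 2], size=(1, m), p=[0.3, 0.4, 0.3]).astype(np.int8)
        calls[0, 150:231] = 0
        g = make_g(calls, pos=pos)
        assert detect_roh(g, "s0", RohParams()).empty

    def test_chromosome_shorter_than_window_skipped(self, make_g):
        g = make_g(np.zeros((1, 30), dtype=np.int8))
        assert detect_roh(g, "s0", RohParams()).empty

    def test_unsorted_markers_rejected(self, make_g):
        g = make_g(np.zeros((1, 3), dtype=np.int8), pos=[300, 100, 200])
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(g, "s0")

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_matrices(self, make_g, seed):
        """Vectorized detector equals brute-force enumeration of the
        window/membership/gap/length/density/min-SNP criteria."""
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(300, 2000))
        pos = np.sort(rng.choice(np.arange(1, m * 20_000), size=m, replace=False))
        # homozygosity-rich genotypes so candidate runs actually occur
        p = rng.beta(0.2, 0.2, size=m)
        calls = rng.binomial(2, p, size=(3, m)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.02] = MISSING
        # make one individual's middle stretch fully homozygous
        lo = m // 3
        calls[0, lo : lo + 200] = 2
        g = make_g(calls, pos=pos)
        params = RohParams(min_snps_in_run=int(rng.integers(0, 60)))
        for i, sample in enumerate(g.samples):
            segs = detect_roh(g, sample, params)
            got = list(
                segs[["start_bp", "end_bp", "n_snps", "length_bp"]]
                .itertuples(index=False, name=None)
            )
            assert got == roh_oracle(calls[i], pos, **oracle_params(params))
            audit_segments(segs, params)

    def test_raising_min_length_never_adds_segments(self, make_g):
        rng = np.random.default_rng(8)
        m = 1500
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=m, replace=False))
        p = rng.beta(0.2, 0.2, size=m)
        calls = rng.binomial(2, p, size=(2, m)).astype(np.int8)
        g = make_g(calls, pos=pos)
        counts = [
            len(detect_roh_population(g, RohParams(min_length_bp=L)))
            for L in (500_000, 1_000_000, 2_000_000, 5_000_000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPlantedRecovery:
    def test_planted_segments_recovered_in_carriers(self):
        """>=95% of carriers of a planted >=2 Mb autozygous segment (pooled
        over 5 seeds) get detected ROH whose outermost breakpoints lie
        within one window span of the planted interval.  A chance cluster
        of missing calls can split one long run into two; the fragments
        still delimit the segment, so recovery is judged on the union.
        """
        recovered = total = 0
        for seed in range(5):
            cfg = SimConfig(
                pop_names=("P",), pop_sizes=(60,), n_snps=2500, n_chroms=1,
                chrom_length_bp=25_000_000, target_fst=0.05, missing_rate=0.02,
                planted_segments=(
                    PlantedSegment("P", 0.5, "1", 8_000_000, 11_000_000),
                ),
                seed=200 + seed,
            )
            g, truth = simulate_genotypes(cfg)
            het = float((g.calls == 1).sum() / (g.calls != MISSING).sum())
            params = RohParams().with_min_snps(0.05, g.n_markers, g.n_samples, het)
            segs = detect_roh_population(g, params)
            audit_segments(segs, params)
            planted = truth.planted[0]
            pos = g.markers["pos_bp"].to_numpy()
            inside = pos[(pos >= planted["start_bp"]) & (pos <= planted["end_bp"])]
            span = int(np.median(np.diff(pos))) * params.window_snps
            for sample in planted["carriers"]:
                s = segs[(segs["sample_id"] == sample)
                         & (segs["end_bp"] >= inside[0])
                         & (segs["start_bp"] <= inside[-1])]
                total += 1
                recovered += (
                    len(s) > 0
                    and s["start_bp"].min() <= inside[0] + span
                    and s["end_bp"].max() >= inside[-1] - span
                )
        assert recovered / total >= 0.95


class TestSummaries:
    def _seg(self, sample, chrom, start, end, n=50):
        return (sample, chrom, start, end, n, end - start)

    def test_length_class_assignment(self):
        cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        segs = pd.DataFrame([self._seg("s1", "1", 1_000_000, 3_000_000)],
                            columns=cols)
        summary = summarize_roh(segs, {"1": 100_000_000})
        counts = dict(zip(summary.length_classes["length_class"],
                          summary.length_classes["count"]))
        assert counts == {"1-5 Mb": 1, "5-10 Mb": 0, ">10 Mb": 0}

    def test_per_individual_totals(self):
        cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        segs = pd.DataFrame(
            [self._seg("s1", "1", 1_000_000, 3_000_000),
             self._seg("s1", "1", 10_000_000, 16_000_000),
             self._seg("s1", "2", 1_000_000, 5_000_000),
             self._seg("s2", "1", 1_000_000, 2_000_000)],
            columns=cols,
        )
        summary = summarize_roh(segs, {"1": 50_000_000, "2": 50_000_000},
                                n_individuals=2)
        s1 = summary.per_individual.set_index("sample_id").loc["s1"]
        assert s1["n_roh"] == 3
        assert s1["total_length_mb"] == pytest.approx(12.0)
        counts = dict(zip(summary.length_classes["length_class"],
                          summary.length_classes["count"]))
        assert counts == {"1-5 Mb": 3, "5-10 Mb": 1, ">10 Mb": 0}
        cov1 = summary.per_chromosome.set_index("chrom").loc["1", "coverage"]
        assert cov1 == pytest.approx((2e6 + 6e6 + 1e6) / (2 * 50e6))

    def test_mixed_length_classes_from_fixture(self):
        cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        segs = pd.DataFrame(
            [self._seg("s1", "1", 1_000_000, 3_000_000),
             self._seg("s1", "1", 10_000_000, 16_000_000),
             self._seg("s1", "2", 1_000_000, 13_000_000)],
            columns=cols,
        )
        summary = summarize_roh(segs, {"1": 50_000_000, "2": 50_000_000})
        assert summary.length_classes["count"].tolist() == [1, 1, 1]

    def test_segment_beyond_chromosome_raises(self):
        cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        segs = pd.DataFrame([self._seg("s1", "1", 1_000_000, 3_000_000)],
                            columns=cols)
        with pytest.raises(ValueError, match="beyond"):
            summarize_roh(segs, {"1": 2_000_000})

    def test_bed_export_is_zero_based_half_open(self):
        cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        segs = pd.DataFrame([self._seg("s1", "1", 100, 200)], columns=cols)
        bed = segments_to_bed(segs)
        assert bed[["start", "end"]].iloc[0].tolist() == [99, 200]
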