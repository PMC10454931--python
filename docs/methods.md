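# Methods

This note records the models and procedures `rohsweep` implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## Data model

Genotypes are alt-allele dosages in an int8 samples × markers matrix
(0 hom-ref, 1 het, 2 hom-alt, −1 missing) with a marker map (chromosome
label, 1-based bp position, marker id) and a population label per
sample. Missing is a first-class fourth state: it is never imputed in
the matrix itself, and each operation declares its own handling (QC and
F<sub>ST</sub> drop missing calls per marker; ROH windows count them;
PCA mean-imputes internally without writing back). Autosomes "1".."18"
(the pig assembly) are the default coordinate universe; markers
elsewhere are treated as unplaced by QC.

PLINK .ped/.map files carry no ref/alt designation, so the reader
recodes each marker to minor-allele = alt (ties broken toward the
lexicographically larger allele). That recode is not invertible when
the alt frequency exceeds 0.5; the writer therefore always emits
ref='A'/alt='C', and `read_plink_text(..., alt_allele="C")` restores
the written polarity exactly. VCF round trips need no such hint because
REF/ALT are explicit. Downstream statistics are polarity-invariant
(tested), so the default recode is safe for analysis either way.

## Quality control

Order is fixed and deliberate: (1) SNPs with unknown position
(chromosome outside the autosome set or position ≤ 0), (2) SNP call
rate < 0.95, (3) MAF < 0.05 computed on pooled non-missing allele
counts, then (4) samples with call rate < 0.95 over the surviving
SNPs. "Less than" is removed, so a marker exactly at a threshold is
kept. Running SNP filters first means a sample is never discarded for
missingness concentrated in markers that were already doomed; a test
constructs a matrix where the two orders disagree to pin this down.
QC can be run jointly (one pooled pass — the default for PCA and
differentiation, matching a single merged PLINK run) or per population
(the default for ROH, where each line's marker set should reflect its
own call rates); the pipeline does both accordingly.

## Weir–Cockerham F<sub>ST</sub>

The two-population diploid estimator of Weir & Cockerham (1984) with
variance components a, b, c computed from per-population sample size,
allele frequency and observed heterozygote fraction — the estimator
VCFtools reports. Per-marker estimates are undefined (flagged, num =
den = 0) when either population has fewer than two genotyped
individuals or the pooled denominator is zero. Negative estimates are
retained; clamping at zero would bias window sums and LSBL branches.

Windows are 1-based inclusive [start, start + size − 1], the first
window starting at bp 1 of each chromosome and starts advancing by the
step (VCFtools convention; defaults 50 kb / 10 kb). A SNP contributes
to every window containing it, so with size/step = 5 an interior SNP
sits in exactly 5 windows. The per-window statistic is the
ratio-of-sums Σnum/Σden ("weighted"); the mean of per-SNP ratios is
carried alongside. Windows with no defined SNP are dropped rather than
reported as zero.

LSBL is computed per window on the three pairwise windowed series
(per-SNP mode is also available): L_a = (F_ab + F_ac − F_bc)/2 and
cyclic permutations. The identities L_a + L_b = F_ab and
ΣL = ½ΣF hold algebraically and are enforced to 1e−12 in tests.
Negative branches are possible with noisy or negative pairwise inputs
and are flagged, not suppressed.

Top-fraction selection takes k = ⌈fraction · n⌉ units, then expands to
include every unit tied with the cut-off score, with a flag when ties
expanded the set. NaN scores are never selected. Overlap between two
scans' selections defaults to exact window identity; an interval-overlap
mode exists for selections on different grids.

## ROH detection

Per individual and chromosome: a 50-SNP window slides one SNP at a
time; a window passes with ≤ 1 heterozygous and ≤ 2 missing calls
(counts, not proportions). Truncated windows at chromosome ends are
not evaluated; a chromosome with fewer than 50 markers yields no calls.
A SNP is a run member when the fraction of evaluated windows covering
it that pass is ≥ 0.05 — the PLINK/detectRUNS convention for turning
window verdicts into SNP verdicts. Maximal member stretches are split
at inter-SNP gaps > 1 Mb, then filtered: span ≥ 1 Mb, density ≥ 1 SNP
per 500 kb, and member count ≥ l, where

    l = ⌈ ln(α / (n_s · n_i)) / ln(1 − het) ⌉

bounds the expected number of chance runs at rate α (default 0.05):
a run of l homozygous calls arises spontaneously with probability
(1 − het)^l, Bonferroni-corrected over the n_s · n_i tested positions.
`het` is the mean observed heterozygosity across the population's
retained SNPs. Missing calls inside a run are permitted members — they
are neither heterozygous nor density-breaking beyond the window rule.

Segment length is end − start (no +1), matching the convention by
which the published pig island table's printed lengths reproduce
exactly from its printed coordinates. Segments are classified 1–5,
5–10 and > 10 Mb. An audit pass re-checks every emitted segment
against all constraints and the within-individual non-overlap
invariant; the vectorized detector is tested for exact equality against
a plain-loop enumerator of the same criteria on random matrices.

One behavioural consequence worth knowing: at ~2% missingness a
50-SNP window fails with probability ≈ 8%, and a chance cluster of
missing calls can split one long autozygous run into two fragments or
shave its edge. Recovery of planted segments is therefore assessed on
the union of detected runs overlapping the truth interval, with the
outermost breakpoints required to lie within one window span; under
the test conditions (60 individuals, 50% carriers of a 3 Mb segment,
~7 kb marker spacing, 2% missingness, five seeds pooled) this recovers
≥ 95% of carriers. Split-rate sensitivity to the missingness pattern
is inherent to the window rule, not to this implementation.

## ROH islands and shared regions

Per-SNP incidence counts, for each marker, the distinct individuals
with a detected segment covering it (both bounds inclusive);
same-individual overlaps are unioned first so nobody is double-counted.
The denominator is the post-QC population size. The top 1% of SNPs by
incidence (same tie rule as the window scans) are merged into regions
while consecutive selected SNPs are ≤ 1 Mb apart — the merge gap reuses
the ROH max-gap default because no separate convention exists; it is a
parameter, and splitting at any unselected SNP is reachable by setting
it small. Region bounds are first/last member SNP positions, so length
is end − start, matching the published table arithmetic.

Shared regions across k populations are the k-way interval
intersections [max(starts), min(ends)], kept when non-empty in every
population, and invariant to population order. On the bundled
published island table, intersecting the three lines' chromosome-6
intervals yields 105,105,811–107,369,304 (2,263,493 bp), which equals
the smallest (Danish) interval — the nested case.

## Annotation

A gene hits a region when its body overlaps the region extended by a
flank on each side, closed intervals, same chromosome required; strand
is carried but ignored. The signed distance is gene start minus region
start, with "Upstream"/"Downstream" labels derived from the sign only.
Two flank conventions are in common use — 50 kb around ROH-island SNPs
and 500 kb around selection-scan SNPs — so the flank is a required
explicit argument with no silent default. BED input is converted
0-based half-open → 1-based closed by a dedicated, tested converter.

## PCA

Dosages are centered on 2p and scaled by √(2p(1−p)) (Patterson-style
normalization; PLINK differs only by constants that do not affect
separation). Missing calls are mean-imputed for the decomposition
only. Monomorphic markers are excluded (their scale is undefined) with
a log entry. The SVD of the standardized matrix gives coordinates
U·S and explained-variance fractions s²ᵢ/Σs²; each PC's sign is fixed
by making its largest-magnitude loading positive, so repeated runs and
sample-order permutations reproduce identical coordinates.

## Simulator

The generator emulates the study design the pipeline targets: three
lines drifted from one ancestral pool, chip-style marker maps, per-call
missingness, planted autozygosity. Ancestral frequencies are
Uniform(0.05, 0.95); each population's frequencies are Beta(p(1−c)/c,
(1−p)(1−c)/c) — Balding–Nichols, where the drift parameter c equals
the expected pairwise F<sub>ST</sub>, giving a closed-form target that
the Weir–Cockerham estimate recovers within ±0.02 at 5,000 SNPs and
100 diploids per population. Genotypes are independent binomial(2, p)
draws; positions are uniform within chromosomes. Defaults follow the
target cohort scale (500/295/1500 individuals, ~45k SNPs, 18
autosomes); tests run the same configuration at reduced size — three
populations of tens of individuals and a few thousand SNPs — which
keeps the whole suite around two minutes on one CPU.

Planted segments overwrite each carrier's genotypes with one shared
homozygous haplotype drawn from the population's frequencies, so both
per-individual detection and cross-individual island incidence see the
same footprint; missingness is applied last, so planted intervals are
fully homozygous before dropout, and the truth registry records exact
coordinates and carrier ids. The same seed yields byte-identical
output.

What the simulator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: linkage disequilibrium
(sites are independent, so background homozygosity runs are rarer and
shorter than on a real 50K chip, and the false-positive behaviour of
the minimum-SNP rule is optimistic), pedigree-driven inbreeding (no
relatedness structure), ascertainment bias of chip SNP selection,
non-uniform marker spacing, genotype-calling error (missingness is the
only error mode), and selection dynamics (differentiation is pure
drift; the planted-sweep test perturbs frequencies directly).

## Numerical and degenerate-input conventions

Undefined per-SNP F<sub>ST</sub> (small samples, monomorphic pooled
pair) is flagged and excluded from windows; an empty chromosome or one
shorter than the ROH window logs and yields nothing; QC raises
explicitly when nothing survives; `min_snp_count` rejects het ∈ {0, 1}
(the bound is undefined at those limits). Ties: top-fraction selection
expands at the cut; PLINK allele recode breaks frequency ties toward
the lexicographically larger allele; PC signs follow the
largest-loading rule. All randomness flows through
`numpy.random.default_rng` seeded from explicit configuration — no
global state.

## Known limitations

Only the sliding-window ROH mode is implemented (no consecutive-runs
mode, no F_ROH against pedigree, no X chromosome). LSBL is defined for
exactly three populations. Binary PLINK .bed is not parsed. Gene
annotation is positional only, against local tables — no enrichment
analysis and no remote databases.
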