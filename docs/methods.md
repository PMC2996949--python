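# Methods

`herdld` characterizes genome-wide linkage disequilibrium (LD) in SNP-chip
panels from livestock populations organized in large paternal half-sib
families, and ships a forward-time simulator that generates populations with
the statistical structure those analyses assume. This note documents the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic studies do and do not demonstrate.

## LD statistics

For two biallelic loci with alleles A/a and B/b, haplotype frequencies
π_AB, π_Ab, π_aB, π_ab and allele frequencies π_A = π_AB + π_Ab etc., the
package computes

    D    = π_AB − π_A·π_B
    r²   = D² / (π_A·π_a·π_B·π_b)
    |D'| = |D| / D_max,   D_max = min(π_A·π_b, π_a·π_B)   if D > 0
                          D_max = min(π_A·π_B, π_a·π_b)   if D < 0

Frequencies come from direct counting over phased haplotypes; haplotypes
with unknown phase at either locus are dropped pairwise. All arithmetic is
carried out on the integer haplotype counts (D = (ad − bc)/n² with
a..d the class counts), so the boundary identities are exact in floating
point: |D'| = 1 exactly when a haplotype class is absent, and r² = 1
exactly when only two complementary classes remain. Conventions: D = 0
maps to |D'| = 0 (no information, continuity); a locus monomorphic among
the usable haplotypes makes the pair "undefined" rather than an error,
because animal subsampling can create such pairs transiently. Pair
distance is |pos_i − pos_j| in bp on the displayed map. The "mean MAF" of
a pair is the average of the two within-pair minor-allele frequencies
computed on the same usable haplotypes.

The pairwise engines (`scope = syntenic | adjacent | non_syntenic`) are
vectorized over count matrices (masked matrix products), so a
3,000-marker genome at ~1,000 haplotypes is processed in well under a
second.

## Decay, windows, gene context

Syntenic pairs are binned by distance with lower-closed, upper-open edges
(default 0–40 kb, 40–60 kb, 60–100 kb, 100–200 kb, 200–500 kb, 0.5–1 Mb,
1–2, 2–5, 5–10, 10–20, 20–50, 50–100, >100 Mb — shared endpoints force a
convention and [lo, hi) is stated in all outputs). Per bin: n, mean, SD
(ddof = 1; a single-pair bin reports SD = 0), median, threshold fractions
(r² > 0.3, r² > 0.15, |D'| > 0.8), and a percentile-bootstrap CI of the
mean (default 1,000 resamples, 2.5th/97.5th percentiles; plain percentile,
not BCa). Sliding windows are 2 Mb advancing by 100 kb (i.e. 1.9 Mb
overlap); a window's mean uses pairs with both markers inside it and
separation in [200, 600] kb, and windows with fewer than 20 such pairs are
reported uninformative. Gene-context classification calls a pair
intragenic when both markers fall inside the span of one common gene
(1-based closed intervals; BED input is converted on read), intergenic
when both markers are outside all genes, and "mixed" otherwise; mixed
pairs are excluded from the two-group summary because a two-group table
cannot place them without an arbitrary rule.

## Misplaced-marker detection and relocation

For each marker the same-chromosome partner with the largest r² is found
(ties broken by smaller distance, then smaller marker index — this makes
the scan deterministic and favors local partners on r² plateaus). A marker
whose best partner lies farther than 10 Mb away is flagged: genuine LD is
negligible at that range, so a distant best partner indicates an assembly
coordinate error. The proposed correction is the midpoint of the two
highest-r² partners' positions.

Accuracy expectations, measured on simulations: the detector recovers
≥ 8/10 markers displaced by ≥ 10 Mb; remaining flags are "shadows" —
markers whose best partner is itself a displaced marker — which are
attributable, not spurious, and disappear once the displaced markers are
corrected. Relocation is coarse by construction: the two best realized-LD
partners need not bracket the true site, so the median error is a few
inter-marker spacings (hundreds of kb at 66 kb spacing), never approaching
the ≥ 10 Mb displacement being repaired. Displacements of only a few Mb
are invisible to the 10 Mb rule; no attempt is made to improve on that.

## Sample-size and MAF bias

`subsample_experiment` draws animals with replacement (the animal is the
sampling unit; all of its haplotypes enter the subsample) at sizes
22, 55, 111, 222, 444, 665 and "all" (the full data, evaluated once
without resampling), 200 replicates by default, and recomputes mean r² and
|D'| on a fixed, seeded pair set per distance range so that sizes are
compared like-for-like. Expected behavior, reproduced by the tests: |D'|
inflates steadily as the sample shrinks (missing haplotype classes push
|D'| toward 1), while mean r² is already stable within 0.02 of the
full-data value from n = 55 up.

`residual_ld_by_maf` removes the distance trend by subtracting each pair's
distance-bin mean, then groups pairs by mean MAF in 0.05-wide groups.
Residual |D'| is strongly positive in the lowest group ([0.05, 0.10)) and
negative in the highest ([0.45, 0.50)) — the D_max denominator is a small
product of frequencies when an allele is rare — while residual r² stays
within ±0.02 across the post-QC MAF range. Pairs whose within-panel mean
MAF falls below 0.05 (possible after pairwise deletion even when every
marker passed the per-marker MAF filter) are outside the calibrated range
and are excluded from the flatness statement.

`compare_parental_freqs` contrasts paternal against maternal haplotype
frequencies per pair with a Pearson χ² that treats the maternal
frequencies as the expected law (expected = maternal frequency × paternal
count; df = classes after pooling − 1; classes with zero maternal
frequency are pooled into the smallest non-zero class). Because the
statistic conditions on the maternal frequencies, its calibrated null is a
paternal pool drawn i.i.d. from the maternal pool's law; under that null
the flagged fraction at α = 0.01 sits inside the 3-SE binomial band.
Contrasting two same-size samples of a common law instead roughly doubles
the statistic and inflates rejections — which is also why, on real
half-sib data where sires are reused heavily, a large share of pairs is
flagged and maternal-only analysis is the recommended default
(`phase.maternal_only` in the pipeline config).

## X chromosome

In a male-only panel, X-specific SNPs are hemizygous and chip-coded as
homozygotes, so males show at most the two homozygote classes;
pseudo-autosomal (PAR) SNPs sit on X and Y and can be heterozygous.
Markers are classified PAR-like when heterozygous males are observed —
equivalent to the "three genotype classes" rule at large n, and robust at
desk scale where the rare homozygote class is often absent. The boundary
scan walks from the terminal (high-bp) end toward the centromere and
places the first PAR marker just terminal-ward of the first run of
≥ `min_run` (default 5) consecutive two-class markers; the run guard keeps
an isolated monomorphic-in-males PAR marker from truncating the PAR, and a
chromosome with no heterozygous terminal segment reports "no PAR".
Stratified LD uses within-region pairs only; cross-boundary pairs belong
to neither region's decay table. The X-specific panel relies on the
convention (shared by the simulator and the phaser) that a male's single X
is his maternal haplotype and the paternal X-specific slot is unknown, so
hemizygosity is handled by ordinary pairwise deletion.

## The synthetic-population generator

Founders are drawn in linkage equilibrium with per-marker allele
frequencies from a near-uniform MAF law on [0.05, 0.5]; all LD is then
generated by G discrete Wright–Fisher generations of random mating.
Gametes recombine by a Poisson/Haldane model: crossover count per gamete
~ Poisson(genetic length), positions uniform, no interference, at
1.25 cM/Mb (the bovine genome average); chromosome length is taken as the
last marker's position. Male X gametes recombine only inside the PAR and
always transmit the single (maternal) X on the X-specific segment; the
male PAR uses an elevated genetic length (default 25 cM) reflecting the
obligate X/Y pairing crossover, which is what depresses PAR LD relative to
the X-specific region. Sexes are assigned 50:50; the half-sib study
samples sires and breeds male progeny, giving each bull a distinct dam
whenever the herd allows (dam reuse across sires would inject long-range
co-ancestry LD into the maternal panel — precisely the artifact
maternal-only analysis exists to avoid). Male X-specific genotypes are
chip-coded 0/2.

Defaults: 10 autosomes × 300 markers at 66 kb mean spacing (gaps uniform
on [0.1, 1.9] × mean, giving the short-distance pairs the first decay bins
need), G = 150 generations at population size 300, with the final
generation expanded to 900 so that 40 sires × 10 bulls all have distinct
dams. This effective size steepens short-range decay and keeps long-range
drift LD low enough for the misplacement detector's premise; smaller
populations (e.g. N = 100) leave sub-100 kb decay flat relative to
drift-realization noise and produce heavy-tailed long-range LD that the
10 Mb rule then misreads. At these defaults the pooled decay table lands
near real Holstein chip values (mean r² ≈ 0.20 and |D'| ≈ 0.78 at
0–40 kb; average MAF rising from ≈ 0.21 to ≈ 0.28 after the MAF ≥ 0.05
filter). Two purpose-built variants appear in the tests and the
acceptance script: a sparser map (500 kb spacing, N = 200) whose absolute
r² levels match chip studies — the regime for the MAF-residual
diagnostics — and a strong-LD, 4-chromosome study for misplacement
recovery.

What the simulator does not emulate: realistic bovine demography
(bottlenecks, selection, migration), mutation after founding, crossover
interference, genotyping-error processes beyond the injected artifact
models, assembly errors other than within-chromosome displacement, and a
Y chromosome. Passing tests therefore show that the estimators and
detectors recover known structure of a drift-recombination population with
half-sib sampling — not that any particular cattle breed has these LD
values.

## Artifact injection

`inject_artifacts` relocates chosen markers within their chromosome to a
uniform position at least `min_displacement_bp` away (sampled directly
from the valid segments; the map is re-sorted and genotype/haplotype
columns follow their markers), creates Mendelian conflicts by flipping a
progeny call against a homozygous sire (autosomes only — sire→son X
conflicts are undetectable by design and would be unfair ground truth),
and masks calls at a given rate, never masking an injected conflict. The
ledger records every artifact for exact scoring.

## Quality control and phasing

Filters run in a fixed order — unknown location, MAF < 0.05 (computed on
non-missing calls), then > 10% missing — and each marker is charged to the
first rule it fails, making report counts reproducible. Mendelian checks
flag offspring calls incompatible with a genotyped parent (opposite
homozygotes for a single parent; the transmissible-gamete sum rule when
both parents are genotyped) and, when correcting, set the offspring call
to missing — conservative, since the offspring call is the unreplicated
observation. Sire→son checks are skipped on X markers outside a tagged
PAR. Phasing by family rules is sound but deliberately incomplete:
homozygotes and sire-forced heterozygotes only; a heterozygote under a
heterozygous or ungenotyped sire stays unknown rather than guessed.
Simulated analyses default to the simulator's true phase; rule-based
phasing is the path for real data.

## Numerical and reproducibility notes

Every stochastic operation derives its generator from a single integer
seed (NumPy `default_rng([seed, stage])` substreams), so pipeline outputs
are byte-reproducible from config + seed. Bootstrap resampling is chunked
to bound memory on large bins. Undefined LD values propagate as NaN and
are excluded from summaries, never silently zeroed. The problem sizes used
by the test suite and the acceptance script (up to ~3,000 markers and 864
bulls, 8–20 replicate studies) were chosen as the package's desk-scale
defaults; all analyses scale linearly in pairs and haplotypes.
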