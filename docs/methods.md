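# Methods

karyoscope analyses chromosome evolution in nematode genomes where extant
chromosomes are combinations of seven ancestral linkage groups (Nigon
elements A–E, N, X), and where X–autosome fusions have repeatedly created
neo-Y chromosomes: the unfused homologue of the fused autosome becomes
male-limited, stops recombining over most of its length, and degenerates.
This note records the models, the parameter choices, and what the
synthetic genomes do and do not capture.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED). BUSCO tables and
VCFs are converted on read. Report strings are rendered 1-based inclusive
(`chrX:22,300,001–24,943,668`), the convention used in genome-browser
style region text. Windows tile each chromosome from 0; the final window
may be short and is always kept — depth and density values are per-base
means, so short windows remain comparable.

## Chromosome painting

Each conserved single-copy ortholog placed on an assembly is assigned an
ancestral element through an external marker→element table; markers absent
from the table are `unassigned`. Window tallies (nominal 500 kb) use the
window containing the marker *start* — a deterministic convention that
avoids midpoint ties. Fragmented markers are excluded by default;
duplicated ones count each placement with weight 1 (duplication rates in
chromosome-level nematode assemblies are ≤ ~1%, so this choice is
low-impact, and it is configurable).

A chromosome's ancestral *components* are the elements contributing at
least `min_fraction` (default 0.05) of its assigned markers **and** at
least `min_count` (default 10) markers; two or more components mean a
fusion chromosome. Both thresholds exist to keep isolated mis-assigned
markers from triggering spurious fusion calls, and both are CLI-exposed.

### Intermixing statistic

Whether a fusion's two partitions have shuffled together is quantified
with a Wald–Wolfowitz runs test on the element labels of the fused
chromosome's markers, ordered by position (ties by marker id). With n₁
and n₂ labels, E[runs] = 1 + 2n₁n₂/(n₁+n₂) and the classical runs
variance gives a z-score: z ≤ −1.96 is reported as *partitioned* (fewer
runs than random interleaving — the partitions remain distinct), |z| <
1.96 as *intermixed*. For n₁ = n₂ = 1 the variance is exactly zero and
runs is deterministically equal to its expectation; z is defined as 0.
The expectation formula is property-tested against exhaustive enumeration
of all orderings for n₁+n₂ ≤ 8.

## Sex linkage and the shared-region caller

Normalised coverage N is window depth divided by the median depth of
autosomal windows; diploid regions sit near N = 1, regions haploid in one
sex near N = 0.5. Because the divisor must exclude the X before the X is
known, inference is two-pass: normalise by the global median, provisionally
call X = chromosomes haploid in every male (median N in [0.3, 0.75)),
then renormalise over the remaining chromosomes and call again. With the X
at most ~1/6 of windows the provisional divisor is within a few percent of
the final one, so the two passes agree except in pathological inputs.
Ploidy cutpoints (0.3 / 0.75 / 1.3) are midpoints between expected N of
0.5 and 1.0 with slack; they deliberately leave embryo-diluted female X
coverage (~0.8) inside the diploid band. Note the haploid-median call is
inapplicable when more than half of an X is male-diploid (as in a
barely-degenerated neo-Y system); there the X identity must be supplied,
as it is for published chromosome-level assemblies.

X–Y shared regions (male-diploid spans of the X) are called per 100 kb
bin:

1. **masked** if N < `low_coverage_N` (0.25) in *both* sexes — such bins
   carry no ploidy signal; long masked runs are reported separately as
   low-coverage exclusions rather than silently breaking or joining
   regions;
2. otherwise **female-dominated** if N_male/N_female < `ratio_threshold`
   (0.8); zero female coverage with adequate male coverage is *not*
   female-dominated (the ratio is effectively infinite);
3. otherwise **qualifying**.

Qualifying bins are merged when the summed length of intervening
non-qualifying bins is ≤ `merge_gap` (200 kb, inclusive at exactly
200 kb); merged intervals are trimmed to start and end on qualifying bins
and kept when ≥ `min_region_length` (1 Mb, inclusive — the published
description uses both "> 1 Mb" and "at least 1 Mb"; we fix the inclusive
reading). The caller is a pure function and is tested for exact equality
against a brute-force search over all candidate intervals satisfying the
boundary/gap/length predicates (maximal satisfying intervals are provably
disjoint, so the two formulations coincide); monotonicity in
`ratio_threshold` and `min_region_length` is property-tested.

Region sizes are reported in Mb rounded half-up to one decimal, matching
report style; SNP spacings round half-up to integer bp and render as
"1 SNP every 2,215 bp".

## Divergence

X–Y divergence is measured exactly as the underlying study design allows:
within the shared region, male reads carry both gametologs, so divergence
appears directly as heterozygous SNP density in males. VCFs are filtered
to heterozygous, biallelic, single-nucleotide records not labelled
`RefCall` (whole-token, case-sensitive — the label DeepVariant attaches
to reference-supporting candidates). Densities use 50 kb windows;
cross-sample means are per-window arithmetic means. No phasing, no
gametolog alignment, and no strata changepoint inference is attempted —
density tracks are the deliverable, and strata are visible in them.

Y-contig placement uses a generic one-to-one alignment table (≥ 1 kb,
inclusive). Covered fraction per 50 kb window is computed on the *union*
of target intervals (no double counting), while weighted mean identity
Σ(identityᵢ·lengthᵢ)/Σlengthᵢ weights each alignment by its full length;
the two statistics intentionally follow different conventions, mirroring
their separate definitions.

## Sequence features

Telomere counting finds non-overlapping occurrences (greedy,
left-to-right, case-insensitive) of the nematode repeat TTAGGC *and* its
reverse complement, so arrays are detected regardless of assembly strand;
neither hexamer can overlap itself, so greedy counting is unambiguous. An
end is "capped" when ≥ 10 occurrences start within 10 kb of it. Repeat
density is the softmasked (lowercase) fraction per 200 kb window; it is
mask-source sensitive — aggressive general-repeat finders can mask an
order of magnitude more sequence than transposon-focused pipelines — so
densities from different maskers are not comparable. N50 follows the
standard smallest-prefix definition and is tested against a brute-force
oracle. A Phred consensus quality QV implies one error every 10^(QV/10)
bp; the exact conversion is reported (QV 52.9 → 194,984 bp ≈ 195 kb).

## Synthetic genomes

The generator builds chromosomes from the seven elements via an ordered
fusion history. Each fusion event carries its own count of random
internal inversions, applied immediately after that event: older fusions
therefore end up intermixed while later ones keep their partner element
as a distinct terminal partition — the qualitative contrast real fused X
chromosomes show between ancient and recent fusion partners. An
inversion picks two uniform breakpoints and reverses the block structure
between them.

**Marker resolution.** K inversions can create at most ~2K+1 element
runs, so after a 200-inversion history a ~11 Mb fused chromosome cannot
have element blocks much below ~30–50 kb. Markers must therefore be
sparser than that block scale for the fusion history to randomise their
order; the presets place 20 markers per element (~500 kb spacing), a
subsample of a conserved-ortholog catalogue that satisfies this
resolution requirement while staying two-fold above the fusion caller's
`min_count`. Denser marker sets on the same history would report
partitioned structure that is real at their resolution — a property of
rearrangement modelling, not a bug.

**Coverage.** Per-window depth is negative-binomial: the window's total
aligned bases are drawn with mean = per-base mean × window length and
size parameter `depth_dispersion` (default 100, i.e. per-window CV ≈
10%, typical of short-read window depths; the Poisson limit is
dispersion → ∞). Means encode ploidy: autosomes diploid in both sexes;
male X haploid except inside the shared region net of haploid
degeneration strata (boundary windows get overlap-weighted means); female
X diploid but diluted by embryo DNA. The dilution model: a gravid female
contributes DNA fraction e from in-utero embryos at a 1:1 sex ratio, so
the female X:autosome ratio is 1 − e/4; the default e = 0.8 yields the
~80% signal seen in viviparous filarial females. e is a knob, not a
biological claim — the true embryo DNA fraction is unknown.

**SNPs.** Heterozygous SNP positions are Poisson-uniform at
`snp_rate_shared` per bp over the male-diploid span, boosted
`snp_rate_boundary_multiplier`-fold (default 7 ≈ 2215/314) in the single
bin bordering the region's proximal edge, and zero elsewhere. Emitted as
a valid single-sample VCF (GT 0/1) that round-trips through the het-SNP
reader.

**Presets.** Four architectures ship as configs: `litomosoides` (5A+X;
X = X⊕D, 200 inversions; X0; e = 0.8; chromosome sizes 10.5–11.7 Mb,
span 65.9 Mb, N50 10.9 Mb), `dirofilaria` (4A+XY; X = X⊕D⊕E, 28.2 Mb;
the whole 15.2 Mb E partition shared; SNP rate 1/2215), `onchocerca`
(3A+XY with an additional A⊕N autosome fusion; only the distal 3.4 Mb of
E still shared; rate 1/314), and `brugia` (4A+XY via an independent X⊕N
fusion; 24.9 Mb X; 2.6 Mb shared region at the distal end of the N
partition; rate 1/2215). Planted shared regions always lie in the
ancestrally autosomal partition of the X — the generator enforces this,
because a neo-Y can only share sequence it once held as the autosomal
homologue.

**Determinism.** Every output stream (karyotype, markers, per-sex
coverage, SNPs, sequence) draws from an independent substream of a
single seed; identical config + seed reproduces byte-identical fixture
files (SHA-256-verified in tests).

**What the generator does not emulate.** Read-level artefacts
(mappability, GC bias, duplicates), real repeat landscapes and
softmasking, gene structure, recombination or population variation,
continuous degeneration gradients (strata are discrete haploid
intervals), and sequence homology between gametologs. Passing tests
therefore demonstrate that the *inference logic* recovers planted signals
under realistic noise levels, not that real data are free of the
confounders above.

## Problem sizes used in tests

The unit and acceptance suites run entirely on generated data: caller ≡
oracle on exhaustive two-class bin vectors to length 12 (the merge logic
is binary) plus three-class vectors to length 8 and 500 random length-30
vectors under three parameter settings; shared-region boundary recovery
on 20 seeded brugia-like systems (25 Mb X, 100 kb bins, 30× depth);
intermixing over 20 seeds; divergence calibration at ~6,900 expected SNPs
over 15.2 Mb; dilution checks over whole-X medians (≥ 100 bins). The
full suite runs in a few seconds; `scripts/acceptance.py` in a few
seconds more.

## Known limitations

- The haploid-median X call assumes < ~half the X is male-diploid.
- The caller's low-coverage mask uses a single N threshold in both
  sexes; systematically uncovered-but-present sequence (e.g. collapsed
  repeats) is reported as an exclusion, not resolved.
- Marker painting trusts the external marker→element table; no attempt
  is made to re-derive element definitions.
- Spacing summaries divide span by count; they are not confidence
  intervals, and sub-1000-SNP regions carry several percent sampling
  error.
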