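# Methods

This note documents the models, numerical choices and limitations of the
package. Everything stated here is computed by the test suite or the
acceptance script; nothing is asserted beyond what the code measures.

## Data model and coordinates

Genotypes are allele-B dosages (0/1/2, missing = −1) in an
individuals × markers `int8` matrix, with a marker map (chromosome label as
text, 1-based bp position) and one population label per individual (taken
from the PED family-ID column). Internal coordinates are 1-based inclusive,
the MAP convention; BED export converts to 0-based half-open
(`start − 1, end`). The dosage-counted allele at each marker is the second
distinct non-missing allele observed in PED file order. Because the PED
format does not record this orientation, a write/read round trip can flip
it at markers whose first observed genotype is an allele-B homozygote,
mapping calls c → 2 − c; `GenotypeDataset.equals` therefore compares
genotypes orientation-canonically, and all downstream statistics (PCA
after centring, F_ST, homozygosity) are invariant under the flip.
Half-missing PED genotypes ("A 0") are rejected rather than guessed at.

## Quality control

Filters, in a fixed order so removal counts are reproducible:

1. positional — markers with unknown position (chromosome "0"/blank or
   bp 0), markers off autosomes 1–29, and *every* member of a set sharing
   one (chromosome, position);
2. individuals with call rate < 90% over the remaining markers;
3. markers with call rate < 99% over the remaining individuals.

Each removal records the first rule that fired. The order (positions →
individuals → markers) puts the genotype-independent filters first; the
listing order of the call-rate thresholds mirrors single-pass practice.
No HWE, LD-pruning or MAF filter exists in any code path: HWE departures
are an expected consequence of inbreeding, LD is the signal ROH analysis
reads, and MAF filtering deletes homozygous regions. A dataset emptied by
filtering is a reported warning, not an error.

Note the strict 0.99 marker threshold removes any marker with a single
missing call whenever fewer than 100 individuals remain; on small cohorts
with array-typical 0.5% missingness this removes ~25% of markers. That is
the filter's defined behaviour, not a bug.

## PCA

Missing calls are mean-imputed per marker, markers are mean-centred, and
the individuals × individuals covariance matrix (divided by the marker
count) is eigen-decomposed. Centring-only is the default because the
analysis is a (co)variance decomposition; `scale=True` standardises to
unit variance per marker for users who prefer correlation PCA. Scores are
eigenvectors scaled by √λ; explained-variance fractions are λ_k / Σλ.
Component signs are fixed by making each component's largest-magnitude
score positive; eigenvalues are sorted descending and clipped at zero
(they are mathematically non-negative; tiny negative values are numerical
noise). A fully monomorphic dataset yields zero scores plus a warning.

## ROH detection

A qualifying run on one chromosome of one individual

* starts and ends on a homozygous, non-missing SNP,
* contains at most `max_het` (default 1) heterozygous and `max_missing`
  (default 1) missing calls,
* has every gap between consecutive member SNPs ≤ `max_gap_bp` (1 Mb),
  evaluated between consecutive retained SNPs regardless of genotype,
* contains ≥ `min_snps` (20) SNPs and spans ≥ `min_length_bp` (250 kb),
  with length defined as `end_bp − start_bp`.

The detector reports, left to right, the qualifying run with the leftmost
feasible start and — for that start — the maximal end, then resumes after
it. This makes the output a well-defined function of the five criteria
rather than of incidental scan/restart details: the test suite checks
exact equality against an independent exhaustive enumeration of intervals
on thousands of random chromosomes. Requiring homozygous endpoints keeps
run boundaries evidence-bearing (a run never starts or ends on a
heterozygote or missing call, which would otherwise pad its length).
Consequences of these rules: runs of one individual never overlap;
quotas are counted per run, not per window; a violating SNP is never a
run endpoint.

Implementation is a two-pointer scan (amortised linear per chromosome),
feasible because loosening the start of a window never invalidates its
extension. Hot loops are plain Python over per-chromosome numpy slices;
the full default map (~46k SNPs) scans at roughly 20 individuals/second.

Length classes are half-open in Mb — [0,2), [2,4), [4,8), [8,16),
[16,∞) — so each segment lands in exactly one class. Breed summaries
count individuals with zero ROH as zeros in the means.

## F_ROH

`F_ROH = Σ length / L_auto` with `L_auto` defaulting to 2.46 Gb (the
SNP-covered caprine autosomes); per-chromosome values divide by the
SNP-covered span (last − first SNP bp) of each chromosome in the filtered
map, so chromosome coverage is measured against what the array can see.
Published breed-mean worked examples reproduce: 306.0 Mb / 2.46 Gb = 0.12
and 261.7 Mb / 2.46 Gb = 0.11 at two decimals.

## Hotspots

Incidence of a marker in a population = fraction of its individuals with
at least one ROH whose [start, end] contains the marker position
(endpoints inclusive — they are member SNPs). Hotspots are maximal runs of
consecutive map SNPs with incidence ≥ threshold (default 0.40; the
comparison operator is configurable because "40%" can be read inclusively
or strictly) of at least 20 SNPs, never spanning chromosomes.
Consecutiveness is defined on the retained map, not on physical distance.

## Weir–Cockerham F_ST

Per SNP, with per-SNP genotyped sample sizes n₁, n₂ (missing excluded),
allele-B frequencies p₁, p₂ and observed heterozygote frequencies h₁, h₂:

    n̄ = (n₁+n₂)/2          n_c = 2n̄ − (n₁²+n₂²)/(2n̄)
    p̄ = (n₁p₁+n₂p₂)/(2n̄)   s² = [n₁(p₁−p̄)² + n₂(p₂−p̄)²]/n̄
    h̄ = (n₁h₁+n₂h₂)/(2n̄)

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2          θ̂ = a/(a+b+c)

θ̂ is undefined (NaN) when a+b+c = 0 (both samples monomorphic without
heterozygotes) or when n̄ ≤ 1. Negative per-SNP estimates are retained in
averages — clamping would bias recovery upward (a `clamp_negative` option
exists for comparison). Two pairwise summaries are reported because
"average F_ST" is ambiguous:

* `mean_theta` — unweighted arithmetic mean of defined per-SNP θ̂;
* `weighted_theta` — ratio of sums Σa / Σ(a+b+c), the multi-locus
  combination Weir & Cockerham recommend.

They differ materially at strong differentiation: on Balding–Nichols
simulations (n = 200/population, 40k SNPs) the ratio-of-sums estimator
recovers drift 0.015 and 0.14 essentially unbiasedly (measured 0.0150 and
0.140), while the mean of per-SNP ratios is Jensen-biased low at high
drift (measured ≈ 0.111 at F = 0.14; ≈ 0.0144 at F = 0.015). Recovery
claims in the tests therefore anchor on the ratio-of-sums estimator, and
the low-drift case additionally checks the unweighted mean. Top-SNP
candidate windows take the k highest θ̂ (ties broken by map order) with
± 500 kb flanks clipped at position 1 and at the chromosome's last SNP.

## Synthetic data

The generator emulates a four-breed ~50K goat array study by default:
populations of (210, 82, 21, 24) individuals, 46,268 autosomal SNPs over
29 chromosomes totalling 2.46 Gb (chromosome lengths decline linearly
150 → 40 Mb, scaled to the total; positions uniform per chromosome),
ancestral frequencies Uniform(0.05, 0.95), drift F = 0.075 per population
(mid-range of pairwise breed differentiation of 0.015–0.14), 0.5%
missingness and 0.5% heterozygote-error rate (array-typical; ≈ 0.1–0.5
expected heterozygote errors per planted tract, so the detector's
1-heterozygote quota is genuinely exercised). All randomness flows from a
mandatory integer seed through one `numpy` generator; identical seeds give
identical datasets.

Planted autozygosity places non-overlapping fixed-length tracts on
length-weighted random autosomes until the summed length reaches the
target fraction of the genome (overshooting by less than one tract);
within a tract each genotype becomes a homozygote for an allele drawn
from the population frequency, preserving realistic allelic composition.
True F_ROH per individual is recorded exactly as planted length over
genome length.

What the generator does **not** emulate — and what that means for test
interpretation: SNPs are statistically independent (no linkage
disequilibrium, no recombination map, no MAF ascertainment). With
frequencies Uniform(0.05, 0.95) the per-SNP heterozygosity is ≈ 0.365, so
*chance* qualifying runs occur at a measurable rate: a cohort with zero
planted autozygosity still shows baseline F_ROH ≈ 0.010, and detected runs
extend a few SNPs beyond planted tract edges into chance-homozygous
flanks (≈ +0.009 at planted F_ROH 0.2, against ≈ −0.002 of boundary
discretisation loss). Planted-truth recovery is therefore accurate to
about +0.02 in absolute level while the true-versus-estimated correlation
across individuals exceeds 0.999; tests that need marker-exact boundary
recovery use controlled heterozygous backgrounds instead. Real array data
behave differently in both directions: LD makes chance homozygous
stretches longer, which is precisely why the 20-SNP/250-kb minima exist.

## Pipeline and CLI

All inter-stage contracts are plain TSV (plus BED for intervals), so every
stage can be re-run standalone on the previous stage's files; a
`manifest.json` records every parameter, seed and output path. The
`rohfst` command exposes `simulate`, `qc`, `pca`, `roh`, `froh`,
`hotspots`, `fst` and `all`; exit code 2 flags validation errors, 3 I/O
errors. Two runs with the same config and seed produce byte-identical
tables.

## Known limitations

* The consecutive-runs scan is the only detector; no sliding-window mode.
* F_ST is two-population only (no r > 2 joint estimator, no bootstrap
  intervals).
* PED/MAP text is the only genotype input (no binary BED/BIM/FAM, no VCF).
* Chromosome labels "1"–"29" are treated as autosomes (caprine karyotype);
  other labels are filtered as non-autosomal.
* The simulator's independence of SNPs understates chance-ROH length and
  overstates per-window heterozygosity relative to real arrays; absolute
  F_ROH levels from simulated data carry the ≈ +0.01 baseline described
  above.
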