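# Methods

## Coordinate frame

All coordinates are 1-based inclusive, the convention in which human
mitochondrial (rCRS) positions are printed. Mitochondrial genes are
single-exon, so transcript ↔ genome mapping is offset arithmetic: for a
heavy-strand (forward-sense) gene, `genome = genome_start + t − 1`. The
packaged ND5 annotation starts at mtDNA 12337, which places transcript
position 1374 at genome 13710 and the G13708A variant at transcript 1372 —
the G of the GCA codon whose wobble position carries the m¹A. BED input, if
used, is converted from 0-based half-open at the boundary.

All pileup bases are reported on the mRNA-sense strand. The experiment
observes cDNA, so an RT-incorporated base appears in the sense frame as its
Watson–Crick complement (incorporated A → sense T mismatch, C → G). Whether
the original analysis tabulated mismatches on the read strand or the sense
strand before drawing the incorporation inference is not documented;
sense-strand reporting was chosen here because it removes per-read strand
bookkeeping from every downstream stage, and the complement map is an
involution so nothing is lost.

## RT outcome model (the generator)

Each molecule is methylated independently with per-sample stoichiometry θ.
Conditional on methylation, the RT outcome at the site is drawn from

| event | default probability | observable consequence |
|---|---|---|
| read-through | 0.80 | reference base call (A) |
| misincorporate A | 0.10 | sense T mismatch |
| misincorporate C | 0.06 | sense G mismatch |
| misincorporate G | 0.01 | sense C mismatch |
| jump | 0.02 | 1-base deletion at the site |
| arrest | 0.01 | read truncated at the site |

Unmethylated molecules always read through. The event probabilities for
this enzyme/site combination are only published as figures, not numbers, so
these defaults are synthetic: they are chosen to reproduce the qualitative
facts the assay reports — read-through dominates with the processive
enzyme used (SuperScript IV), misincorporation favours A over C over G
(observed as T > G > C mismatch composition), and jumps and arrests are
rare secondary signatures. They are package defaults, not measured values.

Arrest direction: cDNA synthesis runs 3′→5′ along the mRNA, so an arrested
molecule yields cDNA covering only the region 3′ of the site. Arrested
reads therefore never contribute a base call or deletion at the site; they
are observable as truncations (counted, but not turned into a rate — the
analysis uses misincorporation and jumps only, the enzyme being chosen
precisely to minimise arrest).

Sequencing error is uniform substitution at rate 0.001 per emitted base, to
one of the three alternative bases uniformly; there are no indel sequencing
errors, so RT jumps are the only source of deletions and the jump signal is
unconfounded. Reads are single-end, span the full amplicon, and carry
constant Phred quality Q40 ('I'), which is written to FASTQ but never used.

SNP carriers: the variant allele is substituted into every template
molecule (mitochondrial haplogroup variants are effectively homoplasmic)
and θ is forced to 0, reflecting abolished methylation.

Closed forms: `site_base_distribution(θ, params)` gives the exact
distribution of what a molecule contributes at the site after the error
channel, and `expected_signature` the implied mismatch/jump expectations —
e.g. the expected mismatch rate among base calls is
θ·Σp_mis·(1−ε) + (reference reads)·ε corrections, handled exactly rather
than by approximation. Tests compare simulated estimates against these
closed forms at 4 binomial standard errors.
`simulate_signature_counts` draws the same per-molecule multinomial
directly at a given depth, which is distributionally identical to
reads → align → pileup under perfect alignment; an equivalence test checks
this. It exists so calibration studies over thousands of cohorts stay
cheap; everything that exercises alignment uses real reads.

## Reference construction

The default amplicon is 200 nt with the site at position 100; real amplicon
boundaries for this assay are not published, and nothing downstream depends
on the length beyond the site having flanks. The codon context GCA is
forced at site−2..site (pinning the SNP reference allele G), and the
sequence is generated with no homopolymer of length ≥ 3 anywhere, so a
single-base deletion left-aligns to a deterministic coordinate at (or
within one base of) the site.

## Alignment

Needleman–Wunsch, match +1 / mismatch −1 / linear gap −2. Affine gaps are
unnecessary because single-base RT jumps are the only expected indels.
Among co-optimal traces, deletions are left-aligned (traceback prefers
M, then D, then I), matching standard variant-normalisation convention.
The production path uses free reference end gaps (end-gap-free semi-global
alignment): the read must be fully consumed but may cover any contiguous
reference stretch, so an arrest-truncated read aligns to the suffix it
covers instead of being charged a giant leading deletion. For full-length
reads this coincides with strict global alignment. N bases never match
anything, including other Ns. The DP kernel is JIT-compiled with numba
(~10 k aligned 200-nt reads per second on one core); tests check it
against an independent pure-Python DP oracle on random sequence pairs.

This aligner is a transparent stand-in for whatever read processing the
original assay used (not published): the pileup stage also accepts external
SAM, read through pysam, so externally aligned data can enter the pipeline
unchanged.

## Pileup and signature statistics

Each spanning read contributes exactly one of: a base call (M covering the
position), a deletion (D covering it). Soft-clipped bases and N calls never
count. Reads whose alignment abuts the position without covering it
(truncated at the site) increment a termination counter only.

- mismatch_rate = non-reference base calls / all base calls,
  decomposed per observed base;
- jump_rate = deletions / spanning reads (base calls + deletions).

The two denominators deliberately differ: the deletion-bearing reads carry
no base call, so including them in the mismatch denominator would deflate
the misincorporation estimate. The exact formula behind the original
figures is not printed; this convention is documented here and kept fixed.
Jumps are counted at the exact site coordinate (not a window) — with the
homopolymer-free reference the left-aligned deletion coordinate is
unambiguous.

`min_depth` defaults to 100 spanning reads: below that, binomial noise is
comparable to the sub-percent signatures of interest, and the sample is
rejected with an explicit low-coverage error.

SNP genotyping thresholds the alternate-allele fraction at 0.8 (carrier) /
0.2 (non-carrier); anything between — heteroplasmy, contamination — is
flagged indeterminate and excluded rather than guessed. Low coverage at
the variant position likewise yields indeterminate with a warning, not an
error, because genotyping feeds sample exclusion.

## Cohort statistics

The comparison pipeline order is fixed and logged: (1) drop SNP carriers
and indeterminate genotypes, (2) optional Braak stratification — controls
at stages 0–3 versus cases at stages 5–6, records missing a stage dropped
with a warning, (3) Grubbs outlier removal within each group, (4) two-sided
unpaired t-test. The original report does not state an order; exclusions
that do not depend on the measured value (SNP, stratum) are applied before
the value-dependent one (outliers) so that outlier detection sees exactly
the population being tested. Results are invariant to input record order.

"Unpaired t-test" is implemented as Student's pooled-variance test (the
default of the commercial software used for the original analysis), with
Welch available behind a flag. Grubbs uses
G = max|x−x̄|/s against the two-sided critical value
((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student quantile with n−2 df,
iterated at most once per group by default ("extreme" outliers only); it
never acts on groups of n < 3 or zero variance. The ROUT method, which the
original statistics section mentions alongside Grubbs, is not implemented:
its tuning parameter is unpublished and it targets regression residuals;
the omission is deliberate. Grubbs is applied per group (pooled-cohort
application would conflate group effects with outliers); no
multiple-testing correction is applied across metrics, matching the
per-metric reporting of the original analysis.

Calibration: with θ identical in both groups, the full pipeline's null
rejection rate at p < 0.05 is ~0.06 (measured over thousands of simulated
cohorts in the acceptance suite) — the t-test alone is calibrated at
~0.05, and conditioning on Grubbs removal adds roughly one percentage
point of anti-conservativeness, the known price of outlier exclusion under
a clean null.

## Cohort generator defaults

Chosen once to emulate the target study's design: 12 controls / 13 cases,
2 case-group SNP carriers, 10,000 molecules per sample. Braak stages are
drawn per sample — controls uniform on {1,2,3,4} (mean 2.5, SD ~1.1),
cases from {4,5,6} with weights (0.4, 0.5, 0.1) (mean 4.7, SD ~0.64) —
matching the reported group means and SDs. Methylation stoichiometries are
unpublished; defaults are θ_control = 0.05, θ_case = 0.15 with
between-sample SD 0.02 (truncated to [0,1]), giving site mismatch rates of
roughly 1% vs 2.5%, the right order of magnitude for this assay class and
a comfortably detectable effect at n ≈ 10 per group. Per-sample seeds are
derived deterministically from the master seed, making cohorts
byte-reproducible.

## What the synthetic data do and do not show

The generator reproduces the mechanistic structure of the assay —
stoichiometry-proportional signatures, base-composition skew, deletion and
truncation events, carrier silence, cohort structure — so passing tests
demonstrate that the estimators recover programmed truth and that the
statistics are calibrated under the model. It does not emulate PCR
duplicates or jackpotting, position- or cycle-dependent quality, indel
sequencing errors, partial heteroplasmy, RT stutter away from the site, or
library-level batch effects; real-data performance on those axes is
untested by design. Absolute group-difference magnitudes in the original
figures depend on its wet-lab samples and are not reproduction targets;
the pipeline's correctness claims are about coordinates, estimator
closure, carrier handling and statistical calibration.

## Problem sizes used in the checks

Estimator-closure and carrier checks run at depth 10,000 per sample
(matching the generator default); the aligner is verified against the DP
oracle on hundreds of random 15-nt pairs plus constructed deletion cases;
type-I calibration uses 5,000 null cohorts of 8 + 8 samples at the
count level; the end-to-end determinism check uses a 4 + 5 cohort at 300
molecules per sample.
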