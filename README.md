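# rtsig

Site-specific quantification of N1-methyladenosine (m¹A) in mRNA from the
reverse-transcription (RT) signature it leaves in targeted amplicon
sequencing reads.

## The problem

m¹A carries its methyl group on the Watson–Crick face of adenosine, so a
reverse transcriptase hitting a methylated template base either reads
through correctly, misincorporates, skips the base ("jump", a single-base
deletion in the cDNA), or stalls ("arrest", truncating the cDNA). The
frequencies of these events in sequencing reads are a quantitative,
antibody-free readout of methylation stoichiometry at single-base
resolution.

The package targets the best-validated mRNA m¹A site in human cells:
position 1374 of the mitochondrially encoded ND5 transcript (mtDNA position
13710, rCRS), the wobble position of codon GCA, written by the
methyltransferase TRMT10C. It implements the analysis used to compare this
site between Alzheimer's disease (AD) cohorts and controls:

- **misincorporation rate** at the site, split by observed base — because RT
  misincorporation of A and C reads back on the mRNA-sense frame as T and G
  mismatches (the Watson–Crick complement);
- **jump rate** — the fraction of site-spanning reads whose alignment
  carries a deletion at the site, an independent second parameter;
- **SNP-based sample exclusion** — carriers of the mtDNA variant G13708A
  (Eurasian J haplogroup), two bases from the target position, lack the
  methylation entirely and are genotyped from the same pileup and excluded;
- **cohort statistics** — Grubbs outlier exclusion, two-sided unpaired
  t-tests, and Braak-stage stratification (controls at stages 0–3 versus
  cases at stages 5–6).

Because no sequencing data are deposited for this assay, the package ships a
first-class synthetic-data generator implementing the same RT-event model
(per-molecule stoichiometry θ, conditional event probabilities, uniform
sequencing error, SNP carriers, cohort metadata), so every stage is testable
end to end and estimator behaviour can be validated against closed-form
expectations.

## What is inside

| module | role |
|---|---|
| `rtsig.refmodel` | transcript ↔ genome coordinate arithmetic (1-based inclusive), codon indexing, RT complement logic, packaged ND5 / G13708A defaults |
| `rtsig.simulate` | amplicon reference builder, per-molecule RT outcome model, FASTQ + metadata + truth-table cohort generator, closed-form expectations |
| `rtsig.align` | Needleman–Wunsch aligner (linear gaps, left-aligned deletions, free reference end gaps for arrest-truncated reads; numba kernel), SAM subset I/O via pysam |
| `rtsig.pileup` | per-site base/deletion/termination counts, signature statistics, variant-allele-fraction SNP genotyping |
| `rtsig.stats` | Grubbs statistic and critical values, outlier removal, Student/Welch unpaired t-tests, Braak stratification, the fixed comparison pipeline |
| `rtsig.pipeline`, `rtsig.cli` | orchestration and the `rtsig` command-line tool |

## Worked example

Simulate the default cohort (12 controls, 13 AD cases of which 2 are
G13708A carriers, 10,000 molecules per sample), quantify every sample, and
run the stratified comparison:

```sh
rtsig simulate --out demo --seed 42
rtsig quantify --dir demo
rtsig compare --signatures demo/signatures.tsv --metadata demo/metadata.tsv \
              --metric mismatch_rate --stratify-braak
```

which prints:

```
mismatch_rate: control 0.0097 +/- 0.0011 (n=10) vs case 0.0244 +/- 0.0013 (n=6)
t = -8.372, df = 14, p = 8.03e-07
excluded SNP carriers: ad01, ad02
```

Reading the numbers: the two programmed carrier samples were genotyped from
their own reads and dropped before testing; stratification kept 10 controls
at Braak 0–3 and 6 cases at Braak 5–6; the remaining groups differ in
mean site mismatch rate (0.97% vs 2.44%, mean ± SEM) with a pooled-variance
t-test p ≈ 8×10⁻⁷ — the generator's programmed stoichiometry difference
(θ = 0.05 vs 0.15, ~17% of methylated molecules leaving a mismatch) recovered
from raw reads. The same command with `--metric jump_rate` tests the
independent deletion-based readout.

The same workflow is available as a library:

```python
from rtsig import CohortConfig
from rtsig.pipeline import run_cohort

signatures, result = run_cohort(CohortConfig(master_seed=42), "demo")
print(result.p, result.excluded_snp)
```

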