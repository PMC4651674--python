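# Methods

## Scope and model

spcquant implements spectral-count-based label-free quantification for
two-condition, replicated shotgun-proteomics experiments. The unit of
evidence is the peptide-spectrum match (PSM); protein abundance is
proxied by the number of MS/MS spectra matching a protein's peptides,
length-normalized and scaled per sample (NSpC, the NSAF measure). The
pipeline assumes the spectrum-to-peptide search has already been done:
its input is the search engine's PSM-level export, not spectra.

Stage order: PSM-level target-decoy FDR filtering → protein grouping on
shared peptide evidence → redundant spectral counting → reproducibility
filtering → NSpC normalization → Ln-NSpC t-tests with expression ratios
→ replicate concordance → GO enrichment of the differential list →
pI/MW profiling of the identified set.

## Target-decoy FDR

Decoys model incorrect identifications via a reversed-sequence database.
The estimator is the plain decoys/targets ratio at each rank (not the
(1+d)/t or 2d/(t+d) variants): it is the most common minimal form and
the choice is visible in one function should a different estimator be
wanted. Ties in score are resolved decoys-first, which is conservative —
a decoy tied with targets counts against them. q-values are the
right-to-left running minimum of the ratio, so acceptance regions are
nested and filtering is monotone in the threshold. FDR is controlled at
PSM level only, pooled within each sample by default (`per_sample=True`),
matching the convention of controlling error within one LC-MS/MS run;
pooling across the whole experiment is a switch. A PSM counts as a decoy
only when *every* candidate parent is a decoy entry.

## Protein grouping and counting

Grouping uses observed peptides only (no theoretical digest): accessions
with identical observed peptide sets merge; an accession whose set is a
strict subset of another's is subsumed into that protein's group; the
rest stand alone. When a subsumed accession has several strict
supersets, it joins the candidate with the largest peptide set, ties
broken by the representative ordering (most distinct peptides, then
longer sequence, then lexicographic accession) — the choice is arbitrary
among indistinguishable options and documented here so it is at least
deterministic. The representative's length is the L_k used in
normalization; a config switch quantifies per individual accession
instead of per group.

Counting is deliberately redundant: a PSM whose peptide is shared
between groups increments every group containing any of its candidate
accessions. Column totals therefore exceed the PSM count exactly when
sharing is present, which the tests exploit as an invariant.

## Normalization, filtering, concordance

NSpC divides each protein's (optionally pseudocounted) SpC by its length
and by the sample total of length-normalized counts; each column sums
to 1. The denominator runs over all rows of the *supplied* matrix: the
pipeline normalizes the reproducibility-filtered matrix for DE, so the
quantified universe and the normalization universe coincide, while
descriptive outputs normalize the full identified matrix. Normalization
is invariant to per-sample scaling of counts (pseudocount 0), which
removes run-depth differences.

The reproducibility filter keeps a protein if some condition has
SpC ≥ min_spc (default 2) in all of its replicates. It is monotone in
min_spc and indifferent to counts in the other condition — a protein
reliably present in only one condition is exactly the interesting
on/off case and is retained.

Replicate concordance is the squared Pearson correlation of linear NSpC
for every within-condition replicate pair (2 × C(3,2) = 6 pairs in the
default design), averaged. Linear rather than log scale is used because
concordance is claimed for the normalized counts themselves;
zero-variance columns make a pair undefined and are excluded with a
warning rather than averaged as NaN.

## Differential expression

The t-test runs on Ln(NSpC). The default variant is the pooled-variance
Student test — the conventional spreadsheet default for this workflow —
with Welch as a switch; both are two-sided at α = 0.05. The DE-stage
pseudocount is 0.5 SpC added before normalization so that Ln is defined
for proteins absent from one condition (the filter guarantees presence
in only one); 0.5 is the standard half-count continuity correction. The
expression ratio is the ratio of linear mean NSpC (treatment/control),
not exp of the Ln-mean difference; the geometric version is a switch.
p-values are uncorrected by default, with a BH column emitted. Rows
where both groups are constant and equal get the degenerate convention
t = 0, p = 1; constant but different groups get p = 0.

Exchanging condition labels negates t, inverts the ratio and preserves
p — a property test guards this.

## pI and molecular weight

Net charge is the Henderson–Hasselbalch sum over the two termini and
the C, D, E, H, K, R, Y side chains with the EMBOSS Pepstats default
pKa set (bundled as data: N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
H 6.5, K 10.8, R 12.5, Y 10.1; alternative sets loadable). Every term
is strictly decreasing in pH and the charge is positive at pH 0 and
negative at pH 14 for any sequence, so bisection on [0, 14] to
|ΔpH| ≤ 1e-4 finds the unique root. Cysteine is treated as ionizable as
plain Pepstats does, even though real experiments commonly
carbamidomethylate it — a deliberate tool-compatibility choice. MW is
the sum of average residue masses plus one water (monoisotopic by
flag), with no modification masses. Distribution profiles clamp
out-of-range values into the end bins with a warning; default bins are
unit-width pH bins over [3, 13] and 10-kDa MW bins with an open top.

Sequences containing extended-IUPAC ambiguity codes (B, X, Z, J, U, O)
are accepted by the FASTA reader but those residues are dropped before
physicochemical math, since they carry no defined mass or pKa.

## GO enrichment

One-sided hypergeometric upper-tail test per term (equivalent to
one-sided Fisher), BH across the tested terms, terms with fewer than 5
background hits untested. Annotations are assumed ancestor-propagated by
the provider; no GO-DAG traversal is performed, so un-propagated input
understates broad terms — this is documented loudly rather than patched,
to keep the module free of ontology files. The background population is
the annotated subset of the supplied background (unannotated proteins
carry no information for any term); a flag includes them.

## Synthetic data generator

The generator emulates the structure of a heat-stress anther proteome
study: 2 conditions × 3 biological replicates, 2,000 proteins with
log-uniform lengths on [60, 3000] residues, log-normal(0, 1) protein
abundances, an expected 30,000 correct PSMs per sample with per-protein
Poisson counts whose mean is proportional to abundance × length, 5 % of
proteins spiked 8-fold (half up, half down), 10 % of each protein's
peptides shared with a second parent, correct-target scores
Normal(30, 5) versus incorrect/decoy scores Normal(15, 5) with a 10 %
incorrect-target fraction, and one decoy PSM per incorrect target in
expectation (the assumption under which the target-decoy estimate is
unbiased). Sequences are generated at physiological amino-acid
frequencies and digested tryptically (cleave after K/R, observable
window 6–30 residues) so that grouping, FASTA lookup and physchem all
operate on one consistent universe. An over-dispersion knob switches
counts to gamma-Poisson for robustness studies. Identical seeds yield
byte-identical output files.

What it does not model — and hence what passing tests do not show about
real data: peptide detectability as a function of sequence, score
correlation with peptide properties, missing-value structure beyond
Poisson sampling, post-translational modifications, and biological
(non-count) variance between replicates. Real spectral-count data are
over-dispersed relative to Poisson; the null calibration measured here
(rejection rate ≈ 0.05 at α = 0.05) is therefore a best case.

## Problem sizes and numerical choices

Stochastic validations (FDR control, null calibration, spike recovery)
average over 20 seeds at the default conditions above; the full-pipeline
checks in the test suite use scaled-down experiments (≈100–150 proteins,
depth 1,500–4,000) chosen so each run still exercises every stage with
non-trivial group structure. NSpC column sums are asserted to 1e-9;
the NSpC implementation is tested against a term-by-term transcription
of the defining formula to 1e-10; hypergeometric tails are tested
against exact binomial-coefficient enumeration; pI bisection is tested
against a two-stage grid scan with 1e-6 local step to 1e-3 pH.

## Known limitations

- No parsimony/set-cover protein inference or razor-peptide assignment;
  grouping is the identical-set/subset rule only.
- No peptide- or protein-level FDR, posterior error probabilities, or
  score recalibration.
- No count-model DE (negative-binomial GLM) or variance moderation; the
  t-test on Ln NSpC is the method under study, not the state of the art.
- NSAF's column-sum-to-1 constraint makes strong spike-ins shift every
  other protein's NSpC slightly (compositional effect); with many or
  abundant spiked proteins this biases null proteins toward the
  opposite direction, visible in the demo run's increased/decreased
  asymmetry.
- Exact reproduction of any particular published experiment requires
  that experiment's PSM-level export; the two analysis switches most
  likely to matter (t-test variant, zero-handling pseudocount) are
  exposed in the config.
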