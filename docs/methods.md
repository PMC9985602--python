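# Methods

`hypermut` implements the computational side of a forward-genetics workflow
for adaptive laboratory evolution (ALE) under an engineered hypermutation
regime in the cyanobacterium *Synechococcus elongatus* PCC 7942: strains
with a disabled mismatch-repair pathway and overexpressed RecA accumulate
mutations thousands of times faster than wild type, survivors of a combined
high-light/high-temperature (HLHT) selection are resequenced, and the
mutation catalog is mined for driver mutations.  This note records the
models, conventions and numerical choices behind each stage.

## Mutation rates from selective plating

The mutation-rate proxy is the resistant-cell frequency of a rifampicin
plating assay: `f = resistant colonies / plated cells`, with typically
1e9–4e9 cells plated and colony counts in the tens.  Strain effects are
fold changes `mean(f_test) / mean(f_reference)` with a two-tailed unpaired
Student's t-test on per-replicate frequencies (Welch's correction by flag).
The reference pool aggregates all its replicates (the study design uses 12
wild-type replicates from 4 experiments); zero-colony replicates are kept
at frequency 0, not dropped.

This is deliberately a *frequency* estimator, not a Luria–Delbrück
fluctuation-corrected rate: frequencies are what the assay reports, and in
the regime of interest (relative comparisons at 10–1000-fold differences)
the jackpot bias largely cancels in the ratio.  Fluctuation-assay
maximum-likelihood estimators (Ma–Sandri–Sarkar) are out of scope.

The matching generator draws colony counts as Poisson(f × plated cells),
appropriate because counts ≪ plated cells; exact binomial sampling is
available by flag.  The standard error of a recovered fold F is, by the
delta method, `F·sqrt(1/(n_t·λ_t) + 1/(n_r·λ_r))` with λ the expected
per-plate counts; recovery tests use a 3-SE band.

## Mutation catalog

Variants are written in a compact token dialect: `G905452A` is a SNP
(1-based position, ref, alt), `158234D1` deletes one base at 158234.  The
deletion token carries only a length, so parsed deletions hold `N`
placeholders until resolved against the genome.  Insertions — which the
token dialect of the source tables never shows — are written
`<position>I<seq>`.

Effects are classified per record: a CDS SNP is translated in its codon on
the coding strand (reverse-complemented for `-` features) — same amino
acid ⇒ synonymous, stop gained ⇒ nonsense, else non-synonymous; a CDS indel
is a frameshift unless its length is a codon multiple; anything outside all
CDS is noncoding.  CDS lengths must be codon multiples or the annotation is
rejected.  The implementation is cross-checked in the test suite against an
independent oracle that rebuilds and diffs both full protein sequences.

Codes follow the locus-tag convention of the organism's KEGG entries: the
numeric suffix of the locus tag (`synpcc7942_0884` → `0884`); when a gene
or intergenic region holds several distinct types, `-k` sub-indices are
assigned by ascending genomic coordinate.  Intergenic regions are the gaps
between annotated CDS (the chromosome is treated as circular for gap
lookup only) and are auto-named `NC1, NC2, …` in genomic order; an explicit
`region_names` map (keyed by flanking locus-tag pair) and a per-type
`code_overrides` map reproduce published names where they deviate from the
automatic convention — the packaged catalog needs both, since its published
NC2 sub-indices do not ascend by coordinate and its region names start
at NC2.

Type identity is the exact `(position, ref, alt)` triple: the same triple
observed in several strains is one recurrent type.  Heterogeneous
(heterozygous) records — possible because the organism is polyploid — count
as present for all downstream statistics; the per-strain mean (88/23 = 3.8)
includes them.

## The packaged 23-strain catalog

The real evolved-strain catalog exists only as journal supplementary
material, so the package carries a synthetic reconstruction
(`synthetic_fixture.py`, labelled as such) constrained to reproduce every
count, frequency, named code and verbatim token the study text reports; see
the module docstring for the full constraint list.  Tokens the study does
not print are invented, as is the reference: a seeded 2.8 Mb random genome
with one CDS per mutated gene whose codon context is installed so each SNP
classifies to its published effect.  Consequences: catalog *statistics* are
faithful to the published dataset, but per-position biology (which exact
passenger sits where) is not, and nothing downstream should interpret
individual invented coordinates.

## Strain clustering

Each strain is a binary vector over mutation types and the pairwise
dissimilarity is `Distance(a, b) = 1/(a·b + 1)` — a reciprocal count of
shared types.  This is not a metric (self-distance `1/(|a|+1) > 0`; no
triangle inequality); the diagonal is zeroed only as a convention so
agglomerative clustering can run.  Linkage is UPGMA by default
(single/complete selectable) — the upstream analysis does not state its
method, so the choice is explicit and recorded in the output.  Strains are
sorted lexicographically before linkage, making the dendrogram invariant to
input row order; trees serialize to Newick with merge heights as branch
lengths.

Mutual exclusivity is an exhaustive scan: all pairs of (optionally
collapsed) mutation groups whose carrier sets are disjoint and jointly
cover every strain.  On the packaged catalog this finds exactly the
0336 / NC2 partition (15 + 8 strains).  With passenger sharing across
groups (e.g. the 1799 and 2215 mutations ride with both drivers, as in the
published data) the dendrogram root need not coincide with the driver
partition; the partition itself is the robust, linkage-independent
statement, and the planted-driver simulations show the root split is exact
when groups share nothing.

## Driver prioritization

Three lines of evidence per mutation type: recurrence (carrier strains),
presence in a minimal strain (≤ K total mutations; K defaults to 2, the
smallest observed strain load), and multi-hit genes/regions (distinct types
per collapsed code prefix).  The source analysis argues these qualitatively
and never defines a score, so the output is the raw evidence plus a
documented lexicographic rank (recurrence desc, multi-hit desc,
minimal-strain desc, code asc) rather than an invented weighted composite;
the rule is recorded in the table's metadata.

## Proteome aromatic composition

The shikimate pathway produces Y, F and W; their share of a proteome
measures aromatic amino-acid demand.  Both the pooled proportion
(ΣY+ΣF+ΣW over total residues — the length-weighted mean) and the
unweighted per-protein mean are reported, because published percentages of
this kind rarely state which was used; on the study's regime the two
coincide to well within the comparison tolerance.  Ambiguity codes
(X, B, Z, U, O) are excluded from numerator and denominator.  Localization
classes (membrane/soluble, e.g. from a transmembrane-topology predictor)
and pathway tags are consumed as input tables; proteins of unknown class
appear only in the overall row.  The generator plants class-specific
aromatic fractions residue-wise (Bernoulli), so recovery is binomial:
tests use 3-SD bands at 15 000 residues per class (50 proteins × 300
residues), where 3 SD ≈ 0.65 percentage points.

## Physiology closed forms

* Chlorophyll a from a methanol extract: `12.9447 × (A665 − A720)` µg/mL.
  Negative values (A720 > A665) are flagged with a warning, never clamped.
* qPCR relative expression: `2^−ΔΔCt` with
  `ΔΔCt = (Ct_tgt,test − Ct_ref,test) − (Ct_tgt,ctrl − Ct_ref,ctrl)`.
* P700 traces: far-red (FR) re-reduction traces are normalized by dividing
  by the maximum of the 1 s window before light-off (pure rescaling, as the
  protocol states); actinic-light (AL) redox traces get an affine map
  sending the post-light-off minimum to 0 and the maximum of the 3 s
  pre-light-off window to 1.  Rate extraction is therefore invariant to
  rescaling of FR signals and to affine transforms of AL signals.

The initial re-reduction rate fits least-squares lines over expanding
windows anchored at light-off and returns the slope of the longest window
with R² ≥ 0.99 (minimum 5 points).  Windows are additionally bounded to a
configurable `max_window` (default 0.3 s): on a saturating recovery
`1 − e^{−kt}` an unbounded window can satisfy the R² gate out to kT ≈ 0.8
while underestimating the tangent slope at light-off by ~30%, whereas at
the default bound the bias is ~7% for k = 0.5/s — the gate alone does not
define "initial".  The bound is in time, not samples, so the rule is
sampling-rate agnostic; a trace in which no window passes the gate raises a
quality error carrying the best achieved R².

The trace generator emits a plateau at 1 before light-off and
`1 − exp(−k(t − t_off))` after, scaled/offset to emulate raw absorbance
units, with seeded Gaussian noise; its initial slope is exactly k, which is
what the recovery tests check (10% band, dominated by the deterministic
window bias above).

## Synthetic catalogs and study-scale defaults

`simulate_catalog` plants two mutually exclusive driver groups: each strain
draws group A with probability p and carries one uniformly chosen type from
its group, plus Poisson(λ) passengers sampled with replacement from a fixed
pool.  Defaults are the study regime: 23 strains, p = 0.652 (the observed
65/35 driver split), λ = 2.8 passengers (≈ 4 mutations/strain total),
heterozygous fraction 0.07.  Positions are drawn on a linear 2 Mb toy
genome of evenly spaced 900 bp CDS on alternating strands — real codon
arithmetic without the real genome.  What the generators do *not* emulate:
mutational spectra (transition bias), selection during the ALE itself,
linkage between passengers, or genome-specific context; passing recovery
tests therefore demonstrates estimator correctness under the stated
sampling models, not robustness to those real-data features.

All generators take explicit seeds and are bit-reproducible; every dataset
is returned with a truth record, and recovery tests consume only the
dataset.

## Problem sizes and limitations

The suite and the acceptance script run at desk scale by design: 1000-SNP
oracle sweeps, 200-replicate prioritization simulations, 15 000-residue
proteome classes, 1.3 s of 100 Hz trace.  Known limitations: no VCF
multi-allelic or structural-variant support; the exclusivity scan is
exhaustive over group pairs (fine at tens of groups, quadratic beyond); the
frequency estimator inherits plating-assay biases it does not model; and
the full-proteome aromatic percentages (7.7/7.3/9.3) can only be checked
against a real downloaded proteome, which the package does not ship — the
tests check parameter recovery on the generator instead.
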