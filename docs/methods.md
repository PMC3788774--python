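# Methods

This note documents the models, conventions and numerical choices behind
`mthet`, and what its synthetic-data tests do and do not demonstrate.

## Coordinate system and genome map

Coordinates are 1-based, inclusive, on the 16,569-bp rCRS. The control
region spans the replication origin and is represented as the two linear
intervals 16024–16569 and 1–576; no circular arithmetic is used anywhere
else. Hypervariable-region defaults are HVRI 16024–16383, HVRII 57–372 and
HVRIII 438–576 — chosen so each contains its classical length-variable
tract (16184–16193, 303–315, 514–525, 568–573) — and are configurable, as
published HVR boundaries vary by a few bases between sources.

Region labels partition the genome with priority HVRI > HVRII > HVRIII >
D-loop inside the control region; outside it a position inside at least one
annotated feature is "coding" and a position in none (e.g. 8272–8294,
between MT-CO2 and tRNA-Lys) is "intergenic". Because cohort summaries
conventionally split events only into control vs coding region, the summary
layer counts intergenic non-control-region events with the coding region;
the per-position annotation keeps the distinction.

Overlapping genes (ATP8/ATP6, ND4L/ND4, the tRNA pairs) are all reported by
annotation; tallies and codon-effect classification use the first feature
in file order, which is therefore a documented, configurable priority.

## Substitution effects

Codon effects use the vertebrate mitochondrial genetic code (NCBI table 2).
For light-strand genes the observed heavy-strand alleles are complemented
and the codon is read in light-strand orientation; codon indices count from
the gene's own start codon. Genes ending in an incomplete stop codon (T or
TA, completed to TAA by mRNA polyadenylation) are classified against the
poly-A-completed codon, so a substitution in the final partial codon can be
a stop-loss. Effects are synonymous, non-synonymous, stop-gain or
stop-loss; amino-acid replacements additionally carry a coarse
polarity/acidity change (acidic D/E, basic K/R/H, neutral otherwise).
Correctness is pinned by an exhaustive oracle test that rebuilds and
re-translates every mutated codon of whole genes on both strands.

## Heteroplasmy detection, levels and authentication

The heteroplasmy level is defined as the secondary/(primary+secondary)
peak-height ratio averaged over sequence reads — the simplest height-ratio
estimator consistent with Sanger electropherograms. At least six reads are
required by default (configurable, overridable per call). A designated base
can be tracked instead of "the secondary peak", in which case the reported
level is that base's height fraction and may exceed 0.5 when the variant is
the major component.

Two thresholds are distinguished: the 2% screening threshold used by
base-calling software to flag candidate mixed bases, and the 10%
operational threshold at which detection is reliable — mixtures at 2% and
5% fall below it, 10% mixtures are detected, a pattern the in-silico
gradient-mixture tests reproduce. Detection is monotone: raising the
threshold never detects more positions. Authentication is
replicate-intersection: a point call is accepted only if its (individual,
position, allele pair) appears in every independent validation step, so the
confirmed set shrinks weakly with each added step.

Length heteroplasmy is recorded categorically (tract present/absent)
against a catalogue of classical control-region tracts; calls outside the
catalogue are tallied under their own coordinates.

## Stability scoring

The probability of mutation at position *i* is hitsᵢ / Σ hits from a
phylogeny hit table; probabilities sum to one and their mean over the *N*
positions considered is exactly 1/*N* (default *N* = 16,569; a different
value — e.g. one implying a slightly different mean, as published tables
sometimes do — can be configured). A position is a hotspot when its
probability is at least ten times the mean; the boundary is inclusive
because the verbal rule leaves the boundary case undefined, and the factor
is configurable.

The conservation index is the percentage of species in a cross-species
alignment carrying the wild-type symbol. Gap entries are excluded from the
denominator by default (a gap is absence of evidence, not a mismatch); a
flag counts them as mismatches. D-loop positions should be scored against a
separate primate-only alignment supplied as the nucleotide alignment input,
since deep metazoan alignments of the control region are unreliable.
Population-database frequencies are per-allele percentages over counted
sequences; the major-variant frequency is the maximum over the four bases.

Stability gates default to the observed minima over the stable positions of
the source cohort — at most 2 hits, major variant ≥ 99.6%, nucleotide CI ≥
77.11%, and amino-acid CI ≥ 92.9% for the highly stable tier — and are
reported alongside results so users can tighten them. A protein position
lacking an amino-acid CI is classified at most "stable" with an explicit
not-assessable flag, never silently promoted.

A note on recovery experiments: planting positions at exactly the 10× mean
probability places them on the hotspot decision boundary, where multinomial
sampling leaves roughly half the planted positions below threshold
regardless of the total hit count; recovery experiments that should succeed
must plant enrichment above the boundary (e.g. 20×, where recall exceeds
95% at 10,000 total hits).

## Proportion intervals and tests

Frequencies are reported with 95% Wilson score intervals by default; the
Jeffreys-prior (Beta(½,½)) equal-tailed credible interval is the documented
Bayesian alternative. The Wilson interval always contains the point
estimate and respects [0, 100] (bounds are clamped against floating-point
fuzz at the extremes); it matches a bisection solution of the score
equation to 10⁻⁹. Most published interval bounds of the reference cohort
are reproduced by Wilson at printed precision; a few cells follow the
Jeffreys interval instead, consistent with intervals originally computed as
Bayesian credible regions.

The two-proportion test is the pooled-variance z test, two-sided.
Chi-squared uses no continuity correction by default (flag available).
Fisher's exact test is exact for 2×2 tables; r×c tables use a seeded
Monte-Carlo estimate (20,000 null tables with fixed margins by default,
p = (1 + #more-extreme)/(1 + B) under the null probability ordering), which
converges to the exact value within Monte-Carlo error. Bonferroni
correction is min(1, m·p). Ratios are reported scaled so the smaller side
is 1 ("15.5:1", "1:1.31"); zero denominators yield the sentinel "∞:1",
never a division failure.

Percentages are carried unrounded internally; TSV output rounds point
estimates to 2 decimals and interval bounds to 1, while JSON output keeps
full precision.

## Synthetic data: what it emulates and what it does not

The generators default to the study conditions of the emulated cohort: 101
individuals, 23.76% point-heteroplasmy and 48.51% length-heteroplasmy
carriers, ~1.2 events per carrier (geometric), 70.9% of length events in
the HVRII poly-C tract, a 15.5:1 transition bias, about 28% of point events
in the control region, uniform levels in 0.10–0.45 over 6 reads, the
published haplogroup label distribution and a balanced sex ratio. Each
generator takes one explicit seed, builds a single local random generator
(no global state), and is byte-reproducible.

The synthetic reference has the real rCRS length and gene layout and valid
mitochondrial ORFs, with documented reference bases/codons anchored at
positions discussed in the literature (e.g. 7754 = G in the GAC codon 57 of
MT-CO2; 11253 = T in the ATC codon 165 of MT-ND4); all other bases are
random. Passing tests therefore demonstrate coordinate, codon and pipeline
logic — not base-level agreement with the real rCRS away from the anchors.
Likewise the simulators draw positions uniformly within regions, use
truncated-normal peak noise, and ignore sequence context, NUMT
contamination, chromatogram artefacts and phylogenetic correlation between
database genomes; recovery tests show internal consistency under these
idealised conditions, not performance on real traces.

Problem sizes in the test and acceptance suites are desk-scale by design:
cohorts of 101–2,000 individuals, alignments of up to 1,491 sequences, hit
tables of 10,000–50,000 hits — large enough for the binomial tolerances
used (typically three standard deviations) while keeping the full suite in
the seconds range.

## Known limitations

* Haplogroup labels are consumed as input metadata; no haplogroup calling.
* Alignments are consumed as input (or simulated); no alignment
  construction.
* RNA secondary structure arrives as a stem/loop lookup table; no folding.
* Length heteroplasmy is presence/absence per tract, not an allele-length
  distribution.
* The event-vs-position distinction matters in outputs: a position can be
  heteroplasmic in several individuals, so event counts can exceed position
  counts; tables state which denominator they use.
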