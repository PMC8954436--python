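# Methods

`stopctx` quantifies how prokaryotic genes choose among the three
termination codons — UAA (ochre), UAG (amber), UGA (opal) — and what
follows the stop on its 3′ side, with particular attention to highly
expressed genes (HEG) in genomes under strong translational selection.
This note records the models, conventions and numerical choices the
package commits to, and what its synthetic-data tests do and do not
establish.

## Position convention

The stop codon occupies positions **+1..+3**; the first downstream base is
**+4**; "+456" is the first full downstream codon. A `GeneRecord.downstream`
string starts at +4 in gene-sense orientation, so 0-based index `i` of that
string is genomic position `+4 + i`. Every context statistic in the package
is defined against this convention; it is asserted in tests because
off-by-three errors are the dominant failure mode in this kind of analysis.

## Sequence handling

Coordinates are GFF3-style (1-based, inclusive) end to end; no half-open
conversion is exposed. Sequences are DNA internally ({A,C,G,T,N}; other
IUPAC letters fold to N at read time) and RNA (UAA, not TAA) in every
reported label. Only single-segment CDS are accepted — the scope is
unspliced prokaryotic genes — and the GFF3 phase column is ignored
(logged when nonzero). On the minus strand the CDS is the reverse
complement of the annotated interval and the downstream window is the
reverse complement of the bases *before* `start`. Circular contigs wrap
the window around the origin (clamped at one full turn); linear contigs
truncate it, and truncated genes still contribute to whatever leading
positions they cover — no imputation, no whole-gene exclusion.

A CDS enters stop/context statistics only if it validates: length ≥ 6 and
divisible by 3, no in-frame internal stop, terminal triplet one of
TAA/TAG/TGA under translation table 11 (bacterial/archaeal/plastid). A
terminal triplet containing N is `ambiguous` rather than guessed — counting
analyses must not impute. Invalid genes are reported in the QC table with
one of four reason codes; validation is total and never raises.

## Gene classes and GC stratification

HEG labels come from an external list (the production path) or from the
codon adaptation index classifier (so synthetic pipelines can run with no
list; a file always overrides CAI). LEG is defined as the valid complement
of HEG — the source analyses contrast HEG with "low expressed genes"
without defining membership, and the complement is the only reproducible
choice. ALL = HEG ∪ LEG.

Genome GC is computed over all contig bases (N excluded from numerator and
denominator), matching the organism-level GC figures this field quotes;
a per-class CDS GC is also available as a sensitivity check. GC bins are
LOW = [0, 0.40), MID = [0.40, 0.60], HIGH = (0.60, 1]: the published bin
description ("between 40% and 60%") leaves the boundaries open, and
closing them into MID makes the bins a partition.

## Statistics

**Stop usage.** Per genome and class, counts of the terminal codon over
valid genes; frequencies are counts/total, left *missing* (not zero) for
an empty class. Percentages are produced only at the reporting layer, by
round-half-up at a stated number of decimals; everything upstream keeps
full precision. Dividing the published E. coli K-12 counts by their own
totals reproduces every printed percentage, including the 87% UAA figure
for the highly expressed set (the printed counts 223+30+2 total 255, and
223/255 → 87 at integer rounding).

**GC correlation.** Pearson product-moment r of each stop codon's
class-level frequency against genome GC across a cohort, p-value from the
t transform with n−2 df (delegated to `scipy.stats.pearsonr` behind the
package surface). Constant inputs raise an undefined-correlation error
rather than returning NaN. The HEG class is the default, matching the
cohort-level figure this statistic reproduces.

**+4 group test.** Within a (gene class, GC bin, stop codon) stratum the
observation unit is the *genome*: one +4 frequency per nucleotide per
genome. All six pairwise two-sided pooled-variance Student t-tests are run
at a bare α = 0.01 — pooled not Welch, uncorrected not Holm, because that
is the procedure being reproduced; both variants sit behind flags.
Degenerate inputs use documented conventions: two constant equal samples
give p = 1, zero pooled variance with unequal means gives p = 0.

Letters are assigned as the **maximal cliques of the non-significance
graph** over the four nucleotides (letters ordered by descending group
mean, ties alphabetical). A purely greedy insertion rule can strand a
non-significant pair in disjoint letters when non-significance is
non-transitive; the clique construction guarantees exactly the intended
semantics — two nucleotides share a letter iff their pairwise test was
non-significant — and is deterministic and order-independent. With four
nodes the enumeration is trivial.

*Calibration caveat.* The 6α family-wise bound used in the null-calibration
test presumes pairwise tests of nominal size, i.e. independent samples per
nucleotide. Real +4 frequencies are compositional (they sum to 1 per
genome), which negatively correlates nucleotides and makes the
independent-samples t mildly anti-conservative: on a compositional null the
measured family-wise rate is ≈0.10 rather than ≤0.06. The calibration null
therefore draws each nucleotide's per-genome frequency as an independent
binomial proportion (measured rate ≈0.05); the compositional null is
available (`compositional=True`) and its inflation is a known limitation of
applying unpaired t-tests to compositional frequencies — as the reproduced
procedure does.

**Downstream codons and tandem stops.** The +456 codon distribution is
compared against the chance line 1/64 ≈ 1.5625% (rendered 2% at integer
rounding); the table also reports the codons at or above chance and the
UNN aggregate (first downstream base U). The tandem-stop fraction is the
share of genes whose +456 triplet is itself a stop, broken down by the
primary stop so the amber-followed-by-stop pattern is directly visible.
Triplets containing N are excluded from codon-level tables, but an
unambiguous +4 base still counts in the +4 profile.

**Extended preference scan.** No published definition exists for the
"extended preference" over the first ten downstream codons, so the package
operationalizes it: per position, preference = (max base frequency) − 0.25,
flagged "preferred" above a configurable threshold (default 0.15). This is
a documented stand-in, exposed in configuration, and the only statistic in
the package without an external definition.

**Amber-rich screen.** Genomes whose HEG UAG fraction strictly exceeds a
threshold (default 0.15), sorted by descending fraction.

## Synthetic genomes

The generator states a world and emits it with full ground truth:

- **Cohort**: default 60 genomes spanning 30–70% GC evenly, 600 genes each
  (half HEG), one contig per genome. The stated correlation-recovery
  experiments use 300 HEG per genome over 20 seeds.
- **Stop choice**: per class, a multinomial over TAA/TAG/TGA whose
  probabilities may be linear in GC (clipped at 0, renormalized). Defaults
  emulate the observed gradient — HEG: p(UAA) = 0.8 − 0.6·GC,
  p(UGA) = 0.1 + 0.6·GC, p(UAG) = 0.1 flat; LEG the same shape attenuated
  (UAG ≈ 8%, the E. coli whole-genome level).
- **Gene bodies**: codons drawn i.i.d. from the 61 sense codons with
  product-of-bases weights governed by a single GC dial θ, solved by
  Brent's method so the expected body GC equals the genome target
  (excluding stops from the support shifts GC slightly, hence the solve);
  intergenic spacers use the target-GC base distribution. Realized genome
  GC lands within 0.02 of target (tested).
- **Context**: the +4 base is drawn per stop codon (default U-dominant:
  U 0.50, A 0.20, C 0.15, G 0.15 — the near-universal HEG pattern);
  later bases are i.i.d. background, or whole downstream codons can be
  drawn per slot (e.g. sense-codons-only, which provably yields zero
  tandem stops). A `tandem_rate` fraction of genes has its +456 forced to
  a uniformly random stop; chance tandems arising from the i.i.d. model
  add on top, which is why measured tandem fractions exceed the planted
  rate and are compared against the realized truth in tests.
- **Placement**: each gene's downstream window is planted literally in the
  adjacent spacer (reverse-complemented upstream for minus-strand genes),
  so re-extraction returns planted strings *exactly*, not statistically.
  Half the genes sit on the minus strand and half the contigs are circular
  by default; circular contigs are rotated so the origin falls inside one
  forward gene's downstream window, which forces the extractor's wrap path
  to be exercised by every closure test.
- **Determinism**: genome *i* uses `default_rng([seed, i])`; identical
  configuration reproduces byte-identical FASTA/GFF3/truth files.

What a green synthetic test establishes: the pipeline's bookkeeping
(coordinates, strands, wrapping, class labels) is exact, and its
estimators recover planted parameters within binomial/multinomial sampling
error at the stated n. What it does not establish: realism of gene length,
operon structure, overlapping genes, amino-acid composition, or any claim
about real genome cohorts — those require the external HEG predictions the
production path consumes.

## CAI scorer (plumbing)

Weights are per-synonymous-family relative adaptiveness from a reference
set (0.5 pseudo-count for unobserved codons, so no weight is zero); a gene
scores the geometric mean of its weights over sense codons, computed in
log space, excluding the stop and the single-codon families ATG/TGG (the
standard convention). The classifier flags the top (1 − q) fraction
(default q = 0.95), ties broken by gene id. This is a stand-in for
external expression predictions, not a reimplementation of them; the HEG
threshold per genome in the original database is unpublished, so the
quantile is explicitly arbitrary and configurable.

## Known limitations

- The pairwise t-test anti-conservatism on compositional frequencies,
  above.
- LEG-as-complement inflates the LEG class with mispredicted or atypical
  genes relative to any curated low-expression set.
- The extended-preference statistic is this package's operationalization;
  alternatives (e.g. entropy-based) would rank positions differently.
- Downstream windows overlapping a neighbouring annotated CDS are profiled
  (flagged, filterable) — on gene-dense genomes part of the "context" is
  coding sequence of the next gene.
- How much downstream sequence the original database stored per gene is
  unstated; the default 30 nt window is this package's choice, sized for
  the 10-codon scan.
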