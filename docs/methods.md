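# Methods

This note documents the models and conventions behind each pipeline stage,
the parameters that matter, and the limits of what the synthetic-data tests
demonstrate.

## Triad bookkeeping

A roster row is one homoeolog: ID, gene (triad) name, subgenome (A/B/D),
chromosome (1A–7D), arm (S/L or unknown), 1-based inclusive coordinates,
and a phylogenetic group label. Triads are keyed by the explicit gene-name
column rather than by decomposing homoeolog IDs, because family ID schemes
are generally not algorithmically invertible. Coordinates are used only for
ordering; no length arithmetic is performed on them.

The parser enforces that a record's chromosome letter equals its subgenome,
which catches the most common data-entry error. Genes carried across
subgenomes by real translocations genuinely violate this (a B-lineage copy
can physically sit on chromosome 4A), so `parse_gene_roster` accepts
`allow_translocated=True`, which admits such rows and flags them
`is_translocated` instead of rejecting them. The packaged
rearrangement-fixture roster is loaded this way.

The distribution summary counts genes per presence pattern
(ABD/AB/AD/BD/A/B/D); the homoeolog total always equals the number of
input records, and `fraction_complete` is the ABD share of genes.

## Rearrangement annotation

Detection is rule-driven, not synteny-driven: the known wheat events are
few and well characterised, so deviations are interpreted against a
packaged declarative table rather than recomputed from alignment blocks.
Each rule records the (chromosome, arm) a relocated copy occupies and the
(chromosome, arm) its collinear partners imply, keyed one-to-one.

The expectation for a triad is a componentwise majority vote: chromosome
number over all members, arm over members with a known arm. A tied
chromosome vote (possible with two members) makes the triad indeterminate
— no guess is made. A tied or empty arm vote restricts comparison and rule
matching to the chromosome level. The deviant's *expected* chromosome
letter is its own subgenome: a translocated copy is expected back on its
ancestral chromosome.

A deviation matching no rule is reported as `unexplained_deviation` (with a
log warning), not raised: an unexplained placement is a finding, not an
input error. A deviation matching two rules indicates a malformed rule
table and raises. The 6B arm-exchange candidate rules are classed
`putative_pericentromeric_inversion`, kept separate from the confirmed
classes in every summary because the event is supported by synteny only.
Event summaries count distinct triads and the *total* membership of those
triads ("six triads, 18 homoeologs" convention), at either class or
event-label granularity.

## Expression-bias classification

TPM is taken as given (no normalisation from counts). Replicates of a
condition are averaged (mean by default, median selectable) before
normalisation. A missing cell (NaN) means *no data* and excludes the triad
from analysis in the affected scope; a 0.0 cell is evidence of no
expression and is kept. A triad whose summed TPM in a condition falls
below `min_total_tpm` (default 0.5, exposed as a flag) is "not expressed"
there and carries no category.

Classification is nearest-centroid in Euclidean distance over the seven
canonical simplex points listed in the README. This is the natural
decision rule for the seven-category framework; no threshold separating
"biased" from "balanced" is published for it, so ties go to Balanced, and
a configurable balanced-radius variant (classify as Balanced within ε of
the centre regardless) is available but off by default. The classifier is
scale-free and equivariant under subgenome permutation, both
property-tested.

Ternary coordinates use the unit-edge triangle A=(0,0), B=(1,0),
D=(1/2, √3/2): x = r_B + r_D/2, y = (√3/2)·r_D — a bijection on the
simplex (round-trip tested to 1e-12).

The log transform for visualisation is log2(TPM + 1); the +1 pseudo-count
keeps zeros finite and is the only convention adopted beyond "log2 TPM".

Shift analysis counts category transitions between two conditions over
triads expressed in both, plus per-subgenome dominant/suppressed tallies
per condition over each condition's expressed triads.

## Nei–Gojobori (NG86) Ka/Ks

Site counting: each codon position contributes (synonymous single-base
changes at that position)/3 to the codon's synonymous site count; changes
creating stop codons count as nonsynonymous. S and N are averaged between
the two sequences, so S + N = 3 × (codons compared) exactly.

Difference counting: for a codon pair differing at k positions, the k!
orderings of single changes are enumerated and (sd, nd) averaged over
orderings that avoid stop-codon intermediates; if every ordering is
blocked (unreachable with the standard code, possible with custom codes),
all orderings are used with equal weight and a warning logged. These are
the most common NG86 conventions; the original description leaves them
open and downstream tools differ.

Correction: Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p). p ≥ 3/4 is
saturated: the distance, and any ratio using it, is undefined rather than
clamped. On very short, highly diverged stretches Sd can exceed S (p > 1);
this is treated as saturation. The ratio is reported as 0 when Ka = 0 with
Ks > 0, and as undefined (not 0, not ∞) when Ks = 0 or either rate is
saturated; an identical pair is all-zero with no flags. Codons containing
gaps or ambiguity characters in either sequence are skipped pairwise,
keeping the site totals consistent with the compared length. The genetic
code is injectable; the standard code is the default and the only one
exercised by the shipped generators.

The difference counter is verified exhaustively against an independent
brute-force pathway enumerator (built on Biopython translation) over all
61×61 sense-codon pairs.

## Synthetic-data models

*Triad expression.* Each triad draws a category from a configurable mix
(uniform over the seven by default), a relative-abundance vector from
Dirichlet(concentration × centroid), and a triad-total TPM from a
log-normal depth model; emitted TPMs are total × rel. The suppressed and
dominant centroids lie on the simplex boundary, so a small ε = 1e-3 is
mixed in before parameterising the Dirichlet to keep all parameters
positive. Defaults: 500 triads, concentration 200 (tight but realistically
noisy triplets), depth log-mean 3.0 / log-sd 1.0 in natural-log units
(median ≈ 20 TPM per triad, a plausible depth for expressed genes in bulk
RNA-seq), missing rate 0. `missing_rate` removes homoeolog rows entirely,
emulating blank cells, never writing zeros.

*Condition shifts.* A 7×7 row-stochastic matrix maps first-condition
categories to second-condition categories; expression is regenerated from
the new category with the same depth model.

*Codon pairs.* Two descendants of a uniformly random sense-codon ancestor
each accept round(n_codons × t) substitutions, proposing uniform
single-base changes, rejecting stops, and accepting synonymous/
nonsynonymous changes in the rate ratio 1 : ω. Rejection of stops was
chosen over renormalised rate matrices — simpler, and adequate for an
estimator oracle. The realized synonymous/nonsynonymous counts are
recorded as truth.

What these generators do *not* emulate: read-level sampling noise,
TPM-estimation error, correlated homoeolog depths, tissue structure, or
real wheat coordinates. Passing recovery tests therefore demonstrates the
*estimators'* correctness under their stated models, not robustness to
real RNA-seq artefacts.

*Fixtures.* The two packaged rosters are deterministic, regenerable
byte-identically. The distribution roster realizes the printed pattern
counts (76/4/3/3/3/3/3 over 95 genes, 257 copies) with synthetic
coordinates — only the pattern structure is meaningful. The rearrangement
roster uses the twelve triads' printed chromosome/arm placements verbatim,
again with synthetic coordinates.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the
statistical checks decisive: 500 triads at concentration 200 for category
recovery (the expected accuracy is ≫ 95%: at this concentration the
per-coordinate spread is ≈ 0.03 while the nearest inter-centroid boundary
is ≈ 0.2 away), 1000 triads for transition-probability recovery (3σ
binomial check), 20 replicates of 10,000 codons at ω = 1 for the
neutrality check and 5 at ω = 0.2 for purifying-selection recovery.
Simplex sums are validated to 1e-6 on input and held to 1e-9 after
normalisation; centroid-distance ties are resolved at 1e-9.

## Known limitations

* Rule matching is one-to-one by (observed, expected) placement; if two
  biologically distinct events ever shared that key the table would need
  explicit priorities.
* Nearest-centroid classification has no "weakly biased" buffer: points
  midway between Balanced and a dominance corner flip categories at the
  perpendicular bisector. The optional balanced-radius ε mitigates but
  does not remove this.
* NG86 ignores transition/transversion bias and codon usage; its Ka/Ks is
  known to be biased for strongly skewed mutation processes. The simulator
  is deliberately matched to NG86's assumptions (uniform proposals), so
  recovery tests validate the implementation, not the method's robustness.
* The expression module assumes TPM inputs are comparable across samples;
  no cross-sample renormalisation is attempted.
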