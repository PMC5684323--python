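# Methods

This note documents the models and procedures implemented in `spliceprobe`,
the assumptions behind them, the synthetic data used to validate them, and
the numerical choices that matter.

## Local alternative-splicing events

Short-read data cannot identify full-length isoforms, so splicing is
quantified at the level of *local events*: bounded structural differences
between two isoforms of a gene, flanked by splice sites the isoforms share.
`events.enumerate_events` compares every transcript pair of a gene.
Candidate anchors are coordinates that are exon ends in both transcripts or
exon starts in both; between each adjacent anchor pair the exonic content
of the two chains is compared, and any difference forms one event whose two
alternatives are the respective exon fragments. Six templates are
classified — `CASSETTE` (one skipped/included internal exon), `LCASSETTE`
(two), `XCASSETTE` (three or more), `INTERNAL3` / `INTERNAL5` (acceptor- /
donor-side length polymorphism, assigned strand-aware), and `MUT_EXCLU`
(two disjoint internal exons used exclusively). Anything else — including
intron retention and multi-fragment differences — is kept as `OTHER` and
excluded from PSI quantification. Events are deduplicated across pairs by
a canonical key (gene, variable-region anchors, category, alternative
coordinates), which makes the catalog invariant to transcript order and
duplication. Differences confined to transcript start/end coordinates never
produce anchors on both sides and are therefore ignored by construction;
the taxonomy concerns internal structure only.

Coordinates are 0-based half-open throughout; GTF input (1-based closed) is
converted at the parser boundary.

### Unique evidence regions

For each alternative, the evidence a read can carry is either an
alternative-specific junction or containment in an exonic segment present
in only that alternative. With read length `L` and minimum junction
overhang `m` (defaults 50 and 1, matching 2 x 50 bp paired-end data), a
junction offers `L - 2m + 1` read-start positions and an exclusive segment
of length `l` offers `max(0, l - L + 1)` fully-contained positions; their
sum is the alternative's *unique length*. `L >= 2m` is required; at
equality each junction retains exactly one valid start. The inclusion
alternative of a cassette event is always at least as long as the skipping
one (two junctions plus the exon body versus one junction).

## PSI quantification

Each aligned read (mates assigned independently) is assigned `ALT1`/`ALT2`
when it spans an alternative-specific junction with at least `m` aligned
nucleotides on both sides or lies fully inside an exclusive segment;
evidence for both alternatives is `AMBIGUOUS`, otherwise `NEITHER`. A read
starting or ending exactly on a splice site has zero overhang and never
counts as junction-spanning. Fragments whose mates support conflicting
alternatives contribute nothing. Counts are normalized by unique lengths,
`c_i = n_i / u_i`, and

    PSI = c1 / (c1 + c2),

undefined (missing, never zero) when both densities vanish. Events are
retained when `max(c1, c2) >= 0.003` reads/nt in at least one sample.
Condition-level change is `dPSI = mean(PSI_treated) - mean(PSI_control)`
over replicates, with missing per-sample values dropped from the means; an
event is called changed when `|dPSI| > 0.4`. `rpkm` and
splice-site-spanning read counting (strict containment; boundary-touching
reads excluded) follow the standard definitions.

## SILAC enrichment statistics

Input tables carry per-protein, per-gel-band heavy/light ratios across 10
pulldown samples. The filter chain retains rows with at least 2 quantified
peptides, search score strictly above 31 and a quantified ratio in at least
7 of 10 samples, then keeps only the band of highest abundance per protein
(the summed sample intensity when provided, otherwise the peptide count —
the field's usual proxy when no intensity is exported). Label-swapped
samples are inverted (`r -> 1/r`) before the log2 transform. Each protein
is tested with a one-sided one-sample t-test of mean log2 ratio > 0;
p-values are Benjamini–Hochberg adjusted across proteins, and a protein is
called enriched when the adjusted p-value is at most 0.05 **and** the mean
linear fold change exceeds 1.5 (`fold_scale="log2"` switches to requiring
mean log2 ratio > 1.5 for users who prefer that reading). Zero-variance
rows at mean zero get t = 0, p = 0.5; fewer than two quantified ratios
yield a missing p-value and no call.

Category enrichment of a hit list against its background uses one-sided
Fisher exact tests per category with a 0.001 cutoff, reporting −log10 p.
An exclusion list (e.g. ribosomal proteins) removes ids from hits *and*
background before testing, supporting the re-run that checks whether a
category survives without the translational machinery.

## Dose-dependent displacement testing

A competition pulldown measures protein abundance at ordered free-compound
concentrations (0, 0.5, 1, 5, 10 µM; 3 replicates each, log-scale values).
Displacement of a true binder shows as a monotone decrease.

**Moderated variances.** Per protein a one-way group-mean fit gives
residual variance `s²` with `d` residual degrees of freedom. Across
proteins, a scaled-F model is fitted by moment matching on
`e = log s² − digamma(d/2) + log(d/2)`, whose mean and excess variance
identify the prior degrees of freedom `d0` (via a Newton trigamma inverse)
and prior variance `s0²`. Posterior variances
`s_post² = (d0·s0² + d·s²)/(d0 + d)` stabilize triplicate-level inference.
When every `s²` is identical the model degenerates to a point mass and
`s_post² = s²` is returned directly; zero-variance proteins are excluded
from the moment fit but still moderated.

**Monotonic contrasts and max-t.** For each cut between consecutive
levels, a two-group statistic compares samples at or below the cut with
those above, using the moderated standard error; positive values mean
displacement. The per-protein statistic is the maximum over the `K − 1`
cuts, which is sensitive to a change point anywhere along the series
without assuming a parametric dose-response shape.

**Step-down minP.** Significance comes from permuting concentration labels
across all samples (default B = 1000), recomputing the entire pipeline —
including the variance prior, unless frozen — per permutation. Raw
per-protein p-values use each protein's own null with add-one smoothing,
`p = (1 + #{perm >= obs}) / (B + 1)`, so the identity labelling is
implicitly part of the null set and p >= 1/(B+1). Family-wise adjustment is
the Westfall–Young step-down minP in its single-pass form: per-permutation
p-values are the self-inclusive exceedance counts within each protein's
own null columns, successive minima are taken over the proteins ordered by
raw p, and the adjusted p-value is the smoothed fraction of permutations
whose minimum p undercuts the observed one, with monotonicity enforced.
The observed statistic is deliberately *not* inserted into the permutation
columns: only this asymmetry (the one the reference single-pass
implementations use) lets a statistic that beats all B permutations reach
an adjusted p below the granularity floor `~1 − (1 − 1/(B+1))^P` that
would otherwise saturate B = 1000 with hundreds of proteins. All
comparisons are made on integer exceedance counts, so an exhaustive
enumeration over all distinct label assignments (`exhaustive=True`,
intended for small designs) reproduces exact permutation p-values with no
floating-point tolerance. Proteins with adjusted p < 0.05 are called
specific binders. An optional further Benjamini–Hochberg pass over the
minP p-values is exposed (`bh_after_minp`) for users who want the FDR
reading chained after FWER adjustment; it is off by default since minP
already adjusts for multiplicity. A protein is tested only when every
concentration level retains at least one observation.

## qPCR and SPR closed forms

Ct values convert to relative abundance as `E^(−Ct)` with the actual
per-cycle efficiency `E ∈ (1, 2]` (default 2; efficiencies are inputs,
never assumed from data). Target abundances are normalized to the
reference gene per sample and to the mean of vehicle-control samples,
giving fold changes that average 1 in the controls. Pulldown enrichment of
an active over an inactive bait is `2^(−ddCt)`. SPR signals are expressed
as percent of the theoretical maximum
`Rmax = immobilized · (analyte MW / ligand MW) · stoichiometry`
(100% = full occupancy of one site at 1:1 stoichiometry).

## Synthetic data

All validation inputs are generated with known truth; every generator is a
pure function of seed and parameters (byte-identical outputs, truth tables
sufficient to score every downstream call).

* **Gene models**: two-isoform genes realizing one requested event per
  category, exon lengths 80–300 nt, drawn introns 100–2000 nt, three
  flanking exons on each side of the variable region, random strand. One
  cassette gene carries the purine-rich ESE2 element `AAAAAGAAGGAAGG`
  inside its variable exon (sequence recorded in the truth table) for
  motif-level fixtures.
* **Reads**: paired-end 2 x 50 bp fragments with insert length
  normal(250, 30) truncated to the read span, placed uniformly on the
  chosen isoform and emitted pre-aligned with M/N CIGAR (alignment itself
  is out of scope, so reads simulate an aligner's output; SEQ is omitted).
  By default the inclusion isoform is chosen with per-fragment probability
  `psi·W1 / (psi·W1 + (1−psi)·W2)`, where `W_i` is the number of valid
  placements — the sampling of a library fragmented from a transcript pool
  whose *molar* inclusion fraction is `psi`. This is the quantity the
  length-normalized PSI estimator measures; under a plain Bernoulli(psi)
  fragment draw (available as `isoform_sampling="bernoulli"`) the estimator
  instead converges to `psi·W2/(psi·W2 + (1−psi)·W1)`, visibly below psi at
  intermediate values for single-gene fixtures. Residual bias of the
  default scheme is below 0.01.
* **SILAC tables**: 500 proteins x 10 samples, spiked enriched subset
  (mean log2 ratio 2, sd 0.3), the last five samples emitted label-swapped,
  5% missingness, plus decoy rows that each violate exactly one filter
  (single peptide, score <= 31, sparse detection) and duplicate gel-band
  rows at lower intensity.
* **Dose-response matrices**: 200 proteins x 15 samples; null proteins
  flat, displaced proteins decreasing linearly across the ordered levels
  with total drop `n_levels · drop_per_level` (default noise sd 0.25 on the
  log2 scale, typical of label-free MS). The validation studies use a
  per-level drop of 2 sd for power and a pure-null matrix for calibration.

What the generators do *not* emulate: sequencing errors and base
qualities, PCR duplicates, multi-mapping reads (handled at the aligner
level in practice), >2-isoform genes, overlapping/nested events,
peptide-level quantification noise structure, and intensity-dependent
missingness. Passing tests therefore demonstrate correctness of the
event/PSI arithmetic and the statistical machinery under idealized
sampling, not robustness to alignment or acquisition artifacts.

## Validation studies and problem sizes

`scripts/acceptance.py --seed N --out results/acceptance.json` reruns all
studies from scratch: exact catalog recovery on 12 genes (2 per category);
PSI mean absolute error at PSI 0.1/0.5/0.9 with 2000 fragments x 5
replicates; dPSI flagging rate over 100 runs of a 0.2-vs-0.7 comparison at
the 0.4 threshold; density-filter exactness against a brute-force scan;
SILAC sensitivity/FDR over 50 spiked tables plus filter-chain exactness;
minP agreement with exhaustive enumeration on a 2x2 design; displacement
type-I error (20 pure-null matrices, B = 1000) and power (10 spiked among
200 over 20 seeds); closed-form checks to 1e-12; and byte-identity of
seeded CLI reruns. These sizes keep a full run under a minute on one core
while leaving Monte-Carlo error well below the decision margins.

## Numerical notes

* Sums inside the variance-prior fit are taken over sorted values, making
  moderation exactly invariant to protein row order.
* Permutation-test comparisons (raw and step-down) use `>=` on integer
  exceedance counts; ties in permuted statistics therefore resolve
  conservatively and reproducibly.
* Missing PSI propagates as missing; it is never coerced to 0 or 0.5.
* The density filter applies per sample to each alternative's normalized
  count; retention is any-sample, any-variant.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces every output byte-for-byte.
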