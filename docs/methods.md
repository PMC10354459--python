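# Methods

## The quantitative model

The screen quantifies proteins captured by six pulldown conditions —
beads only, an unmodified-C RNA bait, and four baits carrying one
cytidine modification each (m⁵C, hm⁵C, hm⁵Cm, f⁵C) — in independent
biological replicates. iBAQ intensities are relative abundances on an
arbitrary per-sample scale, so the first step divides each sample
column by its total; every downstream quantity is a ratio of these
fractions and is therefore invariant to per-sample rescaling (this
invariance is property-tested).

Replicates are aggregated by the median, which tolerates one aberrant
replicate out of three and treats non-detections (zeros) as ordinary
values rather than missing data. No imputation, variance-stabilizing
transform or moderated test statistic is applied: with n = 3 and a
dual-control ratio filter, the procedure is a deterministic enrichment
screen, not an inferential one.

### Pseudocount

Fold changes of medians are undefined when a control median is zero —
common for proteins captured only by a modified bait. A pseudocount
ε is added to **all** medians (numerator and denominator alike), with
two consequences: every ratio is finite and positive, and a protein
absent from both bait and control sits exactly at fold change 1
rather than at an artifactual extreme. In `derived` mode
ε = (smallest positive median)/100; zeros are excluded from the
minimum because a zero-derived ε would defeat its purpose. The /100
factor keeps ε two orders of magnitude below any observed value, so it
never flips a comparison between two detected proteins; `fixed` mode
accepts an explicit value (e.g. 10⁻⁹) for reproducing published runs.

### Candidate calls and boundary semantics

A protein is a candidate reader of bait M when it is ≥2.0-fold over
beads-only **and** ≥1.5-fold over unmodified C. The beads threshold is
the stricter one because beads-only pulldowns capture far less material
overall; the unmodified-C threshold discriminates modification-specific
binding from general RNA affinity. Published descriptions of such
filters vary between "at least" and ">"; the default here is inclusive
(≥) with a `strict` switch, and the choice is echoed into
`run_metadata.json` so reported counts can always be reconciled.
Raising either threshold can only shrink candidate sets (monotonicity,
property-tested).

Candidates are ranked by their median normalized iBAQ in the bait
condition (abundance, the screen's follow-up priority), with fold
change vs unmodified C and then group id as tie-breaks for determinism.

### Unique binders

A unique binder is a candidate for exactly one bait. The full overlap
structure over the four candidate sets (15 regions = nonempty subsets)
is written alongside, and the region counts necessarily sum to the
number of proteins called at least once — an invariant the tests check
by exhaustive enumeration. Uniqueness is defined on post-threshold
calls, not raw detection.

### Phenotype enrichment

Over-representation of a unique-binder set in an annotation term is
tested with the exact upper-tail hypergeometric probability
P(X ≥ k | N, K, n), computed with integer binomials (no normal
approximation; scipy's survival function serves as an independent
cross-check in the tests). p-values are Benjamini–Hochberg adjusted
across the terms of one query (via statsmodels). The background
universe defaults to all proteins retained from the experiment —
detected-proteome backgrounds are the appropriate null for pulldown
queries — and can be replaced by any user-supplied list. Identifier
matching is exact string after lower-casing; annotation files must be
pre-mapped to the table's gene names.

### RRM motif flags

The RRM's two ribonucleoprotein consensus boxes are scanned with
degenerate patterns (RNP1 `[RK]G[FY][GA][FY][ILVM]x[FY]`, RNP2
`[ILVM][FY][ILVM]xNL`, per standard RRM literature). All overlapping
matches are reported; `X` residues never satisfy a constrained
position; patterns are overridable via a two-column pattern file.
Machine output uses 0-based half-open coordinates. This is consensus
flagging, not domain detection — a profile-HMM search is the right tool
when sensitivity matters.

## The synthetic-data generator

`simulate` emulates the screen: per-protein base abundance is
log-normal (natural-log mean 16, sd 1.5 — several orders of magnitude
of dynamic range, as iBAQ tables show), each sample value multiplies
the base by a condition multiplier and log-normal replicate noise, and
dropout zeroes values to mimic non-detection. Roles:

| role | multiplier |
|---|---|
| background | 1 in all samples |
| bead_sticky | ×8 in **all** samples (so fold change vs beads ≈ 1) |
| unique reader of M | ×`effect_size` in bait M only |
| shared_reader | ×`effect_size` in all four modified baits |

Defaults are the study's design scale, chosen once: 6 conditions ×
3 replicates; 2000 background proteins (a typical detected proteome for
such pulldowns); 50 bead-sticky contaminants; 25 unique readers per
bait and 30 shared readers (the published screens of this kind report
tens of unique binders per modification); effect_size 6; log-noise
sd 0.25 (typical LFQ replicate CV ~25–30%); dropout 0.05. Dropout is
intensity-independent by default; an `intensity` mode concentrates
missingness logistically in the low-abundance tail, the regime real
LFQ data shows.

What the generator does **not** emulate: peptide-level identification
and protein inference, match-between-runs, correlated noise between
conditions processed in the same batch, intensity-dependent variance,
or compositional distortion from a few dominant proteins. Passing
recovery tests therefore demonstrates the pipeline's arithmetic and
set logic under a clean generative model, not performance on real
spectra.

### What recovery under noise can and cannot show

With 3 replicates and log-noise sd σ, a condition median carries
log-scale sd ≈ 0.67σ, so a null protein's log fold change (difference
of two independent medians) has sd ≈ 0.95σ, i.e. ≈ 0.28 at σ = 0.3. The dual-threshold filter then passes a
fraction ~0.5% of background proteins per bait by chance — with 2000
background proteins, roughly 10 false candidates per bait. This is an
irreducible property of median-ratio screening at triplicate depth,
which is precisely why the original-style screens treat their
candidate lists as input for orthogonal validation rather than as
final calls. Consequently, planted-reader *recall* is essentially
perfect already at 4-fold effects, while unique-set *precision* is
bounded by the planted-to-false-positive ratio; the acceptance script
reports both honestly rather than hiding the trade-off.

## Numerical and design choices

* Normalization totals are computed over post-QC-filter proteins only
  (filtering precedes all analysis); an all-zero sample column is an
  error naming the sample.
* Even replicate counts take the midpoint of the central values
  (numpy median semantics).
* All output files are written with deterministic row order and
  `repr`-exact float formatting, so identical inputs give byte-identical
  outputs (tested).
* QC policy defaults to dropping MaxQuant reverse and contaminant rows
  and keeping only-by-site rows; all three switches are configurable
  because deposited tables differ in which rows their published counts
  assume.
* Protein identity is the proteinGroups row key; gene names are carried
  for reporting and for joining annotation/FASTA inputs, but rows are
  never collapsed by gene.
* Problem sizes in the test suite (10–2000 proteins, 20 simulation
  seeds) were chosen as the smallest sizes at which the tested
  properties are non-trivial and stable.

## Known limitations

* No moderated statistics or missing-value imputation — deliberate, to
  mirror the median/threshold procedure exactly.
* Gene-symbol joins are exact-string; orthology or alias mapping must
  happen upstream.
* The hypergeometric test assumes the query is a simple random draw
  from the background, which pulldown candidate sets are not; as with
  all over-representation analyses, enrichments are descriptive.
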