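# Methods

## Motif grammars

**Canonical scanner.** A canonical match is four maximal guanine runs of
length ≥ 3 separated by loops of 1–7 bases (any base; N never matches).
Candidate runs are maximal, and every window of four *consecutive* candidate
runs is enumerated, so a stretch of five runs yields two distinct matches
that share three runs. Two matches are distinct iff their four-run index
sets differ. This per-site enumeration (rather than a single greedy regex
match) is deliberate: a long G-rich region harbours several potential
quadruplexes, and region-level consolidation is deferred to merging.

**Bulged scanner.** A bulged match is four stems of *exactly three* tetrad
guanines, each stem carrying 0–2 insertions of 1–3 bases over {A, C, T}
(an insertion slot lies between the first/second or second/third guanine),
with loops of 1–3 bases between stems. Accepted matches satisfy all of:

- at most two insertions in total, and at least two intact stems — which
  restricts layouts to the three validated models G3B1, G3B2, G2B2;
- no loop contains more than one guanine (the "single G linker" rule,
  applied per loop);
- the match core (stems + bulges + loops, no flanks) contains no `CC`;
  contiguous cytosines favour the duplex over the quadruplex. Flanking
  bases are exempt: validated sequences exist whose flanks are `CC`.

All valid stem/bulge layouts are enumerated, so matches may share up to
three of their four G-tracts; a match is identified by (start, end, layout).
When a span admits several layouts the preferred label orders
G3B1 > G3B2 > G2B2 — fewer bulges and more intact stems imply higher
thermodynamic stability. When a maximal G-run is longer than three, every
3-G window inside it is a candidate stem; the choice is immaterial after
region merging. Insertions are strictly non-G (a guanine in a slot would
redefine the stem) and N matches nothing anywhere.

Minus-strand matches are found by scanning the reverse complement and are
reported in forward coordinates with strand `-`. Scanning is exhaustive and
deterministic; the implementation chains candidate stems left to right with
a bulge budget, and is verified in the tests against an independent
brute-force enumerator over 12-guanine subsets.

## Region pipeline

Order: scan both grammars → remove bulged hits that (a) are themselves a
full canonical match or (b) share ≥ 1 nt with a same-strand canonical hit →
remove hits overlapping annotated repeats (strand-blind, ≥ 1 nt) → merge
overlapping same-strand hits into regions. Overlap is always "at least one
shared nucleotide" under half-open coordinates: book-ended intervals do not
overlap and are not merged. Merging is idempotent and conserves covered
bases. Whether repeat exclusion requires ≥ 1 nt overlap or containment was
an open choice; ≥ 1 nt mirrors the canonical rule.

Length statistics report mean, median (midpoint for even samples), mode
(ties toward the smaller length — a determinism choice for regression
tests) and population SD. Two length distributions are compared by the
two-sample Kolmogorov–Smirnov test (asymptotic p), optionally on seeded
same-size subsamples when population sizes differ grossly.

## Gene annotation

Internally all coordinates are 0-based half-open (BED convention);
conversion to 1-based inclusive printed coordinates is report formatting
only. Gene segments derive from one transcript per gene — the longest, when
several exist. The promoter is 2000 bp upstream of the TSS in gene
orientation, clipped at chromosome edges. UTRs and coding exons are split
at the CDS boundaries so the five fine classes (promoter, 5'UTR, coding
exon, intron, 3'UTR) are disjoint within a gene; without CDS information
whole exons are used and no UTRs are emitted.

A region is assigned to a segment class only when it overlaps exactly one
class of that gene (unique mapping); boundary-straddling regions are
excluded from segment-level counts but still count toward overall gene
positivity ("genic or promoter"), which uses any overlap. A gene counts
once per class regardless of orientation; a region overlapping two genes
counts for both. *Sense* means the region lies on the gene's own strand —
the non-template strand carrying the mRNA-like sequence. A promoter with
regions on both strands simultaneously is classed *bf* (back-forward).

Anchored profiles use coverage counting: for each anchor and each offset in
[-flank, flank) the track gains 1 when any region covers the corresponding
base; minus-strand anchors read offsets in gene orientation. The normalized
track divides by the total count, so it sums to 1.

## Enrichment statistics

Background sets are matched to the query per interval: identical length,
same chromosome (optional), re-drawn while overlapping the exclusion set
(by default the query's own positions) or containing N; sampling is seeded
and aborts after 1000×n rejected attempts. An interval is *positive* when
it shares ≥ 1 nt with any peak (strand-blind; peak sets are unstranded).

The enrichment score is ES = (a/n₁)/(b/n₂) from the 2×2 table of positive/
negative events in query and background. Inference uses the score test for
the ratio of two binomial proportions with a Katz log-ratio 95% CI; when
any cell is below 5 (or b = 0, where ES is reported as infinite) the exact
conditional hypergeometric test replaces the score p. The original analyses
used a proprietary package for this test; the score/Katz/exact combination
is specified here as an equivalent, reproducible choice and is verified
against full hypergeometric enumeration in the tests.

The repeated-sampling comparison draws `n_samples` (default 100) samples of
`sample_size` (default 1000) intervals from a query pool, obtains a matched
random set per sample, and compares the per-sample positive ratios by the
two-sided Mann–Whitney U test (exact for min(n) ≤ 8, tie-corrected normal
approximation otherwise).

## Kolmogorov–Waring fitting

The pmf follows the stationary birth–death recurrence
p_{k+1} = p_k·θ(k+α)/(k+1+β) with θ ∈ (0, 1], α, β > 0; p₀ is set by
normalization over 0..K, with K auto-extended until a geometric (θ < 1) or
power-law (θ = 1, tail exponent β+1−α) bound on the remaining mass is below
1e-9. θ = 1 with β − α ≤ 1 does not converge and raises. The exact
normalization of the published parameterization is not fully specified;
the recurrence is exposed directly so alternative parameterizations can be
compared. Fitting is maximum likelihood on transformed coordinates
(logit θ, log α, log(β−α), enforcing β > α) by Nelder–Mead from a 3×3 grid
of starts (θ ∈ {0.5, 0.9, 0.99} × α/β ∈ {0.5, 0.9, 0.99}); the fit is
deterministic given the data. A zero-truncated variant conditions the
likelihood on k ≥ 1. Both p₀ values are reported: the closed form 1 − α/β
and the normalization-based zero class of the fitted pmf; with published
parameters (θ = 0.99, α = 27.2, β = 30) the closed form gives 0.0933,
slightly above the printed 0.0925, presumably reflecting rounding of the
printed parameters.

## Diagnostic accuracy

Predictions (accepted bulged-model match present / absent) are confronted
with experimental structure calls; a call is positive for single major,
major + minor, or multiple G4 conformations, and negative for weak G4,
duplex + G4, two-layer G4, plain duplex or non-G4. Sequences matching only
the canonical grammar are out of scope for the bulged-model evaluation and
are excluded. Reported statistics: accuracy, sensitivity and specificity in
percent, LR⁺ = sensitivity/(1 − specificity) on proportions (undefined at
100% specificity), and Cohen's kappa with a 95% CI from the large-sample
standard error √(p_o(1−p_o)) / ((1−p_e)√n). On a 2×2 table the linearly
weighted kappa equals the unweighted one, so only the latter is computed.

## Synthetic data

Backgrounds are i.i.d. per-base at a configurable GC fraction (default 0.35
for planted-motif fixtures, in the neighbourhood of genomic GC content but
slightly G-poor so that chance motifs are rare). Motif-free backgrounds for
precision tests are produced by rejection sampling against both scanners on
both strands. Planted instances are drawn from each model's grammar and
re-validated against the filters; negative controls are built so no
sub-layout can reach two intact stems (G1B3 instances contain exactly one
GGG run, G0B4 none). Each instance is padded by one non-G base per side so
maximal G-runs cannot extend across the junction, and is locally
re-validated after planting — a positive instance must be recoverable at
its exact coordinates and not covered by a same-strand canonical match, and
a negative control's neighbourhood must contain no accepted bulged match.
Placement keeps ≥ 150 bp between instances so no single match can touch two
planted windows. Simulated gene models place non-overlapping single-
transcript genes on both strands with 1–5 exons (120–300 bp), introns of
200–800 bp, and a CDS starting inside the first and ending inside the last
exon.

What the generator does *not* emulate: genomic base composition structure
(isochores, CpG islands, repeats), clustered G-richness around real
promoters, and correlated peak/annotation tracks. Passing the planted-motif
tests therefore demonstrates correctness of the scanning and interval
algebra — recall, precision, coordinate arithmetic, strand handling — not
genome-realistic motif densities or enrichment magnitudes.

## Problem sizes used in the checks

The acceptance-style tests run at desk scale: oracle equivalence on 1000
random + 50 adversarial strings of ≤ 60 nt; strand symmetry on 500 random
sequences; planted recall/precision on a 1-Mb genome with 200 instances;
enrichment null calibration over 1000 exchangeable draws of 150 intervals;
enrichment recovery with n = 10 000 matched samples over a 10⁸-bp
coordinate space at a construction ratio of 15 (30% query positives vs 2%
background peak coverage); Kolmogorov–Waring recovery at n = 5000 over 20
seeds. Genome-wide census figures require the human reference genome plus
RepeatMasker/Ensembl/peak downloads and are supported by the pipeline but
not recomputed here.

## Known limitations

- The bulged grammar fixes stems at exactly three tetrad guanines; matches
  whose natural reading uses a 4-G stem are represented by 3-G windows
  within the run and consolidate at region level.
- The "single G linker" rule is interpreted per loop (a loop may contain at
  most one guanine); a per-sequence reading would be stricter.
- Loops above 3 nt are outside the bulged models by design; validated
  bulged quadruplexes with longer loops exist and are not captured.
- Enrichment p-values assume independent intervals; heavily overlapping
  query sets violate this and should be merged first.
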