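# g4bulge

Genome-wide discovery and analysis of **bulged G-quadruplex-forming
sequences** (pG4-BS) alongside the canonical motif (pG4-CS).

G-quadruplexes (G4s) are four-stranded DNA structures built from stacked
G-tetrads. The classic sequence model, `G3+N1-7G3+N1-7G3+N1-7G3+`, requires
four uninterrupted runs of at least three guanines. Many experimentally
observed G4s, however, tolerate *bulges* — non-guanine bases inserted inside
a G-stem that protrude from the tetrad core. `g4bulge` implements a scanner
for the bulged motif

```
G Ix G Ix G  Ny  G Ix G Ix G  Ny  G Ix G Ix G  Ny  G Ix G Ix G
```

where each of the four stems contributes exactly three tetrad guanines, `I`
is an insertion of 0–3 bases over {A, C, T} (at most two insertions per
match), and `N` is a loop of 1–3 bases. Matches are kept only for the three
structurally validated models — **G3B1** (three intact stems, one bulge),
**G3B2** (three intact stems, two bulges in one stem) and **G2B2** (two
intact stems, one bulge in each of two) — and must pass stability filters:
no loop may carry more than a single guanine, and the match core must not
contain contiguous cytosines (`CC`), which favour duplex formation.

Around the scanner the package provides the full downstream pipeline:

- canonical-overlap and repeat exclusion, strand-specific merging of hits
  into regions, and length-distribution statistics with two-sample K–S
  comparison (`g4bulge.regions`);
- gene-segment assignment with unique-mapping semantics, promoter
  strand-architecture classification (back-forward / *bf* genes), anchored
  per-nucleotide frequency profiles around TSS-like anchors, and per-gene
  region counting (`g4bulge.annotate`);
- background-matched enrichment of interval sets in experimental peak
  tracks: length-matched random backgrounds, 2×2 enrichment scores
  ES = (a/n₁)/(b/n₂) with Katz log CIs and score/exact p-values, and a
  repeated-sampling Mann–Whitney ratio comparison (`g4bulge.enrich`);
- Kolmogorov–Waring maximum-likelihood fitting of per-gene counts,
  p_{k+1} = p_k·θ(k+α)/(k+1+β), including the closed-form zero-class
  probability p₀ = 1 − α/β (`g4bulge.kw`);
- diagnostic-accuracy evaluation of model predictions against experimental
  structure calls: accuracy, sensitivity, specificity, LR⁺ and Cohen's
  kappa (`g4bulge.diagnostics`);
- a synthetic-data generator — random genomes, motif-free backgrounds,
  planted motif instances with a truth track, simulated gene models — so
  the whole pipeline is testable without external downloads
  (`g4bulge.simulate`).

## Worked example

The E2F8 promoter sequence BS33 (`TAGAGGCGGGAGTGGAGGGCG`, flanking
dinucleotides included) forms a three-layer parallel G4 with two bulges:

```python
>>> from g4bulge import scan_bulged, best_hit
>>> hit = best_hit(scan_bulged("TAGAGGCGGGAGTGGAGGGCG"))
>>> hit.model, hit.n_intact_stems, hit.n_bulges, hit.bulge_seqs
('G2B2', 2, 2, ('A', 'T'))
>>> hit.core_seq
'GAGGCGGGAGTGGAGGG'
```

The match is classified under the G2B2 model: two intact stems, and one
single-base bulge (`A`, `T`) in each of the two interrupted stems — the
core reads `GAGG-C-GGG-A-GTGG-A-GGG` as stem/loop segments. The same
scanner, pointed at a FASTA file, runs from the shell:

```bash
g4bulge scan-bs --fasta genome.fa --out-bed hits.bed --out-tsv hits.tsv
g4bulge merge --in-bed hits.bed --out-bed regions.bed
```

Every subcommand (`scan-bs`, `scan-cs`, `merge`, `stats`, `annotate`,
`profile`, `enrich`, `fit-kw`, `validate`, `simulate`) writes its output
plus a JSON run manifest recording parameters and package version.

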