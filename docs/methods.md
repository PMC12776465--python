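# Methods

## Overview

`tmdslip` searches coding transcriptomes for *TMD-slip motifs*: slippery
heptanucleotide sequences positioned so that their decoding coincides with
translocon-mediated membrane integration of an upstream transmembrane
domain (TMD).  When the ribosome decodes such a heptamer while the nascent
TMD is under translocation tension, the P- and A-site tRNAs can re-pair in
the −1 reading frame at little energetic cost, producing a frameshifted
polypeptide that usually terminates shortly afterwards.  The pipeline has
five computational stages — heptamer scoring, TMD detection/refinement,
motif pairing, frameshift-product prediction, and statistical context —
plus a synthetic-data generator that provides ground truth for all of them.

## Frameshift propensity score (ΔG_FS)

For a heptamer N₁…N₇ read in the classical X₁XXY₄YYZ₇ register, the
0-frame P- and A-site codons are N₂N₃N₄ and N₅N₆N₇; after a −1 shift the
same tRNAs sit on N₁N₂N₃ and N₄N₅N₆.  We score

    ΔG_FS = [E(ac(N₂N₃N₄) : N₁N₂N₃) + E(ac(N₅N₆N₇) : N₄N₅N₆)]
          − [E(ac(N₂N₃N₄) : N₂N₃N₄) + E(ac(N₅N₆N₇) : N₅N₆N₇)]

where ac(·) is the perfect Watson–Crick anticodon of the 0-frame codon and
E is the free energy of the three-base-pair codon–anticodon minihelix.
Model assumptions:

- **One cognate tRNA per codon.**  The anticodon is the exact reverse
  complement of the 0-frame codon; isoacceptor and modified-base effects
  are not modeled.
- **Nearest-neighbor stacking.**  E sums the two stacking steps of the
  minihelix using Turner-rule Watson–Crick stack free energies
  (ΔG°37, kcal/mol), bundled unscaled in
  `data/turner_wc_stacks.tsv` and expanded to all sixteen ordered steps by
  duplex-flip symmetry.
- **G·U wobble as a pair.**  A −1-frame G opposite an anticodon U (or U
  opposite G) counts as paired.  Wobble-specific stack tables are not
  bundled; a wobble-containing step takes the value of its Watson–Crick
  analog (G·U→A·U, U·G→U·A) and each wobble pair adds a flat per-pair term.
- **Mismatches void stacking.**  A mismatched position contributes a flat
  penalty and removes both adjacent stacking steps from the sum (a 3-bp
  helix has no defined internal-mismatch stack).

Because a homopolymer re-pairs onto identical codons, ΔG_FS(homopolymer) is
exactly 0, and since the cognate helix is the energy minimum, ΔG_FS ≥ 0 for
all 16,384 heptamers.  Scores are rounded to 0.01 kcal/mol before
comparison against the classification cutoff so the strict `<` is stable.

### Calibration

Three model parameters are free: a uniform scale α on the stack table, the
mismatch penalty m, and the wobble per-pair term w.  They were calibrated
once against two anchors: (i) the 24 classical X XXY YYZ heptamers
(X ∈ {A,C,G,U}, Y ∈ {A,U}, Z ∈ {A,C,U}, bundled in
`data/reference_slippery_heptamers.txt`) must all fall below the
+2.9 kcal/mol classification cutoff, and (ii) the full census at that
cutoff must classify exactly 465 of 16,384 heptamers as slippery.  The
frozen defaults are

| parameter | value | units |
|---|---|---|
| stack scale α | 0.425 | – |
| mismatch penalty m | 0.52 | kcal/mol per mismatched position |
| wobble term w | 0.50 | kcal/mol per G·U pair |
| cutoff | 2.9 (strict `<`) | kcal/mol |

Under these values the 24 reference motifs span [0, 2.89] kcal/mol (the
two homopolymer members score exactly 0; the maximum, CCCAAAC, scores
2.89); `calibrate_threshold` returns that maximum, and the bundled cutoff
is its value rounded up to one decimal.  The ΔG_FS scale is knowledge-based
and ordinal rather than thermodynamically absolute: only the ranking and
the calibrated cutoff matter to the pipeline.

## TMD detection and refinement (ΔG_app)

Candidate TMD regions come either from an external per-residue topology
string (runs of `M` states, as written by consensus topology predictors)
or from a built-in fallback scan: maximal runs of residues covered by a
sliding 19-residue window whose apparent insertion free energy falls below
a cutoff (default +1.0 kcal/mol), merged when separated by fewer than 5
residues.  The built-in scan is a deliberately simple stand-in for a full
topology predictor; synthetic tests use unambiguous hydrophobic blocks so
no result depends on its subtleties.

Each region is then refined by exhaustive enumeration: every segment of
16–25 residues lying fully inside a window from 10 residues upstream to 10
residues downstream of the region (clipped at the protein termini) is
scored with ΔG_app, and the minimum wins.  Ties break to the shorter
segment, then the smaller start, making refinement deterministic.  The
refined segment's C-terminal residue anchors all distance measurements.

ΔG_app uses the published biological hydrophobicity scale's per-residue
center coefficients (`data/dg_scale.tsv`; e.g. L −0.55, A +0.11, D +3.49
kcal/mol).  The default mode sums center coefficients uniformly
(`center_only`).  A `positional` mode is available that attenuates each
contribution toward the segment edges with a Gaussian depth profile
(σ = 6.5 residues) and adds a quadratic length correction
(0.0123·(L−19)² kcal/mol); it is a simplified approximation of the full
position-specific predictor, not a reimplementation, which is why
`center_only` is the default.

## Motif pairing

Within each in-frame transcript, every phase-aligned heptamer (start
position s with s ≡ 0 mod 3, 1-based, so nucleotides 2–4 and 5–7 are
0-frame codons) is looked up in the slippery table; heptamers overlapping
the stop codon are skipped.  The codon distance is

    L = codon_index(P-site codon) − aa_end(refined TMD)

(the alternative anchor, to the heptamer's first nucleotide, is one codon
smaller and selectable).  Assignment is nearest-to-ideal in both
directions: each slippery heptamer is attributed to the TMD minimizing
|L − 45|, then per TMD only the heptamer minimizing |L − 45| is kept, so no
TMD or heptamer occurrence is double-counted.  Ties (e.g. L = 44 vs 46)
break toward the smaller L.  Motifs are reported when 35 ≤ L ≤ 55, with
L = 45 flagged ideal.

**Splicing dependence.**  Motifs are grouped by gene.  An
alternative-isoform motif is *splicing-dependent* when the gene's canonical
transcript has no in-range motif with the same heptamer sequence — the
situation created when exon loss repositions a TMD relative to a heptamer.
Canonical-transcript motifs are labelled `canonical`; isoform motifs shared
with the canonical also carry `canonical` (the enum has no separate
"shared" state); genes without a canonical transcript give
`not_applicable`, and multiple canonical transcripts per gene raise an
error.

## Frameshift products and peptides

The P-site residue of the slip site is the last 0-frame residue.  A product
is `prefix` (0-frame translation through the P-site codon) plus `extension`
(translation in the shifted frame starting at the shifted A-site codon, up
to the first alternative-frame stop).  A shift directly onto an
alternative-frame stop yields an empty extension — a premature-termination
product.  Frames −1, −2 and +1 are supported; −1 is the default.

In-silico digestion supports trypsin, LysC, LysN, GluC, AspN and
chymotrypsin (cleavage regexes from pyteomics' ExPASy rules; LysN is a
custom N-terminal-to-K rule), with ≤ 2 missed cleavages and a 7–50 residue
length filter by default — common search-engine settings.  The second-pass
peptide database contains, per motif and frame, digest peptides overlapping
the transition point or extension, plus junction-truncated
(semi-specific C-terminus) peptides for premature-termination products; any
peptide identical to a first-pass (0-frame) digest peptide is removed, so
the two databases are disjoint by construction.

Observed peptides are classified by exact substring search: `zero_frame`
(in a 0-frame protein), `transitional` (crosses a junction, ending with ≥ 1
alternative-frame residue), `frameshift` (wholly inside an extension), or
`premature_termination` (ends exactly at the P-site residue of a motif
whose shifted A-site codon is a stop; this call takes precedence over
`zero_frame`, since such peptides are always 0-frame substrings).
Conflicting classes, or one alternative-frame class at several motif loci,
give `ambiguous`; a `zero_frame` match at several transcripts is ordinary
isoform redundancy and keeps its call.  I and L are distinguished by
default; an I=L mode exists because mass spectrometry cannot separate them.

## Statistics

- **Mann–Whitney U** (two-tailed throughout): exact null distribution for
  tie-free samples with n₁·n₂ ≤ 400; otherwise the tie-corrected normal
  approximation without continuity correction (identical samples give
  p = 1 exactly).
- **Fisher's exact test**: conditional hypergeometric, two-sided by the
  point-probability rule; the reported odds ratio is the sample ratio
  ad/bc (infinite when bc = 0).
- **Pearson χ²** (df = 1, no continuity correction) with ad/bc; zero
  expected counts redirect to Fisher.
- **Positional null ensembles.**  Mode 1 re-places each transcript's TMD
  segments uniformly at random (count- and length-preserving,
  non-overlapping; stars-and-bars sampling makes single-segment starts
  exactly uniform) while heptamer positions stay fixed.  Mode 2 re-draws
  the slippery heptamer set uniformly from the 16,384-heptamer space while
  TMDs stay fixed.  Observed distances are compared against the pooled
  null distances with Mann–Whitney (pooling matches reporting a single p
  per analysis), and the ideal-spacing count against the null mean with a
  χ² odds ratio.  Default 200 iterations in tests; the full-scale setting
  is 16,384.
- **NMD association.**  Two Fisher 2×2 tests (motif × upregulated,
  motif × downregulated; default thresholds |log₂FC| > 0.263, i.e. ±20%,
  config-exposed) plus Mann–Whitney on log₂ fold-changes of motif vs
  non-motif transcripts.
- **Term enrichment.**  Per-term Fisher against a background gene set;
  retained terms need ≥ 100 hit genes, odds ratio > 1.4 ("fold enrichment"
  is read as the odds ratio, the quantity plotted), and annotation depth
  3–8 (depth comes from the annotation table; no ontology-graph traversal).
  Benjamini–Hochberg adjusted p-values are reported across all tested
  terms.

## Synthetic data

The generator emulates the structural features the pipeline consumes:
Ensembl-style CDS FASTA headers; one canonical plus optional alternative
isoforms per gene; a hydrophilic background (S/T/N/Q/G/D/E/K/R/H) with a
codon-randomized L/I/V/F-rich TMD block (19 residues by default, weights
0.55/0.20/0.15/0.10) that the built-in scanner detects unambiguously; and
phase-aligned slippery heptamers planted at configured codon distances
(default L = 45, heptamer UUUUUUA).  Splicing-dependent motifs place the
heptamer 67 codons from the TMD in the canonical transcript and delete a
28-codon spacer block in the isoform, bringing the same heptamer to
L = 39.  UPF1 tables draw motif transcripts from N(effect, σ) and others
from N(0, σ).

At background slippery rate 0 the guard zone [30, 60] codons downstream of
each TMD (widened by the spacer length for splicing-dependent genes) is
scrubbed: offending background codons are re-drawn, with the codon carrying
a planted heptamer's first nucleotide treated as semi-protected (its first
two nucleotides may change), for up to 50 passes.  The 0-frame reading is
stop-free by construction and verified.  A positive background rate
instead plants extra random slippery heptamers outside guard zones.

What the generator does **not** emulate: real codon-usage bias, UTRs and
splice-graph structure, signal peptides and multi-pass topologies, mRNA
secondary structure near slip sites, expression levels, or mass spectra.
Passing closed-loop tests therefore demonstrates algorithmic correctness
(recall/precision 1.0 with exact coordinates on unambiguous truth), not
performance on real transcriptomes, where TMD prediction quality and
annotation noise dominate.

## Numerical choices and degenerate inputs

- Coordinates 1-based inclusive everywhere; heptamer phase s ≡ 0 (mod 3).
- ΔG_FS rounded to 0.01 kcal/mol before the strict `<` cutoff.
- Refinement and assignment tie-breaks as above; all randomized operations
  take explicit seeds (NumPy `default_rng`) and are reproducible.
- Records with length not divisible by 3 are kept but flagged and excluded
  from motif search; records shorter than 21 nt or containing IUPAC codes
  other than N are skipped at parse with a warning.  Codons containing N
  translate to X; heptamers containing N are never scored.
- Transcripts too short for a TMD re-placement keep their observed
  geometry (logged), and degenerate 2×2 margins give p = 1 with an
  undefined odds ratio rather than an exception.

## Known limitations

- The ΔG_FS scale reproduces the calibrated census and ordering, not
  per-heptamer values of any external table; absolute energies should not
  be interpreted thermodynamically.
- The built-in TMD scan is not a topology predictor: no signal-peptide
  discrimination, no orientation, no consensus of methods.  For real data,
  supply external topology strings.
- Peptide classification is sequence-level only; it does not model
  cleavage-specificity constraints of a search engine, spectra, or FDR.
- The positional null preserves TMD count and lengths but not any
  correlation between TMD position and sequence composition.
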