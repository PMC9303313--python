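# Methods

## The complementarity distance d

An ASO silences (or inadvertently knocks down) an RNA by Watson–Crick
hybridization, so off-target risk is scored on the *reverse complement*
of the ASO sequence scanned along each transcript's sense strand — one
orientation only, since ASO:RNA duplex formation is directional. The
score is the distance **d**: the minimum over all transcript substrings of
the unit-cost edit distance (mismatches + insertions + deletions) with
the pattern aligned end-to-end and the substring ends free (semi-global
alignment). Per gene, d is minimized over all transcripts (isoforms), and
genes are pooled into classes d0, d1, d2, d3plus.

The implementation is a plain dynamic program (a column-sweep over the
text with the pattern dimension inner). At pattern lengths around 14 and
desk-scale transcriptomes this is fast enough that no bit-vector
optimization or index structure is warranted; the test suite checks the
scan against two independent oracles (a row-major numpy DP, structurally
different, and the edlib C library in infix mode) and against exhaustive
substring enumeration at tiny sizes.

Hit reporting: every text end-position within the distance budget is
traced back through a windowed full DP (ties prefer substitutions over
gaps), and overlapping candidate alignments of the same local site are
merged keeping the lowest d, then the leftmost start, then the fewest
indels — one hit per site, no double-counting of shifted alignments.

The exclusion screen drops any candidate with a complementary region at
d ≤ 1. Because public approximate-search services offer both a full edit
distance and a substitution-only distance, and "1-mismatch" is ambiguous
between them, both modes exist: `edit` (default, Levenshtein) and
`mismatch_only` (sliding-window Hamming). Hamming distance can never be
smaller than Levenshtein on the same input, so `mismatch_only` is the
more permissive screen; this ordering is property-tested.

## Gapmer model conventions

* Wing/gap design defaults to 2–10–2 for a 14-mer (gap = positions 3–12,
  1-based over the full sequence); both are configurable. All attested
  modified positions (3–12) fall in this gap.
* Modification positions are 1-based indices into the **full** sequence.
  The naming convention `{parent}-{code}-{position}` (e.g. `TS1-C1-7`) is
  parsed and validated: the code must be registered, the registered base
  letter must equal the sequence letter at the position, and the position
  must lie in the gap.
* Nucleobase derivatives are **annotations**: the 5-/2-positions of
  pyrimidines and 7-/8-positions of purines sit away from the pairing
  face, so every derivative retains the parent letter's Watson–Crick
  pairing and the search sequence is always the plain letter string.
  Parent and modified ASOs therefore share one distance map — the
  construction underlying the index-ratio analysis.
* The default registry holds 17 derivatives, codes C1–C4, T1–T5, G1–G8;
  chemistry names are recorded where known (C1 = 5-hydroxycytosine,
  T1 = 2-thiothymine, G1 = 8-bromoguanine) and G4–G7 carry a novelty
  flag. Codes are otherwise opaque labels; no thermodynamic modelling of
  individual chemistries is attempted.
* Motif counting counts overlapping occurrences (every matching start
  offset). The default motif list is TGC and TCC, the consensus
  trinucleotides associated with gapmer hepatotoxicity; any user list is
  accepted.
* RNA input (U) is normalized to DNA (T) on read; output is always DNA.

## The off-target down-regulation index

For an expression table of per-gene ratios r (treated/control) and a gene
distance map, the index is

    index(d_cutoff, down) = Σ  |log₂ r_g|   over genes g with
                            d(g) ≤ d_cutoff and r_g < 1

Defaults: d_cutoff = 2, direction `down` (strictly r < 1; r = 1
contributes zero either way; a `both` direction sums all qualifying
genes). Genes absent from the distance map are treated as d ≥ 3 and
excluded at the default cutoff. Genes in the distance map but missing
from the expression table are skipped with a warning by default (strict
mode raises). No fold-change floor is applied before summing.

The log base defaults to 2 and is configurable; the modified-vs-parent
**index ratio** (100 × modified/parent) is invariant to the base, since a
change of base rescales numerator and denominator identically — so
percentage comparisons between ASOs are well-defined whatever base a
reader assumes. The index is monotone in d_cutoff, monotone in knockdown
strength, permutation-invariant, and `down` ≤ `both`; all four are
tested.

`dclass_scatter_summary` provides the numeric backing of the standard
intensity-vs-log-ratio scatter: per class, gene count, mean/median log
ratio and fraction down-regulated.

## Toxicity and Tm analyses

The hepatotoxicity call is conjunctive by default — AST > 100 U/l **and**
ALT > 100 U/l, strict inequalities — because screening tables report both
enzymes elevated together in every positive; a disjunctive `either` mode
is available. AST/ALT span ~300–15,000 U/l across toxic and non-toxic
ASOs, so correlation analyses log-transform them by default.

ΔTm = Tm(modified) − Tm(parent); labels are `large_drop`
(ΔTm < −5 °C, strict — the destabilization reported for C1 and G1
chemistries), `equivalent` (|ΔTm| ≤ 2 °C, the band within which most
modified ASOs fall), `intermediate` otherwise. Tm values are *ingested*
(measured or externally predicted); no Tm prediction is performed.
Pearson/Spearman correlation is delegated to scipy; group-comparison
testing (ANOVA/Tukey) is out of scope.

## Synthetic data generator

The generator emulates the statistical structure of the study data, not
its biology:

* **Transcriptome** — `n_genes` random uniform-composition transcripts
  (default lengths uniform in [200, 500] nt), one per gene,
  rejection-sampled so no transcript has an accidental complementary
  region at d ≤ d_eff to any configured ASO. Sites are then *planted*:
  the reverse complement of the ASO mutated by exactly d random edits
  (certified by a global edit-distance check), inserted at a random
  position, and re-scanned to confirm the minimal distance equals the
  requested d — planted distances are unambiguous ground truth, which the
  round-trip tests exploit at 500 plants per class.
* **Expression** — log₂ r_g = −δ₀·γ^d(g)·1[d(g) ≤ d_eff] + N(0, σ_expr).
  Geometric decay in d is the simplest model consistent with an
  off-target focus on d ≤ 2. Defaults δ₀ = 1 (2-fold knockdown at d = 0),
  γ = 0.5, d_eff = 2, σ_expr = 0.1 — a knockdown depth and array-scale
  noise a microarray ratio experiment would plausibly show. δ₀ is
  recovered within 10% from a 2000-gene simulation by regressing
  −log₂ r on γ^d (tested).
* **Toxicity** — ln AST = α + β_hyb·index + β_indep(aso) + N(0, σ_tox),
  ALT likewise with independent noise. α = ln(50 U/l) is a healthy
  baseline; β_hyb scales the hybridization-dependent component with the
  off-target index; β_indep is the per-ASO latent protein-interaction
  (hybridization-independent) term.

Three scenario bundles wire these together end-to-end
(deterministic and byte-identical per seed):

* `paper_like` — a parent 14-mer (TS1, 2–10–2) with three single-modified
  analogs and one triple-modified analog sharing its sequence; 40 planted
  genes (8/10/12/10 at d = 0/1/2/3) among 160; β_hyb = 0 and β_indep set
  so the parent reaches AST ≈ 12,000 U/l while modifications cut toxicity
  to 0.3–4.1% of parent. Because the family shares one distance map, the
  index ratio is *not set anywhere* — it emerges near 100% from
  independent expression noise, while AST drops 25–300-fold: the
  qualitative dissociation between off-target knockdown and
  hepatotoxicity.
* `hybridization_driven` — six distinct ASOs with 0–10 planted d = 0
  genes each, β_hyb > 0, β_indep = 0: toxicity tracks the index
  (r > 0.99), the counterfactual world the index analysis would detect.
* `null` — clean ASOs, no planted sites, baseline toxicity only: no
  hepatotoxic calls.

What the generator does **not** emulate: real transcript composition and
length distributions, isoform structure, array normalization artifacts,
correlated gene noise, dose–response and animal-to-animal variability.
Passing tests therefore demonstrate the *pipeline's* correctness and the
internal consistency of the models, not in vivo predictive validity.

## Numerical and design notes

* Problem sizes throughout (transcript counts in the low hundreds,
  oracle-agreement sampling at thousands of pairs, 2000-gene parameter
  recovery) are chosen as comfortable desk-scale defaults; everything is
  configurable upward.
* Seeding: every stochastic routine takes either an explicit
  `numpy.random.Generator` or derives one deterministically from the
  config seed plus a CRC-stable label, so per-ASO streams are independent
  and reproducible. Tests assert determinism and distributional
  properties, never specific bit-streams.
* Coordinates are 0-based half-open everywhere in code and outputs;
  1-based indexing appears only in modification positions (a field-entry
  convention) and human-readable names.
* Degenerate inputs: empty transcriptome → empty distance map / all
  candidates pass screening; empty transcript → no hits; zero parent
  index → the index ratio raises rather than returning a silent infinity;
  constant vectors → correlation raises.

## Known limitations

* The selection funnel replaces the original manual curation of
  screen-passing candidates with explicit filters; published survivor
  counts from genome-scale databases are not reproduced (they require the
  external mRNA database release the screen ran against).
* The scan is linear in transcriptome size; it is intended for synthetic
  and subset-scale FASTA inputs, not whole-genome indexes.
* Pre-mRNA (intronic) off-targets are handled only implicitly: the scan
  is agnostic to what FASTA it is given, so scanning pre-mRNA sequences
  is just a different input file.
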