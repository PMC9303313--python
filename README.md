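# gapmertox

Desk-scale analysis toolkit for the hepatotoxicity of LNA gapmer antisense
oligonucleotides (ASOs).

Gapmer ASOs — short DNA oligonucleotides with locked-nucleic-acid (LNA)
wings flanking a central DNA "gap" — silence a target RNA through RNase H
cleavage, but can injure the liver. Part of that toxicity is
*hybridization-dependent* (unintended RNase H knockdown of
near-complementary off-target RNAs) and part *hybridization-independent*
(ASO–protein interactions unrelated to base pairing). `gapmertox`
implements the computational side of dissecting the two:

* **Gapmer model** — wing/gap structure, a registry of 17 nucleobase
  derivatives of C, T and G (e.g. C1 = 5-hydroxycytosine,
  T1 = 2-thiothymine, G1 = 8-bromoguanine) annotated at 1-based gap
  positions (`TS1-C1-7` = parent TS1 with C1 at position 7), and counting
  of the hepatotoxicity-associated TGC/TCC motifs.
* **Off-target search** — semi-global alignment of the reverse complement
  of an ASO along transcript sense strands under the distance
  *d* = mismatches + insertions + deletions (unit-cost Levenshtein,
  pattern end-to-end, free text ends), per-gene minimal-*d* classes
  (d0 / d1 / d2 / d3plus), and the exclusion screen that discards any
  candidate with a complementary region at *d* ≤ 1 ("perfect match or
  1-mismatch"; a substitution-only Hamming mode is also provided).
* **Candidate design** — seeded random 14-mer generation and the selection
  funnel (raw → screen-passing → motif-bearing) with a JSON audit trail.
* **Off-target down-regulation index** — for an expression-ratio table
  (treated/control) and a gene distance map,

  &nbsp;&nbsp;&nbsp;&nbsp;index = Σ<sub>g : d(g) ≤ 2, r<sub>g</sub> < 1</sub> | log₂ r<sub>g</sub> |

  with modified-vs-parent comparisons reported as a percentage
  (base-invariant).
* **Toxicity analysis** — the > 100 U/l serum AST/ALT hepatotoxicity call,
  ΔTm flags for duplex-destabilizing chemistries (drop > 5 °C vs
  Tm-equivalent |Δ| ≤ 2 °C), and Pearson/Spearman correlations.
* **Synthetic data** — seeded generators for transcriptomes with *planted*
  complementary sites at exact distance d, geometric-decay knockdown
  expression tables, and two-component (hybridization-dependent +
  -independent) toxicity, so the full pipeline runs and is tested with no
  external download.

## Worked example

The five hepatotoxic gapmers from the published in vivo screen are bundled
as the standard worked example:

```python
from gapmertox import count_motifs, classify_hepatotoxic
from gapmertox.datasets import hepatotoxic_screen_table, screen_tox_records

for _, row in hepatotoxic_screen_table().iterrows():
    c = count_motifs(row["sequence"])
    print(row["aso_id"], row["sequence"], c["TGC"], c["TCC"])
for r in screen_tox_records():
    print(r.aso_id, r.ast, r.alt, classify_hepatotoxic(r))
```

```
TS1 GTTATGCCACCCTA 1 0
TS2 GTCCGCATGCCTAA 1 1
TS3 GATATGCCCTACTA 1 0
TS4 GTATGCCTCCGTTA 1 1
TS5 GCTATGTTAGTCCG 0 1
TS1 9437.0 15602.0 True
...
TS5 287.0 291.0 True
```

Every TGC/TCC count matches the printed screening table, and all five ASOs
exceed 100 U/l on both enzymes.

The headline dissociation — nucleobase modifications collapse toxicity
while barely moving the off-target index — reproduces qualitatively on the
synthetic `paper_like` scenario (one parent, three single-modified analogs
and a triple-modified analog sharing the same base sequence):

```python
from gapmertox import make_fixture_bundle
m = make_fixture_bundle("paper_like", seed=1)
print(m["derived"]["index_ratio_pct"])   # modified / parent, percent
print(m["derived"]["ast"])               # simulated serum AST, U/l
```

```
{'TS1-C1-7': 96.322, 'TS1-T1-5': 101.219, 'TS1-G1-6': 95.897, 'TS1-G1T1C1': 101.211}
{'TS1': 11894.2, 'TS1-C1-7': 86.7, 'TS1-T1-5': 485.8, 'TS1-G1-6': 299.7, 'TS1-G1T1C1': 38.2}
```

The index ratio stays within a few percent of 100 while simulated AST
drops 25–300-fold: off-target expression changes do not explain the
toxicity reduction.

A `gapmertox` console script wraps the library
(`motifs`, `scan`, `screen`, `design`, `index`, `simulate`, `analyze`):

```bash
gapmertox simulate --scenario paper_like --seed 11 --out fixtures/
gapmertox scan --aso fixtures/asos.tsv --fasta fixtures/transcriptome.fa \
    --tx2gene fixtures/tx2gene.tsv --dmax 3 --out hits.tsv
```

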