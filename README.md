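# ragmerge

Graph-merge combinatorics and a perceptron classifier for RNA
secondary-structure tree motifs.

Secondary RNA structure maps naturally onto an unlabeled tree: stems are
edges; hairpins, bulges/internal loops and junctions are vertices of degree
1, 2 and ≥ 3.  The RNA-As-Graphs (RAG) convention indexes every tree motif
of order *n* as *n.z*, ranking the motifs of an order by ascending
algebraic connectivity λ₂ (second-smallest Laplacian eigenvalue), and
colors them red (known RNA), blue (candidate) or black (non-candidate);
red and blue are "RNA-like".  Trees of orders 2–8 are fully classified,
while order 9 has 4 known red motifs and 43 unclassified ones.

`ragmerge` asks whether a large motif can plausibly arise by *bonding* two
smaller ones and turns the answer into a predictive tool:

1. **Merge.** Identifying a vertex *u* of T₁ with a vertex *v* of T₂
   yields a tree on *n + m − 1* vertices.  All *n·m* labeled
   identifications between every pair of motifs with results of order ≤ 9
   are enumerated and grouped into automorphism-orbit classes with
   frequencies.
2. **Vectorize.** Each class becomes `⟨c₁, c₂, deg(v₁), deg(v₂)⟩` — the
   binary RNA-likeness of the two inputs and the degrees of the identified
   vertices — weighted by its frequency, with target `⟨1, 0⟩` / `⟨0, 1⟩`
   according to the result tree's class.
3. **Learn.** A 4-24-2 perceptron (logistic units, per-pattern
   back-propagation, 10,000 shuffled epochs) is trained on the vectors of
   the 26 classified trees of orders 7–9 (15 red, 11 black).
4. **Score.** A tree's prediction value is the frequency-weighted average
   of the first network output over all identification classes producing
   it, banded into five categories from Highly-RNA-Like (≥ 0.80) to
   Highly-Not-RNA-Like (≤ 0.20), and evaluated by ROC/AUC.

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.

## Worked example

Rank the six motifs of order 6 (index, λ₂, color):

```sh
$ ragmerge enumerate 6
6.1     0.26795 red
6.2     0.32487 red
6.3     0.38197 red
6.4     0.43845 blue
6.5     0.48586 black
6.6     1.00000 red
```

The merge table for the path on 3 vertices (3.1) with the 4-star (4.2) —
12 labeled identifications collapsing into 4 orbit classes:

```sh
$ ragmerge merge --max-order 6 --out merges.tsv && grep '^3.1+4.2' merges.tsv
3.1+4.2 1  leaf     1  leaf     6.2  red    6
3.1+4.2 1  leaf     3  support  6.5  black  2
3.1+4.2 2  support  1  leaf     6.4  blue   3
3.1+4.2 2  support  3  support  6.6  red    1
```

A leaf-to-leaf bond of two RNA-like motifs gives the red motif 6.2 six
ways out of twelve; bonding at the two high-degree support vertices gives
the star 6.6 exactly once.

Train, cross-validate and predict (seeded; a run takes well under a
minute):

```sh
$ ragmerge train-predict --seed 0 --output-dir run
AUC on classified trees: 0.970; outputs in run/
$ head -5 run/predictions.tsv
rag_index       color_class     prediction      category
7.1     red     0.80390 Highly-RNA-Like
7.2     red     0.83683 Highly-RNA-Like
7.3     red     0.84852 Highly-RNA-Like
7.4     blue    0.82585 Highly-RNA-Like
```

Every known red motif scores above 0.50; the ambiguous black motif 7.9 —
whose merge vectors overlap heavily with red-producing ones — lands at
0.55882 (Unclassifiable), and the 9-star scores 0.00062
(Highly-Not-RNA-Like).  `run/` also holds the weight snapshot
(`weights.json`), the ROC points (`roc.tsv`) and a `report.json` with the
per-repetition cross-validation RMSEs and the final training error.
Reruns with the same seed are byte-identical.

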