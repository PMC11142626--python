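# axesbio

Axes-based embedding analysis of molecular networks.

Most network-embedding pipelines in systems biology cluster the *gene*
embedding vectors and interpret the clusters with enrichment analysis.
`axesbio` instead annotates the **axes of the embedding space itself**:
each basis vector of the space becomes a first-class object that
collects statistically associated functional annotations, gets
summarized into a data-driven higher-level annotation, and is placed on
an evolutionary timescale.  The package is aimed at computational
biologists working with protein–protein interaction (PPI) networks and
Gene Ontology-style annotation resources, and it ships a synthetic
generator with planted structure so every stage runs without downloads.

## Method

1. **Network representation.** An undirected PPI network with adjacency
   `A`, degree matrix `D` and volume `vol(N)` is represented by its
   random-walk positive pointwise mutual information matrix

   ```
   PPMI = max{0, log( vol(N) · (1/T) · Σ_{r=1..T} (D⁻¹A)^r )},  T = 10.
   ```

2. **Embedding.** The PPMI matrix is decomposed by non-negative matrix
   tri-factorization, `PPMI ≈ P S Bᵀ` with `P, S, B ≥ 0`, where rows of
   `E = P S` are the gene embedding vectors and columns of `B` are the
   axes.  The orthonormal variant (ONMTF) additionally drives
   `BᵀB → I`.  Quality is tracked by the relative square error
   `RSE = ‖PPMI − P S Bᵀ‖²_F / ‖PPMI‖²_F`.  Externally learned
   embeddings `E1` (e.g. from skip-gram random-walk methods) are given
   an implicit basis in closed form, `B1 = PPMIᵀ · pinv(E1ᵀ)`.

3. **Axis annotation.** A binary term × gene matrix `M` is embedded by
   least squares, `U = M · pinv(Bᵀ)`.  Annotation *i* is associated
   with axis *j* when `U[i, j]` is the maximum of its row and is
   significant under a gene-label permutation null — empirical p-value
   `(c+1)/(n_perm+1)`, Benjamini–Hochberg-corrected across axes,
   q ≤ 0.05.

4. **ASFAs.** Each annotated axis is summarized into an Axes-Specific
   Functional Annotation: the words of its concatenated term
   definitions (or gene descriptions) whose adapted TF-IDF score
   `(1 + log TF) · log(N/DF)` is strictly positive.

5. **Evolution.** An annotation's *conservation degree* is the number
   of distinct taxa (out of a 20-taxon catalog) in which it appears;
   axes inherit the union over their terms and are classified as
   `prokaryotes` / `eukaryotes` / `vertebrates` by a three-rule
   cascade.

## Worked example

```python
import axesbio as ab

spec = ab.SyntheticSpec(seed=42)              # 300 genes, 8 modules
network, modules = ab.make_network(spec)
dag, table, texts, _ = ab.make_ontology_and_annotations(spec, modules)
table = table.aligned_to(network.node_ids)

ppmi = ab.compute_ppmi(network, walk_length=10)
res = ab.NMTF(ppmi, rank=8, orthonormal=True).fit()
print(res.summary())

ann = ab.AxisAnnotator.from_decomposition(table, res).fit(
    n_perm=1000, seed=0)
print(ann.summary())

asfas = ab.build_asfas(ann, texts)
catalog = ab.TaxonCatalog.default()
for a in asfas[:3]:
    union = ab.asfa_conservation(a, table)
    cls = ab.classify_evolution(union, catalog)
    print(f"axis {a.axis_id}: {', '.join(a.top_keywords(4))} "
          f"| conservation degree {len(union)} -> {cls}")
```

prints

```
Tri-factorization results
=========================================
mode:            ONMTF
matrix shape:    (300, 300)
rank (d):        8
iterations:      500
initial RSE:     0.094609
final RSE:       0.033372
||B'B - I||_F/sqrt(d): 0.0161

Axis annotation results
=========================================
terms x axes:       73 x 8
permutations:       1000 (seed 0, one-tailed)
FDR threshold:      0.05
terms associated:   72 (98.6%)
axes annotated:     7 (87.5%)
terms per annotated axis: 10.29

axis 0: kw02x03, kw02x08, kw02x02, kw02x01 | conservation degree 20 -> prokaryotes
axis 1: kw03x09, kw03x00, kw03x02, kw03x06 | conservation degree 4 -> vertebrates
axis 2: kw07x05, kw07x00, kw07x02, kw07x03 | conservation degree 4 -> vertebrates
```

The factorization reaches a basis within 2% of orthonormal, 72 of the
73 synthetic terms land on a significant axis, and the axis summaries
pick up each planted module's vocabulary; axes built from broad-taxon
branches classify as prokaryote-inherited, vertebrate-only branches as
vertebrate innovations.

A command-line interface mirrors the library:

```sh
axesbio synth --seed 3 --out fixture/
axesbio ppmi --edges fixture/edges.tsv --walk-length 10 --out ppmi/
axesbio annotate --edges fixture/edges.tsv --obo fixture/ontology.obo \
    --gene2go fixture/gene2go.tsv -d 8 --out run/
```

## Layout

| module | contents |
| --- | --- |
| `axesbio.network` | edge-list IO, `Network`, PPMI closed form, edge dropout |
| `axesbio.nmtf` | `NMTF` model / `NMTFResults`, NNDSVD init, basis recovery |
| `axesbio.axes` | `AxisAnnotator` model / results, permutation test, capture stats, dimensionality scan |
| `axesbio.ontology` | OBO parsing, ancestor propagation, rare-term filter, Lin similarity |
| `axesbio.annotations` | term × gene incidence tables, gene2go/text readers |
| `axesbio.asfa` | tokenization, adapted TF-IDF, ASFA construction |
| `axesbio.evolution` | taxon catalog, conservation degrees, origin classifier |
| `axesbio.validation` | SeSi statistics, gene-centric baseline, network coherence |
| `axesbio.synth` | planted SBM fixtures: networks, ontologies, annotations, texts |
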