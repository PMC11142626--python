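# Methods

This note documents the models, statistics and numerical choices behind
`axesbio`, in the spirit of the methods documentation of mature
modelling packages: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Network representation

Networks are undirected, unweighted and self-loop-free; weighted input
collapses to 0/1 with a warning, because the intended inputs are binary
physical-interaction records.  Node order is lexicographic, which makes
every downstream matrix deterministic across runs.  Restriction to the
largest connected component is available as an explicit call
(`largest_connected_component`), never applied silently; the PPMI
formula requires every node to have degree ≥ 1 (the degree matrix must
be invertible), so an input with isolated nodes errors with the node
names rather than being repaired behind the caller's back.

The random-walk PPMI uses walk length `T = 10` by default and the
natural logarithm.  The log base is switchable in one place
(`network.LOG_BASE` / the `log_base` argument); changing it rescales
the matrix by a positive constant and therefore rescales RSE-optimal
factors without changing any assignment decision.  Entries whose inner
random-walk sum is zero are clipped to 0 (the `max{0, ·}` in the
definition), implemented by evaluating the log only where the argument
is positive.

## Tri-factorization solver

Both variants minimize `‖X − P S Bᵀ‖²_F` over non-negative factors.

*Initialization* is NNDSVD-style and fully deterministic: for each of
the leading `d` singular triplets, the dominant non-negative part of
the pair (u, v) is kept and normalized, `S` starts as
`diag(σ₁..σ_d)`, and exact zeros are lifted by a small floor
(`1e-6 ×` the matrix mean) because multiplicative updates can never
revive an exactly zero entry.

*NMTF mode* uses the standard tri-factorization multiplicative updates

```
P ← P ∘ (XBSᵀ) ⊘ (P S BᵀB Sᵀ)
S ← S ∘ (PᵀXB) ⊘ (PᵀP S BᵀB)
B ← B ∘ (XᵀPS) ⊘ (B Sᵀ PᵀP S)
```

each of which is a least-squares descent step for its factor, so the
RSE trace is non-increasing; the test suite asserts this per iteration
at tolerance 1e-8.

*ONMTF mode* keeps the `P` and `S` updates and replaces the `B` update
with the Lagrangian orthogonality-preserving rule (with its elementwise
square root, which damps oscillation), augmented by a
`λ‖BᵀB − I‖²_F` penalty:

```
B ← B ∘ sqrt( (XᵀPS + λB) ⊘ (B SᵀPᵀPS + λ B BᵀB) ),
λ = ortho_weight · ‖X‖²_F   (ortho_weight default 1.0).
```

The pure Lagrangian rule shares its fixed points with the constrained
problem, but from a dense deterministic init its approach to
orthonormality is asymptotically slow (exact orthonormality of a
non-negative basis requires disjoint column supports, and
multiplicative updates only drive entries to zero in the limit).  The
scale-free penalty closes that gap: at the default weight the fitted
basis satisfies `‖BᵀB − I‖_F/√d ≈ 0.02` on the 300-gene benchmark,
against the package contract of ≤ 0.05, at a modest cost in
reconstruction error (RSE ≈ 0.03 vs ≈ 0.01 unconstrained).
Orthonormality is *verified post hoc*
(`NMTFResults.orthonormality_residual`), never imposed by projection,
which would break non-negativity.  Because the penalty trades
reconstruction against the constraint, monotonicity of the RSE trace is
only guaranteed (and only asserted) in NMTF mode.

Stopping: relative RSE improvement `< tol` (default 1e-5, a scale-free
operationalization of "the error stopped decreasing") or 500
iterations, whichever first.  Denominators carry an ε = 1e-10 guard.
The solver contains no randomness; repeated fits are bit-identical.

External embeddings get their implicit basis from
`B1 = Xᵀ pinv(E1ᵀ)`, the least-squares solution of `X ≈ E1 B1ᵀ`;
column-rank-deficient `E1` errors with the advice to reduce the
dimensionality rather than silently using a minimum-norm solution.

## Axis annotation

Annotations embed by `U = M pinv(Bᵀ)`.  The permutation null applies
one uniform random permutation of the gene columns of `M` per
iteration — equivalently a row permutation of `pinv(Bᵀ)`, which is how
it is implemented (O(n·d·t) per iteration, one shared permutation for
all terms).  This null preserves every row and column marginal while
destroying the gene–embedding correspondence.  P-values are
`(c+1)/(n_perm+1)` with `c` the count of permutations whose coordinate
reaches the observed one; they live in `[1/(n_perm+1), 1]` by
construction.  The default tail is upper one-sided (coordinates in a
non-negative space); a two-sided option compares absolute values for
sign-unconstrained external embeddings.

FDR control is Benjamini–Hochberg per annotation across its `d` axis
p-values.  A practical resolution constraint follows: the smallest
attainable adjusted q-value is `d/(n_perm+1)`, so `n_perm` must exceed
`d/α` for any assignment to be possible at level α.  The package
default is `n_perm = 100 000`; the tests and the acceptance script run
at 1 000, which is ample for `d ≤ 16` at α = 0.05 and keeps desk-scale
runtimes in seconds.

Hard clustering: an annotation goes to the axis that is both its row
argmax and significant; ties break to the lowest axis index
(measure-zero for real data, deterministic for fixtures).  Genes go to
the axis of their largest embedding coordinate; all-zero rows stay
unassigned.  On the planted benchmark the first axis retains the
network's global-connectivity (Perron) component, so a minority of
genes from well-recovered modules still load highest there —
gene-level modal concentration is 0.76–1.00 per module while
term-level recovery is ≥ 0.9.

The dimensionality scan runs the full pipeline per grid point and
selects the smallest dimensionality whose %-terms-captured is within a
plateau tolerance (default 2 percentage points, exposed in the API
since the flattening criterion is inherently a judgement call) of the
curve's maximum.  On the planted benchmark the capture curve is
already saturated at `d = k/2` — perfectly module-aligned annotations
remain significant on merged axes — so the rule selects the smallest
plateau point; rising capture curves that flatten at the true
dimensionality, as seen on real networks, are the regime the rule is
designed for.

## Ontology, information content, similarity

Only `is_a` and `part_of` links are followed, obsolete terms dropped;
cycles are an error.  Annotation propagation is the transitive closure
to all ancestors, with taxon sets unioned upward along the same edges.
Terms annotating ≤ 3 genes after propagation are removed as
uninformative (boundary tested exactly at 3 vs 4).

Information content is corpus-internal:
`IC(t) = −log(n_genes(t)/n_genes(corpus))` on the propagated table,
with the corpus being the annotated genes of the species itself — no
external reference corpus is needed, and a term annotating every
annotated gene has IC 0.  Lin similarity is
`2·IC(MICA)/(IC(t1)+IC(t2))`, 0 when the only shared ancestor is
uninformative, and 0 across namespaces of a multi-root ontology (each
namespace is treated as a separate annotation set).  The shortest-path
alternative runs on the undirected view of the DAG, since relatedness
through a common parent or a common child is counted alike.

## ASFA construction

Tokens are lowercased alphanumeric runs of length ≥ 2 (so hyphenated
and camel-cased biology terms split and fold predictably) minus a
packaged English stop-word list.  The adapted TF-IDF is
`(1 + log TF) · log(N/DF)` with raw occurrence counts; the sublinear TF
dampens long documents and the IDF zeroes words present in every axis
document.  Natural logs are used; the positive-keyword set — the ASFA
contract — is invariant to the base, which the tests assert.  A corpus
with a single annotated axis has all IDFs zero and yields an empty
ASFA rather than an error: the emptiness is the downstream-visible
flag for a degenerate corpus.  Gene-description ASFAs use the same
machinery over the gene → axis map and exist precisely to cover axes
that annotation incompleteness leaves without terms.

## Evolutionary conservation

The packaged catalog lists the 20 taxa of the standard gene2go GO
annotation set with one clade class each (1 prokaryote, 9 vertebrates,
10 non-vertebrate eukaryotes); it is a plain TSV and editable.
Conservation degree is the taxon-set size, in [1, 20].  The origin
classifier is a strict cascade — any prokaryote ⇒ `prokaryotes`; all
eukaryotes and no vertebrate ⇒ `eukaryotes`; all eukaryotes with a
vertebrate ⇒ `vertebrates` — and is total over non-empty classified
unions.  Published discussion of individual axes occasionally groups a
vertebrate-containing axis under the eukaryote heading; the classifier
here implements the stated rules verbatim, so such an axis classifies
as `vertebrates`.

Distance-vs-conservation reports per-term mean Euclidean distance to
all other term embeddings, its Spearman correlation with the degree,
and the degree at the largest consecutive-degree jump in per-degree
mean distance ("drastic increase" is reported descriptively in the
source analyses; the largest-jump rule is the deterministic
operationalization).  Category bounds are generic 1–4, specific 17–20,
background otherwise.

## Synthetic benchmark

The generator plants everything the method is supposed to find: an
assortative SBM (defaults 300 genes, 8 modules, p_in = 0.3,
p_out = 0.01 — dense modules over a sparse background, the regime where
embedding axes should align with modules), a toy ontology with one
branch per module and 8 leaves per branch, each leaf annotating a
seeded random half of its module's genes (comfortably above the
rare-term filter), taxon labels making alternating branches ancient
(broad span including the prokaryote) or recent (vertebrate-only), and
module-specific vocabularies for term texts and gene descriptions.
All randomness flows from one spec seed through spawned generators.

What passing on this benchmark shows: the full chain — PPMI, ONMTF,
least-squares annotation embedding, permutation test, FDR, hard
clustering, TF-IDF, conservation — is wired correctly and recovers
planted structure with ≥ 80% annotation-level accuracy in seconds on
one CPU.  What it does not show: behavior under the heavy-tailed
degree distributions, annotation noise and redundancy, cross-module
annotation overlap, and the 10³–10⁴-node, 500-dimension scale of real
PPI networks; the benchmark's vocabularies are disjoint by
construction, so ASFA separation is easier than on real GO text.

## Sizes and runtimes

The default test suite and the acceptance script use the 300-gene
benchmark, `d ≤ 16`, and 1 000 permutations; the whole suite runs in a
few seconds and the acceptance script in under ten on a single CPU.
These sizes were chosen as the smallest at which every contract is
exercised meaningfully; all defaults scale to larger inputs unchanged,
with solver cost O(n²d) per iteration and permutation cost O(t·n·d)
per iteration.
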