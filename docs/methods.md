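# Methods

## Model and procedure

`termscape` performs GO term over-representation analysis and summarizes
the significant terms by semantic clustering. The stages, and the
assumptions each makes:

1. **Ontology.** An OBO 1.2 file is loaded as a child→parent DAG,
   restricted to one namespace. Both `is_a` and `part_of` edges are
   traversed (the common convention for annotation propagation); other
   relations (`regulates`, …) are ignored because a gene involved in a
   regulating process is not in general involved in the regulated one.
   The graph is validated acyclic at load; obsolete terms are dropped but
   remembered so lookups fail with a specific message; `alt_id`s resolve
   silently to their canonical accession.

2. **Annotations.** GAF 2.1/2.2 rows are read (gene identity = column 3,
   the object symbol), rows with a `NOT` qualifier are skipped, and
   annotations are propagated up the DAG (true-path rule). All evidence
   codes are kept by default — the right exclusion set depends on the
   organism and use case — with an opt-in exclusion list (e.g. `IEA`).
   The default background is the full annotated universe; with a custom
   background, target genes outside it are dropped with a warning and
   counts are formed inside the background only.

3. **Enrichment.** Hypergeometric upper tail per term (survival function,
   numerically safe), BH step-up FDR, default threshold 0.05. Only terms
   with at least one propagated target gene are tested and define `m`:
   zero-overlap terms can never be called enriched by an upper-tail test,
   so testing them would only inflate the correction. This choice is the
   main analytic degree of freedom in the whole pipeline and is surfaced
   here deliberately; with it, reported q-values are conservative relative
   to a smaller, curated test set. Output ordering breaks ties by term id
   for determinism.

4. **Similarity.** IC uses natural log; Lin is base-invariant, the AIC
   weight is not, so the base is fixed and documented. The annotation
   probability of a term counts genes annotated to the term *or any
   descendant* (the propagated count): this is the reading under which the
   namespace root has probability 1 and IC 0 and IC decreases toward the
   root, as a specificity measure must. The AIC index is pinned as:
   semantic weight `SW(t) = 1/(1+e^(−1/IC(t)))` (limit 1 at IC 0),
   semantic value `SV(t) = Σ SW` over ancestors-or-self, similarity
   `Σ_{common} 2·SW / (SV₁+SV₂)`. Lin's "lowest common ancestor of
   maximal IC" is implemented as the max-IC member of the full common
   ancestor set — the max-IC element is necessarily a lowest one because
   IC is anti-monotone along edges. Conventions: self-similarity 1 when
   IC > 0; similarity 0 when the two terms' ICs are both 0 or their only
   common ancestor is the root (Lin).

5. **Clustering.** The similarity matrix is a precomputed affinity for
   scikit-learn spectral clustering, seeded. `k` defaults to the eigengap
   of the symmetric normalized Laplacian with `k_max = min(15, n−1)`
   (clusterings beyond ~15 groups stop being a summary); the first gap is
   eligible, so `k = 1` is a possible answer. A user-supplied `k`
   (CLI `--clusters`, sentinel −1 = auto) overrides the heuristic. Labels
   are canonicalized (cluster 0 holds the smallest term id, …) so runs are
   comparable; medoids maximize mean within-cluster similarity, ties to
   the smallest term id. With fewer than 3 enriched terms there is no
   usable spectrum and all terms share cluster 0.

6. **Layout.** Distance `d = 1 − sim` (the simplest monotone transform);
   classical (Torgerson) MDS provides the start and seeded SMACOF refines
   it — on Euclidean-embeddable input the classical solution is already
   exact, which is what the planted-configuration tests verify. Axes are
   min-max scaled to [0,1]; an axis whose spread is numerical noise
   (coincident or collinear layouts) collapses to 0.5 rather than
   amplifying that noise. Force-directed dispersal of overlapping points
   is a rendering concern; an optional deterministic jitter (`ε = 10⁻³`,
   off by default) separates exactly coincident points for static plots.

7. **Export.** JSON/CSV records use the field names of the original web
   schema (`termid`, `level`, `semanticdissimilarityx`, …). The `pvalue`
   field stores the BH-adjusted value actually used for filtering; since
   a single field is ambiguous, the raw p-value is also emitted
   (`pvalue_raw`). Floats are written at 6 significant digits with fixed
   key order, making export → load → export byte-identical. The `created`
   timestamp is empty unless `--timestamp` is given, so that identical
   invocations produce identical bytes.

## Synthetic data: what it emulates, what it does not

The generator emits OBO/GAF pairs with a rooted multi-parent DAG (each
non-root term gets 1–2 parents from shallower levels), sparse random gene
annotation (mean ~3 direct annotations per gene, Poisson), and two kinds
of planted truth:

* **a planted enriched term** — defaults: 30 terms, depth 4, 200 genes,
  a 20-gene target with 80% drawn from the planted term's propagated gene
  set (the plant is picked among mid-frequency terms, ≥ the draw size and
  ≤ a quarter of the universe, so it is neither trivial nor generic);
* **separated subtrees** (for clustering) — the DAG is built as `c`
  disjoint subtrees under the root and each gene annotates a single
  subtree, giving the similarity matrix a planted block structure.

Recovery conditions measured by the test suite and `scripts/acceptance.py`
at these settings: the planted term is detected at FDR 0.05 (and ranks
first) in ≥ 95% of 200 seeded runs; with 3 planted subtrees of depth 5
(30 terms, 150 genes), the eigengap returns k = 3 and the spectral
partition matches the subtrees (adjusted Rand ≥ 0.9) in ≥ 90% of 100
seeds. The subtree-recovery check uses the **Lin** index: under Lin,
terms in different subtrees share only the root and their similarity is
exactly 0, which is the clear block separation the plant is designed to
create. Under AIC the shared root contributes weight to every pair
(between-subtree similarity ≈ 0.4 at these depths), so the affinity graph
is connected and the eigengap legitimately sees one community — a property
of the index, not a defect of either stage.

What the toy fixtures do *not* emulate: real GO's scale (tens of
thousands of terms), its heavy-tailed term-size distribution, evidence
code structure, multi-namespace annotations, or annotation noise and
bias. Passing the planted-recovery tests shows the machinery is correct
and well-calibrated at clear separation; it does not certify statistical
behavior on real, messy annotation corpora.

## Numerical choices

* Hypergeometric tail via the survival function (log-space internally in
  scipy); exact-enumeration agreement to 1e-12 verified for all
  contingency tables with N ≤ 12.
* BH via the standard step-up; verified against a quadratic-time
  implementation of the definition.
* Eigengap on a dense symmetric eigendecomposition — enriched-term sets
  are small (tens to hundreds), so dense `eigh` is simpler and exact.
* Medoid and label tie-breaks always resolve to the smallest term id;
  similarity values within 1e-12 are treated as tied.
* Degenerate inputs: a single enriched term gets coordinates (0.5, 0.5);
  an all-equal distance matrix keeps the deterministic classical-MDS
  solution; empty enrichment lists export valid empty JSON/CSV.

## Known limitations

* One-sided over-representation only; no depletion test.
* No gene-identifier mapping: symbols in the target must match GAF
  column 3 (a case-insensitive fallback flag exists).
* Lin and AIC only; no Resnik/Jiang–Conrath/Wang, no gene-level
  best-match-average similarity.
* The eigengap is a heuristic: for affinities without block structure
  (e.g. AIC matrices dominated by shared shallow ancestry) it often
  returns k = 1; supplying `--clusters` is the intended recourse.
* MDS stress is not reported; for strongly non-Euclidean distance
  matrices the 2D embedding is a best-effort summary.
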