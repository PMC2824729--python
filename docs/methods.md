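# Methods

## Model

The prioritization treats disease relevance as a property of a gene's
*domain neighborhood* rather than of the gene itself.  The assumptions, in
order of load-bearing:

1. Protein–protein interactions are mediated by domain–domain contacts, so
   a domain interaction network (nodes: Pfam families; edges: predicted
   domain interactions above a confidence cutoff) is a usable proxy for
   the protein interactome with far better coverage.
2. Disease genes are functionally related to other disease evidence: a
   candidate whose domain's interaction partners are enriched in
   disease-variant domains (class a), disease-process domains (class b),
   domains of proteins in linked regions (class c) and domains of known
   disease proteins (class d) is a better candidate.
3. Disease genes sit in the network periphery: among high-scoring
   candidates, those whose domain has a low local clustering coefficient
   are retained.

### Scoring

For parent domain D_i with partners D_j (j = 1…N, the *distinct* network
neighbors — multiple interaction records for one pair count once):

    raw(D_i) = Σ_j (a_j + b_j + c_j + d_j),
    a_j = D_ja/T_a,  b_j = D_jb/T_b,  c_j = P_jc/T_c,  d_j = P_jd/T_d,

where each indicator is 0/1 (binary scoring; classes c and d fire when
*any* protein harboring D_j qualifies — a logical OR; a count-weighted
variant exists behind a flag but is off by default, since the binary
system is part of the method's definition).  The aggregation over
partners is the sum by default, with a per-partner mean available
(`aggregation="mean"`); the sum rewards well-connected disease
neighborhoods, which is the behavior the downstream threshold expects.

Raw weights are normalized across the run's parent domains by min–max
(`normalization="minmax"`), mapping the run's minimum to 0 and maximum to
1 — the published score tables contain both exact endpoints, which is the
signature of min–max.  Division by the maximum alone is available as
`"maxscale"`.  If all raw weights coincide there is no ranking
information: everything is set to 0 with a warning rather than inventing
an ordering.

A protein is assigned the *maximum* normalized Wv over its domains; ties
break toward the domain with the lower clustering coefficient (the
quantity the next stage filters on), then lexicographically, so output is
deterministic.  Proteins with no mapped domain are excluded and counted,
mirroring the attrition from annotation-poor candidates in real runs.

### Thresholds

- HWE: normalized Wv **> 0.5**, strict.  A candidate at exactly 0.5 is
  not an HWE.
- HWEc: additionally C_i **< 0.015**, strict.  A C_i of 0.016 fails.  The
  0.015 default derives from the observed average clustering coefficient
  of disease genes in published interactome analyses; it is a
  configurable parameter, not a constant.

Both strictness choices are confirmed by the packaged 19-gene benchmark
table, where a gene at C_i = 0.016 is not prioritized.

### Network quantities

- Degree-0/1 nodes carry C_i = 0 (not NaN, not excluded): every HWE must
  be comparable against the cutoff, and peripheral singleton domains are
  exactly the candidates the filter is meant to keep.
- The characteristic path length is the mean BFS distance over connected
  pairs of the largest component; disconnected pairs are excluded rather
  than set to infinity so the summary stays finite on fragmented networks.
- Self-interactions are dropped at ingest (they distort C_i), and
  duplicate or reversed edges merge keeping the maximum confidence.
- The confidence cutoff defaults to 10, the standard threshold for
  InterDom-style predicted interactions.

### Benchmarking

Sensitivity, specificity and accuracy come from the confusion matrix of a
predicted-positive set against disjoint disease/control label sets.  The
ROC is the empirical threshold sweep over distinct score values (ties
grouped into one step, so the curve is order-independent), AUC by the
trapezoid rule — equal to the Mann–Whitney concordant-pair probability,
which the tests verify by brute force.  Fold enrichment defaults to the
density ratio (disease-gene density among predictions over the background
density ΣDG/ΣG), which is 1 in expectation for a label-blind predictor;
the literal "proportion of disease genes predicted" reading (equivalent
to sensitivity) is available via `definition="sensitivity"` because the
verbal definition of the ratio admits both readings.

### Motifs

Connected 3-/4-node induced subgraphs are enumerated with the ESU
algorithm and grouped by isomorphism class (canonical form by brute-force
minimization over ≤ 4! orderings).  The null model is degree-preserving
double-edge-swap rewiring, 10 successful swaps per edge by default;
proposals creating self-loops or parallel edges are rejected and redrawn.
Significance is one-sided over-representation with the add-one empirical
p-value (1 + #{null ≥ real}) / (iterations + 1), so p is never exactly 0
and a motif absent from the real network trivially gets p = 1; the
default is 1000 iterations at α = 0.01.  Only over-representation is
tested — the use case is recurring functional modules, not motif
avoidance.  Function prediction labels the members of significant-class
instances with their Pfam2GO biological processes and proposes the
majority process for unlabeled members (ties report all tied labels).

## Synthetic worlds

`generate_world` emits a complete, self-consistent input bundle:

- a heterogeneous-degree random background graph (gamma-distributed
  expected degrees, target mean 6.5 — a realistic figure for curated
  domain interaction networks) with uniform(0, 50] confidence scores, so
  about 20% of edges fall below the cutoff and the filter is exercised;
- `n_planted` candidates (default 10 of 500) whose unique parent domains
  are wired to an evidence pool of 8 domains that are members of all four
  classes, with those structural edges kept above the confidence cutoff;
- class catalogs at roughly one fifth of the published totals
  (T_a/T_b/T_c/T_d = 12/3/13/349), padded with catalog-only identifiers —
  public catalogs legitimately cover a larger universe than one run's
  candidates, and the loaders must tolerate that;
- a low-level background signal (a few background domains in class a,
  ~5% of background genes inside linked regions, 30 background proteins
  in class d) so unplanted worlds still produce a non-degenerate Wv
  distribution.

What passing on these worlds shows: the pipeline's plumbing, the exact
arithmetic of scoring/normalization/thresholds, and that planted signal
of the designed strength is recovered.  What it does not show: behavior
under the noise, redundancy and ascertainment bias of real interaction
databases — the planted evidence is cleanly separable by construction,
so recovery here is a correctness check, not a power estimate.  Real
network topology (k ≈ 6.5, mean C_i ≈ 0.17, path length ≈ 4.5 at full
scale) depends on the specific interaction database snapshot and is not
reproduced at desk scale.

Identical config + seed gives byte-identical files; all randomness flows
through one `numpy` generator.

## Problem sizes and numerical choices

Desk-scale defaults keep every check fast: 500-candidate worlds (scoring
a world takes ~1 s), motif nulls at 200 iterations in tests (the
production default stays 1000), clustering-coefficient oracles exhaustive
through 5 nodes and sampled at 6.  Floats in TSV output print with 6
significant digits; report tables round percentages to one decimal.
Empty networks are errors for summaries but warnings for construction
(a cutoff that filters everything is a user-visible data property, not a
crash).  The all-equal-scores and no-partner cases degrade to zeros with
warnings rather than NaNs.

## Known limitations

- Min–max normalization makes Wv relative to the run: adding or removing
  candidates rescales everyone's score, so Wv values are comparable
  within a run only.
- The class catalogs are treated as ground truth; no weighting or
  calibration across classes is attempted (class b's small total makes a
  single process hit worth 1/3 under the scaled defaults — the reciprocal
  weighting is inherent to the method).
- The empirical ROC is reported as-is; no parametric (binormal) fit or
  confidence bands.
- Motif sizes stop at 4; exhaustive canonicalization does not scale past
  that, and larger motifs would need a proper canonical labeling
  algorithm.
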