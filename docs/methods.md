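# Methods

## The analysis

`gnossn` implements a genome-neighbourhood sequence-similarity-network
analysis for a "hub" enzyme family — the workflow used to characterise the
gene neighbourhoods of bacterial levoglucosan dehydrogenase (LgdA) homologs
and the co-occurrence of the pathway enzymes (LgdB1/B2/B3/B4, LgdC) encoded
around them.  Five stages:

1. **Two-stage homolog retrieval.**  A pairwise Smith–Waterman scan of the
   protein database with the query at an E-value cutoff; the hits are
   stacked into a query-anchored position-specific scoring matrix (PSSM, a
   star alignment: subject insertions relative to the query are discarded);
   the PSSM is calibrated empirically and re-searched against the database
   at a stricter cutoff.  This mirrors the phmmer → HMM → hmmsearch → filter
   chain of web-server practice.  The PSSM with extreme-value calibration is
   a deliberate simplification of a full profile HMM: the procedure needs "a
   profile built from first-pass hits, re-searched with an E-value
   threshold", and a calibrated PSSM has the same selectivity behaviour at
   desk scale.  It does not model insert/delete states, so gappy families
   will score lower than HMMER would score them.

2. **SSN construction.**  All-vs-all Smith–Waterman over the homolog set;
   an edge joins two proteins when the *alignment score* — defined as
   −log10 of the Karlin–Altschul E-value, E = K·m·n·exp(−λS) — meets the
   threshold.  Clusters are connected components (the "isofunctional
   cluster" semantics of EFI-EST; no community detection), numbered 1..C by
   decreasing size with ties broken by the lexicographically smallest member
   ID.  Isolated nodes are retained and numbered after all multi-node
   clusters, so presence/absence analyses see every hub.  A threshold sweep
   reports the guaranteed refinement between a coarse and a fine partition.

3. **Neighbourhood extraction.**  The ±N ORF window around each hub gene,
   counted in gene rank on the hub's contig (strand-agnostic, CDS only, not
   base pairs), clipped at contig ends with explicit truncation flags.

4. **SSNN and co-occurrence.**  The pooled, deduplicated neighbour proteins
   are clustered into an SSN of neighbours at a lower threshold.  Tracked
   clusters (selected by number or by majority functional label) are mapped
   back onto hubs as a binary presence matrix — a hub is positive for a
   cluster iff at least one gene in its window belongs to it — from which
   pairwise co-occurrence statistics (Jaccard, mutual exclusivity, nesting)
   and Venn region counts for up to three sets follow.  Presence is binary
   because it mirrors node-colouring semantics; raw counts are written to
   the TSV for transparency.

5. **Export.**  GraphML (Cytoscape-loadable) with cluster numbers, taxonomy
   and presence flags on nodes and alignment score / percent identity on
   edges; TSV tables; a JSON run report with a checksummed manifest.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_stage1` | 1e-130 | E-value cutoff of the pairwise query scan |
| `evalue_stage2` | 1e-200 | E-value cutoff after the profile re-search |
| `ssn_threshold_primary` | 120 | SSN edge threshold, −log10 E |
| `ssn_threshold_fine` | 170 | fine SSN threshold (taxonomy-level subclusters) |
| `ssnn_threshold` | 50 | SSN-of-neighbours edge threshold |
| `window_orfs` | 10 | neighbourhood half-width, in ORF ranks |
| `gap_open`, `gap_extend` | 11, 1 | affine gap costs (length-k gap: 11 + k) |
| `lambda_ka`, `k_ka` | 0.267, 0.041 | Karlin–Altschul parameters, gapped BLOSUM62 |
| `n_shuffles` | 200 | null sequences for profile calibration |

The defaults are the published values of the workflow this package
re-implements.  They are knobs, not calibrated constants: the E-value scale
of the profile search depends on the empirical Gumbel fit, so on any
particular database the cutoffs should be placed relative to the realised
score distributions (the synthetic scenarios do exactly that and record the
placement in their ledgers).  The published mapping "score 120 ↔ ≥60%
identity, 170 ↔ ≥70% identity" is dataset-dependent and deliberately not
hard-coded; the cluster tables report per-threshold identity instead.

All E-value arithmetic is done in log10 space: 1e-200 underflows a double as
a probability but not as a log.  Percent identity uses the full alignment
length including gap columns as the denominator (conventions differ between
tools; this one is fixed and stated).  Pairwise alignment is canonicalised
by ID order before traceback so every hit field is symmetric under swapping
query and subject.

## Profile calibration

The PSSM (half-bit log-odds against Robinson–Robinson background
frequencies, with a tunable pseudocount weight) is scored against `n_shuffles`
null sequences drawn i.i.d. from the background at the median database
length; the optimal local scores are fitted with a maximum-likelihood Gumbel
(location mu, scale beta).  Per-sequence P-values come from the Gumbel tail
— evaluated as log10, with the asymptotic form −z/ln 10 beyond z = 35 where
the survival function underflows — and are multiplied by the database size
(Bonferroni-style; stated in the run report).  Degenerate null distributions
(all scores equal) are an error rather than a silent beta of zero.

## The synthetic pangenome generator

The generator is first-class, tested code: it produces the statistical
structure the analysis assumes, with a ledger recording what was *realised*
(not targeted), so recovery can be asserted exactly.

* **Mutation model.**  Uniform substitution: each position is independently
  replaced with probability 1 − target identity by one of the 19 other
  residues.  Realised identity is Binomial(L, t)/L — analytically
  predictable, which is why matrix-biased mutation is not the default.  No
  indels: members of a family share its length.
* **Families.**  Independent uniform-random seed sequences put cross-family
  identity at background (~5–10%); divergence is additionally enforced by
  rejection sampling on a length-normalised identity (identities in the
  optimal local alignment divided by the shorter length — raw local percent
  identity is inflated by short high-identity hits between unrelated
  sequences and cannot be bounded at 0.30).
* **Subfamilies / taxonomy.**  Subfamily seeds are mutations of the family
  seed at the family identity; members are mutations of their subfamily seed
  at the (higher) subfamily identity.  Each genome's taxon label is its hub
  subfamily, so "subclusters align with taxonomy" is true by construction
  and testable.
* **Genomes.**  One contig per genome; the hub at a uniform position; one
  fresh member of each present neighbour family planted at a distinct ORF
  offset within ±N *and within the contig* — so the ledger presence table is
  exactly what a correct window extraction sees, checked at emit time.
  Filler ("decoy") genes are drawn from a finite pool of perfectly conserved
  sequences, emulating conserved housekeeping genes shared across strains;
  this also lets the all-vs-all stage deduplicate identical sequences, which
  is what keeps a 200-genome SSNN tractable on one core.
* **Co-occurrence rules.**  Per family: marginal presence probability,
  optional `requires`/`excludes` constraints, and an exception rate at which
  violations are planted anyway.  The paper-like scenario instead plants
  *exactly one* forced exception (one genome with B3 but no B1),
  deterministically from the seed: with 200 genomes a small per-genome
  exception rate realises zero exceptions more often than one, and the
  single-exception pattern is the structure of interest.

### Scenario identity choices

The hub family uses seed identity 0.85 with subfamily identity 0.95 at
length 350.  Members then sit at ~90% pairwise identity within a subfamily
(alignment score ≈ 200) and ~65% across subfamilies (score ≈ 125–150), so
the published thresholds land inside the gaps: 120 below essentially all
within-family scores, 170 between the cross-subfamily tail and the
within-subfamily floor.  This mirrors the published score-to-identity
anchors (120 ↔ ≥60%, 170 ↔ ≥70%): cross-subfamily pairs are below the 70%
mark, within-subfamily pairs far above it.  Neighbour families use within
identity 0.85 at lengths 220–360 (the two isomerase-like families are set
near 275 aa and 325 aa, the length difference that distinguishes them in
the real data), giving SSNN edge scores ≈ 100–120 against a threshold of
50, with cross-family scores near 0.

Scenario sizes — minimal: 2 families × 10 genomes (smoke/determinism);
hierarchy: 36 genomes, 3 hub subfamilies; paper-like: 200 genomes, 7
neighbour families plus 100 decoy sequences (~5,400 proteins, ~3,300
window members).  These sizes keep a full paper-like run at a few minutes
on one core while leaving thousands of presence cells to compare.

## What passing tests do and do not show

The generator omits real-data features on purpose: no indels or length
variation within a family, no domain shuffling or partial homology, no
compositional bias, no operon structure or intergenic-distance signal, no
horizontal transfer or phylogenetic correlation between genomes (every
genome is an independent draw).  Exact recovery on generated data therefore
demonstrates that the machinery is correct *in the regime the data were
constructed for* — separable families, dense ORF windows — not that the
published counts from a live UniProt snapshot are reproducible: those
(379 → 265 homologs, 4877 neighbours, 253/57/71/151-of-265 presence counts)
depend on the database snapshot and are out of desk-scale reach by design.

## Numerical and degenerate-input choices

* Gene-order ties (equal start) break by ascending end then protein ID;
  runs are byte-reproducible under a fixed seed, including GraphML node and
  edge order.
* A local alignment with no positive-scoring residue pair has raw score 0
  and an empty alignment (length 0, identity 0) rather than an error.
* Hubs without genomic coordinates are skipped from windowing with a
  warning, not an error, so sequence-only databases flow through the SSN
  stages.
* "Mutually exclusive" requires both sets nonempty; an empty presence
  column raises no vacuous flags.  Implications are reported as exception
  counts (|X \ Y|), with the flag holding at zero.
* The profile re-search runs at the stage-1 cutoff and then filters to the
  stage-2 cutoff; the profile pass may legitimately retrieve more sequences
  than the pairwise pass, and the report exposes both counts.
* E-value cutoff comparisons use ≤ (a hit exactly at the cutoff is kept).

## Known limitations

* The PSSM profile ignores indel structure; families with large insertions
  relative to the query lose signal at inserted positions.
* Karlin–Altschul parameters are fixed gapped-BLOSUM62 values, not
  estimated per composition; alignment scores are therefore comparable
  within a run but not calibrated against any specific BLAST build.
* Connected-component clustering is threshold-brittle around the chosen
  score by nature; the threshold sweep and per-cluster identity summaries
  are the intended diagnostic.
* The all-vs-all stage is exact (no k-mer prescreen); very large neighbour
  sets with few duplicate sequences will be slow.  An optional length-ratio
  skip (`length_ratio_min`) is available and off by default.
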