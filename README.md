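# gnossn — genome-neighbourhood SSN analysis

`gnossn` answers a question that comes up whenever a newly characterised
enzyme anchors an uncharacterised pathway: **which other protein families
are encoded around the homologs of this gene, and how do they co-occur?**
It was built for the levoglucosan-degradation setting — bacterial
levoglucosan dehydrogenase (LgdA) homologs whose neighbourhoods encode the
pathway enzymes LgdB1/B2/B3/B4 and LgdC in characteristic, mutually
constrained combinations — but the machinery is generic: any hub family,
any annotated genomes.

The workflow, for microbial genomicists and enzyme hunters:

1. **Two-stage homolog retrieval** — pairwise Smith–Waterman scan of a
   protein database with the query, then a position-specific profile built
   from the first-pass hits, calibrated empirically and re-searched at a
   stricter E-value cutoff.
2. **Sequence similarity network (SSN)** — all-vs-all local alignment over
   the homolog set; nodes are proteins, an edge joins two proteins when the
   *alignment score* meets a threshold; clusters are connected components,
   numbered by decreasing size.
3. **Genome neighbourhoods** — the ±N open reading frames (by gene rank,
   strand-agnostic, clipped at contig ends) around every hub gene.
4. **SSN of neighbours (SSNN)** — the pooled neighbour proteins clustered at
   a lower threshold; selected clusters are mapped back onto each hub as a
   binary presence matrix, from which co-occurrence statistics and Venn
   region counts follow (e.g. "B2 always co-occurs with B1 but never with
   B3").
5. **A synthetic pangenome generator** that plants homology, taxonomy and
   co-occurrence structure with a ground-truth ledger, so the entire
   analysis is testable end to end without downloading anything.

## The score model

Edges are thresholded on the EFI-style alignment score

    alignment_score = −log10 E,   E = K · m · n · exp(−λ S)

where S is the optimal Smith–Waterman score (BLOSUM62, affine gaps: a gap of
length k costs 11 + k by default), m and n are the sequence lengths and
(λ, K) = (0.267, 0.041) are the standard gapped Karlin–Altschul parameters.
Everything is computed in log10 space, so E-values far below the float
underflow limit (the stage-2 default cutoff is 1e-200) remain exact.
Percent identity is counted over all alignment columns, gaps included.

The profile stage scores a query-anchored PSSM (half-bit log-odds) against
each sequence with position-specific Smith–Waterman; its E-values come from
a maximum-likelihood Gumbel fit to the profile's optimal scores on shuffled
null sequences, times the database size.

## Worked example

Generate a small synthetic scenario, run the whole pipeline, and check the
result against the planted ground truth:

```
$ gnossn generate --scenario minimal --seed 1 --out data
scenario 'minimal' written to data

$ gnossn run-all --run-dir data --out results
report -> results/report.json
stage counts: 10 homologs, 14 SSNN clusters

$ gnossn compare --out results --ledger data/ledger.json
PASS: 0/10 presence cells mismatched; venn_match=True
```

What those numbers mean: the scenario planted 10 genomes (69 proteins), each
carrying one hub gene; the two-stage search retrieved all 10 hub homologs
and nothing else (`stage1_hits 10`, `stage2_final 10` in the report); the 10
hubs form a single SSN cluster; their ±10-ORF windows pool 59 neighbour
proteins that cluster into 14 SSNN clusters.  The tracked neighbour family
was planted in 8 of the 10 neighbourhoods, and the pipeline's presence
matrix and Venn regions reproduce the ledger exactly:

```
# results/venn.json (excerpt)
"regions": { "lgdB1": 8, "none": 2 }

# results/ssnn_clusters.tsv (first rows)
cluster  size  majority_label                      majority_fraction  median_length
1        8     3-keto-levoglucosan beta-eliminase  1.0                200.0
2        7     hypothetical protein                1.0                180.0
```

The richer built-in scenarios are `hierarchy` (a hub family whose fine-
threshold subclusters align exactly with a planted taxonomy) and
`paper-like` (200 genomes, seven neighbour families with implication and
exclusion rules, including exactly one planted rule exception).

The same stages are available individually (`gnossn search`, `gnossn ssn`,
`gnossn neighborhood`) and as library functions (`gnossn.two_stage_search`,
`gnossn.build_ssn`, `gnossn.extract_window`, ...).

## File formats

Inputs: protein FASTA; GFF3 with CDS features (attribute `protein_id` or
`ID` matching the FASTA); YAML run configuration.  Outputs: GraphML networks
loadable in Cytoscape (cluster numbers, taxonomy and presence flags on
nodes; alignment score and percent identity on edges), TSV tables, and a
JSON run report with a checksummed manifest.

Pairwise hits stream to a BLAST-tabular-like TSV with columns
`query  subject  raw_score  evalue_log10  alignment_score  pct_identity
aln_length`, where `alignment_score = −evalue_log10` and `pct_identity`
uses the full alignment length (gap columns included) as denominator.

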