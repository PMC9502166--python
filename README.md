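# efam-forge

A pipeline for building annotated profile-HMM databases of viral protein
families from metagenomic viral contigs. It covers the full workflow:

1. **Contig selection** (`contig_select`) — tiered consensus over three
   viral prediction tools at their strictest cut-offs (category 1 for the
   category-based tool; score > 0.9 and p < 0.05 for the score/p-value
   tool; score > 0.90 for the probability tool), with topology-aware
   length filtering (≥5 kb linear, ≥1.5 kb circular) and excision of
   host-typed contamination regions. Contigs called by all three tools
   form the extremely-conservative (XC) tier; at least two tools, the
   conservative tier.
2. **Protein decontamination** (`protein_filter`) — removal of proteins
   with any >95%-identity hit against a prokaryotic reference (no
   coverage requirement, all hits considered) unless every such hit
   carries a virus-related annotation keyword; dereplication at 100%
   identity.
3. **Family clustering** (`family_graph`) — all-vs-all hits filtered at
   e-value ≤ 1e-5, ≥70% mutual coverage, ≥50 aa, transformed to
   `min(-log10 E, 200)` edge weights, then clustered with either a
   cohesiveness-greedy grower (overlapping clusters, ClusterONE-style)
   or native Markov clustering (inflation 2.0), minimum cluster size 2.
4. **Profile HMMs** (`profile_hmm`) — per-cluster multiple alignment
   (builtin deterministic center-star aligner, or external MUSCLE),
   match-column assignment at symfrac 0.5, Laplace-smoothed
   emissions/transitions, global Viterbi scoring, and HMMER3-style ASCII
   flat-file serialization.
5. **Annotation consolidation** (`annotate_consolidate`) — per-cluster
   collapse of four-database annotations into detailed and consensus
   views, informative/structural keyword classification, and
   annotated-vs-unannotated cluster-size statistics (Mann–Whitney U).
6. **Metaproteomic mapping** (`metaproteome_map`) — per-search decoy-FDR
   thresholding of PSMs at 1%, exact-substring peptide-to-protein
   mapping (I/L equivalent), and virion-associated cluster annotation
   with de-novo and concordance statistics.
7. **Benchmarking** (`benchmark_report`) — baseline-vs-augmented
   detection comparisons: per-sample gains, length-binned gains,
   confidence-category transition tables, and secondary-tool validation
   fractions.
8. **Synthetic fixtures** (`synth_fixtures`) — seeded generators with
   planted families, contaminants, detection gains and PSM score
   distributions, so the whole pipeline is testable without external
   data or binaries.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes independent oracles (pure-python long-horizon Markov
flow simulation, brute-force Viterbi path enumeration, brute-force
peptide substring scan, pair-enumeration ARI, exact Mann–Whitney
enumeration) and hypothesis property tests.

## CLI

```bash
efam-forge fixtures --seed 1 --out fx/                       # synthetic inputs
efam-forge select --contigs contigs.fasta --scores scores.tsv \
    [--regions regions.tsv] --tier both --out sel/
efam-forge filter-proteins --proteins prot.fasta --ref-hits ref.tsv \
    --out kept.fasta --removed-report removed.tsv
efam-forge cluster --hits all_vs_all.tsv --algorithm both --out clus/
efam-forge build-hmms --clusters clus/clusters_mcl.tsv \
    --proteins kept.fasta --out efam.hmm [--backend builtin|external]
efam-forge annotate --records dram.tsv --clusters clusters.tsv --out ann.tsv
efam-forge virion-map --psms psms.tsv --proteins kept.fasta \
    --clusters clusters.tsv --out virion/
efam-forge benchmark --baseline base.tsv --augmented aug.tsv --out bench/
```

File dialects: FASTA for sequences (topology via sidecar TSV or a
`circular=true` header token; gene-caller `# start # end # strand`
headers parsed when present); BLAST tabular (12 columns, 13th
subject-annotation column for reference searches); TSVs for scores,
regions, clusters, annotations, PSMs and detection runs. Contamination
region coordinates are 1-based inclusive.

## Notes

- Profile construction uses unweighted counts with Laplace pseudocounts
  (no Henikoff weighting or Dirichlet mixtures) and omits E-value
  calibration; the external-aligner adapter lets users regenerate
  profiles with standard tooling if installed.
- Binary profile pressing is out of scope; the flat file is ASCII.
- Structural-keyword matching uses word boundaries for short ambiguous
  tokens (`mu`, `gp9`, ...); pass `word_boundaries=False` for plain
  substring semantics.
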