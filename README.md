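# ppinet

Predict, filter and analyze protein–protein interaction (PPI) networks
for a target species from reference-organism evidence.

Two complementary prediction routes generate candidate interactions:

* **Ortholog transfer (interologs)** — a pair of target proteins is a
  candidate when their orthologs interact in a reference organism.
  Raw ortholog scores are normalized by a cap (default 4600) and the
  pair score is the sum over supporting organisms of the two normalized
  scores' product; pairs scoring ≥ 0.15 are kept.
* **Domain combinations (dc-pairs)** — every pair of nonempty domain
  subsets of an interacting reference pair is a *dc-pair* scored
  `1/((2^m−1)(2^n−1))`; the per-dc-pair maximum over all reference
  interactions forms a score table, and a target pair scores the sum of
  its rated dc-pairs times the rated/all ratio.

Merged candidates are validated by **five independently trained KNN
classifiers** (balanced positive/negative training groups built from
reference interactions); candidates supported by at least two
classifiers form the final network. Analysis modules cover network
topology (degree, betweenness, clustering, log–log power-law fit,
degree-preserving rewiring), ontology-distance quality assessment,
expression statistics (RPKM, the per-gene expression difference of
interactors *EDI* and its cross-tissue variation, stratified
distributions, a node-removal robustness sweep), and a from-scratch
Markov clustering (MCL) implementation with reference-complex mapping.

A fully seeded synthetic-universe generator (`ppinet.synthetic`)
produces every input format with known ground truth, so the whole
pipeline is testable offline.

## Command line

```sh
# generate a synthetic universe (all pipeline input files)
ppinet simulate --seed 42 --n-proteins 200 --n-domains 60 --out universe/

# individual stages
ppinet predict-ortho  --ortho-table universe/ortholog_table.tsv \
                      --ref-ppi-dir universe/ref_ppis --out ortho.tsv
ppinet predict-domain --domtblout-dir universe/ \
                      --ref-domtblout-dir universe/ref_domtblout \
                      --ref-ppi-dir universe/ref_ppis --out domain.tsv
ppinet merge --ortho ortho.tsv --domain domain.tsv --out merged.tsv
ppinet topology --network network.tsv --report nodes.tsv --random-cc
ppinet go-validate --network network.tsv --obo universe/ontology.obo \
                   --annotations universe/annotations.tsv --out go.json
ppinet edi --network network.tsv --expression universe/expression.tsv --out edi.tsv
ppinet edi-removal --network network.tsv --expression universe/expression.tsv \
                   --thresholds 10:100:1 --seed 1 --out sweep.tsv
ppinet mcl --network network.tsv --out clusters.tsv
ppinet map-complexes --complexes universe/ref_complexes.tsv \
                     --best-hits universe/best_hits.tsv --out mapped.tsv

# everything at once (simulates its own inputs unless input_dir is set)
ppinet run-all --seed 42 --outdir run/
```

`run-all` accepts a YAML config (`--config config.yaml`) whose keys
mirror `ppinet.pipeline.PipelineConfig`; unknown keys are rejected and
the resolved config plus input checksums are written to
`run/manifest.json`. Runs are byte-for-byte reproducible for a fixed
seed.

## Layout

| module | purpose |
| --- | --- |
| `ppinet.io_formats` | readers/writers: ortholog TSV, HMMER3 domtblout, edge lists, SIF, OBO 1.2, annotations, expression, complexes |
| `ppinet.synthetic` | seeded synthetic universe with planted ground truth |
| `ppinet.interolog` | ortholog score normalization and interolog prediction |
| `ppinet.domains` | domain-hit filtering, dc-pair scoring and prediction |
| `ppinet.knn_filter` | pair features, balanced training splits, KNN voting |
| `ppinet.topology` | degree/BC/CC, power-law fit, rewiring, paths, sub-networks |
| `ppinet.go_validation` | ontology shortest-distance quality assessment |
| `ppinet.expression` | RPKM, EDI, EDI variation, distributions, removal sweep |
| `ppinet.mcl` | Markov clustering and reference-complex mapping |
| `ppinet.pipeline` / `ppinet.cli` | configuration, orchestration, CLI |
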