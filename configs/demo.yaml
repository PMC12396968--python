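# Demo pipeline: a small synthetic atlas end-to-end on one CPU.
seed: 0
outdir: atlas_demo
stages:
  - simulate
  - qc
  - pseudobulk_de
  - gene_clusters
  - factors
  - composition
  - deg_similarity
  - cf_modules
  - clonality
atlas:
  n_donors: 8
  n_genes: 260
  genes_per_program: 8
  cells_per_sample: 50
  tissue_groups: [BLO, LN, JEJ]
  tissue_programs: {trm_gut: JEJ}
  lineages:
    T: [cd4, cd8]
    B: [b_naive]
  doublet_rate: 0.03
  erythrocyte_rate: 0.02
  adt_markers: [CD69, CD103, CD95]
effect:
  n_cells: 800
  n_genes: 200
n_gene_clusters: 3
consensus_k_range: [3, 5]
de_lineage: T
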