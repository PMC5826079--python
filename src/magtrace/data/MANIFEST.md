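# Bundled example dataset

Text-encoded inputs for the worked examples and the reconciliation demo.

- `bin_quality.tsv` — quality statistics for 10 hot-spring metagenome bins and
  one cultured isolate (`Kouleothrix_aurantiaca`): coding-sequence counts with
  completeness, contamination and strain-heterogeneity percentages.
- `marker_matrix.tsv` — presence/absence of 11 organismal and metabolic
  markers per bin. Cells starting with `+` are present; parenthetical notes
  annotate reaction-center gene fusion state or copy number; the
  denitrification column lists recovered gene names instead of `+`.
- `organismal.nwk` — rooted organismal cladogram (outgroup:
  Dehalococcoidetes). Only clades supported by explicit statements in the
  source dataset descriptions are resolved; unstated relationships are left
  as polytomies. `JP1_191` is omitted (too incomplete to place).
- `rc_gene_variant_a.nwk` / `rc_gene_variant_b.nwk` — rooted reaction-center
  gene tree on the five phototrophic lineages. The two variants encode the
  two alternative placements of CP2_42A: (a) between Kouleothrix and
  Roseiflexus, i.e. sister to Roseiflexus; (b) basal to the
  Kouleothrix+Roseiflexus clade. Downstream inferences (two transfers, one
  fusion gain) are identical for both.
- `fusion_states.tsv` — reaction-center gene fusion character (1 = fused) for
  the gene-tree leaves. The matrix row for JP3_7 (`+ (unfused)`) is taken as
  authoritative where prose descriptions conflict.
- `phototrophs.txt` — leaves carrying a Type 2 reaction center; equals the
  gene-tree leaf set.
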