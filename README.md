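# regioprot

A tested, reusable pipeline for regional GeLC-MS/MS proteome analysis:

1. **PSM screening** — keep peptide-spectrum matches whose search-engine
   ion score strictly exceeds its per-spectrum significance threshold
   (p < 0.05) and whose matched b+y fragment-ion count exceeds 3
   (a per-series variant is available via `--ion-rule per_series`).
2. **Peptide de-duplication** — one record per (sequence, modifications)
   key, best score kept.
3. **Parsimonious protein inference** — each peptide is assigned to the
   single candidate protein with the maximal number of peptide
   assignments; ties go to the lexicographically smallest accession.
   Protein scores are cutoff-subtracted: sum of (ion score − threshold)
   over assigned peptides. Single-peptide proteins are flagged.
4. **Region comparison** — protein × region (× replicate) score matrix,
   per-region detected and region-unique calls, one-way ANOVA across
   regions with Bonferroni-corrected pairwise t tests.
5. **Localization summary** — primary-compartment classification onto a
   fixed vocabulary (membrane, cytoplasm, mitochondrion, cytoskeleton,
   nucleus, extracellular region, other, ND) with percentage breakdown.
6. **Enrichment** — one-sided Fisher's exact over-representation of
   protein lists against GMT gene-set collections.
7. **Synthetic data** — a ground-truth generator emulating the design
   (six regions × replicates × 24 gel slices, Mascot-like scores above a
   threshold of 40, molecular-weight slice bins, shared peptides between
   homolog pairs, sub-threshold noise) so every stage is testable
   without external data.

## CLI

```bash
# generate a synthetic dataset (PSM CSVs, FASTA, truth JSON, annotations)
regioprot generate --out data/ --seed 1 [--config design.yaml]

# protein inference on one per-(region, replicate) PSM table
regioprot infer --psm data/psms_thalamus_rat1.csv --out report.tsv

# full region landscape from a directory of PSM tables
regioprot compare --psm-dir data/ --out results/ --min-replicates 1

# compartment breakdown / gene-set enrichment
regioprot localize --proteins proteins.txt --annotations ann.tsv --out loc.tsv
regioprot enrich --query query.txt --gmt sets.gmt --universe universe.txt --out enr.tsv

# everything, end to end, on synthetic data
regioprot run-all --out run/ --seed 1
```

The design YAML may override any `SyntheticDesign` field
(`n_proteins`, `n_replicates`, `unique_fraction`, `noise_rate`,
`detect_prob`, `shared_peptide_rate`, ...). Every run writes
`run_log.json` with the filter rule, tolerances, seed and input digests.

## File dialects

* **PSM CSV** (RFC-4180, exact header):
  `region,replicate_id,slice_index,spectrum_id,peptide_sequence,modifications,charge,precursor_mz,ion_score,threshold_score,n_b_matched,n_y_matched,candidate_accessions`
  — modifications as `pos:Name` joined by `;`
  (Oxidation on M, Carbamidomethyl/Propionamide on C), candidate
  accessions semicolon-separated.
* **Annotations TSV**: `accession<TAB>localization` with a
  semicolon-separated, order-preserving compartment list (first label =
  primary compartment; empty = `ND`).
* **Protein summary TSV** (for re-counting a published protein table):
  `accession`, `gene_symbol`, `localization`, then one
  `<region>_peptides` integer column per region (peptides assigned to
  the protein in that region; 0 = not detected).

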