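# roicrosstalk

Analysis toolkit for compartment-labelled region-of-interest (ROI)
transcriptomics, as produced by segmented digital spatial profiling of tissue
microarrays. Each tissue core contributes up to three ROIs — tumour, stroma
and immune-infiltrated tumour — and the core is the adjacency unit that pairs
a "sender" region with a "receiver" region.

The centrepiece is a paired sender→receiver **ligand-activity statistic**:
for every ligand in a weighted ligand→target prior, the ligand's expression
across sender profiles is Pearson-correlated with each prior target's
expression across the paired receiver profiles; the mean of those per-target
correlations is the ligand's activity, and a ligand is called actively
signalling when activity ≥ 0.2.

Around that sit the supporting stages:

| module | what it does |
| --- | --- |
| `core_model` | typed, validated readers/writers for all TSV/MTX artifacts |
| `qc_norm` | ROI QC (raw reads ≥ 1000, saturation > 50 %, aligned/trimmed/stitched > 80 %, ≥ 10 % genes detected), gene detection filter (> 10 % of ROIs), Q3 normalization anchored to the geometric mean of per-ROI third quartiles, log2 transform |
| `diffexp` | empirical-Bayes moderated t (method-of-moments prior fit), Benjamini–Hochberg adjustment, hypergeometric over-representation |
| `deconv` | cell-type proportions per ROI by non-negative least squares against a signature matrix |
| `crosstalk` | core pairing, prior restriction, ligand activity, ligand–cell-type origin correlation, permutation-null calibration |
| `netpath` | max-product ligand→target path through a layered weighted network (first hop must be a ligand–receptor edge) |
| `subtype` | Pearson nearest-centroid molecular subtyping with an "undefined" class |
| `synthdata` | seeded synthetic datasets with planted ground truth for every stage |
| `pipeline` / `cli` | end-to-end orchestration with a JSON run manifest |

## Command line

```sh
# generate a synthetic dataset with ground truth
roicrosstalk simulate --seed 7 --out-dir sim/

# QC + Q3 normalization + log2
roicrosstalk qc --counts sim/counts.tsv --annot sim/annotations.tsv --out-dir qc/

# paired ligand activity, stroma -> tumour
roicrosstalk activity --expr qc/log2.tsv --annot sim/annotations.tsv \
    --prior sim/prior.tsv --sender stroma --receiver tumour --out activity.tsv

# other stages
roicrosstalk de --expr qc/log2.tsv --annot sim/annotations.tsv \
    --contrast tumour:stroma --out de.tsv
roicrosstalk deconv --expr qc/normalized.tsv --profiles sim/profiles.tsv \
    --out proportions.tsv
roicrosstalk subtype --expr qc/log2.tsv --centroids sim/centroids.tsv --out calls.tsv
roicrosstalk path --network sim/network.tsv --ligand G0000 --target G0003 --out path.tsv

# everything from one YAML config
roicrosstalk run --config run.yaml
```

`run.yaml` keys mirror `pipeline.RunConfig`: `counts_path`, `annot_path`,
`prior_path`, optional `profiles_path`/`network_path`/`centroids_path`,
`out_dir`, nested `qc` and `crosstalk` parameter blocks, `compartment_pairs`
and `de_contrasts`. Exit codes: 0 success, 2 validation error, 3 stage
failure.

## File formats

All tables are tab-separated UTF-8 with a header row and the gene/ROI
identifier in the first column. Count matrices may alternatively be
MatrixMarket (`matrix.mtx` + `matrix.rows.txt` + `matrix.cols.txt`).
Annotations require `roi_id, core_id, donor_id, compartment, raw_reads,
saturation, pct_aligned, pct_trimmed, pct_stitched` with compartment one of
`tumour | stroma | immune`; priors `ligand, target, weight`; networks
`source, target, weight, layer` with layer one of
`ligand_receptor | signalling | gene_regulatory`.
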