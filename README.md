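# cpidebias

Construction of debiased compound–protein interaction (CPI) datasets.
The package takes a raw activity table (one row per assay record) and
produces a curated, cluster-aware, label-balanced dataset bundle with
time-split training/validation scenarios, plus the diagnostics and
virtual-screening metrics used to validate the debiasing:

1. **Curation** — activity-unit whitelist (pChEMBL-comparable units),
   optional confidence/assay-type filters, drug-likeness rules (no
   metals, MW < 1000 Da, > 12 heavy atoms), frequent-hitter blocklists,
   1000 nM (pChEMBL = 6) binary labeling, duplicate collapsing and
   removal of conflicting (compound, target) pairs.
2. **Clustering** — complexity-stratified sampling of the compound
   pool, a 95 %-variance PCA of fixed-length bit fingerprints and
   seeded k-means; any compound gets a nearest-centroid cluster id.
3. **Down-sampling** — records of multi-target compounds capped at 3
   per (target, cluster), remaining records capped at 3 per
   (target, cluster, label); seeded, order-independent, cap-monotone.
4. **Putative-negative augmentation** — targets whose positives
   outnumber negatives ≥ 2:1 (or with no negatives) receive putative
   negative compounds from chemical clusters with no recorded
   interaction against them; compounds receive putative-negative
   targets from untouched protein families. Quotas come from the
   rectified half sigmoid `α(x) = max(x, (2−2m)/(1+e^(−g(x−1))) + m)`
   (g = 3, m = 0.4) and `quota = max(0, round(α·N_P − N_N))`. Measured
   rows are never touched; putative rows are labeled negative with a
   sentinel year so they can never leak into time-split validation.
5. **Scenario splitting** — per-family cutoff years separate training
   from validation; validation rows are partitioned into the four
   seen/unseen (target × compound-cluster) scenarios.
6. **Metrics** — per-target/per-cluster positive prevalence, BEDROC
   (Truchon–Bayly, α = 80.5 default), enrichment factor at a top
   fraction, top-decile score summaries, and coverage/IoU of
   high-attention residues against binding-pocket masks.

A seeded synthetic-data generator emulates the assumed structure
(planted chemical clusters, six protein families, Beta-skewed
per-target prevalence, duplicate/conflicting records), so the whole
pipeline is testable offline.

## CLI

```bash
# synthetic bundle
cpidebias simulate --seed 7 --n-targets 200 --n-compounds 5000 --out data/

# individual stages
cpidebias curate data/activity.csv --compounds data/compounds.csv --out curated.csv
cpidebias cluster fit data/compounds.csv --k 100 --seed 7 --out model.json
cpidebias cluster assign data/compounds.csv --model model.json --out clusters.csv
cpidebias downsample clustered.csv --cap 3 --seed 7 --out downsampled.csv
cpidebias augment downsampled.csv --clusters clusters.csv --g 3 --m 0.4 \
    --trigger 2.0 --max-per-cluster 3 --seed 7 --out balanced.csv
cpidebias split balanced.csv --cutoff Kinase=2016 --cutoff default=2015 --out splits/

# metrics
cpidebias metrics bedroc screen.csv --alpha 80.5
cpidebias metrics ef screen.csv --fraction 0.01
cpidebias metrics prevalence balanced.csv --by target --out prevalence.csv
cpidebias metrics attention profile.csv

# orchestrated run (YAML config; equals the stage-wise run byte-for-byte)
cpidebias run config.yaml
```

Minimal `config.yaml`:

```yaml
activity_path: data/activity.csv
compounds_path: data/compounds.csv
out_dir: out/
clustering: {K: 100, variance_target: 0.95}
cutoff_year_by_family: {default: 2015}
seed: 7
```

The run writes `curated.csv`, `cluster_model.json`,
`compound_clusters.csv`, `downsampled.csv`, `balanced.csv`, the five
split files plus a count manifest under `splits/`, and a before/after
prevalence report (`report.json`, `prevalence.csv`). All randomness
derives from the single global seed via per-stage hashed sub-seeds.

## Data formats

* raw activity table (CSV): `compound_id, target_id, family,
  activity_unit, value_nM, year, source` (+ optional `smiles,
  assay_type, confidence`); values must be nanomolar.
* compound properties (CSV): `compound_id, mol_weight, heavy_atoms,
  contains_metal, complexity_bits, fingerprint` (fingerprint as a
  fixed-length string of 0/1).
* interactions (CSV): `compound_id, target_id, label, provenance,
  year, family [, cluster_id]`; `provenance` is `measured` or
  `putative`; putative rows carry `year = -1`.
* screens (CSV): `score, label`; attention profiles: `weight, pocket`.
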