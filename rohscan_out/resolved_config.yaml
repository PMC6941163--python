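ped: missing.ped
map: missing.map
quality_table: null
annotation: null
annotation_format: null
out_dir: rohscan_out
min_call_rate: 0.95
gencall_min: 0.7
gentrain_min: 0.4
autosomes_only: true
min_snps: 30
max_gap_bp: 1000000
classes:
- name: 1-2
  lower_mb: 1
  upper_mb: 2
  max_het: 0
  max_missing: 0
  min_snps: 30
- name: 2-4
  lower_mb: 2
  upper_mb: 4
  max_het: 0
  max_missing: 0
  min_snps: 30
- name: 4-8
  lower_mb: 4
  upper_mb: 8
  max_het: 0
  max_missing: 1
  min_snps: 30
- name: 8-16
  lower_mb: 8
  upper_mb: 16
  max_het: 0
  max_missing: 2
  min_snps: 30
- name: 16+
  lower_mb: 16
  upper_mb: .inf
  max_het: 1
  max_missing: 4
  min_snps: 30
calibrate_het_allowances: false
genome_mb: 2510.6
thresholds:
- 1
- 2
- 4
- 8
- 16
top_fraction: 0.01
min_snps_island: 3
group: population
seed: null
rohscan_version: 0.1.0
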