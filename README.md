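# gambi

A pipeline for presence/absence-compatible benthic biotic index assessment:

- **Biotic index** (`gambi.core_index`): abundance-based and presence-based
  index values from station-by-species matrices, using the five-group
  weighted formula (weights 0 / 1.5 / 3 / 4.5 / 6), with quality-class
  binning (unpolluted ... extremely polluted) and the azoic convention
  (value 7).
- **Agreement** (`gambi.agreement`): unweighted Cohen's kappa between two
  pollution-level classifications, per-class percent agreement, and the
  Monserud–Leemans verbal scale.
- **Subset analysis** (`gambi.subset_analysis`): species frequency ranking,
  index recomputation under species subsets (most-frequent x%, sequenced-only,
  random), and significance of the frequent-subset kappa against a
  100-replicate random-subset null (parametric one-sided normal p-value plus
  an empirical companion).
- **Reference library** (`gambi.reference_library`): per-species sequence
  deduplication (greedy longest-first clustering at 0.9 identity) and barcode
  coverage audits per marker and phylum.
- **In-silico PCR** (`gambi.primer_insilico`): degenerate primer pairs scored
  against template windows with position-weighted mismatch penalties
  (0.4 general / 1.0 in the 3' window / 3.0 at the 3' terminus, amplification
  threshold 1.0); testability gating through a reference alignment so partial
  sequences never yield false negatives; per-phylum species coverage
  summaries.
- **Synthetic data** (`gambi.synthetic_data`): seeded community simulation
  along a pollution gradient (long-tailed species frequencies, logistic
  ecological-group response curves) and barcode-library simulation with
  uniform, frequency-biased, or group-skewed coverage.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (index endpoints,
kappa brute-force oracles, resampling-procedure recovery on 20 synthetic
datasets, the coverage-vs-frequency contrast, primer properties, dedup
invariants).

## CLI

```sh
gambi simulate --seed 42 --out sim/                 # synthetic eg.csv, matrix.csv, FASTA, truth.json
gambi ambi --matrix sim/matrix.csv --eg sim/eg.csv --mode presence --out ambi.csv
gambi agreement --a classes_a.csv --b classes_b.csv --out-prefix agr
gambi subsets --matrix sim/matrix.csv --eg sim/eg.csv \
      --fractions 0.10,0.25,0.50 --replicates 100 --seed 42 --out subsets.json
gambi coverage --eg sim/eg.csv --library CO1=sim/co1.fasta --library 18S=sim/18s.fasta
gambi primers --library sim/co1.fasta --primers primers.tsv \
      --reference sim/ref_co1.fasta --out primer_coverage.csv
```

Every command writes a provenance block (version, config hash, seed) next to
its output. FASTA headers follow `>id|species|phylum`; tables are CSV
(TSV auto-detected by extension).

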