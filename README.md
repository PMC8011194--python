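# sgsd

Spatial genetic structure, gene dispersal and mating-system analysis for
georeferenced codominant genotype tables (e.g. diploid microsatellites), plus
the forward simulators used to validate every estimator by parameter recovery.

## What it does

* **Genotype I/O and QC** (`sgsd.genotype_io`) — a documented CSV dialect
  (`sample_id,x,y,group,<locus>_1,<locus>_2,...`) and a SPAGeDi text-format
  importer/exporter, plus a STRUCTURE-format exporter; minimum-typed-loci
  filtering, duplicate detection via shared-allele coefficients, spatial grid
  subsampling, allele frequencies, Euclidean/great-circle distances.
* **Diversity** (`sgsd.diversity`) — He (unbiased), Ho, effective allele
  number, rarefied allelic richness AR(k), and the multilocus inbreeding
  coefficient with a gene-copy permutation test.
* **Differentiation** (`sgsd.differentiation`) — pairwise Weir–Cockerham FST
  and allele-size-based RST through a shared variance-component engine, and
  the allele-size permutation test for a stepwise-mutation (phylogeographic)
  signal.
* **Spatial genetic structure and dispersal** (`sgsd.sgs_dispersal`) —
  Loiselle pairwise kinship, kinship-on-ln(distance) regression, the Sp
  statistic with location-permutation significance and jackknife-over-loci
  SE, and the iterative Wright–Malécot estimator of gene dispersal σg and
  neighbourhood size Nb = 4πDeσg² at fixed effective density De (with a
  bracketed-bisection fallback when plain iteration oscillates).
* **Mating system** (`sgsd.mating_system`) — selfing rate from identity
  disequilibrium g2 (null-allele robust), inverted through the mixed-mating
  equilibrium relation g2(s) = s/((1−s)(4−s)), with jackknife SE.
* **Clustering** (`sgsd.clustering`) — EM maximum-likelihood mixture
  clustering under within-cluster HWE, AIC-based K selection, and the
  q ≥ 0.8 admixture/assignment rule.
* **Synthetic data** (`sgsd.synthetic_data`) — an individual-based forward
  simulation of isolation by distance on a torus (Gaussian seed/pollen
  kernels, selfing, strict ±1 stepwise mutation) returning the true composite
  dispersal σg = √(σs² + σp²/2), and a Balding–Nichols deme generator with a
  target drift level F.
* **Pipeline** (`sgsd.pipeline`) — YAML-config-driven orchestration
  (import → QC → subsample → cluster → per-cluster statistics) with CSV
  reports and a JSON run manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (estimator/oracle
equivalence to 1e-12, closed-form dispersal arithmetic, σg and selfing
parameter recovery from the simulators, permutation-test type-I error
calibration, clustering recovery). Brute-force oracles live in
`tests/oracles.py`.

## CLI

```bash
sgsd simulate ibd --density 0.002 --sigma-s 50 --sigma-p 200 --selfing 0 \
     --loci 10 --mu 1e-3 --side 1000 --gens 500 --seed 1 -o sim.csv
sgsd simulate demes --k 2 --fst 0.2 --per-deme 100 -o demes.csv
sgsd import data.csv --min-typed 0.6 --dedupe --grid-subsample 0.01,3 \
     --seed 1 -o clean.csv
sgsd diversity clean.csv --perms 10000 --seed 1 -o table1.csv
sgsd differentiation clean.csv --perms 10000 --seed 1 -o table2.csv
sgsd sgs clean.csv --perms 10000 --jackknife --seed 1 -o sgs.csv
sgsd dispersal clean.csv --de-per-ha 9 --range-factor 20 -o dispersal.csv
sgsd selfing clean.csv -o selfing.csv
sgsd cluster clean.csv --kmax 10 --starts 20 --threshold 0.8 --seed 1 -o q.csv
sgsd run --config run.yaml
```

`sgsd run` consumes a YAML serialization of `sgsd.pipeline.PipelineConfig`
(see `PipelineConfig.to_yaml`) and writes Table-1/Table-2-style CSVs, the
kinship-distance curve data, dispersal estimates per density scenario, a
selfing table, a JSON manifest with per-stage sample counts and seeds, and a
plain-text log.

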