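# breedscan

Population-genetic scans for inbred crop breeding panels: quality control,
within-population diversity, outgroup-polarized derived site-frequency
spectra, haploid Weir–Cockerham F_ST outlier scans with dropout-bootstrap
robustness, Bayesian per-population divergence ("c") via MCMC, pairwise
haplotype sharing (PHS) selection scans, windowed identity-by-state sharing
between populations, four-population (f4) gene-flow tests, and a synthetic
generator for hierarchically structured, selfed germplasm with exact ground
truth.

## Data formats

- **Genotypes**: accession × SNP matrix TSV of two-nucleotide diplotype calls
  (`AA`, `AG`, `NN` = missing; header row of SNP ids, first column accession
  id), or a diploid VCF (`0/0`, `0/1`, `1/1`, `./.`).
- **Genetic map**: TSV with columns `snp_id`, `linkage_group`, `cM`.
- **Populations**: TSV with columns `accession`, `population`, `spike_type`
  (2/6), `growth_habit` (spring/winter).
- **Ancestral states**: TSV with `snp_id`, `outgroup_allele` (`NA` missing,
  `A/G` for a segregating outgroup).

## CLI

```bash
breedscan simulate --preset paper-shape --seed 1 --out sim/
breedscan qc        --genotypes sim/genotypes.tsv --pops sim/populations.tsv --out qc/
breedscan diversity --genotypes ... --pops ... --map ... --window 10 --step 5 --out div/
breedscan sfs       --genotypes ... --pops ... --ancestral sim/ancestral.tsv --out sfs/
breedscan fst       --genotypes ... --pops ... --partition growth_habit \
                    --quantile 0.975 --bootstrap drop_snps --iters 100 --frac 0.2 --out fst/
breedscan nicholson --genotypes ... --pops ... --group spring_2 \
                    --burnin 1000 --iters 10000 --m 10 --seed 1 --out c/
breedscan phs       --genotypes ... --pops ... --map ... --pop A --min-freq 0.10 --out phs/
breedscan ibs       --genotypes ... --pops ... --map ... --pair A,B --window 100 --out ibs/
breedscan f4        --genotypes ... --pops ... --config f4_tests.json --block 75 --out f4/
breedscan pipeline  --seed 1 --scale 0.25 --out run/   # end-to-end demo
```

Every stage writes its outputs as TSV/JSON plus a manifest recording
parameters, input checksums and seeds; stochastic stages are bit-reproducible
under a fixed seed.

The f4 config JSON lists tests as
`{"tests": [{"base_pairs": [["N2","X"],["Y1","Y2"]], "substitutions": {"X": [...], "Y1": [...], "Y2": [...]}}]}`;
each concrete quadruple is evaluated under all three pairings and gene flow is
called only when all three deviate significantly from zero.

## Library

One module per analysis: `breedscan.genodata` (data model, I/O, QC),
`diversity`, `sfs`, `fst`, `nicholson`, `hapshare` (PHS + IBS), `f4test`,
`simdata` (generator + `emulate_paper_shape()` preset), `cli`.

```python
from breedscan.simdata import emulate_paper_shape, simulate
from breedscan.fst import fst_scan

matrix, gmap, scheme, ancestral, truth = simulate(emulate_paper_shape(seed=1))
scan = fst_scan(matrix, scheme.partition("growth_habit"), quantile=0.975)
```

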