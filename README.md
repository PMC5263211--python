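# gasel — genomic-assisted selection for line breeding

`gasel` implements a genomic-assisted selection workflow for inbred line
breeding programs, together with a breeding-program simulator that makes
every stage testable without external data:

- **Simulator** (`gasel.simulate`): multi-family inbred genotypes from
  parental haplotype mosaics, two correlated traits of contrasting
  heritability, replicated multi-environment trials (MET) with
  line-by-trial interaction, and unreplicated preliminary yield trials
  (PYT) with replicated checks and row/column field trends. A full program
  chains PYT cohorts into next-year MET retests of a phenotypically
  selected fraction.
- **Genomics core** (`gasel.genomics`): marker QC (call rate, MAF,
  missingness), mean/MVN-EM imputation, the genomic relationship matrix
  `K = WW'/(2 Σ p(1-p))`, and REML mixed models — RR-BLUP on marker
  effects and GBLUP on line effects — solved with a single
  eigendecomposition plus 1-D optimization of the variance ratio. The two
  parameterizations are exactly dual: with K built from the same centered
  markers, line predictions agree to numerical tolerance.
- **Trial analysis** (`gasel.trials`): check-based spatial adjustment of
  unreplicated trials, per-trial BLUEs with standard errors, Piepho
  (`σ²g/(σ²g + MVD/2)`) and Cullis (`1 − VD/2σ²g`) heritabilities, a
  weighted across-trial mixed model with random line-by-trial interaction,
  and KBLUP — GBLUP machinery applied to a trial's own adjusted values so
  unreplicated candidates borrow information from relatives.
- **Selection engine** (`gasel.selection`): candidate-only prediction
  scaling, the heritability index `GEBV = g_scaled·w_g + k_scaled·w_k`
  with model heritabilities as weights (and the inflated genomic weight
  `h²/(1−|r|)` after marker selection), sign-change marker pre-selection
  between MET- and PYT-trained RR-BLUP fits, two-tailed training-set
  sampling, three-year training combinations, year-fold and
  leave-one-year-out cross-validation, and top/bottom hit-rate metrics.

## CLI

```sh
gasel simulate --config sim.yaml --out data/        # dataset + manifest
gasel qc --markers data/markers.tsv --out clean.tsv # filter + impute
gasel adjust --trials data/trials.tsv --out adj/    # spatial adjustment + h2
gasel predict --data data/ --out pred/              # GBLUP/KBLUP/index tables
gasel compare --data data/ --out cmp/               # accuracy + hit-rate report
```

All outputs are TSV/JSON; every run is reproducible from its manifest
(config + seed).

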