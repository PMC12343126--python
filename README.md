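# srdrive

Deterministic population dynamics of an X-linked sex-ratio meiotic drive
allele (SR) whose fitness parameters are estimated from vial-based pesticide
assays.  The package covers the full workflow:

1. **`srdrive.synthetic_data`** — generators for the two experiments with
   known ground truth: a mortality assay (per-vial binomial deaths with a
   logit-linear dose-response per genotype) and a per-female fecundity assay
   (Poisson counts with vial/individual random intercepts and zero-count
   exclusion).
2. **`srdrive.parametrize`** — binomial GLM for mortality (per-genotype
   logit-linear reaction norms), maximum-likelihood Poisson random-intercept
   models for fecundity (adaptive Gauss–Hermite quadrature; automatic
   fallback from individual-in-vial to vial-only when the individual
   variance component collapses), likelihood-ratio model selection,
   marginal-mean genotype contrasts with a multivariate-normal ("Tukey")
   multiplicity adjustment, and exact export of fitted curves and brood
   sizes for the simulation model.
3. **`srdrive.drive_model`** — the five-genotype recursion (SR/ST males;
   SRSR/SRST/STST females): pre-mating dose-dependent mortality, random
   once-mating females, genotype-specific brood sizes, 100%-efficacy drive
   inheritance, Beverton–Holt (or Ricker) recruitment, quasi-extinction
   absorption, iterated to a long-run (t = 1000) equilibrium.
4. **`srdrive.experiments`** — dose × brood-size equilibrium sweeps,
   extinction-threshold detection by grid scan + bisection, curvature
   diagnostics of the dose–frequency relationship, and an end-to-end
   pipeline orchestrator.
5. **`srdrive.io_config`** — CSV dialects with row-level validation, the
   YAML parametrization file, run configuration with exhaustive validation,
   and run logs.

## CLI

```sh
srdrive generate --kind mortality --seed 1 --out mortality.csv
srdrive generate --kind fecundity --seed 1 --out fecundity.csv
srdrive fit --mortality mortality.csv --fecundity fecundity.csv --out params.yaml
srdrive simulate --params params.yaml --dose 1.0 --tmax 1000 --out trajectory.csv
srdrive sweep --params params.yaml --vary bSRSR --out sweeps/
srdrive pipeline --config config.yaml --out bundle/
```

`pipeline` runs generate → fit → parametrize → sweep → diagnostics and
writes a reproducible artifact bundle (data CSVs, `params.yaml`, one sweep
CSV per varied brood size, `diagnostics.json`, and a run log with the seed,
config hash and per-stage timings).  All data artifacts are byte-identical
under a fixed seed.

A config file is plain YAML over the fields of
`srdrive.io_config.RunConfig`, e.g.

```yaml
seed: 7
n_vials_per_genotype: 35
n_females_per_genotype: 150
t_max: 1000
sweep_dose_points: 26
```

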