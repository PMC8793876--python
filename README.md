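# xylemcomp

Comparative analysis of conifer xylem hydraulics: vulnerability-curve
fitting, pit/tracheid trait derivation, and phylogenetic comparative
statistics, with a synthetic-data generator so the whole pipeline is
testable end to end.

## What it does

- **`xylemcomp.vcfit`** — converts centrifuge conductance series to percent
  loss of conductivity (PLC), fits the sigmoid vulnerability model
  `PLC = 100 / (1 + exp(S/25 · (P − P50)))` for P50 and slope S, and computes
  specific hydraulic conductivity Ks (standard `kmax·L/A` or literal
  `kmax/(L·A)` convention).
- **`xylemcomp.anatomy`** — derives pit-sealing traits (torus overlap TO,
  margo flexibility MF, valve effect VE = TO·MF), pit aperture resistance
  R_PA (as-printed `(π·DPA)⁴` channel denominator by default; the
  conventional `π·DPA⁴` is behind a flag), hydraulic diameter, thickness-
  to-span ratio, tracheid density, and wood density.
- **`xylemcomp.treeio`** — newick I/O, validation, pruning, and the
  Brownian-motion trait covariance of a rooted tree.
- **`xylemcomp.compstats`** — Pearson correlation matrices, Felsenstein
  independent contrasts with through-origin correlations, Blomberg's K
  with a tip-shuffle permutation test, one-way ANOVA + Tukey HSD with
  compact letter display, correlation-matrix PCA, VIF screening, and
  exhaustive AICc model selection with zero-substitution averaging and
  variable importance.
- **`xylemcomp.pathmodel`** — recursive path analysis (per-equation OLS on
  standardized traits, likelihood-ratio χ² against the implied covariance,
  direct/indirect/total effect decomposition).
- **`xylemcomp.synthgen`** — Yule trees, Brownian traits with a tunable
  white-noise fraction, and synthetic Cavitron/anatomy datasets with
  ground truth for recovery tests.
- **`xylemcomp.pipeline`** — config-driven orchestration with a
  reproducibility manifest (seed, config hash, per-file SHA-256).

## CLI

```bash
# synthetic dataset (tree.nwk, curves.csv, pits.csv, tracheids.csv, wood.csv, truth.json)
xylemcomp synth --seed 42 --out data/

# fit vulnerability curves
xylemcomp vcfit --input data/curves.csv --ks-mode standard --out fits.csv

# derive anatomical traits
xylemcomp anatomy --pits data/pits.csv --tracheids data/tracheids.csv \
    --wood data/wood.csv --out traits.csv

# comparative statistics (correlations, PIC, Blomberg's K, AICc dredge)
xylemcomp compare --traits traits.csv --tree data/tree.nwk \
    --response P50_abs_MPa --candidates DPA_um,MF,VE --seed 42 --out results/

# path model from a plain-text spec ("VE ~ TO + MF", one equation per line)
xylemcomp sem --traits traits.csv --spec p50_model.txt --out sem/

# full pipeline (synthetic by default; YAML config for user data)
xylemcomp run --seed 42 --out runs/demo
```

## Notes

- Statistical defaults: α = 0.05, ΔAICc < 2 selection, VIF < 5 screening,
  999 permutations — all overridable.
- The R_PA channel term uses the as-printed `(π·DPA)⁴` denominator because
  it reproduces the reference subfamily means; `convention="conventional"`
  selects `π·DPA⁴` (≈31× larger channel term) and is documented as not
  matching those values.
- All stochastic procedures are reproducible under a fixed seed; the
  synthetic generator drives named substreams (tree / traits / anatomy /
  curves) from one master seed.
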