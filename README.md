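# traitdisp

Trait-based community-assembly statistics for presence–absence plot
networks:

- **Within-plot dispersion tests** — compare observed mean pairwise trait
  distance among co-occurring species to a randomization null that redraws
  each plot's species from the trait-covered pool, using the
  median-of-differences effect size over plots. Supports binary trait
  profiles (Jaccard dissimilarity, divergence alternative) and continuous
  trait assemblages (Euclidean distance on z-scored traits, convergence
  alternative).
- **Functional turnover** — pairwise `tau = 1 - Dw/Da` between plots
  (mean distance among distinct species within vs. between plots), with
  Mantel permutation tests against log great-circle distance and soil
  distance (optionally residualized on spatial distance).
- **Ordination utilities** — z-scoring, stepwise VIF elimination of
  collinear variables, correlation-matrix PCA with broken-stick axis
  retention, and axis–variable correlation screening used to pick soil
  distance variables and per-axis trait assemblages.
- **Synthetic generator** — plot networks in spatial clusters over a soil
  gradient with two habitat classes, species pools with controlled
  chemical-profile sharing and niche-linked continuous traits, and
  community assembly under tunable habitat filtering (`sigma_filt`) and
  limiting-similarity divergence (`lambda_div`). Neutral settings give
  uniform assembly, which the calibration tests rely on.

## Data format

All tables are UTF-8 CSV with row identifiers in the first column:

| table | rows | columns |
|---|---|---|
| `occurrence.csv` | plots | species (0/1) |
| `sm.csv` | species | binary traits / metabolites (0/1) |
| `rut.csv` | species | continuous traits |
| `environment.csv` | plots | `longitude`, `latitude`, then soil variables |

## CLI

```sh
traitdisp simulate --seed 1 --out data/sim            # synthetic bundle
traitdisp validate --occurrence ... --sm ... --rut ... --env ...
traitdisp soil-pca ... --out out/soil                 # VIF + PCA + correlations
traitdisp rut-pca  ... --out out/rut
traitdisp within-plot-test ... --traits sm --alternative divergence \
    --reps 1000 --seed 1 --out out/wp
traitdisp turnover ... --traits rut-axis1 --against soil \
    --residualize-soil on --perms 999 --seed 1 --out out/turn
traitdisp run --config cfg.yaml --out out/run         # full pipeline
```

`run` takes a YAML mirroring `RunConfig` (input paths or a `simulate:`
block, `alpha`, `reps_within`, `perms_mantel`, `residualize_soil`,
`null_variant`, `seed`). Reports are written as JSON plus a readable text
summary; every p-value is backed by a persisted replicate/permutation
vector.

## Statistical notes

- The within-plot test reports two p-values. `p` (primary) ranks the
  observed median of (observed − mean expected) within the null medians —
  an exchangeable comparison that is calibrated (type-I error ≈ alpha under
  neutral assembly). `p_zero_threshold` is the proportion of replicate
  medians on the wrong side of zero; it is retained for comparability but
  is strongly conservative.
- The null draw defaults to `subset` (each plot gets N distinct species,
  independently across plots). `multiset` draws with replacement within a
  plot and counts conspecific duplicate pairs as distance zero; this biases
  the divergence test anti-conservatively and is provided as a sensitivity
  variant only.
- `mantel_test` defaults to a one-tailed p in the sign of the observed r
  (`alternative="auto"`); pass `"greater"`/`"less"` for a pre-declared
  direction, which is the calibrated usage.

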