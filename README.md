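# brillmap

Quantitative analysis of confocal Brillouin microscopy frequency-shift maps,
exercised end-to-end on synthetic tissue phantoms.

The package covers:

- **physics** — conversions between Brillouin frequency shift (GHz),
  dimensionless elastic contrast (`shift / 5.066 GHz − 1`), longitudinal
  modulus (`M' = ρ (ν λ₀ / (2 n sin θ/2))²`), longitudinal compressibility
  (`κ_L = 1/M'`) and bulk modulus (`K' = M' − 4/3 G'`).
- **mapio** — CSV grid readers/writers for shift maps
  (`x_um,y_um,shift_GHz`), label masks (`x_um,y_um,label,cell_id`), cohort
  tables (`animal_id,condition,value`), plus deterministic PNG heat maps.
  Floats are serialized at `repr` precision, so write→read round trips are
  bit exact.
- **phantoms** — a digit-phantom generator (medium / epidermis /
  interstitial / ECM band with non-overlapping oval chondrocytes / optional
  joint strip), series factories for three studies (enzymatic digestion
  time course, developmental stages 45–53, regeneration at 0/15/30 dpa), a
  digit-length model and a repeated-measures cohort sampler. Everything is
  a pure function of `(spec, seed)`.
- **quantify** — contrast conversion, rectangular-ROI means (pixel-center,
  half-open), per-cell/per-region mask means, five-line averaged
  transversal profiles, size normalization of profiles (edges at the
  outermost positions with contrast ≥ 0.006 mapped to ±100 %, centre to 0)
  and digit-length ratios.
- **stats** — small-sample nonparametric suite: Friedman (chi-square
  approximation) + Dunn's post hoc (Bonferroni) + Kendall's W;
  Kruskal–Wallis with tie correction + Dunn + η²; exact-enumeration
  Mann–Whitney with continuity-corrected Z and effect size r = |Z|/√N;
  pooled two-sample t-test; Chen–Shapiro normality statistic with seeded
  Monte-Carlo critical values; and a test-selection policy.
- **experiments** — CLI orchestration: generate phantoms per animal, run
  the quantifications and tests, and write a deterministic report tree
  (`maps/`, `cohorts/`, `tables/`, `profiles/`, `stats/`, `log.txt`).

## CLI

```sh
# full pipeline for one study
brillmap run --experiment collagenase --seed 1 --outdir out/collagenase
brillmap run --experiment development --seed 1 --outdir out/development
brillmap run --experiment regeneration --seed 1 --outdir out/regeneration

# phantom maps only
brillmap generate --experiment collagenase --seed 1 --outdir out/maps-only

# quantify one map CSV (optionally with a mask and an ROI)
brillmap quantify --map out/collagenase/maps/A1_t00min.csv \
    --mask out/collagenase/maps/A1_t00min_mask.csv --roi 20 20 50 40

# statistics on a cohort CSV
brillmap test --cohort out/collagenase/cohorts/collagenase_map_means.csv \
    --design repeated
```

`run`/`generate` accept `--config config.yaml` with keys such as

```yaml
seed: 1
n_animals: 5
animal_sd: 0.002
color_limits: [0.0, 0.08]
optical:
  lambda0_nm: 780.24
  theta_deg: 180.0
  water_shift_ghz: 5.066
```

Identical `(config, seed)` produce byte-identical report trees.

## Conventions

- Grids use pixel centers in micrometres, origin at the top-left pixel
  center, x rightward, y downward.
- Shifts are held in GHz, wavelengths in nm, moduli in Pa; the GHz·nm
  product is numerically m/s, so no unit constants appear in formulas.
- Nominal 1 µm profile lines are realized as single pixel rows (pixels are
  2–5 µm); the 5 µm line spacing is rounded to a whole pixel offset and
  logged.
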