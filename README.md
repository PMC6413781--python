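# pigmentrial

Quantitative pigmentation endpoints for ocular albinism (OCA) trials.

In oculocutaneous albinism, reduced melanin lets light reflected off the
retina shine back through the iris — *iris transillumination* (TI). Trials
of pigmentation-modifying drugs therefore need reproducible, quantitative
readouts of melanin in the iris, skin and hair. This package implements a
complete analysis pipeline for such trials:

- **Semiquantitative iris TI image scoring** — from an anterior-segment
  photograph with a hand-annotated circle model (center, iris radius,
  pupil radius), 16 sampling sites are laid out by quadrant subdivision of
  the iris bounding square, the red channel is locally smoothed within the
  iris annulus, averaged over each site's sampling disk, and mapped
  linearly to a 0–8 score (`8 × mean(red)/255`). Higher score = more
  transmitted light = less iris melanin.
- **Grader-panel aggregation and reliability** — a panel of graders scores
  each image on an 8-point photographic standard scale (one decimal
  allowed); per-grader image means are averaged across graders, and
  intergrader reliability is quantified per eye and visit with the
  two-way random-effects, absolute-agreement ICC (single and average
  measure, with F-based 95% CIs). Agreement between panel and automated
  scores is a pooled Spearman rank correlation.
- **Melanin (M) index** from diffuse reflectance spectra:
  `M = 100·log10(1/band)` with
  `band = ((PR₆₅₀ + PR₆₆₀ + 0.5·PR₆₄₀ + 0.5·PR₆₇₀)/3)/100`,
  replicate-averaged per body site, with white/dark calibration checks.
- **Hair melanin markers** — change-from-baseline summaries for PTCA
  (eumelanin) and 4-AHP (pheomelanin), ng/mg hair.
- **Longitudinal statistics** — change from each unit's earliest baseline
  (directional and absolute means, per eye and pooled OU), and linear
  mixed models with categorical visit effects, participant random
  intercept ± slope, compound-symmetry correlation, eyes nested within
  participants, REML estimation, and an automatic intercept-only fallback
  when the slope variance is degenerate. P-values are labeled at the
  0.05 / 0.10 (significant / moderately significant) convention with no
  multiplicity adjustment.
- **Synthetic cohort generator** — renders TI images, grader tables,
  reflectance spectra, hair chemistry and visual-acuity letters from an
  explicit ground-truth model, so every estimator can be validated against
  its generating value.

## Worked example

Run the bundled end-to-end demo (synthetic 5-participant cohort, both
eyes, visits at months 0–18, 18 graders, 2 images per eye-visit):

```bash
pigmentrial run --seed 1 --out demo_run
```

which prints the consolidated report:

```
pigmentrial 0.1.0 run (seed=1)

simulate: 140 images, 2520 grades, 1050 spectra
score_images: 140 images -> 70 eye-visits
panel: 70 eye-visit panel means; ICC range [0.866, 0.918]
method correlation (Spearman): 0.995
reflectometry: 210 site M indices, 6 site models
hair: ptca change +7.15 (7.35) ng/mg; ahp4 change -1.82 (7.80) ng/mg
iris TI panel score: month-12 change +1.19 [0.78, 1.60], P=0.000 (significant)
letters read: month-12 change +4.60 [2.58, 6.62], P=0.000 (significant)
```

Reading the numbers: intergrader reliability is high (ICC ≥ 0.87 at every
visit — an ICC of 1 is perfect agreement, 0 chance agreement); the
automated image score tracks the human panel closely (Spearman ρ 0.995);
the cohort's iris TI increased by ~1.2 points on the 0–8 scale at month
12 (less iris melanin), visual acuity improved by ~4.6 ETDRS letters, and
hair eumelanin (PTCA) rose while pheomelanin (4-AHP) fell — all of which
recover the effects built into the synthetic truth.

Each stage is also available as a library function
(`pigmentrial.semiquant_score`, `panel_scores`, `intergrader_icc`,
`m_index`, `marker_change_summary`, `fit_longitudinal`, ...) and as a CLI
subcommand (`simulate`, `score-ti`, `panel`, `icc`, `mindex`, `hair-chem`,
`fit-long`, `run`).

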