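# nflmd

Structure-function analysis for glaucoma: estimate the visual field mean
deviation (VF_MD) from an OCT peripapillary nerve fiber layer (NFL)
thickness profile.

Glaucoma is monitored with two instruments that disagree by construction:
OCT measures NFL thickness in µm on a linear scale, while perimetry
summarises sensitivity loss in dB on a logarithmic scale and weights by
visual-field area. `nflmd` harmonises the two. Each of the 16
peripapillary sectors is converted to a decibel loss against an
age/axial-length-specific normative reference with a damage floor,
averaged with visual-field-area weights over a modified Garway-Heath map,
and calibrated to the VF_MD scale with a zero-intercept quadratic:

    NFL_dB(i) = 10 · log10( (t_i − f_i) / (N_i − f_i) )   clamped at −12.8 dB
    NFL_WLA   = (1/52) · Σ_i w_i · NFL_dB(i)              Σ w_i = 52
    NFL_MD    = 0.864 · NFL_WLA − 0.075 · NFL_WLA²

where `t_i` is the measured sector thickness, `N_i` the normative
reference (affine in age and axial length), `f_i` the floor (45% of the
reference, axial-length-adjusted), and `w_i` the number of 24-2 visual
field test points whose nerve fiber bundles traverse sector *i*.

The package is aimed at researchers evaluating OCT-based glaucoma indices:
it ships the normative coefficient table and canonical weight scheme,
diagnostic cutoffs at fixed specificity, Hodapp-Parrish-Anderson staging,
agreement / reproducibility / correlation / ROC statistics, and a seeded
synthetic paired OCT/VF cohort generator so every part of the pipeline is
testable without clinical data.

## Worked example

A 55% focal loss in the inferior-most inferotemporal sector of an
otherwise-average eye (`examples/02_worked_examples.py`):

```
focal 55% IT1 loss: sector dB = -12.8, NFL_WLA = -1.881 dB, NFL_MD = -1.89 dB
upper normal-variation bound: relative thickness 1.167 -> NFL_MD = +0.9 dB
lower normal-variation bound: relative thickness 0.833 -> NFL_MD = -1.5 dB
5% diffuse loss, no floor term: -0.22 dB
```

The focal defect leaves the overall average thickness only ~5% below
normal — unremarkable in µm — yet lands at −1.89 dB, beyond a typical
99%-specificity cutoff: the dB scale and VF-area weighting accentuate
focal loss in the arcuate sectors where glaucoma usually starts. The
second pair of lines shows the NFL_MD spread (−1.5 to +0.9 dB) induced
purely by normal between-eye thickness variation (CV 8.5%), which bounds
the achievable structure-function agreement.

More narrative scripts live in `examples/` (decibel transform, cohort
simulation and scoring, cutoffs and staging, reproducibility). A thin CLI
wraps the same functions:

```sh
nflmd simulate --output cohort.csv --seed 7
nflmd compute  --input cohort.csv --output scored.csv
nflmd evaluate --input scored.csv --task correlation
```

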