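# phkin

Estimation of the pH dependence of yeast glycolytic enzyme capacities
from optical progression curves.

During carbon-source transitions the cytosolic pH of *Saccharomyces
cerevisiae* swings by as much as 0.7 units (about 7.1 in glucose excess,
about 6.4 after glucose removal), and the maximal rates of the
glycolytic and fermentative enzymes respond to it — each one
differently. `phkin` is a toolkit for quantifying that response from
coupled and direct spectrophotometric assays of cell-free extracts:

* **Assay models** — reversible Michaelis–Menten ODE systems for eleven
  assays (HXK, PGI, PFK, ALD, TPI, GAPDH forward/reverse, PGM, ENO,
  PYK, PDC), with surplus coupling enzymes, monitored through NAD(P)H
  at 340 nm or PEP at 240 nm.
* **Two Vmax estimators** — the classical initial-slope method
  (maximal linear window at R² ≥ 0.995, background subtraction,
  dilution-series consistency), and a progression-curve fitting method:
  one bounded nonlinear least-squares problem per enzyme with a Vmax
  parameter per pH and Km shared across the pH range, optionally
  regularized toward literature Km.
* **Hypothesis comparisons** — pH-dependent versus frozen equilibrium
  constants, and pH-dependent Vmax versus pH-dependent Km at equal
  parameter counts.
* **Calibrations** — absorbance-to-amount lines and degree-3 polynomial
  pHluorin ratio→pH calibration.
* **Dynamics** — interpolation of activity-vs-pH profiles onto
  feast/famine cytosolic pH traces, with per-enzyme percent-change
  summaries.
* **Synthetic data** — a seeded generator producing noisy plate-reader
  curves from the assay models with known ground truth, plus pHluorin
  titrations and feast/famine pH traces, used to validate the whole
  pipeline end to end.

The core model for one enzyme across the pH grid is

    minimize over {Vmax(pH_k)}, Km:
        sum_curves sum_t [ c_model(t; Vmax(pH), Km) − c_obs(t) ]²
        + λ · Σ log²(Km / Km_ref)

with the model concentrations produced by stiff integration of the
assay's rate equations, e.g. for a uni-uni step

    v = Vmax (S − P/Keq) / Km_S / (1 + S/Km_S + P/Km_P).

## Worked example

Fit the enolase assay on synthetic curves with a known pH profile:

```python
from phkin import ProgressionFitModel, StudyDesign, generate_study, load_scheme

design = StudyDesign(dilution_factors=(1, 2), replicates=3, sigma_au=0.002)
study = generate_study(seed=7, enzymes=["ENO"], design=design)

model = ProgressionFitModel(load_scheme("ENO"), study.curves)
result = model.fit()
print(result.summary())
```

```
Progression-curve fit: ENO
  layout: vmax_per_ph, keq_mode: ph_dependent, lambda: 0
  curves: 48  residuals: 2928  parameters: 9
  SSE: 0.0871261  penalty: 0  converged: True

  pH      Vmax [umol/min/mg]   ~95% half-width      SSE(pH)
   6.19          0.76648          0.00129       0.0106
   6.40           1.1388          0.00137       0.0127
   6.60           1.5581          0.00154      0.01021
   6.80           1.9997          0.00182      0.01105
   7.10           2.5875          0.00239      0.01044
   7.40           2.9091          0.00281     0.009221
   7.60           2.9091          0.00281      0.01141
   7.90           2.5878          0.00239      0.01149

  Km [mM], shared across pH (reference):
    P2G        0.039569  +/- 0.00144  (ref 0.04)
```

Each row is the enzyme's capacity (µmol·min⁻¹ per mg extract protein) at
one assay pH with its approximate 95% half-width; the generating truth
here was 2.0 at pH 6.8 with a bell-shaped optimum at 7.5 and Km = 0.04
mM, recovered within a few tenths of a percent (Vmax) and about 1%
(Km). The per-pH SSE column decomposes the total misfit (in mM² over
2928 residuals), and the shared 2-phosphoglycerate Km is printed against
its literature reference.

Project the packaged activity table onto a feast/famine cycle:

```python
from phkin import PHTrace, generate_feast_famine_trace, load_packaged_profiles, transition_summary

profiles = load_packaged_profiles()          # synthetic per-pH Vmax table
summary = transition_summary(profiles, ph_hi=7.1, ph_lo=6.4)
print(summary.round(1)[["percent_change", "flagged"]])
```

```
        percent_change  flagged
enzyme
ALD               78.2     True
ENO               65.4     True
GAPDHF            83.0     True
GAPDHR           -40.0    False
HXK               57.7    False
PDC               31.6    False
PFK               50.0    False
PGI               64.4     True
PGM               58.7    False
PYK               13.1    False
```

A positive percent change is an activity loss upon acidification from
pH 7.1 to 6.4: the forward reaction of GAPDH loses 83% of its activity,
the reverse reaction gains 40%, and four of the ten enzymes drop by more
than 60%.

The same stages are scriptable from a shell (`phkin synth`,
`phkin fit-slope`, `phkin fit-curve`, `phkin compare-keq`,
`phkin compare-ph`, `phkin dynamics`, `phkin report`); every run echoes
its configuration and seed into the output directory.

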