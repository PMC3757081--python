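# taswitch

Dynamics of conditionally regulated toxin–antitoxin (TA) modules: how
heteromer sequestration plus growth-rate feedback turns a two-gene operon
into a bistable switch between growth and dormancy.

## The problem

Type-II TA operons (e.g. *relBE* in *E. coli*) pair a stable toxin T that
shuts down translation and growth with an unstable antitoxin A that
neutralises it. The operon is autorepressed by the intermediate complex
AT, while the toxin-saturated complex ATT is transcriptionally inert —
"conditional regulation": repression is strongest near T_tot ≈ A_tot and
collapses ultrasensitively once T_tot exceeds 2·A_tot and sequesters the
repressor into ATT. TA modules are a leading candidate mechanism for
bacterial *persisters* — rare, transiently dormant cells that survive
antibiotics. This package implements the minimal quantitative model of
that idea for modellers and systems biologists: mass-action equilibria of
the complexes, the one-variable feedback motif, the full operon ODEs with
growth-rate feedback, and seeded Monte-Carlo robustness scans.

## The model

Complex formation (K1, K2) is fast, so the totals evolve on a
quasi-equilibrium:

    dA_tot/dt = β_A·R·φ_p(t) − Γ_A·A_tot
    dT_tot/dt = β_T·R·φ_p(t) − φ_g(t)·T_tot

    R      = 1 / (1 + ([AT]/K_D)^n)          promoter activity
    φ_p(t) = 1 / (1 + k_tl·t)²               production inhibition
    φ_g(t) = 1 / (1 + k_g·t)²                growth (dilution) inhibition

with t the free-toxin concentration at the current totals. Units: time in
toxin lifetimes, concentration in maximal toxin production per unit time
(β_T = 1). Reference values (dimensionless): β_A = 100, Γ_A = 10,
K_D = 0.015, K1 = K2 = 0.004, k_tl = k_g = 11. Free toxin slows
production and growth but not the active degradation of A — that
asymmetry creates a dormant, toxin-dominated fixed point alongside the
growing, antitoxin-dominated one. The choice of the saturating feedback
law is discussed in `docs/methods.md`.

## Worked example

Fixed points of the reference parameter set:

```
$ taswitch fixed-points --quiet
[
  {"A_tot": 1.2397, "T_tot": 0.1250, "freeT": 0.00037,
   "eigenvalues": [[-11.349, 0.0], [-1.628, 0.0]], "class": "stable"},
  {"A_tot": 0.1850, "T_tot": 0.9182, "freeT": 0.5496,
   "eigenvalues": [[0.334, 0.0], [-0.230, 0.0]], "class": "saddle"},
  {"A_tot": 0.1228, "T_tot": 0.9562, "freeT": 0.7114,
   "eigenvalues": [[-4.493, 0.0], [-0.0082, 0.0]], "class": "stable"}
]
```

(coordinates abbreviated). Reading: the first stable point is the
*growing* state — antitoxin outnumbers toxin 10:1
(1.2397/0.1250 ≈ 9.92 ≈ (β_A/Γ_A)/β_T) and free toxin is negligible
(4e-4, far below K1). The second stable point is the *dormant* state:
nearly all antitoxin is titrated, free toxin is 0.71, and the growth
factor φ_g has dropped 77-fold:

```python
>>> from taswitch import TAParams, dilution_rate_ratio
>>> dilution_rate_ratio(TAParams())
77.2
```

so a cell at that fixed point divides ~77× slower — dormancy. The saddle
between them sets the switching threshold. Python API equivalently:

```python
from taswitch import TAParams, enumerate_fixed_points
fps = enumerate_fixed_points(TAParams())   # ordered by T_tot
```

Scans from the shell (CSV + JSON summary per run):

```
taswitch state-diagram --k-range 1 1000 --n-grid 25 --out out/
taswitch robustness --swept k_g --n-samples 200 --seed 1 --out out/
taswitch kd-scan --n-samples 200 --seed 1 --out out/
```

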