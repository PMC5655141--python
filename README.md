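# docklink

Quantitative analysis of the two-state conformational ensemble of Hsp70-class
chaperones, built around the ER chaperone BiP: the nucleotide-binding and
substrate-binding domains either dock against each other (D) or move
independently (U), and the balance between the two states controls nucleotide
affinity. `docklink` turns the three measurements that characterise this
equilibrium into one reproducible pipeline:

1. **Methyl-NMR doublet populations** — in slow exchange every methyl probe
   shows one peak per conformation; the docked fraction is
   `p_D = I_D/(I_D + I_U) x 100%`, with U identified by overlay with
   isolated-domain reference spectra, heights measured by parabolic
   interpolation, and a conservative `max(SD, propagated)` error.
2. **Single-site ITC thermodynamics** — injection heats fitted to the exact
   quadratic-root isotherm with the perfusion-cell dilution convention,
   yielding `(n, Kd, dH)` and the ledger `dG = RT ln Kd`,
   `-TdS = dG - dH` at 298 K.
3. **Thermodynamic linkage** — the two-state model
   `dG_bind/RT = ln(p_D Kd_D + (1 - p_D) Kd_U)`,
   `dG_dock/RT = -ln(p_D/(1 - p_D))`: the observed dissociation constant is
   the population-weighted sum of pure-state constants, and a construct panel
   is fitted for `(Kd_D, Kd_U)` in log-Kd space.

A first-class synthetic-data module generates ground-truthed spectra
(2D Lorentzian doublets plus Gaussian grid noise), titrations and construct
panels, so every stage is testable without deposited raw data. See
`docs/methods.md` for models, conventions and limitations.

## Worked example

The shipped demo simulates a BiP-like dataset (53% docked, Kd = 0.80 µM /
dH = 11.4 kcal/mol ATP titration, a six-construct ADP panel on a
Kd_D = 1.5 µM / Kd_U = 7 µM linkage curve with ln-Kd scatter 0.3) and then
analyses it blind:

```bash
docklink run-all --config configs/demo.yaml --out runs/demo
```

prints the analysis summary (abridged):

```json
{
  "p_d_percent": 52.503865269027386,
  "p_d_error_percent": 0.7017314466248428,
  "exchange_tau_ms": 45.12045828024514,
  "itc_kd_uM": 0.816664360269948,
  "itc_dH_kcal_mol": 11.444754071701784,
  "itc_dG_kcal_mol": -8.300444559316905,
  "itc_minus_TdS_kcal_mol": -19.745198631018688,
  "linkage_kd_D_uM": 1.700407472351783,
  "linkage_kd_U_uM": 7.547267583747123
}
```

Reading it: the estimator recovers the planted 53% docked population within
its ~0.7 pp error bar from three doublets; the resolved 0.03/0.4 ppm
splittings mean docking/undocking is slower than ~45 ms; the titration fit
returns Kd = 0.82 µM and dH = 11.4 kcal/mol (dG = -8.3, -TdS = -19.7
kcal/mol), i.e. entropy-opposed ATP binding; and the noisy six-point panel
gives pure-state constants 1.7 / 7.5 µM against the planted 1.5 / 7 µM.
`runs/demo/results/` also holds the per-doublet population report, the
presentation-rounded thermodynamics table, the linkage JSON and a run
manifest (config hash, per-stage seeds, artifact paths); reruns with the same
config and seed are byte-identical.

Each stage is also available separately (`simulate-spectra`, `simulate-itc`,
`simulate-panel`, `quantify`, `fit-itc`, `link`, `validate`) and as plain
library calls (`docklink.estimate_populations`, `docklink.fit_single_site`,
`docklink.fit_state_constants`, ...).

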