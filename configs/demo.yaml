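# Demo run: BiP-like synthetic panel, end to end.
#   docklink run-all --config configs/demo.yaml --seed 1 --out runs/demo
mode: all
seed: 20260901

spectra:
  docked_fraction: 0.53   # ATP-bound full-length docked population
  noise_sigma: 0.01       # grid noise sd, amplitude units (peak heights ~0.5)
  offset_h_ppm: 0.03      # D - U splitting, 1H
  offset_c_ppm: 0.4       # D - U splitting, 13C

itc:
  n: 1.0
  kd_uM: 0.80             # ATP binding to full-length chaperone
  dH_kcal_mol: 11.4
  cell_conc_uM: 40.0
  syringe_conc_uM: 300.0
  cell_volume_uL: 200.0
  n_injections: 25
  injection_volume_uL: 1.5
  heat_noise_ucal: 0.05   # ~1% of the pre-equivalence injection heat
  dilution_heat_ucal: 0.1
  construct: "BiP* FL (synthetic)"
  nucleotide: ATP

panel:
  kd_D_uM: 1.5            # ADP-like pure-state constants
  kd_U_uM: 7.0
  nucleotide: ADP
  docked_fractions: [0.02, 0.15, 0.4, 0.6, 0.85, 0.98]
  scatter_sd: 0.3         # ln-Kd units

tolerances:
  match_ppm: 0.02
  doublet_window_ppm: 0.15
  search_radius_h_ppm: 0.02
  search_radius_c_ppm: 0.2

make_plot: false
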