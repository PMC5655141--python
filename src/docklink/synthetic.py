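"""Ground-truthed synthetic inputs for every pipeline stage.

No raw spectra or titrations are deposited with the study this package
models, so each analysis stage is exercised against simulated data with a
known answer:

* 2D methyl spectrum pairs (full-length + isolated-domain reference) with
  slow-exchange doublets split by configurable (ddelta_H, ddelta_C) offsets,
  built from 2D Lorentzian lineshapes plus i.i.d. Gaussian grid noise;
* single-site ITC injection-heat series at the study's concentration regime
  (tens of µM cell protein, 0.1–0.4 mM syringe nucleotide, 25 C);
* construct panels whose (dG_dock, dG_bind) points lie on a known two-state
  linkage curve plus Gaussian scatter.

All randomness in a generator call flows from its single integer seed; fixed
seed means bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import C_FREQ_MHZ, H_FREQ_MHZ
from .grids import Axis, SpectrumGrid
from .itc import ITCTitration, singlesite_injection_heats
from .linkage import ConstructState, LinkageParameters, docking_free_energy, ensemble_kd

__all__ = [
    "ProbeTruth",
    "EnsembleGroundTruth",
    "ITCGroundTruth",
    "ConstructPanel",
    "default_grid",
    "default_probes",
    "generate_spectrum_pair",
    "generate_itc_titration",
    "generate_construct_panel",
]


@dataclass(frozen=True)
class ProbeTruth:
    """One methyl probe: U-state position, D-U offset, linewidths, amplitude."""

    label: str
    delta_h: float  # U-state 1H position, ppm
    delta_c: float  # U-state 13C position, ppm
    offset_h: float  # D - U shift, ppm
    offset_c: float  # D - U shift, ppm
    linewidth_h_hz: float = 15.0  # FWHM
    linewidth_c_hz: float = 15.0  # FWHM
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.linewidth_h_hz <= 0 or self.linewidth_c_hz <= 0:
            raise ValueError(f"probe {self.label}: linewidths must be positive")
        if self.amplitude <= 0:
            raise ValueError(f"probe {self.label}: amplitude must be positive")


@dataclass
class EnsembleGroundTruth:
    """Known docked fraction + probe geometry behind a simulated spectrum pair."""

    docked_fraction: float
    probes: list[ProbeTruth]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.docked_fraction <= 1.0:
            raise ValueError("docked_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.probes:
            raise ValueError("need at least one probe")

    def to_manifest(self) -> dict:
        return {
            "docked_fraction": self.docked_fraction,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "probes": [asdict(p) for p in self.probes],
        }

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_manifest(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_manifest(cls, path: str | Path) -> "EnsembleGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            docked_fraction=d["docked_fraction"],
            noise_sigma=d["noise_sigma"],
            seed=d["seed"],
            probes=[ProbeTruth(**p) for p in d["probes"]],
        )


def default_grid() -> tuple[Axis, Axis]:
    """(13C axis, 1H axis): 256 x 512 points over 2 x 0.8 ppm at 750 MHz 1H.

    Resolves the canonical 0.03 / 0.4 ppm doublet splittings with ~10 grid
    points per 15 Hz linewidth on both axes.
    """
    c_axis = Axis(sfrq_MHz=C_FREQ_MHZ, ppm_max=14.5, ppm_min=12.5, npoints=256)
    h_axis = Axis(sfrq_MHz=H_FREQ_MHZ, ppm_max=1.1, ppm_min=0.3, npoints=512)
    return c_axis, h_axis


def default_probes(
    offset_h: float = 0.03, offset_c: float = 0.4
) -> list[ProbeTruth]:
    """Three well-separated Ile-region doublet probes (offsets in ppm).

    Offset signs alternate so no two probes' peaks approach each other.
    """
    return [
        ProbeTruth("P1", delta_h=0.75, delta_c=13.90, offset_h=offset_h, offset_c=offset_c),
        ProbeTruth("P2", delta_h=0.55, delta_c=13.10, offset_h=-offset_h, offset_c=-offset_c),
        ProbeTruth("P3", delta_h=0.95, delta_c=13.50, offset_h=offset_h, offset_c=-offset_c),
    ]


def _lorentzian_2d(
    h_ppm: np.ndarray,
    c_ppm: np.ndarray,
    center_h: float,
    center_c: float,
    fwhm_h_ppm: float,
    fwhm_c_ppm: float,
) -> np.ndarray:
    """Product of 1D Lorentzians, unit height at the centre; (C, H) layout."""
    lh = 1.0 / (1.0 + (2.0 * (h_ppm - center_h) / fwhm_h_ppm) ** 2)
    lc = 1.0 / (1.0 + (2.0 * (c_ppm - center_c) / fwhm_c_ppm) ** 2)
    return lc[:, None] * lh[None, :]


def generate_spectrum_pair(
    truth: EnsembleGroundTruth,
    grid_spec: tuple[Axis, Axis] | None = None,
) -> tuple[SpectrumGrid, SpectrumGrid]:
    """Simulate (full-length, isolated-domain reference) spectrum planes.

    The full-length plane holds, per probe, a U peak at the reference
    position with height ``(1 - p_D) * amplitude`` and a D peak offset by
    (offset_h, offset_c) with height ``p_D * amplitude``; the reference plane
    holds only the U peak at full amplitude.  Both share axes and receive
    independent Gaussian noise of sd ``noise_sigma``.
    """
    c_axis, h_axis = grid_spec if grid_spec is not None else default_grid()
    h_ppm = h_axis.ppm_scale()
    c_ppm = c_axis.ppm_scale()

    for probe in truth.probes:
        positions = [
            (probe.delta_h, probe.delta_c),
            (probe.delta_h + probe.offset_h, probe.delta_c + probe.offset_c),
        ]
        for ph, pc in positions:
            if not (
                h_axis.contains(ph, margin_points=3)
                and c_axis.contains(pc, margin_points=3)
            ):
                raise ValueError(
                    f"probe {probe.label}: peak at ({ph:.3f}, {pc:.3f}) ppm "
                    f"outside the grid (3-point margin required)"
                )

    p_d = truth.docked_fraction
    full = np.zeros((c_axis.npoints, h_axis.npoints))
    ref = np.zeros_like(full)
    for probe in truth.probes:
        fwhm_h = probe.linewidth_h_hz / h_axis.sfrq_MHz
        fwhm_c = probe.linewidth_c_hz / c_axis.sfrq_MHz
        u_shape = _lorentzian_2d(
            h_ppm, c_ppm, probe.delta_h, probe.delta_c, fwhm_h, fwhm_c
        )
        d_shape = _lorentzian_2d(
            h_ppm, c_ppm,
            probe.delta_h + probe.offset_h, probe.delta_c + probe.offset_c,
            fwhm_h, fwhm_c,
        )
        full += probe.amplitude * ((1.0 - p_d) * u_shape + p_d * d_shape)
        ref += probe.amplitude * u_shape

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        full = full + rng.normal(0.0, truth.noise_sigma, full.shape)
        ref = ref + rng.normal(0.0, truth.noise_sigma, ref.shape)
    return (
        SpectrumGrid(full, c_axis, h_axis),
        SpectrumGrid(ref, c_axis, h_axis),
    )


# ---------------------------------------------------------------------------
# ITC


@dataclass
class ITCGroundTruth:
    """Known single-site parameters behind a simulated titration.

    Defaults mirror a tight-binding chaperone-nucleotide titration in the
    study's regime: 40 µM cell protein, 0.3 mM syringe nucleotide, 200 µL
    cell, 25 x 1.5 µL injections at 25 C (final molar ratio ~1.4, c = 50).
    """

    n: float = 1.0
    kd: float = 0.80e-6  # M
    dh: float = 11.4  # kcal/mol
    cell_conc: float = 40e-6  # M
    syringe_conc: float = 0.3e-3  # M
    cell_volume: float = 200e-6  # L
    injection_volumes: np.ndarray = field(
        default_factory=lambda: np.full(25, 1.5e-6)
    )
    temperature: float = 298.0  # K
    heat_noise_sigma: float = 0.0  # µcal
    dilution_heat: float = 0.0  # µcal per injection
    seed: int = 0

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if len(self.injection_volumes) < 5:
            raise ValueError("need at least 5 injections")
        if self.syringe_conc <= self.cell_conc:
            raise ValueError("syringe concentration must exceed cell concentration")

    def schedule(self) -> ITCTitration:
        return ITCTitration(
            cell_conc=self.cell_conc,
            syringe_conc=self.syringe_conc,
            cell_volume=self.cell_volume,
            temperature=self.temperature,
            injection_volumes=self.injection_volumes.copy(),
        )

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["injection_volumes"] = list(self.injection_volumes)
        return d

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_manifest(), indent=2, sort_keys=True) + "\n")
        return path


def generate_itc_titration(truth: ITCGroundTruth) -> ITCTitration:
    """Forward-model a titration, add heat noise and a constant dilution heat."""
    schedule = truth.schedule()
    heats = singlesite_injection_heats(truth.n, truth.kd, truth.dh, schedule)
    heats = heats + truth.dilution_heat
    if truth.heat_noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        heats = heats + rng.normal(0.0, truth.heat_noise_sigma, heats.shape)
    final_ratio = schedule.molar_ratios(truth.n)[-1]
    if final_ratio <= 1.0:
        warnings.warn(
            f"titration never exceeds molar ratio 1 (final {final_ratio:.2f}); "
            f"the fit will be ill-conditioned",
            RuntimeWarning,
        )
    schedule.heats = heats
    return schedule


# ---------------------------------------------------------------------------
# linkage panels


@dataclass
class ConstructPanel:
    states: list[ConstructState]
    truth: LinkageParameters
    scatter_sd: float
    seed: int

    def to_manifest(self) -> dict:
        return {
            "kd_D_M": self.truth.kd_D,
            "kd_U_M": self.truth.kd_U,
            "scatter_sd": self.scatter_sd,
            "seed": self.seed,
            "docked_fractions": [s.p_d for s in self.states],
        }

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_manifest(), indent=2, sort_keys=True) + "\n")
        return path


#: Docked fractions anchoring both pure states: a linkage recovery panel needs
#: points near p_D = 0 and p_D = 1 for (Kd_U, Kd_D) to be separately identified.
DEFAULT_PANEL_FRACTIONS: tuple[float, ...] = (0.02, 0.15, 0.4, 0.6, 0.85, 0.98)


def generate_construct_panel(
    params: LinkageParameters,
    docked_fractions: Sequence[float] = DEFAULT_PANEL_FRACTIONS,
    scatter_sd: float = 0.0,
    seed: int = 0,
    nucleotide: str = "ATP",
    labels: Sequence[str] | None = None,
) -> ConstructPanel:
    """Panel of constructs on the linkage curve plus Gaussian dG_bind scatter.

    ``scatter_sd`` is in RT units of dG_bind (i.e. of ln Kd).  Every docked
    fraction must lie strictly inside (0, 1): the docking free energy
    diverges at the endpoints.
    """
    fracs = list(docked_fractions)
    for p in fracs:
        if not 0.0 < p < 1.0:
            raise ValueError(
                "docked fractions must lie strictly in (0,1); fully undocked "
                "states are handled by the linkage module's p_D=0 flag"
            )
    if labels is None:
        labels = [f"C{i + 1}" for i in range(len(fracs))]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, scatter_sd, len(fracs)) if scatter_sd > 0 else np.zeros(len(fracs))
    states = []
    for label, p, eps in zip(labels, fracs, noise):
        _ = docking_free_energy(p)  # validates and documents the x-coordinate
        ln_kd = np.log(ensemble_kd(params, p)) + eps
        states.append(
            ConstructState(
                construct=label, nucleotide=nucleotide, p_d=p, kd=float(np.exp(ln_kd))
            )
        )
    return ConstructPanel(states=states, truth=params, scatter_sd=scatter_sd, seed=seed)
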