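"""End-to-end orchestration: simulate -> quantify -> fit -> link -> report.

A run is driven by a single YAML config (unknown keys are rejected — typos
should fail loudly) plus a master seed.  Per-stage seeds are derived from the
master seed with ``numpy.random.SeedSequence`` so that identical config +
seed reproduces every artifact byte for byte.  All outputs land under the run
directory; no stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .grids import read_grid, write_grid
from .itc import (
    fit_result_to_json,
    fit_single_site,
    read_itc_csv,
    thermo_table,
    write_itc_csv,
)
from .linkage import (
    LinkageParameters,
    fit_state_constants,
    fit_to_json,
    plot_linkage,
    read_panel_csv,
    write_panel_csv,
)
from .nmr import (
    Peak,
    combined_csp,
    estimate_populations,
    exchange_timescale_bound,
    measure_peak_intensity,
    pair_doublets,
    read_sparky_list,
    write_population_report,
    write_sparky_list,
)
from .synthetic import (
    EnsembleGroundTruth,
    ITCGroundTruth,
    default_probes,
    generate_construct_panel,
    generate_itc_titration,
    generate_spectrum_pair,
)

logger = logging.getLogger("docklink")

__all__ = ["RunConfig", "load_config", "run_pipeline", "validate_inputs"]


class ConfigError(ValueError):
    pass


@dataclass
class SpectraConfig:
    docked_fraction: float = 0.53
    noise_sigma: float = 0.01
    offset_h_ppm: float = 0.03
    offset_c_ppm: float = 0.4


@dataclass
class ItcConfig:
    n: float = 1.0
    kd_uM: float = 0.80
    dH_kcal_mol: float = 11.4
    cell_conc_uM: float = 40.0
    syringe_conc_uM: float = 300.0
    cell_volume_uL: float = 200.0
    n_injections: int = 25
    injection_volume_uL: float = 1.5
    heat_noise_ucal: float = 0.05
    dilution_heat_ucal: float = 0.1
    construct: str = "BiP* FL (synthetic)"
    nucleotide: str = "ATP"


@dataclass
class PanelConfig:
    kd_D_uM: float = 1.5
    kd_U_uM: float = 7.0
    nucleotide: str = "ADP"
    docked_fractions: list[float] = field(
        default_factory=lambda: [0.02, 0.15, 0.4, 0.6, 0.85, 0.98]
    )
    scatter_sd: float = 0.3


@dataclass
class ToleranceConfig:
    match_ppm: float = 0.02
    doublet_window_ppm: float = 0.15
    search_radius_h_ppm: float = 0.02
    search_radius_c_ppm: float = 0.2

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigError(f"tolerance {name} must be positive")


@dataclass
class RunConfig:
    mode: str = "all"  # simulate | analyze | all
    seed: int = 0
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    itc: ItcConfig = field(default_factory=ItcConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    inputs_dir: str | None = None  # analyze-mode input directory
    make_plot: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "all"):
            raise ConfigError(f"mode must be simulate|analyze|all, got {self.mode!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")

    def canonical_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


_SECTION_TYPES = {
    "spectra": SpectraConfig,
    "itc": ItcConfig,
    "panel": PanelConfig,
    "tolerances": ToleranceConfig,
}
_TOP_KEYS = {"mode", "seed", "inputs_dir", "make_plot"} | set(_SECTION_TYPES)


def _build_section(cls: type, data: dict[str, Any], name: str) -> Any:
    known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; unknown keys anywhere are errors."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        data = raw
    if overrides:
        data = {**data, **overrides}
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    names = ["spectra", "itc", "panel"]
    seeds = {}
    for name, child in zip(names, ss.spawn(len(names))):
        seeds[name] = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    return seeds


def _spectra_truth(cfg: RunConfig, seed: int) -> EnsembleGroundTruth:
    s = cfg.spectra
    return EnsembleGroundTruth(
        docked_fraction=s.docked_fraction,
        probes=default_probes(offset_h=s.offset_h_ppm, offset_c=s.offset_c_ppm),
        noise_sigma=s.noise_sigma,
        seed=seed,
    )


def _itc_truth(cfg: RunConfig, seed: int) -> ITCGroundTruth:
    i = cfg.itc
    return ITCGroundTruth(
        n=i.n,
        kd=i.kd_uM * 1e-6,
        dh=i.dH_kcal_mol,
        cell_conc=i.cell_conc_uM * 1e-6,
        syringe_conc=i.syringe_conc_uM * 1e-6,
        cell_volume=i.cell_volume_uL * 1e-6,
        injection_volumes=np.full(i.n_injections, i.injection_volume_uL * 1e-6),
        heat_noise_sigma=i.heat_noise_ucal,
        dilution_heat=i.dilution_heat_ucal,
        seed=seed,
    )


def simulate_spectra_stage(cfg: RunConfig, outdir: Path, seed: int) -> dict[str, str]:
    """Write a synthetic spectrum pair, truth manifest and candidate peak lists."""
    inputs = outdir / "inputs"
    truth = _spectra_truth(cfg, seed)
    full, ref = generate_spectrum_pair(truth)
    write_grid(full, inputs / "full_length")
    write_grid(ref, inputs / "reference")
    truth.save_manifest(inputs / "spectra_truth.json")
    # candidate peak positions: the analysis stage measures and pairs these
    ref_peaks = [
        Peak(p.label, delta_h=p.delta_h, delta_c=p.delta_c, height=p.amplitude)
        for p in truth.probes
    ]
    fl_peaks = []
    for k, p in enumerate(truth.probes):
        fl_peaks.append(Peak(f"pk{2 * k + 1}", p.delta_h, p.delta_c, height=1.0))
        fl_peaks.append(
            Peak(
                f"pk{2 * k + 2}",
                p.delta_h + p.offset_h,
                p.delta_c + p.offset_c,
                height=1.0,
            )
        )
    write_sparky_list(ref_peaks, inputs / "reference.list")
    write_sparky_list(fl_peaks, inputs / "full_length.list")
    names = (
        "full_length.mat.txt", "full_length.json", "reference.mat.txt",
        "reference.json", "spectra_truth.json", "reference.list",
        "full_length.list",
    )
    logger.info("simulate-spectra: wrote %d files to %s", len(names), inputs)
    return {name: str(inputs / name) for name in names}


def simulate_itc_stage(cfg: RunConfig, outdir: Path, seed: int) -> dict[str, str]:
    """Write a synthetic injection-heat CSV and its ground-truth manifest."""
    inputs = outdir / "inputs"
    truth = _itc_truth(cfg, seed)
    titration = generate_itc_titration(truth)
    write_itc_csv(titration, inputs / "itc.csv")
    truth.save_manifest(inputs / "itc_truth.json")
    logger.info("simulate-itc: wrote titration to %s", inputs / "itc.csv")
    return {name: str(inputs / name) for name in ("itc.csv", "itc_truth.json")}


def simulate_panel_stage(cfg: RunConfig, outdir: Path, seed: int) -> dict[str, str]:
    """Write a synthetic construct panel CSV on a known linkage curve."""
    inputs = outdir / "inputs"
    p = cfg.panel
    panel = generate_construct_panel(
        LinkageParameters(kd_D=p.kd_D_uM * 1e-6, kd_U=p.kd_U_uM * 1e-6),
        docked_fractions=p.docked_fractions,
        scatter_sd=p.scatter_sd,
        seed=seed,
        nucleotide=p.nucleotide,
    )
    write_panel_csv(panel.states, inputs / "panel.csv")
    panel.save_manifest(inputs / "panel_truth.json")
    logger.info("simulate-panel: wrote panel to %s", inputs / "panel.csv")
    return {name: str(inputs / name) for name in ("panel.csv", "panel_truth.json")}


def simulate_stage(cfg: RunConfig, outdir: Path, seeds: dict[str, int]) -> dict[str, str]:
    """Generate all synthetic inputs under <outdir>/inputs, with manifests."""
    artifacts: dict[str, str] = {}
    artifacts.update(simulate_spectra_stage(cfg, outdir, seeds["spectra"]))
    artifacts.update(simulate_itc_stage(cfg, outdir, seeds["itc"]))
    artifacts.update(simulate_panel_stage(cfg, outdir, seeds["panel"]))
    return artifacts


def analyze_stage(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    """Quantify populations, fit the titration, fit the linkage; write reports."""
    inputs = Path(cfg.inputs_dir) if cfg.inputs_dir else outdir / "inputs"
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)
    tol = cfg.tolerances
    artifacts: dict[str, str] = {}

    # --- populations from spectra
    full = read_grid(inputs / "full_length")
    ref = read_grid(inputs / "reference")
    ref_list = read_sparky_list(inputs / "reference.list")
    fl_list = read_sparky_list(inputs / "full_length.list")
    radius = (tol.search_radius_h_ppm, tol.search_radius_c_ppm)
    ref_peaks = [
        measure_peak_intensity(ref, (p.delta_h, p.delta_c), radius, p.assignment)
        for p in ref_list
    ]
    fl_peaks = [
        measure_peak_intensity(full, (p.delta_h, p.delta_c), radius, p.assignment)
        for p in fl_list
    ]
    pairing = pair_doublets(
        fl_peaks,
        ref_peaks,
        match_tolerance=tol.match_ppm,
        doublet_window=tol.doublet_window_ppm,
    )
    if not pairing.doublets:
        raise RuntimeError("quantify: no doublets found (fully undocked input?)")
    noise_sigma = estimate_noise_sigma(full, fl_peaks)
    estimate = estimate_populations(pairing.doublets, noise_sigma=noise_sigma)
    write_population_report(
        estimate, pairing.doublets, results / "population_report.csv"
    )
    artifacts["population_report.csv"] = str(results / "population_report.csv")

    offsets = [
        combined_csp(d.d_peak, d.u_peak) for d in pairing.doublets if d.d_peak
    ]
    bound = exchange_timescale_bound(
        offsets, (full.h_axis.sfrq_MHz, full.c_axis.sfrq_MHz)
    )

    # --- ITC
    titration = read_itc_csv(inputs / "itc.csv")
    fit = fit_single_site(titration)
    fit_result_to_json(fit, results / "itc_fit.json")
    table = thermo_table([(cfg.itc.construct, cfg.itc.nucleotide, fit.thermo)])
    table.to_csv(results / "thermo_table.csv", index=False)
    artifacts["itc_fit.json"] = str(results / "itc_fit.json")
    artifacts["thermo_table.csv"] = str(results / "thermo_table.csv")

    # --- linkage
    states = read_panel_csv(inputs / "panel.csv")
    link_fit = fit_state_constants(states)
    fit_to_json(link_fit, results / "linkage.json")
    artifacts["linkage.json"] = str(results / "linkage.json")
    if cfg.make_plot:
        plot_linkage(
            {states[0].nucleotide: link_fit}, states, results / "linkage.png"
        )
        artifacts["linkage.png"] = str(results / "linkage.png")

    summary = {
        "p_d_percent": estimate.p_d,
        "p_d_error_percent": estimate.error,
        "n_doublets": estimate.n_doublets,
        "noise_sigma_estimate": noise_sigma,
        "exchange_tau_ms": bound.tau_s * 1e3,
        "exchange_tau_2pi_ms": bound.tau_2pi_s * 1e3,
        "itc_kd_uM": fit.thermo.kd * 1e6,
        "itc_dH_kcal_mol": fit.thermo.dH,
        "itc_dG_kcal_mol": fit.thermo.dG,
        "itc_minus_TdS_kcal_mol": fit.thermo.minus_TdS,
        "linkage_kd_D_uM": link_fit.params.kd_D * 1e6,
        "linkage_kd_U_uM": link_fit.params.kd_U * 1e6,
    }
    (results / "analysis_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    artifacts["analysis_summary.json"] = str(results / "analysis_summary.json")
    logger.info(
        "analyze: p_D = %.1f +/- %.1f %%, Kd = %.3g uM",
        estimate.p_d, estimate.error, fit.thermo.kd * 1e6,
    )
    return {"artifacts": artifacts, "summary": summary}


def estimate_noise_sigma(
    spectrum, peaks: list[Peak], exclude_radius: tuple[float, float] = (0.06, 0.6)
) -> float:
    """RMS amplitude of the signal-free region (nodes away from every peak)."""
    h = spectrum.h_axis.ppm_scale()
    c = spectrum.c_axis.ppm_scale()
    mask = np.ones(spectrum.data.shape, dtype=bool)
    for p in peaks:
        near_h = np.abs(h - p.delta_h) < exclude_radius[0]
        near_c = np.abs(c - p.delta_c) < exclude_radius[1]
        mask &= ~(near_c[:, None] & near_h[None, :])
    baseline = spectrum.data[mask]
    return float(np.sqrt(np.mean(baseline**2))) if baseline.size else 0.0


def run_pipeline(
    config: RunConfig, outdir: str | Path, seed: int | None = None
) -> dict[str, Any]:
    """Execute the configured stages; returns the run manifest dict.

    Any stage failure raises ``RuntimeError`` naming the stage; the manifest
    written so far is marked incomplete.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.seed = int(seed)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
        "artifacts": {},
        "complete": False,
    }
    manifest_path = outdir / "run_manifest.json"

    def _relativize(paths: dict[str, str]) -> dict[str, str]:
        out: dict[str, str] = {}
        for key, value in paths.items():
            p = Path(value)
            try:
                out[key] = str(p.relative_to(outdir))
            except ValueError:  # external inputs_dir: keep as given
                out[key] = value
        return out

    def _write_manifest() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    try:
        if config.mode in ("simulate", "all"):
            try:
                manifest["artifacts"].update(
                    _relativize(simulate_stage(config, outdir, seeds))
                )
                manifest["stages"].append("simulate")
            except Exception as exc:
                raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
        if config.mode in ("analyze", "all"):
            try:
                out = analyze_stage(config, outdir)
                manifest["artifacts"].update(_relativize(out["artifacts"]))
                manifest["summary"] = out["summary"]
                manifest["stages"].append("analyze")
            except Exception as exc:
                raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc
        manifest["complete"] = True
        _write_manifest()
    except Exception:
        _write_manifest()
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    message: str = ""


def validate_inputs(config: RunConfig, outdir: str | Path | None = None) -> list[ValidationCheck]:
    """Structured pass/fail checks on config and analyze-mode input files.

    Reports, never raises: every problem becomes a failed check.
    """
    checks: list[ValidationCheck] = []

    def check(name: str, passed: bool, message: str = "") -> None:
        checks.append(ValidationCheck(name=name, passed=bool(passed), message=message))

    s = config.spectra
    check("spectra.docked_fraction in [0,1]", 0.0 <= s.docked_fraction <= 1.0)
    check("spectra.noise_sigma >= 0", s.noise_sigma >= 0)
    i = config.itc
    check("itc concentrations positive", min(i.kd_uM, i.cell_conc_uM, i.syringe_conc_uM) > 0)
    check(
        "itc syringe exceeds cell concentration",
        i.syringe_conc_uM > i.cell_conc_uM,
        "titrant belongs in the syringe",
    )
    p = config.panel
    check("panel constants positive", min(p.kd_D_uM, p.kd_U_uM) > 0)
    check(
        "panel docked fractions in (0,1)",
        all(0.0 < f < 1.0 for f in p.docked_fractions),
    )

    if config.mode == "simulate":
        return checks

    inputs = (
        Path(config.inputs_dir)
        if config.inputs_dir
        else (Path(outdir) / "inputs" if outdir else None)
    )
    if inputs is None:
        check("inputs directory declared", False, "analyze mode needs inputs_dir or outdir")
        return checks
    check("inputs directory exists", inputs.is_dir(), str(inputs))
    if not inputs.is_dir():
        return checks

    for base in ("full_length", "reference"):
        hdr = inputs / f"{base}.json"
        mat = inputs / f"{base}.mat.txt"
        ok = hdr.exists() and mat.exists()
        check(f"spectrum files present: {base}", ok)
        if ok:
            try:
                grid = read_grid(inputs / base)
                sane = (
                    grid.h_axis.ppm_max < 15 and grid.c_axis.ppm_max < 250
                )  # ppm unit sanity
                check(f"spectrum header sane: {base}", sane)
            except Exception as exc:
                check(f"spectrum header sane: {base}", False, str(exc))

    for name in ("reference.list", "full_length.list"):
        path = inputs / name
        if not path.exists():
            check(f"peak list present: {name}", False)
            continue
        check(f"peak list present: {name}", True)
        try:
            peaks = read_sparky_list(path)
            labels = [pk.assignment for pk in peaks]
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            check(
                f"peak list labels unique: {name}",
                not dupes,
                f"duplicated assignment(s): {dupes}" if dupes else "",
            )
        except Exception as exc:
            check(f"peak list parses: {name}", False, str(exc))

    itc_path = inputs / "itc.csv"
    if not itc_path.exists():
        check("ITC CSV present", False)
    else:
        check("ITC CSV present", True)
        try:
            read_itc_csv(itc_path)
            check("ITC CSV parses", True)
        except ValueError as exc:
            check("ITC CSV parses", False, str(exc))

    panel_path = inputs / "panel.csv"
    if not panel_path.exists():
        check("panel CSV present", False)
    else:
        check("panel CSV present", True)
        try:
            states = read_panel_csv(panel_path)
            check(
                "every panel construct has a Kd",
                all(st.kd > 0 for st in states),
            )
        except ValueError as exc:
            check("panel CSV parses", False, str(exc))
    return checks
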