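"""Single-site isothermal titration calorimetry: forward model, fit, state functions.

The forward model reproduces the classic perfusion-cell (overfill) instrument
convention: each injection displaces cell liquid, so active concentrations are
diluted by ``(1 - dV/2V0)/(1 + dV/2V0)`` for the titrand and the injected
titrant accumulates as ``L_syr * (dV/V0)/(1 + dV/2V0)``, with ``dV`` the
cumulative injected volume.  Bound complex comes from the exact quadratic root
of single-site mass action with ``n`` identical sites per protein:

    PL = ((n*P_t + L_t + Kd) - sqrt((n*P_t + L_t + Kd)^2 - 4*n*P_t*L_t)) / 2

Cumulative heat is ``Q_i = V0 * dH * PL_i`` and the observed per-injection heat
carries the displaced-volume correction
``q_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2``.

State functions follow the standard identities at the 1 M standard state:
``dG = R*T*ln(Kd)`` and ``-T*dS = dG - dH`` (kcal/mol, R = 1.987e-3).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import lmfit

from .constants import R_KCAL, T_STANDARD

__all__ = [
    "ITCTitration",
    "BindingThermodynamics",
    "ITCFitResult",
    "singlesite_injection_heats",
    "fit_single_site",
    "derive_state_functions",
    "thermo_table",
    "recompute_state_functions",
    "write_itc_csv",
    "read_itc_csv",
]

KCAL_TO_UCAL = 1e9


@dataclass
class ITCTitration:
    """An injection-heat series with its cell/syringe metadata.

    Concentrations are molar (pre-titration for the cell), volumes in litres,
    heats in microcalories.  ``heats`` may be ``None`` for a bare schedule.
    """

    cell_conc: float
    syringe_conc: float
    cell_volume: float
    temperature: float
    injection_volumes: np.ndarray
    heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats and injection_volumes length mismatch")
            if not np.all(np.isfinite(self.heats)):
                raise ValueError("heats must be finite")
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and cell volume must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self, n_sites: float = 1.0) -> np.ndarray:
        """Cumulative titrant:site molar ratio after each injection."""
        pt, lt = perfusion_concentrations(self)
        return lt / (n_sites * pt)


@dataclass(frozen=True)
class BindingThermodynamics:
    """Fitted/derived single-site thermodynamic ledger for one titration."""

    n: float
    kd: float  # molar
    dG: float  # kcal/mol
    dH: float  # kcal/mol
    minus_TdS: float  # kcal/mol
    T: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        # -TdS = dG - dH is an exact identity, not an independent datum
        if not np.isclose(self.minus_TdS, self.dG - self.dH, atol=1e-9):
            raise ValueError("minus_TdS must equal dG - dH")


@dataclass
class ITCFitResult:
    thermo: BindingThermodynamics
    dilution_heat: float
    stderr: dict[str, float | None]
    residuals: np.ndarray
    c_value: float
    warnings: list[str] = field(default_factory=list)
    lmfit_result: object | None = None


def perfusion_concentrations(schedule: ITCTitration) -> tuple[np.ndarray, np.ndarray]:
    """Active cell concentrations (P_t, L_t) after each injection."""
    dv = schedule.injection_volumes
    v0 = schedule.cell_volume
    cum = np.cumsum(dv)
    f = cum / (2.0 * v0)
    p_t = schedule.cell_conc * (1.0 - f) / (1.0 + f)
    l_t = schedule.syringe_conc * (cum / v0) / (1.0 + f)
    return p_t, l_t


def singlesite_injection_heats(
    n: float, kd: float, dh: float, schedule: ITCTitration
) -> np.ndarray:
    """Model per-injection heats (µcal) for a single-site titration.

    Parameters
    ----------
    n : stoichiometry (sites per protein)
    kd : dissociation constant, molar
    dh : binding enthalpy, kcal/mol
    schedule : titration metadata; any ``heats`` present are ignored
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    p_t, l_t = perfusion_concentrations(schedule)
    sites = n * p_t
    b = sites + l_t + kd
    disc = b * b - 4.0 * sites * l_t
    if np.any(disc < 0):
        warnings.warn("negative discriminant clamped to zero", RuntimeWarning)
        disc = np.clip(disc, 0.0, None)
    pl = 0.5 * (b - np.sqrt(disc))
    v0 = schedule.cell_volume
    q_cum = v0 * dh * pl * KCAL_TO_UCAL
    q_prev = np.concatenate(([0.0], q_cum[:-1]))
    dv = schedule.injection_volumes
    return q_cum - q_prev + (dv / v0) * (q_cum + q_prev) / 2.0


def fit_single_site(
    data: ITCTitration,
    exclude_first: bool = True,
    fit_offset: bool = True,
    temperature: float | None = None,
) -> ITCFitResult:
    """Least-squares fit of (n, Kd, dH, dilution offset) to measured heats.

    The first injection is excluded by default (partial delivery during the
    equilibration delay is endemic to the instrument class).  Kd is optimised
    in log10 space, bounded to [1e-12, 1e-1] M.  Raises ``RuntimeError`` on
    non-convergence; a c-value (n*P0/Kd) outside [1, 1000] adds a
    "Kd poorly constrained" warning to the result.
    """
    if data.heats is None:
        raise ValueError("titration carries no measured heats")
    if data.n_injections < 5:
        raise ValueError("need at least 5 injections")
    keep = np.ones(data.n_injections, dtype=bool)
    if exclude_first:
        keep[0] = False
    if keep.sum() < 4:
        raise ValueError("too few usable injections after exclusion")

    heats = data.heats
    # initial guesses: n = 1; dH from the first retained injection per mole
    # injected; Kd at the cell protein concentration (c ~ 1 starting point)
    i0 = int(np.argmax(keep))
    moles0 = data.injection_volumes[i0] * data.syringe_conc
    dh0 = heats[i0] / (moles0 * KCAL_TO_UCAL) if moles0 > 0 else 1.0
    if dh0 == 0.0:
        dh0 = 1.0

    params = lmfit.Parameters()
    params.add("n", value=1.0, min=0.05, max=20.0)
    params.add("log10_kd", value=np.log10(data.cell_conc), min=-12.0, max=-1.0)
    params.add("dh", value=dh0)
    params.add("q_dil", value=0.0, vary=fit_offset)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = singlesite_injection_heats(
            p["n"].value, 10.0 ** p["log10_kd"].value, p["dh"].value, data
        )
        return (model + p["q_dil"].value - heats)[keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = lmfit.minimize(residual, params, method="leastsq", xtol=1e-14, ftol=1e-14)
    if not out.success:
        raise RuntimeError(
            f"single-site fit did not converge (residual norm "
            f"{np.linalg.norm(out.residual):.3g})"
        )

    n_fit = out.params["n"].value
    kd_fit = 10.0 ** out.params["log10_kd"].value
    dh_fit = out.params["dh"].value
    t = temperature if temperature is not None else data.temperature
    thermo = derive_state_functions(n_fit, kd_fit, dh_fit, t)

    c_value = n_fit * data.cell_conc / kd_fit
    warns: list[str] = []
    if not (1.0 <= c_value <= 1000.0):
        warns.append(
            f"Kd poorly constrained: c-value {c_value:.3g} outside [1, 1000]"
        )

    def _stderr(name: str) -> float | None:
        err = out.params[name].stderr
        return float(err) if err is not None else None

    log_err = _stderr("log10_kd")
    if log_err is None or log_err > 1.0:
        warns.append("Kd poorly constrained: log10(Kd) uncertainty exceeds a decade")
    stderr = {
        "n": _stderr("n"),
        "kd": (kd_fit * np.log(10.0) * log_err) if log_err is not None else None,
        "dh": _stderr("dh"),
        "q_dil": _stderr("q_dil"),
    }
    return ITCFitResult(
        thermo=thermo,
        dilution_heat=out.params["q_dil"].value,
        stderr=stderr,
        residuals=np.asarray(out.residual),
        c_value=c_value,
        warnings=warns,
        lmfit_result=out,
    )


def derive_state_functions(
    n: float, kd: float, dh: float, temperature: float = T_STANDARD
) -> BindingThermodynamics:
    """dG = R*T*ln(Kd / 1 M); -T*dS = dG - dH.  kcal/mol throughout."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature * np.log(kd)
    return BindingThermodynamics(
        n=n, kd=kd, dG=dg, dH=dh, minus_TdS=dg - dh, T=temperature
    )


def recompute_state_functions(
    kd_uM: float,
    dh: float,
    printed_dG: float | None = None,
    printed_minus_TdS: float | None = None,
    temperature: float = T_STANDARD,
    tol: float = 0.1,
) -> dict:
    """Re-derive dG and -TdS from a tabulated (Kd, dH) pair and flag mismatches.

    Returns recomputed values plus ``consistent_*`` booleans comparing against
    the printed values at ``tol`` kcal/mol (skipped when not supplied).
    """
    thermo = derive_state_functions(1.0, kd_uM * 1e-6, dh, temperature)
    out = {
        "kd_uM": kd_uM,
        "dH": dh,
        "dG_recomputed": thermo.dG,
        "minus_TdS_recomputed": thermo.minus_TdS,
    }
    if printed_dG is not None:
        out["dG_printed"] = printed_dG
        out["consistent_dG"] = bool(abs(printed_dG - thermo.dG) <= tol)
    if printed_minus_TdS is not None:
        out["minus_TdS_printed"] = printed_minus_TdS
        out["consistent_minus_TdS"] = bool(
            abs(printed_minus_TdS - thermo.minus_TdS) <= tol
        )
    return out


def thermo_table(
    entries: Sequence[tuple[str, str, BindingThermodynamics]]
) -> pd.DataFrame:
    """Presentation table (one row per construct x nucleotide).

    Kd in µM to 2 d.p., energies in kcal/mol to 1 d.p.; the -TdS = dG - dH
    identity is asserted on the full-precision values before rounding.
    Duplicate (construct, nucleotide) keys are rejected.
    """
    keys = [(c, a) for c, a, _ in entries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (construct, nucleotide) keys: {dupes}")
    rows = []
    for construct, anp, th in entries:
        assert abs(th.minus_TdS - (th.dG - th.dH)) < 1e-9
        rows.append(
            {
                "construct": construct,
                "ANP": anp,
                "Kd_uM": round(th.kd * 1e6, 2),
                "dG_kcal_mol": round(th.dG, 1),
                "dH_kcal_mol": round(th.dH, 1),
                "minus_TdS_kcal_mol": round(th.minus_TdS, 1),
            }
        )
    columns = [
        "construct", "ANP", "Kd_uM", "dG_kcal_mol", "dH_kcal_mol",
        "minus_TdS_kcal_mol",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# on-disk dialect: '#key=value' header lines, then 'injection_volume_uL,heat_ucal'

_HEADER_KEYS = {
    "cell_conc_M": "cell_conc",
    "syringe_conc_M": "syringe_conc",
    "cell_volume_L": "cell_volume",
    "temperature_K": "temperature",
}


def write_itc_csv(titration: ITCTitration, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(f"#cell_conc_M={titration.cell_conc!r}\n")
    buf.write(f"#syringe_conc_M={titration.syringe_conc!r}\n")
    buf.write(f"#cell_volume_L={titration.cell_volume!r}\n")
    buf.write(f"#temperature_K={titration.temperature!r}\n")
    buf.write("injection_volume_uL,heat_ucal\n")
    heats = titration.heats
    if heats is None:
        heats = np.full(titration.n_injections, np.nan)
    for dv, q in zip(titration.injection_volumes, heats):
        buf.write(f"{float(dv) * 1e6!r},{float(q)!r}\n")
    path.write_text(buf.getvalue())
    return path


def read_itc_csv(path: str | Path) -> ITCTitration:
    meta: dict[str, float] = {}
    volumes: list[float] = []
    heats: list[float] = []
    saw_column_row = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip().rstrip("\r")
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key in _HEADER_KEYS:
                    meta[_HEADER_KEYS[key]] = float(value)
            continue
        if line.lower().startswith("injection_volume"):
            saw_column_row = True
            continue
        parts = [p for p in line.split(",") if p != ""]
        volumes.append(float(parts[0]) * 1e-6)
        heats.append(float(parts[1]))
    missing = [k for k, v in _HEADER_KEYS.items() if v not in meta]
    if missing:
        raise ValueError(f"ITC CSV {path}: missing header key(s) {missing}")
    if not saw_column_row or not volumes:
        raise ValueError(f"ITC CSV {path}: no injection rows found")
    return ITCTitration(
        cell_conc=meta["cell_conc"],
        syringe_conc=meta["syringe_conc"],
        cell_volume=meta["cell_volume"],
        temperature=meta["temperature"],
        injection_volumes=np.array(volumes),
        heats=np.array(heats),
    )


def fit_result_to_json(result: ITCFitResult, path: str | Path) -> Path:
    """Full-precision JSON dump of a fit (presentation rounding lives in thermo_table)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "n": result.thermo.n,
        "kd_M": result.thermo.kd,
        "dG_kcal_mol": result.thermo.dG,
        "dH_kcal_mol": result.thermo.dH,
        "minus_TdS_kcal_mol": result.thermo.minus_TdS,
        "temperature_K": result.thermo.T,
        "dilution_heat_ucal": result.dilution_heat,
        "stderr": result.stderr,
        "c_value": result.c_value,
        "warnings": result.warnings,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
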