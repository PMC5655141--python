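"""Two-state thermodynamic linkage between domain docking and nucleotide binding.

An Hsp70 chaperone in solution is modelled as an ensemble of exactly two
conformations, domain-docked (D) and domain-undocked (U), with docked fraction
``p_D``.  Each pure conformation binds nucleotide with its own dissociation
constant, ``Kd_D`` and ``Kd_U``.  In reduced (RT) units:

    dG_dock / RT = -ln(p_D / (1 - p_D))
    dG_bind / RT =  ln(p_D * Kd_D + (1 - p_D) * Kd_U)

i.e. the observed dissociation constant is the population-weighted sum of the
pure-state constants.  Plotting dG_bind/RT against dG_dock/RT traces a
sigmoid running between the asymptotes ln(Kd_U) (fully undocked) and
ln(Kd_D) (fully docked); experimental constructs that shift the docking
equilibrium walk along this single curve if the two-state picture holds.

Fitting ``(Kd_D, Kd_U)`` to a panel of constructs is done by least squares in
log-Kd space (positivity and scale invariance for free).  Constructs with no
detectable docked population enter with p_D = 0: the binding equation, unlike
the docking free energy, is well defined there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ConstructState",
    "LinkageParameters",
    "LinkageFit",
    "docking_free_energy",
    "population_from_docking_energy",
    "ensemble_kd",
    "binding_free_energy",
    "theoretical_curve",
    "fit_state_constants",
    "write_panel_csv",
    "read_panel_csv",
    "plot_linkage",
]


@dataclass(frozen=True)
class LinkageParameters:
    """Pure-state dissociation constants (molar) for one nucleotide."""

    kd_D: float
    kd_U: float

    def __post_init__(self) -> None:
        if self.kd_D <= 0 or self.kd_U <= 0:
            raise ValueError("pure-state dissociation constants must be positive")


@dataclass
class ConstructState:
    """One (construct, nucleotide) point on the linkage plot.

    ``p_d`` is the docked fraction in the open interval (0, 1), or ``None``
    for a construct with no detectable docked population ("fully undocked",
    e.g. the ADP-bound wild-type spectrum that overlays the isolated domains).
    """

    construct: str
    nucleotide: str
    p_d: float | None
    kd: float  # observed dissociation constant, molar

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("observed Kd must be positive")
        if self.p_d is not None and not (0.0 < self.p_d < 1.0):
            raise ValueError(
                "p_d must lie strictly in (0,1); use p_d=None for a fully "
                "undocked construct"
            )

    @property
    def fully_undocked(self) -> bool:
        return self.p_d is None

    @property
    def dg_dock_rt(self) -> float | None:
        """Docking free energy in RT units; undefined for fully undocked states."""
        return None if self.p_d is None else docking_free_energy(self.p_d)

    @property
    def dg_bind_rt(self) -> float:
        return binding_free_energy(self.kd)


def docking_free_energy(p_d: float) -> float:
    """-ln(p_D/(1-p_D)) in RT units.  Requires p_D strictly inside (0, 1)."""
    if not 0.0 < p_d < 1.0:
        raise ValueError(
            "docking free energy diverges at p_d in {0,1}; flag such states "
            "as fully undocked/docked instead"
        )
    return -np.log(p_d / (1.0 - p_d))


def population_from_docking_energy(dg_rt: float) -> float:
    """Exact inverse of :func:`docking_free_energy`: p_D = 1/(1+exp(dG/RT))."""
    return 1.0 / (1.0 + np.exp(dg_rt))


def ensemble_kd(params: LinkageParameters, p_d: float) -> float:
    """Population-weighted observed Kd: p_D*Kd_D + (1-p_D)*Kd_U."""
    if not 0.0 <= p_d <= 1.0:
        raise ValueError("p_d must lie in [0, 1]")
    return p_d * params.kd_D + (1.0 - p_d) * params.kd_U


def binding_free_energy(kd: float) -> float:
    """ln(Kd / 1 M) — binding free energy in RT units."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return float(np.log(kd))


def theoretical_curve(
    params: LinkageParameters, docking_grid: Sequence[float]
) -> np.ndarray:
    """(dG_dock/RT, dG_bind/RT) pairs along the two-state linkage curve.

    Returns an array of shape (len(grid), 2).  As dG_dock/RT -> +inf the
    curve flattens at ln(Kd_U); as it -> -inf, at ln(Kd_D).
    """
    x = np.asarray(docking_grid, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("docking grid must be finite")
    p_d = 1.0 / (1.0 + np.exp(x))
    y = np.log(p_d * params.kd_D + (1.0 - p_d) * params.kd_U)
    return np.column_stack([x, y])


@dataclass
class LinkageFit:
    params: LinkageParameters
    residuals_rt: np.ndarray  # per construct, in ln-Kd (RT) units
    constructs: list[str]
    p_d_spread: float
    warnings: list[str] = field(default_factory=list)
    convention: str = "kd_sum"


def fit_state_constants(
    panel: Sequence[ConstructState],
    convention: str = "kd_sum",
) -> LinkageFit:
    """Fit (Kd_D, Kd_U) to one nucleotide's construct panel.

    Minimises sum of [ln Kd_obs - ln Kd_model]^2 over (ln Kd_D, ln Kd_U).
    ``convention="kd_sum"`` (default) weights dissociation constants, the
    model stated above; ``"affinity_sum"`` weights association constants
    (1/Kd_obs = p_D/Kd_D + p_U/Kd_U) and exists only for sensitivity
    analysis.  Raises on an unidentifiable panel (all p_D identical); warns
    when the p_D spread is below 0.2.
    """
    if convention not in ("kd_sum", "affinity_sum"):
        raise ValueError("convention must be 'kd_sum' or 'affinity_sum'")
    nucs = {s.nucleotide for s in panel}
    if len(nucs) > 1:
        raise ValueError(f"panel mixes nucleotides {sorted(nucs)}")
    p = np.array([0.0 if s.p_d is None else s.p_d for s in panel])
    ln_kd = np.array([np.log(s.kd) for s in panel])
    if len(panel) < 2 or np.allclose(p, p[0]):
        raise ValueError(
            "unidentifiable panel: need >= 2 states with distinct p_D"
        )
    spread = float(p.max() - p.min())
    warns: list[str] = []
    if spread < 0.2:
        msg = f"p_D spread {spread:.2f} < 0.2: pure-state constants weakly identified"
        warns.append(msg)
        warnings.warn(msg, RuntimeWarning)
    if convention == "affinity_sum":
        warns.append("non-default affinity-sum convention in use (sensitivity mode)")

    def model_ln_kd(ln_kd_d: float, ln_kd_u: float) -> np.ndarray:
        kd_d, kd_u = np.exp(ln_kd_d), np.exp(ln_kd_u)
        if convention == "kd_sum":
            return np.log(p * kd_d + (1.0 - p) * kd_u)
        return -np.log(p / kd_d + (1.0 - p) / kd_u)

    def residual(theta: np.ndarray) -> np.ndarray:
        return model_ln_kd(theta[0], theta[1]) - ln_kd

    # anchor the initial guess at the most docked / least docked observations
    x0 = np.array([ln_kd[np.argmax(p)], ln_kd[np.argmin(p)]])
    sol = least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError(f"linkage fit did not converge: {sol.message}")
    params = LinkageParameters(kd_D=float(np.exp(sol.x[0])), kd_U=float(np.exp(sol.x[1])))
    return LinkageFit(
        params=params,
        residuals_rt=sol.fun,
        constructs=[s.construct for s in panel],
        p_d_spread=spread,
        warnings=warns,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# panel I/O: construct,nucleotide,p_D_percent,Kd_uM  ('undocked' flags p_d=None)

def write_panel_csv(states: Sequence[ConstructState], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["construct,nucleotide,p_D_percent,Kd_uM"]
    for s in states:
        pd_field = "undocked" if s.p_d is None else repr(s.p_d * 100.0)
        lines.append(f"{s.construct},{s.nucleotide},{pd_field},{s.kd * 1e6!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_panel_csv(path: str | Path) -> list[ConstructState]:
    states: list[ConstructState] = []
    rows = [
        line.strip().rstrip("\r")
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    header = rows[0].split(",")
    expected = ["construct", "nucleotide", "p_D_percent", "Kd_uM"]
    if [h.strip() for h in header] != expected:
        raise ValueError(f"panel CSV {path}: expected columns {expected}")
    for row in rows[1:]:
        construct, nucleotide, pd_field, kd_field = [x.strip() for x in row.split(",")]
        p_d = None if pd_field.lower() == "undocked" else float(pd_field) / 100.0
        states.append(
            ConstructState(
                construct=construct,
                nucleotide=nucleotide,
                p_d=p_d,
                kd=float(kd_field) * 1e-6,
            )
        )
    return states


def fit_to_json(fit: LinkageFit, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "kd_D_M": fit.params.kd_D,
        "kd_U_M": fit.params.kd_U,
        "convention": fit.convention,
        "p_d_spread": fit.p_d_spread,
        "residuals_rt": {c: float(r) for c, r in zip(fit.constructs, fit.residuals_rt)},
        "warnings": fit.warnings,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def plot_linkage(
    fits: dict[str, LinkageFit],
    states: Sequence[ConstructState],
    path: str | Path,
    dg_dock_range: tuple[float, float] = (-6.0, 6.0),
) -> Path:
    """Curve-plus-points figure: dG_bind/RT vs dG_dock/RT per nucleotide."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"ATP": "tab:red", "ADP": "black"}
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.linspace(*dg_dock_range, 201)
    for nuc, fit in fits.items():
        curve = theoretical_curve(fit.params, x)
        ax.plot(curve[:, 0], curve[:, 1], color=colors.get(nuc, None), label=nuc)
    for s in states:
        if s.p_d is None:
            continue
        ax.plot(
            s.dg_dock_rt, s.dg_bind_rt, "o",
            color=colors.get(s.nucleotide, "grey"), mfc="none",
        )
    ax.set_xlabel(r"$\Delta G_\mathrm{docking}/RT$")
    ax.set_ylabel(r"$\Delta G_\mathrm{binding}/RT$")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
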