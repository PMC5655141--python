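"""Published BiP nucleotide-binding thermodynamics used as pipeline inputs.

One row per (construct, nucleotide): dissociation constant Kd (µM) and the
tabulated state functions dG, dH, -TdS (kcal/mol) at 298 K.  These are
experimental inputs to consistency checks and to the linkage analysis; the
package re-derives dG and -TdS from (Kd, dH) rather than trusting the
tabulated values (the NBD(1-417) rows are internally inconsistent at the
printed precision — see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TableRow", "BIP_THERMO_TABLE", "BIP_DOCKED_FRACTION_ATP"]


@dataclass(frozen=True)
class TableRow:
    construct: str
    nucleotide: str
    kd_uM: float
    dG: float
    dH: float
    minus_TdS: float


BIP_THERMO_TABLE: tuple[TableRow, ...] = (
    TableRow("BiP* FL", "ATP", 0.80, -8.3, 11.4, -19.7),
    TableRow("BiP* FL", "ADP", 5.73, -7.1, -7.4, 0.3),
    TableRow("BiP* NBD(1-413)", "ATP", 7.41, -7.0, 12.3, -19.3),
    TableRow("BiP* NBD(1-413)", "ADP", 5.27, -7.2, -7.4, 0.2),
    TableRow("BiP* NBD(1-417)", "ATP", 1.15, -8.1, 14.7, -22.3),
    TableRow("BiP* NBD(1-417)", "ADP", 3.94, -7.4, -6.4, 1.0),
)

#: ATP-bound full-length docked fraction measured by methyl NMR (53 +/- 6.6 %).
BIP_DOCKED_FRACTION_ATP: float = 0.53
BIP_DOCKED_FRACTION_ATP_ERR: float = 6.6  # percentage points

#: Reported best-fit pure-state dissociation constants (molar), per nucleotide.
FITTED_STATE_CONSTANTS = {
    "ATP": {"kd_U": 800e-9, "kd_D": 1e-9},
    "ADP": {"kd_U": 7e-6, "kd_D": 1.5e-6},
}
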