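"""Complexation bookkeeping over molecular-mechanics optimization outputs.

For a complex and its components, each with a final energy (kJ/mol),
solvation energy (kJ/mol) and dipole moment (Debye), this module computes
the per-property component sums and the complexation deltas
(complex minus sum). The MMFF94-type optimization that produces the
numbers is out of scope; the published values for chondroitin sulfate,
the L-Glu:L-Asp:L-Phe proteinoid and their complex ship as a reference
record set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "EnergeticsRecord",
    "REFERENCE_RECORDS",
    "complexation_deltas",
    "read_energetics_table",
]

_PROPERTIES = ("final_energy", "solvation_energy", "dipole_moment")


@dataclass(frozen=True)
class EnergeticsRecord:
    """One species: energies in kJ/mol, dipole in Debye."""

    species: str
    final_energy: float
    solvation_energy: float
    dipole_moment: float

    def __post_init__(self) -> None:
        import math

        for p in _PROPERTIES:
            if not math.isfinite(getattr(self, p)):
                raise ValueError(f"{p} must be finite")


# Published MMFF94(aq) optimization results for the CS-proteinoid system.
REFERENCE_RECORDS: dict[str, EnergeticsRecord] = {
    "chondroitin_sulfate": EnergeticsRecord(
        "chondroitin_sulfate", -58.02, -183.86, 4.190
    ),
    "proteinoid": EnergeticsRecord("proteinoid", -6.21, -163.01, 9.212),
    "cs_proteinoid_complex": EnergeticsRecord(
        "cs_proteinoid_complex", -137.18, -326.25, 18.880
    ),
}


def complexation_deltas(
    complex_record: EnergeticsRecord, components: Sequence[EnergeticsRecord]
) -> dict[str, dict[str, float]]:
    """Component sums and complex-minus-sum deltas per property.

    Returns ``{property: {"complex": c, "component_sum": s, "delta": c - s}}``
    for final energy, solvation energy and dipole moment. Deltas are
    reported signed, without interpretation: a negative final-energy delta
    means the complex is more stable than its parts.
    """
    if not components:
        raise ValueError("need at least one component")
    out: dict[str, dict[str, float]] = {}
    for p in _PROPERTIES:
        total = sum(getattr(r, p) for r in components)
        cval = getattr(complex_record, p)
        out[p] = {
            "complex": cval,
            "component_sum": round(total, 10),
            "delta": round(cval - total, 10),
        }
    return out


def read_energetics_table(path: str | Path) -> list[EnergeticsRecord]:
    """Read a CSV with columns species, final_energy_kJ_mol,
    solvation_energy_kJ_mol, dipole_D."""
    df = pd.read_csv(path)
    required = {"species", "final_energy_kJ_mol", "solvation_energy_kJ_mol", "dipole_D"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        EnergeticsRecord(
            species=str(row.species),
            final_energy=float(row.final_energy_kJ_mol),
            solvation_energy=float(row.solvation_energy_kJ_mol),
            dipole_moment=float(row.dipole_D),
        )
        for row in df.itertuples()
    ]
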