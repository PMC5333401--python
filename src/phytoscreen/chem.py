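"""Treatment bookkeeping: equilibrium dilution into the gel and screen summaries.

Compounds are dispensed into the liquid medium of a microtitre well and
diffuse into the gel of the Phytostrip well seated above it.  At
equilibrium the compound is distributed over the whole liquid + gel
volume, so the final ("theoretical") concentration follows from simple
mass balance:

    C_final = C_stock * V_aliquot / (V_aliquot + V_medium + V_gel)

The standard screen adds 1.5 ul of a 2.5 mM DMSO stock to 150 ul medium
over ~300 ul of effective gel volume, i.e. 3.75 nmol in 451.5 ul, an
8.3 uM final concentration and 0.33% DMSO.  All internal values are
unrounded; rounding happens only in the reporting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "TreatmentSpec",
    "ScreenSummary",
    "final_concentration",
    "final_concentration_from_well",
    "solvent_fraction",
    "hit_rate",
    "round_half_up",
    "concentration_table",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """One chemical treatment applied to a microtitre well.

    Volumes in microlitres; stock concentration in micromolar.
    ``effective_gel_volume_ul`` is the gel volume the compound equilibrates
    into; the default of 300 ul is the value consistent with the platform's
    standard dilution arithmetic (wells are filled with roughly 320 ul of
    molten gel, but some is lost to evaporation and the meniscus).
    """

    compound_id: str
    stock_concentration_uM: float
    aliquot_volume_ul: float
    medium_volume_ul: float = 150.0
    effective_gel_volume_ul: float = 300.0
    solvent: str = "DMSO"

    def __post_init__(self) -> None:
        if self.stock_concentration_uM < 0:
            raise ValueError("stock concentration must be >= 0")
        for name in ("aliquot_volume_ul", "medium_volume_ul", "effective_gel_volume_ul"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_volume_ul(self) -> float:
        return self.aliquot_volume_ul + self.medium_volume_ul + self.effective_gel_volume_ul


@dataclass(frozen=True)
class ScreenSummary:
    """Outcome counts of a phenotypic screen."""

    n_tested: int
    n_hits: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_hits <= self.n_tested:
            raise ValueError(
                f"need 0 <= n_hits <= n_tested, got {self.n_hits}/{self.n_tested}"
            )


def final_concentration(spec: TreatmentSpec) -> float:
    """Equilibrium concentration (uM) after diffusion into the gel.

    Total moles from the aliquot divided by the total equilibrated volume.
    Mass is conserved exactly: ``final * total_volume == stock * aliquot``.
    """
    total = spec.total_volume_ul
    if total <= 0:
        raise ValueError("total equilibrated volume must be positive")
    return spec.stock_concentration_uM * spec.aliquot_volume_ul / total


def final_concentration_from_well(
    well_concentration_uM: float,
    medium_volume_ul: float = 150.0,
    gel_volume_ul: float = 300.0,
) -> float:
    """Equilibrium concentration when the dose is quoted per microtitre well.

    Used when the aliquot is already mixed into the medium and the quoted
    number is the concentration in the ``medium_volume_ul`` of liquid:
    ``C_well * V_medium / (V_medium + V_gel)``.  A 25 uM well dose over
    300 ul gel gives 8.33 uM.
    """
    total = medium_volume_ul + gel_volume_ul
    if total <= 0:
        raise ValueError("total equilibrated volume must be positive")
    return well_concentration_uM * medium_volume_ul / total


def solvent_fraction(spec: TreatmentSpec) -> float:
    """Solvent content after equilibration, as a percentage of total volume."""
    total = spec.total_volume_ul
    if total <= 0:
        raise ValueError("total equilibrated volume must be positive")
    return 100.0 * spec.aliquot_volume_ul / total


def hit_rate(summary: ScreenSummary) -> float:
    """Hits as a percentage of compounds tested (unrounded)."""
    if summary.n_tested == 0:
        raise ValueError("hit rate undefined for an empty screen")
    return 100.0 * summary.n_hits / summary.n_tested


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Reporting-layer rounding with ties away from zero (70/800 -> 8.8%)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def concentration_table(treatments: pd.DataFrame) -> pd.DataFrame:
    """Compute final concentrations and solvent fractions for a treatment map.

    ``treatments`` needs columns ``compound_id``, ``stock_concentration_uM``
    and ``aliquot_volume_ul``; ``medium_volume_ul``, ``effective_gel_volume_ul``
    and ``solvent`` are optional and default per :class:`TreatmentSpec`.
    Returns a copy with ``final_concentration_uM`` and ``solvent_percent``
    columns appended (unrounded).
    """
    required = {"compound_id", "stock_concentration_uM", "aliquot_volume_ul"}
    missing = required - set(treatments.columns)
    if missing:
        raise ValueError(f"treatment map missing columns {sorted(missing)}")
    out = treatments.copy()
    finals = []
    solvents = []
    for row in out.itertuples(index=False):
        kwargs = {
            "compound_id": str(row.compound_id),
            "stock_concentration_uM": float(row.stock_concentration_uM),
            "aliquot_volume_ul": float(row.aliquot_volume_ul),
        }
        for opt in ("medium_volume_ul", "effective_gel_volume_ul", "solvent"):
            if hasattr(row, opt):
                kwargs[opt] = getattr(row, opt)
        spec = TreatmentSpec(**kwargs)
        finals.append(final_concentration(spec))
        solvents.append(solvent_fraction(spec))
    out["final_concentration_uM"] = finals
    out["solvent_percent"] = solvents
    return out
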