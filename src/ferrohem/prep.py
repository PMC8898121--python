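"""Solution-preparation arithmetic for ferrous sulfate working solutions.

The iron source is iron(II) sulfate heptahydrate, FeSO4·7H2O
(molar mass 278.01 g/mol).  A stock made from 20 mg in 1.0 ml of
water/PBS is 71.9 mM Fe2+; serial aliquot-into-diluent steps bring it to
the micromolar working range used for lysate and suspension exposure.

Volumes are treated as additive (no excess-volume correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ValidationError

#: Molar mass of FeSO4·7H2O in g/mol.
FESO4_7H2O_G_PER_MOL = 278.01


@dataclass(frozen=True)
class StockSpec:
    """A stock solution: solute mass dissolved in a solvent volume."""

    mass_mg: float
    volume_ml: float
    molar_mass_g_per_mol: float = FESO4_7H2O_G_PER_MOL

    def __post_init__(self):
        for name in ("mass_mg", "volume_ml", "molar_mass_g_per_mol"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"StockSpec.{name} must be > 0")


@dataclass(frozen=True)
class DilutionStep:
    """Transfer of an aliquot of the concentrated species into a diluent pool.

    ``aliquot_ul`` is the volume carrying the species; ``diluent_ul`` is the
    volume it is added to.  The concentration factor of the assembled volume
    is ``aliquot / (aliquot + diluent)``.
    """

    aliquot_ul: float
    diluent_ul: float

    def __post_init__(self):
        if not self.aliquot_ul > 0:
            raise ValidationError("DilutionStep.aliquot_ul must be > 0")
        if self.diluent_ul < 0:
            raise ValidationError("DilutionStep.diluent_ul must be >= 0")

    @property
    def factor(self) -> float:
        return self.aliquot_ul / (self.aliquot_ul + self.diluent_ul)


def stock_molarity(spec: StockSpec) -> float:
    """Stock concentration in mM: (mass/molar mass)/volume.

    >>> round(stock_molarity(StockSpec(20.0, 1.0)), 1)
    71.9
    """
    mmol = spec.mass_mg / spec.molar_mass_g_per_mol
    return mmol / spec.volume_ml * 1000.0  # mmol/ml -> mM ... (mmol/l)


def dilution_series(stock_mm: float, steps: Sequence[DilutionStep] | Iterable[DilutionStep]) -> float:
    """Concentration after a chain of dilution steps, in µM.

    Each step multiplies the concentration by ``aliquot/(aliquot+diluent)``.
    The exact arithmetic value is returned; rounding to a nominal label
    (e.g. "1700 µM") is the caller's concern.
    """
    if stock_mm < 0:
        raise ValidationError("stock_mm must be >= 0")
    steps = list(steps)
    if not steps:
        raise ValidationError("dilution_series needs at least one step")
    conc_um = stock_mm * 1000.0
    for step in steps:
        conc_um *= step.factor
    return conc_um
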