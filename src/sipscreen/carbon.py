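"""Microcosm carbon accounting.

Converts added polymer mass to millimoles of carbon, expresses produced
total inorganic carbon (TIC) as a percentage of carbon added, corrects
treatment TIC for background respiration, pools treatment means, and
compares two treatments with a t-test computed from summary statistics
(mean, SD, n) alone.

Polysaccharide carbon is counted on the anhydro-sugar residue: a glucan
(starch or cellulose) monomer unit is C6H10O5, 162.14 g/mol at natural
isotope abundance, 6 carbons — so 150 mg of glucan carries
6 * 0.150 / 162.14 mol = 5.55 mmol C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from scipy import stats

from .errors import ValidationError

__all__ = [
    "ANHYDROHEXOSE_MASS_G_MOL",
    "PolymerSpec",
    "TreatmentSummary",
    "TTestResult",
    "polymer_carbon_mmol",
    "percent_mineralized",
    "net_tic_increase",
    "pooled_mean",
    "welch_t_from_summary",
]

#: Anhydroglucose residue mass (C6H10O5) at natural isotope abundance, g/mol.
ANHYDROHEXOSE_MASS_G_MOL = 162.14


@dataclass(frozen=True)
class PolymerSpec:
    """A polysaccharide addition: mass and monomer stoichiometry."""

    mass_mg: float
    monomer_mass_g_mol: float = ANHYDROHEXOSE_MASS_G_MOL
    carbons_per_monomer: int = 6

    def __post_init__(self) -> None:
        if self.mass_mg < 0:
            raise ValidationError("polymer mass must be non-negative")
        if self.monomer_mass_g_mol <= 0 or self.carbons_per_monomer <= 0:
            raise ValidationError("monomer mass and carbon count must be positive")


@dataclass(frozen=True)
class TreatmentSummary:
    """Summary statistics of TIC production for one treatment."""

    treatment: str
    mean_mmol: float
    sd_mmol: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_mmol < 0:
            raise ValidationError("SD must be non-negative")
        if self.n < 1:
            raise ValidationError("replicate count must be at least 1")


class TTestResult(NamedTuple):
    statistic: float
    df: float
    p_value: float


def polymer_carbon_mmol(spec: PolymerSpec) -> float:
    """Millimoles of carbon in the added polymer.

    carbons_per_monomer * mass(g) / monomer_mass(g/mol) * 1000.
    """
    return spec.carbons_per_monomer * (spec.mass_mg / 1000.0) / spec.monomer_mass_g_mol * 1000.0


def percent_mineralized(tic_produced_mmol: float, carbon_added_mmol: float) -> float:
    """Produced TIC as a percentage of the carbon added."""
    if carbon_added_mmol <= 0:
        raise ValidationError("carbon_added must be positive")
    if tic_produced_mmol < 0:
        raise ValidationError("tic_produced must be non-negative")
    return 100.0 * tic_produced_mmol / carbon_added_mmol


def net_tic_increase(background_mean_mmol: float, treatment_mean_mmol: float) -> float:
    """Background-corrected TIC increase (may be negative)."""
    return treatment_mean_mmol - background_mean_mmol


def pooled_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of treatment means."""
    values = list(values)
    if not values:
        raise ValidationError("cannot pool an empty list of means")
    return sum(values) / len(values)


def welch_t_from_summary(
    a: TreatmentSummary, b: TreatmentSummary, equal_var: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test from summary statistics.

    Default is Welch's unequal-variance form:
    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom. ``equal_var=True`` gives the
    pooled-variance Student form with df = n_a + n_b - 2.
    """
    for s in (a, b):
        if s.n < 2:
            raise ValidationError(
                f"treatment {s.treatment!r} needs n >= 2 for a t-test (got {s.n})"
            )
    if a.sd_mmol == 0 and b.sd_mmol == 0:
        if a.mean_mmol == b.mean_mmol:
            return TTestResult(0.0, float(a.n + b.n - 2), 1.0)
        raise ValidationError("both SDs are zero with unequal means; t undefined")
    va, vb = a.sd_mmol**2 / a.n, b.sd_mmol**2 / b.n
    if equal_var:
        sp2 = ((a.n - 1) * a.sd_mmol**2 + (b.n - 1) * b.sd_mmol**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    else:
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean_mmol - b.mean_mmol) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0))
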