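"""VFA stoichiometry and metabolic-hydrogen balance.

Rumen fermentation of hexose releases reducing equivalents ("metabolic
hydrogen", [2H]) that are captured by propionate, butyrate, valerate and
methanogenesis.  Classical fermentation-balance stoichiometry expresses
both the hexose fermented (FOM) and the [2H] ledger as linear
combinations of the molar yields of the individual volatile fatty acids
(Ac = acetate, Pr = propionate, But = butyrate, Val = valerate, all in
mmol; iso-acids arise from amino-acid fermentation and are excluded):

    FOM              = 0.5 Ac + 0.5 Pr + But + Val        (mmol hexose)
    [2H] produced    = 2 Ac + Pr + 4 But + 3 Val          (mmol)
    [2H] incorporated = 2 Pr + 2 But + 4 Val + 4 CH4      (mmol)
    [2H] recovery    = 100 x incorporated / produced      (%)

Each mole of methane consumes 4 H2 (CO2 + 4 H2 -> CH4 + 2 H2O), hence
the coefficient of 4 on CH4 (exposed as :data:`CH4_H_COEFFICIENT`).

Redox readings taken against an Ag/AgCl reference electrode are reported
relative to the standard hydrogen electrode by adding the reference
offset (+198 mV at 39 degC): Eh = E0 + C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .exceptions import UndefinedResultError, ValidationError

#: Moles of H equivalents consumed per mole of CH4 (4 H2 per CH4).
CH4_H_COEFFICIENT = 4.0

#: Anhydro-hexose monomer mass, mg/mmol (C6H10O5 as polymerised in
#: structural carbohydrate).
HEXOSE_MONOMER_MG_MMOL = 162.0

#: Default Rusitec/batch vessel liquid volume (L) used to convert
#: concentrations (mM) to amounts (mmol) in batch mode.
DEFAULT_VESSEL_VOLUME_L = 0.05

#: Ag/AgCl reference-electrode potential vs. the standard hydrogen
#: electrode at 39 degC (mV).
AGCL_OFFSET_MV_39C = 198.0

_ACIDS = ("acetate", "propionate", "butyrate",
          "isobutyrate", "valerate", "isovalerate")


@dataclass(frozen=True)
class VFAProfile:
    """Per-sample amounts of the six measured volatile fatty acids.

    Amounts are mmol/d in ``outflow`` mode (daily effluent flows) or mmol
    in ``batch`` mode (concentration mM x vessel liquid volume L).
    """

    acetate: float
    propionate: float
    butyrate: float
    isobutyrate: float = 0.0
    valerate: float = 0.0
    isovalerate: float = 0.0
    mode: str = "outflow"

    def __post_init__(self):
        for name in _ACIDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} amount must be finite and >= 0, got {v!r}")
        if self.mode not in ("outflow", "batch"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def total(self) -> float:
        """Total VFA (sum of all six acids)."""
        return sum(getattr(self, a) for a in _ACIDS)

    @property
    def molar_proportions(self) -> dict[str, float]:
        """Molar proportion of each acid (fractions summing to 1)."""
        tot = self.total
        if tot == 0:
            raise UndefinedResultError("all-zero profile has no proportions")
        return {a: getattr(self, a) / tot for a in _ACIDS}

    @classmethod
    def from_concentrations(cls, volume_l: float = DEFAULT_VESSEL_VOLUME_L,
                            **mm: float) -> "VFAProfile":
        """Build a batch-mode profile from concentrations in mM."""
        if volume_l <= 0:
            raise ValidationError("vessel volume must be > 0")
        amounts = {k: v * volume_l for k, v in mm.items()}
        return cls(mode="batch", **amounts)


@dataclass(frozen=True)
class HydrogenBalance:
    """Metabolic-hydrogen budget of one sample."""

    h_produced: float
    h_incorporated: float
    recovery: float
    ch4_vfa_ratio: float


@dataclass(frozen=True)
class FermentationSummary:
    """Stoichiometric summary of one sample's fermentation."""

    fom_hexose: float
    fom_mass: float
    methane: float
    degraded_om: float
    methane_yield: float


@dataclass(frozen=True)
class RedoxReading:
    """A platinum-electrode reading and its reference correction."""

    electrode_mv: float
    reference_offset_mv: float = AGCL_OFFSET_MV_39C
    corrected_eh_mv: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "corrected_eh_mv",
                           self.electrode_mv + self.reference_offset_mv)


def compute_fom(vfa: VFAProfile) -> float:
    """Fermentable organic matter as hexose equivalents (mmol).

    FOM = 0.5 Ac + 0.5 Pr + But + Val; iso-acids are excluded because
    they derive from protein, not carbohydrate, fermentation.
    """
    return (0.5 * vfa.acetate + 0.5 * vfa.propionate
            + vfa.butyrate + vfa.valerate)


def fom_mass(fom_hexose: float,
             monomer_mass: float = HEXOSE_MONOMER_MG_MMOL) -> float:
    """Convert hexose equivalents (mmol) to mass (mg)."""
    if fom_hexose < 0:
        raise ValidationError("fom_hexose must be >= 0")
    return fom_hexose * monomer_mass


def hydrogen_produced(vfa: VFAProfile) -> float:
    """Metabolic hydrogen released by VFA formation: 2Ac + Pr + 4But + 3Val."""
    return (2.0 * vfa.acetate + vfa.propionate
            + 4.0 * vfa.butyrate + 3.0 * vfa.valerate)


def hydrogen_incorporated(vfa: VFAProfile, methane: float,
                          ch4_coefficient: float = CH4_H_COEFFICIENT) -> float:
    """Metabolic hydrogen captured in sinks: 2Pr + 2But + 4Val + 4CH4."""
    if not math.isfinite(methane) or methane < 0:
        raise ValidationError("methane must be finite and >= 0")
    return (2.0 * vfa.propionate + 2.0 * vfa.butyrate
            + 4.0 * vfa.valerate + ch4_coefficient * methane)


def hydrogen_recovery(produced: float, incorporated: float) -> float:
    """Percentage of produced hydrogen accounted for by the sinks."""
    if produced <= 0:
        raise UndefinedResultError("hydrogen recovery undefined: produced <= 0")
    return 100.0 * incorporated / produced


def ch4_vfa_ratio(methane: float, total_vfa: float) -> float:
    """Methane per unit total VFA (mol/mol)."""
    if total_vfa <= 0:
        raise UndefinedResultError("CH4:VFA undefined: total VFA <= 0")
    return methane / total_vfa


def hydrogen_balance(vfa: VFAProfile, methane: float,
                     ch4_coefficient: float = CH4_H_COEFFICIENT
                     ) -> HydrogenBalance:
    """Full metabolic-hydrogen budget for one sample."""
    prod = hydrogen_produced(vfa)
    inc = hydrogen_incorporated(vfa, methane, ch4_coefficient)
    return HydrogenBalance(
        h_produced=prod,
        h_incorporated=inc,
        recovery=hydrogen_recovery(prod, inc),
        ch4_vfa_ratio=ch4_vfa_ratio(methane, vfa.total),
    )


def degraded_om(dm_intake: float, diet_om_fraction: float,
                om_disappearance: float) -> float:
    """Degraded organic matter (g/d) = intake x OM content x disappearance."""
    for name, v in (("dm_intake", dm_intake),
                    ("diet_om_fraction", diet_om_fraction),
                    ("om_disappearance", om_disappearance)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    for name, v in (("diet_om_fraction", diet_om_fraction),
                    ("om_disappearance", om_disappearance)):
        if v > 1:
            raise ValidationError(f"{name} is a fraction and must be <= 1")
    return dm_intake * diet_om_fraction * om_disappearance


def diet_om_fraction(forage_om_pct: float, concentrate_om_pct: float,
                     forage_fraction: float = 0.8) -> float:
    """Intake-weighted diet OM content as a fraction of DM."""
    if not 0 <= forage_fraction <= 1:
        raise ValidationError("forage_fraction must be in [0, 1]")
    pct = (forage_fraction * forage_om_pct
           + (1.0 - forage_fraction) * concentrate_om_pct)
    return pct / 100.0


def methane_yield(methane: float, degraded_om_g_d: float) -> float:
    """Methane per gram of degraded OM (mmol/g)."""
    if degraded_om_g_d <= 0:
        raise UndefinedResultError("methane yield undefined: degraded OM <= 0")
    return methane / degraded_om_g_d


def correct_redox(reading: RedoxReading) -> float:
    """Eh (mV vs. standard hydrogen electrode) = E0 + reference offset."""
    return reading.corrected_eh_mv


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero to ``decimals`` places, as printed tables do."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def scale(vfa: VFAProfile, k: float) -> VFAProfile:
    """Scale every acid amount by ``k`` (stoichiometry is degree-1)."""
    if k < 0:
        raise ValidationError("scale factor must be >= 0")
    return replace(vfa, **{a: getattr(vfa, a) * k for a in _ACIDS})
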