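"""pH-dependent acid–base speciation of coformers and the API.

At the pH of a solubility experiment only the neutral (non-dissociated)
forms of a carboxylic acid and of the API participate in complex
formation, so the quantity of interest here is the availability of the
neutral species: its effective initial concentration times the neutral
fraction, reported as a negative decadic logarithm (a "p-value").

Two ionized-fraction formulas are provided for diprotic acids.  The
default ("printed") mode is

    alpha = 1 / (1 + 10^(pKa1 + pKa2 - 2 pH) + 10^(pKa1 - pH))

while the "textbook" mode replaces the last exponent's pKa1 with pKa2,
which makes alpha exactly the mass-action fraction of the fully
deprotonated dianion.  Both are exposed; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "Protolyte",
    "Conditions",
    "NeutralAvailability",
    "ionized_fraction_monoprotic",
    "ionized_fraction_diprotic",
    "neutral_availability",
]

DiproticMode = Literal["printed", "textbook"]
ConcentrationUnit = Literal["mg_ml", "molar"]


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class Protolyte:
    """An ionizable species: a carboxylic-acid coformer or the API itself.

    Parameters
    ----------
    name : str
        Species label, used in reports and exclusion lists.
    proticity : int
        Number of dissociation stages considered, 1 or 2.
    pka1 : float
        First (or only) dissociation constant, -log10 scale.
    pka2 : float, optional
        Second dissociation constant; required iff ``proticity == 2``
        and must exceed ``pka1``.
    c0 : float
        Initial (nominal) concentration in mg·ml⁻¹.
    molar_mass : float, optional
        g·mol⁻¹; needed only for the molar concentration mode.
    solubility_limit : float, optional
        Aqueous solubility in mg·ml⁻¹.  When the nominal concentration
        exceeds it the solution is saturated and the limit replaces c0.
    """

    name: str
    proticity: int
    pka1: float
    c0: float
    pka2: Optional[float] = None
    molar_mass: Optional[float] = None
    solubility_limit: Optional[float] = None

    def __post_init__(self) -> None:
        if self.proticity not in (1, 2):
            raise ValueError(f"proticity must be 1 or 2, got {self.proticity}")
        if (self.pka2 is not None) != (self.proticity == 2):
            raise ValueError("pka2 must be given iff proticity == 2")
        if self.proticity == 2 and self.pka2 <= self.pka1:  # type: ignore[operator]
            raise ValueError(
                f"pka2 ({self.pka2}) must exceed pka1 ({self.pka1})"
            )
        if not self.c0 > 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if self.solubility_limit is not None and not self.solubility_limit > 0:
            raise ValueError(
                f"solubility_limit must be positive, got {self.solubility_limit}"
            )


@dataclass(frozen=True)
class Conditions:
    """Solution conditions: pH and absolute temperature.

    Defaults are the reference experimental conditions, pH 6.5 and
    normal body temperature (310.15 K).
    """

    ph: float = 6.5
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"ph must lie in [0, 14], got {self.ph}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class NeutralAvailability:
    """Availability of the neutral form of one species at fixed conditions.

    ``p_value`` is -log10(effective_c0 · neutral_fraction), the quantity
    summed over API and acid to form the pH correction p-beta.
    """

    species: str
    alpha: float
    neutral_fraction: float
    effective_c0: float
    p_value: float


def ionized_fraction_monoprotic(pka: float, ph: float) -> float:
    """Ionized share of a monoprotic acid, 1 / (1 + 10^(pKa - pH)).

    Strictly increasing in pH; equals 0.5 at pH == pKa.
    """
    _require_finite(pka=pka, ph=ph)
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def ionized_fraction_diprotic(
    pka1: float,
    pka2: float,
    ph: float,
    mode: DiproticMode = "printed",
) -> float:
    """Ionized share of a diprotic acid, accounting for both stages.

    ``mode="printed"`` evaluates
    1 / (1 + 10^(pKa1 + pKa2 - 2 pH) + 10^(pKa1 - pH));
    ``mode="textbook"`` uses 10^(pKa2 - pH) in the last term, which is
    exactly the dianion fraction of standard mass-action speciation.
    """
    _require_finite(pka1=pka1, pka2=pka2, ph=ph)
    if pka2 <= pka1:
        raise ValueError(f"pka2 ({pka2}) must exceed pka1 ({pka1})")
    if mode not in ("printed", "textbook"):
        raise ValueError(f"unknown diprotic mode: {mode!r}")
    last = pka1 if mode == "printed" else pka2
    return 1.0 / (1.0 + 10.0 ** (pka1 + pka2 - 2.0 * ph) + 10.0 ** (last - ph))


def neutral_availability(
    species: Protolyte,
    cond: Conditions,
    *,
    concentration_unit: ConcentrationUnit = "mg_ml",
    diprotic_mode: DiproticMode = "printed",
) -> NeutralAvailability:
    """Availability of the neutral form of ``species`` at ``cond``.

    The nominal concentration is clamped at the solubility limit when
    one is given (a saturated suspension cannot deliver more dissolved
    material than the solubility allows).  In ``molar`` mode the
    clamped concentration is converted from mg·ml⁻¹ (== g·L⁻¹) to
    mol·L⁻¹ using the molar mass.

    An alpha that rounds to exactly 1 in floating point yields an
    infinite p_value with a warning rather than an exception.
    """
    if species.proticity == 1:
        alpha = ionized_fraction_monoprotic(species.pka1, cond.ph)
    else:
        alpha = ionized_fraction_diprotic(
            species.pka1, species.pka2, cond.ph, mode=diprotic_mode  # type: ignore[arg-type]
        )
    neutral = 1.0 - alpha

    effective_c0 = species.c0
    if species.solubility_limit is not None:
        effective_c0 = min(effective_c0, species.solubility_limit)

    if concentration_unit == "molar":
        if species.molar_mass is None:
            raise ValueError(
                f"molar mode requires molar_mass for species {species.name!r}"
            )
        conc = effective_c0 / species.molar_mass  # g/L over g/mol -> mol/L
    elif concentration_unit == "mg_ml":
        conc = effective_c0
    else:
        raise ValueError(f"unknown concentration unit: {concentration_unit!r}")

    if neutral <= 0.0:
        warnings.warn(
            f"species {species.name!r} is fully ionized at pH {cond.ph}; "
            "p_value is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        p_value = math.inf
    else:
        p_value = -math.log10(conc * neutral)

    return NeutralAvailability(
        species=species.name,
        alpha=alpha,
        neutral_fraction=neutral,
        effective_c0=effective_c0,
        p_value=p_value,
    )
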