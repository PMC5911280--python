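"""Complexation equilibria: free energies to pK_r, pAM assembly, SA.

The chain implemented here converts a COSMO-RS-style pairwise
complexation free energy ΔG_r into the reaction exponent
pK_r = ΔG_r / (RT ln 10), adds the pH/concentration correction pβ
(the sum of the two neutral-availability p-values), and produces

    pAM = binding_events · pK_r + pβ

the negative decadic log of the estimated API–acid complex
concentration.  Monocarboxylic acids bind one API molecule per acid
(one binding event); dicarboxylic acids bridge two API molecules in a
[-MAM-]n motif, and free-energy additivity of the two heterosynthons
makes that two binding events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .speciation import NeutralAvailability, Protolyte

__all__ = [
    "GAS_CONSTANT_KCAL",
    "Stoichiometry",
    "ComplexationRecord",
    "pkr_from_gibbs",
    "p_beta",
    "complex_exponent",
    "solubility_advantage",
    "superstructure_gibbs",
    "dimerization_exponent",
]

# kcal·mol⁻¹·K⁻¹, matching free energies tabulated in kcal/mol
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class Stoichiometry:
    """Counts in the repeating API–acid motif.

    ``binding_events`` is the number of pairwise heterosynthon
    formation steps: 1 for a mono-acid 1:1 pair, 2 for the [-MAM-]n
    motif of a dicarboxylic acid bridging two API molecules.
    """

    n_api: int
    n_acid: int
    binding_events: int

    def __post_init__(self) -> None:
        if min(self.n_api, self.n_acid, self.binding_events) < 1:
            raise ValueError("all stoichiometry counts must be >= 1")
        if self.binding_events > self.n_api + self.n_acid - 1:
            raise ValueError(
                "binding_events cannot exceed n_api + n_acid - 1 "
                "(a connected motif)"
            )

    @classmethod
    def mono(cls) -> "Stoichiometry":
        return cls(n_api=1, n_acid=1, binding_events=1)

    @classmethod
    def di(cls) -> "Stoichiometry":
        return cls(n_api=2, n_acid=1, binding_events=2)

    @classmethod
    def for_acid_class(cls, acid_class: str) -> "Stoichiometry":
        if acid_class == "mono":
            return cls.mono()
        if acid_class == "di":
            return cls.di()
        raise ValueError(f"no stoichiometry rule for acid class {acid_class!r}")


@dataclass(frozen=True)
class ComplexationRecord:
    """Derived equilibrium quantities for one API–coformer system."""

    coformer: Protolyte
    dg_r: float
    pk_r: float
    p_beta: float
    p_am: float
    stoich: Stoichiometry


def pkr_from_gibbs(dg_r: float, temperature: float) -> float:
    """Reaction exponent pK_r = ΔG_r / (ln 10 · R · T).

    Negative for spontaneous (ΔG_r < 0) complexation; linear in ΔG_r
    and proportional to 1/T.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return dg_r / (math.log(10.0) * GAS_CONSTANT_KCAL * temperature)


def p_beta(api_avail: NeutralAvailability, acid_avail: NeutralAvailability) -> float:
    """pH correction pβ = -log10(c_A°(1-α_A) · c_M°(1-α_M)).

    Equal to the sum of the two species p-values; both must have been
    computed under the same conditions and concentration unit.
    """
    total = api_avail.p_value + acid_avail.p_value
    if math.isinf(total):
        warnings.warn(
            "infinite availability p_value propagates to infinite p_beta",
            RuntimeWarning,
            stacklevel=2,
        )
    return total


def complex_exponent(pk_r: float, p_beta: float, stoich: Stoichiometry) -> float:
    """pAM = binding_events · pK_r + pβ.

    Lower pAM means a higher estimated complex concentration.  With one
    binding event this is the plain mono-acid relation; with two it
    realizes the dicarboxylic [-MAM-]n motif via free-energy additivity.
    """
    return stoich.binding_events * pk_r + p_beta


def solubility_advantage(s_cc: float, s_api: float) -> float:
    """SA = log10(S_cc / S_api); positive iff the cocrystal dissolves better."""
    if not (s_cc > 0 and s_api > 0):
        raise ValueError(
            f"solubilities must be positive, got s_cc={s_cc}, s_api={s_api}"
        )
    return math.log10(s_cc / s_api)


def superstructure_gibbs(pair_energies: Sequence[float]) -> float:
    """Total ΔG of a multi-pair motif as the sum of its pairwise energies.

    Free energies of the [-MAM-]n / [-MAAM-]n superstructures are close
    to additive over their constituent heterosynthon pairs, so the sum
    of pair energies is the composition rule.
    """
    if len(pair_energies) == 0:
        raise ValueError("pair_energies must be non-empty")
    return float(sum(pair_energies))


def dimerization_exponent(
    dg_dimer: float,
    api_avail: Optional[NeutralAvailability],
    temperature: float,
) -> float:
    """Exponent for API self-dimerization: pK_r(dimer) + 2 · pM.

    Two neutral API monomers are consumed per dimer, hence the doubled
    availability term.  This composition is a model reconstruction (the
    dimer is bookkept like a complexation with the API as its own
    partner); pass ``api_avail=None`` to obtain the bare pK_r part.
    """
    pk = pkr_from_gibbs(dg_dimer, temperature)
    if api_avail is None:
        return pk
    return pk + 2.0 * api_avail.p_value
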