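"""Seeded generator of synthetic coformer studies.

Emulates the statistical structure the analysis assumes: coformer pKa
and complexation free energies drawn over realistic ranges, the complex
exponent pAM computed through the real speciation and equilibria code,
and an experimental solubility advantage generated as a class-dependent
linear function of pAM plus Gaussian noise — a positive slope for
monocarboxylic acids and a negative one for dicarboxylic acids, the
opposite-trend structure observed for the two cocrystallization
mechanisms.  Measured solubility is back-filled as S = S_API · 10^SA.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; identical (seed, params) regenerate the
study bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from . import equilibria, speciation
from .dataset import CoformerTableRow

__all__ = ["GeneratingParams", "SyntheticStudy", "generate_study", "API_DEFAULT"]

# reference API: meloxicam-like monoprotic acid, saturated at 0.1 mg/ml
API_DEFAULT = speciation.Protolyte(
    name="Synthetic API", proticity=1, pka1=4.18, c0=0.1
)


@dataclass(frozen=True)
class GeneratingParams:
    """Generating distribution of a synthetic study.

    Defaults mirror the reference study conditions: pH 6.5, 310.15 K,
    coformer nominal concentration 0.5 mg·ml⁻¹, API solubility
    0.17 mg·ml⁻¹; pKa and ΔG_r ranges bracket the observed coformer
    set (pKa 1.91–6.33, ΔG_r −9.72 to −4.59 kcal·mol⁻¹).
    """

    n_mono: int = 50
    n_di: int = 50
    slope_mono: float = 0.3
    slope_di: float = -0.2
    intercept_mono: float = 0.3
    intercept_di: float = -1.0
    noise_sd: float = 0.05
    pka1_low: float = 1.5
    pka1_high: float = 5.0
    pka2_gap_low: float = 0.5
    pka2_gap_high: float = 3.0
    dg_low: float = -10.0
    dg_high: float = -4.0
    c0: float = 0.5
    s_api: float = 0.17
    ph: float = 6.5
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if min(self.n_mono, self.n_di) < 3:
            raise ValueError("need at least 3 coformers per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (self.slope_mono > 0 > self.slope_di):
            raise ValueError("require slope_mono > 0 > slope_di")

    def slope(self, acid_class: str) -> float:
        return self.slope_mono if acid_class == "mono" else self.slope_di

    def intercept(self, acid_class: str) -> float:
        return self.intercept_mono if acid_class == "mono" else self.intercept_di


@dataclass(frozen=True)
class SyntheticStudy:
    seed: int
    params: GeneratingParams
    rows: List[CoformerTableRow]
    true_pam: List[float]

    @property
    def coformer_rows(self) -> List[CoformerTableRow]:
        return [r for r in self.rows if r.acid_class != "api"]


def generate_study(
    seed: int, params: GeneratingParams = GeneratingParams()
) -> SyntheticStudy:
    """Draw one synthetic coformer study.

    pKa1 ~ U(pka1_low, pka1_high); for diprotic rows pKa2 = pKa1 +
    U(gap_low, gap_high); ΔG_r ~ U(dg_low, dg_high).  pAM is computed
    through the actual speciation → pβ → pK_r → pAM chain at the study
    conditions, then SA = slope·pAM + intercept + N(0, noise_sd²).
    The first returned row is the API row (S fixed at ``s_api``).
    """
    rng = np.random.default_rng(seed)
    cond = speciation.Conditions(ph=params.ph, temperature=params.temperature)
    api_avail = speciation.neutral_availability(API_DEFAULT, cond)

    rows: List[CoformerTableRow] = [
        CoformerTableRow(
            code="API",
            name=API_DEFAULT.name,
            acid_class="api",
            pka1=API_DEFAULT.pka1,
            dg_r=0.0,
            c0=API_DEFAULT.c0,
            s_mg_ml=params.s_api,
        )
    ]
    true_pam: List[float] = []

    classes = ["mono"] * params.n_mono + ["di"] * params.n_di
    for i, acid_class in enumerate(classes):
        pka1 = rng.uniform(params.pka1_low, params.pka1_high)
        pka2 = (
            pka1 + rng.uniform(params.pka2_gap_low, params.pka2_gap_high)
            if acid_class == "di"
            else None
        )
        dg_r = rng.uniform(params.dg_low, params.dg_high)
        noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0

        coformer = speciation.Protolyte(
            name=f"{acid_class}-{i:03d}",
            proticity=2 if acid_class == "di" else 1,
            pka1=pka1,
            pka2=pka2,
            c0=params.c0,
        )
        acid_avail = speciation.neutral_availability(coformer, cond)
        pb = equilibria.p_beta(api_avail, acid_avail)
        pk_r = equilibria.pkr_from_gibbs(dg_r, cond.temperature)
        stoich = equilibria.Stoichiometry.for_acid_class(acid_class)
        pam = equilibria.complex_exponent(pk_r, pb, stoich)

        sa = params.slope(acid_class) * pam + params.intercept(acid_class) + noise
        rows.append(
            CoformerTableRow(
                code=str(i + 1),
                name=coformer.name,
                acid_class=acid_class,
                pka1=pka1,
                pka2=pka2,
                dg_r=dg_r,
                c0=params.c0,
                sa_exp=sa,
                s_mg_ml=params.s_api * 10.0**sa,
                log_beta_printed=-pb,
            )
        )
        true_pam.append(pam)

    return SyntheticStudy(seed=seed, params=params, rows=rows, true_pam=true_pam)
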