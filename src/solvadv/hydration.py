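"""Relative hydration free energy of an API–coformer pair vs its monomers.

ΔΔG_hydr = ΔG_hydr(pair) - ΔG_hydr(API) - ΔG_hydr(coformer).
Positive values mean the separated monomers are better hydrated than
the pair — hydration is lost on complex formation, typically because
the most polar fragments are the ones buried in the heterosynthon.
Hydration free energies are user-supplied inputs (kcal·mol⁻¹); this
module only does the bookkeeping and hands ΔΔG to the trends analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["HydrationTriple", "relative_hydration"]


def relative_hydration(dg_complex: float, dg_api: float, dg_coformer: float) -> float:
    """ΔΔG_hydr = dg_complex - dg_api - dg_coformer (kcal·mol⁻¹)."""
    for name, v in (
        ("dg_complex", dg_complex),
        ("dg_api", dg_api),
        ("dg_coformer", dg_coformer),
    ):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    return dg_complex - dg_api - dg_coformer


@dataclass(frozen=True)
class HydrationTriple:
    """Hydration free energies of a pair and its monomers, plus their ΔΔG."""

    dg_complex: float
    dg_api: float
    dg_coformer: float
    ddg: float

    @classmethod
    def from_energies(
        cls, dg_complex: float, dg_api: float, dg_coformer: float
    ) -> "HydrationTriple":
        return cls(
            dg_complex=dg_complex,
            dg_api=dg_api,
            dg_coformer=dg_coformer,
            ddg=relative_hydration(dg_complex, dg_api, dg_coformer),
        )

    def __post_init__(self) -> None:
        expected = self.dg_complex - self.dg_api - self.dg_coformer
        if self.ddg != expected:
            raise ValueError(
                f"ddg ({self.ddg}) inconsistent with components ({expected})"
            )
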