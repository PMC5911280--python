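"""The bundled meloxicam–coformer reference table and CSV I/O.

The reference dataset covers meloxicam (the API) and eleven carboxylic
acid coformers: measured cocrystal solubility S (mg·ml⁻¹), experimental
solubility advantage SA, experimental pKa values, the pairwise
complexation free energy ΔG_r (kcal·mol⁻¹) from COSMO-RS computations,
and the derived columns pK_r, pMA^est and logβ as printed in the source
compilation.  The ``log_beta_printed`` column stores log10 of the
neutral-concentration product, i.e. the NEGATIVE of pβ; accessors
negate it.

``validate_against_printed`` recomputes the derivable columns with this
package's own equilibria code and reports per-column maximum deviations
against the printed values.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .equilibria import Stoichiometry, pkr_from_gibbs, solubility_advantage
from .speciation import Conditions, Protolyte

__all__ = [
    "CoformerTableRow",
    "ValidationReport",
    "load_reference_table",
    "read_table",
    "write_table",
    "rows_to_frame",
    "validate_against_printed",
]

_RESOURCE = "meloxicam_coformers.csv"
_RESOURCE_SHA256 = "ee42d6ad84ef40eaabfd00f2800d60ffb4e5ae8fe8c5cb4a52341abffe6e953c"

REQUIRED_COLUMNS = ("name", "acid_class", "pka1", "dg_r", "c0")
_NUMERIC_COLUMNS = (
    "s_mg_ml",
    "sa_exp",
    "pka1",
    "pka2",
    "dg_r",
    "pk_r_printed",
    "p_ma_printed",
    "log_beta_printed",
    "c0",
    "solubility_limit",
    "molar_mass",
)
_KNOWN_COLUMNS = ("code", "name", "acid_class") + _NUMERIC_COLUMNS

# default tolerances for the printed-column validation
TOL_PK_R = 0.01
TOL_P_MA = 0.015
TOL_SA = 0.02


@dataclass(frozen=True)
class CoformerTableRow:
    """One coformer (or the API row) of a study table."""

    code: str
    name: str
    acid_class: str  # "mono" | "di" | "api"
    pka1: float
    dg_r: float
    c0: float
    s_mg_ml: Optional[float] = None
    sa_exp: Optional[float] = None
    pka2: Optional[float] = None
    pk_r_printed: Optional[float] = None
    p_ma_printed: Optional[float] = None
    log_beta_printed: Optional[float] = None
    solubility_limit: Optional[float] = None
    molar_mass: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.acid_class not in ("mono", "di", "api"):
            raise ValueError(f"unknown acid_class {self.acid_class!r}")
        if self.acid_class == "di" and self.pka2 is None:
            raise ValueError(f"diprotic row {self.name!r} lacks pka2")
        if self.acid_class != "di" and self.pka2 is not None:
            raise ValueError(f"row {self.name!r} has pka2 but is not diprotic")
        if not self.c0 > 0:
            raise ValueError(f"c0 must be positive in row {self.name!r}")
        if self.s_mg_ml is not None and not self.s_mg_ml > 0:
            raise ValueError(f"s_mg_ml must be positive in row {self.name!r}")

    @property
    def p_beta_printed(self) -> Optional[float]:
        """pβ as implied by the printed logβ column (sign flipped)."""
        if self.log_beta_printed is None:
            return None
        return -self.log_beta_printed

    @property
    def proticity(self) -> int:
        return 2 if self.acid_class == "di" else 1

    def to_protolyte(self) -> Protolyte:
        return Protolyte(
            name=self.name,
            proticity=self.proticity,
            pka1=self.pka1,
            pka2=self.pka2,
            c0=self.c0,
            molar_mass=self.molar_mass,
            solubility_limit=self.solubility_limit,
        )

    def stoichiometry(self) -> Stoichiometry:
        return Stoichiometry.for_acid_class(self.acid_class)


def _clean_number(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip().replace("−", "-").replace("–", "-")
        if value in ("", "-", "–"):
            return None
    return float(value)


def _frame_to_rows(frame: pd.DataFrame, source: str) -> List[CoformerTableRow]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{source}: missing required column(s): {', '.join(missing)}"
        )
    extra_cols = [c for c in frame.columns if c not in _KNOWN_COLUMNS]
    rows: List[CoformerTableRow] = []
    for idx, rec in frame.iterrows():
        numeric: Dict[str, Optional[float]] = {}
        for col in _NUMERIC_COLUMNS:
            if col not in frame.columns:
                numeric[col] = None
                continue
            try:
                numeric[col] = _clean_number(rec[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{source}, row {idx}: non-numeric value "
                    f"{rec[col]!r} in column {col!r}"
                ) from exc
        for col in ("pka1", "dg_r", "c0"):
            if numeric[col] is None:
                raise ValueError(f"{source}, row {idx}: empty required column {col!r}")
        extras = {c: rec[c] for c in extra_cols}
        rows.append(
            CoformerTableRow(
                code=str(rec["code"]) if "code" in frame.columns else str(idx),
                name=str(rec["name"]).strip(),
                acid_class=str(rec["acid_class"]).strip(),
                pka1=numeric["pka1"],
                dg_r=numeric["dg_r"],
                c0=numeric["c0"],
                s_mg_ml=numeric["s_mg_ml"],
                sa_exp=numeric["sa_exp"],
                pka2=numeric["pka2"],
                pk_r_printed=numeric["pk_r_printed"],
                p_ma_printed=numeric["p_ma_printed"],
                log_beta_printed=numeric["log_beta_printed"],
                solubility_limit=numeric["solubility_limit"],
                molar_mass=numeric["molar_mass"],
                extras=extras,
            )
        )
    return rows


def load_reference_table() -> List[CoformerTableRow]:
    """The bundled 12-row reference table (11 coformers + the API row).

    The resource is checksum-pinned; a corrupted installation raises
    rather than silently validating against wrong numbers.
    """
    ref = resources.files("solvadv.data").joinpath(_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _RESOURCE_SHA256:
        raise IOError(
            f"bundled reference table corrupted (sha256 {digest[:12]}…, "
            f"expected {_RESOURCE_SHA256[:12]}…)"
        )
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, dtype={"code": str})
    return _frame_to_rows(frame, _RESOURCE)


def read_table(path: Union[str, Path]) -> List[CoformerTableRow]:
    """Read a coformer table CSV.

    Required columns: name, acid_class, pka1, dg_r, c0.  Unknown
    columns are preserved in ``row.extras`` (e.g. a user-supplied
    ``mp_delta`` melting-point shift for trend analysis).  Unicode
    minus signs are normalized on read.
    """
    frame = pd.read_csv(path, dtype={"code": str})
    return _frame_to_rows(frame, str(path))


def rows_to_frame(rows: Sequence[CoformerTableRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        rec = {
            "code": row.code,
            "name": row.name,
            "acid_class": row.acid_class,
            "s_mg_ml": row.s_mg_ml,
            "sa_exp": row.sa_exp,
            "pka1": row.pka1,
            "pka2": row.pka2,
            "dg_r": row.dg_r,
            "pk_r_printed": row.pk_r_printed,
            "p_ma_printed": row.p_ma_printed,
            "log_beta_printed": row.log_beta_printed,
            "c0": row.c0,
            "solubility_limit": row.solubility_limit,
            "molar_mass": row.molar_mass,
        }
        rec.update(row.extras)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_table(rows: Sequence[CoformerTableRow], path: Union[str, Path]) -> None:
    """Write rows as CSV; round-trips losslessly through ``read_table``."""
    rows_to_frame(rows).to_csv(path, index=False)


def find_api_row(rows: Sequence[CoformerTableRow]) -> CoformerTableRow:
    for row in rows:
        if row.acid_class == "api":
            return row
    raise ValueError("table has no API row (acid_class == 'api')")


@dataclass(frozen=True)
class ValidationReport:
    """Recomputed-vs-printed deviations for the derivable columns."""

    pk_r_deviations: Dict[str, float]
    p_ma_deviations: Dict[str, float]
    sa_deviations: Dict[str, float]
    pk_r_max_dev: float
    p_ma_max_dev: float
    sa_max_dev: float
    pk_r_pass: bool
    p_ma_pass: bool
    sa_pass: bool

    @property
    def all_pass(self) -> bool:
        return self.pk_r_pass and self.p_ma_pass and self.sa_pass

    def to_dict(self) -> dict:
        return {
            "pk_r": {
                "max_abs_deviation": self.pk_r_max_dev,
                "tolerance": TOL_PK_R,
                "pass": self.pk_r_pass,
                "per_row": self.pk_r_deviations,
            },
            "p_ma": {
                "max_abs_deviation": self.p_ma_max_dev,
                "tolerance": TOL_P_MA,
                "pass": self.p_ma_pass,
                "per_row": self.p_ma_deviations,
            },
            "sa": {
                "max_abs_deviation": self.sa_max_dev,
                "tolerance": TOL_SA,
                "pass": self.sa_pass,
                "per_row": self.sa_deviations,
            },
            "all_pass": self.all_pass,
        }


def validate_against_printed(
    rows: Sequence[CoformerTableRow],
    cond: Conditions = Conditions(),
) -> ValidationReport:
    """Recompute pK_r, pMA^est and SA and compare with the printed columns.

    pK_r is recomputed from ΔG_r at ``cond.temperature``; pMA^est as
    binding_events·pK_r + pβ with pβ taken from the table's logβ column
    (sign flipped) and the class stoichiometry rule; SA from the S
    column against the API row's solubility.
    """
    api = find_api_row(rows)
    pk_dev: Dict[str, float] = {}
    pma_dev: Dict[str, float] = {}
    sa_dev: Dict[str, float] = {}

    for row in rows:
        pk_r = pkr_from_gibbs(row.dg_r, cond.temperature)
        if row.pk_r_printed is not None:
            pk_dev[row.name] = abs(pk_r - row.pk_r_printed)
        if row.acid_class == "api":
            continue
        if row.p_ma_printed is not None and row.p_beta_printed is not None:
            n_bind = row.stoichiometry().binding_events
            p_ma = n_bind * pk_r + row.p_beta_printed
            pma_dev[row.name] = abs(p_ma - row.p_ma_printed)
        if row.sa_exp is not None and row.s_mg_ml is not None:
            sa = solubility_advantage(row.s_mg_ml, api.s_mg_ml)
            sa_dev[row.name] = abs(sa - row.sa_exp)

    def _max(d: Dict[str, float]) -> float:
        return max(d.values()) if d else 0.0

    return ValidationReport(
        pk_r_deviations=pk_dev,
        p_ma_deviations=pma_dev,
        sa_deviations=sa_dev,
        pk_r_max_dev=_max(pk_dev),
        p_ma_max_dev=_max(pma_dev),
        sa_max_dev=_max(sa_dev),
        pk_r_pass=_max(pk_dev) <= TOL_PK_R,
        p_ma_pass=_max(pma_dev) <= TOL_P_MA,
        sa_pass=_max(sa_dev) <= TOL_SA,
    )
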