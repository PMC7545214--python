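"""Pigment census and stoichiometry ratios.

Counts pigments per class, split between core and antenna chains, and
derives the standard stoichiometry ratios for an antenna system that
binds chlorophyll a/c and carotenoids:

* ``chl_a_to_c``      = antenna-bound Chl a / Chl c
  (antenna-bound Chl a = total Chl a minus core-bound Chl a)
* ``avg_chl_c_per_antenna`` = Chl c / number of antenna subunits
* ``chl_to_car``      = (antenna Chl a + Chl c) / (fucoxanthin + diadinoxanthin)

The chlorophyll/carotenoid denominator includes every fucoxanthin and
diadinoxanthin in the complex, core-bound ones included; that is the
arithmetic convention under which the published ratios are internally
consistent.  Ratios are reported half-up at the printed precision
(2 decimals, 1 decimal for the per-antenna average); full precision is
retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .exceptions import AnalysisError, ConfigError
from .layers import LayerAssignment
from .network import round_half_up
from .structure_io import PigmentClass, Role, StructureModel


@dataclass
class RatioReport:
    """Derived stoichiometry ratios (rounded at printed precision)."""

    chl_a_to_c: float
    avg_chl_c_per_antenna: float
    chl_to_car: float
    total_pigments: Optional[int] = None
    # full-precision values
    chl_a_to_c_exact: float = 0.0
    avg_chl_c_per_antenna_exact: float = 0.0
    chl_to_car_exact: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "chl_a_to_c": self.chl_a_to_c,
            "avg_chl_c_per_antenna": self.avg_chl_c_per_antenna,
            "chl_to_car": self.chl_to_car,
        }
        if self.total_pigments is not None:
            d["total_pigments"] = self.total_pigments
        return d


@dataclass
class CensusReport:
    """Per-class pigment counts, core/antenna split, and derived ratios."""

    totals: dict[str, int]
    core: dict[str, int]
    antenna: dict[str, int]
    per_subunit: pd.DataFrame
    n_antennas: int
    ratios: Optional[RatioReport] = None

    @property
    def total_pigments(self) -> int:
        return sum(self.totals.values())

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "core": self.core,
            "antenna": self.antenna,
            "n_antennas": self.n_antennas,
            "total_pigments": self.total_pigments,
            "ratios": self.ratios.to_dict() if self.ratios else None,
        }


def census(model: StructureModel,
           layers: Optional[LayerAssignment] = None) -> CensusReport:
    """Exact integer pigment counts per class, split core vs antenna.

    ``layers`` is accepted for interface symmetry with the pipeline (the
    split is by chain role, which the annotations already carry).
    """
    classes = [c.value for c in PigmentClass]
    totals = {c: 0 for c in classes}
    core = {c: 0 for c in classes}
    antenna = {c: 0 for c in classes}
    per_subunit: dict[str, dict[str, int]] = {}
    role_of = {c.subunit_label: c.role for c in model.chains}
    for p in model.pigments:
        cls = p.pigment_class.value
        totals[cls] += 1
        role = role_of.get(p.subunit_label, Role.OTHER)
        if role is Role.CORE:
            core[cls] += 1
        elif role is Role.ANTENNA:
            antenna[cls] += 1
        row = per_subunit.setdefault(p.subunit_label, {c: 0 for c in classes})
        row[cls] += 1
    per_subunit_df = (pd.DataFrame.from_dict(per_subunit, orient="index")
                      .rename_axis("subunit").reset_index()
                      .sort_values("subunit").reset_index(drop=True))
    n_antennas = sum(1 for c in model.chains if c.role is Role.ANTENNA)
    report = CensusReport(totals=totals, core=core, antenna=antenna,
                          per_subunit=per_subunit_df, n_antennas=n_antennas)
    try:
        report.ratios = ratio_report(
            chl_a_total=totals[PigmentClass.CHL_A.value],
            chl_a_core=core[PigmentClass.CHL_A.value],
            chl_c_total=totals[PigmentClass.CHL_C.value],
            fx_total=totals[PigmentClass.FUCOXANTHIN.value],
            ddx_total=totals[PigmentClass.DIADINOXANTHIN.value],
            n_antennas=n_antennas,
            bcr_total=totals[PigmentClass.BETA_CAROTENE.value],
        )
    except AnalysisError:
        report.ratios = None  # zero denominators on sparse models
    return report


def ratio_report(chl_a_total: int, chl_a_core: int, chl_c_total: int,
                 fx_total: int, ddx_total: int, n_antennas: int,
                 bcr_total: Optional[int] = None) -> RatioReport:
    """Stoichiometry ratios from integer pigment counts.

    When ``bcr_total`` is given, ``total_pigments`` is the sum over all
    five pigment classes.
    """
    for name, v in [("chl_a_total", chl_a_total), ("chl_a_core", chl_a_core),
                    ("chl_c_total", chl_c_total), ("fx_total", fx_total),
                    ("ddx_total", ddx_total)]:
        if v < 0:
            raise AnalysisError(f"count {name} must be non-negative, got {v}")
    if n_antennas <= 0:
        raise AnalysisError("n_antennas must be positive")
    if chl_c_total == 0:
        raise AnalysisError("division by zero: chl_c_total is 0 (chl_a_to_c)")
    if fx_total + ddx_total == 0:
        raise AnalysisError("division by zero: fx_total + ddx_total is 0 "
                            "(chl_to_car)")
    chl_a_antenna = chl_a_total - chl_a_core
    chl_a_to_c = chl_a_antenna / chl_c_total
    avg_c = chl_c_total / n_antennas
    chl_to_car = (chl_a_antenna + chl_c_total) / (fx_total + ddx_total)
    total = (chl_a_total + chl_c_total + fx_total + ddx_total + bcr_total
             if bcr_total is not None else None)
    return RatioReport(
        chl_a_to_c=round_half_up(chl_a_to_c, 2),
        avg_chl_c_per_antenna=round_half_up(avg_c, 1),
        chl_to_car=round_half_up(chl_to_car, 2),
        total_pigments=total,
        chl_a_to_c_exact=chl_a_to_c,
        avg_chl_c_per_antenna_exact=avg_c,
        chl_to_car_exact=chl_to_car,
    )


def load_counts(path: str | Path) -> dict:
    """Read a pigment-counts YAML file (pure-arithmetic census mode)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"counts file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"counts file {path} must be a mapping")
    required = {"chl_a_total", "chl_a_core", "chl_c_total",
                "fx_total", "ddx_total", "n_antennas"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"counts file {path} lacks fields: {sorted(missing)}")
    return {k: int(v) for k, v in raw.items()}
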