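"""Cross-condition heat-capacity regression and stability-curve extrapolation.

Kirchhoff's relation makes the slope of dHd(Td) versus Td across cosolute
conditions an estimate of dCp,d, the heat capacity change upon denaturation,
provided dCp is treated as temperature- and cosolute-independent.  With that
slope, the Gibbs-Helmholtz relation extrapolates the denaturation enthalpy
of any condition to a common reference temperature,

    dH(T) = dHd(Td) + dCp * (T - Td),

which, normalised per residue, puts thermophilic and mesophilic proteins on
the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .dsc import TwoStateParams, delta_g

__all__ = [
    "ConditionRecord",
    "DcpRegression",
    "DENATURANT_COSOLUTES",
    "load_conditions",
    "packaged_conditions",
    "select_regression_records",
    "fit_dcp",
    "extrapolate_dh",
    "per_residue_dh",
    "stability_curve",
]

#: Cosolute labels eligible for the dCp regression: the buffer reference and
#: pure denaturants.  Mixtures with stabilizing osmolytes shift Td without a
#: matching dHd change and are excluded.
DENATURANT_COSOLUTES = frozenset({"buffer", "KSCN", "GdmSCN", "GdmCl"})


@dataclass(frozen=True)
class ConditionRecord:
    """One scan condition: cosolute, its molarity, and (Td, dHd[, dHvH])."""

    cosolute: str
    conc: float  # M
    td: float  # K
    dh: float  # kJ/mol
    dh_vh: float | None = None

    def __post_init__(self):
        if not self.td > 0 or not self.dh > 0:
            raise ValueError("Td and dHd must be positive")

    @property
    def td_celsius(self) -> float:
        return kelvin_to_celsius(self.td)

    @property
    def ratio(self) -> float | None:
        return None if self.dh_vh is None else self.dh / self.dh_vh


@dataclass(frozen=True)
class DcpRegression:
    """OLS of dHd(Td) on Td; the slope estimates dCp,d."""

    slope: float  # kJ/K/mol
    intercept: float  # kJ/mol
    r_squared: float
    slope_se: float
    n_points: int


def load_conditions(path) -> list[ConditionRecord]:
    """Read a conditions CSV (`cosolute,conc_M,td_C,dh_kJ_mol,dhvh_kJ_mol`)."""
    df = pd.read_csv(path, comment="#")
    required = {"cosolute", "conc_M", "td_C", "dh_kJ_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"conditions file missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        dh_vh = getattr(row, "dhvh_kJ_mol", None)
        dh_vh = None if dh_vh is None or pd.isna(dh_vh) else float(dh_vh)
        records.append(ConditionRecord(
            cosolute=str(row.cosolute), conc=float(row.conc_M),
            td=celsius_to_kelvin(float(row.td_C)), dh=float(row.dh_kJ_mol),
            dh_vh=dh_vh))
    return records


def packaged_conditions() -> list[ConditionRecord]:
    """The packaged transcription of the published D2 condition table."""
    ref = resources.files("thermoshell.data") / "d2_conditions.csv"
    with resources.as_file(ref) as path:
        return load_conditions(path)


def select_regression_records(records) -> list[ConditionRecord]:
    """Keep buffer and pure-denaturant conditions (drop stabilizer mixtures)."""
    return [r for r in records if r.cosolute in DENATURANT_COSOLUTES]


def fit_dcp(records) -> DcpRegression:
    """Least-squares slope of dHd(Td) vs Td across conditions."""
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 conditions for the dCp regression")
    td = np.array([r.td for r in records])
    dh = np.array([r.dh for r in records])
    if np.ptp(td) == 0:
        raise ValueError("zero variance in Td: slope undefined")
    res = stats.linregress(td, dh)
    return DcpRegression(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2),
                         slope_se=float(res.stderr), n_points=len(records))


def extrapolate_dh(record: ConditionRecord, dcp: float, t_target: float) -> float:
    """dH at ``t_target`` [K] assuming temperature-independent dCp [kJ/K/mol]."""
    return record.dh + dcp * (t_target - record.td)


def per_residue_dh(dh: float, n_residues: int) -> float:
    """Enthalpy normalised per residue [kJ/mol/residue]."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return dh / n_residues


def stability_curve(record: ConditionRecord, dcp: float, t_grid) -> np.ndarray:
    """Gibbs-Helmholtz dG(T) [kJ/mol] on ``t_grid`` [K] for one condition."""
    params = TwoStateParams(record.td, record.dh, dcp)
    return np.asarray(delta_g(np.asarray(t_grid, dtype=float), params))
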