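"""Equal-and-independent-sites analysis of ITC titrations.

A protein P with n identical, independent sites for a ligand L obeys the
per-site equilibrium Kb = [B] / ((n[P0] - [B]) ([L0] - [B])), whose bound
concentration [B] is the smaller root of the quadratic

    a x^2 - b x + c = 0,  a = n Kb,  b = 1 + n [P0] Kb + [L0] Kb,
    c = [L0] [P0] Kb

(x = [B]/n, so [B]/(n [P0]) = (b - sqrt(b^2 - 4ac)) / (2 a [P0]) is the
fractional saturation).  The cumulative heat after k injections, per mole of
protein, is dHb_total times the fractional saturation at the composition
([P0]_k, [L0]_k); the total enthalpy at saturation is the fitted dHb_total.

Concentration bookkeeping models an overfilled cell by displacement: each
injection of volume v into a cell of volume V scales resident species by
(1 - v/V) ("displacement"); a "none" strategy is available for instruments
where injections do not displace cell contents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .dsc import FitError

__all__ = [
    "BindingParams",
    "TitrationSchedule",
    "TitrationData",
    "concentrations_after_injection",
    "bound_fraction",
    "cumulative_heat",
    "subtract_dilution",
    "simulate_titration",
    "fit_binding",
]


@dataclass(frozen=True)
class BindingParams:
    """(n sites, per-site Kb [1/M], total binding enthalpy [kJ/mol protein])."""

    n: float
    kb: float
    dh_total: float

    def __post_init__(self):
        if not self.n > 0:
            raise ValueError(f"n must be positive (got {self.n})")
        if not self.kb > 0:
            raise ValueError(f"Kb must be positive (got {self.kb})")

    @property
    def dh_per_site(self) -> float:
        return self.dh_total / self.n


@dataclass(frozen=True)
class TitrationSchedule:
    """Injection protocol: volumes [ul], counts, concentrations [M]."""

    cell_volume_ul: float
    injection_volume_ul: float
    n_injections: int
    syringe_conc: float
    protein_conc: float

    def __post_init__(self):
        for name in ("cell_volume_ul", "injection_volume_ul", "syringe_conc",
                     "protein_conc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if self.injection_volume_ul >= self.cell_volume_ul:
            raise ValueError("injection volume must be below the cell volume")

    @property
    def cell_protein_moles(self) -> float:
        """Moles of protein initially in the cell."""
        return self.protein_conc * self.cell_volume_ul * 1e-6  # ul -> l


def concentrations_after_injection(schedule: TitrationSchedule, k: int,
                                   dilution: str = "displacement"
                                   ) -> tuple[float, float]:
    """Cell (protein, ligand) concentrations [M] after injection ``k``.

    ``k = 0`` is the pre-titration state.  Under "displacement" each
    injection multiplies resident concentrations by (1 - v/V); under "none"
    the ligand simply accumulates with no dilution of the cell contents.
    """
    if not 0 <= k <= schedule.n_injections:
        raise ValueError(f"injection index {k} outside 0..{schedule.n_injections}")
    v, cell = schedule.injection_volume_ul, schedule.cell_volume_ul
    if dilution == "displacement":
        r = (1.0 - v / cell) ** k
        return schedule.protein_conc * r, schedule.syringe_conc * (1.0 - r)
    if dilution == "none":
        return (schedule.protein_conc,
                schedule.syringe_conc * k * v / cell)
    raise ValueError(f"unknown dilution strategy {dilution!r}")


def bound_fraction(l0, p0, params: BindingParams):
    """Fractional saturation [B]/(n [P0]) from the quadratic mass balance."""
    l0 = np.asarray(l0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if np.any(l0 < 0):
        raise ValueError("ligand concentration must be non-negative")
    if np.any(p0 <= 0):
        raise ValueError("protein concentration must be positive")
    n, kb = params.n, params.kb
    a = n * kb
    b = 1.0 + n * p0 * kb + l0 * kb
    c = l0 * p0 * kb
    disc = b * b - 4.0 * a * c
    if np.any(disc < 0):
        raise ValueError("negative discriminant in binding quadratic")
    # smaller root via the cancellation-free form:
    # (b - sqrt(disc)) / (2 a P0) == 2 Kb L0 / (b + sqrt(disc))
    frac = 2.0 * kb * l0 / (b + np.sqrt(disc))
    frac = np.clip(frac, 0.0, 1.0)
    return frac if frac.ndim else float(frac)


def cumulative_heat(l0, p0, params: BindingParams, cell_protein_moles=None):
    """Cumulative binding heat, kJ per mole of protein (or uJ if moles given)."""
    q = params.dh_total * bound_fraction(l0, p0, params)
    if cell_protein_moles is not None:
        q = q * cell_protein_moles * 1e9  # kJ -> uJ
    return q


def subtract_dilution(heats, dilution_heats):
    """Elementwise dilution-heat correction of per-injection heats."""
    heats = np.asarray(heats, dtype=float)
    dilution_heats = np.asarray(dilution_heats, dtype=float)
    if heats.shape != dilution_heats.shape:
        raise ValueError("heat vectors differ in length")
    return heats - dilution_heats


@dataclass
class TitrationData:
    """Per-injection heats plus the concentration ledger of the titration."""

    schedule: TitrationSchedule
    heats_uJ: np.ndarray
    dilution: str = "displacement"

    def __post_init__(self):
        self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
        if self.heats_uJ.size != self.schedule.n_injections:
            raise ValueError("heats length must equal n_injections")

    @property
    def p0(self) -> np.ndarray:
        return np.array([concentrations_after_injection(self.schedule, k, self.dilution)[0]
                         for k in range(1, self.schedule.n_injections + 1)])

    @property
    def l0(self) -> np.ndarray:
        return np.array([concentrations_after_injection(self.schedule, k, self.dilution)[1]
                         for k in range(1, self.schedule.n_injections + 1)])

    @property
    def cumulative_uJ(self) -> np.ndarray:
        return np.cumsum(self.heats_uJ)

    @property
    def cumulative_kJ_per_mol(self) -> np.ndarray:
        """Cumulative heat normalised by the initial cell protein content."""
        return self.cumulative_uJ * 1e-9 / self.schedule.cell_protein_moles


def simulate_titration(params: BindingParams, schedule: TitrationSchedule,
                       noise_sd_uJ: float = 0.0, seed=None,
                       dilution: str = "displacement",
                       dilution_heats_uJ=None) -> TitrationData:
    """Per-injection heats from the isotherm, plus optional noise/dilution heat.

    ``noise_sd_uJ`` is the Gaussian standard deviation added independently to
    each injection heat, in uJ.  ``dilution_heats_uJ`` (same length) is added
    on top, emulating the salt-dilution exotherm a buffer titration measures.
    """
    qc = []
    for k in range(1, schedule.n_injections + 1):
        p0_k, l0_k = concentrations_after_injection(schedule, k, dilution)
        qc.append(cumulative_heat(l0_k, p0_k, params))
    dq = np.diff(np.concatenate([[0.0], qc]))
    heats = dq * schedule.cell_protein_moles * 1e9  # kJ/mol -> uJ per injection
    if dilution_heats_uJ is not None:
        heats = heats + np.asarray(dilution_heats_uJ, dtype=float)
    if noise_sd_uJ > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd_uJ, size=heats.size)
    return TitrationData(schedule, heats, dilution=dilution)


def _profile_fit(l0, p0, qc, n_sites, kb_bounds, dh_scale):
    """Inner (log Kb, dH) least squares at fixed site count."""
    lo = np.log(kb_bounds[0]), -np.inf
    hi = np.log(kb_bounds[1]), np.inf
    x0 = [np.log(np.sqrt(kb_bounds[0] * kb_bounds[1])), dh_scale]

    def residuals(theta):
        ln_kb, dh = theta
        p = BindingParams(n_sites, np.exp(ln_kb), dh)
        return cumulative_heat(l0, p0, p) - qc

    return least_squares(residuals, x0, bounds=(lo, hi),
                         xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)


def fit_binding(data: TitrationData, init: BindingParams | None = None,
                n_bounds: tuple[float, float] = (0.5, 1e4),
                kb_bounds: tuple[float, float] = (1e-4, 1e7)
                ) -> tuple[BindingParams, dict]:
    """Fit (n, Kb, dHb_total) to dilution-corrected cumulative heats.

    The RSS is profiled over log n (the stoichiometry is the flattest
    direction for weak binding) with an inner bounded (log Kb, dH) fit, then
    polished by a full three-parameter refinement.  Returns the parameters
    and a diagnostics dict with asymptotic standard errors.
    """
    if data.schedule.n_injections < 5:
        raise FitError("need at least 5 injections")
    qc = data.cumulative_kJ_per_mol
    l0, p0 = data.l0, data.p0
    scale = float(np.max(np.abs(qc)))
    if scale <= 0 or np.ptp(qc) == 0:
        raise FitError("flat heat curve: binding parameters not identifiable")
    dh_scale = qc[-1] * 1.5 if init is None else init.dh_total
    if init is not None:
        n_star = float(np.clip(init.n, *n_bounds))
    else:
        prof = minimize_scalar(
            lambda ln_n: 2.0 * _profile_fit(l0, p0, qc, np.exp(ln_n),
                                            kb_bounds, dh_scale).cost,
            bounds=(np.log(n_bounds[0]), np.log(n_bounds[1])),
            method="bounded", options={"xatol": 1e-8})
        n_star = float(np.exp(prof.x))
    inner = _profile_fit(l0, p0, qc, n_star, kb_bounds, dh_scale)

    def residuals(theta):
        ln_n, ln_kb, dh = theta
        p = BindingParams(np.exp(ln_n), np.exp(ln_kb), dh)
        return cumulative_heat(l0, p0, p) - qc

    x0 = [np.log(n_star), inner.x[0], inner.x[1]]
    res = least_squares(
        residuals, x0,
        bounds=([np.log(n_bounds[0]), np.log(kb_bounds[0]), -np.inf],
                [np.log(n_bounds[1]), np.log(kb_bounds[1]), np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    if not res.success or 2.0 * res.cost > 2.0 * inner.cost + 1e-12:
        # keep the profiled solution when the polish stalls on a flat valley
        # (an exhausted evaluation budget at these tolerances still leaves a
        # converged-in-practice iterate; only a failed evaluation is fatal)
        if not np.all(np.isfinite(inner.x)) or not np.isfinite(inner.cost):
            raise FitError(f"binding fit did not converge: {res.message}",
                           last_iterate=res.x)
        res = inner
        res.x = np.array([np.log(n_star), inner.x[0], inner.x[1]])
        res.jac = np.column_stack([np.zeros(len(qc)), inner.jac])
    n_hat, kb_hat = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    dh_hat = float(res.x[2])
    params = BindingParams(n_hat, kb_hat, dh_hat)
    rss = float(2.0 * res.cost)
    dof = max(qc.size - 3, 1)
    # asymptotic covariance in (ln n, ln kb, dh) space
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        var = np.diag(cov)
        if np.any(var < 0):  # numerically singular: errors are meaningless
            raise np.linalg.LinAlgError
        se_log = np.sqrt(var)
        se = {"n": n_hat * se_log[0], "kb": kb_hat * se_log[1], "dh": se_log[2]}
    except np.linalg.LinAlgError:
        se = {"n": float("inf"), "kb": float("inf"), "dh": float("inf")}
    diag = {"rss": rss, "n_points": int(qc.size), "stderr": se}
    return params, diag
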