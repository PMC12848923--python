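"""Shrub-herb biomass dynamics and eigenvalue stability analysis.

The two functional groups follow coupled growth equations modulated by the
herb-to-shrub water-use ratio R = k_h·W_h / (k_s·W_s):

    dW_s/dt = r_s·∅(R)·W_s − u_s·W_s      (shrubs)
    dW_h/dt = r_h·φ(R)·W_h − u_h·W_h      (herbs)

with the shrub stress response ∅(R) = exp(−k·max(R − R₀, 0)) — growth
unimpaired until the ratio exceeds the onset R₀, then exponentially
suppressed — and the herb self-limitation sigmoid φ(R) = 2/(1 + e^{b(R−Rc)}),
which doubles herb growth at low ratios and chokes it beyond the midpoint
Rc. Default rates come from long-term dryland monitoring
(r_s = 0.35, u_s = 0.08, r_h = 0.80, u_h = 0.25, k = 1.2, b = 3.0);
R₀ = 0.9 and Rc = 1.4 identify the modulation breakpoints with the
empirical stability thresholds of the ratio statistic.

Stability is assessed from the analytic Jacobian (exact for k_h = k_s,
where the matrix depends on the state only through R) via the
trace/determinant eigenvalue formula; :func:`bifurcation_scan` locates
sign changes of the dominant real part over a ratio grid, and
:func:`calibrate_regimes` searches the modulation parameters for a regime
pattern and reports honestly whether the target pattern is attainable.

A structural caveat, implemented as printed rather than "fixed": the
equilibrium expressions W* = r·∅/u are rate ratios (dimensionless), and at
a strict coexistence equilibrium the Jacobian has a zero eigenvalue; the
per-site analysis therefore evaluates the Jacobian at the imposed site
ratio, which is the only quantity the matrix actually depends on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    IntegrationError,
    InvalidSettingsError,
    UnsupportedConfigurationError,
)

__all__ = [
    "DynParams",
    "SystemState",
    "StabilityResult",
    "CalibrationResult",
    "DEFAULT_SITE_RATIOS",
    "REPORTED_REGIMES",
    "phi_shrub",
    "phi_herb",
    "vector_field",
    "simulate",
    "equilibrium_biomass",
    "jacobian_analytic",
    "eigen_stability",
    "site_stability",
    "bifurcation_scan",
    "calibrate_regimes",
]

#: Reported per-site herb-to-shrub ratios of the revegetation
#: chronosequence (CK = natural vegetation), used as dynamics-validation
#: defaults.
DEFAULT_SITE_RATIOS: dict[str, float] = {
    "1953a": 0.81,
    "1970a": 0.86,
    "1995a": 1.01,
    "2000a": 1.03,
    "2005a": 1.05,
    "2009a": 1.08,
    "2015a": 1.45,
    "2020a": 1.61,
    "CK": 1.40,
}

#: Dynamical regime reported for each site (sign of the dominant
#: eigenvalue's real part; "marginal" = critical/bifurcation state).
REPORTED_REGIMES: dict[str, str] = {
    "1953a": "stable",
    "1970a": "stable",
    "1995a": "stable",
    "2000a": "stable",
    "2005a": "stable",
    "2009a": "stable",
    "2015a": "unstable",
    "2020a": "unstable",
    "CK": "marginal",
}


@dataclass(frozen=True)
class DynParams:
    """Model parameters (rates in 1/time, the rest dimensionless)."""

    r_s: float = 0.35   # shrub intrinsic growth rate
    u_s: float = 0.08   # shrub death rate
    r_h: float = 0.80   # herb intrinsic growth rate
    u_h: float = 0.25   # herb death rate
    k: float = 1.2      # shrub stress-decay steepness
    b: float = 3.0      # herb sigmoid steepness
    R0: float = 0.9     # shrub stress onset ratio
    Rc: float = 1.4     # herb sigmoid midpoint ratio
    k_h: float = 1.0    # herb contribution-per-biomass coefficient
    k_s: float = 1.0    # shrub contribution-per-biomass coefficient

    def validate(self) -> "DynParams":
        for name in ("r_s", "u_s", "r_h", "u_h", "k", "b", "R0", "Rc", "k_h", "k_s"):
            if getattr(self, name) <= 0:
                raise InvalidSettingsError(f"{name} must be > 0")
        return self


@dataclass(frozen=True)
class SystemState:
    """Biomass state; R is the derived water-use ratio k_h·W_h/(k_s·W_s)."""

    W_s: float
    W_h: float
    R: float

    @classmethod
    def from_biomass(
        cls, W_s: float, W_h: float, params: DynParams | None = None
    ) -> "SystemState":
        if W_s <= 0:
            raise DegenerateInputError(f"W_s must be > 0, got {W_s}")
        if W_h < 0:
            raise DegenerateInputError(f"W_h must be >= 0, got {W_h}")
        p = params or DynParams()
        return cls(W_s=W_s, W_h=W_h, R=p.k_h * W_h / (p.k_s * W_s))

    def check(self, params: DynParams, tol: float = 1e-12) -> None:
        r = params.k_h * self.W_h / (params.k_s * self.W_s)
        if abs(r - self.R) > tol * max(1.0, abs(r)):
            raise DegenerateInputError(
                f"stored R={self.R} inconsistent with biomasses (recomputed {r})"
            )


@dataclass(frozen=True)
class StabilityResult:
    jacobian: np.ndarray
    eigenvalues: tuple[complex, complex]
    max_re: float
    regime: str  # stable | marginal | unstable
    evaluation_point: SystemState | None = None


def phi_shrub(R: float, params: DynParams | None = None) -> float:
    """Shrub growth modulation: 1 up to the stress onset R₀, exponential
    decay beyond. Continuous, in (0, 1]."""
    p = params or DynParams()
    if R < 0:
        raise DegenerateInputError(f"R must be >= 0, got {R}")
    return float(np.exp(-p.k * max(R - p.R0, 0.0)))


def phi_herb(R: float, params: DynParams | None = None) -> float:
    """Herb growth modulation sigmoid: ≈2 at low ratios, 1 at the midpoint
    Rc, →0 at high ratios. Strictly decreasing, in (0, 2)."""
    p = params or DynParams()
    if R < 0:
        raise DegenerateInputError(f"R must be >= 0, got {R}")
    return float(2.0 / (1.0 + np.exp(p.b * (R - p.Rc))))


def _dphi_shrub(R: float, p: DynParams) -> float:
    # one-sided (right) derivative at the kink R = R0
    return -p.k * phi_shrub(R, p) if R >= p.R0 else 0.0


def _dphi_herb(R: float, p: DynParams) -> float:
    e = np.exp(p.b * (R - p.Rc))
    return float(-2.0 * p.b * e / (1.0 + e) ** 2)


def _as_ratio(state) -> float:
    return state.R if isinstance(state, SystemState) else float(state)


def vector_field(state: SystemState, params: DynParams | None = None) -> tuple[float, float]:
    """(dW_s/dt, dW_h/dt) at a state. W_h = 0 is the shrub-only limit
    (R = 0); non-positive W_s is a domain error."""
    p = (params or DynParams()).validate()
    if state.W_s <= 0 or state.W_h < 0:
        raise DegenerateInputError(
            f"biomasses must satisfy W_s > 0, W_h >= 0; got ({state.W_s}, {state.W_h})"
        )
    R = p.k_h * state.W_h / (p.k_s * state.W_s)
    dWs = p.r_s * phi_shrub(R, p) * state.W_s - p.u_s * state.W_s
    dWh = p.r_h * phi_herb(R, p) * state.W_h - p.u_h * state.W_h
    return dWs, dWh


def simulate(
    initial: SystemState,
    params: DynParams | None = None,
    t_span: tuple[float, float] = (0.0, 50.0),
    step: float = 0.01,
    floor: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the system with the classical fixed-step RK4 scheme.

    The exact flow preserves positivity (each equation is linear in its own
    biomass); the integrator clips at ``floor`` and warns if the clip is
    ever active. Non-finite values raise :class:`IntegrationError` naming
    the failing time.
    """
    p = (params or DynParams()).validate()
    if step <= 0:
        raise InvalidSettingsError(f"step must be > 0, got {step}")
    t0, t1 = t_span
    n = max(1, int(round((t1 - t0) / step)))
    ts = t0 + step * np.arange(n + 1)
    y = np.empty((n + 1, 2))
    y[0] = (initial.W_s, initial.W_h)
    clipped = False

    def f(v):
        s = SystemState.from_biomass(max(v[0], floor), max(v[1], 0.0), p)
        return np.asarray(vector_field(s, p))

    for i in range(n):
        v = y[i]
        k1 = f(v)
        k2 = f(v + 0.5 * step * k1)
        k3 = f(v + 0.5 * step * k2)
        k4 = f(v + step * k3)
        nxt = v + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(nxt)):
            raise IntegrationError(
                f"non-finite state at t = {ts[i + 1]:.6g}; reduce the step",
                t=float(ts[i + 1]),
            )
        if (nxt < floor).any():
            clipped = True
            nxt = np.maximum(nxt, floor)
        y[i + 1] = nxt
    if clipped:
        warnings.warn("trajectory clipped at the positivity floor", stacklevel=2)
    return pd.DataFrame({"t": ts, "W_s": y[:, 0], "W_h": y[:, 1]})


def equilibrium_biomass(params: DynParams | None, R: float) -> tuple[float, float]:
    """Equilibrium expressions W_s* = r_s·∅(R)/u_s, W_h* = r_h·φ(R)/u_h,
    evaluated verbatim (note these are rate ratios; see module docstring)."""
    p = (params or DynParams()).validate()
    return (
        p.r_s * phi_shrub(R, p) / p.u_s,
        p.r_h * phi_herb(R, p) / p.u_h,
    )


def jacobian_analytic(
    state: SystemState | float,
    params: DynParams | None = None,
    form: str = "printed",
) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field.

    ``form="printed"`` uses the canonical entries

        J11 = r_s∅ − r_s·R·∂∅ − u_s      J12 = r_s·∂∅
        J21 = −r_h·R²·∂φ                 J22 = r_hφ + r_h·R·∂φ − u_h

    which the chain rule yields exactly when k_h = k_s (the matrix then
    depends on the state only through R). ``form="general"`` carries the
    k_h/k_s factors on the off-diagonal and is valid for any coefficients.

    ``state`` may be a :class:`SystemState` or the ratio R directly.
    """
    p = (params or DynParams()).validate()
    R = _as_ratio(state)
    if R < 0:
        raise DegenerateInputError(f"R must be >= 0, got {R}")
    if form not in ("printed", "general"):
        raise InvalidSettingsError(f"unknown form {form!r}")
    if form == "printed" and p.k_h != p.k_s:
        raise UnsupportedConfigurationError(
            "printed-form Jacobian requires k_h = k_s; use form='general'"
        )
    dphi_s = _dphi_shrub(R, p)
    dphi_h = _dphi_herb(R, p)
    ratio = p.k_h / p.k_s if form == "general" else 1.0
    j11 = p.r_s * phi_shrub(R, p) - p.r_s * R * dphi_s - p.u_s
    j12 = p.r_s * dphi_s * ratio
    j21 = -p.r_h * R**2 * dphi_h / ratio
    j22 = p.r_h * phi_herb(R, p) + p.r_h * R * dphi_h - p.u_h
    return np.array([[j11, j12], [j21, j22]])


def eigen_stability(
    J: np.ndarray,
    zero_tol: float = 0.02,
    evaluation_point: SystemState | None = None,
) -> StabilityResult:
    """Eigenvalues via the trace/determinant formula
    λ = tr/2 ± sqrt((tr/2)² − det) and regime from the dominant real part:
    stable below −zero_tol, unstable above +zero_tol, else marginal."""
    J = np.asarray(J, dtype=float)
    if J.shape != (2, 2):
        raise DegenerateInputError(f"expected a 2x2 matrix, got shape {J.shape}")
    half_tr = np.trace(J) / 2.0
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = complex(half_tr**2 - det)
    root = np.sqrt(disc)
    lam = (complex(half_tr) + root, complex(half_tr) - root)
    max_re = max(l.real for l in lam)
    if max_re < -zero_tol:
        regime = "stable"
    elif max_re > zero_tol:
        regime = "unstable"
    else:
        regime = "marginal"
    return StabilityResult(
        jacobian=J,
        eigenvalues=lam,
        max_re=float(max_re),
        regime=regime,
        evaluation_point=evaluation_point,
    )


def site_stability(
    R: float, params: DynParams | None = None, zero_tol: float = 0.02
) -> StabilityResult:
    """Stability at a site's observed ratio: evaluation state from the
    equilibrium expressions with the site's R imposed, analytic Jacobian,
    eigenvalue classification."""
    p = (params or DynParams()).validate()
    if R <= 0:
        raise DegenerateInputError(f"R must be > 0, got {R}")
    ws, wh = equilibrium_biomass(p, R)
    state = SystemState(W_s=ws, W_h=wh, R=R)
    form = "printed" if p.k_h == p.k_s else "general"
    J = jacobian_analytic(R, p, form=form)
    return eigen_stability(J, zero_tol=zero_tol, evaluation_point=state)


def bifurcation_scan(
    params: DynParams | None,
    R_grid: Sequence[float],
    zero_tol: float = 0.02,
    stability_fn: Callable[[float], StabilityResult] | None = None,
) -> tuple[pd.DataFrame, list[float]]:
    """Dominant real part and regime over a ratio grid.

    Returns the per-grid-point table and the list of candidate bifurcation
    points: sign changes of max Re(λ), located by linear interpolation
    between neighbouring grid points. ``stability_fn`` may replace
    :func:`site_stability` (e.g. for constructed matrix families).
    """
    grid = np.asarray(list(R_grid), dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0) or grid[0] <= 0:
        raise InvalidSettingsError("R_grid must be strictly increasing and positive")
    fn = stability_fn or (lambda r: site_stability(r, params, zero_tol=zero_tol))
    rows = [(r, (res := fn(r)).max_re, res.regime) for r in grid]
    table = pd.DataFrame(rows, columns=["R", "max_re", "regime"])
    crossings = []
    mr = table["max_re"].to_numpy()
    for i in range(len(grid) - 1):
        a, b = mr[i], mr[i + 1]
        if a == 0.0:
            crossings.append(float(grid[i]))
        elif a * b < 0:
            crossings.append(float(grid[i] - a * (grid[i + 1] - grid[i]) / (b - a)))
    if mr[-1] == 0.0:
        crossings.append(float(grid[-1]))
    return table, crossings


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the regime-pattern search."""

    params: DynParams
    n_misclassified: int
    attainable: bool
    misclassified: list[tuple[float, str, str]]  # (R, wanted, got)
    table: pd.DataFrame  # per-target evaluation under the fitted params

    def summary(self) -> str:
        lines = [
            f"regime calibration: {self.n_misclassified} of "
            f"{len(self.table)} targets misclassified "
            f"({'attainable' if self.attainable else 'NOT attainable'})"
        ]
        for r, want, got in self.misclassified:
            lines.append(f"  R = {r:g}: wanted {want}, best achievable {got}")
        return "\n".join(lines)


def calibrate_regimes(
    targets: Sequence[tuple[float, str]],
    params: DynParams | None = None,
    free: Sequence[str] = ("R0", "Rc", "k", "b"),
    grids: dict[str, Sequence[float]] | None = None,
    zero_tol: float = 0.02,
) -> CalibrationResult:
    """Deterministic grid search of the modulation parameters for a target
    regime pattern.

    Minimizes the misclassification count over ``targets`` (pairs of ratio
    and wanted regime); ties are broken by the summed margin of the
    dominant real part on the regime-consistent side. If the supplied
    parameters already reproduce every target they are returned unchanged.
    The result states explicitly whether the full pattern is attainable —
    a negative answer is reported, never papered over.
    """
    p = (params or DynParams()).validate()
    tgt = list(targets)
    if len(tgt) < 2:
        raise InsufficientDataError(f"need >= 2 calibration targets, got {len(tgt)}")
    bad_free = [f for f in free if f not in ("R0", "Rc", "k", "b")]
    if bad_free:
        raise InvalidSettingsError(f"free parameters must be in R0/Rc/k/b, got {bad_free}")
    if not free:
        raise InvalidSettingsError("empty free parameter set: nothing to fit")

    def score(cand: DynParams) -> tuple[int, float, list[tuple[float, str, str]]]:
        miss, margin, details = 0, 0.0, []
        for r, want in tgt:
            res = site_stability(r, cand, zero_tol=zero_tol)
            got = res.regime
            if got != want:
                miss += 1
                # distance of max_re from the regime-consistent sign region
                if want == "stable":
                    margin += max(res.max_re + zero_tol, 0.0)
                elif want == "unstable":
                    margin += max(zero_tol - res.max_re, 0.0)
                else:
                    margin += abs(res.max_re) - zero_tol
                details.append((r, want, got))
        return miss, margin, details

    def target_table(cand: DynParams) -> pd.DataFrame:
        rows = [
            (r, (res := site_stability(r, cand, zero_tol=zero_tol)).max_re, res.regime)
            for r in sorted({r for r, _ in tgt})
        ]
        return pd.DataFrame(rows, columns=["R", "max_re", "regime"])

    miss0, margin0, det0 = score(p)
    if miss0 == 0:
        return CalibrationResult(p, 0, True, [], target_table(p))

    default_grids: dict[str, Sequence[float]] = {
        "R0": np.round(np.arange(0.1, 2.01, 0.1), 3),
        "Rc": np.round(np.arange(0.2, 2.41, 0.2), 3),
        "k": np.round(np.geomspace(0.3, 15.0, 8), 3),
        "b": np.round(np.geomspace(0.5, 10.0, 6), 3),
    }
    grids = {**default_grids, **(grids or {})}
    best = (miss0, margin0, p, det0)
    for combo in product(*(grids[f] for f in free)):
        cand = replace(p, **dict(zip(free, map(float, combo))))
        try:
            cand.validate()
        except InvalidSettingsError:
            continue
        miss, margin, det = score(cand)
        if (miss, margin) < (best[0], best[1]):
            best = (miss, margin, cand, det)
            if miss == 0:
                break
    miss, _, fitted, details = best
    return CalibrationResult(
        params=fitted,
        n_misclassified=miss,
        attainable=miss == 0,
        misclassified=details,
        table=target_table(fitted),
    )

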