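"""DSC thermogram analysis: progress baseline, two-state van't Hoff fit,
Gaussian deconvolution, and temperature extrapolation of the thermodynamic
state functions.

Model
-----
A unimolecular two-state equilibrium folded <-> unfolded with

    dG(T) = dH_M * (1 - T/T_M) + dCp * (T - T_M - T * ln(T/T_M))
    K(T)  = exp(-dG(T) / (R*T)),      theta = K / (1 + K)
    Cp_exc(T) = dH(T) * dtheta/dT,    dH(T) = dH_M + dCp * (T - T_M)

with R = 1.9872e-3 kcal/(mol*K).  ``theta`` is the unfolded fraction, so
``dtheta/dT = theta*(1-theta)*dH(T)/(R*T^2)`` (van't Hoff).  Although duplex
dissociation is strictly bimolecular, the covalently tethered conjugate and
the free duplex are both treated with the unimolecular equations, which is
the convention the melting-parameter bookkeeping here follows; a bimolecular
variant is deliberately out of scope.

Units: temperatures Kelvin internally (I/O converts from Celsius), energies
kcal/mol, heat capacities kcal/(mol*K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitConvergenceError, FitError, ProfileError

R_KCAL = 1.9872e-3  # gas constant, kcal/(mol*K)
C_TO_K = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + C_TO_K


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - C_TO_K


@dataclass
class Thermogram:
    """A molar excess-heat-capacity trace vs temperature.

    ``temperature`` strictly increasing, Kelvin; ``cp`` in kcal/(mol*K).
    ``concentration`` (mg/mL) and ``molar_mass`` (Da) record how a raw
    instrument signal was normalized, when applicable.
    """

    temperature: np.ndarray
    cp: np.ndarray
    label: str = ""
    concentration: float | None = None
    molar_mass: float | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature.shape != self.cp.shape:
            raise ProfileError("temperature and cp must have equal length")
        if len(self.temperature) < 50:
            raise ProfileError(
                f"thermogram needs >= 50 points spanning the transition, "
                f"got {len(self.temperature)}"
            )
        if np.any(np.diff(self.temperature) <= 0):
            raise ProfileError("temperature grid must be strictly increasing")


def molar_normalize(
    raw_signal: np.ndarray,
    molar_mass: float,
    concentration_mg_ml: float,
    cell_volume_ml: float = 0.299,
) -> np.ndarray:
    """Convert a raw heat-capacity signal (kcal/K) to molar units.

    moles in cell = concentration * volume / molar_mass, so
    Cp_molar = signal * molar_mass / (concentration * volume).
    """
    moles = concentration_mg_ml * cell_volume_ml / (molar_mass * 1e3)
    return np.asarray(raw_signal, dtype=float) / moles


# ---------------------------------------------------------------------------
# Two-state model primitives (single source of truth; synthkit reuses these).
# ---------------------------------------------------------------------------

def two_state_delta_g(T, t_m: float, dh_m: float, dcp: float):
    """dG(T) of the unimolecular two-state transition, kcal/mol."""
    T = np.asarray(T, dtype=float)
    return dh_m * (1.0 - T / t_m) + dcp * (T - t_m - T * np.log(T / t_m))


def two_state_theta(T, t_m: float, dh_m: float, dcp: float):
    """Unfolded fraction theta(T) = K/(1+K)."""
    T = np.asarray(T, dtype=float)
    # -dG/(RT); expit-style stable evaluation
    x = -two_state_delta_g(T, t_m, dh_m, dcp) / (R_KCAL * T)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def two_state_excess_cp(T, t_m: float, dh_m: float, dcp: float):
    """Analytic excess heat capacity dH(T) * dtheta/dT, kcal/(mol*K)."""
    T = np.asarray(T, dtype=float)
    theta = two_state_theta(T, t_m, dh_m, dcp)
    dh_t = dh_m + dcp * (T - t_m)
    return dh_t * dh_t * theta * (1.0 - theta) / (R_KCAL * T * T)


@dataclass
class TwoStateModel:
    """Fitted two-state melting parameters."""

    t_m: float  # K
    dh_m: float  # kcal/mol
    dcp: float  # kcal/(mol*K)
    baseline_folded: tuple[float, float] = (0.0, 0.0)  # (b0, b1)
    baseline_unfolded: tuple[float, float] = (0.0, 0.0)
    residual_norm: float = float("nan")

    def __post_init__(self):
        if self.dh_m <= 0:
            raise FitError(f"dH_M must be positive, got {self.dh_m}")

    @property
    def t_m_celsius(self) -> float:
        return self.t_m - C_TO_K

    def excess_cp(self, T):
        return two_state_excess_cp(T, self.t_m, self.dh_m, self.dcp)


@dataclass
class BaselineResult:
    """Progress-baseline decomposition of a thermogram."""

    temperature: np.ndarray
    baseline: np.ndarray
    excess_cp: np.ndarray
    theta: np.ndarray
    folded_coefficients: tuple[float, float]  # Cp_f(T) = b0 + b1*T
    unfolded_coefficients: tuple[float, float]
    dcp_at_tm: float
    t_peak: float
    iterations: int


def guess_transition_window(
    thermogram: Thermogram, half_width: float = 12.0
) -> tuple[float, float]:
    """Heuristic transition window: peak of the detrended trace +/- half_width (K)."""
    T, cp = thermogram.temperature, thermogram.cp
    slope = (cp[-1] - cp[0]) / (T[-1] - T[0])
    detrended = cp - (cp[0] + slope * (T - T[0]))
    t_peak = T[int(np.argmax(detrended))]
    return (max(t_peak - half_width, T[0] + 1e-9), min(t_peak + half_width, T[-1] - 1e-9))


def fit_progress_baseline(
    thermogram: Thermogram,
    transition_window: tuple[float, float] | None = None,
    max_iter: int = 50,
    rtol: float = 1e-6,
) -> BaselineResult:
    """Iterative sigmoidal (progress) baseline subtraction.

    Linear pre- and post-transition baselines Cp_f, Cp_u are interpolated by
    the running normalized integral of the excess signal:
    ``baseline = Cp_f + theta_hat*(Cp_u - Cp_f)``, iterated to convergence.
    dCp is reported as Cp_u(T_peak) - Cp_f(T_peak).
    """
    T, cp = thermogram.temperature, thermogram.cp
    if transition_window is None:
        transition_window = guess_transition_window(thermogram)
    lo, hi = transition_window
    if lo >= hi or lo >= T[-1] or hi <= T[0]:
        raise ProfileError(f"transition window [{lo}, {hi}] outside data range")
    pre = T < lo
    post = T > hi
    if pre.sum() < 2 or post.sum() < 2:
        raise ProfileError(
            "transition window leaves fewer than 2 points on a flank"
        )
    bf = np.polyfit(T[pre], cp[pre], 1)[::-1]  # (b0, b1)
    bu = np.polyfit(T[post], cp[post], 1)[::-1]
    cp_f = bf[0] + bf[1] * T
    cp_u = bu[0] + bu[1] * T

    theta_hat = np.where(T < 0.5 * (lo + hi), 0.0, 1.0)
    baseline = cp_f + theta_hat * (cp_u - cp_f)
    trace = []
    for it in range(1, max_iter + 1):
        excess = cp - baseline
        integral = np.concatenate(
            ([0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1]) * np.diff(T)))
        )
        total = integral[-1]
        if total <= 0:
            raise FitConvergenceError(
                "excess heat capacity integrates to <= 0; no transition found",
                trace,
            )
        theta_hat = np.clip(integral / total, 0.0, 1.0)
        new_baseline = cp_f + theta_hat * (cp_u - cp_f)
        delta = np.max(np.abs(new_baseline - baseline)) / max(
            np.max(np.abs(baseline)), 1e-12
        )
        trace.append(delta)
        baseline = new_baseline
        if delta < rtol:
            break
    else:
        raise FitConvergenceError(
            f"progress baseline did not converge in {max_iter} iterations",
            trace,
        )
    excess = cp - baseline
    t_peak = T[int(np.argmax(excess))]
    dcp = (bu[0] + bu[1] * t_peak) - (bf[0] + bf[1] * t_peak)
    return BaselineResult(
        temperature=T,
        baseline=baseline,
        excess_cp=excess,
        theta=theta_hat,
        folded_coefficients=(float(bf[0]), float(bf[1])),
        unfolded_coefficients=(float(bu[0]), float(bu[1])),
        dcp_at_tm=float(dcp),
        t_peak=float(t_peak),
        iterations=it,
    )


def fit_two_state(
    temperature: np.ndarray,
    excess_cp: np.ndarray,
    dh_bounds: tuple[float, float] = (10.0, 1000.0),
    dcp_bounds: tuple[float, float] = (-5.0, 5.0),
) -> TwoStateModel:
    """Least-squares fit of the two-state excess heat capacity model.

    Initialized at the peak temperature with the calorimetric integral as
    the enthalpy guess; trust-region reflective with parameter bounds
    (T_M inside the data range).  A boundary solution raises ``FitError``.
    """
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(excess_cp, dtype=float)
    if T.shape != y.shape or len(T) < 10:
        raise FitError("need matching temperature/excess arrays, >= 10 points")
    if np.all(np.abs(y) < 1e-12):
        raise FitError("excess trace is identically zero; nothing to fit")

    t0 = T[int(np.argmax(y))]
    dh0 = float(np.trapezoid(np.clip(y, 0.0, None), T))
    dh0 = min(max(dh0, dh_bounds[0] * 1.5), dh_bounds[1] / 1.5)

    lb = [T[0], dh_bounds[0], dcp_bounds[0]]
    ub = [T[-1], dh_bounds[1], dcp_bounds[1]]

    def resid(p):
        return two_state_excess_cp(T, p[0], p[1], p[2]) - y

    sol = optimize.least_squares(
        resid, x0=[t0, dh0, 0.0], bounds=(lb, ub), method="trf"
    )
    if not sol.success:
        raise FitError(f"two-state fit failed: {sol.message}")
    t_m, dh_m, dcp = sol.x
    eps = 1e-6
    if not (lb[0] + eps < t_m < ub[0] - eps) or not (
        lb[1] + eps < dh_m < ub[1] - eps
    ):
        raise FitError(
            f"two-state fit hit a parameter bound: T_M={t_m}, dH_M={dh_m}"
        )
    return TwoStateModel(
        t_m=float(t_m),
        dh_m=float(dh_m),
        dcp=float(dcp),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def integrate_enthalpy(
    temperature: np.ndarray,
    excess_cp: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Calorimetric enthalpy: trapezoidal area under the excess Cp (kcal/mol)."""
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(excess_cp, dtype=float)
    if window is not None:
        m = (T >= window[0]) & (T <= window[1])
        T, y = T[m], y[m]
    return float(np.trapezoid(y, T))


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component of the excess heat capacity.

    ``area`` is the component heat in kcal/mol; the amplitude is
    ``area / (sigma * sqrt(2*pi))``.
    """

    center: float  # K
    sigma: float  # K
    area: float  # kcal/mol

    def __post_init__(self):
        if self.sigma <= 0:
            raise FitError(f"sigma must be positive, got {self.sigma}")
        if self.area <= 0:
            raise FitError(f"area must be positive, got {self.area}")

    def evaluate(self, T):
        T = np.asarray(T, dtype=float)
        return (
            self.area
            / (self.sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((T - self.center) / self.sigma) ** 2)
        )


def _gaussian_sum(T, params):
    out = np.zeros_like(np.asarray(T, dtype=float))
    for c, s, a in params.reshape(-1, 3):
        out += a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((T - c) / s) ** 2)
    return out


def _greedy_peel_init(T: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Initial components by residual peeling: repeatedly place a Gaussian
    at the residual maximum with the local half-width, then subtract."""
    r = y.copy()
    step = float(np.median(np.diff(T)))
    params = []
    for _ in range(k):
        i = int(np.argmax(r))
        h = max(float(r[i]), 1e-9)
        half = h / 2.0
        j = i
        while j + 1 < len(r) and r[j + 1] > half:
            j += 1
        l = i
        while l - 1 >= 0 and r[l - 1] > half:
            l -= 1
        fwhm = max(T[j] - T[l], 2.0 * step)
        s = fwhm / 2.355
        a = h * s * np.sqrt(2.0 * np.pi)
        params.append((float(T[i]), s, a))
        r = r - a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((T - T[i]) / s) ** 2)
    return np.ravel(params)


def deconvolve_gaussians(
    temperature: np.ndarray,
    excess_cp: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> list[GaussianComponent]:
    """Decompose the excess Cp into K Gaussian components (sorted by center).

    Two deterministic initializations — centers at the K quantiles of the
    cumulative area with equal area split, and greedy residual peeling —
    plus a few seeded jittered restarts; the lowest-cost solution wins.
    Component heats are the areas.
    """
    if not 1 <= k <= 5:
        raise FitError(f"component count must be in 1..5, got {k}")
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(excess_cp, dtype=float)
    y_pos = np.clip(y, 0.0, None)
    total = np.trapezoid(y_pos, T)
    if total <= 0:
        raise FitError("excess trace has no positive area to deconvolve")

    cum = np.concatenate(
        ([0.0], np.cumsum(0.5 * (y_pos[1:] + y_pos[:-1]) * np.diff(T)))
    )
    cum /= cum[-1]
    qs = (np.arange(k) + 0.5) / k
    centers0 = np.interp(qs, cum, T)
    span = T[-1] - T[0]
    sigma0 = max(span / (6.0 * k), 0.5)

    x_quant = np.ravel([[c, sigma0, total / k] for c in centers0])
    x_peel = _greedy_peel_init(T, y, k)
    lb = np.ravel([[T[0], 0.05, 1e-6]] * k)
    ub = np.ravel([[T[-1], span, 10.0 * total]] * k)

    def resid(p):
        return _gaussian_sum(T, p) - y

    # Sequential refinement: least-squares fit one component at a time on
    # the running residual, then let the joint fit polish from there.
    x_seq = []
    r = y.copy()
    for j in range(k):
        g0 = _greedy_peel_init(T, r, 1)
        try:
            one = optimize.least_squares(
                lambda p: _gaussian_sum(T, p) - r,
                x0=np.clip(g0, lb[:3], ub[:3]),
                bounds=(lb[:3], ub[:3]),
                method="trf",
            )
            g0 = one.x
        except Exception:
            pass
        x_seq.extend(g0.tolist())
        r = r - _gaussian_sum(T, np.asarray(g0))
    x_seq = np.asarray(x_seq)

    rng = np.random.default_rng(seed)
    inits = [x_quant, x_peel, x_seq]
    for trial in range(max(n_restarts - 2, 0)):
        base = inits[trial % 2].copy()
        base[0::3] = np.clip(
            base[0::3] + rng.normal(0.0, sigma0, size=k), T[0], T[-1]
        )
        base[1::3] = base[1::3] * rng.uniform(0.5, 2.0, size=k)
        inits.append(base)
    best = None
    for x_init in inits:
        try:
            sol = optimize.least_squares(
                resid, x0=np.clip(x_init, lb, ub), bounds=(lb, ub), method="trf"
            )
        except Exception:  # optimizer blowup on a restart is not fatal
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("gaussian deconvolution failed in all restarts")
    comps = [
        GaussianComponent(center=float(c), sigma=float(s), area=float(a))
        for c, s, a in best.x.reshape(-1, 3)
    ]
    return sorted(comps, key=lambda g: g.center)


@dataclass
class ThermoFunctions:
    """State functions extrapolated to a reference temperature.

    dS_M = dH_M / T_M (dG(T_M) = 0);
    dH(T) = dH_M + dCp*(T - T_M);
    dS(T) = dS_M + dCp*ln(T/T_M);
    dG(T) = dH(T) - T*dS(T).
    """

    temperature: float  # K
    delta_h: float  # kcal/mol
    delta_s: float  # kcal/(mol*K)
    delta_g: float  # kcal/mol
    delta_s_m: float
    model: TwoStateModel = field(repr=False, default=None)


def thermo_at(model: TwoStateModel, T: float) -> ThermoFunctions:
    """Evaluate dH, dS, dG at temperature T (K) from fitted melting params."""
    if T <= 0:
        raise FitError(f"temperature must be positive Kelvin, got {T}")
    ds_m = model.dh_m / model.t_m
    dh = model.dh_m + model.dcp * (T - model.t_m)
    ds = ds_m + model.dcp * np.log(T / model.t_m)
    dg = dh - T * ds
    return ThermoFunctions(
        temperature=float(T),
        delta_h=float(dh),
        delta_s=float(ds),
        delta_g=float(dg),
        delta_s_m=float(ds_m),
        model=model,
    )


def delta_g_difference(
    model_free: TwoStateModel, model_bound: TwoStateModel, T: float
) -> float:
    """dG_bound(T) - dG_free(T): the stabilization from the bound ligand."""
    return thermo_at(model_bound, T).delta_g - thermo_at(model_free, T).delta_g


def analyze_thermogram(
    thermogram: Thermogram,
    transition_window: tuple[float, float] | None = None,
    n_gaussians: int | None = None,
    t_ref: float = 298.0,
) -> dict:
    """Full single-thermogram pipeline; returns a result bundle.

    Baseline -> two-state fit -> calorimetric integral -> (optional)
    Gaussian deconvolution -> state functions at ``t_ref``.
    """
    base = fit_progress_baseline(thermogram, transition_window)
    model = fit_two_state(base.temperature, base.excess_cp)
    dh_cal = integrate_enthalpy(base.temperature, base.excess_cp)
    out = {
        "label": thermogram.label,
        "baseline": base,
        "model": model,
        "dh_calorimetric": dh_cal,
        "thermo_at_ref": thermo_at(model, t_ref),
    }
    if n_gaussians:
        out["gaussians"] = deconvolve_gaussians(
            base.temperature, base.excess_cp, n_gaussians
        )
    return out
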