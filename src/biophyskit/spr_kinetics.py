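"""Bivalent-analyte SPR kinetics: simulation, global fitting, avidity.

The surface reaction scheme couples a soluble analyte A (molar) to an
immobilised ligand L (surface density, resonance units):

    A + L  <-> AL      (ka1 [1/M/s], kd1 [1/s])
    AL + L <-> AL2     (ka2 [1/RU/s], kd2 [1/s])

so a single analyte molecule can bridge two ligand molecules.  The surface
species obey

    dL/dt   = -(ka1*A*L - kd1*AL) - (ka2*AL*L - kd2*AL2)
    dAL/dt  =  (ka1*A*L - kd1*AL) - (ka2*AL*L - kd2*AL2)
    dAL2/dt =   ka2*AL*L - kd2*AL2

with L(0) = Rmax and AL(0) = AL2(0) = 0, which conserves L + AL + 2*AL2
exactly.  The instrument response is modelled as R(t) = AL(t) + AL2(t):
each captured analyte molecule adds its mass to the surface once, whether
or not it bridges.  Setting ka2 = kd2 = 0 reduces the scheme to the 1:1
Langmuir model, for which the association phase has the closed form
R(t) = Req*(1 - exp(-(ka1*C + kd1)*t)) with Req = Rmax*C/(C + kd1/ka1).

The steady-state (avidity) analysis fits equilibrium responses to the
saturation hyperbola Req(C) = Rmax_eq*C/(C + KD_app_tot); KD_app_tot
absorbs both binding steps and is therefore generally much larger than the
first-step constant KD_app1 = kd1/ka1 when bridging is strong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

from .errors import IntegrationError, PreconditionError

__all__ = [
    "RateConstants",
    "SurfaceState",
    "InjectionProtocol",
    "Sensorgram",
    "KineticFitResult",
    "SteadyStateResult",
    "ModelComparison",
    "CIB2_A7BM_MG",
    "CIB2_A7BM_CAMG",
    "bivalent_rhs",
    "simulate_sensorgram",
    "simulate_series",
    "langmuir_association",
    "fit_global",
    "compare_models",
    "kd_app1",
    "steady_state_affinity",
]

PARAM_NAMES = ("ka1", "ka2", "kd1", "kd2", "rmax")


@dataclass(frozen=True)
class RateConstants:
    """The four kinetic constants of the bivalent-analyte scheme.

    ka1 : 1/M/s   analyte capture by free ligand
    ka2 : 1/RU/s  bridging of a 1:1 complex by a second ligand
    kd1 : 1/s     dissociation of the 1:1 complex
    kd2 : 1/s     un-bridging of the 2:1 complex

    ``ka2 = kd2 = 0`` reduces the model to 1:1 Langmuir binding.
    """

    ka1: float
    ka2: float
    kd1: float
    kd2: float

    def __post_init__(self):
        for name in ("ka1", "ka2", "kd1", "kd2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise PreconditionError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def is_langmuir(self) -> bool:
        return self.ka2 == 0.0 and self.kd2 == 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ka1, self.ka2, self.kd1, self.kd2])


#: Published kinetic constants for the CIB2 / alpha7B membrane-proximal
#: peptide interaction, used as realistic defaults for synthetic data.
CIB2_A7BM_MG = RateConstants(ka1=3.1e4, ka2=1.9e-3, kd1=3.6e-1, kd2=2.0e-2)
CIB2_A7BM_CAMG = RateConstants(ka1=1.6e4, ka2=4.2e-4, kd1=4.0e-1, kd2=5.3e-2)


@dataclass(frozen=True)
class SurfaceState:
    """Instantaneous surface composition in RU: free ligand L, 1:1 complex
    AL, bridged complex AL2."""

    L: float
    AL: float
    AL2: float

    def __post_init__(self):
        if min(self.L, self.AL, self.AL2) < 0:
            raise PreconditionError(f"surface species must be >= 0, got {self}")


@dataclass(frozen=True)
class InjectionProtocol:
    """One injection cycle: constant-concentration association phase
    followed by a buffer-only dissociation phase.

    Defaults: 120 s association (2-minute injection), 200 s dissociation,
    1 s sampling.  ``flow_rate_ul_min`` is recorded metadata only — the
    kinetic model carries no mass-transport term.
    """

    analyte_concentration: float  # M
    t_association: float = 120.0  # s
    t_dissociation: float = 200.0  # s
    sampling_interval: float = 1.0  # s
    flow_rate_ul_min: float = 20.0

    def __post_init__(self):
        if self.analyte_concentration < 0:
            raise PreconditionError("analyte concentration must be >= 0")
        if min(self.t_association, self.t_dissociation, self.sampling_interval) <= 0:
            raise PreconditionError("durations and sampling interval must be > 0")

    def time_grid(self) -> np.ndarray:
        t_end = self.t_association + self.t_dissociation
        n = int(round(t_end / self.sampling_interval))
        return np.linspace(0.0, n * self.sampling_interval, n + 1)


@dataclass
class Sensorgram:
    """A time/response trace with its injection protocol.

    ``species`` optionally carries the simulated (L, AL, AL2) trajectories
    as a (3, n) array; it is present on simulator output and None for
    traces read from files.
    """

    time: np.ndarray  # s, strictly increasing, time[0] == 0
    response: np.ndarray  # RU
    protocol: InjectionProtocol
    species: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise PreconditionError("time and response must have equal length")
        if self.time[0] != 0.0 or np.any(np.diff(self.time) <= 0):
            raise PreconditionError("time must start at 0 and be strictly increasing")

    @property
    def concentration(self) -> float:
        return self.protocol.analyte_concentration


def bivalent_rhs(
    state: SurfaceState, analyte_concentration: float, k: RateConstants
) -> tuple[float, float, float]:
    """Time derivatives (dL/dt, dAL/dt, dAL2/dt) of the bivalent scheme.

    The algebra conserves L + AL + 2*AL2: the returned derivatives satisfy
    dL + dAL + 2*dAL2 = 0 identically.
    """
    if analyte_concentration < 0:
        raise PreconditionError("analyte concentration must be >= 0")
    step1 = k.ka1 * analyte_concentration * state.L - k.kd1 * state.AL
    step2 = k.ka2 * state.AL * state.L - k.kd2 * state.AL2
    return (-step1 - step2, step1 - step2, step2)


def _rhs_vec(t, y, A, ka1, ka2, kd1, kd2):
    # stacked (L, AL, AL2) blocks for an arbitrary number of concentrations
    n = A.shape[0]
    L, AL, AL2 = y[:n], y[n : 2 * n], y[2 * n :]
    step1 = ka1 * A * L - kd1 * AL
    step2 = ka2 * AL * L - kd2 * AL2
    return np.concatenate([-step1 - step2, step1 - step2, step2])


def _integrate_series(
    k: RateConstants,
    rmax: float,
    concentrations: np.ndarray,
    protocol: InjectionProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the bivalent ODEs for several concentrations sharing one
    protocol.  Returns (time, species) with species shaped (n_conc, 3, n_t).
    """
    concentrations = np.asarray(concentrations, dtype=float)
    n = concentrations.shape[0]
    t = protocol.time_grid()
    ta = t[t <= protocol.t_association]
    td = t[t > protocol.t_association] - protocol.t_association

    y0 = np.concatenate([np.full(n, rmax), np.zeros(2 * n)])
    args = (concentrations, k.ka1, k.ka2, k.kd1, k.kd2)
    sol_a = solve_ivp(
        _rhs_vec, (0.0, ta[-1]), y0, t_eval=ta, args=args,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol_a.success:
        raise IntegrationError(
            "association-phase integration failed",
            {"message": sol_a.message, "constants": k, "rmax": rmax},
        )
    args0 = (np.zeros(n), k.ka1, k.ka2, k.kd1, k.kd2)
    sol_d = solve_ivp(
        _rhs_vec, (0.0, td[-1]), sol_a.y[:, -1], t_eval=td, args=args0,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol_d.success:
        raise IntegrationError(
            "dissociation-phase integration failed",
            {"message": sol_d.message, "constants": k, "rmax": rmax},
        )
    y = np.concatenate([sol_a.y, sol_d.y], axis=1)
    species = y.reshape(3, n, t.size).transpose(1, 0, 2)
    # tiny negative excursions from the integrator are clipped
    np.clip(species, 0.0, None, out=species)
    return t, species


def simulate_sensorgram(
    k: RateConstants,
    rmax: float,
    protocol: InjectionProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Sensorgram:
    """Integrate the bivalent scheme through one injection cycle.

    Association uses the protocol's constant analyte concentration;
    dissociation continues from the end state with analyte = 0.  The
    response is R(t) = AL(t) + AL2(t); the full species trajectories are
    attached to the returned sensorgram.
    """
    if rmax <= 0:
        raise PreconditionError("rmax must be > 0")
    t, species = _integrate_series(
        k, rmax, np.array([protocol.analyte_concentration]), protocol, rtol, atol
    )
    sp = species[0]
    return Sensorgram(time=t, response=sp[1] + sp[2], protocol=protocol, species=sp)


def simulate_series(
    k: RateConstants,
    rmax: float,
    concentrations,
    protocol: InjectionProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[Sensorgram]:
    """Simulate one sensorgram per concentration (shared protocol)."""
    if rmax <= 0:
        raise PreconditionError("rmax must be > 0")
    concentrations = np.asarray(concentrations, dtype=float)
    t, species = _integrate_series(k, rmax, concentrations, protocol, rtol, atol)
    out = []
    for c, sp in zip(concentrations, species):
        out.append(
            Sensorgram(
                time=t.copy(),
                response=sp[1] + sp[2],
                protocol=replace(protocol, analyte_concentration=float(c)),
                species=sp,
            )
        )
    return out


def langmuir_association(
    t: np.ndarray, k: RateConstants, rmax: float, concentration: float
) -> np.ndarray:
    """Closed-form 1:1 Langmuir association response.

    R(t) = Req*(1 - exp(-(ka1*C + kd1)*t)), Req = Rmax*C/(C + kd1/ka1).
    Used as an independent check of the ODE path when ka2 = kd2 = 0.
    """
    kobs = k.ka1 * concentration + k.kd1
    req = rmax * concentration / (concentration + k.kd1 / k.ka1)
    return req * (1.0 - np.exp(-kobs * np.asarray(t, dtype=float)))


def kd_app1(k: RateConstants) -> float:
    """First-step apparent dissociation constant KD_app1 = kd1/ka1 (M)."""
    if k.ka1 == 0:
        raise PreconditionError("kd_app1 undefined for ka1 = 0")
    return k.kd1 / k.ka1


@dataclass
class KineticFitResult:
    """Outcome of a global kinetic fit.

    ``kd_app1_molar`` is kd1/ka1 of the fitted constants, computed by
    :func:`kd_app1` (never stored independently).  ``stderr`` holds
    linear-scale standard errors from the Jacobian at the optimum (NaN
    when the information matrix is singular).
    """

    constants: RateConstants
    rmax: float
    model: str
    residual_sse: float
    per_curve_sse: np.ndarray
    n_points: int
    n_parameters: int
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    degenerate: bool = False
    message: str = ""
    baselines: np.ndarray | None = None

    @property
    def kd_app1_molar(self) -> float:
        return kd_app1(self.constants)

    @property
    def aic(self) -> float:
        n = self.n_points
        return n * np.log(max(self.residual_sse, 1e-300) / n) + 2 * self.n_parameters


def _check_grid(sensorgrams: list[Sensorgram]) -> None:
    if not sensorgrams:
        raise PreconditionError("no sensorgrams given")
    t0 = sensorgrams[0].time
    for s in sensorgrams[1:]:
        if s.time.shape != t0.shape or not np.allclose(s.time, t0):
            raise PreconditionError("sensorgrams must share a common time grid")

def _default_guess(model: str, data_max: float) -> dict:
    g = {"ka1": 1e4, "kd1": 0.1, "ka2": 1e-3, "kd2": 0.01, "rmax": max(data_max, 1.0)}
    if model == "langmuir_1to1":
        g["ka2"] = g["kd2"] = 0.0
    return g


def fit_global(
    sensorgrams: list[Sensorgram],
    model: str = "bivalent",
    initial_guess: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
    include_baselines: bool = False,
    fit_rtol: float = 1e-8,
) -> KineticFitResult:
    """Globally fit one kinetic model to a multi-concentration series.

    All curves share the kinetic constants and Rmax; optionally each curve
    gets a free constant baseline offset.  Parameters are optimised on a
    log10 scale (they span eight decades) by trust-region least squares;
    ``n_starts`` log-uniform perturbations (+/- half a decade, seeded) of
    the initial guess guard against local minima.  Non-convergence and
    degenerate (flat) data are reported on the result, not raised.

    Parameters
    ----------
    model : "bivalent" or "langmuir_1to1"
        The 1:1 model is the bivalent scheme with ka2 = kd2 frozen at 0.
    """
    if model not in ("bivalent", "langmuir_1to1"):
        raise PreconditionError(f"unknown model {model!r}")
    _check_grid(sensorgrams)
    data = np.stack([s.response for s in sensorgrams])
    protocol = sensorgrams[0].protocol
    n_curves, n_t = data.shape

    # flat data carries no kinetic information at all: flag, don't raise
    if np.max(np.abs(data)) < 1e-9:
        return KineticFitResult(
            constants=RateConstants(0.0, 0.0, 0.0, 0.0),
            rmax=0.0, model=model, residual_sse=0.0,
            per_curve_sse=np.zeros(n_curves), n_points=data.size,
            n_parameters=0, converged=False, degenerate=True,
            message="all responses are zero; kinetic constants unidentifiable",
        )

    concs = np.array([s.concentration for s in sensorgrams])
    if np.unique(concs).size < 2:
        raise PreconditionError("global fit needs >= 2 distinct concentrations")

    guess = _default_guess(model, float(data.max()))
    if initial_guess:
        guess.update(initial_guess)

    if model == "langmuir_1to1":
        free = ["ka1", "kd1", "rmax"]
    else:
        free = ["ka1", "ka2", "kd1", "kd2", "rmax"]
    n_kin = len(free)

    def unpack(x):
        p = dict(zip(free, 10.0 ** x[:n_kin]))
        if model == "langmuir_1to1":
            p["ka2"] = p["kd2"] = 0.0
        k = RateConstants(p["ka1"], p["ka2"], p["kd1"], p["kd2"])
        base = x[n_kin:] if include_baselines else np.zeros(n_curves)
        return k, p["rmax"], base

    def residuals(x):
        k, rmax, base = unpack(x)
        try:
            _, species = _integrate_series(k, rmax, concs, protocol, rtol=fit_rtol)
        except IntegrationError:
            return np.full(data.size, 1e6)
        mod = species[:, 1, :] + species[:, 2, :] + base[:, None]
        return (mod - data).ravel()

    x0 = np.log10([max(guess[p], 1e-12) for p in free])
    if include_baselines:
        x0 = np.concatenate([x0, np.zeros(n_curves)])

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts, 1) - 1):
        pert = x0.copy()
        pert[:n_kin] += rng.uniform(-0.5, 0.5, n_kin)
        starts.append(pert)

    best = None
    for x_init in starts:
        try:
            res = least_squares(
                residuals, x_init, method="trf", diff_step=1e-4, x_scale=1.0
            )
        except Exception:  # pragma: no cover - solver blow-up on a start
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return KineticFitResult(
            constants=RateConstants(*[guess[p] for p in ("ka1", "ka2", "kd1", "kd2")]),
            rmax=guess["rmax"], model=model, residual_sse=np.inf,
            per_curve_sse=np.full(n_curves, np.inf), n_points=data.size,
            n_parameters=n_kin, converged=False,
            message="all optimisation starts failed",
        )

    k_fit, rmax_fit, base_fit = unpack(best.x)
    resid = residuals(best.x).reshape(n_curves, n_t)
    per_curve = (resid**2).sum(axis=1)
    sse = float(per_curve.sum())
    n_par = best.x.size

    # linear-scale standard errors via the log-space Jacobian at the optimum
    stderr = {}
    try:
        J = best.jac
        dof = max(data.size - n_par, 1)
        cov_log = np.linalg.inv(J.T @ J) * (sse / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        vals = dict(zip(free, 10.0 ** best.x[:n_kin]))
        for i, name in enumerate(free):
            stderr[name] = float(np.log(10.0) * vals[name] * se_log[i])
    except np.linalg.LinAlgError:
        stderr = {name: float("nan") for name in free}

    return KineticFitResult(
        constants=k_fit,
        rmax=rmax_fit,
        model=model,
        residual_sse=sse,
        per_curve_sse=per_curve,
        n_points=data.size,
        n_parameters=n_par,
        stderr=stderr,
        converged=bool(best.status > 0),
        message=best.message,
        baselines=base_fit if include_baselines else None,
    )


@dataclass
class ModelComparison:
    """1:1 Langmuir vs bivalent-analyte discrimination on one series."""

    langmuir: KineticFitResult
    bivalent: KineticFitResult

    @property
    def sse_ratio(self) -> float:
        """SSE(1:1) / SSE(bivalent); >> 1 favours the bivalent scheme."""
        return self.langmuir.residual_sse / self.bivalent.residual_sse

    @property
    def delta_aic(self) -> float:
        """AIC(1:1) - AIC(bivalent); positive favours the bivalent scheme."""
        return self.langmuir.aic - self.bivalent.aic


def compare_models(sensorgrams: list[Sensorgram], **fit_kwargs) -> ModelComparison:
    """Fit both kinetic models globally and report SSE ratio and delta-AIC."""
    return ModelComparison(
        langmuir=fit_global(sensorgrams, model="langmuir_1to1", **fit_kwargs),
        bivalent=fit_global(sensorgrams, model="bivalent", **fit_kwargs),
    )


@dataclass
class SteadyStateResult:
    """Avidity analysis: hyperbolic fit of equilibrium responses.

    kd_app_tot_molar is the overall apparent dissociation constant; it
    folds both binding steps (avidity) into a single equilibrium constant.
    """

    kd_app_tot_molar: float
    rmax_eq: float
    kd_stderr: float
    rmax_stderr: float
    residual_sse: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def steady_state_affinity(responses) -> SteadyStateResult:
    """Fit Req(C) = Rmax_eq * C / (C + KD_app_tot) by least squares.

    Parameters
    ----------
    responses : sequence of (concentration_molar, r_eq_ru)
        Equilibrium (maximum) responses; replicate concentrations allowed.
    """
    arr = np.asarray(list(responses), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise PreconditionError("responses must be (concentration, r_eq) pairs")
    c, r = arr[:, 0], arr[:, 1]
    if np.unique(c).size < 3:
        raise PreconditionError("steady-state fit needs >= 3 distinct concentrations")
    if np.any(r < 0) or np.any(c < 0):
        raise PreconditionError("concentrations and responses must be >= 0")
    if np.ptp(r) < 1e-12 * max(np.max(np.abs(r)), 1.0) or np.max(r) == 0:
        return SteadyStateResult(
            kd_app_tot_molar=np.nan, rmax_eq=np.nan, kd_stderr=np.nan,
            rmax_stderr=np.nan, residual_sse=0.0, converged=False,
            degenerate=True, message="constant responses: affinity unidentifiable",
        )

    def hyperbola(cc, rmax_eq, kd):
        return rmax_eq * cc / (cc + kd)

    p0 = (float(np.max(r)), float(np.median(c)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                hyperbola, c, r, p0=p0,
                bounds=([0, 0], [np.inf, np.inf]), maxfev=10000,
            )
    except RuntimeError as exc:
        return SteadyStateResult(
            kd_app_tot_molar=np.nan, rmax_eq=np.nan, kd_stderr=np.nan,
            rmax_stderr=np.nan, residual_sse=np.inf, converged=False,
            message=str(exc),
        )
    sse = float(np.sum((hyperbola(c, *popt) - r) ** 2))
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return SteadyStateResult(
        kd_app_tot_molar=float(popt[1]), rmax_eq=float(popt[0]),
        kd_stderr=float(se[1]), rmax_stderr=float(se[0]),
        residual_sse=sse, converged=True,
    )
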