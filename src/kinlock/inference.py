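"""Estimation of kinetic and thermodynamic parameters from dwell sets.

The headline estimator is a single global fit of the two-exponential
phase-type dwell law across all binder concentrations, sharing
(k_f, k_on, k_off).  Dwell histograms use geometrically growing bins
(ratio ``a`` in [1.2, 2]) so sparse long-time tails stay populated; bin
densities carry relative errors 1/sqrt(n).  Errors come from bootstrap
resampling (refit 100 resamples; report mean and sd), with a binning-free
EM mixture fit as a cross-check of the long-time proportion.  The
association constant, and hence the binding free energy, comes from the
weighted linear titration fit of mean dwell versus concentration; for
slow binders k_on can instead be counted directly from the rate of long
locking events per unit unbound time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dwell_models import (
    BindingRates,
    PhaseTypeOpenModel,
    ThermoContext,
    TwoStateRates,
    deltaG_from_Ka,
)
from .state_detection import CLOSED, OPEN, DwellSet

__all__ = [
    "BinnedDensity",
    "FitResult",
    "geometric_bins",
    "fit_global_double_exp",
    "bootstrap_errors",
    "em_two_exp_mixture",
    "EMResult",
    "fit_titration_line",
    "kon_from_long_event_rate",
    "LongEventRateResult",
]


@dataclass(frozen=True)
class BinnedDensity:
    """Geometrically binned dwell-time density (integrates to 1)."""

    edges: np.ndarray
    counts: np.ndarray
    densities: np.ndarray
    ratio: float

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and fit diagnostics."""

    parameters: dict[str, float]
    errors: dict[str, float] = field(default_factory=dict)
    n_events: int = 0
    n_boot: int = 0
    method: str = ""
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, err in self.errors.items():
            if err is not None and err < 0:
                raise ValueError(f"negative error for {name}")

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "errors": self.errors,
            "n_events": self.n_events,
            "n_boot": self.n_boot,
            "method": self.method,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


MIN_HEADLINE_EVENTS = 4000  # below this, mean-dwell statistics are flagged


def geometric_bins(
    times: np.ndarray,
    a: float = 1.4,
    t_min: float | None = None,
    t_max: float | None = None,
) -> BinnedDensity:
    """Histogram dwell times into bins growing geometrically by ``a``.

    Densities are ``(n_i / s_i) / N`` with ``N`` the total in-range count,
    so that ``sum(density_i * s_i) == 1`` exactly.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("no dwell times to bin")
    if not (1.2 <= a <= 2.0):
        raise ValueError("bin growth ratio a must lie in [1.2, 2]")
    if t_min is None:
        t_min = max(times.min(), np.finfo(float).tiny)
    if t_max is None:
        t_max = times.max() * 1.01
    if t_min <= 0 or t_max <= t_min:
        raise ValueError("need 0 < t_min < t_max")
    n_bins = int(np.ceil(np.log(t_max / t_min) / np.log(a)))
    edges = t_min * a ** np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    n_in = counts.sum()
    if n_in == 0:
        raise ValueError("all dwell times fall outside [t_min, t_max]")
    widths = np.diff(edges)
    densities = counts / widths / n_in
    return BinnedDensity(edges=edges, counts=counts, densities=densities, ratio=a)


def _models_for(params: np.ndarray, concentrations: np.ndarray) -> list[PhaseTypeOpenModel]:
    k_esc, k_on, k_off = params
    return [PhaseTypeOpenModel(k_esc, c * k_on, k_off) for c in concentrations]


def _moment_init(dwellsets: dict[float, np.ndarray]) -> np.ndarray:
    """Method-of-moments starting point, avoiding eigenvalue label switching.

    From the highest-concentration sample, fit the two-exponential mixture
    by EM and invert the eigen-parameterization:
    a = w*lam+ + (1-w)*lam-  (the density at t=0), d = lam+*lam-/a,
    b = lam+ + lam- - a - d.
    """
    concs = sorted(dwellsets)
    t0 = dwellsets[concs[0]]
    k_esc0 = 1.0 / t0.mean() if concs[0] == 0 else None
    c_hi = concs[-1]
    if c_hi == 0:
        return np.array([k_esc0, 1e-3, 1.0])
    em = em_two_exp_mixture(dwellsets[c_hi])
    if em.degenerate:
        # fast exchange or weak locking: seed with a generic slow component
        k_esc = k_esc0 if k_esc0 is not None else em.rate_fast
        mean_hi = dwellsets[c_hi].mean()
        ka_c = max(k_esc * mean_hi - 1.0, 1e-3)
        return np.array([k_esc, ka_c / c_hi, 1.0])
    lam_p, lam_m, w_long = em.rate_fast, em.rate_slow, em.weight_long
    a = (1.0 - w_long) * lam_p + w_long * lam_m
    d = lam_p * lam_m / a
    b = max(lam_p + lam_m - a - d, 1e-6 * a)
    if k_esc0 is not None:
        a = k_esc0
    return np.array([a, b / c_hi, d])


def fit_global_double_exp(
    dwellsets: dict[float, np.ndarray],
    init: np.ndarray | None = None,
    method: str = "binned",
    a: float = 1.4,
    min_events: int = 50,
    downweight_below: int = 500,
) -> FitResult:
    """Global fit of the locking dwell law across concentrations.

    Parameters
    ----------
    dwellsets :
        Map concentration (nM) -> array of dwell times (s) for the locked
        phase (open dwells for fluctuating-strand binders).
    method :
        ``"binned"`` — weighted least squares of the binned density against
        the exact two-exponential law, bin weights from sqrt(n) relative
        errors; ``"mle"`` — binning-free maximum likelihood.

    Returns a :class:`FitResult` with parameters ``k_escape`` (k_f for open
    dwells), ``k_on`` and ``k_off``.  With only c = 0 data the fit reduces
    to a single exponential and the binding rates are flagged
    unidentifiable.
    """
    if method not in ("binned", "mle"):
        raise ValueError("method must be 'binned' or 'mle'")
    clean = {
        float(c): np.asarray(t, dtype=float)
        for c, t in dwellsets.items()
        if len(t) >= min_events
    }
    dropped = sorted(set(map(float, dwellsets)) - set(clean))
    if not clean:
        raise ValueError(f"no concentration series with >= {min_events} events")
    concs = np.array(sorted(clean))
    n_events = int(sum(len(clean[c]) for c in concs))

    if len(concs) == 1 and concs[0] == 0.0:
        t = clean[0.0]
        k_esc = 1.0 / t.mean()
        return FitResult(
            parameters={"k_escape": k_esc, "k_on": np.nan, "k_off": np.nan},
            n_events=n_events,
            method=f"{method}-single-exp",
            diagnostics={"unidentifiable": ["k_on", "k_off"], "dropped_concentrations": dropped},
        )
    if len(concs) < 2:
        raise ValueError("global fit needs >= 2 concentration series (one may be 0)")

    x0 = np.asarray(init, dtype=float) if init is not None else _moment_init(clean)
    log_x0 = np.log(np.maximum(x0, 1e-12))
    # per-concentration weights: sqrt down-weighting of thin series
    series_w = {c: min(1.0, len(clean[c]) / downweight_below) ** 0.5 for c in concs}

    if method == "binned":
        binned = {c: geometric_bins(clean[c], a=a) for c in concs}

        def residuals(log_p: np.ndarray) -> np.ndarray:
            models = _models_for(np.exp(log_p), concs)
            res = []
            for c, model in zip(concs, models):
                bd = binned[c]
                nz = bd.counts > 0
                sigma = bd.densities[nz] / np.sqrt(bd.counts[nz])
                r = (model.pdf(bd.centers[nz]) - bd.densities[nz]) / sigma
                res.append(series_w[c] * r)
            return np.concatenate(res)

        sol = optimize.least_squares(residuals, log_x0, method="lm", max_nfev=2000)
        converged = sol.status > 0
        cost = float(sol.cost)
    else:

        def nll(log_p: np.ndarray) -> float:
            models = _models_for(np.exp(log_p), concs)
            total = 0.0
            for c, model in zip(concs, models):
                total -= series_w[c] * np.sum(np.log(np.maximum(model.pdf(clean[c]), 1e-300)))
            return total

        opt = optimize.minimize(nll, log_x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 5000})
        sol = opt
        converged = bool(opt.success)
        cost = float(opt.fun)

    params = np.exp(sol.x)
    if not converged:
        err = RuntimeError("global dwell fit did not converge")
        err.last_iterate = {"k_escape": params[0], "k_on": params[1], "k_off": params[2]}
        raise err
    k_esc, k_on, k_off = params
    diagnostics: dict = {
        "cost": cost,
        "dropped_concentrations": dropped,
        "n_per_concentration": {c: len(clean[c]) for c in concs},
    }
    # ill-conditioning: nearly equal eigenvalues at the top concentration
    top = PhaseTypeOpenModel(k_esc, concs[-1] * k_on, k_off)
    if top.lam_plus / top.lam_minus < 1.5:
        warnings.warn("eigenvalues nearly degenerate; k_on/k_off poorly identified", stacklevel=2)
        diagnostics["ill_conditioned"] = True
    if n_events < MIN_HEADLINE_EVENTS:
        warnings.warn(
            f"only {n_events} events (< {MIN_HEADLINE_EVENTS}); headline-quality fits need more",
            stacklevel=2,
        )
    return FitResult(
        parameters={"k_escape": k_esc, "k_on": k_on, "k_off": k_off},
        n_events=n_events,
        method=method,
        diagnostics=diagnostics,
    )


def bootstrap_errors(
    fit_fn,
    dwellsets: dict[float, np.ndarray],
    n_boot: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    max_failure_rate: float = 0.2,
) -> FitResult:
    """Bootstrap parameter uncertainties for any dwell-set fitting procedure.

    Each concentration series is resampled with replacement at its original
    size; ``fit_fn`` is refit on every resample.  The reported parameter
    values are the means over the bootstrap distribution and the errors its
    standard deviations.
    """
    base = fit_fn(dwellsets)
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in base.parameters}
    failures = 0
    for _ in range(n_boot):
        resampled = {
            c: rng.choice(t, size=len(t), replace=True) for c, t in dwellsets.items()
        }
        try:
            fit = fit_fn(resampled)
        except Exception:
            failures += 1
            continue
        for k, v in fit.parameters.items():
            samples[k].append(v)
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    params = {k: float(np.mean(v)) if v else np.nan for k, v in samples.items()}
    errors = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in samples.items()}
    return FitResult(
        parameters=params,
        errors=errors,
        n_events=base.n_events,
        n_boot=n_boot - failures,
        method=base.method + "+bootstrap",
        diagnostics={"point_estimate": base.parameters, "n_failures": failures},
    )


@dataclass(frozen=True)
class EMResult:
    """Two-component exponential mixture fit (binning-free)."""

    weight_long: float
    rate_fast: float
    rate_slow: float
    log_likelihood: float
    n_iter: int
    degenerate: bool


def em_two_exp_mixture(
    times: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-10,
    degenerate_ratio: float = 1.5,
) -> EMResult:
    """Expectation-maximization fit of w*Exp(rate_slow) + (1-w)*Exp(rate_fast).

    Deterministic initialization from the median split.  If the fitted rates
    differ by less than ``degenerate_ratio`` the sample is effectively
    single-exponential and the result is flagged degenerate.
    """
    t = np.asarray(times, dtype=float)
    if len(t) < 100:
        raise ValueError("EM needs at least 100 events")
    med = np.median(t)
    lo, hi = t[t <= med], t[t > med]
    lam_fast = 1.0 / max(lo.mean(), 1e-12)
    lam_slow = 1.0 / max(hi.mean(), 1e-12)
    w = 0.5  # weight of the slow (long-time) component
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p_slow = w * lam_slow * np.exp(-lam_slow * t)
        p_fast = (1.0 - w) * lam_fast * np.exp(-lam_fast * t)
        total = p_slow + p_fast
        total = np.maximum(total, 1e-300)
        gamma = p_slow / total  # responsibility of the slow component
        ll = float(np.sum(np.log(total)))
        w = float(gamma.mean())
        w = min(max(w, 1e-12), 1.0 - 1e-12)
        lam_slow = float(gamma.sum() / np.maximum(np.sum(gamma * t), 1e-300))
        lam_fast = float((1.0 - gamma).sum() / np.maximum(np.sum((1.0 - gamma) * t), 1e-300))
        if ll - ll_prev < tol * max(abs(ll), 1.0) and n_iter > 2:
            ll_prev = ll
            break
        ll_prev = ll
    if lam_slow > lam_fast:
        lam_fast, lam_slow = lam_slow, lam_fast
        w = 1.0 - w
    degenerate = (lam_fast / lam_slow) < degenerate_ratio
    return EMResult(
        weight_long=w,
        rate_fast=lam_fast,
        rate_slow=lam_slow,
        log_likelihood=ll_prev,
        n_iter=n_iter,
        degenerate=degenerate,
    )


def fit_titration_line(
    concentrations: np.ndarray,
    mean_times: np.ndarray,
    errors: np.ndarray,
    conc_rel_err: float = 0.05,
    ctx: ThermoContext = ThermoContext(),
    include_reference: bool = True,
) -> FitResult:
    """Binding free energy from the titration line of mean locked-phase dwell.

    Fits T(c)/T(0) = intercept + slope*c by weighted least squares.  The
    association constant is slope/intercept (nM^-1) and
    dG0 = -kT ln(Ka * 1e9).  Concentration uncertainty (default 5% relative)
    enters through effective-variance weighting: sigma_eff^2 = sigma_y^2 +
    (slope * sigma_c)^2, iterated once.  Parameter errors come from the
    weighted-fit covariance.

    The association constant is taken as slope/intercept rather than the
    raw slope, so a detection bias that rescales every mean by a common
    factor cancels.  With ``include_reference=False`` the (0, 1) reference
    point is used only as the normalizer and the line is fitted through the
    c > 0 points alone; this also cancels a bias common to the finite
    concentrations only, at the price of a roughly doubled Ka variance.
    """
    c = np.asarray(concentrations, dtype=float)
    y_raw = np.asarray(mean_times, dtype=float)
    e_raw = np.asarray(errors, dtype=float)
    if len(c) < 3:
        raise ValueError("titration fit needs >= 3 concentrations")
    if 0.0 not in c:
        raise ValueError("titration fit needs a c = 0 reference for T(0)")
    i0 = int(np.argmin(np.abs(c)))
    t0, e0 = y_raw[i0], e_raw[i0]
    y = y_raw / t0
    sigma_y = y * np.sqrt((e_raw / y_raw) ** 2 + (e0 / t0) ** 2)
    sigma_y[i0] = e_raw[i0] / t0  # reference point: no double counting
    if not include_reference:
        if np.sum(c > 0) < 2:
            raise ValueError("need >= 2 positive concentrations to fit the line")
        keep = c > 0
        c, y, sigma_y = c[keep], y[keep], sigma_y[keep]

    slope = 0.0
    for _ in range(2):  # effective-variance iteration
        sigma_eff = np.sqrt(sigma_y**2 + (slope * conc_rel_err * c) ** 2)
        wt = 1.0 / sigma_eff**2
        # weighted linear regression y = b0 + b1 c with covariance
        sw, swc, swc2 = wt.sum(), (wt * c).sum(), (wt * c * c).sum()
        swy, swcy = (wt * y).sum(), (wt * c * y).sum()
        det = sw * swc2 - swc**2
        b0 = (swc2 * swy - swc * swcy) / det
        b1 = (sw * swcy - swc * swy) / det
        slope = b1
    var_b0 = swc2 / det
    var_b1 = sw / det
    cov_b0b1 = -swc / det
    if b1 <= 0:
        raise ValueError("non-positive titration slope: no binding detected")
    ka = b1 / b0  # nM^-1
    var_ka = ka**2 * (var_b1 / b1**2 + var_b0 / b0**2 - 2 * cov_b0b1 / (b0 * b1))
    sd_ka = float(np.sqrt(max(var_ka, 0.0)))
    dg = deltaG_from_Ka(ka, ctx)
    sd_dg = ctx.kT * sd_ka / ka
    return FitResult(
        parameters={"Ka_nM": ka, "dG0_kcal_mol": dg, "slope": b1, "intercept": b0},
        errors={"Ka_nM": sd_ka, "dG0_kcal_mol": sd_dg,
                "slope": float(np.sqrt(var_b1)), "intercept": float(np.sqrt(var_b0))},
        n_events=len(c),
        method="titration-wls",
        diagnostics={"T0_s": float(t0), "conc_rel_err": conc_rel_err},
    )


@dataclass(frozen=True)
class LongEventRateResult:
    """k_on estimated from the frequency of long locking events."""

    k_on: float  # nM^-1 s^-1
    n_long: int
    t_unbound: float  # s
    sd: float  # Poisson (sqrt N) propagated
    upper_95: float | None = None  # one-sided bound when n_long == 0


def kon_from_long_event_rate(
    dwells: DwellSet,
    long_threshold: float,
    c: float,
    mode: str = "gap",
) -> LongEventRateResult:
    """Direct k_on estimate: long events counted per unit unbound time.

    ``mode="gap"`` (gapped-fork probe): the binding site is single-stranded
    in both phases, so binding can lock either phase; long dwells of both
    phases count as events and the unbound time pools open and closed
    dwells.  ``mode="fluctuating"``: binding only in the open state; long
    *open* dwells are the events and only open time counts as unbound.
    Long events are treated as bound for their whole duration and excluded
    from the unbound time (the sub-second free tail inside them is
    negligible against typical locking times).
    """
    if c <= 0:
        raise ValueError("concentration must be > 0")
    if mode not in ("gap", "fluctuating"):
        raise ValueError("mode must be 'gap' or 'fluctuating'")
    if long_threshold <= 0:
        raise ValueError("long_threshold must be > 0")
    event_states = (OPEN, CLOSED) if mode == "gap" else (OPEN,)
    event_durs = np.concatenate([dwells.durations(s) for s in event_states])
    long_mask = event_durs > long_threshold
    n_long = int(long_mask.sum())
    t_total = sum(float(dwells.durations(s).sum()) for s in event_states)
    t_unbound = float(t_total - event_durs[long_mask].sum())
    if t_unbound <= 0:
        raise ValueError("no unbound time left after removing long events")
    k_on = n_long / (t_unbound * c)
    sd = np.sqrt(n_long) / (t_unbound * c)
    upper = None
    if n_long == 0:
        upper = 3.0 / (t_unbound * c)  # one-sided 95% Poisson bound
    return LongEventRateResult(k_on=float(k_on), n_long=n_long,
                               t_unbound=t_unbound, sd=float(sd), upper_95=upper)
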