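"""Stopped-flow kinetics and equilibrium binding analytics.

Fluorescence time courses from rapid-mixing experiments are fit with a one-
or two-exponential decay,

    F(t) = F_inf + A1 * exp(-k_app1 * t)              (one phase)
    F(t) = F_inf + A1 * exp(-k_app1 * t) + A2 * exp(-k_app2 * t)

where F_inf is the final fluorescence, A_i signed amplitudes (ligand binding
to these biosensors quenches fluorescence, so a decaying signal has positive
amplitudes above F_inf; the fitted sign is kept, and binding-curve fits use
magnitudes), and k_app_i apparent rates (s^-1), reported fast-first.  Concentration series of amplitudes are
fit with the hyperbolic binding isotherm

    Y(c) = B_max * c / (K_D + c)

and series of apparent rates with a straight line whose slope is the
association rate constant k_on (uM^-1 s^-1).  A responsiveness classifier
turns an equilibrium fluorescence-change panel (variant x ligand, percent
change in peak fluorescence) into per-variant verdicts and a success rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourse",
    "ExpFitResult",
    "BindingCurve",
    "ResponsePanel",
    "exp_model",
    "fit_exponential",
    "select_model",
    "hyperbola",
    "fit_kd",
    "fit_kon",
    "classify_responses",
]


@dataclass
class TimeCourse:
    """A fluorescence-vs-time record (seconds, arbitrary units)."""

    time: np.ndarray
    signal: np.ndarray
    label: str = ""
    meta: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        if (self.time < 0).any():
            raise ValueError("times must be non-negative")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("times must be strictly increasing")

    def truncate_dead_time(self, dead_time: float) -> "TimeCourse":
        """Drop points earlier than the instrument dead time (no extrapolation)."""
        keep = self.time >= dead_time
        return TimeCourse(self.time[keep], self.signal[keep], self.label, self.meta)


def exp_model(t, f_inf, amplitudes, rates):
    """Evaluate F_inf + sum_i A_i exp(-k_i t)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, float(f_inf))
    for a, k in zip(np.atleast_1d(amplitudes), np.atleast_1d(rates)):
        out = out + a * np.exp(-k * t)
    return out


@dataclass
class ExpFitResult:
    """Result of an exponential fit, phases ordered fast-first."""

    n_phases: int
    f_inf: float
    amplitudes: np.ndarray
    rates: np.ndarray
    stderr_f_inf: float
    stderr_amplitudes: np.ndarray
    stderr_rates: np.ndarray
    rss: float
    n_points: int
    success: bool = True
    flags: list[str] = field(default_factory=list)
    selection: dict = field(default_factory=dict)

    def predict(self, t):
        return exp_model(t, self.f_inf, self.amplitudes, self.rates)

    @property
    def dof(self) -> int:
        return self.n_points - (1 + 2 * self.n_phases)


def _linear_amplitudes(t, y, rates):
    """Given rates, solve F_inf and amplitudes by linear least squares."""
    cols = [np.ones_like(t)] + [np.exp(-k * t) for k in rates]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _start_rates(t, n_phases, n_starts, rng):
    """Candidate rate sets log-spaced across the observable window, jittered."""
    t_pos = t[t > 0]
    lo = 0.1 / t.max()
    hi = 10.0 / max(t_pos.min(), 1e-12) if t_pos.size else 1e4
    grid = np.logspace(np.log10(lo), np.log10(hi), max(n_starts, 4))
    sets = []
    if n_phases == 1:
        sets = [[k] for k in grid]
    else:
        for i, k1 in enumerate(grid):
            for k2 in grid[:i]:
                sets.append([k1, k2])
    jitter = np.exp(rng.normal(0.0, 0.05, size=(len(sets), n_phases)))
    return [list(np.sort(np.asarray(s) * j)[::-1]) for s, j in zip(sets, jitter)]


def fit_exponential(tc: TimeCourse, n_phases: int = 1, n_starts: int = 8,
                    seed: int = 0) -> ExpFitResult:
    """Nonlinear least-squares exponential fit with seeded multi-start.

    For each candidate rate set (log-spaced over the observed time window,
    with small seeded log-normal jitter) the amplitudes and F_inf are first
    solved linearly (variable projection), then all parameters are refined
    with trust-region least squares; the lowest-RSS refinement wins.
    Standard errors come from the local Gauss-Newton covariance.

    A constant or near-constant signal yields a flagged
    ``unidentifiable-rate`` result rather than an exception; total failure of
    every start yields ``success=False``.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = tc.time, tc.signal
    if t.size < 5:
        raise ValueError("need at least 5 points to fit")
    scale = float(np.ptp(y))
    rng = np.random.default_rng(seed)

    noise_floor = max(1e-12, 1e-9 * max(scale, abs(float(np.mean(y))), 1.0))
    if scale <= noise_floor:
        return ExpFitResult(n_phases=n_phases, f_inf=float(np.mean(y)),
                            amplitudes=np.zeros(n_phases), rates=np.full(n_phases, np.nan),
                            stderr_f_inf=float(np.std(y) / np.sqrt(t.size)),
                            stderr_amplitudes=np.full(n_phases, np.nan),
                            stderr_rates=np.full(n_phases, np.nan),
                            rss=float(np.sum((y - np.mean(y)) ** 2)), n_points=t.size,
                            success=True, flags=["unidentifiable-rate", "constant-signal"])

    def residuals(params):
        f_inf = params[0]
        amps = params[1:1 + n_phases]
        # clip log-rates: e^60 s^-1 already decays within any float time step
        rates = np.exp(np.clip(params[1 + n_phases:], -60.0, 60.0))
        return exp_model(t, f_inf, amps, rates) - y

    best = None
    for rates0 in _start_rates(t, n_phases, n_starts, rng):
        beta, _ = _linear_amplitudes(t, y, rates0)
        p0 = np.concatenate([beta, np.log(rates0)])
        try:
            sol = optimize.least_squares(residuals, p0, method="trf", xtol=1e-14,
                                         ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:  # singular starts are simply skipped
            continue
        rss = float(2.0 * sol.cost)
        if sol.x[1 + n_phases:].max() > 50:  # rate beyond any resolvable scale
            continue
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return ExpFitResult(n_phases=n_phases, f_inf=np.nan,
                            amplitudes=np.full(n_phases, np.nan),
                            rates=np.full(n_phases, np.nan), stderr_f_inf=np.nan,
                            stderr_amplitudes=np.full(n_phases, np.nan),
                            stderr_rates=np.full(n_phases, np.nan), rss=np.nan,
                            n_points=t.size, success=False, flags=["no-convergence"])

    rss, sol = best
    f_inf = float(sol.x[0])
    amps = sol.x[1:1 + n_phases].copy()
    rates = np.exp(sol.x[1 + n_phases:])

    # covariance in the fitted parameterization (log-rates), then delta method
    dof = max(t.size - sol.x.size, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        diag = np.diag(cov)
        # singular/ill-conditioned fits can give tiny negative diagonals
        perr = np.sqrt(np.where(diag >= 0, diag, np.nan))
    except np.linalg.LinAlgError:
        perr = np.full(sol.x.size, np.nan)
    se_f = float(perr[0])
    se_a = perr[1:1 + n_phases].copy()
    se_k = perr[1 + n_phases:] * rates  # d(exp u) = exp(u) du

    order = np.argsort(rates)[::-1]  # fast phase first
    amps, rates = amps[order], rates[order]
    se_a, se_k = se_a[order], se_k[order]

    flags = []
    amp_floor = 3.0 * np.sqrt(s2)
    if any(abs(a) < amp_floor for a in amps):
        flags.append("small-amplitude")
    if any(not np.isfinite(e) or (np.isfinite(e) and abs(a) < e)
           for a, e in zip(amps, se_a)):
        flags.append("unidentifiable-rate")
    return ExpFitResult(n_phases=n_phases, f_inf=f_inf, amplitudes=amps, rates=rates,
                        stderr_f_inf=se_f, stderr_amplitudes=se_a, stderr_rates=se_k,
                        rss=rss, n_points=t.size, success=True, flags=flags)


def select_model(tc: TimeCourse, alpha: float = 0.01, criterion: str = "ftest",
                 seed: int = 0) -> ExpFitResult:
    """Fit one- and two-exponential models and keep the better-supported one.

    The two-phase fit is preferred only when it converged, both amplitudes
    exceed a noise-scaled floor (3 x residual sd of the richer model), the
    recovered rates are distinct, and either the extra-sum-of-squares F-test
    (default, level ``alpha``) or AICc favors it.  The decision trail is
    recorded on the returned result.
    """
    fit1 = fit_exponential(tc, 1, seed=seed)
    fit2 = fit_exponential(tc, 2, seed=seed)
    trail: dict = {"criterion": criterion, "alpha": alpha}
    n = tc.time.size

    if not fit1.success and not fit2.success:
        fit1.flags.append("selection-failed")
        fit1.selection = trail
        return fit1
    if not fit2.success or "constant-signal" in fit1.flags:
        trail["chosen"] = 1
        trail["reason"] = "2-phase unavailable" if not fit2.success else "constant signal"
        fit1.selection = trail
        return fit1

    scale = float(np.ptp(tc.signal))
    # both models at numerical-precision residuals: parsimony wins
    precision_rss = n * (1e-8 * scale) ** 2
    if fit1.success and fit1.rss <= precision_rss:
        trail["chosen"] = 1
        trail["reason"] = "one-phase residuals at numerical precision"
        fit1.selection = trail
        return fit1

    sigma2 = fit2.rss / max(fit2.dof, 1)
    amp_floor = 3.0 * np.sqrt(sigma2)
    amps_ok = all(abs(a) > amp_floor for a in fit2.amplitudes)
    # the fast phase must still be decaying at the first sampled time,
    # otherwise its amplitude/rate pair is unconstrained by the data
    t_pos = tc.time[tc.time > 0]
    t_first = float(t_pos.min()) if t_pos.size else np.inf
    rates_ok = (np.isfinite(fit2.rates).all() and
                fit2.rates[0] > 1.05 * fit2.rates[1] and
                fit2.rates[0] * t_first <= 3.0)
    trail["amp_floor"] = float(amp_floor)
    trail["amplitudes_ok"] = bool(amps_ok)
    trail["rates_distinct"] = bool(rates_ok)

    if criterion == "ftest":
        num = (fit1.rss - fit2.rss) / 2.0
        den = fit2.rss / max(fit2.dof, 1)
        fstat = num / den if den > 0 else np.inf
        pval = float(stats.f.sf(fstat, 2, max(fit2.dof, 1))) if np.isfinite(fstat) else 0.0
        trail["F"] = float(fstat)
        trail["p"] = pval
        stat_ok = pval < alpha
    elif criterion == "aicc":
        def aicc(rss, k):
            if n - k - 1 <= 0:
                return np.inf
            return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        a1, a2 = aicc(max(fit1.rss, 1e-300), 3), aicc(max(fit2.rss, 1e-300), 5)
        trail["aicc_1"], trail["aicc_2"] = a1, a2
        stat_ok = a2 < a1
    else:
        raise ValueError("criterion must be 'ftest' or 'aicc'")

    if fit1.success and not (amps_ok and rates_ok and stat_ok):
        trail["chosen"] = 1
        fit1.selection = trail
        return fit1
    trail["chosen"] = 2
    fit2.selection = trail
    return fit2


def hyperbola(c, b_max, k_d):
    """Binding isotherm Y(c) = B_max * c / (K_D + c)."""
    c = np.asarray(c, dtype=float)
    return b_max * c / (k_d + c)


@dataclass
class BindingCurve:
    """A fitted concentration-response relationship.

    ``kind`` is "hyperbolic" (K_D / B_max from amplitudes) or "linear"
    (k_on slope / intercept from apparent rates).
    """

    kind: str
    concentration: np.ndarray
    response: np.ndarray
    params: dict
    stderr: dict
    rss: float
    flags: list[str] = field(default_factory=list)

    @property
    def k_d(self) -> float:
        return self.params.get("k_d", np.nan)

    @property
    def b_max(self) -> float:
        return self.params.get("b_max", np.nan)

    @property
    def k_on(self) -> float:
        return self.params.get("slope", np.nan)


def fit_kd(concentration, response) -> BindingCurve:
    """Fit the hyperbolic isotherm to (concentration, amplitude) points.

    Response magnitudes are used (stopped-flow amplitudes of a fluorescence
    decrease are reported signed).  Requires >= 3 distinct concentrations.
    An ill-conditioned design (all concentrations far below or above the
    fitted K_D) is flagged, with the wide standard errors reported as-is.
    """
    c = np.asarray(concentration, dtype=float)
    y = np.abs(np.asarray(response, dtype=float))
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if (c < 0).any():
        raise ValueError("concentrations must be non-negative")
    p0 = (float(y.max()) or 1.0, float(np.median(c[c > 0])) or 1.0)
    popt, pcov = optimize.curve_fit(hyperbola, c, y, p0=p0,
                                    bounds=([0, 1e-12], [np.inf, np.inf]),
                                    maxfev=10000, xtol=1e-14, ftol=1e-14)
    resid = y - hyperbola(c, *popt)
    rss = float(resid @ resid)
    perr = np.sqrt(np.diag(pcov))
    flags = []
    k_d = float(popt[1])
    if not np.isfinite(perr[1]) or perr[1] > k_d or k_d < 0.5 * c.min() or k_d > 2 * c.max():
        flags.append("ill-conditioned")
        logger.warning("K_D fit poorly constrained by the concentration range "
                       "(K_D=%.3g, range %.3g-%.3g)", k_d, c.min(), c.max())
    return BindingCurve(kind="hyperbolic", concentration=c, response=y,
                        params={"b_max": float(popt[0]), "k_d": k_d},
                        stderr={"b_max": float(perr[0]), "k_d": float(perr[1])},
                        rss=rss, flags=flags)


def fit_kon(concentration, k_app, through_origin: bool = False) -> BindingCurve:
    """Linear fit of apparent rate vs concentration; the slope is k_on.

    The intercept (nominally the dissociation rate) is reported but fitted
    freely by default; ``through_origin=True`` pins it at zero.
    """
    c = np.asarray(concentration, dtype=float)
    y = np.asarray(k_app, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations for a slope")
    if through_origin:
        slope = float((c @ y) / (c @ c))
        resid = y - slope * c
        rss = float(resid @ resid)
        dof = max(c.size - 1, 1)
        se_slope = float(np.sqrt(rss / dof / (c @ c)))
        params = {"slope": slope, "intercept": 0.0}
        stderr = {"slope": se_slope, "intercept": 0.0}
    else:
        res = stats.linregress(c, y)
        resid = y - (res.intercept + res.slope * c)
        rss = float(resid @ resid)
        params = {"slope": float(res.slope), "intercept": float(res.intercept)}
        stderr = {"slope": float(res.stderr), "intercept": float(res.intercept_stderr)}
    return BindingCurve(kind="linear", concentration=c, response=y,
                        params=params, stderr=stderr, rss=rss)


@dataclass
class ResponsePanel:
    """Percent change in peak fluorescence, per variant and ligand."""

    values: pd.DataFrame  # index: variant, columns: ligand, cells: percent change

    @classmethod
    def from_records(cls, records) -> "ResponsePanel":
        """Build from (variant, ligand, percent_change) triples."""
        df = pd.DataFrame(records, columns=["variant", "ligand", "percent_change"])
        return cls(df.pivot(index="variant", columns="ligand", values="percent_change"))

    def percent(self, variant: str, ligand: str) -> float:
        try:
            v = self.values.loc[variant, ligand]
        except KeyError:
            raise KeyError(f"no panel entry for variant {variant!r}, ligand {ligand!r}")
        if pd.isna(v):
            raise KeyError(f"missing panel entry for variant {variant!r}, ligand {ligand!r}")
        return float(v)


def classify_responses(panel: ResponsePanel, target_ligands: list[str],
                       control_ligands: list[str], threshold: float = 5.0) -> dict:
    """Classify biosensor variants as responsive or not; compute success rate.

    A variant is responsive iff |percent change| >= threshold for every
    target ligand AND |percent change| < threshold for every control ligand
    (specificity).  Returns per-variant verdicts, per-ligand detail and the
    success rate in percent.
    """
    if threshold <= 0:
        warnings.warn("non-positive threshold: any nonzero control change fails "
                      "every variant", stacklevel=2)
    verdicts = {}
    for variant in panel.values.index:
        detects = {lig: abs(panel.percent(variant, lig)) >= threshold
                   for lig in target_ligands}
        specific = {lig: abs(panel.percent(variant, lig)) < threshold
                    for lig in control_ligands}
        verdicts[variant] = {
            "responsive": all(detects.values()) and all(specific.values()),
            "detects": detects,
            "specific": specific,
        }
    n = len(verdicts)
    n_resp = sum(v["responsive"] for v in verdicts.values())
    return {
        "verdicts": verdicts,
        "n_variants": n,
        "n_responsive": n_resp,
        "success_rate_percent": 100.0 * n_resp / n if n else 0.0,
        "threshold_percent": threshold,
    }
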