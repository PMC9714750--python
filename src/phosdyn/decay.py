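"""Multi-exponential deconvolution of phosphorescence decay traces.

A heterogeneous population of emitters gives a decay

    I(t) = sum_i A_i exp(-t / tau_i),        1 <= n <= 5,

and the quantity carried forward is the intensity-weighted ensemble average

    <tau> = sum_i A_i tau_i^2 / sum_i A_i tau_i,

the first moment of the multi-exponential.  ``MultiExponentialDecay`` is a
scikit-learn style regressor implementing a separable (variable-projection
flavoured) least-squares fit with a parsimony rule for the component count;
``moment_average_oracle`` is an independent brute-force estimate of <tau>
used for cross-checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import DecayFitResult, DecayTrace, LifetimeMixture

__all__ = [
    "MultiExponentialDecay",
    "fit_multiexponential",
    "ensemble_average_lifetime",
    "moment_average_oracle",
]


def ensemble_average_lifetime(mixture: LifetimeMixture) -> float:
    """Intensity-weighted mean lifetime sum(A tau^2)/sum(A tau), ms.

    Invariant to a common amplitude rescaling; homogeneous of degree 1 in
    the lifetimes; equals tau for a single component.
    """
    a, t = mixture.amplitudes, mixture.lifetimes
    denom = float(np.sum(a * t))
    if denom <= 0:
        raise ValueError("all-zero amplitudes: ensemble average undefined")
    return float(np.sum(a * t**2) / denom)


def moment_average_oracle(trace: DecayTrace, background: float = 0.0) -> float:
    """Discrete moment-ratio lifetime sum(t_c * c_net)/sum(c_net), ms.

    An independent, model-free estimate of <tau>: bin-centre times weighted
    by background-subtracted counts.  Biased low when the tail is truncated;
    the truncation fraction is not corrected for, so use traces at least
    ~20 lifetimes long for percent-level accuracy.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    net = trace.counts - background
    total = float(np.sum(net))
    if total <= 0:
        raise ValueError("net counts <= 0: no signal above background")
    centres = trace.times + 0.5 * trace.bin_width
    return float(np.sum(centres * net) / total)


def _bin_means(times: np.ndarray, dt: float, amplitudes: np.ndarray,
               lifetimes: np.ndarray, background: float) -> np.ndarray:
    """Exact per-bin integral of the multi-exponential plus flat background.

    Integral of A exp(-t/tau) over [t, t+dt) is A tau (e^{-t/tau}-e^{-(t+dt)/tau});
    dividing by nothing — counts are per-bin integrals, background is per bin.
    """
    out = np.full(times.shape, float(background))
    for a, tau in zip(amplitudes, lifetimes):
        out = out + a * tau * np.exp(-times / tau) * (-np.expm1(-dt / tau))
    return out


def _deviance_residuals(model: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Signed square-root Poisson deviance residuals.

    Minimising their sum of squares is exactly the Poisson maximum-likelihood
    fit, the correct treatment for single-photon-counting data where many
    bins hold only a few counts (plain 1/c weights are biased low there).
    """
    m = np.maximum(model, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / m), 0.0)
    d2 = 2.0 * (m - counts + term)
    return np.sign(counts - m) * np.sqrt(np.maximum(d2, 0.0))


class MultiExponentialDecay(BaseEstimator, RegressorMixin):
    """Sum-of-exponentials fit with automatic component-count selection.

    The component count n is grown from 1: lifetimes for the candidate model
    are warm-started from the accepted n-component fit plus one log-spaced
    extra, amplitudes re-seeded by nonnegative linear least squares at fixed
    lifetimes, then all 2n+1 parameters (amplitudes, lifetimes, flat
    background) are refined by bounded least squares.  Growth stops when the
    reduced chi-square improves by less than ``chi2_improvement`` (relative),
    when the newest component carries less than ``min_amplitude_frac`` of the
    total amplitude, or at ``n_max``.

    Parameters
    ----------
    n_max : int, default 5
        Maximum number of discrete components.
    weighting : {"poisson", "uniform"}
        "poisson" performs the Poisson maximum-likelihood fit (least squares
        on signed square-root deviance residuals), appropriate for
        single-photon counting; "uniform" is ordinary least squares.  The
        reported reduced chi-square is the reduced deviance in the Poisson
        case (both approach 1 for a correct model).
    fit_background : bool, default True
        Fit a flat nonnegative background; otherwise fixed at 0.
    chi2_improvement : float, default 0.05
        Minimum relative reduced-chi-square improvement to accept another
        component.
    min_amplitude_frac : float, default 1e-3
        A new component below this fraction of total amplitude is rejected.
    merge_rtol : float, default 1e-3
        Two fitted lifetimes closer than this relative separation are merged
        (amplitude sum, amplitude-weighted lifetime) and the model refitted
        with n-1 components.

    Attributes
    ----------
    amplitudes_, lifetimes_ : fitted components, lifetimes strictly increasing
    background_ : fitted flat background per bin
    n_components_, reduced_chi2_, tau_avg_, selection_trace_, converged_
    """

    def __init__(self, n_max: int = 5, weighting: str = "poisson",
                 fit_background: bool = True, chi2_improvement: float = 0.05,
                 min_amplitude_frac: float = 1e-3, merge_rtol: float = 1e-3):
        self.n_max = n_max
        self.weighting = weighting
        self.fit_background = fit_background
        self.chi2_improvement = chi2_improvement
        self.min_amplitude_frac = min_amplitude_frac
        self.merge_rtol = merge_rtol

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Fit to bin-start times ``X`` (ms, uniform) and counts ``y``."""
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single time column")
            t = t[:, 0]
        c = np.asarray(y, dtype=float)
        if t.shape != c.shape:
            raise ValueError("X and y must have the same length")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if t.size < 2 * self.n_max + 1:
            raise ValueError(
                f"fewer bins ({t.size}) than parameters (2*n_max+1 = {2 * self.n_max + 1})"
            )
        dt_all = np.diff(t)
        if np.any(dt_all <= 0) or not np.allclose(dt_all, dt_all[0], rtol=1e-9, atol=0.0):
            raise ValueError("non-uniform binning: times must be uniformly spaced")
        if not np.any(c > 0):
            raise ValueError("empty signal: trace is all zeros")
        dt = float(dt_all[0])

        if self.weighting == "poisson":
            sigma = np.sqrt(np.maximum(c, 1.0))  # used only for the linear warm start
        elif self.weighting == "uniform":
            sigma = np.ones_like(c)
        else:
            raise ValueError("weighting must be 'poisson' or 'uniform'")

        t_end = float(t[-1] + dt)
        trace_data = (t, c, dt, sigma)
        self._poisson = self.weighting == "poisson"

        trace: list[dict[str, float]] = []
        best = None
        prev_lifetimes: np.ndarray | None = None
        for n in range(1, self.n_max + 1):
            cand = self._fit_n(trace_data, n, t_end, prev_lifetimes)
            record = {"n": n, "reduced_chi2": cand["reduced_chi2"]}
            if best is not None:
                improvement = 1.0 - cand["reduced_chi2"] / max(best["reduced_chi2"], 1e-300)
                amp_frac = cand["new_amp_frac"]
                if improvement < self.chi2_improvement or amp_frac < self.min_amplitude_frac:
                    record["rejected"] = 1.0
                    trace.append(record)
                    break
            trace.append(record)
            best = cand
            prev_lifetimes = cand["lifetimes"]
            if cand["reduced_chi2"] < 1e-12:  # machine-precision fit; nothing left
                break

        assert best is not None
        self.amplitudes_ = best["amplitudes"]
        self.lifetimes_ = best["lifetimes"]
        self.background_ = float(best["background"])
        self.n_components_ = int(best["lifetimes"].size)
        self.reduced_chi2_ = float(best["reduced_chi2"])
        self.converged_ = bool(best["converged"])
        self.selection_trace_ = trace
        self.tau_avg_ = ensemble_average_lifetime(self.to_mixture())
        self._dt = dt
        return self

    # ------------------------------------------------------------------
    def _nnls_amplitudes(self, trace_data, lifetimes: np.ndarray,
                         with_background: bool) -> tuple[np.ndarray, float]:
        """Nonnegative linear least squares for amplitudes at fixed lifetimes."""
        t, c, dt, sigma = trace_data
        cols = [tau * np.exp(-t / tau) * (-np.expm1(-dt / tau)) for tau in lifetimes]
        if with_background:
            cols.append(np.ones_like(t))
        M = np.column_stack(cols) / sigma[:, None]
        coef, _ = optimize.nnls(M, c / sigma)
        if with_background:
            return coef[:-1], float(coef[-1])
        return coef, 0.0

    def _fit_n(self, trace_data, n: int, t_end: float,
               prev_lifetimes: np.ndarray | None) -> dict:
        t, c, dt, sigma = trace_data
        lo, hi = 2.0 * dt, 2.0 * t_end
        if prev_lifetimes is None or prev_lifetimes.size != n - 1:
            lifetimes0 = np.geomspace(lo, hi, n) if n > 1 else np.array(
                [moment_average_oracle(DecayTrace(t, np.maximum(c, 0.0)), 0.0)])
            lifetimes0 = np.clip(lifetimes0, lo, hi)
        else:
            # warm start: keep accepted lifetimes, add one in the largest log gap
            grid = np.sort(np.concatenate([[lo], prev_lifetimes, [hi]]))
            gaps = np.diff(np.log(grid))
            k = int(np.argmax(gaps))
            extra = np.sqrt(grid[k] * grid[k + 1])
            lifetimes0 = np.sort(np.concatenate([prev_lifetimes, [extra]]))
        amps0, bg0 = self._nnls_amplitudes(trace_data, lifetimes0, self.fit_background)
        amps0 = np.maximum(amps0, 1e-12 * max(float(np.max(amps0)), 1.0))

        nb = 1 if self.fit_background else 0

        def resid_fn(p):
            a = p[:n]
            tau = np.exp(p[n:2 * n])
            bg = p[-1] if nb else 0.0
            model = _bin_means(t, dt, a, tau, bg)
            if self._poisson:
                return _deviance_residuals(model, c)
            return (model - c) / sigma

        p0 = np.concatenate([amps0, np.log(lifetimes0), [bg0] if nb else []])
        lower = np.concatenate([np.zeros(n), np.full(n, np.log(dt * 0.1)),
                                [0.0] if nb else []])
        upper = np.concatenate([np.full(n, np.inf), np.full(n, np.log(hi * 10.0)),
                                [np.inf] if nb else []])
        sol = optimize.least_squares(resid_fn, p0, bounds=(lower, upper),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                     max_nfev=40000)
        a = sol.x[:n]
        tau = np.exp(sol.x[n:2 * n])
        bg = float(sol.x[-1]) if nb else 0.0

        a, tau, merged = self._merge_degenerate(a, tau)
        if merged:
            return self._refit_fixed(trace_data, a, tau, bg, t_end)

        order = np.argsort(tau)
        a, tau = a[order], tau[order]
        dof = max(t.size - (2 * n + nb), 1)
        red = float(np.sum(resid_fn(sol.x) ** 2) / dof)
        total_amp = float(np.sum(a))
        new_amp_frac = (float(np.min(a)) / total_amp) if total_amp > 0 else 0.0
        return {"amplitudes": a, "lifetimes": tau, "background": bg,
                "reduced_chi2": red, "converged": sol.success,
                "new_amp_frac": new_amp_frac}

    def _merge_degenerate(self, a: np.ndarray, tau: np.ndarray):
        """Merge lifetime pairs closer than merge_rtol (amplitude-weighted)."""
        order = np.argsort(tau)
        a, tau = a[order].copy(), tau[order].copy()
        merged = False
        i = 0
        while i < tau.size - 1:
            if (tau[i + 1] - tau[i]) / tau[i] < self.merge_rtol:
                w = a[i] + a[i + 1]
                tau[i] = (a[i] * tau[i] + a[i + 1] * tau[i + 1]) / w if w > 0 \
                    else 0.5 * (tau[i] + tau[i + 1])
                a[i] = w
                a = np.delete(a, i + 1)
                tau = np.delete(tau, i + 1)
                merged = True
            else:
                i += 1
        return a, tau, merged

    def _refit_fixed(self, trace_data, a, tau, bg, t_end) -> dict:
        """Polish a merged (reduced-n) model with a fresh bounded fit."""
        t, c, dt, sigma = trace_data
        n = tau.size
        nb = 1 if self.fit_background else 0

        def resid_fn(p):
            model = _bin_means(t, dt, p[:n], np.exp(p[n:2 * n]),
                               p[-1] if nb else 0.0)
            if self._poisson:
                return _deviance_residuals(model, c)
            return (model - c) / sigma

        p0 = np.concatenate([np.maximum(a, 0.0), np.log(tau), [bg] if nb else []])
        lower = np.concatenate([np.zeros(n), np.full(n, np.log(dt * 0.1)),
                                [0.0] if nb else []])
        upper = np.concatenate([np.full(n, np.inf), np.full(n, np.log(t_end * 20.0)),
                                [np.inf] if nb else []])
        sol = optimize.least_squares(resid_fn, p0, bounds=(lower, upper),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                     max_nfev=40000)
        a2 = sol.x[:n]
        tau2 = np.exp(sol.x[n:2 * n])
        order = np.argsort(tau2)
        a2, tau2 = a2[order], tau2[order]
        dof = max(t.size - (2 * n + nb), 1)
        red = float(np.sum(resid_fn(sol.x) ** 2) / dof)
        total = float(np.sum(a2))
        return {"amplitudes": a2, "lifetimes": tau2,
                "background": float(sol.x[-1]) if nb else 0.0,
                "reduced_chi2": red, "converged": sol.success,
                "new_amp_frac": (float(np.min(a2)) / total) if total > 0 else 0.0}

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Model per-bin counts on bin-start times ``X``."""
        check_is_fitted(self, "lifetimes_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return _bin_means(t, self._dt, self.amplitudes_, self.lifetimes_,
                          self.background_)

    def to_mixture(self) -> LifetimeMixture:
        check_is_fitted(self, "lifetimes_")
        a = self.amplitudes_.copy()
        if not np.any(a > 0):  # all mass in background; keep the dominant shape
            a = np.ones_like(a)
        return LifetimeMixture(a, self.lifetimes_.copy())


def fit_multiexponential(trace: DecayTrace, n_max: int = 5,
                         weighting: str = "poisson",
                         fit_background: bool = True) -> DecayFitResult:
    """Fit ``background + sum_i A_i exp(-t/tau_i)`` to a decay trace.

    Components are nonnegative-amplitude, lifetime-ordered; the component
    count is the smallest that the parsimony rule accepts (see
    :class:`MultiExponentialDecay`).
    """
    est = MultiExponentialDecay(n_max=n_max, weighting=weighting,
                                fit_background=fit_background)
    est.fit(trace.times, trace.counts)
    return DecayFitResult(
        mixture=est.to_mixture(),
        background=est.background_,
        reduced_chi2=max(est.reduced_chi2_, 0.0),
        tau_avg=est.tau_avg_,
        n_tried=[int(rec["n"]) for rec in est.selection_trace_],
        selection_trace=est.selection_trace_,
        converged=est.converged_,
    )
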