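"""Two-state thermal-activation model of dynamic phosphorescence quenching.

The protein matrix is modelled as switching between a "frozen" state, in
which molecular oxygen cannot diffuse and the probe decays at its intrinsic
rate 1/tau0, and a thermally activated "molten" state in which dynamic
quenching speeds the decay up by a factor K_d.  With x(T) the Boltzmann
factor of the activation,

    x(T) = exp(-(dE - T dS) / (R T)),

the population-weighted mean decay rate gives the normalized ensemble
average lifetime

    <tau>/tau0 (T) = (1 + x) / (1 + K_d x),

a sigmoid dropping from 1 (frozen) to 1/K_d (fully molten) with midpoint

    T_MP = dE / (dS + R ln K_d).

``TwoStateTransition`` is a scikit-learn style regressor fitting (dE, dS,
K_d) to a normalized lifetime-vs-temperature series by weighted least
squares; module-level functions wrap it and add baseline normalisation and
derivative curves.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    R_GAS,
    RoiConfig,
    TemperatureSeries,
    TransitionFitResult,
    TwoStateParams,
)

__all__ = [
    "TwoStateTransition",
    "two_state_ratio",
    "molten_fraction",
    "midpoint_temperature",
    "compute_tau0",
    "normalize_series",
    "fit_transition",
    "negative_derivative",
]


def _log_boltzmann(delta_E: float, delta_S: float, T: np.ndarray) -> np.ndarray:
    """log x(T) = -(dE - T dS)/(R T), dE in kJ/mol, clamped for safety."""
    u = -(delta_E * 1000.0 - T * delta_S) / (R_GAS * T)
    return np.clip(u, -700.0, 700.0)


def _ratio_from_params(T: np.ndarray, delta_E: float, delta_S: float, K_d: float) -> np.ndarray:
    # log-sum form: log r = log(1+x) - log(1+K_d x), overflow-free for any exponent
    u = _log_boltzmann(delta_E, delta_S, np.asarray(T, dtype=float))
    return np.exp(np.logaddexp(0.0, u) - np.logaddexp(0.0, u + np.log(K_d)))


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 K")
    return T


def two_state_ratio(params: TwoStateParams, T) -> np.ndarray | float:
    """Normalized lifetime <tau>/tau0 at temperature(s) ``T`` (K).

    Value lies in (1/K_d, 1]; equals the reciprocal of the population-weighted
    mean decay rate, relative to the frozen rate.
    """
    T = _check_temperature(T)
    out = _ratio_from_params(T, params.delta_E, params.delta_S, params.K_d)
    return float(out) if out.ndim == 0 else out


def molten_fraction(params: TwoStateParams, T) -> np.ndarray | float:
    """Occupancy x/(1+x) of the thermally activated state; monotone in T for dE > 0."""
    T = _check_temperature(T)
    u = _log_boltzmann(params.delta_E, params.delta_S, T)
    # expit(u) = x/(1+x) with x = e^u
    out = np.exp(u - np.logaddexp(0.0, u))
    return float(out) if out.ndim == 0 else out


def midpoint_temperature(params: TwoStateParams) -> float:
    """T_MP = dE / (dS + R ln K_d), K (dE converted from kJ/mol to J/mol)."""
    denom = params.delta_S + R_GAS * np.log(params.K_d)
    if not denom > 0:
        raise ValueError("non-identifiable: dS + R ln K_d must be positive")
    return float(params.delta_E * 1000.0 / denom)


def compute_tau0(series: TemperatureSeries, roi: RoiConfig | None = None) -> tuple[float, float]:
    """Frozen-plateau normalisation factor: mean and sample SD of tau_avg
    over the baseline window."""
    roi = roi or RoiConfig()
    if series.tau_avg is None:
        raise ValueError("series has no tau_avg values; cannot compute tau0")
    mask = series.window_mask(*roi.baseline_window)
    vals = series.tau_avg[mask]
    if vals.size < 3:
        raise ValueError(
            f"too few baseline points: need >= 3 in {roi.baseline_window}, got {vals.size}"
        )
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def normalize_series(series: TemperatureSeries, tau0: float) -> TemperatureSeries:
    """Divide tau_avg by tau0; per-point uncertainties are divided alongside."""
    if not tau0 > 0:
        raise ValueError("tau0 must be > 0")
    if series.tau_avg is None:
        raise ValueError("series has no tau_avg values to normalize")
    sd = None if series.sd is None else series.sd / tau0
    return series.with_ratio(series.tau_avg / tau0, tau0=tau0, sd=sd)


class TwoStateTransition(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of the two-state activation sigmoid.

    Parameters
    ----------
    init : TwoStateParams or None
        Starting point.  If None, a deterministic data-driven start is used:
        dE0 = 100 kJ/mol, dS0 chosen so dE0/dS0 sits at the steepest observed
        drop, K_d0 = 1/min(ratio).
    uncertainty : {"covariance", "bootstrap"}
        Parameter SDs from the fit covariance (default) or from a residual
        bootstrap with ``n_boot`` seeded replicates.
    n_boot : int
        Bootstrap replicates (used only for uncertainty="bootstrap").
    seed : int
        Seed for the bootstrap resampler.

    Attributes
    ----------
    delta_E_, delta_S_, K_d_ : fitted parameters (kJ/mol, J/(mol K), -)
    sd_ : dict of parameter standard deviations
    T_MP_, T_MP_sd_ : midpoint temperature (K) and its propagated SD
    reduced_chi2_, residuals_, converged_ : fit diagnostics
    """

    def __init__(self, init: TwoStateParams | None = None,
                 uncertainty: str = "covariance", n_boot: int = 500, seed: int = 0):
        self.init = init
        self.uncertainty = uncertainty
        self.n_boot = n_boot
        self.seed = seed

    # ------------------------------------------------------------------
    def _initial_guess(self, T: np.ndarray, r: np.ndarray) -> np.ndarray:
        if self.init is not None:
            return np.array([self.init.delta_E, self.init.delta_S, self.init.K_d])
        dE0 = 100.0
        slope = np.diff(r) / np.diff(T)
        T_mid = 0.5 * (T[:-1] + T[1:])
        T_steep = float(T_mid[np.argmin(slope)])  # steepest drop
        dS0 = dE0 * 1000.0 / T_steep
        K_d0 = max(1.0 / max(float(np.min(r)), 1e-6), 1.0 + 1e-6)
        return np.array([dE0, dS0, K_d0])

    def fit(self, X, y, sample_weight=None):
        """Fit (dE, dS, K_d) to temperatures ``X`` (K) and ratios ``y``.

        ``X`` may be 1-d or a single-column 2-d array; ``sample_weight`` are
        inverse-variance weights (per-point 1/sd^2 if uncertainties exist).
        """
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            if T.shape[1] != 1:
                raise ValueError("X must be a single temperature column")
            T = T[:, 0]
        r = np.asarray(y, dtype=float)
        if T.shape != r.shape:
            raise ValueError("X and y must have the same length")
        if T.size < 6:
            raise ValueError(f"too few points for a 3-parameter fit: {T.size} < 6")
        if np.any(T <= 0):
            raise ValueError("temperature must be > 0 K")
        if float(np.min(r)) >= 0.95:
            raise ValueError(
                "non-identifiable: no transition in window (min ratio >= 0.95)"
            )
        order = np.argsort(T)
        T, r = T[order], r[order]
        if sample_weight is None:
            sigma = np.ones_like(r)
        else:
            w = np.asarray(sample_weight, dtype=float)[order]
            if np.any(w <= 0):
                raise ValueError("sample_weight must be positive")
            sigma = 1.0 / np.sqrt(w)

        p0 = self._initial_guess(T, r)
        lower = [1e-6, 1e-6, 1.0]
        upper = [np.inf, np.inf, np.inf]
        popt, pcov, ok = self._solve(T, r, sigma, p0, (lower, upper))
        self.delta_E_, self.delta_S_, self.K_d_ = (float(v) for v in popt)
        self.converged_ = bool(ok)

        resid = r - _ratio_from_params(T, *popt)
        dof = max(T.size - 3, 1)
        self.reduced_chi2_ = float(np.sum((resid / sigma) ** 2) / dof)
        self.residuals_ = resid
        self.n_points_ = int(T.size)

        if self.uncertainty == "bootstrap":
            pcov = self._bootstrap_cov(T, r, sigma, popt)
            meta = {"uncertainty": "bootstrap", "n_boot": int(self.n_boot),
                    "seed": int(self.seed)}
        elif self.uncertainty == "covariance":
            meta = {"uncertainty": "covariance"}
        else:
            raise ValueError("uncertainty must be 'covariance' or 'bootstrap'")
        meta["optimizer"] = "scipy.optimize.least_squares (trf)"
        self.cov_ = pcov
        psd = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        self.sd_ = {"delta_E": float(psd[0]), "delta_S": float(psd[1]),
                    "K_d": float(psd[2])}
        self.T_MP_ = float(self.delta_E_ * 1000.0
                           / (self.delta_S_ + R_GAS * np.log(self.K_d_)))
        self.T_MP_sd_ = self._midpoint_sd(popt, pcov)
        self.method_meta_ = meta
        return self

    # ------------------------------------------------------------------
    def _solve(self, T, r, sigma, p0, bounds):
        def resid_fn(p):
            return (_ratio_from_params(T, p[0], p[1], p[2]) - r) / sigma

        sol = optimize.least_squares(resid_fn, p0, bounds=bounds,
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=20000)
        # covariance from the Jacobian at the solution, scaled by residual variance
        dof = max(T.size - p0.size, 1)
        s2 = 2.0 * sol.cost / dof
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * s2
        except np.linalg.LinAlgError:
            cov = np.full((p0.size, p0.size), np.nan)
        return sol.x, cov, sol.success

    def _bootstrap_cov(self, T, r, sigma, popt) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        fitted = _ratio_from_params(T, *popt)
        resid = r - fitted
        reps = []
        bounds = ([1e-6, 1e-6, 1.0], [np.inf, np.inf, np.inf])
        for _ in range(int(self.n_boot)):
            idx = rng.integers(0, resid.size, size=resid.size)
            y_star = fitted + resid[idx]
            try:
                p_star, _, ok = self._solve(T, y_star, sigma, popt, bounds)
            except Exception:
                continue
            if ok:
                reps.append(p_star)
        if len(reps) < 2:
            return np.full((3, 3), np.nan)
        return np.cov(np.asarray(reps).T, ddof=1)

    @staticmethod
    def _midpoint_sd(popt: np.ndarray, pcov: np.ndarray) -> float:
        """Delta-method SD of T_MP = 1000 dE / (dS + R ln K_d)."""
        dE, dS, Kd = popt
        denom = dS + R_GAS * np.log(Kd)
        grad = np.array([
            1000.0 / denom,
            -1000.0 * dE / denom**2,
            -1000.0 * dE * R_GAS / (Kd * denom**2),
        ])
        var = float(grad @ pcov @ grad)
        return float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else float("nan")

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "delta_E_")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            T = T[:, 0]
        return _ratio_from_params(T, self.delta_E_, self.delta_S_, self.K_d_)

    def to_params(self, tau0: float = 1.0) -> TwoStateParams:
        check_is_fitted(self, "delta_E_")
        return TwoStateParams(self.delta_E_, self.delta_S_, self.K_d_, tau0)


def fit_transition(series: TemperatureSeries, roi: RoiConfig | None = None,
                   init: TwoStateParams | None = None,
                   uncertainty: str = "covariance",
                   n_boot: int = 500, seed: int = 0,
                   weight_by_sd: bool = False) -> TransitionFitResult:
    """Fit the two-state sigmoid to the normalized series over the ROI window.

    Weighting is uniform unless ``weight_by_sd`` and per-point uncertainties
    are present.  SDs come from the fit covariance by default, or a seeded
    residual bootstrap.  Raises on a flat (non-identifiable) window.
    """
    roi = roi or RoiConfig()
    if series.ratio is None:
        raise ValueError("series has no normalized ratio values; normalize first")
    mask = series.window_mask(*roi.fit_window)
    T = series.temperatures[mask]
    r = series.ratio[mask]
    if T.size < 6:
        raise ValueError(
            f"too few points in fit window {roi.fit_window}: {T.size} < 6"
        )
    weights = None
    if weight_by_sd and series.sd is not None:
        sd = series.sd[mask]
        if np.any(sd <= 0):
            raise ValueError("per-point sd must be positive for sd weighting")
        weights = 1.0 / sd**2

    est = TwoStateTransition(init=init, uncertainty=uncertainty,
                             n_boot=n_boot, seed=seed)
    est.fit(T, r, sample_weight=weights)

    tau0 = float(series.provenance.get("tau0_ms", 1.0))
    params = TwoStateParams(est.delta_E_, est.delta_S_, est.K_d_, tau0)
    meta = dict(est.method_meta_)
    meta["fit_window"] = list(roi.fit_window)
    meta["weighting"] = "1/sd^2" if weights is not None else "uniform"
    return TransitionFitResult(
        params=params,
        sd=est.sd_,
        T_MP=est.T_MP_,
        T_MP_sd=est.T_MP_sd_,
        reduced_chi2=est.reduced_chi2_,
        residuals=est.residuals_,
        n_points=est.n_points_,
        converged=est.converged_,
        method_meta=meta,
    )


def negative_derivative(source: TemperatureSeries | TwoStateParams,
                        grid: np.ndarray | None = None) -> dict[str, Any]:
    """-d(ratio)/dT curve, with the peak reported.

    For a data series, central finite differences on the (sorted) measured
    grid; for model parameters, the analytic sigmoid is differentiated
    numerically on the supplied grid (required).
    """
    if isinstance(source, TwoStateParams):
        if grid is None:
            raise ValueError("a temperature grid is required for a model curve")
        T = _check_temperature(np.asarray(grid, dtype=float))
        if T.size < 3:
            raise ValueError("need at least 3 grid points")
        r = two_state_ratio(source, T)
    else:
        if source.ratio is None:
            raise ValueError("series has no ratio values")
        T = source.temperatures
        r = source.ratio
        if T.size < 3:
            raise ValueError("need at least 3 points for a derivative")
    deriv = -np.gradient(r, T)
    i_peak = int(np.argmax(deriv))
    return {
        "temperatures": T,
        "neg_derivative": deriv,
        "peak_temperature": float(T[i_peak]),
        "peak_height": float(deriv[i_peak]),
    }
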