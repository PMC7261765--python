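"""Per-biomarker two-component Gaussian mixtures with control anchoring.

For each region a two-component Gaussian mixture is fitted by EM.  The
"healthy" component is anchored to the control cohort: a Gaussian is
fitted to the controls alone and the 95% confidence intervals of its
mean (Student-t) and SD (chi-square) become a box within which the
healthy component must stay; after every M-step the healthy parameters
are clamped back into that box (projected EM).  The diseased component
and the mixing proportion are unconstrained by default, though per-region
mixing-proportion bounds can be configured (useful when a marker barely
discriminates and the fit would otherwise collapse).

Robustness to outliers comes from bootstrap aggregation: the mixture is
refitted on B bootstrap resamples, replicates whose mixing proportion
collapsed to 0 or 1 are discarded as biologically unrealistic, and the
element-wise median of the surviving parameters is reported.

A "weak" constraint mode (mixing proportion in [0.01, 0.99], diseased SD
>= 0.001) supports bootstrap cross-validation, where each replicate gets
a single direct fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BiomarkerTable
from .exceptions import (
    DegenerateDataError,
    EstimationFailureError,
    SampleSizeError,
)

_SIGMA_FLOOR = 1e-8  # absolute floor keeping densities proper
_MAX_ITER = 500
_LL_TOL = 1e-6
_LOG_2PI = float(np.log(2.0 * np.pi))


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


@dataclass(frozen=True)
class ControlFit:
    """Gaussian fit to one region's control sample with 95% CIs."""

    mu: float
    sigma: float
    mu_lo: float
    mu_hi: float
    sigma_lo: float
    sigma_hi: float
    n: int


@dataclass
class ControlModel:
    """Per-region control Gaussians; mapping region label -> ControlFit."""

    fits: Mapping[str, ControlFit]

    def __getitem__(self, label: str) -> ControlFit:
        return self.fits[label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: vars(v) for k, v in self.fits.items()}).T


@dataclass(frozen=True)
class MixtureFit:
    """Five-parameter mixture for one region.

    The healthy component (mu_h, sigma_h) models P(x | event has not
    occurred); the diseased component (mu_d, sigma_d) models P(x | event
    has occurred); theta is the mixing weight of the healthy component.
    """

    mu_h: float
    sigma_h: float
    mu_d: float
    sigma_d: float
    theta: float
    collapsed: bool = False
    converged: bool = True
    log_likelihood: float = float("nan")
    n_retained: int | None = None  # bootstrap replicates surviving exclusion


@dataclass(frozen=True)
class ConstraintConfig:
    """Mixing-proportion bounds and numerical guards for the EM fit.

    ``theta_bounds`` applies to every region unless overridden per label
    in ``per_region_theta``; ``sigma_d_floor`` is the weak-mode lower
    bound on the diseased SD; ``collapse_tol`` is the epsilon deciding
    when theta has collapsed to 0 or 1.
    """

    theta_bounds: tuple[float, float] = (0.0, 1.0)
    per_region_theta: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    sigma_d_floor: float = _SIGMA_FLOOR
    collapse_tol: float = 1e-3

    def __post_init__(self) -> None:
        lo, hi = self.theta_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("theta bounds must satisfy 0 <= lo < hi <= 1")
        if self.collapse_tol <= 0:
            raise ValueError("collapse tolerance must be positive")

    @classmethod
    def weak(cls) -> "ConstraintConfig":
        """Weak constraints used during cross-validation."""
        return cls(theta_bounds=(0.01, 0.99), sigma_d_floor=1e-3)

    def bounds_for(self, label: str | None) -> tuple[float, float]:
        if label is not None and label in self.per_region_theta:
            return self.per_region_theta[label]
        return self.theta_bounds


def fit_control_gaussian(values: np.ndarray, confidence: float = 0.95) -> ControlFit:
    """Maximum-likelihood Gaussian fit with exact small-sample CIs.

    The mean CI is the Student-t interval; the SD CI is the chi-square
    interval, both at ``confidence``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise SampleSizeError(f"need >= 3 control values, got {n}")
    s = x.std(ddof=1)
    if s == 0.0:
        raise DegenerateDataError("control sample has zero variance")
    mu = x.mean()
    sigma_ml = x.std(ddof=0)
    alpha = 1.0 - confidence
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    half = tcrit * s / np.sqrt(n)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df=n - 1)
    chi_lo = stats.chi2.ppf(alpha / 2.0, df=n - 1)
    return ControlFit(
        mu=float(mu),
        sigma=float(sigma_ml),
        mu_lo=float(mu - half),
        mu_hi=float(mu + half),
        sigma_lo=float(np.sqrt((n - 1) * s**2 / chi_hi)),
        sigma_hi=float(np.sqrt((n - 1) * s**2 / chi_lo)),
        n=int(n),
    )


def fit_control_model(table: BiomarkerTable) -> ControlModel:
    """Fit per-region control Gaussians on the table's control rows."""
    controls = table.controls()
    if controls.n_subjects == 0:
        raise SampleSizeError("table contains no controls")
    values = controls.value_matrix()
    fits = {
        label: fit_control_gaussian(values[:, i])
        for i, label in enumerate(table.region_labels)
    }
    return ControlModel(fits=fits)


def _em_batch(
    X: np.ndarray,
    control: ControlFit,
    theta_bounds: tuple[float, float],
    sigma_d_floor: float,
    collapse_tol: float,
) -> list[MixtureFit]:
    """Projected EM run independently on each row of X (B samples of
    length n).  Rows iterate until their own log-likelihood gain drops
    below tolerance; converged rows are frozen so every row's result is
    identical to a stand-alone run."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, n = X.shape
    lo, hi = theta_bounds
    sd_floor = max(sigma_d_floor, _SIGMA_FLOOR)

    # Healthy component starts at the control fit; the diseased one at
    # the mean/SD of values outside the control 95% band (separation-
    # seeking, deterministic), falling back to a 2-SD downward shift.
    mu_h = np.full(B, control.mu)
    sd_h = np.full(B, control.sigma)
    tail = np.abs(X - control.mu) > 1.96 * control.sigma
    cnt = tail.sum(axis=1)
    safe = np.maximum(cnt, 1)
    mu_t = (X * tail).sum(axis=1) / safe
    sd_t = np.sqrt(((X - mu_t[:, None]) ** 2 * tail).sum(axis=1) / safe)
    fallback = (cnt < 2) | (sd_t <= 0)
    mu_d = np.where(fallback, control.mu - 2.0 * control.sigma, mu_t)
    sd_d = np.maximum(np.where(fallback, control.sigma, sd_t), sd_floor)
    theta = np.full(B, float(np.clip(0.5, lo, hi)))

    ll = np.full(B, -np.inf)
    ll_prev = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    active = np.arange(B)
    for _ in range(_MAX_ITER):
        Xa = X[active]
        with np.errstate(divide="ignore"):
            log_h = np.log(theta[active])[:, None] + _norm_logpdf(
                Xa, mu_h[active, None], sd_h[active, None]
            )
            log_d = np.log1p(-theta[active])[:, None] + _norm_logpdf(
                Xa, mu_d[active, None], sd_d[active, None]
            )
        log_tot = np.logaddexp(log_h, log_d)
        ll[active] = log_tot.sum(axis=1)
        w = np.exp(log_h - log_tot)  # healthy responsibility

        wsum = w.sum(axis=1)
        vsum = n - wsum
        theta[active] = np.clip(wsum / n, lo, hi)
        ok_h = wsum > 0
        mu_new = (w * Xa).sum(axis=1) / np.where(ok_h, wsum, 1.0)
        mu_h[active] = np.where(ok_h, mu_new, mu_h[active])
        sd_new = np.sqrt(
            (w * (Xa - mu_h[active, None]) ** 2).sum(axis=1)
            / np.where(ok_h, wsum, 1.0)
        )
        sd_h[active] = np.where(ok_h, sd_new, sd_h[active])
        ok_d = vsum > 0
        mu_new = ((1 - w) * Xa).sum(axis=1) / np.where(ok_d, vsum, 1.0)
        mu_d[active] = np.where(ok_d, mu_new, mu_d[active])
        sd_new = np.sqrt(
            ((1 - w) * (Xa - mu_d[active, None]) ** 2).sum(axis=1)
            / np.where(ok_d, vsum, 1.0)
        )
        sd_d[active] = np.where(ok_d, sd_new, sd_d[active])
        # projection onto the control 95% CI box and numerical floors
        mu_h[active] = np.clip(mu_h[active], control.mu_lo, control.mu_hi)
        sd_h[active] = np.clip(sd_h[active], control.sigma_lo, control.sigma_hi)
        sd_d[active] = np.maximum(sd_d[active], sd_floor)

        done = np.abs(ll[active] - ll_prev[active]) < _LL_TOL
        converged[active[done]] = True
        ll_prev[active] = ll[active]
        active = active[~done]
        if active.size == 0:
            break

    # Collapse: theta at (or within tolerance of) 0/1, or the smaller
    # component left with less than two observations' worth of mass — a
    # two-parameter Gaussian carried by fewer points has degenerated onto
    # outliers, which is the situation the exclusion rule targets.
    collapsed = (
        (theta < collapse_tol)
        | (theta > 1.0 - collapse_tol)
        | (n * np.minimum(theta, 1.0 - theta) < 2.0)
    )
    return [
        MixtureFit(
            mu_h=float(mu_h[b]),
            sigma_h=float(sd_h[b]),
            mu_d=float(mu_d[b]),
            sigma_d=float(sd_d[b]),
            theta=float(theta[b]),
            collapsed=bool(collapsed[b]),
            converged=bool(converged[b]),
            log_likelihood=float(ll[b]),
        )
        for b in range(B)
    ]


def _em(
    x: np.ndarray,
    control: ControlFit,
    theta_bounds: tuple[float, float],
    sigma_d_floor: float,
    collapse_tol: float,
) -> MixtureFit:
    return _em_batch(x[None, :], control, theta_bounds, sigma_d_floor, collapse_tol)[0]


def fit_constrained_mixture(
    values: np.ndarray,
    control: ControlFit,
    constraints: ConstraintConfig | None = None,
    region: str | None = None,
) -> MixtureFit:
    """Single projected-EM fit of the two-component mixture for one region."""
    constraints = constraints or ConstraintConfig()
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise SampleSizeError(f"need >= 10 values for a mixture fit, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all values identical; mixture is degenerate")
    return _em(
        x,
        control,
        constraints.bounds_for(region),
        constraints.sigma_d_floor,
        constraints.collapse_tol,
    )


def bootstrap_median_fit(
    values: np.ndarray,
    control: ControlFit,
    constraints: ConstraintConfig | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    region: str | None = None,
) -> MixtureFit:
    """Bootstrap-median mixture fit for one region.

    Fits the constrained mixture on B resamples (with replacement),
    drops replicates whose mixing proportion collapsed, and returns the
    element-wise median of the surviving parameters. ``n_retained``
    reports how many replicates survived.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    constraints = constraints or ConstraintConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise SampleSizeError(f"need >= 10 values for a mixture fit, got {x.size}")
    resamples = np.stack(
        [x[rng.integers(0, x.size, size=x.size)] for _ in range(B)]
    )
    usable = np.ptp(resamples, axis=1) > 0.0  # degenerate resamples skipped
    fits = _em_batch(
        resamples[usable],
        control,
        constraints.bounds_for(region),
        constraints.sigma_d_floor,
        constraints.collapse_tol,
    )
    kept = [f for f in fits if not f.collapsed]
    if not kept:
        name = region or "<unnamed>"
        raise EstimationFailureError(
            f"all {B} bootstrap replicates collapsed for region {name}"
        )
    med = lambda attr: float(np.median([getattr(f, attr) for f in kept]))
    return MixtureFit(
        mu_h=med("mu_h"),
        sigma_h=med("sigma_h"),
        mu_d=med("mu_d"),
        sigma_d=med("sigma_d"),
        theta=med("theta"),
        collapsed=False,
        converged=all(f.converged for f in kept),
        log_likelihood=med("log_likelihood"),
        n_retained=len(kept),
    )


def event_densities(
    fit: MixtureFit, x: np.ndarray | float, log: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihoods (p_event, p_no_event) of measurement(s) x.

    p_no_event is the healthy-component density, p_event the diseased-
    component density; with ``log=True`` both are returned as log
    densities.
    """
    if log:
        return (
            stats.norm.logpdf(x, fit.mu_d, fit.sigma_d),
            stats.norm.logpdf(x, fit.mu_h, fit.sigma_h),
        )
    return (
        stats.norm.pdf(x, fit.mu_d, fit.sigma_d),
        stats.norm.pdf(x, fit.mu_h, fit.sigma_h),
    )


def fit_mixture_models(
    table: BiomarkerTable,
    constraints: ConstraintConfig | None = None,
    B: int = 1000,
    pooled: bool = True,
    seed: int = 0,
    control_model: ControlModel | None = None,
) -> tuple[dict[str, MixtureFit], ControlModel]:
    """Fit every region's mixture with the bootstrap-median procedure.

    ``pooled=True`` fits on patients + controls together (the anchored
    healthy component needs control mass); ``pooled=False`` uses
    patients only.  ``B=0`` requests a single direct fit per region (the
    cross-validation mode).
    """
    constraints = constraints or ConstraintConfig()
    if control_model is None:
        control_model = fit_control_model(table)
    data = table if pooled else table.patients()
    values = data.value_matrix()
    rng = np.random.default_rng(seed)
    fits: dict[str, MixtureFit] = {}
    for i, label in enumerate(table.region_labels):
        if B == 0:
            fits[label] = fit_constrained_mixture(
                values[:, i], control_model[label], constraints, label
            )
        else:
            fits[label] = bootstrap_median_fit(
                values[:, i],
                control_model[label],
                constraints,
                B=B,
                seed=rng,
                region=label,
            )
    return fits, control_model


def fits_to_frame(fits: Mapping[str, MixtureFit]) -> pd.DataFrame:
    return pd.DataFrame({k: vars(v) for k, v in fits.items()}).T
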