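"""Sequential nonlinear least-squares estimation of clearance kinetics.

The dual-probe design identifies the kinetics in two stages:

1. the MCC parameters (``k_lt``, FFCA — and ``k_dl`` under the Case-2
   structure variant) are fit to the particle-probe (Tc-SC) retention data,
   which is insensitive to absorption;
2. with the MCC parameters frozen, the absorption rate constants
   (``k_lb``, ``k_db``) are fit to the absorption curve (Tc-SC retention
   minus DTPA retention).

Both stages pool residuals over all subjects and frames in a group
(N = frames x subjects points per probe). Confidence intervals come from
the standard nonlinear-regression covariance ``s^2 (J^T W J)^{-1}`` with a
Student-t quantile, and trajectory uncertainty is propagated by evaluating
the model at every {lower, nominal, upper} combination of the fitted
parameters and taking the pointwise extremes ("CI envelopes").

:class:`ClearanceEstimator` wraps the whole procedure in a scikit-learn
style estimator; the module-level functions are thin functional entry
points over the same machinery.
"""

from __future__ import annotations

import itertools
import math
import warnings as _warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .compartment_model import (
    AbsorptionSeries,
    DepositionState,
    ModelParameters,
    RetentionSeries,
    retention_curve,
)

__all__ = [
    "FitResult",
    "TrajectoryEnvelope",
    "ClearanceEstimator",
    "normalize_counts",
    "fit_mcc",
    "fit_absorption",
    "parameter_ci",
    "trajectory_envelope",
    "compare_parameters",
    "SubjectSeries",
]

# isotope half-lives, minutes
HALF_LIFE_MIN = {"TCSC": 6.01 * 60.0, "DTPA": 67.3 * 60.0}

PROBES = ("TCSC", "DTPA")

_DEFAULT_INIT = {"k_lt": 0.03, "ffca": 0.5, "k_lb": 0.005, "k_db": 0.01, "k_dl": 0.001}
_DEFAULT_BOUNDS = {
    "k_lt": (0.0, 1.0),
    "ffca": (0.0, 1.0),
    "k_lb": (0.0, 1.0),
    "k_db": (0.0, 1.0),
    "k_dl": (0.0, 1.0),
}


class FitFailureError(RuntimeError):
    """Optimizer failed to converge; carries scipy diagnostics."""


class UnidentifiabilityError(RuntimeError):
    """The Jacobian at the solution is rank deficient: a parameter is not
    informed by the data and its covariance is undefined."""


class PairingError(ValueError):
    """A subject is missing a probe or the probes' frame grids differ."""


class NormalizationError(ValueError):
    """Frame-0 counts are zero; retention is undefined."""


@dataclass(frozen=True)
class SubjectSeries:
    """Normalized observables and deposition for one subject."""

    subject_id: str
    group: str
    times: np.ndarray
    retention: dict  # probe -> RetentionSeries (whole-lung, frame-0 normalized)
    central_retention: dict  # probe -> RetentionSeries (central ROI)
    absorption: AbsorptionSeries
    deposition: dict  # probe -> DepositionState


@dataclass(frozen=True)
class FitResult:
    """Point estimates, covariance and CIs for one estimation stage."""

    stage: str  # "mcc" or "absorption"
    param_names: tuple
    estimates: dict
    se: dict
    ci_lower: dict
    ci_upper: dict
    level: float
    residual_sum_squares: float
    n_points: int
    n_params: int
    covariance: np.ndarray
    jacobian: np.ndarray
    frozen: dict
    success: bool = True
    warnings: tuple = ()

    def __post_init__(self):
        if self.n_points <= self.n_params:
            raise ValueError("need more data points than free parameters")

    def half_width(self, name: str) -> float:
        return 0.5 * (self.ci_upper[name] - self.ci_lower[name])


@dataclass(frozen=True)
class TrajectoryEnvelope:
    """Pointwise min/max of model curves over all CI-corner combinations."""

    times: np.ndarray
    nominal: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    target: str


# ---------------------------------------------------------------------------
# data preparation


def _decay_correct(counts: np.ndarray, times: np.ndarray, probe: str) -> np.ndarray:
    lam = math.log(2.0) / HALF_LIFE_MIN[probe]
    return counts * np.exp(lam * times)


def normalize_counts(
    dataset: pd.DataFrame,
    decay_correct: bool = False,
    tracheal_fraction: float = 0.10,
) -> list[SubjectSeries]:
    """Turn a long-format counts table into per-subject normalized series.

    The table must carry columns ``subject_id, group, probe, frame,
    time_min, counts_whole_lung, counts_central`` with both probes on a
    common frame grid per subject. Each probe's series is divided by its
    own frame-0 value (after optional physical-decay correction); the
    absorption series is the pointwise Tc-SC minus DTPA whole-lung
    retention. Deposition is read off the frame-0 central/peripheral split.
    """
    required = {
        "subject_id", "group", "probe", "frame", "time_min",
        "counts_whole_lung", "counts_central",
    }
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    out = []
    for sid, sub in dataset.groupby("subject_id", sort=True):
        probes = set(sub["probe"].unique())
        if not set(PROBES) <= probes:
            raise PairingError(
                f"subject {sid!r} is missing probe(s) {sorted(set(PROBES) - probes)}"
            )
        retention, central_ret, deposition = {}, {}, {}
        times_ref = None
        for probe in PROBES:
            s = sub[sub["probe"] == probe].sort_values("frame")
            times = s["time_min"].to_numpy(dtype=float)
            if times_ref is None:
                times_ref = times
            elif times.shape != times_ref.shape or not np.array_equal(times, times_ref):
                raise PairingError(f"subject {sid!r}: probes are on different frame grids")
            whole = s["counts_whole_lung"].to_numpy(dtype=float)
            central = s["counts_central"].to_numpy(dtype=float)
            if np.any(whole < 0) or np.any(central < 0):
                raise ValueError(f"subject {sid!r}: negative counts")
            if decay_correct:
                whole = _decay_correct(whole, times, probe)
                central = _decay_correct(central, times, probe)
            if whole[0] <= 0 or central[0] <= 0:
                raise NormalizationError(
                    f"subject {sid!r}, probe {probe}: frame-0 counts must be positive"
                )
            retention[probe] = RetentionSeries(
                times=times, values=whole / whole[0], probe=probe, roi="whole_lung"
            )
            central_ret[probe] = RetentionSeries(
                times=times, values=central / central[0], probe=probe, roi="central"
            )
            deposition[probe] = DepositionState(
                c0=float(central[0]),
                p0=float(whole[0] - central[0]),
                tracheal_fraction=tracheal_fraction,
            )
        absorption = AbsorptionSeries(
            times=times_ref,
            values=retention["TCSC"].values - retention["DTPA"].values,
        )
        out.append(
            SubjectSeries(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                times=times_ref,
                retention=retention,
                central_retention=central_ret,
                absorption=absorption,
                deposition=deposition,
            )
        )
    return out


def _as_subjects(dataset, decay_correct=False) -> list[SubjectSeries]:
    if isinstance(dataset, pd.DataFrame):
        return normalize_counts(dataset, decay_correct=decay_correct)
    return list(dataset)


# ---------------------------------------------------------------------------
# model evaluation helpers (fast closed forms used inside the optimizer)


def _tc_retention_model(theta: dict, dep: DepositionState, times: np.ndarray) -> np.ndarray:
    p = ModelParameters(
        k_lt=theta["k_lt"], ffca=theta["ffca"], k_dl=theta.get("k_dl", 0.0)
    )
    return retention_curve(p, dep, times, roi="whole_lung").values


def _absorption_model(
    theta: dict, dep_tc: DepositionState, dep_dtpa: DepositionState, times: np.ndarray
) -> np.ndarray:
    shared = dict(
        k_lt=theta["k_lt"], ffca=theta["ffca"], k_dl=theta.get("k_dl", 0.0)
    )
    p_tc = ModelParameters(**shared)
    p_dtpa = ModelParameters(
        k_lb=theta.get("k_lb", 0.0), k_db=theta.get("k_db", 0.0), **shared
    )
    r_tc = retention_curve(p_tc, dep_tc, times, roi="whole_lung").values
    r_dtpa = retention_curve(p_dtpa, dep_dtpa, times, roi="whole_lung").values
    return r_tc - r_dtpa


def _clip_theta(names, x, bounds):
    return {
        n: float(np.clip(v, bounds[n][0], bounds[n][1])) for n, v in zip(names, x)
    }


# ---------------------------------------------------------------------------
# core least-squares driver


def _pooled_fit(
    names: tuple,
    frozen: dict,
    residual_fn,
    n_points: int,
    stage: str,
    init: dict | None = None,
    bounds: dict | None = None,
    multistart: int = 5,
    level: float = 0.95,
    random_state: int | None = 0,
) -> FitResult:
    """Multi-start bounded least squares + covariance-based CIs."""
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    x0_base = np.array([(init or {}).get(n, _DEFAULT_INIT[n]) for n in names])
    lo = np.array([b[n][0] for n in names])
    hi = np.array([b[n][1] for n in names])
    x0_base = np.clip(x0_base, lo, hi)

    def fun(x):
        theta = dict(frozen)
        theta.update(_clip_theta(names, x, b))
        return residual_fn(theta)

    rng = np.random.default_rng(random_state)
    starts = [x0_base]
    for _ in range(max(0, multistart - 1)):
        jitter = x0_base * rng.lognormal(0.0, 0.5, size=x0_base.size)
        jitter = np.where(x0_base == 0, rng.uniform(lo, np.minimum(hi, 0.1)), jitter)
        starts.append(np.clip(jitter, lo, hi))

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                fun, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:  # pragma: no cover - scipy raising is itself failure
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError(f"{stage} fit failed to converge from {len(starts)} starts")

    estimates = _clip_theta(names, best.x, b)
    rss = float(2.0 * best.cost)
    warn: list[str] = []
    for n, v, l_, h_ in zip(names, best.x, lo, hi):
        span = max(h_ - l_, 1e-300)
        if min(v - l_, h_ - v) < 1e-6 * span:
            warn.append(f"parameter {n} is at a bound ({v:.3g})")

    fit = FitResult(
        stage=stage,
        param_names=tuple(names),
        estimates=estimates,
        se={n: np.nan for n in names},
        ci_lower={n: np.nan for n in names},
        ci_upper={n: np.nan for n in names},
        level=level,
        residual_sum_squares=rss,
        n_points=n_points,
        n_params=len(names),
        covariance=np.full((len(names), len(names)), np.nan),
        jacobian=best.jac,
        frozen=dict(frozen),
        success=True,
        warnings=tuple(warn),
    )
    try:
        fit = parameter_ci(fit, level=level)
    except UnidentifiabilityError:
        fit = _dc_replace(
            fit,
            se={n: np.inf for n in names},
            ci_lower={n: -np.inf for n in names},
            ci_upper={n: np.inf for n in names},
            warnings=fit.warnings + ("covariance singular: parameters unidentifiable",),
        )
    return fit


def parameter_ci(fit: FitResult, level: float = 0.95) -> FitResult:
    """Covariance-based CIs: ``s^2 (J^T J)^{-1}`` with a t quantile.

    ``s^2`` is the weighted residual sum of squares over the residual
    degrees of freedom N - k; the Jacobian is that of the (weighted)
    residual vector at the solution. Rank deficiency of ``J^T J`` raises
    :class:`UnidentifiabilityError` — the expected outcome when a rate on a
    timescale far beyond the experiment (such as distal-lung MCC) is freed.
    """
    J = np.asarray(fit.jacobian, dtype=float)
    n, k = fit.n_points, fit.n_params
    jtj = J.T @ J
    if not np.all(np.isfinite(jtj)):
        raise UnidentifiabilityError("non-finite Jacobian at the solution")
    rank = np.linalg.matrix_rank(jtj)
    if rank < k or np.linalg.cond(jtj) > 1e14:
        raise UnidentifiabilityError(
            f"J^T J has rank {rank} < {k}: parameter(s) not informed by the data"
        )
    s2 = fit.residual_sum_squares / (n - k)
    cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=n - k)
    names = fit.param_names
    return _dc_replace(
        fit,
        level=level,
        se={nm: float(se[i]) for i, nm in enumerate(names)},
        ci_lower={nm: float(fit.estimates[nm] - tq * se[i]) for i, nm in enumerate(names)},
        ci_upper={nm: float(fit.estimates[nm] + tq * se[i]) for i, nm in enumerate(names)},
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# stage fits


def _stack_residuals(parts):
    return np.concatenate(parts) if parts else np.empty(0)


def fit_mcc(
    dataset,
    init: dict | None = None,
    bounds: dict | None = None,
    free: tuple = ("k_lt", "ffca"),
    weights: str = "uniform",
    multistart: int = 5,
    level: float = 0.95,
    decay_correct: bool = False,
    random_state: int | None = 0,
) -> FitResult:
    """Fit the MCC kinetics to the pooled Tc-SC retention data.

    Minimizes the pooled (all subjects x all frames) weighted squared
    residuals between each subject's normalized whole-lung Tc-SC retention
    and the model curve with that subject's frame-0 deposition. ``free``
    may include ``k_dl`` for the Case-2 structure variant.
    """
    subjects = _as_subjects(dataset, decay_correct)
    n_points = sum(s.times.size for s in subjects)
    if n_points < 10 and len(subjects) < 2:
        raise ValueError("need at least 2 subjects or 10 frames to fit")

    sqrt_w = _sqrt_weights(subjects, "TCSC", weights)

    def residuals(theta):
        parts = []
        for s, w in zip(subjects, sqrt_w):
            model = _tc_retention_model(theta, s.deposition["TCSC"], s.times)
            parts.append(w * (model - s.retention["TCSC"].values))
        return _stack_residuals(parts)

    return _pooled_fit(
        names=tuple(free), frozen={}, residual_fn=residuals, n_points=n_points,
        stage="mcc", init=init, bounds=bounds, multistart=multistart,
        level=level, random_state=random_state,
    )


def fit_absorption(
    dataset,
    mcc_fit: FitResult,
    init: dict | None = None,
    bounds: dict | None = None,
    free: tuple = ("k_lb", "k_db"),
    weights: str = "uniform",
    multistart: int = 5,
    level: float = 0.95,
    decay_correct: bool = False,
    random_state: int | None = 0,
) -> FitResult:
    """Fit the absorption rate constants with the MCC kinetics frozen.

    The observable is the per-subject absorption series (Tc-SC minus DTPA
    whole-lung retention); the model curve shares ``k_lt``/FFCA (and
    ``k_dl``) with the first-stage fit. ``free`` is ``("k_db",)`` under the
    Case-1 variant (no central absorption).
    """
    if not mcc_fit.success:
        raise FitFailureError("MCC stage did not converge; cannot fit absorption")
    subjects = _as_subjects(dataset, decay_correct)
    n_points = sum(s.times.size for s in subjects)
    frozen = dict(mcc_fit.estimates)
    frozen.update(mcc_fit.frozen)

    sqrt_w = _sqrt_weights(subjects, "DTPA", weights)

    def residuals(theta):
        parts = []
        for s, w in zip(subjects, sqrt_w):
            model = _absorption_model(
                theta, s.deposition["TCSC"], s.deposition["DTPA"], s.times
            )
            parts.append(w * (model - s.absorption.values))
        return _stack_residuals(parts)

    return _pooled_fit(
        names=tuple(free), frozen=frozen, residual_fn=residuals, n_points=n_points,
        stage="absorption", init=init, bounds=bounds, multistart=multistart,
        level=level, random_state=random_state,
    )


def _sqrt_weights(subjects, probe, weights: str):
    """Per-subject sqrt-weight arrays for the residual vector."""
    if weights == "uniform":
        return [np.ones_like(s.times) for s in subjects]
    if weights == "poisson":
        # inverse-variance weights for frame-normalized Poisson counts:
        # Var R(t) ~= R(t) / N0, so w = N0 / max(R, eps)
        out = []
        for s in subjects:
            n0 = s.deposition[probe].total_lung
            r = np.maximum(s.retention[probe].values, 1e-6)
            out.append(np.sqrt(n0 / r))
        return out
    raise ValueError(f"unknown weighting scheme {weights!r}")


# ---------------------------------------------------------------------------
# uncertainty propagation and group contrasts


def trajectory_envelope(
    mcc_fit: FitResult,
    abs_fit: FitResult | None,
    deposition: DepositionState,
    times,
    target: str = "retention",
) -> TrajectoryEnvelope:
    """Model-prediction envelope from all CI-corner combinations.

    Evaluates the target curve at every combination of {lower, nominal,
    upper} for each fitted parameter (3^k curves), clipping FFCA to [0, 1]
    and rates to be non-negative, and takes the pointwise min/max. The
    nominal curve is the one at the point estimates.
    """
    times = np.asarray(times, dtype=float)
    fits = [mcc_fit] + ([abs_fit] if abs_fit is not None else [])
    names, levels, nominal_theta = [], [], {}
    for f in fits:
        for n in f.param_names:
            est, lo, hi = f.estimates[n], f.ci_lower[n], f.ci_upper[n]
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"CI for {n} is not finite; envelope undefined")
            names.append(n)
            levels.append((lo, est, hi))
            nominal_theta[n] = est
        nominal_theta.update(f.frozen)

    def curve(theta):
        theta = dict(theta)
        for n in ("k_lt", "k_lb", "k_db", "k_dl"):
            if n in theta:
                theta[n] = max(theta[n], 0.0)
        if "ffca" in theta:
            theta["ffca"] = min(max(theta["ffca"], 0.0), 1.0)
        if target == "retention":
            return _tc_retention_model(theta, deposition, times)
        if target == "absorption":
            return _absorption_model(theta, deposition, deposition, times)
        raise ValueError(f"target must be 'retention' or 'absorption', got {target!r}")

    nominal = curve(nominal_theta)
    lower = nominal.copy()
    upper = nominal.copy()
    for combo in itertools.product(*levels):
        theta = dict(nominal_theta)
        theta.update(dict(zip(names, combo)))
        c = curve(theta)
        lower = np.minimum(lower, c)
        upper = np.maximum(upper, c)
    return TrajectoryEnvelope(times=times, nominal=nominal, lower=lower, upper=upper, target=target)


def compare_parameters(fit_a: FitResult, fit_b: FitResult, parameter: str):
    """Wald z-test for a parameter difference between two fitted groups.

    Returns ``(z, p)`` with ``z = (a - b) / sqrt(se_a^2 + se_b^2)`` and a
    two-sided normal p-value.
    """
    for f in (fit_a, fit_b):
        if parameter not in f.estimates:
            raise KeyError(f"parameter {parameter!r} not in {f.stage} fit")
        if not np.isfinite(f.se[parameter]):
            raise ValueError(f"standard error for {parameter!r} is not finite")
    denom = math.hypot(fit_a.se[parameter], fit_b.se[parameter])
    diff = fit_a.estimates[parameter] - fit_b.estimates[parameter]
    if denom == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(np.inf, diff)
    else:
        z = diff / denom
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return float(z), float(p)


# ---------------------------------------------------------------------------
# scikit-learn estimator


class ClearanceEstimator(BaseEstimator):
    """Sequential dual-probe clearance fit as a scikit-learn estimator.

    Parameters
    ----------
    structure : {"nominal", "case1_no_kLB", "case2_with_kDL"}
        Model structure variant. The nominal structure frees
        (k_lt, ffca, k_lb, k_db); Case 1 fixes k_lb = 0; Case 2 additionally
        frees the distal-to-central MCC rate k_dl in the first stage.
    weights : {"uniform", "poisson"}
        Residual weighting; uniform by default.
    multistart : int
        Number of jittered optimizer starts per stage (best RSS wins).
    ci_level : float
        Confidence level for parameter intervals.
    decay_correct : bool
        Apply physical isotope-decay correction to raw counts before
        normalization (off by default: deposited counts are assumed already
        decay-corrected).
    random_state : int or None
        Seed for the start-point jitter.

    Attributes
    ----------
    mcc_fit_, absorption_fit_ : FitResult
        Stage results with estimates, covariance and CIs.
    k_lt_, ffca_, k_lb_, k_db_, k_dl_ : float
        Convenience point estimates.
    aic_ : float
        Combined AIC, ``N ln(RSS_tc + RSS_abs) + 2 k`` with N the pooled
        per-probe point count.
    deposition_ : DepositionState
        Pooled frame-0 deposition (summed over subjects, Tc-SC probe),
        used by :meth:`predict` and :meth:`envelope`.
    """

    def __init__(
        self,
        structure: str = "nominal",
        weights: str = "uniform",
        multistart: int = 5,
        ci_level: float = 0.95,
        decay_correct: bool = False,
        init: dict | None = None,
        bounds: dict | None = None,
        random_state: int | None = 0,
    ):
        self.structure = structure
        self.weights = weights
        self.multistart = multistart
        self.ci_level = ci_level
        self.decay_correct = decay_correct
        self.init = init
        self.bounds = bounds
        self.random_state = random_state

    _STRUCTURES = {
        "nominal": (("k_lt", "ffca"), ("k_lb", "k_db")),
        "case1_no_kLB": (("k_lt", "ffca"), ("k_db",)),
        "case2_with_kDL": (("k_lt", "ffca", "k_dl"), ("k_lb", "k_db")),
    }

    def fit(self, X, y=None):
        """Run the two-stage fit on a long-format counts table."""
        if self.structure not in self._STRUCTURES:
            raise ValueError(
                f"structure must be one of {sorted(self._STRUCTURES)}, got {self.structure!r}"
            )
        mcc_free, abs_free = self._STRUCTURES[self.structure]
        subjects = _as_subjects(X, self.decay_correct)
        kw = dict(
            init=self.init, bounds=self.bounds, weights=self.weights,
            multistart=self.multistart, level=self.ci_level,
            random_state=self.random_state,
        )
        self.mcc_fit_ = fit_mcc(subjects, free=mcc_free, **kw)
        self.absorption_fit_ = fit_absorption(subjects, self.mcc_fit_, free=abs_free, **kw)
        est = {**self.mcc_fit_.estimates, **self.absorption_fit_.estimates}
        self.k_lt_ = est["k_lt"]
        self.ffca_ = est["ffca"]
        self.k_lb_ = est.get("k_lb", 0.0)
        self.k_db_ = est["k_db"]
        self.k_dl_ = est.get("k_dl", 0.0)
        self.n_points_ = self.mcc_fit_.n_points
        self.k_free_ = self.mcc_fit_.n_params + self.absorption_fit_.n_params
        self.rss_ = (
            self.mcc_fit_.residual_sum_squares
            + self.absorption_fit_.residual_sum_squares
        )
        # combined AIC over the pooled Tc-SC + absorption residuals
        from .model_selection import weighted_aic

        self.aic_ = weighted_aic(rss=self.rss_, n_points=self.n_points_, k_free=self.k_free_)
        self.deposition_ = DepositionState(
            c0=sum(s.deposition["TCSC"].c0 for s in subjects),
            p0=sum(s.deposition["TCSC"].p0 for s in subjects),
        )
        self.subjects_ = subjects
        return self

    def _check_fitted(self):
        if not hasattr(self, "mcc_fit_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    @property
    def parameters_(self) -> ModelParameters:
        """Fitted kinetics as a small-molecule (DTPA) parameter set."""
        self._check_fitted()
        return ModelParameters(
            k_lt=self.k_lt_, ffca=self.ffca_, k_lb=self.k_lb_, k_db=self.k_db_,
            k_dl=self.k_dl_,
        )

    def predict(self, T, target: str = "retention", probe: str = "TCSC",
                roi: str = "whole_lung"):
        """Model curve at the point estimates on time grid ``T`` (minutes)."""
        self._check_fitted()
        T = np.asarray(T, dtype=float)
        p = self.parameters_
        if target == "absorption":
            theta = {
                "k_lt": p.k_lt, "ffca": p.ffca, "k_dl": p.k_dl,
                "k_lb": p.k_lb, "k_db": p.k_db,
            }
            return _absorption_model(theta, self.deposition_, self.deposition_, T)
        if target != "retention":
            raise ValueError(f"target must be 'retention' or 'absorption', got {target!r}")
        params = p.as_particle() if probe == "TCSC" else p
        return retention_curve(params, self.deposition_, T, roi=roi).values

    def envelope(self, T, target: str = "retention") -> TrajectoryEnvelope:
        """CI trajectory envelope on time grid ``T``."""
        self._check_fitted()
        abs_fit = self.absorption_fit_ if target == "absorption" else None
        return trajectory_envelope(self.mcc_fit_, abs_fit, self.deposition_, T, target=target)

    def score(self, X, y=None) -> float:
        """Negative pooled weighted RSS on ``X`` (larger is better)."""
        self._check_fitted()
        subjects = _as_subjects(X, self.decay_correct)
        rss = 0.0
        theta = {
            "k_lt": self.k_lt_, "ffca": self.ffca_, "k_dl": self.k_dl_,
            "k_lb": self.k_lb_, "k_db": self.k_db_,
        }
        for s in subjects:
            r_tc = _tc_retention_model(theta, s.deposition["TCSC"], s.times)
            rss += float(np.sum((r_tc - s.retention["TCSC"].values) ** 2))
            a = _absorption_model(theta, s.deposition["TCSC"], s.deposition["DTPA"], s.times)
            rss += float(np.sum((a - s.absorption.values) ** 2))
        return -rss
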