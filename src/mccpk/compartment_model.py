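"""Three-compartment lung model of mucociliary clearance (MCC) and absorption.

The lung is lumped into a central large-airway region ``L`` — split into a
ciliated, MCC-competent sub-compartment ``L_M`` and a non-functional
sub-compartment ``L_N`` — and a distal region ``D`` (small airways and
alveoli). Deposited probe clears from ``L_M`` to the trachea ``T`` by MCC
(rate constant ``k_LT``) and is absorbed into blood ``B`` from the central
region (``k_LB``) and from the distal region (``k_DB``). All kinetics are
first order. The fraction of the central dose landing in the ciliated
sub-compartment is the fraction of functional ciliated airway (FFCA).

Two probes are modelled: a ~300 nm sulfur-colloid particle (Tc-SC) cleared
only by MCC (absorption rates identically zero) and a ~500 Da small molecule
(In-DTPA) cleared by both MCC and paracellular absorption. A structure
variant ("Case 2") adds a slow distal-to-central MCC route ``k_DL``.

The linear system has a closed-form exponential solution, implemented
directly; :func:`solve_compartments` also exposes the full five-state
trajectory via the matrix exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelParameters",
    "DepositionState",
    "CompartmentTrajectory",
    "RetentionSeries",
    "AbsorptionSeries",
    "solve_compartments",
    "retention_curve",
    "absorption_curve",
]


class ParameterDomainError(ValueError):
    """Raised when kinetic parameters violate their physical domain."""


class DegenerateDepositionError(ValueError):
    """Raised when the deposited dose is zero and retention is undefined."""


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic rate constants (per minute) and FFCA for one probe/group.

    ``k_lt`` is the MCC rate constant from the ciliated central
    sub-compartment to the trachea; ``k_lb`` and ``k_db`` are the central
    and distal absorption rate constants; ``ffca`` is the dimensionless
    fraction of the central dose in the MCC-competent sub-compartment.
    ``k_dl`` (distal-to-central MCC) is zero except under the Case-2
    structure variant.
    """

    k_lt: float
    ffca: float
    k_lb: float = 0.0
    k_db: float = 0.0
    k_dl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_lt", "k_lb", "k_db", "k_dl"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterDomainError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.ffca <= 1.0:
            raise ParameterDomainError(f"ffca must lie in [0, 1], got {self.ffca!r}")

    @property
    def is_particle(self) -> bool:
        """True for a pure-MCC (Tc-SC-like) parameterization."""
        return self.k_lb == 0.0 and self.k_db == 0.0

    def as_particle(self) -> "ModelParameters":
        """Copy with absorption switched off (the Tc-SC constraint)."""
        return replace(self, k_lb=0.0, k_db=0.0)


@dataclass(frozen=True)
class DepositionState:
    """Initial counts in the central (``c0``) and peripheral (``p0``) ROIs.

    Derived from the first imaging frame. ``tracheal_fraction`` is the
    fraction of the *inhaled* dose assumed to land in the trachea (default
    10%); ``c0 + p0`` is the remaining lung dose. The trachea is excluded
    from every observable, so this only matters for mass-balance bookkeeping.
    """

    c0: float
    p0: float
    tracheal_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.p0 < 0:
            raise DegenerateDepositionError(
                f"need c0 > 0 and p0 >= 0, got c0={self.c0!r}, p0={self.p0!r}"
            )
        if not 0.0 <= self.tracheal_fraction < 1.0:
            raise ValueError("tracheal_fraction must lie in [0, 1)")

    @property
    def total_lung(self) -> float:
        return self.c0 + self.p0

    @property
    def t0(self) -> float:
        """Initial tracheal counts implied by the tracheal-fraction assumption."""
        f = self.tracheal_fraction
        return f / (1.0 - f) * (self.c0 + self.p0)


@dataclass(frozen=True)
class CompartmentTrajectory:
    """Counts in each compartment (L_M, L_N, D, T, B) on a minute grid."""

    times: np.ndarray
    lm: np.ndarray
    ln: np.ndarray
    d: np.ndarray
    t: np.ndarray
    b: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.lm + self.ln + self.d + self.t + self.b


@dataclass(frozen=True)
class RetentionSeries:
    """Normalized (frame-0 = 1) probe retention in an ROI over time."""

    times: np.ndarray
    values: np.ndarray
    probe: str = "TCSC"
    roi: str = "whole_lung"


@dataclass(frozen=True)
class AbsorptionSeries:
    """Tc-SC retention minus DTPA retention: the absorbed fraction."""

    times: np.ndarray
    values: np.ndarray


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t


def _rate_matrix(p: ModelParameters) -> np.ndarray:
    """Linear system matrix over the state (L_M, L_N, D, T, B)."""
    return np.array(
        [
            [-(p.k_lt + p.k_lb), 0.0, p.k_dl, 0.0, 0.0],
            [0.0, -p.k_lb, 0.0, 0.0, 0.0],
            [0.0, 0.0, -(p.k_db + p.k_dl), 0.0, 0.0],
            [p.k_lt, 0.0, 0.0, 0.0, 0.0],
            [p.k_lb, p.k_lb, p.k_db, 0.0, 0.0],
        ]
    )


def initial_state(params: ModelParameters, deposition: DepositionState) -> np.ndarray:
    """(L_M, L_N, D, T, B) at t=0: FFCA splits the central dose."""
    return np.array(
        [
            params.ffca * deposition.c0,
            (1.0 - params.ffca) * deposition.c0,
            deposition.p0,
            deposition.t0,
            0.0,
        ]
    )


def _lung_states(params: ModelParameters, deposition: DepositionState, t: np.ndarray):
    """Closed-form L_M(t), L_N(t), D(t) — the observable compartments.

    With a = k_DB + k_DL and b = k_LT + k_LB:
        D(t)   = p0 e^{-a t}
        L_N(t) = (1-FFCA) c0 e^{-k_LB t}
        L_M(t) = FFCA c0 e^{-b t} + k_DL p0 (e^{-a t} - e^{-b t}) / (b - a)
    with the b -> a limit k_DL p0 t e^{-a t}.
    """
    a = params.k_db + params.k_dl
    b = params.k_lt + params.k_lb
    d = deposition.p0 * np.exp(-a * t)
    ln = (1.0 - params.ffca) * deposition.c0 * np.exp(-params.k_lb * t)
    lm = params.ffca * deposition.c0 * np.exp(-b * t)
    if params.k_dl > 0.0:
        if abs(b - a) > 1e-12 * max(a, b, 1e-300):
            lm = lm + params.k_dl * deposition.p0 * (np.exp(-a * t) - np.exp(-b * t)) / (b - a)
        else:
            lm = lm + params.k_dl * deposition.p0 * t * np.exp(-a * t)
    return lm, ln, d


def solve_compartments(
    params: ModelParameters, deposition: DepositionState, times
) -> CompartmentTrajectory:
    """Solve the five-state linear system on the given minute grid.

    Uses the closed-form matrix-exponential solution
    ``x(t) = expm(A t) x(0)``; a generic numerical integrator on the same
    right-hand side serves as the independent cross-check in the test suite.
    """
    t = _check_times(times)
    A = _rate_matrix(params)
    x0 = initial_state(params, deposition)
    states = np.empty((t.size, 5))
    for i, ti in enumerate(t):
        states[i] = expm(A * ti) @ x0
    # clip tiny negative round-off from the matrix exponential
    tol = 1e-9 * max(1.0, x0.sum())
    states[(states < 0) & (states > -tol)] = 0.0
    return CompartmentTrajectory(
        times=t, lm=states[:, 0], ln=states[:, 1], d=states[:, 2],
        t=states[:, 3], b=states[:, 4],
    )


def retention_curve(
    params: ModelParameters,
    deposition: DepositionState,
    times,
    roi: str = "whole_lung",
) -> RetentionSeries:
    """Model retention (normalized to frame 0) in the whole-lung or central ROI.

    Whole-lung retention is ``(L_M + L_N + D) / (c0 + p0)``; central retention
    is ``(L_M + L_N) / c0``. Trachea and blood are unobserved sinks. For a
    pure-MCC probe the whole-lung curve is a monoexponential decay to the
    plateau ``((1 - FFCA) c0 + p0) / (c0 + p0)``.
    """
    t = _check_times(times)
    if deposition.total_lung <= 0:
        raise DegenerateDepositionError("c0 + p0 must be positive")
    lm, ln, d = _lung_states(params, deposition, t)
    if roi == "whole_lung":
        values = (lm + ln + d) / deposition.total_lung
    elif roi == "central":
        values = (lm + ln) / deposition.c0
    else:
        raise ValueError(f"roi must be 'whole_lung' or 'central', got {roi!r}")
    probe = "TCSC" if params.is_particle else "DTPA"
    return RetentionSeries(times=t, values=values, probe=probe, roi=roi)


def absorption_curve(
    tc_params: ModelParameters,
    dtpa_params: ModelParameters,
    deposition: DepositionState,
    times,
    roi: str = "whole_lung",
) -> AbsorptionSeries:
    """Model absorption: Tc-SC retention minus DTPA retention.

    Both probes deposit identically and share the MCC kinetics (``k_lt``,
    ``ffca``, ``k_dl``); the particle probe must have zero absorption rates.
    """
    if not tc_params.is_particle:
        raise ParameterDomainError("tc_params must have k_lb = k_db = 0")
    for name in ("k_lt", "ffca", "k_dl"):
        if getattr(tc_params, name) != getattr(dtpa_params, name):
            raise ParameterDomainError(
                f"probes must share MCC kinetics: {name} differs "
                f"({getattr(tc_params, name)!r} vs {getattr(dtpa_params, name)!r})"
            )
    r_tc = retention_curve(tc_params, deposition, times, roi=roi)
    r_dtpa = retention_curve(dtpa_params, deposition, times, roi=roi)
    return AbsorptionSeries(times=r_tc.times, values=r_tc.values - r_dtpa.values)
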