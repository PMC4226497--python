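"""Fraction of functional ciliated area (FFCA) from phase-contrast stacks.

Ciliary beat shows up in a phase-contrast image series as frame-to-frame
intensity flicker. The assay quantifies it per pixel as the mean absolute
intensity change between successive frames; pixels whose change exceeds a
baseline threshold — the grand mean change over untreated non-CF control
cultures — are called functionally ciliated, and the functional fraction is
the proportion of such pixels.

This in vitro pixel fraction and the in vivo FFCA model parameter (the
fraction of the central-lung dose in the MCC-competent sub-compartment) are
deliberately kept as distinct quantities; the package never equates them
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "FFCAResult",
    "FFCAEstimator",
    "pixel_change_map",
    "baseline_threshold",
    "ffca_fraction",
    "as_grayscale_stack",
]

# ITU-R BT.601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def as_grayscale_stack(stack) -> np.ndarray:
    """Validate a stack and reduce color frames to luminance.

    Accepts ``(F, H, W)`` grayscale or ``(F, H, W, 3)``/``(F, H, W, 4)``
    color arrays (alpha ignored); returns float64 ``(F, H, W)``.
    """
    a = np.asarray(stack)
    if a.ndim == 4 and a.shape[-1] in (3, 4):
        a = a[..., :3].astype(float) @ _LUMA
    if a.ndim != 3:
        raise ValueError(f"expected a (frames, H, W) stack, got shape {a.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 frames to measure intensity change")
    return a.astype(float)


@dataclass(frozen=True)
class FFCAResult:
    """Change map, threshold and the derived functional-area fraction."""

    change_map: np.ndarray
    threshold: float
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def pixel_change_map(stack) -> np.ndarray:
    """Mean absolute successive-frame intensity change per pixel.

    ``m(p) = mean_f |I_{f+1}(p) - I_f(p)|`` over the F-1 frame pairs,
    computed in float to avoid unsigned-integer wraparound.
    """
    a = as_grayscale_stack(stack)
    return np.abs(np.diff(a, axis=0)).mean(axis=0)


def baseline_threshold(control_stacks) -> float:
    """Grand mean pixel change over untreated control stacks.

    All pixels of all control change maps are pooled; the mean is the
    baseline above which a pixel is called functionally ciliated.
    """
    stacks = list(control_stacks)
    if not stacks:
        raise ValueError("need at least one control stack")
    total, n = 0.0, 0
    for s in stacks:
        m = pixel_change_map(s)
        total += float(m.sum())
        n += m.size
    return total / n


def mean_of_means_threshold(control_stacks) -> float:
    """Per-culture-mean alternative baseline (mean of per-stack means)."""
    stacks = list(control_stacks)
    if not stacks:
        raise ValueError("need at least one control stack")
    return float(np.mean([pixel_change_map(s).mean() for s in stacks]))


def ffca_fraction(stack, threshold: float, mean_subtract: bool = False) -> FFCAResult:
    """Fraction of pixels whose mean intensity change exceeds the baseline.

    The comparison is strictly greater-than (ties count as non-functional).
    ``mean_subtract`` removes each frame's spatial mean first, a crude guard
    against global illumination drift.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    a = as_grayscale_stack(stack)
    if mean_subtract:
        a = a - a.mean(axis=(1, 2), keepdims=True)
    m = np.abs(np.diff(a, axis=0)).mean(axis=0)
    fraction = float(np.count_nonzero(m > threshold)) / m.size
    return FFCAResult(change_map=m, threshold=float(threshold), fraction=fraction)


class FFCAEstimator(BaseEstimator):
    """Functional-ciliated-area assay as a scikit-learn estimator.

    ``fit`` learns the baseline threshold from untreated control stacks;
    ``predict`` returns the functional fraction for each test stack.

    Parameters
    ----------
    baseline : {"grand_pixel_mean", "mean_of_means"}
        Pool all control pixels (default) or average per-culture means.
    mean_subtract : bool
        Per-frame spatial-mean subtraction before differencing.

    Attributes
    ----------
    threshold_ : float
        Baseline mean intensity change learned from the controls.
    """

    def __init__(self, baseline: str = "grand_pixel_mean", mean_subtract: bool = False):
        self.baseline = baseline
        self.mean_subtract = mean_subtract

    def fit(self, X, y=None):
        """Learn the baseline threshold from a list of control stacks."""
        if self.baseline == "grand_pixel_mean":
            self.threshold_ = baseline_threshold(X)
        elif self.baseline == "mean_of_means":
            self.threshold_ = mean_of_means_threshold(X)
        else:
            raise ValueError(f"unknown baseline rule {self.baseline!r}")
        return self

    def transform(self, X) -> list[FFCAResult]:
        """Full :class:`FFCAResult` (change map included) per stack."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return [
            ffca_fraction(s, self.threshold_, mean_subtract=self.mean_subtract)
            for s in X
        ]

    def predict(self, X) -> np.ndarray:
        """Functional-area fraction for each stack in ``X``."""
        return np.array([r.fraction for r in self.transform(X)])
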