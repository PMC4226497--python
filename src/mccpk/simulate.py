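"""Synthetic dual-probe scan datasets and ciliary-motion image stacks.

Every pipeline stage is testable without clinical data: the scan generator
emulates an 80-frame, 1-minute dynamic scintigraphy study of two
co-deposited probes (a pure-MCC particle and an absorbable small molecule)
with a central/peripheral deposition split, Poisson counting noise and
log-normal inter-subject parameter variability; the image generator emulates
10-frame phase-contrast stacks of epithelial cultures in which ciliated
regions flicker frame to frame while the rest is static sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compartment_model import DepositionState, ModelParameters, retention_curve

__all__ = [
    "ScanSimConfig",
    "GROUP_PARAMETERS",
    "GROUP_SIZES",
    "simulate_scan_dataset",
    "simulate_image_stack",
]

# Study-group kinetic parameters, per minute. k_lt and k_db follow the
# clinical estimates for non-CF adults (NCF), CF adults on isotonic or 7%
# hypertonic saline (CF_IS / CF_HS), and pediatric CF (CF_Ped). k_lb tracks
# k_db in the untreated groups and is insensitive to hypertonic saline;
# FFCA is high in non-CF airways, depressed in CF and partially restored by
# hypertonic saline.
GROUP_PARAMETERS: dict[str, ModelParameters] = {
    "NCF": ModelParameters(k_lt=0.0450, ffca=0.70, k_lb=0.0071, k_db=0.0071),
    "CF_HS": ModelParameters(k_lt=0.0393, ffca=0.60, k_lb=0.0181, k_db=0.0105),
    "CF_IS": ModelParameters(k_lt=0.0349, ffca=0.35, k_lb=0.0181, k_db=0.0181),
    "CF_Ped": ModelParameters(k_lt=0.0481, ffca=0.40, k_lb=0.0157, k_db=0.0157),
}

# Subjects per imaging group in the clinical study design.
GROUP_SIZES: dict[str, int] = {"NCF": 9, "CF_HS": 11, "CF_IS": 12, "CF_Ped": 9}


@dataclass(frozen=True)
class ScanSimConfig:
    """Configuration for one simulated study group.

    ``params`` are the group-mean kinetics (the small-molecule probe's
    parameter set; the particle probe uses the same MCC kinetics with
    absorption off). ``inter_subject_cv`` applies log-normal multiplicative
    variability to the rate constants and logit-normal variability to FFCA.
    ``noise`` is one of ``poisson``, ``gaussian`` or ``none``.
    """

    params: ModelParameters
    group: str = "NCF"
    n_subjects: int = 9
    frames: int = 80
    frame_interval: float = 1.0
    c0_mean: float = 5e4
    p0_mean: float = 5e4
    inter_subject_cv: float = 0.2
    noise: str = "poisson"
    gaussian_sd: float = 0.0
    tracheal_fraction: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.inter_subject_cv < 0:
            raise ValueError("inter_subject_cv must be >= 0")
        if self.c0_mean <= 0 or self.p0_mean <= 0:
            raise ValueError("deposition count means must be positive")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @classmethod
    def for_group(cls, group: str, **overrides) -> "ScanSimConfig":
        """Study-condition config for a named clinical group."""
        if group not in GROUP_PARAMETERS:
            raise KeyError(f"unknown group {group!r}; known: {sorted(GROUP_PARAMETERS)}")
        kw = dict(
            params=GROUP_PARAMETERS[group],
            group=group,
            n_subjects=GROUP_SIZES[group],
        )
        kw.update(overrides)
        return cls(**kw)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _draw_subject_params(
    rng: np.random.Generator, mean: ModelParameters, cv: float
) -> ModelParameters:
    if cv == 0:
        return mean
    rates = {
        name: getattr(mean, name) * _lognormal_factor(rng, cv)
        for name in ("k_lt", "k_lb", "k_db", "k_dl")
    }
    # logit-normal FFCA: delta-method sd on the logit scale reproducing the
    # requested CV of ffca near its mean
    f = mean.ffca
    if 0.0 < f < 1.0:
        sigma = cv / (1.0 - f)
        logit = np.log(f / (1.0 - f)) + rng.normal(0.0, sigma)
        f = 1.0 / (1.0 + np.exp(-logit))
    return ModelParameters(ffca=float(f), **{k: float(v) for k, v in rates.items()})


def simulate_scan_dataset(config: ScanSimConfig):
    """Simulate a dual-probe scan dataset with known ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` is a long-format
    DataFrame with columns ``subject_id, group, probe, frame, time_min,
    counts_whole_lung, counts_central`` and ``truth`` is a JSON-able dict
    holding the group-mean parameters and each subject's drawn parameters
    and deposition.

    Central counts are the central-ROI compartments (L_M + L_N); peripheral
    counts are the distal compartment D; whole-lung counts are their sum, so
    the nested-ROI convention (whole includes central) is preserved exactly.
    Poisson noise is applied to the central and peripheral expectations
    independently, per probe.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(config.frames, dtype=float) * config.frame_interval
    rows = []
    truth: dict = {
        "group": config.group,
        "params_mean": _params_dict(config.params),
        "subjects": {},
    }
    for i in range(config.n_subjects):
        sid = f"{config.group}_{i + 1:02d}"
        p_dtpa = _draw_subject_params(rng, config.params, config.inter_subject_cv)
        p_tc = p_dtpa.as_particle()
        c0 = float(config.c0_mean * _lognormal_factor(rng, config.inter_subject_cv))
        p0 = float(config.p0_mean * _lognormal_factor(rng, config.inter_subject_cv))
        dep = DepositionState(c0=c0, p0=p0, tracheal_fraction=config.tracheal_fraction)
        truth["subjects"][sid] = {
            "params": _params_dict(p_dtpa),
            "c0": c0,
            "p0": p0,
        }
        for probe, params in (("TCSC", p_tc), ("DTPA", p_dtpa)):
            central = retention_curve(params, dep, times, roi="central").values * c0
            whole = retention_curve(params, dep, times, roi="whole_lung").values * (c0 + p0)
            peripheral = whole - central
            if config.noise == "poisson":
                central = rng.poisson(central).astype(float)
                peripheral = rng.poisson(peripheral).astype(float)
            elif config.noise == "gaussian":
                central = central + rng.normal(0.0, config.gaussian_sd, central.shape)
                peripheral = peripheral + rng.normal(0.0, config.gaussian_sd, peripheral.shape)
                central = np.maximum(central, 0.0)
                peripheral = np.maximum(peripheral, 0.0)
            whole = central + peripheral
            for f in range(config.frames):
                rows.append(
                    (sid, config.group, probe, f, times[f], whole[f], central[f])
                )
    dataset = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "probe", "frame", "time_min",
            "counts_whole_lung", "counts_central",
        ],
    )
    return dataset, truth


def _params_dict(p: ModelParameters) -> dict:
    return {"k_lt": p.k_lt, "ffca": p.ffca, "k_lb": p.k_lb, "k_db": p.k_db, "k_dl": p.k_dl}


def simulate_image_stack(
    shape: tuple[int, int] = (128, 128),
    active_fraction: float = 0.3,
    flicker_amplitude: float = 25.0,
    noise_sd: float = 2.0,
    frames: int = 10,
    layout: str = "contiguous",
    baseline: float = 100.0,
    seed: int | None = None,
):
    """Simulate a phase-contrast stack with flickering (ciliated) regions.

    Active pixels alternate around the baseline with the given amplitude
    (emulating periodic ciliary beat seen as intensity flicker); every pixel
    additionally receives Gaussian sensor noise. ``layout`` is
    ``"contiguous"`` (a single block, like a ciliated patch) or
    ``"speckled"`` (independent random pixels). Returns ``(stack, mask)``
    with ``stack`` a ``(frames, H, W)`` float array and ``mask`` the binary
    ground-truth active map.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    if flicker_amplitude < 0:
        raise ValueError("flicker_amplitude must be >= 0")
    if frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    h, w = shape
    n_pix = h * w
    n_active = int(round(active_fraction * n_pix))
    mask = np.zeros(n_pix, dtype=bool)
    if layout == "contiguous":
        mask[:n_active] = True
    elif layout == "speckled":
        mask[rng.choice(n_pix, size=n_active, replace=False)] = True
    else:
        raise ValueError(f"layout must be 'contiguous' or 'speckled', got {layout!r}")
    mask = mask.reshape(h, w)
    stack = np.full((frames, h, w), baseline, dtype=float)
    flicker = np.where(np.arange(frames) % 2 == 0, 0.5, -0.5) * flicker_amplitude
    stack[:, mask] += flicker[:, None]
    stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack, mask
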