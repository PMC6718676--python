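"""Quantification of fluorescence lipid extraction, transport and binding assays.

The assays share a min-max calibration vocabulary:

* ``F0``   — signal before protein addition (baseline),
* ``Fmax`` — signal for complete transfer / fully bound reference,
* ``Fmin`` — buffer-only reference (binding assays).

From these the package computes

* extraction percentage     ``100·(1 − (F − F0)/(Fmax − F0))``,
* normalized transport      ``F_Norm = (F − F0)/(Fmax − F0)`` and the amount
  of ligand delivered, ``accessible_concentration · F_Norm`` (µM),
* bound percentage          ``100·(F − Fmin)/(Fmax − Fmin)``,
* initial transport rates   from an ordinary least-squares line through the
  first few normalized points after protein injection (defaults: 8 points
  spanning 4 s), converted to lipids·min⁻¹ per protein by
  ``slope · 60 / [protein]``.

The accessible ligand concentration is ``total_lipid × mole_fraction ×
accessible_fraction`` with ``accessible_fraction = 0.5`` by default (outer
leaflet of a large unilamellar vesicle): 200 µM lipids with 5% ligand give
5 µM accessible, 80 µM with 2% give 0.8 µM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "KineticTrace",
    "AssayConfig",
    "RateResult",
    "CalibrationWarning",
    "accessible_concentration",
    "extraction_percentage",
    "bound_percentage",
    "normalize_transport",
    "initial_rate",
    "fit_transfer_k",
    "normalize_dissociation",
]


class CalibrationWarning(UserWarning):
    """Signal fell outside the [calibration floor, ceiling] range."""


@dataclass
class KineticTrace:
    """Fluorescence time series with calibration anchors.

    ``time`` in s, ``F`` in arbitrary units.  ``t_inject`` marks the ligand /
    acceptor-liposome injection, ``t_protein`` the protein injection.
    """

    time: np.ndarray
    F: np.ndarray
    F0: float | None = None
    Fmax: float | None = None
    Fmin: float | None = None
    t_inject: float | None = None
    t_protein: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise ValueError("time and F must have the same length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"trace lacks calibration fields {missing}")


@dataclass
class AssayConfig:
    """Cuvette composition for converting normalized signal into µM lipid."""

    total_lipid: float = 200.0        # µM
    ligand_mole_fraction: float = 0.05
    accessible_fraction: float = 0.5  # outer leaflet of a LUV
    protein_conc: float = 0.2         # µM
    fit_points: int = 8
    fit_span: float = 4.0             # s

    def __post_init__(self) -> None:
        for name in ("ligand_mole_fraction", "accessible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.total_lipid < 0:
            raise ValueError("total_lipid must be >= 0")
        if self.fit_points < 2:
            raise ValueError("need at least two points for a rate fit")


@dataclass
class RateResult:
    """Outcome of a transport-trace normalization and/or rate fit."""

    f_norm: np.ndarray | None = None
    delivered: np.ndarray | None = None   # µM
    time: np.ndarray | None = None        # s
    initial_rate: float | None = None     # µM/s
    per_protein_rate: float | None = None  # lipids·min⁻¹·protein⁻¹
    slope_stderr: float | None = None
    r_squared: float | None = None
    clipped: bool = False
    extras: dict = field(default_factory=dict)


def accessible_concentration(config: AssayConfig) -> float:
    """Volume concentration (µM) of ligand in the accessible leaflet."""
    return (
        config.total_lipid
        * config.ligand_mole_fraction
        * config.accessible_fraction
    )


def _check_range(value, lo, hi, what):
    out = np.any(np.asarray(value) < lo) or np.any(np.asarray(value) > hi)
    if out:
        warnings.warn(
            f"{what} outside [{lo}, {hi}]: signal exceeds the calibration range",
            CalibrationWarning,
            stacklevel=3,
        )
    return bool(out)


def extraction_percentage(F, F0: float, Fmax: float):
    """Percent of accessible ligand removed: 100·(1 − (F − F0)/(Fmax − F0)).

    ``F = Fmax`` (probe fully membrane-bound) gives 0%; ``F = F0`` (signal
    back to the ligand-free reference) gives 100%.  Values outside [0, 100]
    are returned as-is with a :class:`CalibrationWarning`.
    """
    if Fmax == F0:
        raise ValueError("degenerate calibration: Fmax == F0")
    value = 100.0 * (1.0 - (np.asarray(F, dtype=float) - F0) / (Fmax - F0))
    _check_range(value, 0.0, 100.0, "extraction percentage")
    return value if value.ndim else float(value)


def bound_percentage(F, Fmin: float, Fmax: float):
    """Percent of protein bound to membrane: 100·(F − Fmin)/(Fmax − Fmin)."""
    if Fmax == Fmin:
        raise ValueError("degenerate calibration: Fmax == Fmin")
    value = 100.0 * (np.asarray(F, dtype=float) - Fmin) / (Fmax - Fmin)
    _check_range(value, 0.0, 100.0, "bound percentage")
    return value if value.ndim else float(value)


def normalize_transport(trace: KineticTrace, config: AssayConfig) -> RateResult:
    """Min-max normalize a transport trace and convert it to µM delivered.

    ``F_Norm(t) = (F − F0)/(Fmax − F0)``; delivered(t) is F_Norm scaled by
    the accessible ligand concentration (e.g. 5 µM for 200 µM lipids at 5%).
    """
    trace.require("F0", "Fmax")
    if trace.Fmax == trace.F0:
        raise ValueError("degenerate calibration: Fmax == F0")
    f_norm = (trace.F - trace.F0) / (trace.Fmax - trace.F0)
    clipped = _check_range(f_norm, 0.0, 1.0, "F_Norm")
    delivered = accessible_concentration(config) * f_norm
    return RateResult(
        f_norm=f_norm, delivered=delivered, time=trace.time, clipped=clipped
    )


def initial_rate(
    trace: KineticTrace,
    config: AssayConfig,
    t_protein: float | None = None,
) -> RateResult:
    """Initial transport rate from the first points after protein injection.

    An ordinary least-squares line (intercept free, to absorb injection
    artifacts) is fitted through the first ``config.fit_points`` delivered(t)
    samples strictly after ``t_protein``; they must span no more than
    ``config.fit_span`` seconds.  The slope is the initial rate in µM/s; the
    per-protein rate is ``slope × 60 / protein_conc`` in lipids·min⁻¹ per
    protein.
    """
    if t_protein is None:
        t_protein = trace.t_protein
    if t_protein is None:
        raise ValueError("no protein-injection time available")
    result = normalize_transport(trace, config)
    after = np.flatnonzero(trace.time > t_protein)
    if after.size < config.fit_points:
        raise ValueError(
            f"only {after.size} samples after injection; need {config.fit_points}"
        )
    idx = after[: config.fit_points]
    t = trace.time[idx]
    if t[-1] - t[0] > config.fit_span + 1e-9:
        raise ValueError(
            f"first {config.fit_points} samples span {t[-1] - t[0]:.3g} s, "
            f"more than fit_span = {config.fit_span} s"
        )
    y = result.delivered[idx]
    fit = linregress(t, y)
    result.initial_rate = float(fit.slope)
    result.per_protein_rate = float(fit.slope * 60.0 / config.protein_conc)
    result.slope_stderr = float(fit.stderr)
    result.r_squared = float(fit.rvalue**2)
    result.extras["fit_window"] = (float(t[0]), float(t[-1]))
    return result


def fit_transfer_k(
    trace: KineticTrace,
    t_inject: float | None = None,
) -> tuple[float, dict]:
    """Fit the single-exponential transfer model and return the rate constant.

    Model: ``F(t) = F0 + (Fmax − F0)(1 − exp(−k(t − t_inject)))`` for
    ``t ≥ t_inject`` with the trace's calibration anchors held fixed; the
    rate constant k (s⁻¹) is the only free parameter.  Returns ``(k, diag)``
    with the standard error and residual summary in ``diag``.
    """
    trace.require("F0", "Fmax")
    if t_inject is None:
        t_inject = trace.t_inject
    if t_inject is None:
        raise ValueError("no injection time available")
    mask = trace.time >= t_inject
    if mask.sum() < 3:
        raise ValueError("too few post-injection samples to fit")
    t = trace.time[mask] - t_inject
    y = trace.F[mask]
    F0, Fmax = trace.F0, trace.Fmax
    amp = Fmax - F0

    def model(t, k):
        return F0 + amp * (1.0 - np.exp(-np.clip(k, 0.0, None) * t))

    # crude initial guess from the half-rise time
    half = np.flatnonzero(y - F0 >= 0.5 * amp)
    k0 = np.log(2.0) / t[half[0]] if half.size and t[half[0]] > 0 else 1.0 / t[-1]
    try:
        popt, pcov = curve_fit(model, t, y, p0=[max(k0, 1e-6)], maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    k = float(max(popt[0], 0.0))
    resid = y - model(t, k)
    diag = {
        "stderr": float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan,
        "rss": float((resid**2).sum()),
        "n": int(mask.sum()),
    }
    return k, diag


def normalize_dissociation(trace: KineticTrace) -> np.ndarray:
    """Min-max normalize a dissociation trace to [0, 1] over its own range.

    Used for real-time membrane-release traces where only the relative decay
    matters; the extrema of the recorded signal serve as the anchors.
    """
    lo, hi = float(trace.F.min()), float(trace.F.max())
    if hi == lo:
        raise ValueError("flat trace cannot be min-max normalized")
    return (trace.F - lo) / (hi - lo)
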