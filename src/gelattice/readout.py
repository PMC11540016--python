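"""Gel CBCT readout: adaptive filtering, remnant-artifact removal, tanh
dose-response calibration and inversion to dose.

The dose response of the polymer gel is modelled as

    dN = alpha + beta * tanh(gamma * D - phi)

where ``dN`` is the change in CBCT number between averaged post- and
pre-irradiation scans and ``D`` the dose in Gy. The curve is fitted
pixel-by-pixel on a self-calibration slice spanning the full dose range,
then inverted over the whole volume.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .volumes import Quantity, ScalarVolume

__all__ = [
    "CalibrationCurve",
    "FilterConfig",
    "FitError",
    "tanh_response",
    "adaptive_mean_filter",
    "remove_remnant_artifacts",
    "fit_calibration",
    "apply_calibration",
]

_PARAM_NAMES = ("alpha", "beta", "gamma_", "phi")


class FitError(RuntimeError):
    """Calibration fit failed or the design is degenerate."""


@dataclass
class CalibrationCurve:
    """Fitted tanh dose-response curve and its diagnostics.

    ``alpha`` (CBCT-number offset), ``beta`` (amplitude, > 0), ``gamma_``
    (rate, 1/Gy, > 0), ``phi`` (dimensionless shift). The forward curve is
    strictly increasing in dose because beta and gamma_ are positive.
    """

    alpha: float
    beta: float
    gamma_: float
    phi: float
    param_cov: Optional[np.ndarray] = None
    rmse: Optional[float] = None
    dose_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma_ <= 0:
            raise ValueError("gamma_ must be > 0")
        if self.rmse is not None and self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.param_cov is not None:
            self.param_cov = np.asarray(self.param_cov, dtype=float).reshape(4, 4)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma_, self.phi])

    def forward(self, dose: np.ndarray | float) -> np.ndarray | float:
        return tanh_response(dose, self)

    def inverse(self, delta: np.ndarray | float, eps: float = 1e-6) -> np.ndarray:
        """Dose from CBCT-number change; saturated values are clamped into
        the invertible band and negative doses clamped to zero."""
        t = np.clip((np.asarray(delta, dtype=float) - self.alpha) / self.beta, -1 + eps, 1 - eps)
        dose = (np.arctanh(t) + self.phi) / self.gamma_
        return np.clip(dose, 0.0, None)

    def ci95(self) -> dict[str, tuple[float, float]]:
        """95% confidence intervals from the parameter covariance."""
        if self.param_cov is None:
            raise ValueError("curve carries no covariance (not fitted)")
        se = np.sqrt(np.diag(self.param_cov))
        out = {}
        for name, value, s in zip(_PARAM_NAMES, self.params, se):
            out[name] = (value - 1.96 * s, value + 1.96 * s)
        return out

    # ------------------------------------------------------------- persist

    def to_json(self, path: str, extra: Optional[dict] = None) -> None:
        payload = {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma_": self.gamma_,
            "phi": self.phi,
            "rmse": self.rmse,
            "dose_range_Gy": None if self.dose_range is None else list(self.dose_range),
            "param_cov": None if self.param_cov is None else self.param_cov.tolist(),
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "CalibrationCurve":
        with open(path) as fh:
            payload = json.load(fh)
        cov = payload.get("param_cov")
        rng = payload.get("dose_range_Gy")
        return cls(
            alpha=float(payload["alpha"]),
            beta=float(payload["beta"]),
            gamma_=float(payload["gamma_"]),
            phi=float(payload["phi"]),
            param_cov=None if cov is None else np.asarray(cov, dtype=float),
            rmse=payload.get("rmse"),
            dose_range=None if rng is None else (float(rng[0]), float(rng[1])),
        )


def tanh_response(dose: np.ndarray | float, curve: CalibrationCurve) -> np.ndarray | float:
    """Forward dose-response: ``alpha + beta * tanh(gamma * D - phi)``."""
    return curve.alpha + curve.beta * np.tanh(curve.gamma_ * np.asarray(dose, dtype=float) - curve.phi)


@dataclass(frozen=True)
class FilterConfig:
    """Noise/artefact reduction parameters (in-plane, per axial slice)."""

    mean_window: int = 3
    artefact_span: int = 7
    baseline_span: Optional[int] = None  # radial trend-protection window

    def __post_init__(self) -> None:
        for name in ("mean_window", "artefact_span"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.baseline_span is not None and (
            self.baseline_span < 1 or self.baseline_span % 2 == 0
        ):
            raise ValueError("baseline_span must be odd and >= 1 when given")


def _require_delta(vol: ScalarVolume, op: str) -> None:
    if vol.quantity is not Quantity.DELTA_CBCT:
        raise ValueError(f"{op} expects a delta_cbct volume, got {vol.quantity.value}")


def adaptive_mean_filter(vol: ScalarVolume, window: int = 3) -> ScalarVolume:
    """Local-statistics adaptive (Wiener-type) mean filter, per axial slice.

    ``out = mu + max(var - nu2, 0) / max(var, nu2) * (x - mu)`` with ``mu``,
    ``var`` the local window mean/variance and ``nu2`` the slice-wide mean
    of the local variances: flat regions collapse to the local mean, strong
    edges (high local variance) pass through nearly unchanged.
    """
    _require_delta(vol, "adaptive_mean_filter")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = np.empty_like(vol.values)
    for k in range(vol.geometry.dims[2]):
        x = vol.values[:, :, k]
        mu = ndimage.uniform_filter(x, size=window, mode="nearest")
        var = ndimage.uniform_filter(x * x, size=window, mode="nearest") - mu * mu
        np.clip(var, 0.0, None, out=var)
        nu2 = float(var.mean())
        gain = np.maximum(var - nu2, 0.0) / np.maximum(var, max(nu2, 1e-300))
        out[:, :, k] = mu + gain * (x - mu)
    return vol.copy_with(out)


def _moving_mean(profile: np.ndarray, span: int) -> np.ndarray:
    """Centered moving mean with edge-value padding."""
    if span <= 1:
        return profile.copy()
    half = span // 2
    padded = np.pad(profile, half, mode="edge")
    kernel = np.ones(span) / span
    return np.convolve(padded, kernel, mode="valid")


def remove_remnant_artifacts(
    vol: ScalarVolume,
    span: int = 7,
    axis_center: tuple[float, float] = (0.0, 0.0),
    region: Optional[np.ndarray] = None,
    baseline_span: Optional[int] = None,
    exclude_model: Optional[np.ndarray] = None,
) -> ScalarVolume:
    """Subtract the azimuthally symmetric remnant (ring/cupping residual
    surviving background subtraction), per axial slice.

    The remnant is estimated as the angular median of the slice in polar
    coordinates about ``axis_center``, radially smoothed with a centered
    moving mean of ``span`` samples; the mean of the subtracted remnant
    over the slice is removed so the slice mean is preserved. Robustness
    extensions: pixels more than 4 robust standard deviations above the
    slice median (vertex peaks) are excluded from the estimate, and an
    optional wide ``baseline_span`` moving mean is subtracted from the
    remnant so that broad radial structure — including a cylindrical
    phantom's genuine azimuthally symmetric dose trend — is left in place
    and only ring-scale artifacts are removed. ``region`` restricts both
    estimation and correction (e.g. to the gel body).

    When a cylindrical phantom's dose distribution is itself nearly
    azimuthally symmetric, the angular median cannot distinguish dose from
    artifact at any radial scale. ``exclude_model`` (an expected-signal
    field, e.g. the forward-calibrated plan dose from a first-pass fit) is
    subtracted before the remnant is estimated and the correction is
    derived from the residual, so only structure unexplained by the model
    is treated as artifact.
    """
    _require_delta(vol, "remove_remnant_artifacts")
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span}")
    if baseline_span is not None and (baseline_span < 1 or baseline_span % 2 == 0):
        raise ValueError(f"baseline_span must be odd and >= 1, got {baseline_span}")
    geom = vol.geometry
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != tuple(geom.dims):
            raise ValueError("region shape must match the volume")
    if exclude_model is not None:
        exclude_model = np.asarray(exclude_model, dtype=float)
        if exclude_model.shape != tuple(geom.dims):
            raise ValueError("exclude_model shape must match the volume")
    xs = geom.axis_coords(0)[:, None] - axis_center[0]
    ys = geom.axis_coords(1)[None, :] - axis_center[1]
    r_pix = np.sqrt(xs**2 + ys**2)
    bin_width = min(geom.spacing[0], geom.spacing[1])
    bin_idx = np.rint(r_pix / bin_width).astype(int)
    n_bins = int(bin_idx.max()) + 1
    if span > n_bins:
        raise ValueError(f"span ({span}) exceeds the radial sample count ({n_bins})")
    bin_r = bin_width * np.arange(n_bins)

    out = vol.values.copy()
    work = vol.values if exclude_model is None else vol.values - exclude_model
    for k in range(geom.dims[2]):
        x = work[:, :, k]
        sel = np.ones_like(x, dtype=bool) if region is None else region[:, :, k]
        if sel.sum() < 16:
            continue
        med = float(np.median(x[sel]))
        sigma = 1.4826 * float(np.median(np.abs(x[sel] - med)))
        include = sel & (x <= med + 4.0 * max(sigma, 1e-12))
        if include.sum() < 16:
            include = sel
        # angular median per radial bin
        profile = np.full(n_bins, np.nan)
        flat_bins = bin_idx[include]
        flat_vals = x[include]
        order = np.argsort(flat_bins, kind="stable")
        flat_bins = flat_bins[order]
        flat_vals = flat_vals[order]
        starts = np.searchsorted(flat_bins, np.arange(n_bins))
        stops = np.searchsorted(flat_bins, np.arange(n_bins), side="right")
        for b in range(n_bins):
            if stops[b] > starts[b]:
                profile[b] = np.median(flat_vals[starts[b]:stops[b]])
        valid = np.isfinite(profile)
        if valid.sum() < 2:
            continue
        profile = np.interp(bin_r, bin_r[valid], profile[valid])
        remnant = _moving_mean(profile, span)
        if baseline_span is not None:
            remnant = remnant - _moving_mean(remnant, baseline_span)
        correction = np.interp(r_pix, bin_r, remnant)
        correction = correction - correction[sel].mean()
        out[:, :, k][sel] = vol.values[:, :, k][sel] - correction[sel]
    return vol.copy_with(out)


def _tanh_model(dose: np.ndarray, alpha: float, beta: float, gamma_: float, phi: float) -> np.ndarray:
    return alpha + beta * np.tanh(gamma_ * dose - phi)


def fit_calibration(
    delta_slice: np.ndarray,
    dose_slice: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> CalibrationCurve:
    """Pixel-by-pixel nonlinear least squares of the tanh dose response.

    Fits ``dN = alpha + beta * tanh(gamma * D - phi)`` over all (D, dN)
    pixel pairs of a self-calibration slice (optionally restricted by an
    in-slice mask). The slice should span low-to-high doses; a dose span
    below 50% of the maximum dose triggers a conditioning warning. Returns
    the curve with parameter covariance and residual RMSE.
    """
    delta = np.asarray(delta_slice, dtype=float)
    dose = np.asarray(dose_slice, dtype=float)
    if delta.shape != dose.shape:
        raise ValueError(f"slice shapes differ: {delta.shape} vs {dose.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != delta.shape:
            raise ValueError("mask shape must match the slices")
        delta = delta[mask]
        dose = dose[mask]
    delta = delta.ravel()
    dose = dose.ravel()
    if delta.size < 8:
        raise FitError(f"too few pixels to fit 4 parameters ({delta.size})")
    d_min, d_max = float(dose.min()), float(dose.max())
    span = d_max - d_min
    if span <= 0 or d_max <= 0:
        raise FitError("degenerate design: dose slice has no dose range")
    if span < 0.5 * d_max:
        warnings.warn(
            f"calibration dose span ({span:.1f} Gy) is below 50% of the maximum "
            f"dose ({d_max:.1f} Gy); the fit may be poorly conditioned",
            stacklevel=2,
        )
    low = dose <= d_min + 0.1 * span
    alpha0 = float(np.median(delta[low])) if low.any() else float(np.median(delta))
    beta0 = max(float(np.ptp(delta)) / 2.0, 1e-6)
    gamma0 = 2.0 / span
    phi0 = gamma0 * (d_min + span / 2.0)
    try:
        popt, pcov = optimize.curve_fit(
            _tanh_model,
            dose,
            delta,
            p0=(alpha0, beta0, gamma0, phi0),
            bounds=([-np.inf, 1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(
            f"calibration fit did not converge (n={delta.size}, dose range "
            f"[{d_min:.2f}, {d_max:.2f}] Gy): {exc}"
        ) from exc
    resid = delta - _tanh_model(dose, *popt)
    return CalibrationCurve(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        gamma_=float(popt[2]),
        phi=float(popt[3]),
        param_cov=pcov,
        rmse=float(np.sqrt(np.mean(resid**2))),
        dose_range=(d_min, d_max),
    )


def apply_calibration(
    vol: ScalarVolume,
    curve: CalibrationCurve,
    eps: float = 1e-6,
    return_stats: bool = False,
):
    """Invert the calibration curve over a delta-CBCT volume to dose (Gy).

    Values outside the invertible band ``(alpha - beta, alpha + beta)`` are
    clamped ``eps`` inside it and negative doses clamped to zero; when the
    curve carries its fitted ``dose_range``, saturating responses clamp to
    the upper end of that range (doses beyond the calibrated range are not
    measurable). The fractions of affected voxels are reported in the
    optional stats dict.
    """
    _require_delta(vol, "apply_calibration")
    t = (vol.values - curve.alpha) / curve.beta
    saturated = np.mean((t <= -1 + eps) | (t >= 1 - eps))
    dose_raw = (np.arctanh(np.clip(t, -1 + eps, 1 - eps)) + curve.phi) / curve.gamma_
    negative = np.mean(dose_raw < 0)
    upper = curve.dose_range[1] if curve.dose_range is not None else None
    dose = ScalarVolume(vol.geometry, np.clip(dose_raw, 0.0, upper), Quantity.DOSE_GY)
    if return_stats:
        return dose, {
            "saturated_fraction": float(saturated),
            "negative_clamped_fraction": float(negative),
        }
    return dose
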