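"""Von Bertalanffy growth fitting and the growth performance index Φ′.

The specialized von Bertalanffy growth function

    H(t) = H∞ · (1 − e^(−k·(t − t0)))

describes saturating shell height (mm) at age t (yr) with asymptotic height
H∞ (mm), Brody growth coefficient k (yr⁻¹) and theoretical age at zero height
t0 (yr).  The overall growth performance index

    Φ′ = log10(k) + 2·log10(0.1·H∞)

is the growth rate at the curve's inflexion point and is the standard
cross-population comparator for pectinids (k in yr⁻¹, H∞ in mm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import vb_height

__all__ = ["VBFit", "VBFitError", "fit_von_bertalanffy", "compute_phi_prime"]


class VBFitError(RuntimeError):
    """Nonlinear fit failed after the documented restarts."""


@dataclass(frozen=True)
class VBFit:
    """Fitted von Bertalanffy parameters with asymptotic 95% CIs."""

    h_inf_mm: float
    h_inf_ci: tuple[float, float]
    k_per_yr: float
    k_ci: tuple[float, float]
    t0_yr: float
    t0_ci: tuple[float, float]
    r2: float
    n: int
    ssr: float
    phi_prime: float

    def as_dict(self) -> dict:
        return {
            "h_inf": self.h_inf_mm,
            "h_inf_lo": self.h_inf_ci[0],
            "h_inf_hi": self.h_inf_ci[1],
            "k": self.k_per_yr,
            "k_lo": self.k_ci[0],
            "k_hi": self.k_ci[1],
            "t0": self.t0_yr,
            "t0_lo": self.t0_ci[0],
            "t0_hi": self.t0_ci[1],
            "r2": self.r2,
            "n": self.n,
            "phi_prime": self.phi_prime,
        }


def compute_phi_prime(k_per_yr: float, h_inf_mm: float) -> float:
    """Growth performance index Φ′ = log10(k) + 2·log10(0.1·H∞).

    Base-10 logarithms; the value is returned unrounded (round to 2 decimals
    only when reporting).
    """
    if k_per_yr <= 0 or h_inf_mm <= 0:
        raise ValueError("k and H∞ must be positive")
    return math.log10(k_per_yr) + 2.0 * math.log10(0.1 * h_inf_mm)


def fit_von_bertalanffy(
    ages,
    heights=None,
    n_restarts: int = 5,
    restart_seed: int = 0,
) -> VBFit:
    """Least-squares von Bertalanffy fit via Levenberg–Marquardt.

    Accepts either parallel ``ages``/``heights`` sequences or a single
    sequence of ``(age, height)`` pairs.  Starting values are
    ``H∞ = 1.1·max(height), k = 0.3 yr⁻¹, t0 = 0``; on non-convergence up to
    ``n_restarts`` deterministically jittered restarts are attempted, so the
    fit is reproducible for given data.  95% CIs are asymptotic (Wald),
    Student-t based on the residual degrees of freedom.

    Raises
    ------
    VBFitError
        If no restart converges, or the converged solution is degenerate
        (non-finite covariance with non-informative data).
    ValueError
        Fewer than 4 distinct ages, or negative heights.
    """
    if heights is None:
        pairs = np.asarray(ages, dtype=float)
        t, h = pairs[:, 0], pairs[:, 1]
    else:
        t = np.asarray(ages, dtype=float)
        h = np.asarray(heights, dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct ages for a 3-parameter fit")
    if np.any(h < 0):
        raise ValueError("heights must be non-negative")

    p0 = np.array([1.1 * float(h.max() or 1.0), 0.3, 0.0])
    rng = np.random.default_rng(restart_seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, size=3) + (
            0.0,
            0.0,
            rng.normal(0.0, 0.2),
        )
        try:
            with warnings.catch_warnings():
                # an inestimable covariance means no usable CIs: treat as failure
                warnings.simplefilter("error", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    vb_height, t, h, p0=start, method="lm", maxfev=20000
                )
        except (RuntimeError, optimize.OptimizeWarning) as err:  # no convergence
            last_err = err
            continue
        if popt[0] <= 0 or popt[1] <= 0:
            last_err = VBFitError(f"non-physical optimum {popt}")
            continue
        # a curve already saturated before the first observed age fits any
        # constant-height dataset perfectly; k is then unidentified
        if math.exp(-popt[1] * (float(t.min()) - popt[2])) < 1e-6:
            raise VBFitError(
                "degenerate fit: heights carry no rising limb, growth rate unidentifiable"
            )
        return _package_fit(t, h, popt, pcov)
    raise VBFitError(f"von Bertalanffy fit failed after restarts: {last_err}")


def _package_fit(t: np.ndarray, h: np.ndarray, popt, pcov) -> VBFit:
    n = t.size
    resid = h - vb_height(t, *popt)
    ssr = float(resid @ resid)
    sst = float(((h - h.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    dfe = max(n - 3, 1)
    se = np.sqrt(np.diag(pcov))
    tcrit = stats.t.ppf(0.975, dfe)
    cis = [(float(p - tcrit * s), float(p + tcrit * s)) for p, s in zip(popt, se)]
    return VBFit(
        h_inf_mm=float(popt[0]),
        h_inf_ci=cis[0],
        k_per_yr=float(popt[1]),
        k_ci=cis[1],
        t0_yr=float(popt[2]),
        t0_ci=cis[2],
        r2=r2,
        n=int(n),
        ssr=ssr,
        phi_prime=compute_phi_prime(float(popt[1]), float(popt[0])),
    )
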