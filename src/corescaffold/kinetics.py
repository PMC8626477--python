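"""Absorbance-to-rate conversion and Michaelis–Menten fitting.

Product concentrations come from the Lambert–Beer law, c = A/(ε·l), with
the formazan extinction coefficient ε = 3.07 × 10⁴ L mol⁻¹ cm⁻¹ as the
default. Initial rates versus substrate are fitted to the hyperbola
v = V_max·S/(K_M + S) by nonlinear least squares, with standard errors
from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticsConfig",
    "MMFit",
    "absorbance_to_concentration",
    "fit_michaelis_menten",
    "fit_michaelis_menten_table",
]


@dataclass
class KineticsConfig:
    """Lambert–Beer parameters: ε (L mol⁻¹ cm⁻¹) and path length l (cm)."""

    extinction: float = 3.07e4
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if self.extinction <= 0 or self.path_length <= 0:
            raise ValueError("extinction coefficient and path length must be > 0")


@dataclass
class MMFit:
    km: float          # µM
    vmax: float        # caller's rate units
    km_se: float
    vmax_se: float
    rss: float
    n_points: int

    def rate_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


def absorbance_to_concentration(absorbance, cfg: KineticsConfig = KineticsConfig()):
    """Lambert–Beer: concentration (mol L⁻¹) = A / (ε·l)."""
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be non-negative")
    out = a / (cfg.extinction * cfg.path_length)
    return float(out) if out.ndim == 0 else out


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def _initial_guess(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_o, v_o = s[order], v[order]
    km0 = float(np.interp(half, v_o, s_o)) if v_o.max() > half > v_o.min() \
        else float(np.median(s_o))
    return max(vmax0, 1e-12), max(km0, 1e-9)


def fit_michaelis_menten(substrate: Sequence[float], rate: Sequence[float],
                         weights: Optional[Sequence[float]] = None) -> MMFit:
    """Nonlinear least-squares fit of v = V_max·S/(K_M + S).

    ``substrate`` in µM, ``rate`` in arbitrary rate units; optional
    per-point weights are applied as 1/weight standard deviations. Initial
    guesses: V_max = max(v), K_M = S at half-max (interpolated)."""
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    if np.any(v < -np.finfo(float).eps * 100):
        # tiny negatives from noise are tolerated by the fit itself
        pass
    vmax0, km0 = _initial_guess(s, v)
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)
    try:
        popt, pcov = curve_fit(_mm, s, v, p0=[vmax0, km0], sigma=sigma,
                               absolute_sigma=False, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if km <= 0 or vmax <= 0:
        raise RuntimeError(f"fit produced non-positive parameters "
                           f"(Vmax={vmax:.4g}, Km={km:.4g})")
    resid = v - _mm(s, *popt)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan,) * 2
    return MMFit(km=float(km), vmax=float(vmax),
                 km_se=float(perr[1]), vmax_se=float(perr[0]),
                 rss=float((resid ** 2).sum()), n_points=len(s))


def fit_michaelis_menten_table(table: pd.DataFrame, mode: str = "means"
                               ) -> MMFit:
    """Fit a rate table with columns substrate_uM, rate, replicate.

    ``mode='means'`` fits the per-concentration replicate means (matching
    figures that show mean ± sd); ``mode='pooled'`` fits every replicate
    point."""
    if mode == "means":
        g = table.groupby("substrate_uM", as_index=False)["rate"].mean()
        return fit_michaelis_menten(g["substrate_uM"], g["rate"])
    if mode == "pooled":
        return fit_michaelis_menten(table["substrate_uM"], table["rate"])
    raise ValueError(f"unknown mode {mode!r}")
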