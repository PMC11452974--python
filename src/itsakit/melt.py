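"""CETSA melt curves: simulation, sigmoid fitting, Tm and delta-Tm.

A cellular thermal shift assay heats lysate aliquots over a temperature
ladder (the package default is the 10-point grid 37-67 degC) and
measures the soluble fraction of a protein at each point, normalized to
the lowest temperature.  The melting model is the descending
three-parameter logistic

    f(T) = (1 - plateau) / (1 + exp((T - tm) / slope)) + plateau

with tm the midpoint (melting temperature, degC), slope the transition
width (degC) and plateau the residual non-denatured fraction.  Because
measured curves are normalized to the first temperature, the fitted
model is f(T)/f(T_min), which recovers the generating parameters
exactly on noiseless data.  Ligand binding stabilizes the target:
delta-Tm = Tm(treated) - Tm(control) > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: The package's default CETSA temperature ladder (degC).
DEFAULT_TEMPERATURES = (37.0, 40.6, 43.7, 47.5, 51.2, 54.5, 57.9, 61.5, 64.0, 67.0)

#: Curves whose dynamic range is below this are flagged as non-melters.
NON_MELTER_RANGE = 0.2


@dataclass(frozen=True)
class MeltCurve:
    temperatures: tuple[float, ...]
    soluble_fraction: tuple[float, ...]
    condition: str = "control"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        f = np.asarray(self.soluble_fraction)
        if t.size != f.size or t.size < 5:
            raise ValueError("need >= 5 matched (temperature, fraction) points")
        if not (np.diff(t) > 0).all():
            raise ValueError("temperatures must be strictly increasing")
        if not math.isclose(f[0], 1.0, rel_tol=1e-6):
            raise ValueError("curve must be normalized to 1 at the lowest temperature")


@dataclass(frozen=True)
class MeltFit:
    tm: float | None          # degC; None for non-melters
    slope: float | None       # degC
    plateau: float | None     # residual soluble fraction
    rss: float
    converged: bool
    non_melter: bool


def logistic_melt(t: np.ndarray, tm: float, slope: float, plateau: float) -> np.ndarray:
    return (1.0 - plateau) / (1.0 + np.exp((t - tm) / slope)) + plateau


def simulate_melt(
    tm: float,
    slope: float,
    plateau: float,
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "control",
) -> MeltCurve:
    """Logistic curve plus additive Gaussian noise, renormalized to f(T_min)=1."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not 0 <= plateau < 1:
        raise ValueError("plateau must be in [0, 1)")
    t = np.asarray(temperatures, dtype=float)
    if not (np.diff(t) > 0).all():
        raise ValueError("temperatures must be strictly increasing")
    rng = np.random.default_rng(seed)
    f = logistic_melt(t, tm, slope, plateau)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    f = np.maximum(f, 1e-6)
    f = f / f[0]
    return MeltCurve(tuple(t.tolist()), tuple(f.tolist()), condition)


def fit_melt_curve(curve: MeltCurve, n_starts: int = 8) -> MeltFit:
    """Least-squares fit of the normalized logistic with a deterministic
    multi-start over an even tm grid spanning the temperature range.

    A curve whose empirical or fitted dynamic range (max - min fraction)
    falls below 0.2 is a non-melter: tm/slope/plateau are None and the
    caller should review it qualitatively.
    """
    t = np.asarray(curve.temperatures)
    y = np.asarray(curve.soluble_fraction)
    if t.size < 5:
        raise ValueError("need >= 5 points to fit")
    if y.max() - y.min() < NON_MELTER_RANGE:
        return MeltFit(None, None, None, float(np.sum((y - y.mean()) ** 2)), True, True)

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = logistic_melt(t, *theta)
        return model / model[0] - y

    lo = [t[0], 1e-3, 0.0]
    hi = [t[-1], 50.0, 1.0 - 1e-9]
    best = None
    for tm0 in t[0] + (t[-1] - t[0]) * _van_der_corput(n_starts):
        theta0 = np.clip([tm0, 2.0, max(1e-3, y.min())], lo, hi)
        res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    tm, slope, plateau = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    fitted = logistic_melt(t, tm, slope, plateau)
    fitted = fitted / fitted[0]
    if fitted.max() - fitted.min() < NON_MELTER_RANGE:
        return MeltFit(None, None, None, rss, bool(best.success), True)
    return MeltFit(tm, slope, plateau, rss, bool(best.success), False)


def _van_der_corput(n: int) -> np.ndarray:
    """First n points of the base-2 van der Corput sequence, prefixed by 0.5.

    Nested start grids make the multi-start fit monotone: the best
    residual over n+1 starts can never exceed the best over n.
    """
    out = []
    i = 1
    while len(out) < n:
        x, denom, k = 0.0, 2.0, i
        while k:
            x += (k % 2) / denom
            k //= 2
            denom *= 2
        out.append(x)
        i += 1
    return np.array(out)


def delta_tm(control_fit: MeltFit, treated_fit: MeltFit) -> float:
    """Tm(treated) - Tm(control), degC; positive means stabilization."""
    for name, fit in (("control", control_fit), ("treated", treated_fit)):
        if fit.non_melter or fit.tm is None:
            raise ValueError(
                f"{name} fit is a non-melter; review the curve qualitatively"
            )
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge")
    return treated_fit.tm - control_fit.tm
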