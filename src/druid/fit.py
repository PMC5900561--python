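"""Per-gene kinetic model fitting and half-life conversion.

Two models are fit by weighted nonlinear least squares:

* bounded growth, for approach-to-equilibrium labeling courses:
  ``N(t) = N0 * (1 - exp(-(lambda + gamma) * t))``, where ``gamma`` is the
  dilution due to cell growth, ``gamma = ln(2) / delta`` for doubling time
  ``delta`` (``gamma = 0`` for intron-normalized data, where no growth
  correction is applied);
* exponential decay, for transcription-shutoff courses:
  ``N(t) = N0 * exp(-lambda * t)``.

Half-life is ``ln(2) / lambda``. Genes whose optimization fails, lands on a
rate bound, or whose curve never approaches saturation are flagged
non-converged and carry no half-life — poorly normalized data produce
behavior the bounded-growth form cannot fit, and such genes are excluded
rather than reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LAMBDA_BOUNDS = (1e-5, 50.0)  # per hour
_EPS = 1e-8
_N_REWEIGHT = 2  # IRLS passes after the initial fit
_SATURATION_MIN = 0.05  # required (1 - exp(-k*t_max)) for a trusted fit
# saturation before the first measurement leaves no kinetic information
# (a constant series is "fit" perfectly by any sufficiently large rate)
_FIRST_POINT_SAT_MAX = 1.0 - 1e-4


def half_life(lam: float) -> float:
    """Half-life in hours from a decay constant (per hour): ln(2)/lambda."""
    if lam <= 0:
        raise ValueError(f"decay constant must be positive, got {lam}")
    return math.log(2) / lam


def growth_rate(delta: float) -> float:
    """Growth-dilution constant gamma = ln(2)/delta for doubling time delta (h)."""
    if delta <= 0:
        raise ValueError(f"doubling time must be positive, got {delta}")
    return math.log(2) / delta


@dataclass
class KineticParams:
    """Fitted parameters: plateau N0, decay constant lambda (per hour), and
    the growth-dilution constant gamma (per hour) the fit was run with."""

    n0: float
    lam: float
    gamma: float = 0.0


@dataclass
class FitResult:
    gene_id: str
    params: KineticParams
    converged: bool
    rss: float
    n_points: int

    @property
    def half_life(self) -> float:
        """ln(2)/lambda; NaN for non-converged genes."""
        if not self.converged:
            return float("nan")
        return half_life(self.params.lam)


def _weights(pred: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        return np.ones_like(pred)
    if scheme == "poisson":
        # Poisson-like variance stabilization: w = 1/max(yhat, eps)
        return 1.0 / np.maximum(pred, _EPS)
    raise ValueError(f"unknown weights scheme {scheme!r}")


def _fit_curve(
    t: np.ndarray,
    y: np.ndarray,
    model,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    weights_scheme: str,
) -> tuple[np.ndarray, float, bool]:
    """Weighted NLS with two reweighting passes; returns (params, wrss, ok)."""
    w = _weights(np.maximum(y, _EPS), weights_scheme)
    params = x0
    ok = True
    for _ in range(1 + _N_REWEIGHT):
        sw = np.sqrt(w)

        def resid(x):
            return sw * (y - model(t, x))

        res = least_squares(
            resid, params, bounds=(lower, upper), xtol=1e-12, ftol=1e-12,
            gtol=1e-12, max_nfev=500 * (len(params) + 1),
        )
        params = res.x
        ok = bool(res.success)
        if not ok:
            break
        w = _weights(model(t, params), weights_scheme)
    wrss = float(np.sum(_weights(model(t, params), weights_scheme) * (y - model(t, params)) ** 2))
    return params, wrss, ok


def _bounded_model(t: np.ndarray, x: np.ndarray, gamma: float) -> np.ndarray:
    n0, lam = x
    return n0 * (1.0 - np.exp(-(lam + gamma) * t))


def _init_bounded(t: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Deterministic initialization: N0 from the largest observation, lambda
    from a through-origin log-linear regression of the rise."""
    n0 = float(np.max(y))
    cap = 1.05 * n0
    mask = (y > 0) & (y < n0)
    lam = None
    if mask.sum() >= 2:
        z = -np.log1p(-np.minimum(y[mask] / cap, 1 - 1e-12))
        tt = t[mask]
        denom = float(np.sum(tt * tt))
        if denom > 0:
            k = float(np.sum(z * tt)) / denom
            lam = k - gamma
    if lam is None or not np.isfinite(lam) or lam <= 0:
        lam = math.log(2) / float(np.median(t))
    lam = float(np.clip(lam, LAMBDA_BOUNDS[0] * 10, LAMBDA_BOUNDS[1] / 10))
    return np.array([n0, lam])


def _at_bound(value: float, lo: float, hi: float) -> bool:
    return value <= lo * (1 + 1e-3) or value >= hi * (1 - 1e-3)


def fit_bounded_growth(
    time_points,
    values,
    gamma: float = 0.0,
    weights_scheme: str = "poisson",
    gene_id: str = "",
) -> FitResult:
    """Fit ``N0 * (1 - exp(-(lambda+gamma) t))`` to one gene's series.

    Points at ``t <= 0`` are excluded (no labeling measurement exists at
    t=0). Requires >=3 positive-time points. Never raises on an
    unfittable series — returns ``converged=False`` instead.
    """
    t = np.asarray(time_points, dtype=float)
    y = np.asarray(values, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    keep = t > 0
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("bounded-growth fit needs >=3 positive-time points")
    if np.max(y) <= 0:
        return FitResult(gene_id, KineticParams(0.0, float("nan"), gamma), False, float("nan"), len(t))

    x0 = _init_bounded(t, y, gamma)
    lower = np.array([np.max(y) * 1e-12, LAMBDA_BOUNDS[0]])
    upper = np.array([np.max(y) * 1e6, LAMBDA_BOUNDS[1]])
    model = lambda tt, x: _bounded_model(tt, x, gamma)
    params, wrss, ok = _fit_curve(t, y, model, x0, lower, upper, weights_scheme)
    n0, lam = float(params[0]), float(params[1])
    saturation = 1.0 - math.exp(-(lam + gamma) * float(np.max(t)))
    first_sat = 1.0 - math.exp(-(lam + gamma) * float(np.min(t)))
    converged = (
        ok
        and not _at_bound(lam, *LAMBDA_BOUNDS)
        and n0 > 0
        and _SATURATION_MIN <= saturation
        and first_sat <= _FIRST_POINT_SAT_MAX
    )
    return FitResult(gene_id, KineticParams(n0, lam, gamma), converged, wrss, len(t))


def fit_exponential_decay(
    time_points,
    values,
    weights_scheme: str = "poisson",
    gene_id: str = "",
) -> FitResult:
    """Fit ``N0 * exp(-lambda t)`` to one gene's shutoff series (t=0 included).

    Same convergence contract as :func:`fit_bounded_growth`.
    """
    t = np.asarray(time_points, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise ValueError("exponential-decay fit needs >=3 time points")
    if np.max(y) <= 0:
        return FitResult(gene_id, KineticParams(0.0, float("nan"), 0.0), False, float("nan"), len(t))

    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        lam0 = float(np.clip(-slope, LAMBDA_BOUNDS[0] * 10, LAMBDA_BOUNDS[1] / 10))
    else:
        lam0 = math.log(2) / float(np.median(t[t > 0])) if (t > 0).any() else 0.1
    x0 = np.array([float(np.max(y)), lam0])
    lower = np.array([np.max(y) * 1e-12, LAMBDA_BOUNDS[0]])
    upper = np.array([np.max(y) * 1e6, LAMBDA_BOUNDS[1]])
    model = lambda tt, x: x[0] * np.exp(-x[1] * tt)
    params, wrss, ok = _fit_curve(t, y, model, x0, lower, upper, weights_scheme)
    n0, lam = float(params[0]), float(params[1])
    converged = ok and not _at_bound(lam, *LAMBDA_BOUNDS) and n0 > 0
    return FitResult(gene_id, KineticParams(n0, lam, 0.0), converged, wrss, len(t))


def fit_table(
    series,
    gamma: float = 0.0,
    model: str = "bounded_growth",
    weights_scheme: str = "poisson",
) -> pd.DataFrame:
    """Fit every gene of a :class:`~druid.normalize.NormalizedSeries`.

    Returns a DataFrame indexed by gene_id with columns half_life_hours,
    lambda_per_hour, N0, gamma_per_hour, converged, rss, n_points.
    Non-converged genes carry NaN half-lives; drop them with
    ``table[table.converged]``.
    """
    t = series.time_points
    rows = []
    for gene_id, row in series.data.iterrows():
        y = row.to_numpy(dtype=float)
        if model == "bounded_growth":
            fr = fit_bounded_growth(t, y, gamma=gamma, weights_scheme=weights_scheme, gene_id=gene_id)
        elif model == "exponential_decay":
            fr = fit_exponential_decay(t, y, weights_scheme=weights_scheme, gene_id=gene_id)
        else:
            raise ValueError(f"unknown model {model!r}")
        rows.append(
            {
                "gene_id": gene_id,
                "half_life_hours": fr.half_life,
                "lambda_per_hour": fr.params.lam,
                "N0": fr.params.n0,
                "gamma_per_hour": fr.params.gamma,
                "converged": fr.converged,
                "rss": fr.rss,
                "n_points": fr.n_points,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def write_half_lives(table: pd.DataFrame, path: str | Path) -> None:
    """Write the half-life table as TSV (half-lives to 4 significant figures)."""
    out = table.copy()
    for col in ("half_life_hours", "lambda_per_hour", "N0"):
        out[col] = out[col].map(lambda v: float(f"{v:.4g}") if np.isfinite(v) else v)
    out.to_csv(path, sep="\t")


def read_half_lives(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
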