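"""Confusion functions and Gaussian tuning-precision fits.

The classifier's held-out class probabilities carry more information than
its argmax: if neural patterns of nearby walking directions are more
similar, probability mass should fall off smoothly with the angular
distance between a candidate class and the true class. Aligning each
example's six class probabilities by their signed circular offset from the
true class (-120, -60, 0, 60, 120, 180 degrees) and averaging over examples
yields the session's *confusion function*.

Tuning specificity is then summarized by fitting a discrete Gaussian

    g(x) = (1 / Z) * exp(-tau * x^2 / 2),

where x is the angular offset in degrees, tau the precision (inverse
variance, 1/sigma^2, in deg^-2) and Z normalizes g over the six offsets so
that the model, like the confusion function itself, sums to one. Large tau
means sharp, direction-specific patterns; tau = 0 is the flat
(fully dedifferentiated) limit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize_scalar

from ._circular import signed_circular_diff

#: canonical relative offsets for a 6 x 60-degree binning
OFFSETS = np.array([-120.0, -60.0, 0.0, 60.0, 120.0, 180.0])

#: search interval for the precision, deg^-2; the upper end is far beyond
#: the delta regime for 60-degree spacing (tau = 1 -> g(60)/g(0) ~ e^-1800)
TAU_BOUNDS = (0.0, 1.0)


@dataclasses.dataclass
class ConfusionFunction:
    """Mean class probability by relative angular offset."""

    offsets: np.ndarray
    mean_prob: np.ndarray
    n_examples: int

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.mean_prob = np.asarray(self.mean_prob, dtype=float)
        if self.offsets.shape != self.mean_prob.shape:
            raise ValueError("offsets and mean_prob must align")
        if np.any(self.mean_prob < -1e-12):
            raise ValueError("confusion probabilities must be nonnegative")


@dataclasses.dataclass
class GaussianFit:
    """Fitted discrete Gaussian tuning model."""

    tau: float  # precision, deg^-2
    Z: float  # normalization over the six offsets
    sse: float
    converged: bool
    free_z: bool = False


def confusion_function(prob, y_true, centers) -> ConfusionFunction:
    """Align class probabilities by offset from the true class and average.

    Parameters
    ----------
    prob : (n_examples, n_classes) array
        Held-out class probabilities, columns ordered as ``centers``.
    y_true : (n_examples,) array
        True bin-center labels.
    centers : (n_classes,) array
        Bin centers corresponding to the probability columns.
    """
    prob = np.asarray(prob, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if prob.ndim != 2 or prob.shape[1] != len(centers):
        raise ValueError("prob must be examples x classes")
    if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_off = len(centers)
    offsets = np.sort(signed_circular_diff(centers, centers[0]))
    acc = np.zeros(n_off)
    for i in range(len(y_true)):
        off = signed_circular_diff(centers, y_true[i])
        pos = np.searchsorted(offsets, off)
        acc[pos] += prob[i]
    mean_prob = acc / len(y_true)
    return ConfusionFunction(offsets, mean_prob, len(y_true))


def gaussian_model(x, tau: float, offsets=OFFSETS):
    """Discrete Gaussian g(x) = exp(-tau x^2 / 2) / Z, normalized over offsets."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    x = np.asarray(x, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    log_w = -0.5 * tau * offsets**2
    shift = log_w.max()  # overflow-safe for large tau (0 when 0 in offsets)
    Z = np.exp(log_w - shift).sum()
    g = np.exp(-0.5 * tau * x**2 - shift) / Z
    if np.ndim(x) == 0:
        return float(g)
    return g


def _model_z(tau: float, offsets) -> float:
    log_unnorm = -0.5 * tau * np.asarray(offsets, dtype=float) ** 2
    shift = log_unnorm.max()
    return float(np.exp(log_unnorm - shift).sum() * np.exp(shift))


def moment_tau_estimate(cf: ConfusionFunction) -> float:
    """Moment initializer: tau ~ 1 / Var_p(x) from the offset-weighted mass."""
    p = np.clip(cf.mean_prob, 0.0, None)
    p = p / p.sum()
    var = float(np.sum(p * cf.offsets**2))
    if var <= 0:
        return TAU_BOUNDS[1]
    return min(max(1.0 / var, TAU_BOUNDS[0]), TAU_BOUNDS[1])


def fit_tuning(cf: ConfusionFunction, free_z: bool = False) -> GaussianFit:
    """Least-squares fit of the Gaussian tuning model to a confusion function.

    Minimizes sum over the six offsets of (mean_prob - g(x; tau))^2 for
    tau in [0, 1] deg^-2. The default model has a single free parameter:
    Z is constrained to normalize g over the offsets, as the confusion
    function itself sums to one. ``free_z=True`` fits amplitude and
    precision jointly (sensitivity variant).

    The scalar search brackets the minimum on a log-spaced tau grid seeded
    by a moment estimate, then polishes with bounded Brent to ~1e-12.
    A fit pinned at the upper tau bound (a delta-like confusion function)
    is flagged ``converged=False``.
    """
    if np.any(cf.mean_prob < 0):
        raise ValueError("confusion function has negative entries")
    offsets = cf.offsets
    target = cf.mean_prob

    if free_z:

        def sse_of(tau):
            shape = np.exp(-0.5 * tau * offsets**2)
            denom = float(shape @ shape)
            amp = float(shape @ target) / denom if denom > 0 else 0.0
            return float(np.sum((target - amp * shape) ** 2)), amp

    else:

        def sse_of(tau):
            g = np.exp(-0.5 * tau * offsets**2)
            g = g / g.sum()
            return float(np.sum((target - g) ** 2)), None

    # coarse bracket: tau = 0 plus a log grid spanning the bounds
    grid = np.concatenate([[0.0], np.geomspace(1e-7, TAU_BOUNDS[1], 80)])
    guess = moment_tau_estimate(cf)
    grid = np.sort(np.concatenate([grid, [guess]]))
    sse_grid = np.array([sse_of(t)[0] for t in grid])
    best = int(np.argmin(sse_grid))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        tau_hat = lo
    else:
        res = minimize_scalar(
            lambda t: sse_of(t)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-13},
        )
        tau_hat = float(res.x)
        if sse_of(lo)[0] < sse_of(tau_hat)[0]:
            tau_hat = lo
        if sse_of(hi)[0] < sse_of(tau_hat)[0]:
            tau_hat = hi
    sse, amp = sse_of(tau_hat)
    # delta-regime degeneracy: beyond ~0.01 deg^-2 all taus fit a one-hot
    # confusion function equally well; snap to the bound and flag
    if sse_of(TAU_BOUNDS[1])[0] <= sse + 1e-20:
        tau_hat = TAU_BOUNDS[1]
        sse, amp = sse_of(tau_hat)
    at_bound = tau_hat >= TAU_BOUNDS[1] * (1.0 - 1e-9)
    if free_z:
        Z = 1.0 / amp if amp and amp > 0 else float("inf")
    else:
        Z = _model_z(tau_hat, offsets)
    return GaussianFit(tau_hat, Z, sse, converged=not at_bound, free_z=free_z)


def tau_deg_to_rad(tau_deg: float) -> float:
    """Convert a precision from deg^-2 to rad^-2."""
    return tau_deg * (180.0 / np.pi) ** 2
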