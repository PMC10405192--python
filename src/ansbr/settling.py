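"""Sludge settleability analytics.

Zone settling velocity (ZSV) follows the Vesilind hindered-settling model

    v = v0 * exp(-k * X)

with v0 the unhindered settling velocity (m h^-1), k the compressibility
factor (L per g TSS) and X the sludge concentration (g TSS L^-1). Fitting is
done on the standard linearisation ln v = ln v0 - k X by ordinary least
squares, which is deterministic and exact on noiseless data; an optional
nonlinear refinement minimises squared error on the original scale.

Batch settling tests record the distance from the liquid surface to the
sludge blanket at a handful of checkpoint times; `settling_distance_summary`
expresses each checkpoint as a fraction of the final settled distance, the
form used for stacked-bar settleability comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import PSDRecord, SettlingObservation
from .errors import DomainError, InsufficientDataError

DEFAULT_CHECKPOINTS_MIN = (15.0, 30.0, 45.0, 90.0, 120.0)
DEFAULT_PSD_EDGES_UM = (1.0, 30.0, 300.0, 600.0)


@dataclass(frozen=True)
class VesilindFit:
    """Fitted Vesilind parameters with log-space diagnostics."""

    v0: float  # m/h
    k: float  # L / g TSS
    n_points: int
    r_squared: float
    residuals: tuple[float, ...]  # ln(v) - ln(v_hat)

    def predict(self, X: float | np.ndarray) -> float | np.ndarray:
        return predict_zsv(self, X)


@dataclass(frozen=True)
class SettlingSummary:
    """Checkpoint fractions of the final settled distance for one test."""

    day: float
    checkpoint_min: tuple[float, ...]
    fractions: tuple[float, ...]  # depth(t) / depth(final checkpoint)
    total_fraction: float  # depth(final) / column height
    degenerate: bool  # no measurable settling


def fit_vesilind(
    observations: Sequence[tuple[float, float]], nonlinear_refine: bool = False
) -> VesilindFit:
    """Least-squares fit of the Vesilind model to (X, v) pairs.

    Parameters
    ----------
    observations:
        Pairs of sludge concentration X (g TSS L^-1) and measured ZSV v
        (m h^-1). All v must be positive; at least two distinct X values are
        required for identifiability.
    nonlinear_refine:
        If True, polish the log-linear solution by nonlinear least squares on
        the original (untransformed) scale.
    """
    if not observations:
        raise InsufficientDataError("no (X, v) observations")
    X = np.asarray([o[0] for o in observations], dtype=float)
    v = np.asarray([o[1] for o in observations], dtype=float)
    if np.any(v <= 0):
        raise DomainError("all settling velocities must be > 0 (log undefined)")
    if len(np.unique(X)) < 2:
        raise InsufficientDataError("need >= 2 distinct sludge concentrations to fit")
    res = stats.linregress(X, np.log(v))
    v0 = float(np.exp(res.intercept))
    k = float(-res.slope)
    if nonlinear_refine:
        popt, _ = optimize.curve_fit(
            lambda x, v0_, k_: v0_ * np.exp(-k_ * x), X, v, p0=[v0, k], maxfev=10000
        )
        v0, k = float(popt[0]), float(popt[1])
    residuals = np.log(v) - (np.log(v0) - k * X)
    return VesilindFit(
        v0=v0,
        k=k,
        n_points=len(X),
        r_squared=float(res.rvalue**2),
        residuals=tuple(float(r) for r in residuals),
    )


def predict_zsv(fit: VesilindFit, X: float | np.ndarray) -> float | np.ndarray:
    """Predicted zone settling velocity v0 * exp(-k X) at concentration X."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DomainError("sludge concentration X must be >= 0")
    out = fit.v0 * np.exp(-fit.k * X)
    return float(out) if out.ndim == 0 else out


def settling_distance_summary(
    obs: SettlingObservation,
    checkpoints_min: Sequence[float] = DEFAULT_CHECKPOINTS_MIN,
    column_height: float = 1.0,
) -> SettlingSummary:
    """Summarise one settling test as fractions of the final settled distance.

    Interface depth is interpolated linearly at each checkpoint; fraction_t =
    depth(t) / depth(final checkpoint), so the final checkpoint fraction is 1
    by construction, and total_fraction = depth(final) / column_height.

    A trajectory that never moves (all depths equal) or ends at zero depth is
    flagged degenerate; its fractions are NaN.
    """
    if column_height <= 0:
        raise DomainError("column_height must be > 0")
    checkpoints = np.asarray(sorted(checkpoints_min), dtype=float)
    times, depths = obs.times_min, obs.depths
    if times[-1] < checkpoints[-1]:
        raise InsufficientDataError(
            f"trajectory ends at {times[-1]} min, before final checkpoint "
            f"{checkpoints[-1]} min"
        )
    at = np.interp(checkpoints, times, depths)
    final = at[-1]
    degenerate = final == 0 or np.ptp(depths) == 0
    if degenerate:
        fractions = tuple(float("nan") for _ in checkpoints)
    else:
        fractions = tuple(float(d / final) for d in at)
    return SettlingSummary(
        day=obs.day,
        checkpoint_min=tuple(float(c) for c in checkpoints),
        fractions=fractions,
        total_fraction=float(final / column_height),
        degenerate=bool(degenerate),
    )


def psd_fractions(
    psd: PSDRecord, bin_edges_um: Sequence[float] = DEFAULT_PSD_EDGES_UM
) -> Mapping[str, float]:
    """Sum PSD volume fractions into half-open diameter bins [lo, hi).

    Mass below the first edge and at/above the last edge is reported under
    ``"<lo"`` and ``">=hi"`` keys; a diameter equal to an interior edge falls
    in the higher bin.
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DomainError("bin edges must be strictly increasing with >= 2 entries")
    diam, frac = psd.diameters_um, psd.volume_fractions
    out: dict[str, float] = {f"<{edges[0]:g}": float(frac[diam < edges[0]].sum())}
    for lo, hi in zip(edges, edges[1:]):
        mask = (diam >= lo) & (diam < hi)
        out[f"[{lo:g},{hi:g})"] = float(frac[mask].sum())
    out[f">={edges[-1]:g}"] = float(frac[diam >= edges[-1]].sum())
    return out
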