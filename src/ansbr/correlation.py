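"""Correlation layer: Pearson coefficients with a four-level classification,
and PERMANOVA of a community distance matrix against operational covariates.

Classification scheme
---------------------
A pair is "none" when its p-value exceeds alpha (default 0.05); otherwise the
absolute coefficient is banded: |r| <= 0.30 low, 0.30 < |r| <= 0.60 moderate,
|r| > 0.60 high. The band bounds are configurable.

PERMANOVA
---------
Single-term distance-based ANOVA (Anderson's partition). Squared distances
are Gower-centred, G = -J D^2 J / 2; for a model matrix X (an intercept plus
either a continuous covariate or group dummies) with hat matrix H,

    SS_model = tr(H G),  SS_total = tr(G),
    F = (SS_model / (m - 1)) / ((SS_total - SS_model) / (n - m)),
    R^2 = SS_model / SS_total,

with m the model rank. Significance comes from permuting sample labels;
p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DistanceMatrix
from .errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_BAND_BOUNDS = (0.30, 0.60)
DEFAULT_PERMUTATIONS = 999
DEFAULT_DAY_WINDOW = 2.0

CATEGORIES = ("none", "low", "moderate", "high")


@dataclass(frozen=True)
class CorrelationResult:
    output: str
    predictor: str
    r: float
    p: float
    n: int
    category: str


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    R2: float
    p: float
    pseudo_F: float
    n_permutations: int
    seed: Optional[int]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided t-distribution p-value (n-2 df).

    Pairs where either value is missing (NaN) are deleted pairwise; at least
    three complete pairs are required and both series must vary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"series lengths differ: {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def classify_correlation(
    r: float,
    p: float,
    alpha: float = DEFAULT_ALPHA,
    band_bounds: tuple[float, float] = DEFAULT_BAND_BOUNDS,
) -> str:
    """Map (r, p) to one of none / low / moderate / high."""
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise DomainError(f"|r| must be <= 1, got {r}")
    low_hi, mod_hi = band_bounds
    if p > alpha:
        return "none"
    a = abs(r)
    if a <= low_hi:
        return "low"
    if a <= mod_hi:
        return "moderate"
    return "high"


def correlation_table(
    series_map: Mapping[str, pd.Series],
    outputs: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    day_window: float = DEFAULT_DAY_WINDOW,
) -> list[CorrelationResult]:
    """Pearson + classification for every (output, predictor) pair.

    Each series is indexed by operational day; observations are aligned by a
    nearest-day join within ``day_window`` days. Pairs without enough
    overlapping days are skipped with a warning.
    """
    results = []
    for output in outputs:
        if output not in series_map:
            raise ValidationError(f"output series {output!r} not provided")
        out_series = series_map[output].dropna().sort_index()
        for predictor, pred_series in series_map.items():
            if predictor == output:
                continue
            pred = pred_series.dropna().sort_index()
            if out_series.empty or pred.empty:
                logger.warning("pair (%s, %s): empty series; skipped", output, predictor)
                continue
            left = out_series.rename("y").reset_index().rename(columns={"index": "day"})
            right = pred.rename("x").reset_index().rename(columns={"index": "day"})
            left.columns = ["day", "y"]
            right.columns = ["day", "x"]
            merged = pd.merge_asof(
                left.sort_values("day"),
                right.sort_values("day"),
                on="day",
                direction="nearest",
                tolerance=day_window,
            ).dropna()
            if len(merged) < 3:
                logger.warning(
                    "pair (%s, %s): only %d overlapping days; skipped",
                    output, predictor, len(merged),
                )
                continue
            try:
                r, p, n = pearson(merged["x"].to_numpy(), merged["y"].to_numpy())
            except UndefinedCorrelationError:
                logger.warning("pair (%s, %s): zero variance; skipped", output, predictor)
                continue
            results.append(
                CorrelationResult(
                    output=output, predictor=predictor, r=r, p=p, n=n,
                    category=classify_correlation(r, p, alpha=alpha),
                )
            )
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"output": c.output, "predictor": c.predictor, "r": c.r, "p": c.p,
             "n": c.n, "category": c.category}
            for c in results
        ]
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _hat_matrix(X: np.ndarray) -> np.ndarray:
    # pinv tolerates rank deficiency (e.g. redundant dummies)
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _model_matrix(values: np.ndarray, categorical: bool) -> tuple[np.ndarray, int]:
    n = len(values)
    if categorical:
        levels = pd.unique(values)
        X = np.column_stack([np.ones(n)] + [(values == lv).astype(float) for lv in levels[1:]])
        m = len(levels)
    else:
        z = values.astype(float)
        z = (z - z.mean()) / z.std()
        X = np.column_stack([np.ones(n), z])
        m = 2
    return X, m


def permanova(
    dm: DistanceMatrix,
    variable: Sequence,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    categorical: Optional[bool] = None,
    factor_name: str = "variable",
) -> PermanovaResult:
    """Single-factor PERMANOVA of a distance matrix against one covariate.

    ``variable`` holds one value per sample, in distance-matrix order. It is
    treated as categorical when non-numeric (or when ``categorical=True``),
    otherwise as a continuous covariate in the distance-based linear model.
    The permutation p-value uses the +1 correction and is exact under
    exhaustive enumeration (triggered automatically when the number of
    distinct permutations is small; see ``n_permutations``).
    """
    values = np.asarray(variable)
    n = len(dm.ids)
    if len(values) != n:
        raise ValidationError(f"variable has {len(values)} entries for {n} samples")
    if len(pd.unique(values)) < 2:
        raise DomainError("variable is constant; PERMANOVA undefined")
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    if categorical is None:
        categorical = not np.issubdtype(np.asarray(values).dtype, np.number)

    G = _gower_center(dm.data)
    ss_total = float(np.trace(G))
    X, m = _model_matrix(values, categorical)
    if m >= n:
        raise DomainError("model has no residual degrees of freedom")
    H = _hat_matrix(X)

    def pseudo_f(perm: np.ndarray) -> tuple[float, float]:
        Gp = G[np.ix_(perm, perm)]
        ss_model = float(np.sum(H * Gp))  # tr(H Gp), H symmetric
        ss_resid = ss_total - ss_model
        f = (ss_model / (m - 1)) / (ss_resid / (n - m))
        return f, ss_model

    identity = np.arange(n)
    f_obs, ss_model_obs = pseudo_f(identity)
    r2 = ss_model_obs / ss_total

    exhaustive = math.factorial(n) <= n_permutations if n <= 8 else False
    if exhaustive:
        f_perm = np.array([pseudo_f(np.array(p))[0] for p in itertools.permutations(range(n))])
        # identity is among the enumerated relabelings: exact p
        p_value = float(np.mean(f_perm >= f_obs - 1e-12))
        n_used = len(f_perm)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if pseudo_f(perm)[0] >= f_obs - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_permutations)
        n_used = n_permutations
    return PermanovaResult(
        factor=factor_name,
        R2=float(r2),
        p=float(p_value),
        pseudo_F=float(f_obs),
        n_permutations=n_used,
        seed=seed,
    )


def permanova_table(
    dm: DistanceMatrix,
    covariates: pd.DataFrame,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One single-term PERMANOVA per covariate column, matching sample order."""
    missing = [s for s in dm.ids if s not in covariates.index]
    if missing:
        raise ValidationError(f"covariates missing for samples: {missing}")
    aligned = covariates.loc[list(dm.ids)]
    rows = []
    for col in aligned.columns:
        series = aligned[col]
        if series.isna().any():
            logger.warning("covariate %s has missing values; skipped", col)
            continue
        res = permanova(
            dm, series.to_numpy(), n_permutations=n_permutations, seed=seed, factor_name=col
        )
        rows.append({"factor": col, "R2": res.R2, "p": res.p, "pseudo_F": res.pseudo_F})
    return pd.DataFrame(rows, columns=["factor", "R2", "p", "pseudo_F"])
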