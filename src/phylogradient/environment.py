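"""Environmental layers and their correlation with diversity indices.

Three predictors are supported, matching the drivers commonly invoked for
tropical wet-forest gradients:

* CWD -- climatic water deficit (mm/yr): the sum over *dry* months of
  monthly precipitation minus evapotranspiration.  Always <= 0; more
  negative means stronger seasonal drought.
* MAP -- mean annual precipitation (mm/yr, >= 0).
* TRI -- topographic ruggedness index (m): mean absolute elevation
  difference between a cell and its neighbours (the "mean absolute
  difference" reading; the original root-sum-of-squares variant is offered
  as an option).

Correlations are plain Pearson on pairwise-complete cells, with no spatial
autocorrelation correction (a documented limitation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "tri",
    "aggregate",
    "cwd_from_monthly",
    "correlate_diversity_env",
    "validate_env_table",
]

ENV_COLUMNS = ("cwd", "map", "tri")


def validate_env_table(env):
    """Check EnvTable invariants: cwd <= 0, map >= 0, tri >= 0."""
    for col in ENV_COLUMNS:
        if col not in env.columns:
            raise ValidationError(f"environment table missing column {col!r}")
    if (env["cwd"].dropna() > 0).any():
        raise ValidationError("CWD must be <= 0")
    if (env["map"].dropna() < 0).any():
        raise ValidationError("MAP must be >= 0")
    if (env["tri"].dropna() < 0).any():
        raise ValidationError("TRI must be >= 0")
    return env


def tri(elevation, *, variant="mean_abs"):
    """Topographic ruggedness of a rectangular elevation grid (metres).

    Each cell is scored against its (up to 8) neighbours; edge cells use
    the neighbours that exist, NaN cells propagate NaN.  ``variant`` is
    ``"mean_abs"`` (mean absolute difference, default) or ``"riley"``
    (root of summed squared differences).
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or min(z.shape) < 2:
        raise ValidationError("elevation grid must be 2-D and at least 2x2")
    if np.isnan(z).all():
        raise ValidationError("elevation grid is entirely missing")
    nr, nc = z.shape
    acc = np.zeros_like(z)
    cnt = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            rs = slice(max(dr, 0), nr + min(dr, 0))
            rd = slice(max(-dr, 0), nr + min(-dr, 0))
            cs = slice(max(dc, 0), nc + min(dc, 0))
            cd = slice(max(-dc, 0), nc + min(-dc, 0))
            shifted[rd, cd] = z[rs, cs]
            diff = z - shifted
            ok = ~np.isnan(diff)
            if variant == "mean_abs":
                acc[ok] += np.abs(diff[ok])
            else:
                acc[ok] += diff[ok] ** 2
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        if variant == "mean_abs":
            out = acc / cnt
        elif variant == "riley":
            out = np.sqrt(acc)
        else:
            raise ValueError(f"unknown TRI variant {variant!r}")
    out[np.isnan(z)] = np.nan
    out[cnt == 0] = np.nan
    return out


def aggregate(grid, factor, method="mean"):
    """Block-aggregate a 2-D grid by ``factor`` (partial edge blocks use the
    cells available)."""
    z = np.asarray(grid, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise DomainError("factor must be a positive integer")
    factor = int(factor)
    if factor > max(z.shape):
        raise DomainError(f"factor {factor} larger than grid {z.shape}")
    if factor == 1:
        return z.copy()
    nr = -(-z.shape[0] // factor)
    nc = -(-z.shape[1] // factor)
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            block = z[i * factor:(i + 1) * factor, j * factor:(j + 1) * factor]
            vals = block[~np.isnan(block)]
            if vals.size:
                out[i, j] = vals.mean() if method == "mean" else vals.sum()
    return out


def cwd_from_monthly(precip, et=100.0):
    """Climatic water deficit (mm/yr) from 12 monthly precipitation values.

    ``et`` is monthly evapotranspiration: a constant (default 100 mm/month,
    the usual fixed-ET convention) or a 12-vector.  Only months where
    precipitation minus ET is negative (dry months) contribute; the result
    is <= 0, and 0 when no month is dry.  ``precip`` may be shaped (12,)
    or (12, ...) for gridded input.
    """
    p = np.asarray(precip, dtype=float)
    if p.shape[0] != 12:
        raise ValidationError(f"expected 12 monthly values, got {p.shape[0]}")
    if np.any(p < 0):
        raise ValidationError("precipitation must be non-negative")
    e = np.asarray(et, dtype=float)
    if e.ndim == 0:
        e = np.full(12, float(e))
    if e.shape[0] != 12:
        raise ValidationError("et must be scalar or 12 monthly values")
    diff = p - e.reshape((12,) + (1,) * (p.ndim - 1))
    return np.minimum(diff, 0.0).sum(axis=0)


def correlate_diversity_env(div, env):
    """Pearson r of each diversity index against each predictor.

    ``div`` columns: sr, pd, pe, tild; ``env`` columns: cwd, map, tri;
    matched on cell id, pairwise-complete.  Returns a long DataFrame with
    columns ``index, predictor, n, r, p``; a pair whose columns have zero
    variance gets NaN r/p (flagged, not fabricated).
    """
    shared = div.index.intersection(env.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared cells to correlate")
    rows = []
    for idx in ("sr", "pd", "pe", "tild"):
        if idx not in div.columns:
            continue
        for pred in ENV_COLUMNS:
            if pred not in env.columns:
                continue
            x = div.loc[shared, idx].to_numpy(float)
            y = env.loc[shared, pred].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"index": idx, "predictor": pred, "n": n,
                         "r": r, "p": p})
    return pd.DataFrame(rows)
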