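"""Pre-calibration assumption checks.

* Monotonicity: kernel-smoothed mean item score against the rest score.
* Essential unidimensionality: mixed polychoric / polyserial / Pearson
  correlations, hierarchical exploratory factor analysis with a
  Schmid-Leiman orthogonalization, omega-hierarchical and explained
  common variance (ECV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .data import MISSING, ResponseData

# ---------------------------------------------------------------------------
# monotonicity


@dataclass
class MonotonicityCurve:
    item_id: str
    grid: np.ndarray
    smooth: np.ndarray
    bandwidth: float
    max_decrease: float
    flagged: bool
    n: int


def _silverman(x: np.ndarray) -> float:
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1.0)
    return 0.9 * scale * len(x) ** (-0.2)


def monotonicity_curves(
    data: ResponseData,
    item_id: str,
    bandwidth: float | None = None,
    n_grid: int = 50,
    tolerance: float = 0.05,
    min_obs: int = 50,
) -> MonotonicityCurve | None:
    """Nadaraya-Watson smooth of item score vs rest score; flag decreases.

    Returns ``None`` (skipped) when fewer than ``min_obs`` persons have the
    item plus at least one other item observed.
    """
    j = data.col(item_id)
    x = data.X.astype(float)
    x[x == MISSING] = np.nan
    item = x[:, j]
    rest = np.nansum(np.delete(x, j, axis=1), axis=1)
    n_rest = np.sum(~np.isnan(np.delete(x, j, axis=1)), axis=1)
    ok = ~np.isnan(item) & (n_rest > 0)
    if ok.sum() < min_obs:
        return None
    item, rest = item[ok], rest[ok]
    h = bandwidth if bandwidth is not None else _silverman(rest)
    # evaluate inside the 1st-99th percentile span: the extreme tails hold
    # too few persons for the smooth to be meaningful
    lo, hi = np.percentile(rest, [1, 99])
    grid = np.linspace(lo, hi, n_grid)
    w = np.exp(-0.5 * ((grid[:, None] - rest[None, :]) / h) ** 2)
    smooth = (w @ item) / np.maximum(w.sum(axis=1), 1e-300)
    running_max = np.maximum.accumulate(smooth)
    max_dec = float(np.max(running_max - smooth))
    return MonotonicityCurve(
        item_id, grid, smooth, float(h), max_dec, max_dec > tolerance, int(ok.sum())
    )


def monotonicity_report(
    data: ResponseData, tolerance: float = 0.05, min_obs: int = 50
) -> tuple[dict[str, MonotonicityCurve], list[str]]:
    curves: dict[str, MonotonicityCurve] = {}
    skipped: list[str] = []
    for iid in data.item_ids:
        c = monotonicity_curves(data, iid, tolerance=tolerance, min_obs=min_obs)
        if c is None:
            skipped.append(iid)
        else:
            curves[iid] = c
    return curves, skipped


# ---------------------------------------------------------------------------
# bivariate normal CDF (Gauss-Legendre on the correlation integral)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho."""
    # +/-12 SD is numerically identical to +/-inf for the normal CDF
    h = np.clip(np.asarray(h, dtype=float), -12.0, 12.0)
    k = np.clip(np.asarray(k, dtype=float), -12.0, 12.0)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # map [-1,1] -> [0, rho]
    wr = 0.5 * abs(rho) * _GL_WEIGHTS * np.sign(rho)
    one_m = 1.0 - r**2
    hh = h[..., None]
    kk = k[..., None]
    integrand = np.exp(
        -(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * one_m)
    ) / np.sqrt(one_m)
    return base + (integrand * wr).sum(axis=-1) / (2.0 * np.pi)


def _thresholds(counts: np.ndarray) -> np.ndarray:
    """Normal thresholds (with +/- inf endpoints) from marginal counts."""
    cum = np.cumsum(counts) / counts.sum()
    inner = norm.ppf(np.clip(cum[:-1], 1e-10, 1 - 1e-10))
    return np.concatenate([[-np.inf], inner, [np.inf]])


def polychoric(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two integer-coded variables."""
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    table[table == 0] = 0.5  # continuity correction for empty cells
    tau_x = _thresholds(table.sum(axis=1))
    tau_y = _thresholds(table.sum(axis=0))
    gx, gy = np.meshgrid(tau_x, tau_y, indexing="ij")

    def neg_ll(rho: float) -> float:
        cdf = _bvn_cdf(gx, gy, rho)
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        cell = np.clip(cell, 1e-12, None)
        return -float((table * np.log(cell)).sum())

    res = minimize_scalar(neg_ll, bounds=(-0.995, 0.995), method="bounded")
    if not res.success:
        raise RuntimeError("polychoric estimation did not converge")
    return float(res.x)


def polyserial(x: np.ndarray, y: np.ndarray) -> float:
    """ML polyserial correlation: continuous x, integer-coded ordinal y."""
    z = (x - x.mean()) / x.std()
    counts = np.bincount(y, minlength=int(y.max()) + 1)
    tau = _thresholds(counts)
    hi = tau[y + 1]
    lo = tau[y]

    def neg_ll(rho: float) -> float:
        s = np.sqrt(1.0 - rho**2)
        p = norm.cdf((hi - rho * z) / s) - norm.cdf((lo - rho * z) / s)
        return -float(np.log(np.clip(p, 1e-12, None)).sum())

    res = minimize_scalar(neg_ll, bounds=(-0.995, 0.995), method="bounded")
    if not res.success:
        raise RuntimeError("polyserial estimation did not converge")
    return float(res.x)


def mixed_correlation_matrix(
    data: ResponseData, category_threshold: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item correlation matrix mixing polychoric/polyserial/Pearson.

    Items with more than ``category_threshold`` observed response options
    are treated as continuous.  Cells use pairwise-complete persons; a
    non-convergent polychoric/polyserial falls back to Pearson (logged in
    ``R.attrs['fallbacks']``).
    """
    ids = data.item_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 items")
    x = data.X.astype(float)
    x[x == MISSING] = np.nan
    continuous = {}
    for iid in ids:
        col = x[:, data.col(iid)]
        n_opts = len(np.unique(col[~np.isnan(col)]))
        continuous[iid] = n_opts > category_threshold
    p = len(ids)
    r_mat = np.eye(p)
    methods = np.full((p, p), "", dtype=object)
    fallbacks: list[tuple[str, str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            xi = x[:, data.col(ids[i])]
            xj = x[:, data.col(ids[j])]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            a, b = xi[ok], xj[ok]
            ci, cj = continuous[ids[i]], continuous[ids[j]]
            method = (
                "pearson" if ci and cj else "polyserial" if ci or cj else "polychoric"
            )
            try:
                if method == "pearson":
                    r = float(np.corrcoef(a, b)[0, 1])
                elif method == "polyserial":
                    cont, ordi = (a, b) if ci else (b, a)
                    r = polyserial(cont, ordi.astype(int))
                else:
                    r = polychoric(a.astype(int), b.astype(int))
            except Exception as exc:  # fall back, keep going
                r = float(np.corrcoef(a, b)[0, 1])
                method = "pearson"
                fallbacks.append((ids[i], ids[j], str(exc)))
            r_mat[i, j] = r_mat[j, i] = r
            methods[i, j] = methods[j, i] = method
    r_df = pd.DataFrame(r_mat, index=ids, columns=ids)
    r_df.attrs["fallbacks"] = fallbacks
    return r_df, pd.DataFrame(methods, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# hierarchical EFA / Schmid-Leiman


def _smooth_psd(r: np.ndarray, log: list[str]) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r)
    if vals.min() > 1e-8:
        return r
    log.append(f"correlation matrix smoothed (min eigenvalue {vals.min():.2e})")
    vals = np.clip(vals, 1e-6, None)
    r2 = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(r2))
    return r2 / np.outer(d, d)


_PSI_FLOOR = 0.005


def ml_factor(r: np.ndarray, k: int) -> np.ndarray:
    """Maximum-likelihood factor loadings (p x k) for a correlation matrix.

    Profile likelihood over uniquenesses: given psi, the loadings come from
    the top eigenpairs of psi^{-1/2} R psi^{-1/2}.  Uniquenesses are floored
    (Heywood protection); a warning is emitted when the floor binds.
    """
    p = r.shape[0]
    inv_diag = np.diag(np.linalg.inv(r + 1e-8 * np.eye(p)))
    psi0 = np.clip(1.0 - (1.0 - 1.0 / inv_diag), 0.05, 0.95)

    def objective(log_psi: np.ndarray) -> float:
        psi = np.exp(log_psi)
        s = 1.0 / np.sqrt(psi)
        vals = np.linalg.eigvalsh(r * np.outer(s, s))[::-1]
        tail = np.clip(vals[k:], 1e-10, None)
        return float(np.sum(tail - np.log(tail) - 1.0))

    res = minimize(
        objective,
        np.log(psi0),
        method="L-BFGS-B",
        bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
    )
    psi = np.exp(res.x)
    if np.any(psi <= _PSI_FLOOR * 1.01):
        warnings.warn("Heywood case: uniqueness at floor, loading bounded", RuntimeWarning)
    s = 1.0 / np.sqrt(psi)
    vals, vecs = np.linalg.eigh(r * np.outer(s, s))
    vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    load = vecs * np.sqrt(np.clip(vals - 1.0, 0.0, None))
    return load / s[:, None]


def varimax(load: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    p, k = load.shape
    if k < 2:
        return load.copy()
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = load @ rot
        u, s, vt = np.linalg.svd(
            load.T @ (lam**3 - lam * (lam**2).sum(axis=0) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return load @ rot


def promax(load: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation; returns (pattern, factor correlation)."""
    x = varimax(load)
    k = x.shape[1]
    if k < 2:
        return x.copy(), np.eye(1)
    target = x * np.abs(x) ** (power - 1)
    u = np.linalg.lstsq(x, target, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(u.T @ u)))
    u = u * d
    pattern = x @ u
    phi = np.linalg.inv(u.T @ u)
    # orient factors positively so the general factor is interpretable
    signs = np.sign(pattern.sum(axis=0))
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return pattern, phi


def _general_loadings(phi: np.ndarray) -> np.ndarray:
    """One-factor solution of the factor correlation matrix."""
    k = phi.shape[0]
    if k == 1:
        return np.ones(1)
    if k == 3:  # closed form from the three pairwise correlations
        r12, r13, r23 = phi[0, 1], phi[0, 2], phi[1, 2]
        if min(r12, r13, r23) > 1e-3:
            g = np.sqrt(
                np.clip(
                    [r12 * r13 / r23, r12 * r23 / r13, r13 * r23 / r12], 0.0, 0.9995
                )
            )
            return g
    load = ml_factor(phi, 1)[:, 0]
    if load.sum() < 0:
        load = -load
    return np.clip(load, 0.0, 0.9995)


@dataclass
class DiagnosticsReport:
    omega_h: float
    ecv_general: float
    ecv_group_factors: list[float]
    general_loadings: np.ndarray
    group_loadings: np.ndarray
    factor_pattern: np.ndarray
    factor_phi: np.ndarray
    correlation: pd.DataFrame | None = None
    methods: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def hierarchical_omega_ecv(
    data: ResponseData | None = None,
    n_group_factors: int = 3,
    corr: pd.DataFrame | np.ndarray | None = None,
    category_threshold: int = 10,
) -> DiagnosticsReport:
    """General-factor saturation via hierarchical EFA + Schmid-Leiman.

    Extracts ``n_group_factors`` primary factors (ML), rotates obliquely
    (promax), factors the factor correlations into a single second-order
    factor, and orthogonalizes.  ``omega_h`` is the squared sum of general
    loadings over the total score variance implied by the correlation
    matrix; ECV splits the common variance between the general and group
    factors.
    """
    notes: list[str] = []
    methods = None
    if corr is None:
        if data is None:
            raise ValueError("provide data or a correlation matrix")
        corr, methods = mixed_correlation_matrix(data, category_threshold)
    corr_df = (
        corr if isinstance(corr, pd.DataFrame) else pd.DataFrame(np.asarray(corr))
    )
    r = _smooth_psd(corr_df.to_numpy(dtype=float), notes)
    p = r.shape[0]
    k = min(n_group_factors, max(1, p // 2))
    if k != n_group_factors:
        notes.append(f"group factors reduced to {k} for {p} items")
    load = ml_factor(r, k)
    # factors with essentially no loadings (rank-deficient common space)
    # destabilize the oblique rotation; drop them before rotating
    keep = (load**2).sum(axis=0) > 1e-3
    if not keep.all():
        notes.append(f"dropped {int((~keep).sum())} null factors before rotation")
        load = load[:, keep]
        k = load.shape[1]
    pattern, phi = promax(load)
    g2 = _general_loadings(phi)
    general = pattern @ g2
    group = pattern * np.sqrt(np.clip(1.0 - g2**2, 0.0, 1.0))[None, :]
    ssg = float((general**2).sum())
    ss_groups = (group**2).sum(axis=0)
    common = ssg + float(ss_groups.sum())
    ecv_general = ssg / common if common > 0 else 0.0
    omega_h = float(general.sum()) ** 2 / float(r.sum())
    return DiagnosticsReport(
        omega_h=float(omega_h),
        ecv_general=float(ecv_general),
        ecv_group_factors=[float(v / common) for v in ss_groups],
        general_loadings=general,
        group_loadings=group,
        factor_pattern=pattern,
        factor_phi=phi,
        correlation=corr_df,
        methods=methods,
        notes=notes,
    )
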