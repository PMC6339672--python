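"""Concurrent multi-group MML-EM calibration of PCM/GPCM item banks.

All linked datasets enter one persons x items matrix with structurally
missing cells.  The E-step integrates each person's likelihood over a fixed
quadrature grid under their dataset's normal latent density; the M-step
runs per-item Newton updates in the slope/intercept parameterization
(which is concave) and re-estimates each dataset's latent mean and SD,
holding the reference dataset at N(0, 1) for identification.

Also provides the post-fit machinery: PCM-vs-GPCM comparison, LM-type
DIF and item-fit tests with an effect-size screen, Yen's Q3 residual
correlations, and subgroup-parameter respecification for flagged items.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .core import ItemBank, ItemParams, QuadGrid, _probs_matrix
from .data import MISSING, ResponseData
from .simulate import GroupDist, LinkDesign

Model = Literal["PCM", "GPCM"]

_OVERRIDE_SEP = "@@"


class LinkageError(ValueError):
    """Raised when the common-item design cannot identify a common scale."""


class ComparisonError(ValueError):
    """Raised when two fits being compared were not run on the same data."""


@dataclass(frozen=True)
class CalibOptions:
    grid: QuadGrid | None = None
    tol: float = 1e-5
    max_iter: int = 500
    reference_group: str | None = None  # default: first dataset in the design
    a_min: float = 0.05
    a_max: float = 8.0
    sd_floor: float = 0.05
    newton_steps: int = 3
    compute_se: bool = True
    init_bank: ItemBank | None = None


@dataclass
class CalibrationResult:
    bank: ItemBank
    dists: GroupDist
    loglik: float
    n_params: int
    aic: float
    n_iter: int
    converged: bool
    model: Model
    grid: QuadGrid
    ll_history: list[float]
    data_fingerprint: str
    se_table: pd.DataFrame | None = None


def data_fingerprint(data: ResponseData) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.X).tobytes())
    h.update("|".join(data.item_ids).encode())
    h.update("|".join(map(str, data.dataset)).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# EM internals


def _check_item_categories(data: ResponseData) -> dict[str, int]:
    """Observed max score per item; every category 0..m must be observed."""
    m_of: dict[str, int] = {}
    for iid in data.item_ids:
        x = data.X[:, data.col(iid)]
        x = x[x != MISSING]
        if x.size == 0:
            raise LinkageError(f"item {iid!r} has no observed responses")
        counts = np.bincount(x)
        if len(counts) < 2:
            raise LinkageError(
                f"item {iid!r} has < 2 observed categories; collapse or drop it"
            )
        if np.any(counts == 0):
            empty = np.where(counts == 0)[0].tolist()
            raise LinkageError(
                f"item {iid!r} has unobserved interior categories {empty}; "
                "collapse sparse categories first"
            )
        m_of[iid] = len(counts) - 1
    return m_of


def _init_item(x: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    """Start values: a = 1, steps from adjacent-category log odds."""
    counts = np.bincount(x, minlength=m + 1).astype(float) + 0.5
    b = np.log(counts[:-1] / counts[1:])
    return 1.0, np.clip(b, -3.0, 3.0)


def _item_update(
    r: np.ndarray,
    nodes: np.ndarray,
    a: float,
    c: np.ndarray,
    estimate_a: bool,
    a_bounds: tuple[float, float],
    n_steps: int,
) -> tuple[float, np.ndarray]:
    """Newton ascent of the expected complete-data log-likelihood of one item.

    Parameterization: z_k(theta) = a*k*theta - C_k with C_k = sum_{v<=k} c_v
    (c_v = a*b_v), linear in (a, c), so the objective is concave.
    """
    q_n, k_n = r.shape
    m = k_n - 1
    kvec = np.arange(k_n, dtype=float)
    nq = r.sum(axis=1)
    d_c = -(kvec[:, None] >= np.arange(1, m + 1)[None, :]).astype(float)  # (K, m)

    def logp(a_: float, c_: np.ndarray) -> np.ndarray:
        z = a_ * np.outer(nodes, kvec)
        z -= np.concatenate([[0.0], np.cumsum(c_)])[None, :]
        z -= z.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    def objective(a_: float, c_: np.ndarray) -> float:
        return float((r * logp(a_, c_)).sum())

    obj = objective(a, c)
    p = m + 1 if estimate_a else m
    for _ in range(n_steps):
        lp = logp(a, c)
        prob = np.exp(lp)
        d = np.empty((q_n, k_n, p))
        off = 0
        if estimate_a:
            d[:, :, 0] = nodes[:, None] * kvec[None, :]
            off = 1
        d[:, :, off:] = d_c[None, :, :]
        e_d = np.einsum("qk,qkp->qp", prob, d)
        grad = np.einsum("qk,qkp->p", r, d) - nq @ e_d
        if np.max(np.abs(grad)) < 1e-9 * (1.0 + nq.sum()):
            break
        hess = np.einsum("q,qkp,qk,qkr->pr", nq, d, prob, d) - np.einsum(
            "q,qp,qr->pr", nq, e_d, e_d
        )
        hess[np.diag_indices_from(hess)] += 1e-10
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(12):
            if estimate_a:
                a_new = float(np.clip(a + step * delta[0], *a_bounds))
                c_new = c + step * delta[1:]
            else:
                a_new, c_new = a, c + step * delta
            obj_new = objective(a_new, c_new)
            if obj_new >= obj - 1e-12:
                a, c, obj = a_new, c_new, obj_new
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return a, c


def _loglik_matrix(
    bank_params: Mapping[str, tuple[float, np.ndarray]],
    data: ResponseData,
    nodes: np.ndarray,
) -> np.ndarray:
    """Sum of per-item log category probabilities, shape (n_persons, n_nodes)."""
    n = data.n_persons
    ll = np.zeros((n, len(nodes)))
    for iid in data.item_ids:
        a, b = bank_params[iid]
        j = data.col(iid)
        obs = data.X[:, j] != MISSING
        if not obs.any():
            continue
        x = data.X[obs, j]
        lp = np.log(_probs_matrix(a, b, nodes))  # (Q, K)
        ll[obs] += lp[:, x].T
    return ll


def concurrent_calibrate(
    data: ResponseData,
    design: LinkDesign,
    model: Model = "GPCM",
    opts: CalibOptions = CalibOptions(),
) -> CalibrationResult:
    """Jointly calibrate all items across linked datasets via MML-EM.

    Raises :class:`LinkageError` for a disconnected design or degenerate
    items; returns ``converged=False`` (with a warning) when the
    log-likelihood tolerance is not reached within ``max_iter`` cycles.
    """
    design.require_connected()
    m_of = _check_item_categories(data)
    grid = opts.grid or QuadGrid.equally_spaced()
    nodes = grid.nodes
    q_n = len(nodes)

    groups = list(design.datasets)
    ref = opts.reference_group or groups[0]
    if ref not in groups:
        raise LinkageError(f"reference group {ref!r} not in design")
    g_of = {g: i for i, g in enumerate(groups)}
    g_idx = np.array([g_of[str(d)] for d in data.dataset])
    n_g = np.bincount(g_idx, minlength=len(groups))
    if np.any(n_g == 0):
        empty = [g for g, c in zip(groups, n_g) if c == 0]
        raise LinkageError(f"datasets with no respondents: {empty}")

    item_ids = list(data.item_ids)
    estimate_a = model == "GPCM"
    a_par: dict[str, float] = {}
    c_par: dict[str, np.ndarray] = {}
    for iid in item_ids:
        if opts.init_bank is not None and iid in opts.init_bank:
            it = opts.init_bank[iid]
            a0 = it.a if estimate_a else 1.0
            b0 = np.asarray(it.b, dtype=float)
            if len(b0) != m_of[iid]:
                a0, b0 = _init_item(
                    data.X[data.observed(iid), data.col(iid)], m_of[iid]
                )
        else:
            a0, b0 = _init_item(
                data.X[data.observed(iid), data.col(iid)], m_of[iid]
            )
        a_par[iid] = float(np.clip(a0, opts.a_min, opts.a_max)) if estimate_a else 1.0
        c_par[iid] = a_par[iid] * b0

    mu = np.zeros(len(groups))
    sd = np.ones(len(groups))
    ref_i = g_of[ref]

    obs_mask = data.X != MISSING
    x_cols = {iid: data.X[:, data.col(iid)] for iid in item_ids}
    obs_cols = {iid: obs_mask[:, data.col(iid)] for iid in item_ids}

    ll_history: list[float] = []
    converged = False
    post = np.zeros((data.n_persons, q_n))
    for it_no in range(1, opts.max_iter + 1):
        params = {iid: (a_par[iid], c_par[iid] / a_par[iid]) for iid in item_ids}
        ll_mat = _loglik_matrix(params, data, nodes)
        log_w = np.empty((len(groups), q_n))
        for gi in range(len(groups)):
            w = grid.reweight_normal(mu[gi], sd[gi])
            log_w[gi] = np.log(w)
        a_mat = ll_mat + log_w[g_idx]
        lse = logsumexp(a_mat, axis=1)
        ll = float(lse.sum())
        np.exp(a_mat - lse[:, None], out=post)

        if ll_history and ll < ll_history[-1] - 1e-6 * (1.0 + abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at cycle {it_no}: "
                f"{ll_history[-1]:.6f} -> {ll:.6f}"
            )
        done = bool(ll_history) and abs(ll - ll_history[-1]) < opts.tol
        ll_history.append(ll)
        if done:
            converged = True
            break

        # M-step: items
        for iid in item_ids:
            obs = obs_cols[iid]
            x = x_cols[iid][obs]
            k_n = m_of[iid] + 1
            pi = post[obs]
            r = np.empty((q_n, k_n))
            for k in range(k_n):
                sel = x == k
                r[:, k] = pi[sel].sum(axis=0) if sel.any() else 0.0
            a_new, c_new = _item_update(
                r,
                nodes,
                a_par[iid],
                c_par[iid],
                estimate_a,
                (opts.a_min, opts.a_max),
                opts.newton_steps,
            )
            a_par[iid], c_par[iid] = a_new, c_new

        # M-step: group distributions (reference pinned at N(0,1))
        m1 = post @ nodes
        m2 = post @ nodes**2
        for gi in range(len(groups)):
            if gi == ref_i:
                continue
            sel = g_idx == gi
            mu[gi] = float(m1[sel].mean())
            var = float(m2[sel].mean()) - mu[gi] ** 2
            sd[gi] = max(np.sqrt(max(var, 0.0)), opts.sd_floor)

    if not converged:
        warnings.warn(
            f"EM did not reach tol={opts.tol} in {opts.max_iter} cycles "
            f"(last change {ll_history[-1] - ll_history[-2]:.3e})",
            RuntimeWarning,
        )

    items = []
    for iid in item_ids:
        a = a_par[iid]
        b = tuple(c_par[iid] / a)
        instrs: frozenset[str] = frozenset(design.item_instruments.get(iid, ()))
        if not instrs and opts.init_bank is not None and iid in opts.init_bank:
            instrs = opts.init_bank[iid].instrument_ids
        items.append(ItemParams(iid, a, b, instrs))
    bank = ItemBank(items)

    dists = GroupDist(
        {g: float(mu[g_of[g]]) for g in groups},
        {g: float(sd[g_of[g]]) for g in groups},
        ref,
    )
    n_params = sum(m_of[i] + (1 if estimate_a else 0) for i in item_ids)
    n_params += 2 * (len(groups) - 1)
    ll = ll_history[-1]
    se_table = _se_table(bank, data, post, m_of, nodes) if opts.compute_se else None
    return CalibrationResult(
        bank=bank,
        dists=dists,
        loglik=ll,
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * ll,
        n_iter=len(ll_history),
        converged=converged,
        model=model,
        grid=grid,
        ll_history=ll_history,
        data_fingerprint=data_fingerprint(data),
        se_table=se_table,
    )


def _se_table(
    bank: ItemBank,
    data: ResponseData,
    post: np.ndarray,
    m_of: Mapping[str, int],
    nodes: np.ndarray,
) -> pd.DataFrame:
    """Approximate SEs from the expected complete-data information.

    These ignore the E-step uncertainty, so they are lower bounds on the
    sampling SEs; adequate for reporting relative precision.
    """
    rows = []
    for iid in data.item_ids:
        item = bank[iid]
        a, b = item.params_for(None)
        obs = data.observed(iid)
        x = data.X[obs, data.col(iid)]
        k_n = m_of[iid] + 1
        kvec = np.arange(k_n, dtype=float)
        r = np.empty((len(nodes), k_n))
        pi = post[obs]
        for k in range(k_n):
            sel = x == k
            r[:, k] = pi[sel].sum(axis=0) if sel.any() else 0.0
        nq = r.sum(axis=1)
        prob = _probs_matrix(a, b, nodes)
        m = k_n - 1
        d = np.empty((len(nodes), k_n, m + 1))
        d[:, :, 0] = nodes[:, None] * kvec[None, :]
        d[:, :, 1:] = -(kvec[:, None] >= np.arange(1, m + 1)[None, :]).astype(float)
        e_d = np.einsum("qk,qkp->qp", prob, d)
        info = np.einsum("q,qkp,qk,qkr->pr", nq, d, prob, d) - np.einsum(
            "q,qp,qr->pr", nq, e_d, e_d
        )
        info[np.diag_indices_from(info)] += 1e-9
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        row = {"item_id": iid, "se_a": se[0]}
        for v in range(m):
            row[f"se_c{v + 1}"] = se[v + 1]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fit_pcm: CalibrationResult, fit_gpcm: CalibrationResult) -> dict:
    """Likelihood-ratio test and AIC difference for PCM nested in GPCM."""
    if fit_pcm.data_fingerprint != fit_gpcm.data_fingerprint:
        raise ComparisonError("fits were not run on the same data")
    if fit_pcm.model != "PCM" or fit_gpcm.model != "GPCM":
        raise ComparisonError("expected a PCM fit and a GPCM fit, in that order")
    lr = 2.0 * (fit_gpcm.loglik - fit_pcm.loglik)
    lr = max(lr, 0.0)
    df = fit_gpcm.n_params - fit_pcm.n_params
    return {
        "lr_stat": lr,
        "df": df,
        "p": float(chi2.sf(lr, df)) if df > 0 else float("nan"),
        "delta_aic": fit_pcm.aic - fit_gpcm.aic,
    }


# ---------------------------------------------------------------------------
# posteriors shared by the diagnostics


def person_posteriors(
    fit: CalibrationResult, data: ResponseData
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(unnormalized-log, normalized posterior, EAP) per person on the grid.

    Uses each person's dataset latent density as prior and resolves any
    subgroup parameter overrides by dataset label.
    """
    nodes = fit.grid.nodes
    n = data.n_persons
    ll = np.zeros((n, len(nodes)))
    ds = np.asarray([str(d) for d in data.dataset])
    for iid in data.item_ids:
        item = fit.bank[iid]
        j = data.col(iid)
        obs = data.X[:, j] != MISSING
        if not obs.any():
            continue
        variants: dict[str | None, np.ndarray] = {None: np.ones(n, dtype=bool)}
        if item.subgroup_overrides:
            rest = np.ones(n, dtype=bool)
            variants = {}
            for g in item.subgroup_overrides:
                sel = ds == g
                variants[g] = sel
                rest &= ~sel
            variants[None] = rest
        for g, sel in variants.items():
            take = sel & obs
            if not take.any():
                continue
            a, b = item.params_for(g)
            lp = np.log(_probs_matrix(a, b, nodes))
            ll[take] += lp[:, data.X[take, j]].T
    log_prior = np.empty((n, len(nodes)))
    for g in fit.dists.means:
        sel = ds == g
        if sel.any():
            w = fit.grid.reweight_normal(fit.dists.means[g], fit.dists.sds[g])
            log_prior[sel] = np.log(w)
    known = np.isin(ds, list(fit.dists.means))
    if not known.all():
        w = fit.grid.reweight_normal(0.0, 1.0)
        log_prior[~known] = np.log(w)
    a_mat = ll + log_prior
    lse = logsumexp(a_mat, axis=1)
    post = np.exp(a_mat - lse[:, None])
    eap = post @ nodes
    return a_mat, post, eap


# ---------------------------------------------------------------------------
# LM-type DIF / item-fit tests


def _equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    bins = np.empty(len(values), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(values)) * n_bins) // max(len(values), 1), n_bins - 1
    )
    return bins


def _loo_predictive(
    fit: CalibrationResult,
    data: ResponseData,
    iid: str,
    a_mat: np.ndarray,
    ds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-item-out posterior predictive mean/variance of one item.

    Removing the item's own likelihood factor before predicting makes the
    observed-minus-expected contrast mean-zero under the fitted model, so
    the binned score statistic has a clean chi-square reference.  The
    leave-one-out EAP is returned for binning: conditioning only on the
    *other* items keeps the contrast mean-zero within bins too.
    """
    nodes = fit.grid.nodes
    item = fit.bank[iid]
    j = data.col(iid)
    obs = data.X[:, j] != MISSING
    idx = np.where(obs)[0]
    x = data.X[idx, j]
    kvec = np.arange(item.n_cat, dtype=float)

    mu = np.empty(len(idx))
    var = np.empty(len(idx))
    eap_loo = np.empty(len(idx))
    groups_here = (
        list(item.subgroup_overrides) + [None] if item.subgroup_overrides else [None]
    )
    assigned = np.zeros(len(idx), dtype=bool)
    for g in groups_here:
        if g is None:
            sel = ~assigned
        else:
            sel = (ds[idx] == g) & ~assigned
        if not sel.any():
            continue
        assigned |= sel
        a, b = item.params_for(g)
        prob = _probs_matrix(a, b, nodes)  # (Q, K)
        lp = np.log(prob)
        sub = idx[sel]
        log_loo = a_mat[sub] - lp[:, x[sel]].T
        log_loo -= logsumexp(log_loo, axis=1, keepdims=True)
        w = np.exp(log_loo)
        e_q = prob @ kvec
        v_q = prob @ kvec**2 - e_q**2
        m1 = w @ e_q
        mu[sel] = m1
        var[sel] = w @ v_q + w @ e_q**2 - m1**2
        eap_loo[sel] = w @ nodes
    return idx, mu, np.maximum(var, 1e-12), eap_loo


def _binned_stat(
    x_obs: np.ndarray, mu: np.ndarray, var: np.ndarray, bins: np.ndarray, n_bins: int
) -> tuple[float, int, float, int]:
    """Chi-square-type statistic and weighted |O - E| over bins."""
    stat = 0.0
    abs_gap = 0.0
    n_tot = 0
    used = 0
    for b in range(n_bins):
        sel = bins == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        diff = float((x_obs[sel] - mu[sel]).sum())
        v = float(var[sel].sum())
        if v <= 0:
            continue
        stat += diff * diff / v
        abs_gap += abs(diff)
        n_tot += nb
        used += 1
    es_raw = abs_gap / n_tot if n_tot else 0.0
    return stat, max(used - 1, 1), es_raw, n_tot


def lm_dif_test(
    fit: CalibrationResult,
    data: ResponseData,
    grouping: np.ndarray | Mapping[str, str] | None = None,
    alpha: float = 0.05,
    es_threshold: float = 0.05,
    n_bins: int = 4,
    min_per_group: int = 50,
) -> pd.DataFrame:
    """Per-item LM-type DIF screen across person groups.

    Within each group, respondents are binned by EAP score and the observed
    item score sums are contrasted with the model-predicted ones
    (leave-one-item-out posterior predictive).  The per-group chi-squares
    are summed into the item statistic.  ``es_dif`` is the sample-size
    weighted mean absolute observed-minus-expected item score in the worst
    group, divided by the item score range; an item is flagged only when
    the test is significant AND ``es_dif`` exceeds the threshold.
    """
    ds = np.asarray([str(d) for d in data.dataset])
    if grouping is None:
        labels = ds
    elif isinstance(grouping, Mapping):
        labels = np.asarray([str(grouping[p]) for p in data.person_ids])
    else:
        labels = np.asarray([str(g) for g in grouping])
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for a DIF test")

    a_mat, _, _ = person_posteriors(fit, data)
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for iid in data.item_ids:
        idx, mu, var, eap_loo = _loo_predictive(fit, data, iid, a_mat, ds)
        x = data.X[idx, data.col(iid)].astype(float)
        g_lab = labels[idx]
        e_lab = eap_loo
        m = fit.bank[iid].max_score
        stat_total = 0.0
        df_total = 0
        es_best = 0.0
        focal = None
        for g in uniq:
            sel = g_lab == g
            ng = int(sel.sum())
            if ng < min_per_group:
                skipped.append((iid, str(g), f"n={ng} < {min_per_group}"))
                continue
            bins = _equal_count_bins(e_lab[sel], n_bins)
            stat, df, es_raw, _ = _binned_stat(x[sel], mu[sel], var[sel], bins, n_bins)
            stat_total += stat
            df_total += df
            es_g = es_raw / m
            if es_g > es_best:
                es_best, focal = es_g, str(g)
        if df_total == 0:
            rows.append(
                dict(item_id=iid, statistic=np.nan, df=0, p=np.nan,
                     es_dif=np.nan, focal_group=None, flagged=False)
            )
            continue
        p = float(chi2.sf(stat_total, df_total))
        rows.append(
            dict(
                item_id=iid,
                statistic=stat_total,
                df=df_total,
                p=p,
                es_dif=es_best,
                focal_group=focal,
                flagged=bool(p < alpha and es_best > es_threshold),
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def item_fit_lm(
    fit: CalibrationResult,
    data: ResponseData,
    alpha: float = 0.05,
    es_threshold: float = 0.05,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Per-item fit screen: observed vs predicted scores across EAP bins."""
    ds = np.asarray([str(d) for d in data.dataset])
    a_mat, _, _ = person_posteriors(fit, data)
    rows = []
    for iid in data.item_ids:
        idx, mu, var, eap_loo = _loo_predictive(fit, data, iid, a_mat, ds)
        x = data.X[idx, data.col(iid)].astype(float)
        m = fit.bank[iid].max_score
        bins = _equal_count_bins(eap_loo, n_bins)
        stat, df, es_raw, n_used = _binned_stat(x, mu, var, bins, n_bins)
        p = float(chi2.sf(stat, df))
        es = es_raw / m
        rows.append(
            dict(
                item_id=iid,
                statistic=stat,
                df=df,
                p=p,
                es_dif=es,
                n=n_used,
                flagged=bool(p < alpha and es > es_threshold),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup parameter assignment for flagged items


def assign_group_parameters(
    fit: CalibrationResult,
    flags: pd.DataFrame,
    data: ResponseData,
    design: LinkDesign,
    opts: CalibOptions = CalibOptions(),
    grouping: np.ndarray | None = None,
) -> CalibrationResult:
    """Refit with free parameters for flagged (item, focal group) pairs.

    Each flagged item's focal-group responses are split into a virtual
    column calibrated separately (dropping the item's anchor role for that
    group), then folded back into the bank as a subgroup override.
    """
    flagged = flags[flags["flagged"]] if "flagged" in flags else flags
    if flagged.empty:
        return fit
    ds = np.asarray([str(d) for d in data.dataset])
    labels = ds if grouping is None else np.asarray([str(g) for g in grouping])

    X = data.X.copy()
    item_ids = list(data.item_ids)
    n_cat = dict(data.n_cat) if data.n_cat else {}
    new_cols = []
    new_ids = []
    split: list[tuple[str, str]] = []
    for _, row in flagged.iterrows():
        iid, g = row["item_id"], row["focal_group"]
        if g is None:
            continue
        j = data.col(iid)
        sel = (labels == g) & (X[:, j] != MISSING)
        if not sel.any():
            continue
        col = np.full(data.n_persons, MISSING, dtype=np.int16)
        col[sel] = X[sel, j]
        X[sel, j] = MISSING
        new_cols.append(col)
        vid = f"{iid}{_OVERRIDE_SEP}{g}"
        new_ids.append(vid)
        if iid in n_cat:
            n_cat[vid] = n_cat[iid]
        split.append((iid, g))
    if not new_cols:
        return fit

    keep = [j for j, iid in enumerate(item_ids) if (X[:, j] != MISSING).any()]
    kept_ids = [item_ids[j] for j in keep]
    X2 = np.concatenate([X[:, keep]] + [c[:, None] for c in new_cols], axis=1)
    ids2 = kept_ids + new_ids
    data2 = ResponseData(X2, data.person_ids, ids2, data.dataset, n_cat or None)

    incidence = dict(design.item_incidence)
    for vid, (iid, g) in zip(new_ids, split):
        col = data2.X[:, data2.col(vid)]
        incidence[vid] = frozenset(
            str(d) for d in np.unique(data.dataset[col != MISSING])
        )
    design2 = LinkDesign(
        design.datasets, design.instrument_map, incidence, design.item_instruments
    )

    refit = concurrent_calibrate(
        data2, design2, fit.model, replace(opts, init_bank=fit.bank)
    )

    merged: dict[str, ItemParams] = {}
    for iid in kept_ids:
        old = fit.bank[iid]
        new = refit.bank[iid]
        merged[iid] = ItemParams(iid, new.a, new.b, old.instrument_ids)
    for vid, (iid, g) in zip(new_ids, split):
        v = refit.bank[vid]
        if iid not in merged:  # focal group held all the item's data
            old = fit.bank[iid]
            merged[iid] = ItemParams(iid, v.a, v.b, old.instrument_ids)
        merged[iid] = merged[iid].with_override(g, v.a, v.b)
    bank = ItemBank([merged[i] for i in merged])
    return replace(
        refit,
        bank=bank,
        data_fingerprint=fit.data_fingerprint,
    )


# ---------------------------------------------------------------------------
# Yen's Q3 local dependence


def q3_matrix(
    fit: CalibrationResult,
    data: ResponseData,
    threshold: float = 0.25,
    min_overlap: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Residual correlations (Yen's Q3) and flagged item pairs.

    Residual = observed score minus expected score at the person's EAP;
    correlations use pairwise-complete persons.  Pairs with overlap below
    ``min_overlap`` are set missing.  Returns (q3, flags, overlap_n).
    """
    _, _, eap = person_posteriors(fit, data)
    ds = np.asarray([str(d) for d in data.dataset])
    resid = np.full(data.X.shape, np.nan)
    kmax = max(it.n_cat for it in fit.bank)
    for iid in data.item_ids:
        item = fit.bank[iid]
        j = data.col(iid)
        obs = data.X[:, j] != MISSING
        if not obs.any():
            continue
        if item.subgroup_overrides:
            exp_score = np.empty(int(obs.sum()))
            sub_ds = ds[obs]
            theta = eap[obs]
            done = np.zeros(len(exp_score), dtype=bool)
            for g in list(item.subgroup_overrides) + [None]:
                sel = (sub_ds == g) & ~done if g is not None else ~done
                if sel.any():
                    a, b = item.params_for(g)
                    k = np.arange(item.n_cat)
                    exp_score[sel] = _probs_matrix(a, b, theta[sel]) @ k
                    done |= sel
        else:
            a, b = item.params_for(None)
            k = np.arange(item.n_cat)
            exp_score = _probs_matrix(a, b, eap[obs]) @ k
        resid[obs, j] = data.X[obs, j] - exp_score
    rf = pd.DataFrame(resid, columns=data.item_ids)
    q3 = rf.corr(min_periods=min_overlap)
    overlap = rf.notna().astype(int).T @ rf.notna().astype(int)
    flags = []
    ids = data.item_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = q3.iloc[i, j]
            if np.isfinite(v) and abs(v) > threshold:
                flags.append(
                    dict(item_1=ids[i], item_2=ids[j], q3=float(v),
                         n=int(overlap.iloc[i, j]))
                )
    return q3, pd.DataFrame(flags, columns=["item_1", "item_2", "q3", "n"]), overlap
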