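"""EAP scoring, the standardized reporting metric, reliability and
score-level summaries.

The standardized metric is an affine rescaling of the logit scale:
``S = 10 * (theta - theta0)``, where ``theta0`` (the bank's scale origin)
is the highest latent value at which every instrument's expected mean item
score is still essentially zero — so 0 marks the measurable floor and ten
metric points correspond to one logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .core import (
    ItemBank,
    QuadGrid,
    _probs_matrix,
    item_information,
)
from .data import MISSING, ResponseData


class MetricError(RuntimeError):
    """Raised when the metric origin is required but unset."""


class EapScore(NamedTuple):
    theta: float
    se: float
    all_missing: bool


def eap_score(
    bank: ItemBank,
    pattern: Mapping[str, int],
    prior: tuple[float, float] = (0.0, 1.0),
    grid: QuadGrid | None = None,
    group: str | None = None,
) -> EapScore:
    """Posterior mean and SD of theta for one response pattern.

    ``pattern`` maps item ids to observed categories; items missing from
    the mapping are ignored.  An all-missing pattern returns the prior
    moments with ``all_missing=True``.
    """
    grid = grid or QuadGrid.equally_spaced()
    nodes = grid.nodes
    log_post = np.log(grid.reweight_normal(*prior))
    any_obs = False
    for iid, x in pattern.items():
        if x is None or x == MISSING:
            continue
        item = bank[iid]
        if not 0 <= int(x) < item.n_cat:
            raise ValueError(
                f"category {x} invalid for item {iid!r} with {item.n_cat} categories"
            )
        a, b = item.params_for(group)
        log_post += np.log(_probs_matrix(a, b, nodes))[:, int(x)]
        any_obs = True
    if not any_obs:
        return EapScore(prior[0], prior[1], True)
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()
    mean = float(w @ nodes)
    var = float(w @ nodes**2) - mean**2
    return EapScore(mean, float(np.sqrt(max(var, 0.0))), False)


def eap_scores(
    bank: ItemBank,
    data: ResponseData,
    item_ids: Sequence[str] | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
    grid: QuadGrid | None = None,
) -> pd.DataFrame:
    """Vectorized EAP over all persons; columns theta, se, n_items_answered."""
    grid = grid or QuadGrid.equally_spaced()
    nodes = grid.nodes
    ids = list(item_ids) if item_ids is not None else list(data.item_ids)
    n = data.n_persons
    log_post = np.tile(np.log(grid.reweight_normal(*prior)), (n, 1))
    n_answered = np.zeros(n, dtype=int)
    for iid in ids:
        item = bank[iid]
        j = data.col(iid)
        obs = data.X[:, j] != MISSING
        if not obs.any():
            continue
        a, b = item.params_for(None)
        lp = np.log(_probs_matrix(a, b, nodes))
        log_post[obs] += lp[:, data.X[obs, j]].T
        n_answered += obs
    log_post -= log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post)
    w /= w.sum(axis=1, keepdims=True)
    mean = w @ nodes
    var = np.maximum(w @ nodes**2 - mean**2, 0.0)
    return pd.DataFrame(
        {
            "person_id": data.person_ids,
            "theta": mean,
            "se": np.sqrt(var),
            "n_items_answered": n_answered,
        }
    )


# ---------------------------------------------------------------------------
# standardized metric


def locate_metric_origin(
    bank: ItemBank, epsilon: float = 0.01, grid: QuadGrid | None = None
) -> float:
    """Set the bank's metric origin theta0.

    theta0 is the largest grid value at which every instrument's expected
    *mean* item score is still <= epsilon.  The expected score approaches 0
    only asymptotically, so epsilon = 0 falls back to the grid floor with a
    warning.
    """
    grid = grid or QuadGrid.equally_spaced()
    nodes = grid.nodes
    instruments = bank.instrument_ids
    if not instruments:
        raise MetricError("bank has no instrument memberships")
    worst = np.zeros(len(nodes))
    for ins in instruments:
        items = bank.instrument_items(ins)
        mean_score = np.zeros(len(nodes))
        for it in items:
            k = np.arange(it.n_cat)
            mean_score += _probs_matrix(it.a, np.asarray(it.b), nodes) @ k
        mean_score /= len(items)
        worst = np.maximum(worst, mean_score)
    ok = worst <= epsilon
    if not ok.any():
        warnings.warn(
            f"expected mean item score never <= {epsilon} on the grid; "
            "using the grid floor as metric origin",
            RuntimeWarning,
        )
        theta0 = float(nodes[0])
    else:
        theta0 = float(nodes[np.nonzero(ok)[0].max()])
    bank.scale_origin_theta = theta0
    return theta0


def standardize_score(theta: float | np.ndarray, bank: ItemBank) -> float | np.ndarray:
    """S = 10 * (theta - theta0): ten metric points per logit."""
    if bank.scale_origin_theta is None:
        raise MetricError("metric origin not set; run locate_metric_origin first")
    out = 10.0 * (np.asarray(theta, dtype=float) - bank.scale_origin_theta)
    return float(out) if np.ndim(theta) == 0 else out


# ---------------------------------------------------------------------------
# reliability


def marginal_reliability(scores: pd.DataFrame) -> float:
    """var(theta_hat) / (var(theta_hat) + mean(se^2)) over scored persons."""
    if len(scores) < 2:
        raise ValueError("need >= 2 scored persons")
    v = float(np.var(scores["theta"], ddof=1))
    e = float(np.mean(scores["se"] ** 2))
    if v + e <= 0:
        warnings.warn("degenerate score variance; reliability set to 0", RuntimeWarning)
        return 0.0
    return v / (v + e)


@dataclass
class ConditionalReliability:
    thetas: np.ndarray
    cr: np.ndarray
    theta_range: tuple[float, float] | None
    standardized_range: tuple[float, float] | None


def conditional_reliability(
    bank: ItemBank,
    instrument_id: str,
    grid: QuadGrid | None = None,
    threshold: float = 0.70,
) -> ConditionalReliability:
    """CR(theta) = I(theta) / (I(theta) + 1) with summed item information."""
    grid = grid or QuadGrid.equally_spaced()
    nodes = grid.nodes
    info = np.zeros(len(nodes))
    for it in bank.instrument_items(instrument_id):
        info += np.asarray(item_information(it, nodes))
    cr = info / (info + 1.0)
    above = np.nonzero(cr > threshold)[0]
    theta_range = None
    std_range = None
    if above.size:
        theta_range = (float(nodes[above.min()]), float(nodes[above.max()]))
        if bank.scale_origin_theta is not None:
            std_range = (
                float(standardize_score(theta_range[0], bank)),
                float(standardize_score(theta_range[1], bank)),
            )
    return ConditionalReliability(nodes, cr, theta_range, std_range)


def cronbach_alpha(data: ResponseData, item_ids: Sequence[str]) -> float:
    sub = data.subset_items(list(item_ids))
    x = sub.X.astype(float)
    x[x == MISSING] = np.nan
    complete = ~np.isnan(x).any(axis=1)
    x = x[complete]
    p = x.shape[1]
    s = np.cov(x, rowvar=False)
    return p / (p - 1) * (1.0 - np.trace(s) / s.sum())


def glb_reliability(
    data: ResponseData, item_ids: Sequence[str], min_n: int = 50
) -> float:
    """Greatest-lower-bound reliability, factor-analytic approximation.

    Iterates communality substitution on the observed covariance diagonal:
    the diagonal is replaced by common variance from a factor decomposition
    until stable; GLB = 1 - unique variance / total variance.
    """
    ids = list(item_ids)
    if len(ids) < 2:
        raise ValueError("GLB undefined for a single item")
    sub = data.subset_items(ids)
    x = sub.X.astype(float)
    x[x == MISSING] = np.nan
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < min_n:
        raise ValueError(
            f"only {int(complete.sum())} complete cases; need >= {min_n}"
        )
    s = np.cov(x[complete], rowvar=False)
    p = s.shape[0]
    vt = float(s.sum())
    nf = max(1, p // 2)
    h = np.diag(s).copy() * 0.9
    for _ in range(200):
        c = s.copy()
        np.fill_diagonal(c, h)
        vals, vecs = np.linalg.eigh(c)
        vals, vecs = vals[::-1][:nf], vecs[:, ::-1][:, :nf]
        lam = vecs * np.sqrt(np.clip(vals, 0.0, None))
        h_new = np.minimum((lam**2).sum(axis=1), np.diag(s))
        if np.max(np.abs(h_new - h)) < 1e-8:
            h = h_new
            break
        h = h_new
    glb = 1.0 - float((np.diag(s) - h).sum()) / vt
    return float(np.clip(glb, 0.0, 1.0))


# ---------------------------------------------------------------------------
# score-level correlations


def rescale_summed(
    pattern: Mapping[str, int], bank: ItemBank, instrument_id: str
) -> float:
    """Summed score rescaled to 0-100; requires a complete pattern."""
    items = bank.instrument_items(instrument_id)
    max_sum = sum(it.max_score for it in items)
    if max_sum == 0:
        raise ValueError(f"instrument {instrument_id!r} has zero score range")
    total = 0
    for it in items:
        x = pattern.get(it.item_id, MISSING)
        if x is None or x == MISSING:
            raise ValueError(
                f"missing response for {it.item_id!r}; person must be excluded"
            )
        total += int(x)
    return 100.0 * total / max_sum


def _summed_scores(data: ResponseData, ids: list[str]) -> np.ndarray:
    """Summed score per person; NaN unless complete on the given items."""
    x = data.X[:, [data.col(i) for i in ids]].astype(float)
    x[x == MISSING] = np.nan
    out = x.sum(axis=1)
    out[np.isnan(x).any(axis=1)] = np.nan
    return out


def score_correlations(
    data: ResponseData,
    bank: ItemBank,
    scales: Mapping[str, Sequence[str]] | None = None,
    grid: QuadGrid | None = None,
) -> dict:
    """Observed-vs-EAP correlation per scale and overlap-corrected
    between-scale summed-score correlations.

    The IRT score is the EAP from the person's *full* response pattern, so
    a short scale's summed score can correlate noticeably lower with it.
    Shared items are excluded from the larger member of each overlapping
    pair before correlating; fully nested pairs are labeled ``nested`` and
    left uncorrected.
    """
    if scales is None:
        scales = {ins: [it.item_id for it in bank.instrument_items(ins)]
                  for ins in bank.instrument_ids}
    scales = {k: list(v) for k, v in scales.items()}
    names = list(scales)
    scorable = [i for i in data.item_ids if i in bank]
    eap = eap_scores(bank, data, scorable, grid=grid)["theta"].to_numpy()
    obs_irt = {}
    for name, ids in scales.items():
        summed = _summed_scores(data, ids)
        ok = ~np.isnan(summed)
        obs_irt[name] = (
            float(np.corrcoef(summed[ok], eap[ok])[0, 1]) if ok.sum() > 2 else np.nan
        )
    inter = pd.DataFrame(index=names, columns=names, dtype=float)
    notes = pd.DataFrame("", index=names, columns=names, dtype=object)
    for s1, s2 in combinations(names, 2):
        i1, i2 = set(scales[s1]), set(scales[s2])
        shared = i1 & i2
        if i1 <= i2 or i2 <= i1:
            notes.loc[s1, s2] = notes.loc[s2, s1] = "nested"
            continue
        use1, use2 = list(scales[s1]), list(scales[s2])
        if shared:
            if len(use1) >= len(use2):
                use1 = [i for i in use1 if i not in shared]
            else:
                use2 = [i for i in use2 if i not in shared]
            notes.loc[s1, s2] = notes.loc[s2, s1] = f"excluded {len(shared)} shared"
        a = _summed_scores(data, use1)
        b = _summed_scores(data, use2)
        ok = ~np.isnan(a) & ~np.isnan(b)
        r = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 2 else np.nan
        inter.loc[s1, s2] = inter.loc[s2, s1] = r
    return {"observed_irt": obs_irt, "inter_scale": inter, "notes": notes}


# ---------------------------------------------------------------------------
# congruence of instrument-level scores


def _paired_test(d: np.ndarray) -> tuple[float, float]:
    """Paired t-test p-value and Cohen's d (mean diff / SD of diffs)."""
    d = d[~np.isnan(d)]
    n = len(d)
    if n < 2:
        return np.nan, np.nan
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return (1.0, 0.0)
    t_stat = float(np.mean(d)) / (sd / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 1))
    return p, float(np.mean(d)) / sd


@dataclass
class CongruenceReport:
    instrument_stats: pd.DataFrame
    irt_pairs: pd.DataFrame
    summed_pairs: pd.DataFrame
    alpha: float
    n_comparisons: int


def congruence_report(
    data: ResponseData,
    bank: ItemBank,
    instruments: Sequence[str],
    alpha: float = 0.05,
    grid: QuadGrid | None = None,
) -> CongruenceReport:
    """Compare per-instrument standardized IRT scores and 0-100 summed
    scores across instruments answered by the same persons.

    All pairwise paired t-tests are Bonferroni-corrected within each
    scoring method; effect size is paired Cohen's d.
    """
    if len(instruments) < 2:
        raise ValueError("need >= 2 instruments to compare")
    std_scores = {}
    summed = {}
    for ins in instruments:
        ids = [it.item_id for it in bank.instrument_items(ins)]
        sc = eap_scores(bank, data, ids, grid=grid)
        theta = sc["theta"].to_numpy()
        answered = sc["n_items_answered"].to_numpy() > 0
        s = np.asarray(standardize_score(theta, bank), dtype=float)
        s[~answered] = np.nan
        std_scores[ins] = s
        max_sum = sum(bank[i].max_score for i in ids)
        raw = _summed_scores(data, ids)
        summed[ins] = 100.0 * raw / max_sum

    n_answered = np.sum(
        [~np.isnan(std_scores[ins]) for ins in instruments], axis=0
    )
    usable = n_answered >= 2
    pairs = list(combinations(instruments, 2))
    n_comp = len(pairs)

    stats_rows = []
    for ins in instruments:
        sv = std_scores[ins][usable]
        rv = summed[ins][usable]
        stats_rows.append(
            dict(
                instrument=ins,
                n_irt=int(np.sum(~np.isnan(sv))),
                irt_mean=float(np.nanmean(sv)),
                irt_sd=float(np.nanstd(sv, ddof=1)),
                n_summed=int(np.sum(~np.isnan(rv))),
                summed_mean=float(np.nanmean(rv)) if np.any(~np.isnan(rv)) else np.nan,
                summed_sd=float(np.nanstd(rv, ddof=1)) if np.sum(~np.isnan(rv)) > 1 else np.nan,
            )
        )

    def pair_table(scores: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = []
        for s1, s2 in pairs:
            d = (scores[s1] - scores[s2])[usable]
            p, eff = _paired_test(d)
            rows.append(
                dict(
                    instrument_1=s1,
                    instrument_2=s2,
                    n=int(np.sum(~np.isnan(d))),
                    mean_diff=float(np.nanmean(d)) if np.any(~np.isnan(d)) else np.nan,
                    p_raw=p,
                    p_bonferroni=min(1.0, p * n_comp) if np.isfinite(p) else np.nan,
                    cohen_d=eff,
                )
            )
        return pd.DataFrame(rows)

    return CongruenceReport(
        instrument_stats=pd.DataFrame(stats_rows),
        irt_pairs=pair_table(std_scores),
        summed_pairs=pair_table(summed),
        alpha=alpha,
        n_comparisons=n_comp,
    )
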