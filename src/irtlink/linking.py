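"""Stocking-Lord characteristic-curve linking.

Finds slope ``A`` and shift ``B`` placing an externally calibrated (source)
bank on the target scale: transformed source items get ``a/A`` and
``A*b + B``, chosen so the common items' scale characteristic curves match
the target's over a weighted latent grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import ItemBank, ItemParams, QuadGrid, _probs_matrix


class NoCommonItemsError(ValueError):
    pass


@dataclass(frozen=True)
class LinkCoefficients:
    A: float
    B: float
    objective_value: float
    grid: QuadGrid

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("slope A must be positive")

    def inverse(self) -> "LinkCoefficients":
        return LinkCoefficients(1.0 / self.A, -self.B / self.A, np.nan, self.grid)


def _common_item_ids(
    source: ItemBank, target: ItemBank, common: str | list[str]
) -> list[str]:
    if isinstance(common, str):
        ids = [
            it.item_id for it in source if common in it.instrument_ids
        ]
        ids = [i for i in ids if i in target]
    else:
        ids = [i for i in common if i in source and i in target]
    if not ids:
        raise NoCommonItemsError("no common items shared by both banks")
    for iid in ids:
        if source[iid].n_cat != target[iid].n_cat:
            raise NoCommonItemsError(
                f"common item {iid!r} has different category counts in the two banks"
            )
    return ids


def _scc(items: list[ItemParams], thetas: np.ndarray) -> np.ndarray:
    total = np.zeros(len(thetas))
    for it in items:
        k = np.arange(it.n_cat)
        total += _probs_matrix(it.a, np.asarray(it.b), thetas) @ k
    return total


def stocking_lord(
    source_bank: ItemBank,
    target_bank: ItemBank,
    common: str | list[str],
    grid: QuadGrid | None = None,
) -> LinkCoefficients:
    """Minimize the weighted squared gap between common-item SCCs.

    ``common`` is either an instrument id or an explicit list of item ids.
    The grid's weights (default: standard-normal density on the default
    support) weight the squared SCC differences; the optimum is found by
    bounded quasi-Newton from a small multistart.
    """
    grid = grid or QuadGrid.normal(0.0, 1.0)
    ids = _common_item_ids(source_bank, target_bank, common)
    src = [source_bank[i] for i in ids]
    tgt = [target_bank[i] for i in ids]
    thetas = grid.nodes
    w = grid.weights
    scc_target = _scc(tgt, thetas)

    def objective(x: np.ndarray) -> float:
        a_, b_ = x
        # transformed source evaluated at theta equals source SCC at (theta-B)/A
        scc_src = _scc(src, (thetas - b_) / a_)
        return float(np.sum(w * (scc_target - scc_src) ** 2))

    best = None
    bounds = [(1e-3, 1e3), (-20.0, 20.0)]
    for a0 in (0.5, 1.0, 2.0):
        for b0 in (-1.0, 0.0, 1.0):
            res = minimize(
                objective,
                np.array([a0, b0]),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-15, "gtol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
    a_opt, b_opt = best.x
    if np.isclose(a_opt, bounds[0][0]) or np.isclose(a_opt, bounds[0][1]):
        warnings.warn(f"Stocking-Lord slope hit its bound: A={a_opt}", RuntimeWarning)
    return LinkCoefficients(float(a_opt), float(b_opt), float(best.fun), grid)


def apply_transform(bank: ItemBank, coeffs: LinkCoefficients) -> ItemBank:
    """Rescale every item (and its overrides): a* = a/A, b* = A*b + B."""
    a_c, b_c = coeffs.A, coeffs.B
    items = []
    for it in bank:
        ov = {
            g: (a_g / a_c, tuple(a_c * np.asarray(b_g) + b_c))
            for g, (a_g, b_g) in it.subgroup_overrides.items()
        }
        items.append(
            ItemParams(
                it.item_id,
                it.a / a_c,
                tuple(a_c * np.asarray(it.b) + b_c),
                it.instrument_ids,
                ov,
            )
        )
    origin = bank.scale_origin_theta
    if origin is not None:
        origin = a_c * origin + b_c
    return ItemBank(items, origin)
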