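"""Partial-credit / generalized partial-credit model primitives.

Category probabilities, expected item scores, item information, scale
characteristic curves (SCC) and their inverses, for ordered polytomous
items parameterized as ``a * (theta - b_v)`` step terms.  Step difficulties
are kept in step order and are *not* required to be sorted: disordered
steps are a legitimate GPCM configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

#: Default latent-trait support for every grid operation.
THETA_LO: float = -8.0
THETA_HI: float = 8.0
DEFAULT_N_NODES: int = 61


class InvalidParameterError(ValueError):
    """Raised for inadmissible item parameters (e.g. non-positive slope)."""


class UnknownInstrumentError(KeyError):
    """Raised when an instrument id is not present in a bank."""


@dataclass(frozen=True)
class ItemParams:
    """One item's GPCM parameters on the logit scale.

    Parameters
    ----------
    item_id:
        Unique identifier.
    a:
        Discrimination, must be positive.
    b:
        Step difficulties ``b_1..b_m``; the item has ``m + 1`` categories
        scored ``0..m``.
    instrument_ids:
        Instruments (scales) this item belongs to.
    subgroup_overrides:
        Optional per-group replacement parameters ``{group: (a, b)}`` for
        items that function differently in a subgroup.
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    instrument_ids: frozenset[str] = frozenset()
    subgroup_overrides: Mapping[str, tuple[float, tuple[float, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.a <= 0 or not np.isfinite(self.a):
            raise InvalidParameterError(
                f"item {self.item_id!r}: discrimination must be positive, got {self.a}"
            )
        if len(self.b) < 1:
            raise InvalidParameterError(
                f"item {self.item_id!r}: at least one step difficulty required"
            )
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        object.__setattr__(self, "instrument_ids", frozenset(self.instrument_ids))
        for g, (a_g, b_g) in self.subgroup_overrides.items():
            if a_g <= 0:
                raise InvalidParameterError(
                    f"item {self.item_id!r}, group {g!r}: override slope must be positive"
                )
            if len(b_g) != len(self.b):
                raise InvalidParameterError(
                    f"item {self.item_id!r}, group {g!r}: override step count mismatch"
                )

    @property
    def n_cat(self) -> int:
        return len(self.b) + 1

    @property
    def max_score(self) -> int:
        return len(self.b)

    def params_for(self, group: str | None) -> tuple[float, np.ndarray]:
        """Resolve (a, b) for ``group``: exact-label override or the default."""
        if group is not None and group in self.subgroup_overrides:
            a_g, b_g = self.subgroup_overrides[group]
            return float(a_g), np.asarray(b_g, dtype=float)
        return float(self.a), np.asarray(self.b, dtype=float)

    def with_override(
        self, group: str, a: float, b: Sequence[float]
    ) -> "ItemParams":
        ov = dict(self.subgroup_overrides)
        ov[group] = (float(a), tuple(float(v) for v in b))
        return ItemParams(self.item_id, self.a, self.b, self.instrument_ids, ov)


@dataclass
class ItemBank:
    """A collection of calibrated items plus the metric origin ``theta0``."""

    items: list[ItemParams]
    scale_origin_theta: float | None = None

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidParameterError(f"duplicate item ids in bank: {dupes}")
        self._by_id = {it.item_id: it for it in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParams:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def instrument_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            for ins in sorted(it.instrument_ids):
                seen.setdefault(ins)
        return list(seen)

    def instrument_items(self, instrument_id: str) -> list[ItemParams]:
        found = [it for it in self.items if instrument_id in it.instrument_ids]
        if not found:
            raise UnknownInstrumentError(instrument_id)
        return found

    def replace_items(self, items: Iterable[ItemParams]) -> "ItemBank":
        return ItemBank(list(items), self.scale_origin_theta)


@dataclass(frozen=True)
class QuadGrid:
    """Quadrature nodes and normalized weights on the latent scale."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing 1-d")
        if np.any(weights < 0) or weights.shape != nodes.shape:
            raise ValueError("weights must be nonnegative, same shape as nodes")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def equally_spaced(
        cls,
        lo: float = THETA_LO,
        hi: float = THETA_HI,
        n: int = DEFAULT_N_NODES,
    ) -> "QuadGrid":
        nodes = np.linspace(lo, hi, n)
        return cls(nodes, np.full(n, 1.0 / n))

    @classmethod
    def normal(
        cls,
        mean: float = 0.0,
        sd: float = 1.0,
        lo: float = THETA_LO,
        hi: float = THETA_HI,
        n: int = DEFAULT_N_NODES,
    ) -> "QuadGrid":
        nodes = np.linspace(lo, hi, n)
        w = np.exp(-0.5 * ((nodes - mean) / sd) ** 2)
        return cls(nodes, w)

    def reweight_normal(self, mean: float, sd: float) -> np.ndarray:
        """Normalized normal density weights at the existing nodes."""
        w = np.exp(-0.5 * ((self.nodes - mean) / sd) ** 2)
        return w / w.sum()


# ---------------------------------------------------------------------------
# model functions


def _probs_matrix(a: float, b: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """GPCM category probabilities, shape (len(thetas), m + 1).

    P(X=k | theta) = exp(sum_{v<=k} a (theta - b_v)) / normalizer, with the
    empty sum for k = 0.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    m = b.shape[0]
    k = np.arange(m + 1)
    cum_b = np.concatenate([[0.0], np.cumsum(b)])
    # z_{qk} = a * (k * theta_q - sum_{v<=k} b_v)
    z = a * (np.outer(thetas, k) - cum_b[None, :])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def gpcm_category_probs(
    item: ItemParams, theta: float | np.ndarray, group: str | None = None
) -> np.ndarray:
    """Category probabilities for one item at one or more latent values.

    Returns shape ``(n_cat,)`` for scalar ``theta``, else ``(n_theta, n_cat)``.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    a, b = item.params_for(group)
    out = _probs_matrix(a, b, theta_arr)
    return out[0] if theta_arr.ndim == 0 else out


def expected_item_score(
    item: ItemParams, theta: float | np.ndarray, group: str | None = None
) -> float | np.ndarray:
    """E[X | theta] = sum_k k P_k(theta); lies in [0, m], nondecreasing."""
    p = gpcm_category_probs(item, theta, group)
    k = np.arange(item.n_cat)
    out = p @ k
    return float(out) if np.ndim(out) == 0 else out


def item_information(
    item: ItemParams, theta: float | np.ndarray, group: str | None = None
) -> float | np.ndarray:
    """Fisher information a^2 * Var(X | theta) for the GPCM."""
    a, _ = item.params_for(group)
    p = gpcm_category_probs(item, theta, group)
    k = np.arange(item.n_cat)
    mean = p @ k
    var = p @ (k**2) - mean**2
    out = a**2 * var
    return float(out) if np.ndim(out) == 0 else out


def scale_characteristic(
    bank: ItemBank,
    instrument_id: str,
    theta: float | np.ndarray,
    group: str | None = None,
) -> float | np.ndarray:
    """Expected summed score of an instrument at ``theta`` (the SCC)."""
    items = bank.instrument_items(instrument_id)
    total = sum(np.asarray(expected_item_score(it, theta, group)) for it in items)
    return float(total) if np.ndim(theta) == 0 else np.asarray(total)


class SccInverse(NamedTuple):
    theta: float
    at_boundary: bool


def invert_scc(
    bank: ItemBank,
    instrument_id: str,
    summed_score: float,
    group: str | None = None,
    lo: float = THETA_LO,
    hi: float = THETA_HI,
) -> SccInverse:
    """Latent value whose expected summed score equals ``summed_score``.

    Monotone root find on ``[lo, hi]``.  Scores at or beyond what the SCC
    attains on the interval return the endpoint with ``at_boundary=True``.
    """
    items = bank.instrument_items(instrument_id)
    max_sum = float(sum(it.max_score for it in items))
    if not 0.0 <= summed_score <= max_sum:
        raise ValueError(
            f"summed score {summed_score} outside [0, {max_sum}] for {instrument_id!r}"
        )

    def f(t: float) -> float:
        return float(scale_characteristic(bank, instrument_id, t, group)) - summed_score

    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0.0:
        return SccInverse(lo, True)
    if f_hi <= 0.0:
        return SccInverse(hi, True)
    root = brentq(f, lo, hi, xtol=1e-10)
    return SccInverse(float(root), False)


def bank_to_dict(bank: ItemBank) -> dict:
    """JSON-ready representation of a bank (see :mod:`irtlink.io`)."""
    return {
        "scale_origin_theta": bank.scale_origin_theta,
        "items": [
            {
                "item_id": it.item_id,
                "instrument_ids": sorted(it.instrument_ids),
                "a": it.a,
                "b": list(it.b),
                "subgroup_overrides": {
                    g: {"a": a_g, "b": list(b_g)}
                    for g, (a_g, b_g) in sorted(it.subgroup_overrides.items())
                },
            }
            for it in bank.items
        ],
    }


def bank_from_dict(payload: Mapping) -> ItemBank:
    items = [
        ItemParams(
            item_id=rec["item_id"],
            a=rec["a"],
            b=tuple(rec["b"]),
            instrument_ids=frozenset(rec.get("instrument_ids", ())),
            subgroup_overrides={
                g: (ov["a"], tuple(ov["b"]))
                for g, ov in rec.get("subgroup_overrides", {}).items()
            },
        )
        for rec in payload["items"]
    ]
    return ItemBank(items, payload.get("scale_origin_theta"))
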