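"""Synthetic multi-dataset, multi-instrument response generation.

Emulates a common-item linking design: several datasets, each administering
a subset of instruments, connected through anchor instruments that appear
in more than one dataset.  Supports dataset-specific latent distributions,
uniform DIF injection, testlet local dependence, sparse extreme categories
and MCAR missingness.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import ItemBank, ItemParams, _probs_matrix
from .data import MISSING, ResponseData


class DesignError(ValueError):
    """Raised when a linking design cannot be connected."""


class DegenerateItemError(ValueError):
    """Raised when category collapsing leaves an item with < 2 categories."""


@dataclass(frozen=True)
class LinkDesign:
    """Dataset x instrument x item incidence of a common-item design.

    The bipartite dataset-item graph must be connected: every pair of
    datasets is joined through a chain of shared (anchor) items.
    """

    datasets: tuple[str, ...]
    instrument_map: Mapping[str, frozenset[str]]
    item_incidence: Mapping[str, frozenset[str]]
    item_instruments: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "datasets", tuple(self.datasets))
        object.__setattr__(
            self,
            "instrument_map",
            {d: frozenset(v) for d, v in self.instrument_map.items()},
        )
        object.__setattr__(
            self,
            "item_incidence",
            {i: frozenset(v) for i, v in self.item_incidence.items()},
        )
        object.__setattr__(
            self,
            "item_instruments",
            {i: frozenset(v) for i, v in self.item_instruments.items()},
        )
        self.require_connected()

    def require_connected(self) -> None:
        if len(self.datasets) < 2:
            return
        # union datasets that share at least one item
        adj: dict[str, set[str]] = {d: set() for d in self.datasets}
        for ds in self.item_incidence.values():
            ds = sorted(ds)
            for d in ds[1:]:
                adj[ds[0]].add(d)
                adj[d].add(ds[0])
        seen = {self.datasets[0]}
        stack = [self.datasets[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.datasets):
            missing = sorted(set(self.datasets) - seen)
            raise DesignError(
                f"linking design is not connected; unreachable datasets: {missing}"
            )

    def items_for_dataset(self, dataset: str) -> list[str]:
        return sorted(i for i, ds in self.item_incidence.items() if dataset in ds)

    @classmethod
    def from_instrument_map(
        cls,
        instrument_map: Mapping[str, set[str]],
        item_instruments: Mapping[str, set[str]],
    ) -> "LinkDesign":
        datasets = tuple(instrument_map)
        incidence = {
            item: frozenset(
                d for d in datasets if instrument_map[d] & set(instrs)
            )
            for item, instrs in item_instruments.items()
        }
        return cls(datasets, dict(instrument_map), incidence, dict(item_instruments))


@dataclass(frozen=True)
class GroupDist:
    """Per-dataset latent normal distributions; the reference is N(0, 1)."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    reference_group: str

    def __post_init__(self) -> None:
        if self.reference_group not in self.means:
            raise ValueError(f"reference group {self.reference_group!r} unknown")
        if (
            self.means[self.reference_group] != 0.0
            or self.sds[self.reference_group] != 1.0
        ):
            raise ValueError("reference group must be exactly N(0, 1)")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("latent SDs must be positive")

    @classmethod
    def standard(cls, datasets: Sequence[str]) -> "GroupDist":
        return cls({d: 0.0 for d in datasets}, {d: 1.0 for d in datasets}, datasets[0])


@dataclass(frozen=True)
class DifSpec:
    item_id: str
    focal_group: str
    shift: float  # added to every step difficulty in the focal group


@dataclass(frozen=True)
class TestletSpec:
    item_ids: tuple[str, ...]
    loading: float  # gamma: theta_eff = theta + gamma * u, u ~ N(0,1) shared


@dataclass(frozen=True)
class SimSpec:
    """Everything needed to generate a linked multi-dataset study."""

    n_datasets: int = 5
    n_instruments: int = 6
    items_per_instrument: int | tuple[int, ...] = 8
    n_cat_range: tuple[int, int] = (3, 5)
    instruments_per_dataset: tuple[int, int] = (2, 4)
    n_per_dataset: int | Mapping[str, int] = 500
    a_log_mean: float = 0.0
    a_log_sd: float = 0.25
    b_range: tuple[float, float] = (-2.0, 2.0)
    b_step_gap: float = 0.7
    b_jitter: float = 0.15
    group_mean_range: tuple[float, float] = (-0.5, 0.5)
    group_sd_range: tuple[float, float] = (0.8, 1.2)
    dif: tuple[DifSpec, ...] = ()
    testlets: tuple[TestletSpec, ...] = ()
    missing_rate: float = 0.0
    sparse_extremes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for d in self.dif:
            if not np.isfinite(d.shift):
                raise ValueError("DIF shift must be finite")
        for t in self.testlets:
            if not np.isfinite(t.loading):
                raise ValueError("testlet loading must be finite")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _instrument_names(spec: SimSpec) -> list[str]:
    return [f"Q{k:02d}" for k in range(spec.n_instruments)]


def _items_per(spec: SimSpec) -> list[int]:
    if isinstance(spec.items_per_instrument, int):
        return [spec.items_per_instrument] * spec.n_instruments
    counts = list(spec.items_per_instrument)
    if len(counts) != spec.n_instruments:
        raise ValueError("items_per_instrument length mismatch")
    return counts


def _item_names(spec: SimSpec) -> dict[str, list[str]]:
    return {
        ins: [f"{ins}_i{j:02d}" for j in range(cnt)]
        for ins, cnt in zip(_instrument_names(spec), _items_per(spec))
    }


def generate_link_design(spec: SimSpec) -> LinkDesign:
    """Assign instruments to datasets so the anchor graph is connected.

    Dataset ``d`` (d >= 1) always shares one anchor instrument with dataset
    ``d - 1`` (a chain), then extra instruments are dealt round-robin up to
    the requested instruments-per-dataset range.
    """
    if spec.n_datasets < 2:
        raise DesignError("need at least 2 datasets to link")
    lo, hi = spec.instruments_per_dataset
    if lo < 1 or hi < lo:
        raise DesignError("invalid instruments_per_dataset range")
    if spec.n_instruments < spec.n_datasets - 1:
        raise DesignError("too few instruments to chain all datasets")
    rng = spec.rng(0)
    instruments = _instrument_names(spec)
    datasets = [f"D{d}" for d in range(spec.n_datasets)]
    imap: dict[str, set[str]] = {d: set() for d in datasets}
    # chain anchors: instrument k links dataset k and k+1
    for d in range(spec.n_datasets - 1):
        anchor = instruments[d % spec.n_instruments]
        imap[datasets[d]].add(anchor)
        imap[datasets[d + 1]].add(anchor)
    # top up with remaining instruments, round-robin with random start
    remaining = [i for i in instruments if not any(i in s for s in imap.values())]
    order = list(rng.permutation(len(datasets)))
    targets = {d: int(rng.integers(lo, hi + 1)) for d in datasets}
    pos = 0
    for ins in remaining:
        placed = False
        for _ in range(len(datasets)):
            d = datasets[order[pos % len(datasets)]]
            pos += 1
            if len(imap[d]) < targets[d]:
                imap[d].add(ins)
                placed = True
                break
        if not placed:  # everyone at target: give it to the emptiest dataset
            d = min(datasets, key=lambda dd: len(imap[dd]))
            imap[d].add(ins)
    item_instruments = {
        item: {ins} for ins, items in _item_names(spec).items() for item in items
    }
    return LinkDesign.from_instrument_map(imap, item_instruments)


def generate_bank(spec: SimSpec) -> ItemBank:
    """Draw a GPCM item bank (deterministic under the spec seed)."""
    rng = spec.rng(1)
    lo_k, hi_k = spec.n_cat_range
    items: list[ItemParams] = []
    for ins, names in _item_names(spec).items():
        for name in names:
            n_cat = int(rng.integers(lo_k, hi_k + 1))
            m = n_cat - 1
            a = float(np.exp(rng.normal(spec.a_log_mean, spec.a_log_sd)))
            loc = float(rng.uniform(*spec.b_range))
            offsets = (np.arange(m) - (m - 1) / 2.0) * spec.b_step_gap
            b = loc + offsets + rng.normal(0.0, spec.b_jitter, m)
            if name in spec.sparse_extremes:
                b = b.copy()
                b[-1] += float(spec.sparse_extremes[name])
            items.append(ItemParams(name, a, tuple(b), frozenset({ins})))
    return ItemBank(items)


def generate_group_dists(design: LinkDesign, spec: SimSpec) -> GroupDist:
    """Dataset latent distributions; first dataset is the N(0,1) reference."""
    rng = spec.rng(3)
    means = {}
    sds = {}
    for k, d in enumerate(design.datasets):
        if k == 0:
            means[d], sds[d] = 0.0, 1.0
        else:
            means[d] = float(rng.uniform(*spec.group_mean_range))
            sds[d] = float(rng.uniform(*spec.group_sd_range))
    return GroupDist(means, sds, design.datasets[0])


def simulate_responses(
    bank: ItemBank,
    design: LinkDesign,
    dists: GroupDist,
    spec: SimSpec,
    return_theta: bool = False,
):
    """Draw a ResponseData matrix from the generating model.

    Per person: theta ~ N(mu_g, sd_g^2); testlet items see
    ``theta + gamma * u`` with a shared per-person testlet draw; DIF items
    use shifted steps in their focal dataset; items whose instrument is not
    administered in the person's dataset stay missing; an MCAR mask is
    applied on top.
    """
    rng = spec.rng(2)
    item_ids = bank.item_ids
    col = {iid: j for j, iid in enumerate(item_ids)}
    dif_lookup = {(d.item_id, d.focal_group): d.shift for d in spec.dif}
    testlet_of: dict[str, int] = {}
    for t_idx, t in enumerate(spec.testlets):
        for iid in t.item_ids:
            testlet_of[iid] = t_idx

    rows_X: list[np.ndarray] = []
    rows_theta: list[np.ndarray] = []
    rows_dataset: list[np.ndarray] = []
    rows_pid: list[str] = []
    for ds in design.datasets:
        n = (
            spec.n_per_dataset
            if isinstance(spec.n_per_dataset, int)
            else spec.n_per_dataset[ds]
        )
        theta = rng.normal(dists.means[ds], dists.sds[ds], n)
        u = rng.normal(0.0, 1.0, (n, max(1, len(spec.testlets))))
        X = np.full((n, len(item_ids)), MISSING, dtype=np.int16)
        administered = set(design.items_for_dataset(ds))
        for iid in item_ids:
            if iid not in administered:
                continue
            item = bank[iid]
            a, b = item.params_for(None)
            shift = dif_lookup.get((iid, ds))
            if shift is not None:
                b = b + shift
            t_eff = theta
            if iid in testlet_of:
                t_idx = testlet_of[iid]
                t_eff = theta + spec.testlets[t_idx].loading * u[:, t_idx]
            probs = _probs_matrix(a, b, t_eff)
            cum = np.cumsum(probs, axis=1)
            draws = rng.random(n)
            X[:, col[iid]] = (draws[:, None] > cum[:, :-1]).sum(axis=1)
        if spec.missing_rate > 0:
            mask = rng.random(X.shape) < spec.missing_rate
            X[mask & (X != MISSING)] = MISSING
        rows_X.append(X)
        rows_theta.append(theta)
        rows_dataset.append(np.full(n, ds, dtype=object))
        rows_pid.extend(f"{ds}_p{i}" for i in range(n))

    data = ResponseData(
        np.vstack(rows_X),
        np.array(rows_pid, dtype=object),
        list(item_ids),
        np.concatenate(rows_dataset),
        n_cat={it.item_id: it.n_cat for it in bank},
    )
    if return_theta:
        return data, np.concatenate(rows_theta)
    return data


def collapse_sparse_categories(
    data: ResponseData, min_count: int = 20
) -> tuple[ResponseData, dict[str, dict[int, int]]]:
    """Merge categories observed fewer than ``min_count`` times.

    A sparse category is merged into its adjacent category nearer the scale
    interior (floor merges upward, ceiling merges downward), iterating until
    no observed count falls below the threshold; codes are then made
    contiguous from 0.  Returns the recoded data and, for each changed
    item, the old -> new category mapping.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    X = data.X.copy()
    log: dict[str, dict[int, int]] = {}
    new_n_cat = dict(data.n_cat) if data.n_cat else {}
    for iid in data.item_ids:
        counts = data.category_counts(iid)
        k0 = len(counts)
        if k0 < 2:
            raise DegenerateItemError(f"item {iid!r} has < 2 categories")
        groups: list[list[int]] = [[c] for c in range(k0)]
        gcounts = list(int(c) for c in counts)
        while any(c < min_count for c in gcounts):
            if len(groups) <= 2:
                if len(groups) < 2 or min(gcounts) < min_count:
                    raise DegenerateItemError(
                        f"item {iid!r}: collapsing to < 2 categories "
                        f"(counts {gcounts})"
                    )
                break
            sparse = [g for g, c in enumerate(gcounts) if c < min_count]
            g = min(sparse, key=lambda gg: gcounts[gg])
            mid = (len(groups) - 1) / 2.0
            target = g + 1 if g < mid else g - 1
            lo_g, hi_g = min(g, target), max(g, target)
            groups[lo_g] = groups[lo_g] + groups[hi_g]
            gcounts[lo_g] += gcounts[hi_g]
            del groups[hi_g]
            del gcounts[hi_g]
        if len(groups) == k0:
            continue
        mapping = {
            old: new for new, members in enumerate(groups) for old in members
        }
        lut = np.arange(k0 + 1, dtype=np.int16)  # +1 slot for MISSING via index -1
        for old, new in mapping.items():
            lut[old] = new
        lut[-1] = MISSING
        j = data.col(iid)
        X[:, j] = lut[X[:, j]]
        log[iid] = dict(sorted(mapping.items()))
        new_n_cat[iid] = len(groups)
    out = ResponseData(
        X, data.person_ids, list(data.item_ids), data.dataset, new_n_cat or None
    )
    return out, log
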