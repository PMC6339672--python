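"""File formats, run configuration and structured logging.

Responses travel as wide CSV (person_id, dataset, one column per item;
blank = missing), item metadata as CSV (item_id, instruments, n_cat),
banks as JSON or flat CSV, and configs as YAML/JSON.  Every artifact
writer can stamp the config hash and seed into a JSON-lines log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    ItemBank,
    ItemParams,
    QuadGrid,
    bank_from_dict,
    bank_to_dict,
    invert_scc,
)
from .data import MISSING, ResponseData
from .simulate import GroupDist, LinkDesign


class ValidationError(ValueError):
    pass


@dataclass
class Thresholds:
    """The reusable numeric decision rules, overridable per run."""

    min_count: int = 20          # sparse-category collapse threshold
    q3: float = 0.25             # local-dependence flag
    es_dif: float = 0.05         # DIF effect-size screen
    alpha: float = 0.05          # LM test significance level
    omega: float = 0.70          # general-factor saturation cutoff
    ecv: float = 0.60            # explained-common-variance cutoff
    cr: float = 0.70             # conditional reliability cutoff
    congruence_es: float = 0.20  # trivial-effect bound

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")
        for name in ("q3", "es_dif", "alpha", "omega", "ecv", "cr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"threshold {name}={v} outside [0, 1]")
        if self.congruence_es < 0:
            raise ValidationError("congruence_es must be >= 0")


@dataclass
class RunConfig:
    responses: str | None = None
    metadata: str | None = None
    bank_in: str | None = None
    bank_out: str | None = None
    model: str = "GPCM"
    theta_lo: float = -8.0
    theta_hi: float = 8.0
    n_nodes: int = 61
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def grid(self) -> QuadGrid:
        return QuadGrid.equally_spaced(self.theta_lo, self.theta_hi, self.n_nodes)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    raw = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    ) or {}
    thr = Thresholds(**raw.pop("thresholds", {}))
    known = {
        k: raw.pop(k)
        for k in list(raw)
        if k in RunConfig.__dataclass_fields__ and k not in ("thresholds", "extra")
    }
    return RunConfig(thresholds=thr, extra=raw, **known)


# ---------------------------------------------------------------------------
# responses + metadata


def write_responses(data: ResponseData, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_responses(
    path: str | Path, metadata: pd.DataFrame | None = None
) -> ResponseData:
    df = pd.read_csv(path, dtype={"person_id": str, "dataset": str})
    if "person_id" not in df or "dataset" not in df:
        raise ValidationError("responses CSV needs person_id and dataset columns")
    n_cat = None
    if metadata is not None:
        n_cat = dict(zip(metadata["item_id"], metadata["n_cat"].astype(int)))
        unknown = [
            c for c in df.columns
            if c not in ("person_id", "dataset") and c not in n_cat
        ]
        if unknown:
            raise ValidationError(f"unknown item columns: {unknown}")
    data = ResponseData.from_frame(df, n_cat)
    if n_cat:
        for iid in data.item_ids:
            x = data.X[:, data.col(iid)]
            bad = np.nonzero((x != MISSING) & ((x < 0) | (x >= n_cat[iid])))[0]
            if bad.size:
                row = int(bad[0])
                raise ValidationError(
                    f"category {int(x[bad[0]])} out of range for item {iid!r} "
                    f"at person {data.person_ids[row]!r} "
                    f"(valid: 0..{n_cat[iid] - 1})"
                )
    return data


def write_metadata(bank: ItemBank, path: str | Path) -> None:
    rows = [
        {
            "item_id": it.item_id,
            "instruments": ";".join(sorted(it.instrument_ids)),
            "n_cat": it.n_cat,
        }
        for it in bank
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"item_id", "instruments", "n_cat"}
    if not need <= set(df.columns):
        raise ValidationError(f"metadata CSV needs columns {sorted(need)}")
    return df


def design_from_data(data: ResponseData, metadata: pd.DataFrame) -> LinkDesign:
    """Reconstruct the linking design from observed incidence + metadata."""
    item_instruments = {
        r["item_id"]: set(str(r["instruments"]).split(";")) if r["instruments"] else set()
        for _, r in metadata.iterrows()
    }
    datasets = data.datasets
    ds_arr = np.asarray([str(d) for d in data.dataset])
    incidence: dict[str, set[str]] = {}
    imap: dict[str, set[str]] = {d: set() for d in datasets}
    for iid in data.item_ids:
        obs = data.observed(iid)
        present = set(np.unique(ds_arr[obs]).tolist())
        incidence[iid] = present
        for d in present:
            imap[d] |= item_instruments.get(iid, set())
    return LinkDesign(tuple(datasets), imap, incidence, item_instruments)


# ---------------------------------------------------------------------------
# banks


def write_bank_json(bank: ItemBank, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bank_to_dict(bank), indent=2))


def read_bank_json(path: str | Path) -> ItemBank:
    return bank_from_dict(json.loads(Path(path).read_text()))


def write_bank_csv(bank: ItemBank, path: str | Path) -> None:
    """Flat CSV: one row per item (group blank) plus one row per override."""
    max_m = max(it.max_score for it in bank)
    rows = []

    def row(iid: str, instrs: frozenset[str], group: str, a: float, b) -> dict:
        r = {
            "item_id": iid,
            "instruments": ";".join(sorted(instrs)),
            "group": group,
            "a": a,
        }
        for v in range(max_m):
            r[f"b_{v + 1}"] = b[v] if v < len(b) else ""
        return r

    for it in bank:
        rows.append(row(it.item_id, it.instrument_ids, "", it.a, it.b))
        for g, (a_g, b_g) in sorted(it.subgroup_overrides.items()):
            rows.append(row(it.item_id, it.instrument_ids, g, a_g, b_g))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bank_csv(path: str | Path) -> ItemBank:
    df = pd.read_csv(path, keep_default_na=False)
    b_cols = sorted(
        [c for c in df.columns if c.startswith("b_")], key=lambda c: int(c[2:])
    )
    items: dict[str, dict] = {}
    for _, r in df.iterrows():
        b = tuple(float(r[c]) for c in b_cols if r[c] != "")
        if r["group"] == "":
            items[r["item_id"]] = {
                "a": float(r["a"]),
                "b": b,
                "instruments": frozenset(
                    s for s in str(r["instruments"]).split(";") if s
                ),
                "overrides": {},
            }
        else:
            items[r["item_id"]]["overrides"][str(r["group"])] = (float(r["a"]), b)
    return ItemBank(
        [
            ItemParams(iid, d["a"], d["b"], d["instruments"], d["overrides"])
            for iid, d in items.items()
        ]
    )


def write_group_dists(dists: GroupDist, path: str | Path) -> None:
    pd.DataFrame(
        {
            "dataset": list(dists.means),
            "mean": [dists.means[g] for g in dists.means],
            "sd": [dists.sds[g] for g in dists.means],
            "reference": [g == dists.reference_group for g in dists.means],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# crosswalks


def crosswalk_table(
    bank: ItemBank, instrument_id: str, grid: QuadGrid | None = None
) -> pd.DataFrame:
    """Summed score -> theta -> standardized score lookup for one instrument."""
    from .scoring import standardize_score

    items = bank.instrument_items(instrument_id)
    max_sum = sum(it.max_score for it in items)
    rows = []
    for s in range(max_sum + 1):
        inv = invert_scc(bank, instrument_id, float(s))
        rows.append(
            {
                "summed_score": s,
                "theta": inv.theta,
                "at_boundary": inv.at_boundary,
                "standardized_score": (
                    standardize_score(inv.theta, bank)
                    if bank.scale_origin_theta is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logging


class RunLog:
    """Append-only JSON-lines log stamping every record with run identity."""

    def __init__(self, path: str | Path, config: RunConfig | None = None):
        from . import __version__

        self.path = Path(path)
        self._stamp = {
            "config_hash": config.digest() if config else None,
            "seed": config.seed if config else None,
            "version": __version__,
        }
        if config is not None:
            self.write("run_config", thresholds=asdict(config.thresholds),
                       model=config.model)

    def write(self, event: str, **fields) -> None:
        rec = {"time": time.time(), "event": event, **self._stamp, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
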