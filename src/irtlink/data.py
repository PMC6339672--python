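"""Shared response-data container.

Responses are a persons x items integer category matrix with ``MISSING``
(-1) for unobserved cells, plus a dataset label per person.  Structural
missingness (items never administered in a dataset) and incidental
missingness share the same sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1


@dataclass
class ResponseData:
    X: np.ndarray
    person_ids: np.ndarray
    item_ids: list[str]
    dataset: np.ndarray
    n_cat: dict[str, int] | None = None
    _col_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int16)
        self.person_ids = np.asarray(self.person_ids)
        self.dataset = np.asarray(self.dataset)
        n, j = self.X.shape
        if len(self.person_ids) != n or len(self.dataset) != n:
            raise ValueError("person_ids / dataset length mismatch with matrix")
        if len(self.item_ids) != j:
            raise ValueError("item_ids length mismatch with matrix")
        if len(set(self.item_ids)) != j:
            raise ValueError("duplicate item ids")
        self._col_index = {iid: k for k, iid in enumerate(self.item_ids)}

    @property
    def n_persons(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.dataset:
            seen.setdefault(str(d))
        return list(seen)

    def col(self, item_id: str) -> int:
        return self._col_index[item_id]

    def observed(self, item_id: str) -> np.ndarray:
        """Boolean mask of persons with this item observed."""
        return self.X[:, self.col(item_id)] != MISSING

    def category_counts(self, item_id: str) -> np.ndarray:
        """Observed counts per category (length = declared or observed max + 1)."""
        x = self.X[:, self.col(item_id)]
        x = x[x != MISSING]
        if self.n_cat and item_id in self.n_cat:
            k = self.n_cat[item_id]
        else:
            k = int(x.max()) + 1 if x.size else 0
        return np.bincount(x, minlength=k)

    def subset_items(self, item_ids: list[str]) -> "ResponseData":
        cols = [self.col(i) for i in item_ids]
        n_cat = (
            {i: self.n_cat[i] for i in item_ids if i in self.n_cat}
            if self.n_cat
            else None
        )
        return ResponseData(
            self.X[:, cols], self.person_ids, list(item_ids), self.dataset, n_cat
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table with blank (NA) cells for missing responses."""
        df = pd.DataFrame(self.X, columns=self.item_ids).astype("Int64")
        df = df.mask(df == MISSING)
        df.insert(0, "dataset", self.dataset)
        df.insert(0, "person_id", self.person_ids)
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, n_cat: dict[str, int] | None = None
    ) -> "ResponseData":
        item_ids = [c for c in df.columns if c not in ("person_id", "dataset")]
        x = df[item_ids].to_numpy(dtype=float)
        x = np.where(np.isnan(x), MISSING, x).astype(np.int16)
        return cls(
            x,
            df["person_id"].to_numpy(),
            item_ids,
            df["dataset"].astype(str).to_numpy(),
            n_cat,
        )
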