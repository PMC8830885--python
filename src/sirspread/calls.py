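"""In-memory container for per-read modified-base calls."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of the per-read text dialect.
COLUMNS = [
    "read_id",
    "contig",
    "strand",
    "position",
    "mod_log_prob",
    "can_log_prob",
    "mod_code",
]


@dataclass
class PerReadCallSet:
    """Per-read, per-adenine modified-base probability records for one sample.

    Wraps a :class:`pandas.DataFrame` with columns ``read_id``, ``contig``,
    ``strand``, ``position`` (0-based), ``mod_log_prob`` and ``can_log_prob``
    (natural-log probabilities, <= 0) and ``mod_code``. After binarization a
    boolean ``methylated`` column is present and ``threshold`` records the
    probability cutoff used.
    """

    df: pd.DataFrame
    threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_binarized(self) -> bool:
        return "methylated" in self.df.columns

    @property
    def probabilities(self) -> np.ndarray:
        """Modified-base probabilities, exp(mod_log_prob)."""
        return np.exp(self.df["mod_log_prob"].to_numpy())

    def sorted(self) -> "PerReadCallSet":
        """Records sorted by (contig, position, read_id) — the on-disk order."""
        out = self.df.sort_values(
            ["contig", "position", "read_id"], kind="mergesort"
        ).reset_index(drop=True)
        return PerReadCallSet(out, threshold=self.threshold, meta=dict(self.meta))

    def subset(self, contig: str, start: int | None = None, end: int | None = None) -> "PerReadCallSet":
        m = self.df["contig"] == contig
        if start is not None:
            m &= self.df["position"] >= start
        if end is not None:
            m &= self.df["position"] < end
        return PerReadCallSet(
            self.df.loc[m].reset_index(drop=True),
            threshold=self.threshold,
            meta=dict(self.meta),
        )

    @classmethod
    def from_arrays(
        cls,
        read_id,
        contig,
        strand,
        position,
        mod_prob,
        mod_code: str = "Y",
        meta: dict | None = None,
    ) -> "PerReadCallSet":
        """Build a call set from parallel arrays of linear probabilities."""
        p = np.clip(np.asarray(mod_prob, dtype=float), 1e-300, 1.0 - 1e-16)
        df = pd.DataFrame(
            {
                "read_id": read_id,
                "contig": contig,
                "strand": strand,
                "position": np.asarray(position, dtype=np.int64),
                "mod_log_prob": np.log(p),
                "can_log_prob": np.log1p(-p),
                "mod_code": mod_code,
            }
        )
        return cls(df, meta=meta or {})

    @classmethod
    def empty(cls) -> "PerReadCallSet":
        return cls(
            pd.DataFrame(
                {
                    "read_id": pd.Series(dtype=str),
                    "contig": pd.Series(dtype=str),
                    "strand": pd.Series(dtype=str),
                    "position": pd.Series(dtype=np.int64),
                    "mod_log_prob": pd.Series(dtype=float),
                    "can_log_prob": pd.Series(dtype=float),
                    "mod_code": pd.Series(dtype=str),
                }
            )
        )
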