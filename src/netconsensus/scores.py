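"""Per-algorithm score vectors with provenance and tie-aware ranks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError


def tie_average_ranks(values: np.ndarray) -> np.ndarray:
    """Descending tie-averaged ranks: rank 1 = highest score, ties share the
    average of the positions they span (so ranks always sum to n(n+1)/2)."""
    return rankdata(-np.asarray(values, dtype=float), method="average")


@dataclass(frozen=True)
class ScoreVector:
    """One algorithm's scores for every node of a network.

    ``values`` is aligned to ``node_ids``; ``algorithm`` and ``params``
    record how the scores were produced.
    """

    node_ids: tuple[str, ...]
    values: np.ndarray
    algorithm: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(str(i) for i in self.node_ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "params", dict(self.params))
        if v.shape != (len(self.node_ids),):
            raise DataError("values must align one-to-one with node_ids")
        if not np.all(np.isfinite(v)):
            raise DataError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def ranks(self) -> np.ndarray:
        return tie_average_ranks(self.values)

    def __getitem__(self, node: str) -> float:
        return float(self.values[self.node_ids.index(node)])

    def rank_of(self, node: str) -> float:
        return float(self.ranks[self.node_ids.index(node)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.node_ids), name=self.algorithm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.node_ids), "score": self.values, "rank": self.ranks}
        )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Write `node<TAB>score<TAB>rank`, optionally preceded by '#' comments."""
        path = Path(path)
        body = self.to_frame().to_csv(sep="\t", index=False)
        prefix = "".join(f"# {line}\n" for line in header_lines)
        path.write_text(prefix + body)
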