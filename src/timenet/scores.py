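"""Node/edge score tables shared by the information and centrality scorers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["ScoreTable", "min_max_normalize"]


def min_max_normalize(scores: Mapping[str, float]) -> dict[str, float]:
    """Min-max rescale a score vector to [0, 1].

    A degenerate all-equal vector maps to all zeros so the output is always
    well defined.
    """
    if not scores:
        return {}
    vals = list(scores.values())
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return {k: 0.0 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}


@dataclass
class ScoreTable:
    """Identifier -> score mapping with method provenance.

    Mutual-information scores (ECF/NCF/DNCF) are in bits; centrality scores
    are min-max normalized and unitless.
    """

    scores: dict[str, float]
    method: str = ""
    params: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.scores[key]

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, key: str) -> bool:
        return key in self.scores

    def items(self):
        return self.scores.items()

    def ranked(self) -> list[tuple[str, float]]:
        """Scores sorted high-to-low, ties broken by identifier."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self) -> str:
        if not self.scores:
            raise ValueError("empty score table")
        return self.ranked()[0][0]

    def normalized(self) -> "ScoreTable":
        return ScoreTable(
            min_max_normalize(self.scores),
            method=self.method,
            params={**self.params, "normalized": "min-max"},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.scores), "score": list(self.scores.values())}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "") -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df, method=method)

    @classmethod
    def from_excel(
        cls, path: str | Path, sheet: int | str = 0, method: str = ""
    ) -> "ScoreTable":
        """Read an id/score sheet from a spreadsheet (first two columns)."""
        df = pd.read_excel(path, sheet_name=sheet)
        return cls.from_frame(df, method=method)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method: str = "") -> "ScoreTable":
        if df.shape[1] < 2:
            raise ValueError("score table needs an id and a score column")
        ids = df.iloc[:, 0].astype(str)
        vals = df.iloc[:, 1].astype(float)
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate identifiers in score table: {dupes}")
        return cls(dict(zip(ids, vals)), method=method)
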