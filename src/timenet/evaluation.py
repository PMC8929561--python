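"""ROC/PR benchmarking of residue scores against binary allosteric labels.

Residue score tables (higher score = predicted allosteric) are swept over
every distinct score value as a threshold, predicting positive at
``score >= threshold`` with ties entering together.  The areas under the
ROC and precision-recall curves are computed by trapezoidal integration.

The PR curve is anchored at recall 0 with the precision observed at the
highest threshold -- no extrapolated precision-1 point -- and integrated
over the observed recall range.  These conventions matter at the printed
precision of AUC values and are therefore stated explicitly here and in
the methods note.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import residue_name_of
from .scores import ScoreTable

__all__ = [
    "ReferenceSet",
    "CurvePoints",
    "EvaluationResult",
    "evaluate",
    "optimal_threshold",
    "make_variant",
    "GridConfig",
    "full_grid",
    "grid_search",
    "grouped_summary",
]


@dataclass
class ReferenceSet:
    """Binary residue labels: 1 = allosteric, 0 = non-allosteric.

    ``residue_names`` maps identifiers to three-letter residue names when
    the identifiers themselves do not embed one; the alanine-excluded
    variant is derived with :func:`make_variant`.
    """

    labels: dict[str, int]
    variant: str = "full"
    residue_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.labels.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"labels must be binary 0/1; offending: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def positives(self) -> list[str]:
        return [k for k, v in self.labels.items() if v == 1]

    def residue_name(self, rid: str) -> str:
        if rid in self.residue_names:
            return self.residue_names[rid]
        return residue_name_of(rid)

    @classmethod
    def from_tsv(cls, path: str | Path, variant: str = "full") -> "ReferenceSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), variant=variant)

    @classmethod
    def from_excel(
        cls, path: str | Path, sheet: int | str = 0, variant: str = "full"
    ) -> "ReferenceSet":
        return cls.from_frame(pd.read_excel(path, sheet_name=sheet), variant=variant)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variant: str = "full") -> "ReferenceSet":
        """First column: residue id; last column: 0/1 label; an optional
        middle column named like 'residue'/'name' supplies residue names."""
        if df.shape[1] < 2:
            raise ValueError("label table needs an id and a label column")
        ids = df.iloc[:, 0].astype(str).tolist()
        labels = dict(zip(ids, df.iloc[:, -1].astype(int).tolist()))
        names: dict[str, str] = {}
        for col in df.columns[1:-1]:
            if str(col).lower() in ("residue", "res_name", "resname", "name"):
                names = dict(zip(ids, df[col].astype(str).str.upper()))
        return cls(labels, variant=variant, residue_names=names)


@dataclass
class CurvePoints:
    """Ordered curve points of a threshold sweep plus trapezoidal area."""

    thresholds: np.ndarray  # descending; +inf anchor first
    x: np.ndarray  # FPR (ROC) or recall (PR)
    y: np.ndarray  # TPR (ROC) or precision (PR)
    area: float

    def to_frame(self, x_name: str = "x", y_name: str = "y") -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, x_name: self.x, y_name: self.y}
        )


@dataclass
class EvaluationResult:
    roc: CurvePoints
    pr: CurvePoints

    @property
    def roc_auc(self) -> float:
        return self.roc.area

    @property
    def pr_auc(self) -> float:
        return self.pr.area


def evaluate(
    scores: ScoreTable | Mapping[str, float], labels: ReferenceSet
) -> EvaluationResult:
    """ROC and PR curves of a residue score table against binary labels.

    Every labeled residue must be scored (scored-but-unlabeled residues
    are ignored, as reference sets typically cover a subset of residues);
    both classes must be present.
    """
    table = scores.scores if isinstance(scores, ScoreTable) else dict(scores)
    missing = [rid for rid in labels.labels if rid not in table]
    if missing:
        raise ValueError(f"no score for labeled residues: {sorted(missing)}")
    ids = list(labels.labels)
    y_true = np.array([labels.labels[rid] for rid in ids])
    y_score = np.array([float(table[rid]) for rid in ids])
    n_pos = int(y_true.sum())
    n_neg = len(ids) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels contain a single class; cannot evaluate")

    thresholds = np.unique(y_score)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    recall = []
    precision = []
    for th in thresholds:
        pred = y_score >= th
        tp = int(np.sum(pred & (y_true == 1)))
        fp = int(np.sum(pred & (y_true == 0)))
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        recall.append(tp / n_pos)
        precision.append(tp / (tp + fp) if tp + fp else 0.0)

    roc_thresholds = np.concatenate([[np.inf], thresholds])
    fpr_arr, tpr_arr = np.array(fpr), np.array(tpr)
    roc_auc = float(np.trapezoid(tpr_arr, fpr_arr))
    roc = CurvePoints(roc_thresholds, fpr_arr, tpr_arr, roc_auc)

    # recall-0 anchor carries the precision of the strictest threshold
    pr_thresholds = np.concatenate([[np.inf], thresholds])
    rec_arr = np.concatenate([[0.0], recall])
    prec_arr = np.concatenate([[precision[0]], precision])
    pr_auc = float(np.trapezoid(prec_arr, rec_arr))
    pr = CurvePoints(pr_thresholds, rec_arr, prec_arr, pr_auc)
    return EvaluationResult(roc, pr)


def optimal_threshold(curve: CurvePoints) -> float:
    """Threshold of the ROC point closest to the top-left corner (0, 1).

    Ties are broken toward the higher threshold (the stricter predictor).
    """
    if curve.x.size < 2:
        raise ValueError("ROC curve needs at least two points")
    dist = np.hypot(curve.x, 1.0 - curve.y)
    best = int(np.argmin(dist))  # argmin returns the first (highest-threshold) tie
    return float(curve.thresholds[best])


def make_variant(
    labels: ReferenceSet, exclude_residue_type: str = "ALA"
) -> ReferenceSet:
    """Label-set variant excluding one residue type (alanine by default)."""
    excl = exclude_residue_type.upper()
    kept = {
        rid: lab
        for rid, lab in labels.labels.items()
        if labels.residue_name(rid).upper() != excl
    }
    return ReferenceSet(
        kept,
        variant=f"{labels.variant}-no-{excl}",
        residue_names={k: v for k, v in labels.residue_names.items() if k in kept},
    )


@dataclass(frozen=True)
class GridConfig:
    """One cell of the network-parameter grid."""

    cutoff: float  # carbon-contact distance cutoff, Angstrom
    subset: str  # "all" | "sidechain"
    source: str  # "apo" | "pep" | "apo-NMR" | "pep-NMR"
    method: str  # "BC" | "CPLC" | "NCF" | "DNCF"


CUTOFFS = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
SUBSETS = ("all", "sidechain")
SOURCES = ("apo", "pep", "apo-NMR", "pep-NMR")


def full_grid(method: str) -> list[GridConfig]:
    """The canonical 6 cutoffs x 2 subsets x 4 sources = 48 combinations."""
    return [
        GridConfig(c, sub, src, method)
        for c, sub, src in itertools.product(CUTOFFS, SUBSETS, SOURCES)
    ]


def grid_search(
    score_tables: Mapping[GridConfig, ScoreTable | Mapping[str, float]],
    labels: ReferenceSet,
    grid: Iterable[GridConfig] | None = None,
) -> pd.DataFrame:
    """Evaluate one score table per grid configuration.

    Returns one row per configuration with rocAUC/prAUC; configurations in
    ``grid`` (default: the keys of ``score_tables``) that lack a score
    table are flagged ``missing`` rather than silently dropped.
    """
    configs = list(grid) if grid is not None else list(score_tables)
    rows = []
    for cfg in configs:
        row = {
            "cutoff": cfg.cutoff,
            "subset": cfg.subset,
            "source": cfg.source,
            "method": cfg.method,
        }
        if cfg in score_tables:
            result = evaluate(score_tables[cfg], labels)
            row.update(
                roc_auc=result.roc_auc, pr_auc=result.pr_auc, status="ok"
            )
        else:
            row.update(roc_auc=np.nan, pr_auc=np.nan, status="missing")
        rows.append(row)
    return pd.DataFrame(rows)


def grouped_summary(results: pd.DataFrame, by: str) -> pd.DataFrame:
    """Mean and SD of rocAUC per method, grouped by one grid category."""
    ok = results[results["status"] == "ok"]
    out = (
        ok.groupby(["method", by])["roc_auc"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out.rename(columns={"mean": "roc_auc_mean", "std": "roc_auc_sd"})
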