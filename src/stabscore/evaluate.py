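"""Evaluation statistics over design sets sharing folds.

Designed sequences come in groups ("folds") sharing one backbone, one
sequence per generative model.  Between-fold analyses correlate a metric with
absolute stability across all designs; within-fold analyses difference out
the backbone by comparing the models' sequences for the same fold.  This
module provides the rank correlations, within-fold deltas and pass-fraction
statistics, threshold filters, medians, and sequence identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from Bio import Align
from scipy.stats import rankdata

from .io import ScoreTable, StabscoreError

__all__ = [
    "FilterSpec",
    "Predicate",
    "spearman",
    "within_fold_deltas",
    "fraction_more_stable",
    "apply_filters",
    "median_stability",
    "sequence_identity",
]

_OPS = {
    "gt": np.greater,
    "lt": np.less,
    "ge": np.greater_equal,
    "le": np.less_equal,
}


@dataclass(frozen=True)
class Predicate:
    metric: str
    op: Literal["gt", "lt", "ge", "le"]
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise StabscoreError(f"unknown operator {self.op!r}")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.metric not in df.columns:
            raise StabscoreError(f"metric {self.metric!r} not in table")
        values = df[self.metric].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            keep = _OPS[self.op](values, self.threshold)
        return np.where(np.isnan(values), False, keep)


@dataclass
class FilterSpec:
    """Ordered conjunction of threshold predicates.

    Published design-selection thresholds expressed in this form:
    ``plddt_af2_3rec gt 85`` (confident structure), ``mpnn_cce lt 1.5``
    (per-residue conditional cross-entropy below average inverse-folding
    perplexity), ``inter_pae gt 15`` (kept as monomers: high inter-chain PAE
    means no confident chain-chain packing), ``dG_unfold gt 5`` / ``lt 0``
    (stable / unstable classes, kcal/mol).
    """

    predicates: list[Predicate] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "FilterSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        return cls([Predicate(p["metric"], p["op"], float(p["threshold"])) for p in raw])


#: conventional stability classes, kcal/mol
STABLE_CLASS = Predicate("dG_unfold", "gt", 5.0)
UNSTABLE_CLASS = Predicate("dG_unfold", "lt", 0.0)
#: retain-if rule for monomers; threshold and direction are configurable
MONOMER_FILTER = Predicate("inter_pae", "gt", 15.0)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Pairs with a missing value in either vector are removed first; at least
    three complete pairs are required.  Zero rank variance in either argument
    is undefined and returned as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StabscoreError("spearman needs two equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise StabscoreError(f"need >= 3 complete pairs, got {len(x)}")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("zero rank variance; Spearman undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _per_fold_metric(df: pd.DataFrame, model: str, metric: str) -> pd.Series:
    sub = df[df["model_tag"] == model]
    return sub.groupby("fold_id")[metric].mean()


def within_fold_deltas(
    table: ScoreTable,
    reference_model: str,
    other_model: str,
    metric: str = "dG_unfold",
) -> tuple[pd.Series, int]:
    """Per-fold differences metric_ref − metric_other, aligned by fold_id.

    Folds lacking either model (or with a missing metric value) are skipped;
    the skip count is returned alongside the delta vector.
    """
    if reference_model == other_model:
        raise StabscoreError("reference and other model must differ")
    for col in ("fold_id", "model_tag", metric):
        table.column(col)
    df = table.df
    ref = _per_fold_metric(df, reference_model, metric)
    oth = _per_fold_metric(df, other_model, metric)
    all_folds = ref.index.union(oth.index)
    deltas = (ref - oth).dropna()
    n_skipped = len(all_folds) - len(deltas)
    return deltas, n_skipped


def fraction_more_stable(
    table: ScoreTable,
    reference_model: str,
    other_model: str,
    metric: str = "dG_unfold",
) -> dict:
    """Percentage of shared folds where the reference model's design is more
    stable than the other model's.

    Exact ties count as not-more-stable and are reported separately.
    """
    deltas, n_skipped = within_fold_deltas(table, reference_model, other_model, metric)
    if len(deltas) == 0:
        raise StabscoreError(
            f"no folds shared by {reference_model!r} and {other_model!r}"
        )
    n = len(deltas)
    n_wins = int((deltas > 0).sum())
    n_ties = int((deltas == 0).sum())
    return {
        "percent": 100.0 * n_wins / n,
        "fraction": n_wins / n,
        "n_folds": n,
        "n_ties": n_ties,
        "tie_percent": 100.0 * n_ties / n,
        "n_skipped": n_skipped,
    }


@dataclass
class FilterResult:
    table: ScoreTable
    n_in: int
    n_out: int
    attrition: list[dict]


def apply_filters(table: ScoreTable, spec: FilterSpec) -> FilterResult:
    """Keep rows satisfying every predicate; log per-predicate attrition.

    The keep-set is order-independent (a conjunction); the attrition report
    counts removals in predicate order.
    """
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    attrition = []
    for pred in spec.predicates:
        new_keep = keep & pred.mask(df)
        attrition.append(
            {
                "metric": pred.metric,
                "op": pred.op,
                "threshold": pred.threshold,
                "n_removed": int(keep.sum() - new_keep.sum()),
                "n_remaining": int(new_keep.sum()),
            }
        )
        keep = new_keep
    out = ScoreTable(df[keep].reset_index(drop=True), key=table.key, metadata=dict(table.metadata))
    return FilterResult(table=out, n_in=len(df), n_out=int(keep.sum()), attrition=attrition)


def median_stability(table: ScoreTable, column: str = "dG_unfold") -> float:
    """Median ΔG_unfold (kcal/mol); mean of the middle two for even counts."""
    values = table.column(column).dropna()
    if len(values) == 0:
        raise StabscoreError(f"no non-missing values in {column!r}")
    return float(values.median())


def sequence_identity(seq_a: str, seq_b: str, align: bool = False) -> float:
    """Fraction of identical positions between two sequences.

    Same-fold designs share a length, so the default is positional identity
    over equal-length sequences.  With ``align=True`` unequal lengths are
    allowed: a global alignment (match +1, mismatch 0, linear gap −1) is
    computed and identity is matches / alignment length.
    """
    seq_a = getattr(seq_a, "sequence", seq_a)
    seq_b = getattr(seq_b, "sequence", seq_b)
    if not seq_a or not seq_b:
        raise StabscoreError("empty sequence")
    if len(seq_a) == len(seq_b) and not align:
        matches = sum(a == b for a, b in zip(seq_a, seq_b))
        return matches / len(seq_a)
    if not align:
        raise StabscoreError(
            f"length mismatch ({len(seq_a)} vs {len(seq_b)}); pass align=True"
        )
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-1,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(a_row, b_row))
    return matches / len(a_row)
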