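"""Cohort aggregation: top-N success rates by CAPRI level and ROC/AUC discrimination.

A benchmark run produces one EvaluationRecord per model; complexes succeed
at a (top-N, accuracy level) cell when at least one of their N best-ranked
models reaches that CAPRI level or better.  Score discrimination is
summarised as ROC AUC in the rank-sum (Mann-Whitney) formulation, both for
binary contrasts (Incorrect vs High; Incorrect vs Medium-and-High) and as
an unweighted one-vs-rest macro average over the four classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .complex_scoring import CAPRI_ORDER, DockScores
from .confidence import ConfidenceRecord

__all__ = [
    "EvaluationRecord",
    "success_rate",
    "success_table",
    "roc_auc",
    "discrimination_report",
    "records_from_manifest",
]

CAPRI_LEVELS = ("Incorrect", "Acceptable", "Medium", "High")


@dataclass
class EvaluationRecord:
    complex_id: str
    model_label: str
    rank: int
    dock: DockScores
    confidence: ConfidenceRecord | None = None
    cdr: dict = field(default_factory=dict)
    has_interface_glycan: bool = False
    antibody_type: str = "Ab"

    def score(self, score_field: str):
        """Look up a named score on the record (dock or confidence fields)."""
        if hasattr(self.dock, score_field):
            return getattr(self.dock, score_field)
        if self.confidence is not None and hasattr(self.confidence, score_field):
            return getattr(self.confidence, score_field)
        return None


def _check_records(records) -> None:
    if not records:
        raise ValueError("empty record set")
    seen = set()
    for rec in records:
        if (rec.complex_id, rec.rank) in seen:
            raise ValueError(f"duplicate rank {rec.rank} in complex {rec.complex_id}")
        seen.add((rec.complex_id, rec.rank))


def success_rate(records, top_n: int, min_level: str) -> float:
    """Percentage of complexes with >= 1 model of rank <= top_n at >= min_level."""
    _check_records(records)
    if min_level not in CAPRI_ORDER:
        raise ValueError(f"unknown CAPRI level {min_level!r}")
    threshold = CAPRI_ORDER[min_level]
    complexes: dict[str, bool] = {}
    for rec in records:
        ok = complexes.setdefault(rec.complex_id, False)
        if not ok and rec.rank <= top_n and CAPRI_ORDER[rec.dock.capri_class] >= threshold:
            complexes[rec.complex_id] = True
    return 100.0 * sum(complexes.values()) / len(complexes)


def success_table(records, top_ns=(1, 5, 25),
                  levels=("Acceptable", "Medium", "High")) -> pd.DataFrame:
    """Success-rate table: rows top-N, columns minimum CAPRI level."""
    data = {level: [success_rate(records, n, level) for n in top_ns] for level in levels}
    return pd.DataFrame(data, index=pd.Index(top_ns, name="top_n"))


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _binary_auc(records, score_field: str, positive_levels, negative_levels):
    scores, labels = [], []
    for rec in records:
        value = rec.score(score_field)
        if value is None:
            continue
        level = rec.dock.capri_class
        if level in positive_levels:
            scores.append(value)
            labels.append(1)
        elif level in negative_levels:
            scores.append(value)
            labels.append(0)
    if not scores or len(set(labels)) < 2:
        return np.nan
    return roc_auc(scores, labels)


def _macro_auc(records, score_field: str):
    """Unweighted one-vs-rest macro average over the four CAPRI classes."""
    aucs = []
    for level in CAPRI_LEVELS:
        rest = [lv for lv in CAPRI_LEVELS if lv != level]
        auc = _binary_auc(records, score_field, {level}, set(rest))
        if not np.isnan(auc):
            # a single quality score cannot be monotone for every
            # one-vs-rest contrast (middle classes); use the
            # direction-free discriminability max(auc, 1-auc)
            aucs.append(max(auc, 1.0 - auc))
    if not aucs:
        return np.nan
    return float(np.mean(aucs))


def discrimination_report(records, score_fields=("iplddt", "model_confidence"),
                          ) -> pd.DataFrame:
    """Per score field: binary AUCs and the multi-class macro AUC.

    Score fields absent from every record are reported as missing (NaN)
    without affecting the other columns.
    """
    _check_records(records)
    rows = []
    for score_field in score_fields:
        rows.append({
            "score": score_field,
            "auc_incorrect_vs_high": _binary_auc(
                records, score_field, {"High"}, {"Incorrect"}),
            "auc_incorrect_vs_medium_high": _binary_auc(
                records, score_field, {"Medium", "High"}, {"Incorrect"}),
            "auc_multiclass_macro": _macro_auc(records, score_field),
        })
    return pd.DataFrame(rows).set_index("score")


def records_from_manifest(manifest: pd.DataFrame) -> list[EvaluationRecord]:
    """Build EvaluationRecords from a manifest table (one row per model)."""
    records = []
    for row in manifest.itertuples():
        dock = DockScores(fnat=float(row.fnat), i_rmsd=float(row.i_rmsd),
                          l_rmsd=float(row.l_rmsd), dockq=float(row.dockq),
                          capri_class=str(row.capri_class))
        conf = None
        if hasattr(row, "iplddt"):
            conf = ConfidenceRecord(
                label=str(row.model),
                iplddt=float(row.iplddt),
                ptm=float(row.ptm) if hasattr(row, "ptm") else None,
                iptm=float(row.iptm) if hasattr(row, "iptm") else None,
                model_confidence=(float(row.model_confidence)
                                  if hasattr(row, "model_confidence") else None),
                rank=int(row.rank),
            )
        records.append(EvaluationRecord(
            complex_id=str(row.complex_id),
            model_label=str(row.model),
            rank=int(row.rank),
            dock=dock,
            confidence=conf,
            has_interface_glycan=bool(getattr(row, "has_interface_glycan", False)),
            antibody_type=str(getattr(row, "antibody_type", "Ab")),
        ))
    return records
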