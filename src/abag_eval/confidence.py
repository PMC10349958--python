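"""Model confidence metrics: interface pLDDT, model confidence, ranking.

Interface pLDDT (I-pLDDT) is the mean per-residue pLDDT over the union of
antibody and antigen residues at the interface, where an interface residue
has any non-hydrogen atom within 4.0 A of the binding partner.  Models with
no interface residues receive the fixed floor score of 30, which is also
the lower bound of a meaningful pLDDT.  The model confidence score is the
standard linear combination 0.8*ipTM + 0.2*pTM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complex_scoring import find_contacts
from .structure_model import ComplexPartition, StructureModel, extract_plddt

__all__ = [
    "ConfidenceRecord",
    "interface_plddt",
    "model_confidence",
    "rank_models",
    "read_confidence_file",
    "NO_INTERFACE_PLDDT",
    "IPLDDT_CUTOFF",
]

NO_INTERFACE_PLDDT = 30.0
IPLDDT_CUTOFF = 4.0  # A, non-hydrogen atoms
MODEL_CONFIDENCE_WEIGHTS = (0.8, 0.2)  # (ipTM, pTM)


@dataclass
class ConfidenceRecord:
    label: str
    iplddt: float
    per_residue_plddt: dict = field(default_factory=dict, repr=False)
    ptm: float | None = None
    iptm: float | None = None
    model_confidence: float | None = None
    rank: int | None = None
    ranked_by: str = "model_confidence"


def interface_plddt(model: StructureModel, partition: ComplexPartition,
                    cutoff: float = IPLDDT_CUTOFF) -> float:
    """Mean pLDDT over interface residues of both sides; 30 when no interface."""
    contacts = find_contacts(model, partition, cutoff)
    residues = {key for pair in contacts.pairs for key in pair}
    if not residues:
        return NO_INTERFACE_PLDDT
    plddt = extract_plddt(model)
    return float(np.mean([plddt[key] for key in residues]))


def model_confidence(ptm: float, iptm: float) -> float:
    """Weighted combination 0.8*ipTM + 0.2*pTM."""
    if not 0.0 <= ptm <= 1.0 or not 0.0 <= iptm <= 1.0:
        raise ValueError("pTM and ipTM must lie in [0, 1]")
    w_iptm, w_ptm = MODEL_CONFIDENCE_WEIGHTS
    return w_iptm * iptm + w_ptm * ptm


def rank_models(records: list[ConfidenceRecord]) -> list[ConfidenceRecord]:
    """Order records by descending confidence; rank 1 is best.

    Uses model confidence when every record has one, otherwise falls back
    to I-pLDDT (flagged in `ranked_by`).  Ties are broken by model label
    so the ordering is reproducible regardless of input order.
    """
    if not records:
        raise ValueError("no records to rank")
    use_mc = all(r.model_confidence is not None for r in records)
    key_name = "model_confidence" if use_mc else "iplddt"
    ordered = sorted(records, key=lambda r: (-getattr(r, key_name), r.label))
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
        rec.ranked_by = key_name
    return ordered


def read_confidence_file(path) -> dict[str, float]:
    """Parse a per-model key-value text file (``ptm 0.82`` / ``iptm=0.74``)."""
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for sep in ("=", ":", None):
            parts = line.split(sep, 1) if sep else line.split(None, 1)
            if len(parts) == 2 and parts[1].strip():
                try:
                    values[parts[0].strip().lower()] = float(parts[1].strip())
                    break
                except ValueError:
                    continue
    return values


def build_confidence_record(model: StructureModel, partition: ComplexPartition,
                            label: str | None = None,
                            scores: dict[str, float] | None = None) -> ConfidenceRecord:
    """Assemble the full confidence record for one model."""
    scores = scores or {}
    ptm = scores.get("ptm")
    iptm = scores.get("iptm")
    mc = model_confidence(ptm, iptm) if ptm is not None and iptm is not None else None
    return ConfidenceRecord(
        label=label or model.label,
        iplddt=interface_plddt(model, partition),
        per_residue_plddt=extract_plddt(model),
        ptm=ptm,
        iptm=iptm,
        model_confidence=mc,
    )
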