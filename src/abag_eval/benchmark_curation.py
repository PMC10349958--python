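"""Benchmark nonredundancy and quality filters as a deterministic rule engine.

Candidate antibody-antigen entries are screened against a prior set (and
against earlier-accepted candidates) with four rule families, applied in
order: basic (resolution <= 3.0 A, release date after the cutoff), length
(unresolved-region fractions), sequence redundancy (>= 90% heavy or full
variable-domain identity together with an antigen sequence match) and
structural redundancy (< 5 A heavy-chain CA RMSD after antigen
superposition together with > 70% identity of heavy, light or concatenated
CDR sequences).  Every removal cites exactly one fired rule; processing in
release-date order makes the surviving set independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from Bio import Align

from .geometry import kabsch_superpose, rmsd
from .structure_model import ComplexPartition, StructureModel, map_chains

__all__ = [
    "BenchmarkEntry",
    "CurationDecision",
    "CurationConfig",
    "percent_identity",
    "antigen_match",
    "sequence_redundant",
    "structural_redundant",
    "length_filters",
    "basic_filters",
    "curate",
]


@dataclass
class BenchmarkEntry:
    entry_id: str
    release_date: date | None
    resolution: float
    heavy_variable: str
    light_variable: str | None = None
    antigen_sequences: list[str] = field(default_factory=list)
    antigen_seqres_lengths: list[int] = field(default_factory=list)
    antigen_resolved_lengths: list[int] = field(default_factory=list)
    cdr_sequence: str | None = None
    structure: StructureModel | None = None
    partition: ComplexPartition | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be positive")
        for seqres, resolved in zip(self.antigen_seqres_lengths,
                                    self.antigen_resolved_lengths):
            if resolved > seqres:
                raise ValueError(
                    f"{self.entry_id}: resolved length {resolved} exceeds seqres {seqres}")

    @property
    def full_variable(self) -> str:
        return self.heavy_variable + (self.light_variable or "")


@dataclass(frozen=True)
class CurationDecision:
    entry_id: str
    verdict: str  # keep | remove
    rule_fired: str = ""
    details: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in ("keep", "remove"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "remove" and not self.rule_fired:
            raise ValueError("removal decisions must cite a rule")


@dataclass
class CurationConfig:
    resolution_cutoff: float = 3.0
    date_cutoff: date = date(2018, 4, 30)
    sequence_identity_threshold: float = 0.90
    structural_identity_threshold: float = 0.70
    structural_rmsd_threshold: float = 5.0
    antigen_match_min_length: int = 30
    antigen_match_min_identity: float = 0.30
    exclusions: set = field(default_factory=set)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def _aligned_stats(alignment) -> tuple[int, int]:
    """(identical pairs, aligned columns) of a Bio.Align alignment."""
    seq_a, seq_b = alignment.sequences
    ident = cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols += 1
            if seq_a[i] == seq_b[j]:
                ident += 1
    return ident, cols


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity, normalised by the shorter sequence."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    ident, _ = _aligned_stats(aln)
    return ident / min(len(seq_a), len(seq_b))


def antigen_match(seq_a: str, seq_b: str, min_length: int = 30,
                  min_identity: float = 0.30) -> bool:
    """Local-alignment hit criterion standing in for a BLAST default hit."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if min(len(seq_a), len(seq_b)) < min_length:
        return False
    aln = _local_aligner().align(seq_a, seq_b)[0]
    ident, cols = _aligned_stats(aln)
    return cols >= min_length and (ident / cols if cols else 0.0) >= min_identity


def sequence_redundant(candidate: BenchmarkEntry, prior: BenchmarkEntry,
                       config: CurationConfig | None = None) -> bool:
    """Redundant iff high antibody identity AND an antigen sequence match.

    Nonredundancy requires either both heavy and full variable-domain
    identities below 90%, or no antigen chain match at all.
    """
    config = config or CurationConfig()
    heavy_id = percent_identity(candidate.heavy_variable, prior.heavy_variable)
    full_id = percent_identity(candidate.full_variable, prior.full_variable)
    antibody_similar = (heavy_id >= config.sequence_identity_threshold
                        or full_id >= config.sequence_identity_threshold)
    if not antibody_similar:
        return False
    return any(
        antigen_match(a, b, config.antigen_match_min_length,
                      config.antigen_match_min_identity)
        for a in candidate.antigen_sequences for b in prior.antigen_sequences)


def _heavy_ca_rmsd_after_antigen_superposition(candidate: BenchmarkEntry,
                                               prior: BenchmarkEntry) -> float:
    cand, pri = candidate.structure, prior.structure
    mapping = map_chains(cand, pri, candidate.partition, prior.partition)
    ag_mapping = mapping.restrict(candidate.partition.antigen_chains)
    ag_mod, ag_ref = [], []
    for mod_key, ref_key in ag_mapping.all_pairs():
        ca_m = cand.residue_by_key(mod_key).get_atom("CA")
        ca_r = pri.residue_by_key(ref_key).get_atom("CA")
        if ca_m is not None and ca_r is not None:
            ag_mod.append(ca_m.position)
            ag_ref.append(ca_r.position)
    if len(ag_mod) < 3:
        raise ValueError("antigen correspondence too small")
    transform, _ = kabsch_superpose(np.array(ag_mod), np.array(ag_ref))

    h_mapping = mapping.restrict([candidate.partition.heavy_chain])
    h_mod, h_ref = [], []
    for mod_key, ref_key in h_mapping.all_pairs():
        ca_m = cand.residue_by_key(mod_key).get_atom("CA")
        ca_r = pri.residue_by_key(ref_key).get_atom("CA")
        if ca_m is not None and ca_r is not None:
            h_mod.append(ca_m.position)
            h_ref.append(ca_r.position)
    if not h_mod:
        raise ValueError("no heavy-chain CA correspondence")
    return rmsd(transform.apply(np.array(h_mod)), np.array(h_ref))


def structural_redundant(candidate: BenchmarkEntry, prior: BenchmarkEntry,
                         config: CurationConfig | None = None) -> bool:
    """Redundant iff heavy-chain CA RMSD < 5 A after antigen superposition
    AND any of heavy/light/CDR sequence identities exceeds 70%."""
    config = config or CurationConfig()
    if candidate.structure is None or prior.structure is None:
        return False
    try:
        ca_rmsd = _heavy_ca_rmsd_after_antigen_superposition(candidate, prior)
    except ValueError as exc:
        warnings.warn(f"{candidate.entry_id} vs {prior.entry_id}: cannot build antigen "
                      f"correspondence ({exc}); keeping", stacklevel=2)
        return False
    if ca_rmsd >= config.structural_rmsd_threshold:
        return False
    identities = [percent_identity(candidate.heavy_variable, prior.heavy_variable)]
    if candidate.light_variable and prior.light_variable:
        identities.append(percent_identity(candidate.light_variable, prior.light_variable))
    if candidate.cdr_sequence and prior.cdr_sequence:
        identities.append(percent_identity(candidate.cdr_sequence, prior.cdr_sequence))
    return any(ident > config.structural_identity_threshold for ident in identities)


def length_filters(entry: BenchmarkEntry) -> CurationDecision:
    """Remove entries with largely unresolved antigen chains.

    Removal when the unresolved fraction (seqres - resolved)/seqres of any
    antigen chain exceeds 0.70, or exceeds 0.35 with a resolved length
    over 500 residues.
    """
    for seqres, resolved in zip(entry.antigen_seqres_lengths,
                                entry.antigen_resolved_lengths):
        if seqres == 0:
            raise ValueError(f"{entry.entry_id}: zero seqres length")
        frac = (seqres - resolved) / seqres
        if frac > 0.70:
            return CurationDecision(entry.entry_id, "remove", "length_unresolved_70",
                                    f"unresolved fraction {frac:.2f} > 0.70")
        if frac > 0.35 and resolved > 500:
            return CurationDecision(entry.entry_id, "remove", "length_unresolved_35_large",
                                    f"unresolved fraction {frac:.2f} > 0.35 and "
                                    f"resolved length {resolved} > 500")
    return CurationDecision(entry.entry_id, "keep")


def basic_filters(entry: BenchmarkEntry, resolution_cutoff: float = 3.0,
                  date_cutoff: date = date(2018, 4, 30)) -> CurationDecision:
    """Resolution <= cutoff (inclusive) and release strictly after the date cutoff."""
    if entry.release_date is None:
        raise ValueError(f"{entry.entry_id}: missing release date")
    if entry.resolution > resolution_cutoff:
        return CurationDecision(entry.entry_id, "remove", "resolution",
                                f"{entry.resolution} > {resolution_cutoff}")
    if entry.release_date <= date_cutoff:
        return CurationDecision(entry.entry_id, "remove", "release_date",
                                f"{entry.release_date} <= {date_cutoff}")
    return CurationDecision(entry.entry_id, "keep")


def curate(candidates, priors=(), config: CurationConfig | None = None
           ) -> tuple[list[CurationDecision], list[BenchmarkEntry]]:
    """Apply all filters; return (decisions, surviving entries).

    Candidates are processed in (release date, entry id) order; each
    survivor joins the comparison pool for later candidates, so the
    surviving identity set does not depend on input order.
    """
    config = config or CurationConfig()
    ordered = sorted(candidates, key=lambda e: (e.release_date or date.min, e.entry_id))
    decisions: list[CurationDecision] = []
    survivors: list[BenchmarkEntry] = []
    pool = list(priors)
    for entry in ordered:
        if entry.entry_id in config.exclusions:
            decisions.append(CurationDecision(entry.entry_id, "remove", "manual_exclusion"))
            continue
        decision = basic_filters(entry, config.resolution_cutoff, config.date_cutoff)
        if decision.verdict == "keep":
            decision = length_filters(entry)
        if decision.verdict == "keep":
            for other in pool:
                if sequence_redundant(entry, other, config):
                    decision = CurationDecision(
                        entry.entry_id, "remove", "sequence_redundant",
                        f"redundant with {other.entry_id}")
                    break
                if structural_redundant(entry, other, config):
                    decision = CurationDecision(
                        entry.entry_id, "remove", "structural_redundant",
                        f"redundant with {other.entry_id}")
                    break
        decisions.append(decision)
        if decision.verdict == "keep":
            survivors.append(entry)
            pool.append(entry)
    return decisions, survivors
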