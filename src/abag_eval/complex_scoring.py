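"""Model-vs-reference complex accuracy: fnat, I-RMSD, L-RMSD, DockQ, CAPRI class.

Conventions follow the DockQ / CAPRI assessment standard for
antibody-antigen complexes: the antigen is the receptor body and the
antibody (heavy + light pooled) is the ligand body.  Native contacts use a
5 A heavy-atom cutoff; the reference interface for I-RMSD uses 10 A.
All cutoffs are inclusive and hydrogens are excluded by element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import kabsch_superpose, rmsd
from .structure_model import (ChainMapping, ComplexPartition, ResidueKey,
                              StructureModel, map_chains)

__all__ = [
    "ContactSet",
    "DockScores",
    "find_contacts",
    "fnat",
    "i_rmsd",
    "l_rmsd",
    "dockq_score",
    "capri_class",
    "score_model",
    "CAPRI_ORDER",
]

FNAT_CUTOFF = 5.0       # A, heavy-atom, native contact definition
INTERFACE_CUTOFF = 10.0  # A, heavy-atom, I-RMSD interface definition
DOCKQ_D1 = 1.5          # A, I-RMSD scaling constant
DOCKQ_D2 = 8.5          # A, L-RMSD scaling constant

CAPRI_ORDER = {"Incorrect": 0, "Acceptable": 1, "Medium": 2, "High": 3}


@dataclass(frozen=True)
class ContactSet:
    """Cross-partition residue contacts (antibody side first in each pair)."""

    pairs: frozenset
    cutoff: float
    atom_scope: str = "heavy"


@dataclass(frozen=True)
class DockScores:
    fnat: float
    i_rmsd: float
    l_rmsd: float
    dockq: float
    capri_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat outside [0, 1]")
        if self.i_rmsd < 0 or self.l_rmsd < 0:
            raise ValueError("RMSD values must be non-negative")
        if self.capri_class not in CAPRI_ORDER:
            raise ValueError(f"unknown CAPRI class {self.capri_class!r}")


def _side_atoms(structure: StructureModel, chain_ids):
    """(coords, residue keys) for heavy atoms of the given chains' polymer residues."""
    coords, keys = [], []
    for cid in chain_ids:
        for res in structure.chains[cid]:
            if res.kind != "polymer":
                continue
            for atom in res.heavy_atoms():
                coords.append(atom.position)
                keys.append(res.key)
    return np.array(coords, dtype=float).reshape(-1, 3), keys


def find_contacts(structure: StructureModel, partition: ComplexPartition,
                  cutoff: float = FNAT_CUTOFF, atom_scope: str = "heavy") -> ContactSet:
    """All antibody-antigen residue pairs with any heavy-atom pair within `cutoff`."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if atom_scope != "heavy":
        raise ValueError("only heavy-atom scope is supported")
    ab_xyz, ab_keys = _side_atoms(structure, partition.antibody_chains)
    ag_xyz, ag_keys = _side_atoms(structure, partition.antigen_chains)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(ab_xyz) and len(ag_xyz):
        tree = cKDTree(ag_xyz)
        for i, js in enumerate(tree.query_ball_point(ab_xyz, cutoff)):
            for j in js:
                pairs.add((ab_keys[i], ag_keys[j]))
    return ContactSet(frozenset(pairs), cutoff, atom_scope)


def native_contact_recovery(model: StructureModel, reference: StructureModel,
                            mapping: ChainMapping, partition: ComplexPartition,
                            reference_partition: ComplexPartition | None = None,
                            cutoff: float = FNAT_CUTOFF) -> tuple[int, int]:
    """(native contacts preserved in the model, total native contacts)."""
    ref_part = reference_partition or partition
    native = find_contacts(reference, ref_part, cutoff).pairs
    if not native:
        raise ValueError("no native interface: reference has zero contacts")
    model_contacts = find_contacts(model, partition, cutoff).pairs
    ref_to_model = mapping.ref_to_model()
    preserved = 0
    for ab_ref, ag_ref in native:
        ab_mod = ref_to_model.get(ab_ref)
        ag_mod = ref_to_model.get(ag_ref)
        if ab_mod is not None and ag_mod is not None and (ab_mod, ag_mod) in model_contacts:
            preserved += 1
    return preserved, len(native)


def fnat(model: StructureModel, reference: StructureModel, mapping: ChainMapping,
         partition: ComplexPartition,
         reference_partition: ComplexPartition | None = None) -> float:
    """Fraction of native (reference) interface contacts reproduced by the model."""
    preserved, total = native_contact_recovery(model, reference, mapping,
                                               partition, reference_partition)
    return preserved / total


def _paired_backbone(model: StructureModel, reference: StructureModel,
                     mapping_pairs) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (by atom name) over mapped residue pairs."""
    mod_xyz, ref_xyz = [], []
    for mod_key, ref_key in mapping_pairs:
        mod_res = model.residue_by_key(mod_key)
        ref_res = reference.residue_by_key(ref_key)
        for atom in ref_res.backbone_atoms():
            mod_atom = mod_res.get_atom(atom.name)
            if mod_atom is not None:
                ref_xyz.append(atom.position)
                mod_xyz.append(mod_atom.position)
    return (np.array(mod_xyz, dtype=float).reshape(-1, 3),
            np.array(ref_xyz, dtype=float).reshape(-1, 3))


def reference_interface_residues(reference: StructureModel,
                                 partition: ComplexPartition,
                                 cutoff: float = INTERFACE_CUTOFF) -> set[ResidueKey]:
    """Residues of either side with any heavy atom within `cutoff` of the partner."""
    contacts = find_contacts(reference, partition, cutoff)
    residues: set[ResidueKey] = set()
    for ab_key, ag_key in contacts.pairs:
        residues.add(ab_key)
        residues.add(ag_key)
    return residues


def i_rmsd(model: StructureModel, reference: StructureModel, mapping: ChainMapping,
           partition: ComplexPartition,
           reference_partition: ComplexPartition | None = None) -> float:
    """Backbone RMSD over the reference-defined interface, after superposing on it."""
    ref_part = reference_partition or partition
    interface = reference_interface_residues(reference, ref_part)
    pairs = [(m, r) for m, r in mapping.all_pairs() if r in interface]
    mod_xyz, ref_xyz = _paired_backbone(model, reference, pairs)
    if len(mod_xyz) < 3:
        raise ValueError("interface too small for superposition")
    _, value = kabsch_superpose(mod_xyz, ref_xyz)
    return value


def l_rmsd(model: StructureModel, reference: StructureModel, mapping: ChainMapping,
           partition: ComplexPartition,
           reference_partition: ComplexPartition | None = None) -> float:
    """Antibody (ligand) backbone RMSD after superposing on the antigen (receptor)."""
    ref_part = reference_partition or partition
    rec_pairs = [(m, r) for m, r in mapping.all_pairs()
                 if m[0] in partition.antigen_chains]
    lig_pairs = [(m, r) for m, r in mapping.all_pairs()
                 if m[0] in partition.antibody_chains]
    rec_mod, rec_ref = _paired_backbone(model, reference, rec_pairs)
    lig_mod, lig_ref = _paired_backbone(model, reference, lig_pairs)
    if len(rec_mod) < 3:
        raise ValueError("receptor backbone too small for superposition")
    if len(lig_mod) < 1:
        raise ValueError("no mapped ligand backbone atoms")
    transform, _ = kabsch_superpose(rec_mod, rec_ref)
    return rmsd(transform.apply(lig_mod), lig_ref)


def dockq_score(fnat_value: float, i_rmsd_value: float, l_rmsd_value: float) -> float:
    """DockQ = (fnat + 1/(1+(I-RMSD/1.5)^2) + 1/(1+(L-RMSD/8.5)^2)) / 3."""
    if not 0.0 <= fnat_value <= 1.0:
        raise ValueError("fnat outside [0, 1]")
    if i_rmsd_value < 0 or l_rmsd_value < 0:
        raise ValueError("RMSD values must be non-negative")
    irms_term = 1.0 / (1.0 + (i_rmsd_value / DOCKQ_D1) ** 2)
    lrms_term = 1.0 / (1.0 + (l_rmsd_value / DOCKQ_D2) ** 2)
    return (fnat_value + irms_term + lrms_term) / 3.0


def capri_class(fnat_value: float, i_rmsd_value: float, l_rmsd_value: float) -> str:
    """CAPRI accuracy class from (fnat, I-RMSD, L-RMSD)."""
    if not 0.0 <= fnat_value <= 1.0:
        raise ValueError("fnat outside [0, 1]")
    if i_rmsd_value < 0 or l_rmsd_value < 0:
        raise ValueError("RMSD values must be non-negative")
    if fnat_value >= 0.5 and (i_rmsd_value <= 1.0 or l_rmsd_value <= 1.0):
        return "High"
    if fnat_value >= 0.3 and (i_rmsd_value <= 2.0 or l_rmsd_value <= 5.0):
        return "Medium"
    if fnat_value >= 0.1 and (i_rmsd_value <= 4.0 or l_rmsd_value <= 10.0):
        return "Acceptable"
    return "Incorrect"


def score_model(model: StructureModel, reference: StructureModel,
                partition: ComplexPartition,
                reference_partition: ComplexPartition | None = None,
                mapping: ChainMapping | None = None) -> DockScores:
    """Full DockQ-style assessment of one model against its reference."""
    ref_part = reference_partition or partition
    if mapping is None:
        mapping = map_chains(model, reference, partition, ref_part)
    f = fnat(model, reference, mapping, partition, ref_part)
    i = i_rmsd(model, reference, mapping, partition, ref_part)
    l = l_rmsd(model, reference, mapping, partition, ref_part)
    return DockScores(fnat=f, i_rmsd=i, l_rmsd=l,
                      dockq=dockq_score(f, i, l),
                      capri_class=capri_class(f, i, l))
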