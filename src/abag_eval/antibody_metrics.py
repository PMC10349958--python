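"""CDR/framework partition from AHo numbering and per-loop RMSD.

The AHo scheme numbers antibody variable domains 1-149; CDR loops occupy
fixed position ranges (CDR1 24-42, CDR2 57-76, CDR3 107-138) and every
other position is framework.  Numbering is consumed as an externally
produced table (e.g. from ANARCI); this module never derives it from
sequence.  Loop accuracy is the backbone RMSD of a loop after a single
joint superposition of the heavy+light framework backbone, so a mis-built
loop cannot hide behind a loop-local fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose, rmsd
from .structure_model import (ChainMapping, ComplexPartition, ResidueKey,
                              StructureModel, map_chains)

__all__ = [
    "CDR_RANGES",
    "NumberedAntibody",
    "CdrRmsdResult",
    "region_for_position",
    "assign_regions",
    "read_numbering_table",
    "cdr_rmsd",
    "cdr_rmsd_all",
    "antibody_type",
]

CDR_RANGES = {"CDR1": (24, 42), "CDR2": (57, 76), "CDR3": (107, 138)}
AHO_MAX_POSITION = 149


def region_for_position(scheme_position: int) -> str:
    for region, (lo, hi) in CDR_RANGES.items():
        if lo <= scheme_position <= hi:
            return region
    return "FR"


@dataclass(frozen=True)
class NumberedResidue:
    chain_id: str
    residue_key: ResidueKey
    scheme_position: int
    insertion_code: str
    region: str


@dataclass
class NumberedAntibody:
    residues: list[NumberedResidue]

    def by_chain(self, chain_id: str) -> list[NumberedResidue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def region_keys(self, chain_id: str, region: str) -> list[ResidueKey]:
        return [r.residue_key for r in self.by_chain(chain_id) if r.region == region]

    def framework_keys(self, chain_ids) -> list[ResidueKey]:
        return [r.residue_key for r in self.residues
                if r.chain_id in chain_ids and r.region == "FR"]


@dataclass
class CdrRmsdResult:
    loop_rmsd: dict[str, float]
    framework_rmsd: float


def read_numbering_table(path) -> pd.DataFrame:
    """Read a numbering TSV: chain, seq_position, insertion_code, scheme_position."""
    table = pd.read_csv(path, sep="\t", dtype={"chain": str, "insertion_code": str})
    table["insertion_code"] = table["insertion_code"].fillna("")
    return table


def assign_regions(numbering_table: pd.DataFrame) -> NumberedAntibody:
    """Label each numbered antibody residue FR/CDR1/CDR2/CDR3 by AHo position.

    The table must contain columns chain, seq_position, insertion_code,
    scheme_position.  Insertions at a shared scheme position are ordered
    alphabetically by insertion code.
    """
    required = {"chain", "seq_position", "insertion_code", "scheme_position"}
    missing = required - set(numbering_table.columns)
    if missing:
        raise ValueError(f"numbering table missing columns: {sorted(missing)}")
    residues: list[NumberedResidue] = []
    for chain_id, group in numbering_table.groupby("chain", sort=False):
        pairs = list(zip(group["scheme_position"], group["insertion_code"].fillna("")))
        if len(set(pairs)) != len(pairs):
            raise ValueError(f"chain {chain_id}: duplicate scheme position in numbering")
        group = group.sort_values(["scheme_position", "insertion_code"], kind="stable")
        for row in group.itertuples():
            pos = int(row.scheme_position)
            if not 1 <= pos <= AHO_MAX_POSITION:
                raise ValueError(f"scheme position {pos} outside 1-{AHO_MAX_POSITION}")
            icode = row.insertion_code if isinstance(row.insertion_code, str) else ""
            residues.append(NumberedResidue(
                chain_id=str(chain_id),
                residue_key=(str(chain_id), int(row.seq_position), icode),
                scheme_position=pos,
                insertion_code=icode,
                region=region_for_position(pos),
            ))
    return NumberedAntibody(residues)


def _backbone_pairs(model: StructureModel, reference: StructureModel,
                    ref_to_model: dict, keys) -> tuple[np.ndarray, np.ndarray]:
    mod_xyz, ref_xyz = [], []
    for ref_key in keys:
        mod_key = ref_to_model.get(ref_key)
        if mod_key is None:
            continue
        ref_res = reference.residue_by_key(ref_key)
        mod_res = model.residue_by_key(mod_key)
        for atom in ref_res.backbone_atoms():
            mod_atom = mod_res.get_atom(atom.name)
            if mod_atom is not None:
                ref_xyz.append(atom.position)
                mod_xyz.append(mod_atom.position)
    return (np.array(mod_xyz, dtype=float).reshape(-1, 3),
            np.array(ref_xyz, dtype=float).reshape(-1, 3))


def _loop_name(chain_id: str, partition: ComplexPartition, region: str) -> str:
    prefix = "H" if chain_id == partition.heavy_chain else "L"
    return prefix + region[-1]


def cdr_rmsd_all(model: StructureModel, reference: StructureModel,
                 numbered: NumberedAntibody, partition: ComplexPartition,
                 mapping: ChainMapping | None = None) -> CdrRmsdResult:
    """Backbone RMSD of every CDR loop after joint framework superposition.

    The numbering table refers to reference residue keys; model residues
    are located through the chain mapping.  Heavy and light frameworks are
    superposed as a single rigid body, then each loop's RMSD is measured
    in place (no per-loop refit).
    """
    if mapping is None:
        mapping = map_chains(model, reference, partition)
    ref_to_model = mapping.ref_to_model()
    ab_chains = partition.antibody_chains

    fw_mod, fw_ref = _backbone_pairs(model, reference, ref_to_model,
                                     numbered.framework_keys(ab_chains))
    if len(fw_mod) < 3:
        raise ValueError("fewer than 3 mapped framework residue pairs")
    transform, framework_rmsd = kabsch_superpose(fw_mod, fw_ref)

    loops: dict[str, float] = {}
    for chain_id in ab_chains:
        for region in CDR_RANGES:
            keys = numbered.region_keys(chain_id, region)
            if not keys:
                continue
            loop_mod, loop_ref = _backbone_pairs(model, reference, ref_to_model, keys)
            name = _loop_name(chain_id, partition, region)
            if len(loop_mod) == 0:
                raise ValueError(f"loop {name} unresolved in reference or model")
            loops[name] = rmsd(transform.apply(loop_mod), loop_ref)
    return CdrRmsdResult(loop_rmsd=loops, framework_rmsd=framework_rmsd)


def cdr_rmsd(model: StructureModel, reference: StructureModel,
             numbered: NumberedAntibody, partition: ComplexPartition,
             loop: str, mapping: ChainMapping | None = None) -> float:
    """RMSD of a single named loop (H1..H3, L1..L3)."""
    result = cdr_rmsd_all(model, reference, numbered, partition, mapping)
    if loop not in result.loop_rmsd:
        raise ValueError(f"loop {loop} absent from the antibody")
    return result.loop_rmsd[loop]


def antibody_type(partition: ComplexPartition) -> str:
    """"Nano" (single-domain VHH) when no light chain is present, else "Ab"."""
    return "Nano" if partition.is_nanobody else "Ab"
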