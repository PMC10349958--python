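"""Macromolecular structure data model with PDB/mmCIF I/O and complex partitioning.

The in-memory model is deliberately small: ordered chains of residues of
atoms, keyed by author numbering ``(chain_id, seq_position, insertion_code)``.
Predicted models carry per-residue pLDDT (0-100) in the atom temperature
factor, exactly as structure predictors write it.  Parsing and PDB output go
through gemmi; this module only normalises the result (altloc selection,
polymer/hetero classification) into the package's containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ComplexPartition",
    "ChainMapping",
    "read_structure",
    "write_pdb",
    "partition_complex",
    "map_chains",
    "extract_plddt",
]

HYDROGEN_ELEMENTS = frozenset({"H", "D"})
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_ONE_TO_THREE = {v: k for k, v in reversed(_THREE_TO_ONE.items())}

ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    tempfactor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not np.isfinite(self.tempfactor):
            raise ValueError(f"atom {self.name}: tempfactor must be finite")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS


@dataclass
class Residue:
    chain_id: str
    seq_position: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    kind: str = "polymer"  # polymer | hetero

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.seq_position}: no atoms")
        if self.kind not in ("polymer", "hetero"):
            raise ValueError(f"unknown residue kind {self.kind!r}")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_position, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def backbone_atoms(self) -> list[Atom]:
        """Backbone atoms N, CA, C, O present in the residue, in that order."""
        return [a for name in BACKBONE_ATOMS if (a := self.get_atom(name)) is not None]

    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name.upper(), "X")


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"
    label: str = ""
    seqres: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            seen: set[ResidueKey] = set()
            for res in residues:
                if res.key in seen:
                    raise ValueError(f"duplicate residue key {res.key}")
                seen.add(res.key)

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def polymer_residues(self, chain_id: str | None = None) -> list[Residue]:
        chains = [chain_id] if chain_id is not None else list(self.chains)
        return [r for c in chains for r in self.chains[c] if r.kind == "polymer"]

    def hetero_residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues if r.kind == "hetero"]

    def residue_by_key(self, key: ResidueKey) -> Residue:
        chain_id = key[0]
        for res in self.chains.get(chain_id, []):
            if res.key == key:
                return res
        raise KeyError(f"no residue {key}")

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter() for r in self.polymer_residues(chain_id))

    def copy(self) -> "StructureModel":
        chains = {
            cid: [
                Residue(r.chain_id, r.seq_position, r.insertion_code, r.name,
                        [Atom(a.name, a.element, a.position.copy(), a.occupancy,
                              a.tempfactor, a.altloc, a.is_hetero) for a in r.atoms],
                        r.kind)
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return StructureModel(chains, self.source_format, self.label,
                              {c: list(s) for c, s in self.seqres.items()})

    def coordinates(self, chain_ids=None, heavy_only: bool = False) -> np.ndarray:
        chain_ids = list(self.chains) if chain_ids is None else list(chain_ids)
        coords = [a.position
                  for cid in chain_ids for r in self.chains[cid]
                  for a in (r.heavy_atoms() if heavy_only else r.atoms)]
        return np.array(coords, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class ComplexPartition:
    """Role assignment of chains: antibody heavy/light versus antigen."""

    heavy_chain: str | None
    light_chain: str | None
    antigen_chains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.antigen_chains:
            raise ValueError("antigen chain list must be non-empty")
        if self.light_chain is not None and self.heavy_chain is None:
            raise ValueError("light chain present without a heavy chain")
        ab = self.antibody_chains
        if set(ab) & set(self.antigen_chains):
            raise ValueError("antibody and antigen chain sets overlap")
        object.__setattr__(self, "antigen_chains", tuple(self.antigen_chains))

    @property
    def antibody_chains(self) -> tuple[str, ...]:
        chains = []
        if self.heavy_chain is not None:
            chains.append(self.heavy_chain)
        if self.light_chain is not None:
            chains.append(self.light_chain)
        return tuple(chains)

    @property
    def is_nanobody(self) -> bool:
        return self.light_chain is None


@dataclass
class ChainMapping:
    """Model-to-reference residue correspondences, per aligned chain pair."""

    pairs: dict[tuple[str, str], list[tuple[ResidueKey, ResidueKey]]]

    def all_pairs(self) -> list[tuple[ResidueKey, ResidueKey]]:
        return [p for chain_pairs in self.pairs.values() for p in chain_pairs]

    def model_to_ref(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.all_pairs())

    def ref_to_model(self) -> dict[ResidueKey, ResidueKey]:
        return {ref: mod for mod, ref in self.all_pairs()}

    def restrict(self, model_chains) -> "ChainMapping":
        model_chains = set(model_chains)
        return ChainMapping({k: v for k, v in self.pairs.items() if k[0] in model_chains})


def _select_altlocs(raw_atoms):
    """Keep one conformer per atom name: highest occupancy, tie -> first seen."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in raw_atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > by_name[atom.name].occupancy:
            by_name[atom.name] = atom
    return [by_name[name] for name in order]


def read_structure(path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    The first model of multi-model files is used.  Hydrogens are retained
    (flagged by element); alternate conformers are reduced to the
    highest-occupancy one.  Chain names follow the author (PDB-dialect)
    naming in both formats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path.name}: {exc}") from exc
    if format is None:
        format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path.name}: structure contains no models")

    model = StructureModel(source_format=format, label=path.stem)
    gmodel = st[0]
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            is_het = gres.het_flag == "H"
            atoms = []
            for gatom in gres:
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name,
                    position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=min(max(gatom.occ, 0.0), 1.0),
                    tempfactor=gatom.b_iso,
                    altloc=gatom.altloc if gatom.altloc != "\x00" else "",
                    is_hetero=is_het,
                ))
            atoms = _select_altlocs(atoms)
            if not atoms:
                continue
            residues.append(Residue(
                chain_id=gchain.name,
                seq_position=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name=gres.name,
                atoms=atoms,
                kind="hetero" if is_het else "polymer",
            ))
        if residues:
            model.chains.setdefault(gchain.name, []).extend(residues)

    # SEQRES (full polymer sequence) when present, for curation length checks
    for entity in st.entities:
        if entity.entity_type == gemmi.EntityType.Polymer and entity.full_sequence:
            names = [gemmi.Entity.first_mon(m) for m in entity.full_sequence]
            for sub in entity.subchains:
                chain_name = next((ch.name for ch in gmodel
                                   if any(r.subchain == sub for r in ch)), None)
                if chain_name is not None:
                    model.seqres[chain_name] = names

    if not model.chains:
        raise ValueError(f"{path.name}: empty structure")
    if not any(r.kind == "polymer" for rs in model.chains.values() for r in rs):
        raise ValueError(f"{path.name}: no polymer residues")
    return model


def write_pdb(structure: StructureModel, path) -> None:
    """Write the model as a PDB file (coordinates at 0.001 A precision)."""
    st = gemmi.Structure()
    st.name = structure.label or "model"
    gmodel = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_position, res.insertion_code or " ")
            gres.het_flag = "H" if res.kind == "hetero" else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.tempfactor
                if atom.altloc:
                    gatom.altloc = atom.altloc
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    # populate entity sequences so SEQRES records are written
    for entity in st.entities:
        if entity.entity_type != gemmi.EntityType.Polymer or not entity.subchains:
            continue
        sub = entity.subchains[0]
        entity.full_sequence = [r.name for ch in st[0] for r in ch if r.subchain == sub]
    st.write_pdb(str(path))


def partition_complex(structure: StructureModel, heavy: str | None,
                      light: str | None, antigens) -> ComplexPartition:
    """Validate chain roles against the structure and build a partition.

    An antibody with no light chain is a nanobody (VHH).
    """
    antigens = tuple(antigens)
    named = [c for c in (heavy, light, *antigens) if c is not None]
    missing = [c for c in named if c not in structure.chains]
    if missing:
        raise ValueError(f"chains not present in structure: {missing}")
    return ComplexPartition(heavy_chain=heavy, light_chain=light, antigen_chains=antigens)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _align_chain_pair(model: StructureModel, ref: StructureModel,
                      model_chain: str, ref_chain: str):
    """Align one-letter sequences; return (pairs, identity over shorter chain)."""
    mod_res = model.polymer_residues(model_chain)
    ref_res = ref.polymer_residues(ref_chain)
    seq_m = "".join(r.one_letter() for r in mod_res)
    seq_r = "".join(r.one_letter() for r in ref_res)
    if not seq_m or not seq_r:
        raise ValueError(f"empty polymer chain in alignment: {model_chain}/{ref_chain}")
    aln = _make_aligner().align(seq_m, seq_r)[0]
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    n_ident = 0
    for (m_start, m_end), (r_start, r_end) in zip(*aln.aligned):
        for i, j in zip(range(m_start, m_end), range(r_start, r_end)):
            pairs.append((mod_res[i].key, ref_res[j].key))
            if seq_m[i] == seq_r[j]:
                n_ident += 1
    identity = n_ident / min(len(seq_m), len(seq_r))
    return pairs, identity


def map_chains(model: StructureModel, reference: StructureModel,
               partition: ComplexPartition,
               reference_partition: ComplexPartition | None = None,
               identity_floor: float = 0.6) -> ChainMapping:
    """Residue correspondence between a model and its reference complex.

    Heavy maps to heavy and light to light; antigen chains are assigned
    greedily by best alignment identity, which resolves multi-copy
    antigens deterministically.  Only polymer residues participate;
    reference residues missing from the alignment are simply absent from
    the mapping (mirroring removal of unresolved residues before scoring).
    """
    ref_part = reference_partition or partition
    pair_map: dict[tuple[str, str], list[tuple[ResidueKey, ResidueKey]]] = {}

    def add(model_chain: str, ref_chain: str) -> None:
        pairs, identity = _align_chain_pair(model, reference, model_chain, ref_chain)
        if identity < identity_floor:
            raise ValueError(
                f"chain {model_chain} vs {ref_chain}: alignment identity "
                f"{identity:.2f} below floor {identity_floor}; probable chain mis-assignment")
        pair_map[(model_chain, ref_chain)] = pairs

    if (partition.heavy_chain is None) != (ref_part.heavy_chain is None) or \
       (partition.light_chain is None) != (ref_part.light_chain is None):
        raise ValueError("model and reference partitions assign different antibody roles")
    if partition.heavy_chain is not None:
        add(partition.heavy_chain, ref_part.heavy_chain)
    if partition.light_chain is not None:
        add(partition.light_chain, ref_part.light_chain)

    # antigen chains: greedy best-identity assignment
    remaining_ref = list(ref_part.antigen_chains)
    for model_chain in partition.antigen_chains:
        if not remaining_ref:
            break
        scored = []
        for ref_chain in remaining_ref:
            pairs, identity = _align_chain_pair(model, reference, model_chain, ref_chain)
            scored.append((identity, ref_chain, pairs))
        scored.sort(key=lambda t: (-t[0], t[1]))
        identity, ref_chain, pairs = scored[0]
        if identity < identity_floor:
            raise ValueError(
                f"antigen chain {model_chain}: best identity {identity:.2f} "
                f"below floor {identity_floor}")
        pair_map[(model_chain, ref_chain)] = pairs
        remaining_ref.remove(ref_chain)

    return ChainMapping(pair_map)


def extract_plddt(structure: StructureModel) -> dict[ResidueKey, float]:
    """Per-residue pLDDT from the temperature-factor column.

    Predictors write one value per residue on every atom; the CA atom is
    taken as the residue representative, with a mean over heavy atoms as
    fallback for residues lacking a CA.
    """
    scores: dict[ResidueKey, float] = {}
    for res in structure.polymer_residues():
        ca = res.get_atom("CA")
        if ca is not None:
            scores[res.key] = float(ca.tempfactor)
        else:
            heavy = res.heavy_atoms() or res.atoms
            scores[res.key] = float(np.mean([a.tempfactor for a in heavy]))
    if scores and all(v == 0.0 for v in scores.values()):
        warnings.warn("all temperature factors are zero; pLDDT may be absent",
                      stacklevel=2)
    return scores
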