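"""Synthetic complexes, decoys, MSAs and glycans with planted ground truth.

The generator emulates the inputs of an antibody-antigen model evaluation
study at desk scale: a reference complex with an antibody-like chain
(framework plus CDR loops under AHo-style numbering) in contact with an
antigen chain; rigid-body decoys of known displacement spanning all CAPRI
accuracy classes; per-residue pLDDT planted as a linear-in-error signal
with Gaussian noise; MSAs with a planted cluster structure; and saccharide
hetero-residues placed at controlled distances from the antibody.

Planted truths are exact where geometry allows: a pure-translation decoy
has L-RMSD equal to the translation magnitude, and a cluster-planted MSA
has a recoverable cluster count.  Everything is bit-reproducible given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .antibody_metrics import CDR_RANGES, antibody_type
from .complex_scoring import find_contacts, score_model
from .confidence import interface_plddt, model_confidence
from .geometry import RigidTransform
from .structure_model import (Atom, ChainMapping, ComplexPartition, Residue,
                              StructureModel, write_pdb)

__all__ = [
    "DecoyConfig",
    "SyntheticComplex",
    "Decoy",
    "build_toy_complex",
    "make_decoys",
    "make_msa",
    "attach_glycan",
    "make_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# backbone atom offsets relative to CA (idealized, A)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, -0.5, 0.3]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.5, 0.3]),
    "O": np.array([1.4, 1.6, 0.4]),
}
_CONTACT_OFFSET = 3.9   # A between facing antibody/antigen residues
_ANTIGEN_START = 105    # 0-based heavy residue index the antigen runs along


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy family specification with planted pLDDT model."""

    seed: int = 0
    translation_magnitudes: tuple = (0.0, 0.5, 1.5, 3.0, 5.0, 8.0, 12.0, 20.0, 40.0)
    translation_direction: tuple = (1.0, 0.0, 0.0)
    rotation_magnitudes: tuple = ()     # degrees
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    loop_noise_sd: float = 0.0          # A, Gaussian, CDR atoms only
    plddt_base: float = 95.0
    plddt_slope: float = 1.5            # pLDDT units per A of planted error
    plddt_noise_sd: float = 4.0
    glycan_placements: tuple = ()       # (code, distance-to-antibody A)

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.translation_magnitudes):
            raise ValueError("translation magnitudes must be non-negative")
        if any(m < 0 for m in self.rotation_magnitudes):
            raise ValueError("rotation magnitudes must be non-negative")
        if self.loop_noise_sd < 0 or self.plddt_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class SyntheticComplex:
    reference: StructureModel
    partition: ComplexPartition
    numbering: pd.DataFrame
    seed: int
    label: str = "synthetic"


@dataclass
class Decoy:
    label: str
    structure: StructureModel
    planted_translation: float
    planted_rotation_deg: float
    planted_error: float          # RMS antibody backbone displacement, A
    expected_l_rmsd: float | None  # exact only for pure rigid decoys
    transform: RigidTransform


def _make_residue(chain_id: str, seq_position: int, letter: str,
                  ca: np.ndarray, hetero: bool = False) -> Residue:
    atoms = [Atom(name=name, element=name[0], position=ca + off)
             for name, off in _BACKBONE_OFFSETS.items()]
    return Residue(chain_id=chain_id, seq_position=seq_position,
                   insertion_code="", name=_ONE_TO_THREE[letter], atoms=atoms,
                   kind="hetero" if hetero else "polymer")


def _helix_ca(i: int, phase: float) -> np.ndarray:
    return np.array([3.0 * i,
                     1.8 * np.sin(0.8 * i + phase),
                     1.8 * np.cos(0.8 * i + phase)])


def build_toy_complex(seed: int = 0, include_light: bool = False,
                      n_antibody: int = 149, n_antigen: int = 40) -> SyntheticComplex:
    """Deterministic idealized antibody(-like)/antigen complex.

    The heavy chain is a gentle helix of `n_antibody` backbone-only
    residues numbered 1..n (scheme position equal to author position, so
    all three CDR ranges are populated); the antigen chain runs parallel
    to the CDR3-containing segment at a fixed 3.9 A offset, creating a
    well-defined native interface.  An optional light chain sits away
    from the antigen.  Sequences are random per seed, which makes chain
    mapping by alignment unambiguous.
    """
    if n_antibody < 142:
        raise ValueError("antibody chain too short to populate all CDR ranges")
    if not 5 <= n_antigen <= n_antibody - _ANTIGEN_START:
        raise ValueError("antigen length incompatible with the interface segment")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi))

    chains: dict[str, list[Residue]] = {}
    heavy_seq = rng.choice(list(AMINO_ACIDS), n_antibody)
    chains["H"] = [_make_residue("H", i + 1, heavy_seq[i], _helix_ca(i, phase))
                   for i in range(n_antibody)]
    if include_light:
        light_seq = rng.choice(list(AMINO_ACIDS), n_antibody)
        chains["L"] = [_make_residue("L", i + 1, light_seq[i],
                                     _helix_ca(i, phase) + np.array([0.0, -25.0, 0.0]))
                       for i in range(n_antibody)]
    antigen_seq = rng.choice(list(AMINO_ACIDS), n_antigen)
    chains["A"] = [
        _make_residue("A", j + 1, antigen_seq[j],
                      _helix_ca(_ANTIGEN_START + j, phase)
                      + np.array([0.0, _CONTACT_OFFSET, 0.0]))
        for j in range(n_antigen)
    ]

    reference = StructureModel(chains=chains, label=f"synthetic_{seed}")
    partition = ComplexPartition(heavy_chain="H",
                                 light_chain="L" if include_light else None,
                                 antigen_chains=("A",))
    rows = [{"chain": cid, "seq_position": i + 1, "insertion_code": "",
             "scheme_position": i + 1}
            for cid in partition.antibody_chains for i in range(n_antibody)]
    numbering = pd.DataFrame(rows)

    n_contacts = len(find_contacts(reference, partition).pairs)
    if n_contacts < 5:
        raise ValueError(f"construction produced only {n_contacts} native contacts")
    return SyntheticComplex(reference=reference, partition=partition,
                            numbering=numbering, seed=seed,
                            label=reference.label)


def _rotation_about_axis(axis, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(degrees)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def _cdr_keys(cx: SyntheticComplex) -> set:
    keys = set()
    for row in cx.numbering.itertuples():
        pos = int(row.scheme_position)
        if any(lo <= pos <= hi for lo, hi in CDR_RANGES.values()):
            keys.add((str(row.chain), int(row.seq_position), ""))
    return keys


def _antibody_backbone(structure: StructureModel, partition: ComplexPartition):
    return np.array([a.position
                     for cid in partition.antibody_chains
                     for r in structure.chains[cid]
                     for a in r.backbone_atoms()])


def make_decoys(cx: SyntheticComplex, config: DecoyConfig) -> list[Decoy]:
    """Rigid-body decoys of the reference with planted truth and planted pLDDT.

    One decoy per translation magnitude (applied along the configured
    direction, default along the chain axis so native contacts decay
    gradually) and one per rotation magnitude (about the configured axis
    through the antibody interface centroid).  Per-residue pLDDT is
    written to the temperature factor as
    ``clip(base - slope * error + N(0, sd), 0, 100)``.
    """
    rng = np.random.default_rng(config.seed)
    ref_backbone = _antibody_backbone(cx.reference, cx.partition)
    cdr_keys = _cdr_keys(cx) if config.loop_noise_sd > 0 else set()

    ab_interface = np.array([
        cx.reference.residue_by_key(pair[0]).get_atom("CA").position
        for pair in find_contacts(cx.reference, cx.partition).pairs])
    pivot = ab_interface.mean(axis=0)

    transforms: list[tuple[str, RigidTransform, float, float]] = []
    direction = np.asarray(config.translation_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    for t in config.translation_magnitudes:
        transforms.append((f"t{t:g}", RigidTransform.from_translation(t * direction),
                           float(t), 0.0))
    for deg in config.rotation_magnitudes:
        rot = _rotation_about_axis(config.rotation_axis, deg)
        tr = pivot - rot @ pivot
        transforms.append((f"r{deg:g}", RigidTransform(rot, tr), 0.0, float(deg)))

    decoys: list[Decoy] = []
    for idx, (tag, transform, t_mag, r_deg) in enumerate(transforms):
        structure = cx.reference.copy()
        for cid in cx.partition.antibody_chains:
            for res in structure.chains[cid]:
                for atom in res.atoms:
                    atom.position = transform.apply(atom.position)
                if config.loop_noise_sd > 0 and res.key in cdr_keys:
                    for atom in res.atoms:
                        atom.position = atom.position + rng.normal(
                            0.0, config.loop_noise_sd, 3)
        decoy_backbone = _antibody_backbone(structure, cx.partition)
        error = float(np.sqrt(np.mean(
            np.sum((decoy_backbone - ref_backbone) ** 2, axis=1))))
        pure_rigid = config.loop_noise_sd == 0
        for residues in structure.chains.values():
            for res in residues:
                plddt = float(np.clip(
                    config.plddt_base - config.plddt_slope * error
                    + rng.normal(0.0, config.plddt_noise_sd), 0.0, 100.0))
                for atom in res.atoms:
                    atom.tempfactor = plddt
        structure.label = f"{cx.label}_decoy_{idx:03d}_{tag}"
        decoys.append(Decoy(
            label=structure.label,
            structure=structure,
            planted_translation=t_mag,
            planted_rotation_deg=r_deg,
            planted_error=error,
            expected_l_rmsd=error if pure_rigid else None,
            transform=transform,
        ))
    return decoys


def make_msa(n_clusters: int, members_per_cluster: int, within_identity: float,
             between_identity: float, length: int, seed: int = 0
             ) -> list[tuple[str, str]]:
    """MSA with a planted cluster structure.

    Each cluster is founded by a centre sequence (emitted as its first
    row); members carry exactly ``round(length * (1 - within_identity))``
    substitutions relative to the centre, so member-to-centre identity
    equals the requested value.  Centres are derived from a shared base
    sequence with cluster-specific substitutions sized so that
    centre-centre identity is approximately `between_identity`.
    """
    if n_clusters < 1 or members_per_cluster < 1 or length < 1:
        raise ValueError("cluster counts and length must be positive")
    if not 0.0 <= between_identity < within_identity <= 1.0:
        raise ValueError("infeasible identity targets: need between < within")
    if n_clusters > 19:
        raise ValueError("at most 19 clusters supported")
    m_center = int(round(length * (1.0 - np.sqrt(between_identity))))
    m_member = int(round(length * (1.0 - within_identity)))
    if n_clusters > 1 and m_center == 0:
        raise ValueError("infeasible identity targets: clusters would coincide")

    rng = np.random.default_rng(seed)
    base = rng.choice(list(AMINO_ACIDS), length)

    def mutate(seq: np.ndarray, positions, offset=None) -> np.ndarray:
        out = seq.copy()
        for pos in positions:
            shift = offset if offset is not None else int(rng.integers(1, 20))
            out[pos] = AMINO_ACIDS[(AMINO_ACIDS.index(out[pos]) + shift) % 20]
        return out

    msa: list[tuple[str, str]] = []
    for k in range(n_clusters):
        positions = rng.choice(length, size=m_center, replace=False)
        center = mutate(base, positions, offset=k + 1)
        msa.append((f"c{k}_rep", "".join(center)))
        for m in range(1, members_per_cluster):
            mpos = rng.choice(length, size=m_member, replace=False)
            member = mutate(center, mpos)
            msa.append((f"c{k}_m{m}", "".join(member)))
    return msa


def attach_glycan(structure: StructureModel, partition: ComplexPartition,
                  code: str = "NAG", target_distance: float = 4.0,
                  seed: int = 0) -> StructureModel:
    """Copy of the structure with a saccharide placed at a controlled distance.

    The closest glycan atom ends up exactly `target_distance` from the
    nearest antibody atom: the anchor atom is placed along the chain axis
    beyond the antibody's extremal atom, where the extremal atom is
    provably the nearest one.
    """
    if target_distance <= 0:
        raise ValueError("target distance must be positive")
    ab_xyz = np.array([a.position
                       for cid in partition.antibody_chains
                       for r in structure.chains[cid] for a in r.heavy_atoms()])
    if len(ab_xyz) == 0:
        raise ValueError("no placement found: antibody has no atoms")
    direction = np.array([1.0, 0.0, 0.0])
    anchor_idx = int(np.argmax(ab_xyz @ direction))
    anchor = ab_xyz[anchor_idx]

    new = structure.copy()
    base = anchor + target_distance * direction
    # ring atoms trail further along +x; every one is farther from the
    # antibody than the C1 anchor atom
    offsets = [np.zeros(3)] + [np.array([0.8 * i, 0.5 * ((-1) ** i), 0.2 * i])
                               for i in range(1, 6)]
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    atoms = [Atom(name=n, element=n[0], position=base + off, is_hetero=True)
             for n, off in zip(names, offsets)]
    host_chain = partition.antigen_chains[0]
    max_pos = max(r.seq_position for r in new.chains[host_chain])
    new.chains[host_chain].append(Residue(
        chain_id=host_chain, seq_position=max_pos + 100, insertion_code="",
        name=code, atoms=atoms, kind="hetero"))

    placed = min(np.linalg.norm(a.position - b) for a in atoms for b in ab_xyz)
    if abs(placed - target_distance) > 0.05:
        raise ValueError(f"no placement found at {target_distance} A "
                         f"(achieved {placed:.3f} A)")
    return new


def _identity_mapping(cx: SyntheticComplex) -> ChainMapping:
    pairs = {}
    for cid in cx.reference.chains:
        keys = [r.key for r in cx.reference.polymer_residues(cid)]
        pairs[(cid, cid)] = [(k, k) for k in keys]
    return ChainMapping(pairs)


def make_cohort(n_complexes: int, decoys_per_complex: int,
                config: DecoyConfig | None = None, seed: int = 0,
                out_dir=None) -> pd.DataFrame:
    """Evaluated decoy cohort: one manifest row per (complex, decoy).

    Complexes alternate between nanobody and heavy-light antibodies;
    decoy translation magnitudes cycle through the configured list with a
    small deterministic jitter so every CAPRI class is represented.  Each
    decoy is scored against its reference, confidence metrics (I-pLDDT
    from planted pLDDT; planted pTM/ipTM) are attached, and models are
    ranked within each complex by model confidence.  With `out_dir`, the
    full directory tree (reference and decoy PDBs, numbering TSV,
    confidence key-value files, manifest CSV) is also written.
    """
    if n_complexes < 1 or decoys_per_complex < 1:
        raise ValueError("cohort sizes must be positive")
    config = config or DecoyConfig()
    rng = np.random.default_rng(seed)
    complex_seeds = rng.integers(0, 2**31 - 1, size=n_complexes)
    decoy_seeds = rng.integers(0, 2**31 - 1, size=n_complexes)

    rows = []
    base_mags = list(config.translation_magnitudes)
    for i in range(n_complexes):
        cx = build_toy_complex(seed=int(complex_seeds[i]), include_light=(i % 2 == 1))
        jitter_rng = np.random.default_rng(int(decoy_seeds[i]))
        mags = tuple(
            base_mags[d % len(base_mags)]
            + (float(jitter_rng.uniform(0, 0.4)) if base_mags[d % len(base_mags)] > 0 else 0.0)
            for d in range(decoys_per_complex))
        cx_config = replace(config, seed=int(decoy_seeds[i]),
                            translation_magnitudes=mags, rotation_magnitudes=())
        decoys = make_decoys(cx, cx_config)
        mapping = _identity_mapping(cx)

        complex_rows = []
        for decoy in decoys:
            scores = score_model(decoy.structure, cx.reference, cx.partition,
                                 mapping=mapping)
            iplddt = interface_plddt(decoy.structure, cx.partition)
            iptm = float(np.clip(0.90 - 0.015 * decoy.planted_error
                                 + jitter_rng.normal(0, 0.02), 0.0, 1.0))
            ptm = float(np.clip(0.85 - 0.008 * decoy.planted_error
                                + jitter_rng.normal(0, 0.02), 0.0, 1.0))
            complex_rows.append({
                "complex_id": cx.label,
                "model": decoy.label,
                "fnat": scores.fnat,
                "i_rmsd": scores.i_rmsd,
                "l_rmsd": scores.l_rmsd,
                "dockq": scores.dockq,
                "capri_class": scores.capri_class,
                "iplddt": iplddt,
                "ptm": ptm,
                "iptm": iptm,
                "model_confidence": model_confidence(ptm, iptm),
                "planted_translation": decoy.planted_translation,
                "planted_error": decoy.planted_error,
                "has_interface_glycan": False,
                "antibody_type": antibody_type(cx.partition),
                "seed": int(decoy_seeds[i]),
            })
        order = sorted(range(len(complex_rows)),
                       key=lambda j: (-complex_rows[j]["model_confidence"],
                                      complex_rows[j]["model"]))
        for rank, j in enumerate(order, start=1):
            complex_rows[j]["rank"] = rank
        rows.extend(complex_rows)

        if out_dir is not None:
            from pathlib import Path
            cdir = Path(out_dir) / cx.label
            cdir.mkdir(parents=True, exist_ok=True)
            write_pdb(cx.reference, cdir / "reference.pdb")
            cx.numbering.to_csv(cdir / "numbering.tsv", sep="\t", index=False)
            for decoy, row in zip(decoys, complex_rows):
                write_pdb(decoy.structure, cdir / f"{decoy.label}.pdb")
                (cdir / f"{decoy.label}.scores.txt").write_text(
                    f"ptm {row['ptm']:.4f}\niptm {row['iptm']:.4f}\n")

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest
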