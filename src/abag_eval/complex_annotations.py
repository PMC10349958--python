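"""Per-complex annotations: interface glycans, antigen TM-score, MSA depth.

Three independent annotations used to stratify benchmark results:

* glycan flag - does any saccharide hetero-residue sit within 4.5 A of the
  antibody in the reference structure;
* antigen TM-score - length-normalised structural similarity of the
  modelled antigen to the experimental one, maximised over rigid
  superpositions with the standard d0 distance scale;
* Neff - effective sequence count of an MSA, the number of clusters under
  greedy incremental clustering at 80% identity (gaps replaced by 'U'
  before identity computation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import kabsch_superpose
from .structure_model import ChainMapping, ComplexPartition, StructureModel

__all__ = [
    "SACCHARIDE_CODES",
    "GlycanAnnotation",
    "AntigenSimilarity",
    "NeffResult",
    "interface_glycans",
    "tm_score",
    "tm_d0",
    "neff",
    "read_msa",
]

# Common saccharide component codes; editable because the full chemical
# component dictionary is not bundled.
SACCHARIDE_CODES = frozenset({
    "NAG", "NDG", "BMA", "MAN", "FUC", "GAL", "GLC", "SIA", "XYS", "BGC",
})

GLYCAN_CUTOFF = 4.5  # A, any glycan atom to any antibody non-hydrogen atom


@dataclass
class GlycanAnnotation:
    has_interface_glycan: bool
    hits: list  # (hetero residue key, saccharide code, min distance to antibody)
    cutoff: float = GLYCAN_CUTOFF


@dataclass(frozen=True)
class AntigenSimilarity:
    tm: float
    d0: float
    n_aligned: int
    normalizing_length: int


@dataclass(frozen=True)
class NeffResult:
    n_sequences: int
    neff: int
    identity_cutoff: float

    def __post_init__(self) -> None:
        if not 1 <= self.neff <= self.n_sequences:
            raise ValueError("neff must lie in [1, n_sequences]")


def interface_glycans(reference: StructureModel, partition: ComplexPartition,
                      cutoff: float = GLYCAN_CUTOFF,
                      saccharide_codes=None) -> GlycanAnnotation:
    """Flag saccharide hetero-residues within `cutoff` of the antibody."""
    codes = SACCHARIDE_CODES if saccharide_codes is None else set(saccharide_codes)
    ab_xyz = []
    for cid in partition.antibody_chains:
        for res in reference.chains[cid]:
            for atom in res.heavy_atoms():
                ab_xyz.append(atom.position)
    ab_xyz = np.array(ab_xyz, dtype=float).reshape(-1, 3)
    hits = []
    for res in reference.hetero_residues():
        if res.name.upper() not in codes:
            continue
        res_xyz = np.array([a.position for a in res.heavy_atoms()]).reshape(-1, 3)
        if len(res_xyz) == 0 or len(ab_xyz) == 0:
            continue
        dmin = float(np.min(np.linalg.norm(
            res_xyz[:, None, :] - ab_xyz[None, :, :], axis=2)))
        if dmin <= cutoff:
            hits.append((res.key, res.name.upper(), dmin))
    hits.sort(key=lambda h: h[0])
    return GlycanAnnotation(has_interface_glycan=bool(hits), hits=hits, cutoff=cutoff)


def tm_d0(normalizing_length: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 A."""
    if normalizing_length > 15:
        d0 = 1.24 * (normalizing_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_sum(dists: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)))


def tm_score(model: StructureModel, reference: StructureModel,
             mapping: ChainMapping,
             normalizing_length: int | None = None) -> AntigenSimilarity:
    """TM-score of mapped CA pairs, maximised over rigid superpositions.

    The search seeds superpositions from the full-length least-squares fit
    and from sliding sequence windows (lengths 4, L/2 and L), then
    iteratively refits on residues closer than d0 until the selected set
    stabilises.  Normalisation is by reference length, so missing model
    residues lower the score.
    """
    pairs = mapping.all_pairs()
    mod_xyz, ref_xyz = [], []
    for mod_key, ref_key in pairs:
        ca_m = model.residue_by_key(mod_key).get_atom("CA")
        ca_r = reference.residue_by_key(ref_key).get_atom("CA")
        if ca_m is not None and ca_r is not None:
            mod_xyz.append(ca_m.position)
            ref_xyz.append(ca_r.position)
    mod_xyz = np.array(mod_xyz, dtype=float).reshape(-1, 3)
    ref_xyz = np.array(ref_xyz, dtype=float).reshape(-1, 3)
    n = len(mod_xyz)
    if n < 5:
        raise ValueError("fewer than 5 mapped CA pairs")

    if normalizing_length is None:
        ref_chains = {ref_key[0] for _, ref_key in pairs}
        normalizing_length = sum(len(reference.polymer_residues(c)) for c in ref_chains)
    d0 = tm_d0(normalizing_length)

    def refine(idx: np.ndarray) -> float:
        best_local = 0.0
        for _ in range(20):
            if len(idx) < 3:
                break
            try:
                transform, _ = kabsch_superpose(mod_xyz[idx], ref_xyz[idx])
            except ValueError:  # collinear window
                break
            dists = np.linalg.norm(transform.apply(mod_xyz) - ref_xyz, axis=1)
            best_local = max(best_local, _tm_sum(dists, d0))
            new_idx = np.where(dists < d0)[0]
            if len(new_idx) < 3 or np.array_equal(new_idx, idx):
                break
            idx = new_idx
        return best_local

    best = refine(np.arange(n))
    for win in sorted({4, max(4, n // 2), n}):
        if win > n:
            continue
        for start in range(0, n - win + 1):
            best = max(best, refine(np.arange(start, start + win)))

    tm = min(best / normalizing_length, 1.0)
    return AntigenSimilarity(tm=tm, d0=d0, n_aligned=n,
                             normalizing_length=normalizing_length)


def read_msa(path) -> list[tuple[str, str]]:
    """Read FASTA or A3M; lowercase (insertion) columns are removed."""
    records: list[tuple[str, str]] = []
    name, parts = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(parts)))
            name, parts = line[1:].split()[0] if line[1:].strip() else "", []
        elif line.strip() and name is not None:
            parts.append("".join(c for c in line.strip() if not c.islower()))
    if name is not None:
        records.append((name, "".join(parts)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def _row_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a == b))


def neff(msa, identity_cutoff: float = 0.80) -> NeffResult:
    """Effective sequence count by greedy incremental clustering.

    Rows are ordered longest-ungapped-first (stable); each row joins the
    first cluster whose founding representative is at least
    `identity_cutoff` identical over the full row, else founds a new
    cluster.  Identity is computed after replacing gaps by 'U', so shared
    gap columns count as matches, mirroring the usual MSA-depth
    preprocessing.
    """
    rows = [seq for _, seq in msa] if msa and isinstance(msa[0], tuple) else list(msa)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    if 0 in lengths:
        raise ValueError("empty alignment rows")

    processed = [r.upper().replace("-", "U").replace(".", "U") for r in rows]
    arrays = [np.frombuffer(r.encode("ascii"), dtype="S1") for r in processed]
    ungapped = [sum(c != "U" for c in r) for r in processed]
    order = sorted(range(len(rows)), key=lambda i: -ungapped[i])

    representatives: list[np.ndarray] = []
    for i in order:
        row = arrays[i]
        for rep in representatives:
            if _row_identity(row, rep) >= identity_cutoff:
                break
        else:
            representatives.append(row)
    return NeffResult(n_sequences=len(rows), neff=len(representatives),
                      identity_cutoff=identity_cutoff)
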