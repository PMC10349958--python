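"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: exhaustive all-pairs distance enumeration for contacts,
scipy's rotation fitting (a different code path from the package's own
superposition), pair enumeration for AUC, and connected components over the
full pairwise identity matrix for MSA clustering.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


def residue_heavy_coords(structure, chain_ids):
    out = []
    for cid in chain_ids:
        for res in structure.chains[cid]:
            if res.kind != "polymer":
                continue
            xyz = np.array([a.position for a in res.atoms
                            if a.element.upper() not in ("H", "D")])
            out.append((res.key, xyz))
    return out


def brute_force_contacts(structure, partition, cutoff):
    """All cross-partition residue pairs with min heavy-atom distance <= cutoff."""
    ab = residue_heavy_coords(structure, partition.antibody_chains)
    ag = residue_heavy_coords(structure, partition.antigen_chains)
    pairs = set()
    for ab_key, ab_xyz in ab:
        for ag_key, ag_xyz in ag:
            if cdist(ab_xyz, ag_xyz).min() <= cutoff:
                pairs.add((ab_key, ag_key))
    return pairs


def brute_force_fnat(model, reference, partition, cutoff=5.0):
    """(preserved, total) native contacts, identity residue-key mapping."""
    native = brute_force_contacts(reference, partition, cutoff)
    model_pairs = brute_force_contacts(model, partition, cutoff)
    preserved = len(native & model_pairs)
    return preserved, len(native)


def scipy_superposed_rmsd(mobile, target):
    """Optimal-superposition RMSD via scipy's rotation fitting."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, mc)
    # measure the RMSD the fitted rotation actually achieves; scipy's
    # reported rssd loses precision near zero
    d = mc @ rot.as_matrix().T - tc
    return float(np.sqrt(np.mean(np.sum(d ** 2, axis=1))))


def scipy_superpose(mobile, target):
    """(rotation matrix, translation) mapping mobile onto target, via scipy."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    rot, _ = Rotation.align_vectors(target - target.mean(axis=0),
                                    mobile - mobile.mean(axis=0))
    r = rot.as_matrix()
    t = target.mean(axis=0) - r @ mobile.mean(axis=0)
    return r, t


def backbone_coords(structure, keys):
    out = {}
    for key in keys:
        res = structure.residue_by_key(key)
        for atom in res.backbone_atoms():
            out[(key, atom.name)] = atom.position
    return out


def brute_force_i_rmsd(model, reference, partition, cutoff=10.0):
    """Explicit interface listing + scipy superposition."""
    interface = set()
    for ab_key, ag_key in brute_force_contacts(reference, partition, cutoff):
        interface.update((ab_key, ag_key))
    ref_bb = backbone_coords(reference, sorted(interface))
    mod_bb = backbone_coords(model, sorted(interface))
    shared = sorted(set(ref_bb) & set(mod_bb))
    mob = np.array([mod_bb[k] for k in shared])
    tgt = np.array([ref_bb[k] for k in shared])
    return scipy_superposed_rmsd(mob, tgt)


def brute_force_l_rmsd(model, reference, partition):
    ag_keys = [r.key for c in partition.antigen_chains
               for r in reference.chains[c] if r.kind == "polymer"]
    ab_keys = [r.key for c in partition.antibody_chains
               for r in reference.chains[c] if r.kind == "polymer"]
    ref_ag = backbone_coords(reference, ag_keys)
    mod_ag = backbone_coords(model, ag_keys)
    shared_ag = sorted(set(ref_ag) & set(mod_ag))
    r, t = scipy_superpose(np.array([mod_ag[k] for k in shared_ag]),
                           np.array([ref_ag[k] for k in shared_ag]))
    ref_ab = backbone_coords(reference, ab_keys)
    mod_ab = backbone_coords(model, ab_keys)
    shared_ab = sorted(set(ref_ab) & set(mod_ab))
    moved = np.array([mod_ab[k] for k in shared_ab]) @ r.T + t
    tgt = np.array([ref_ab[k] for k in shared_ab])
    return float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))


def pair_enumeration_auc(scores, labels):
    """AUC by enumerating every positive-negative pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def identity_components(rows, cutoff):
    """Connected components of the >=cutoff pairwise-identity graph."""
    processed = [r.upper().replace("-", "U").replace(".", "U") for r in rows]
    arr = np.array([list(r) for r in processed])
    n = len(arr)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = np.mean(arr[i] == arr[j]) >= cutoff
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp
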