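import math

import numpy as np
import pytest

import chbkit as ck
from chbkit.structure import Atom, Residue, Structure, StructureMetadata


@pytest.fixture
def toy():
    """One feasible toy fixture with a comfortably passing ChB."""
    return ck.build_toy_chb(ck.ToyGeometrySpec(d=3.0, alpha=10.0))


def make_bare_disulphide(acceptors=(), metadata=None):
    """Hand-built minimal structure: a disulphide plus arbitrary extra atoms.

    ``acceptors`` is a list of (atom_name, element, coords) placed in a
    separate glycine-like residue.  Coordinates are NOT quantized, so tests
    can probe thresholds at 1e-6 A resolution.
    """
    serial = iter(range(1, 100))
    donor = Residue("A", 1, "", "CYS", [
        Atom(next(serial), "CB", "C", "", [-1.81, 0.0, 0.0]),
        Atom(next(serial), "SG", "S", "", [0.0, 0.0, 0.0]),
    ])
    partner = Residue("A", 2, "", "CYS", [
        Atom(next(serial), "CB", "C", "", [0.60, -1.76, -2.41]),
        Atom(next(serial), "SG", "S", "", [0.4959, 0.0, -1.9891]),
    ])
    extra = Residue("A", 5, "", "GLY", [
        Atom(next(serial), name, elem, "", coords)
        for name, elem, coords in acceptors
    ]) if acceptors else None
    residues = [donor, partner] + ([extra] if extra else [])
    meta = metadata or StructureMetadata(entry_id="BARE", method="X-RAY DIFFRACTION",
                                         resolution=1.2, temperature=100.0)
    return Structure(metadata=meta, residues=residues)


def brute_force_chbs(structure, distance_tolerance=0.1, alpha_max=25.0,
                     ssbond_max=2.5, radii=None):
    """Independent O(N^2) oracle: no spatial index, own vector math.

    Returns a set of (donor residue key, acceptor residue key, acceptor atom
    name, d rounded to 6 decimals).
    """
    radii = radii or {"O": 1.52, "S": 1.80}

    sgs = []
    for res in structure.residues:
        if res.res_name == "CYS":
            for atom in res.atoms:
                if atom.name == "SG":
                    sgs.append((res, atom))
    # greedy closest-pair disulphides
    cand = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            dist = math.dist(sgs[i][1].coords, sgs[j][1].coords)
            if dist <= ssbond_max:
                cand.append((dist, i, j))
    cand.sort(key=lambda t: (t[0], sgs[t[1]][0].key, sgs[t[2]][0].key))
    used, bridges = set(), []
    for dist, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        bridges.append((sgs[i], sgs[j]))

    out = set()
    for (res_a, sg_a), (res_b, sg_b) in bridges:
        for donor_res, donor, partner in ((res_a, sg_a, sg_b), (res_b, sg_b, sg_a)):
            partners = [partner.coords]
            cb = donor_res.get_atom("CB")
            if cb is not None:
                partners.append(cb.coords)
            for res in structure.residues:
                if res.res_name in ("HOH", "WAT"):
                    continue
                for atom in res.atoms:
                    if atom.element not in ("O", "S"):
                        continue
                    if atom is donor or atom is partner or (cb is not None and atom is cb):
                        continue
                    if res.key == donor_res.key:
                        continue
                    v = np.asarray(atom.coords, float) - donor.coords
                    d = float(np.linalg.norm(v))
                    if d > radii[atom.element] + radii["S"] + distance_tolerance:
                        continue
                    alpha_min = 180.0
                    for p in partners:
                        w = np.asarray(p, float) - donor.coords
                        cos_t = float(np.dot(v, w) / (d * np.linalg.norm(w)))
                        theta = math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))
                        alpha_min = min(alpha_min, 180.0 - theta)
                    if alpha_min <= alpha_max:
                        out.add((donor_res.key, res.key, atom.name, round(d, 6)))
    return out


def chb_set(chbs):
    return {(c.donor_residue, c.acceptor_residue, c.acceptor_atom, round(c.d, 6))
            for c in chbs}
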