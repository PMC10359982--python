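"""Chalcogen-bond detection in disulphide bridges.

A chalcogen bond (ChB) is an attractive noncovalent interaction between a
nucleophile Nu (here an oxygen or sulfur heavy atom) and a divalent sulfur,
directional along the prolongation of one of the sulfur's covalent bonds.
For a disulphide SG the two covalent partners are its own CB and the partner
cysteine's SG, so two prolongation axes exist per donor.  Each candidate
(C,S)-S...Nu triple is scored by

* ``d``      — the Nu-S distance (Angstrom), and
* ``alpha``  — 180 - theta, where theta is the Nu-S-partner angle, i.e. the
  deviation of Nu from the covalent-bond prolongation (degrees);

and accepted when ``d <= vdw_sum + tolerance`` (vdw_sum = sum of the two
van der Waals radii) and ``min(alpha) <= alpha_max``.  Both comparisons are
inclusive.  With the default radii (O 1.52, S 1.80) and 0.1 A tolerance the
O...S distance cutoff is 3.42 A and the angular cutoff is 25 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, UnknownElementError
from .structure import Atom, Residue, Structure

DEFAULT_VDW_RADII = {"O": 1.52, "S": 1.80}

_EPS = 1e-12


@dataclass
class ChBParams:
    """All detection thresholds.

    The defaults implement the macromolecular criteria: van der Waals
    contact with a +0.1 A tolerance and alpha <= 25 degrees (looser than
    the 20 degrees used for small-molecule crystals, to absorb the lower
    coordinate accuracy of protein structures).
    """

    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    distance_tolerance: float = 0.1
    alpha_max: float = 25.0
    ssbond_distance_max: float = 2.5
    acceptor_elements: frozenset[str] = frozenset({"O", "S"})
    exclude_same_residue: bool = True
    exclude_waters: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("van der Waals radii must be positive")
        if self.distance_tolerance < 0:
            raise ValueError("distance_tolerance must be >= 0")
        if not 0 < self.alpha_max < 90:
            raise ValueError("alpha_max must lie in (0, 90) degrees")
        self.acceptor_elements = frozenset(e.capitalize() for e in self.acceptor_elements)

    def max_search_radius(self) -> float:
        """Largest S...acceptor distance that can still pass the d criterion."""
        return max(
            vdw_contact_threshold(elem, "S", self.distance_tolerance, self.vdw_radii)
            for elem in self.acceptor_elements
        )


@dataclass
class DisulphideBond:
    res_a: Residue
    sg_a: Atom
    res_b: Residue
    sg_b: Atom
    ss_distance: float


@dataclass
class ChalcogenBond:
    """One detected (C,S)-S...Nu interaction."""

    donor_residue: tuple[str, int, str]
    donor_atom: str
    acceptor_residue: tuple[str, int, str]
    acceptor_atom: str
    acceptor_element: str
    d: float
    alphas: dict[str, float]  # covalent-partner atom name -> alpha (degrees)
    alpha_min: float
    vdw_sum: float
    passes: bool
    donor: Optional[Atom] = None
    acceptor: Optional[Atom] = None


def vdw_contact_threshold(elem_a: str, elem_b: str, tolerance: float = 0.1,
                          radii: Optional[dict[str, float]] = None) -> float:
    """Contact cutoff: sum of the two van der Waals radii plus a tolerance."""
    radii = DEFAULT_VDW_RADII if radii is None else radii
    try:
        return radii[elem_a.capitalize()] + radii[elem_b.capitalize()] + tolerance
    except KeyError as exc:
        raise UnknownElementError(f"element {exc.args[0]!r} not in radii table") from exc


def chb_geometry(nu, s, partners) -> tuple[float, list[float], float]:
    """Distance d and per-partner deviation angles alpha for one Nu...S contact.

    ``partners`` is one or two coordinates of atoms covalently bound to the
    sulfur.  For each partner P, theta = angle(Nu, S, P) and alpha =
    180 - theta; alpha is 0 when Nu lies exactly on the prolongation of the
    P->S bond.  Rotation- and translation-invariant by construction.
    """
    nu = np.asarray(nu, dtype=float)
    s = np.asarray(s, dtype=float)
    partners = np.atleast_2d(np.asarray(partners, dtype=float))
    v_nu = nu - s
    d = float(np.linalg.norm(v_nu))
    if d < _EPS:
        raise DegenerateGeometryError("nucleophile coincides with the sulfur")
    alphas: list[float] = []
    for p in partners:
        v_p = p - s
        norm_p = float(np.linalg.norm(v_p))
        if norm_p < _EPS:
            raise DegenerateGeometryError("covalent partner coincides with the sulfur")
        cos_theta = float(np.dot(v_nu, v_p) / (d * norm_p))
        theta = float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))
        alphas.append(180.0 - theta)
    return d, alphas, min(alphas)


def find_disulphides(structure: Structure, params: Optional[ChBParams] = None
                     ) -> list[DisulphideBond]:
    """Disulphide bridges: SSBOND-declared plus geometric CYS SG pairs.

    Predicted models carry no SSBOND records, so SG pairs within
    ``ssbond_distance_max`` are detected geometrically as well.  Each SG
    joins at most one bridge; when a sulfur has several partners within the
    cutoff the closest wins.
    """
    params = params or ChBParams()
    cutoff = params.ssbond_distance_max
    index = structure.residue_index()

    sg_atoms: list[tuple[Residue, Atom]] = []
    for res in structure.residues:
        if res.res_name == "CYS":
            sg = res.get_atom("SG")
            if sg is not None:
                sg_atoms.append((res, sg))

    candidates: dict[frozenset, tuple[Residue, Atom, Residue, Atom, float]] = {}

    def consider(res_a: Residue, sg_a: Atom, res_b: Residue, sg_b: Atom) -> None:
        if res_a.key == res_b.key:
            return
        dist = float(np.linalg.norm(sg_a.coords - sg_b.coords))
        if dist <= cutoff:
            candidates[frozenset((res_a.key, res_b.key))] = (res_a, sg_a, res_b, sg_b, dist)

    for i, (res_a, sg_a) in enumerate(sg_atoms):
        for res_b, sg_b in sg_atoms[i + 1:]:
            consider(res_a, sg_a, res_b, sg_b)
    for rec in structure.metadata.ssbond_records:
        res_a = index.get((rec.chain_1, rec.seq_1, rec.icode_1))
        res_b = index.get((rec.chain_2, rec.seq_2, rec.icode_2))
        if res_a is None or res_b is None:
            continue
        sg_a, sg_b = res_a.get_atom("SG"), res_b.get_atom("SG")
        if sg_a is not None and sg_b is not None:
            consider(res_a, sg_a, res_b, sg_b)

    bonds: list[DisulphideBond] = []
    used: set[tuple[str, int, str]] = set()
    for res_a, sg_a, res_b, sg_b, dist in sorted(
            candidates.values(), key=lambda c: (c[4], c[0].key, c[2].key)):
        if res_a.key in used or res_b.key in used:
            continue
        used.update((res_a.key, res_b.key))
        a, b = sorted(((res_a, sg_a), (res_b, sg_b)), key=lambda t: t[0].key)
        bonds.append(DisulphideBond(a[0], a[1], b[0], b[1], dist))
    bonds.sort(key=lambda b: b.res_a.key)
    return bonds


def _covalent_partners(donor_res: Residue, partner_sg: Atom) -> list[tuple[str, Atom]]:
    partners = []
    cb = donor_res.get_atom("CB")
    if cb is not None:
        partners.append(("CB", cb))
    partners.append(("SG", partner_sg))
    return partners


def detect_chbs(structure: Structure, params: Optional[ChBParams] = None
                ) -> list[ChalcogenBond]:
    """All chalcogen bonds whose donor is a disulphide sulfur.

    Both sulfurs of every bridge are evaluated as donors; a single
    nucleophile may bond to both (counted twice).  The donor's covalent
    partners, atoms of the donor residue (by default) and waters (by
    default) are never acceptors.  Output order is deterministic: donor
    residue, then acceptor residue and atom name.
    """
    params = params or ChBParams()
    bridges = find_disulphides(structure, params)
    if not bridges:
        return []

    acceptors: list[tuple[Residue, Atom]] = []
    for res in structure.residues:
        if params.exclude_waters and res.is_water:
            continue
        for atom in res.atoms:
            if atom.element in params.acceptor_elements:
                acceptors.append((res, atom))
    if not acceptors:
        return []
    tree = cKDTree(np.array([a.coords for _, a in acceptors]))
    radius = params.max_search_radius()

    found: list[ChalcogenBond] = []
    for bridge in bridges:
        for donor_res, donor_sg, partner_sg in (
                (bridge.res_a, bridge.sg_a, bridge.sg_b),
                (bridge.res_b, bridge.sg_b, bridge.sg_a)):
            partners = _covalent_partners(donor_res, partner_sg)
            partner_ids = {id(atom) for _, atom in partners}
            partner_coords = [atom.coords for _, atom in partners]
            for idx in tree.query_ball_point(donor_sg.coords, radius):
                acc_res, acc = acceptors[idx]
                if id(acc) == id(donor_sg) or id(acc) in partner_ids:
                    continue
                if params.exclude_same_residue and acc_res.key == donor_res.key:
                    continue
                vdw_sum = vdw_contact_threshold(acc.element, "S", 0.0, params.vdw_radii)
                d, alphas, alpha_min = chb_geometry(acc.coords, donor_sg.coords,
                                                    partner_coords)
                passes = (d <= vdw_sum + params.distance_tolerance
                          and alpha_min <= params.alpha_max)
                if passes:
                    found.append(ChalcogenBond(
                        donor_residue=donor_res.key,
                        donor_atom="SG",
                        acceptor_residue=acc_res.key,
                        acceptor_atom=acc.name,
                        acceptor_element=acc.element,
                        d=d,
                        alphas={name: alpha for (name, _), alpha in zip(partners, alphas)},
                        alpha_min=alpha_min,
                        vdw_sum=vdw_sum,
                        passes=True,
                        donor=donor_sg,
                        acceptor=acc,
                    ))
    found.sort(key=lambda c: (c.donor_residue, c.acceptor_residue, c.acceptor_atom))
    return found


def chbs_to_table(chbs: Iterable[ChalcogenBond], entry_id: str = "") -> pd.DataFrame:
    """Detection results as a tidy table (one row per chalcogen bond)."""
    rows = []
    for chb in chbs:
        rows.append({
            "entry_id": entry_id,
            "donor_chain": chb.donor_residue[0],
            "donor_resnum": chb.donor_residue[1],
            "donor_atom": chb.donor_atom,
            "acceptor_chain": chb.acceptor_residue[0],
            "acceptor_resnum": chb.acceptor_residue[1],
            "acceptor_atom": chb.acceptor_atom,
            "acceptor_element": chb.acceptor_element,
            "d": round(chb.d, 3),
            "alpha_CB": round(chb.alphas["CB"], 2) if "CB" in chb.alphas else None,
            "alpha_SS": round(chb.alphas["SG"], 2) if "SG" in chb.alphas else None,
            "alpha_min": round(chb.alpha_min, 2),
            "vdw_sum": round(chb.vdw_sum, 3),
            "passes": chb.passes,
        })
    return pd.DataFrame(rows)


def write_chb_tsv(chbs: Iterable[ChalcogenBond], path, entry_id: str = "") -> None:
    chbs_to_table(chbs, entry_id).to_csv(path, sep="\t", index=False)
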