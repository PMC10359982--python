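"""Synthetic fixtures: toy disulphide/nucleophile structures and noisy
"predicted" counterparts.

``build_toy_chb`` inverts the (d, alpha) measurement: it places a
nucleophile at a prescribed distance and deviation angle from a disulphide
sulfur, measured against the CB-SG prolongation, inside a minimal but
chemically shaped pair of cysteines plus an acceptor fragment.
``perturb_structure`` emulates the experimental/model coordinate
discrepancy with isotropic i.i.d. Gaussian noise, the simplest model
consistent with a single scalar positional standard error; real predicted
models have correlated, confidence-dependent errors that this generator
deliberately does not mimic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InfeasibleSpecError
from .structure import (
    EXPERIMENTAL,
    PREDICTED,
    Atom,
    DBRef,
    Residue,
    SSBondRecord,
    Structure,
    StructureMetadata,
)

# Detection-relevant constants used for generator-side ground truth.  These
# duplicate the default thresholds on purpose: the truth table must not
# depend on the detection module it validates.
_VDW = {"O": 1.52, "S": 1.80}
_DIST_TOL = 0.1
_ALPHA_MAX = 25.0
_SS_MAX = 2.5

# Fixed donor-side scaffold (Angstrom).  Donor SG at the origin, CB along -x,
# so the CB->SG prolongation is the +x axis; the partner SG sits out of the
# acceptor hemisphere at the canonical 2.05 A with a ~104 deg CB-S-S angle.
_SG_A = np.array([0.0, 0.0, 0.0])
_CB_A = np.array([-1.81, 0.0, 0.0])
_CA_A = np.array([-2.432, -1.398, 0.0])
_N_A = np.array([-2.961, -1.776, 1.330])
_C_A = np.array([-2.054, -2.659, -0.871])
_O_A = np.array([-1.703, -3.706, -1.308])
_SG_B = np.array([0.4959, 0.0, -1.9891])
_CB_B = np.array([0.6018, -1.7562, -2.4140])
_CA_B = np.array([0.6018, -2.8381, -3.4958])
_N_B = np.array([-0.1319, -3.5718, -2.4687])
_C_B = np.array([1.5134, -3.7497, -4.3011])
_O_B = np.array([1.5134, -4.7337, -5.0391])

ACCEPTOR_CONTEXTS = {
    "backbone-O": ("GLY", "O", "O"),
    "sidechain-O": ("SER", "OG", "O"),
    "sidechain-S": ("CYS", "SG", "S"),
}


@dataclass
class ToyGeometrySpec:
    """Prescribed ChB geometry for one toy fixture.

    ``dihedral_phi`` rotates the nucleophile about the CB-SG prolongation
    axis; 0 places it in the +y half-plane, away from the partner sulfur.
    """

    d: float
    alpha: float
    dihedral_phi: float = 0.0
    acceptor_element: str = "O"
    acceptor_context: str = "backbone-O"

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0.0 <= self.alpha <= 180.0:
            raise ValueError("alpha must lie in [0, 180] degrees")
        if self.acceptor_context not in ACCEPTOR_CONTEXTS:
            raise ValueError(f"unknown acceptor_context {self.acceptor_context!r}")
        expected = ACCEPTOR_CONTEXTS[self.acceptor_context][2]
        if self.acceptor_element.capitalize() != expected:
            raise ValueError(
                f"context {self.acceptor_context} carries element {expected}, "
                f"not {self.acceptor_element}")


@dataclass
class PairedDatasetSpec:
    """Conditions for a synthetic experimental/model survey.

    Defaults place every experimental ChB inside the detection window
    (d uniform on [3.0, 3.42] A, alpha uniform on [0, 25] deg, backbone-O
    acceptors) and perturb the model counterpart with the 0.046 A
    positional standard error typical of high-resolution structures.
    """

    n_entries: int
    d_range: tuple[float, float] = (3.0, 3.42)
    alpha_range: tuple[float, float] = (0.0, 25.0)
    phi_range: tuple[float, float] = (0.0, 360.0)
    acceptor_context: str = "backbone-O"
    noise_sigma: float = 0.046
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(axis, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(axis, ref)
    p1 /= np.linalg.norm(p1)
    return p1, np.cross(axis, p1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _acceptor_fragment(nu: np.ndarray, context: str) -> list[tuple[str, str, np.ndarray]]:
    """Smallest chemically sensible carrier of the nucleophile."""
    a = _unit(nu)
    p1, p2 = _orthonormal_frame(a)
    fwd = _unit(0.55 * a + 0.84 * p1)
    back = _unit(0.55 * a - 0.84 * p1)
    side = _unit(0.55 * a + 0.84 * p2)
    if context == "backbone-O":
        c = nu + 1.23 * a
        ca = c + 1.52 * fwd
        n = ca + 1.46 * back
        return [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", nu)]
    bond = 1.43 if context == "sidechain-O" else 1.81
    cb = nu + bond * a
    ca = cb + 1.52 * fwd
    n = ca + 1.46 * back
    c = ca + 1.52 * side
    o = c + 1.23 * a
    tip = "OG" if context == "sidechain-O" else "SG"
    tip_elem = "O" if context == "sidechain-O" else "S"
    return [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o),
            ("CB", "C", cb), (tip, tip_elem, nu)]


def _direct_geometry(nu: np.ndarray, s: np.ndarray,
                     partners: list[np.ndarray]) -> tuple[float, float]:
    """(d, alpha_min) by plain vector arithmetic; generator-side oracle math."""
    v = nu - s
    d = float(np.linalg.norm(v))
    alpha_min = 180.0
    for p in partners:
        w = p - s
        cos_t = float(np.dot(v, w) / (d * np.linalg.norm(w)))
        theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
        alpha_min = min(alpha_min, 180.0 - theta)
    return d, alpha_min


def _chb_pass(d: float, alpha_min: float, acceptor_element: str) -> bool:
    return (d <= _VDW[acceptor_element] + _VDW["S"] + _DIST_TOL
            and alpha_min <= _ALPHA_MAX)


def build_toy_chb(spec: ToyGeometrySpec, entry_id: str = "SYN1",
                  accession: str = "SYNTH001") -> Structure:
    """Minimal structure realizing one prescribed (d, alpha) chalcogen bond.

    Two cysteines (SG-SG 2.05 A, CB-SG 1.81 A) form the disulphide; the
    nucleophile of the requested acceptor context sits at exactly (d, alpha)
    from the donor SG against the CB-SG prolongation, rotated by
    ``dihedral_phi`` about that axis.  Coordinates are quantized to the PDB
    format's 3-decimal precision so in-memory and written fixtures measure
    identically.  Raises :class:`InfeasibleSpecError` when the placement
    would clash or admit a second detectable contact.
    """
    alpha = np.radians(spec.alpha)
    phi = np.radians(spec.dihedral_phi)
    nu = spec.d * np.array([np.cos(alpha),
                            np.sin(alpha) * np.cos(phi),
                            np.sin(alpha) * np.sin(phi)])
    res_name, nu_name, nu_elem = ACCEPTOR_CONTEXTS[spec.acceptor_context]

    donor_atoms = [("N", "N", _N_A), ("CA", "C", _CA_A), ("C", "C", _C_A),
                   ("O", "O", _O_A), ("CB", "C", _CB_A), ("SG", "S", _SG_A)]
    partner_atoms = [("N", "N", _N_B), ("CA", "C", _CA_B), ("C", "C", _C_B),
                     ("O", "O", _O_B), ("CB", "C", _CB_B), ("SG", "S", _SG_B)]
    acceptor_atoms = _acceptor_fragment(nu, spec.acceptor_context)

    quant = lambda p: np.round(np.asarray(p, dtype=float), 3)
    groups = [[(n, e, quant(p)) for n, e, p in grp]
              for grp in (donor_atoms, partner_atoms, acceptor_atoms)]
    _validate_fixture(groups, spec)

    residues = []
    serial = itertools.count(1)
    for (name3, seq), atoms in zip((("CYS", 1), ("CYS", 10), (res_name, 20)), groups):
        residues.append(Residue(
            chain_id="A", seq_number=seq, icode="", res_name=name3,
            atoms=[Atom(serial=next(serial), name=n, element=e, altloc="",
                        coords=p, occupancy=1.0, bfactor=10.0)
                   for n, e, p in atoms]))
    metadata = StructureMetadata(
        entry_id=entry_id,
        source=EXPERIMENTAL,
        method="X-RAY DIFFRACTION",
        resolution=1.2,
        temperature=100.0,
        n_models=1,
        dbrefs=[DBRef("A", "UNP", accession, 1, 20, 1, 20)],
        ssbond_records=[SSBondRecord("A", 1, "", "A", 10, "")],
    )
    return Structure(metadata=metadata, residues=residues)


def _validate_fixture(groups: list[list[tuple[str, str, np.ndarray]]],
                      spec: ToyGeometrySpec) -> None:
    donor, partner, acceptor = groups
    sg_a = dict((n, p) for n, _, p in donor)["SG"]
    sg_b = dict((n, p) for n, _, p in partner)["SG"]
    cb_a = dict((n, p) for n, _, p in donor)["CB"]
    cb_b = dict((n, p) for n, _, p in partner)["CB"]
    nu_name = ACCEPTOR_CONTEXTS[spec.acceptor_context][1]
    nu = dict((n, p) for n, _, p in acceptor)[nu_name]

    # no nonbonded inter-residue clash (< 1.5 A); SG_A-SG_B is bonded
    for (ga, gb) in ((donor, partner), (donor, acceptor), (partner, acceptor)):
        for na, _, pa in ga:
            for nb, _, pb in gb:
                if {na, nb} == {"SG"} and ga is donor and gb is partner:
                    continue
                if float(np.linalg.norm(pa - pb)) < 1.5:
                    raise InfeasibleSpecError(
                        f"spec(d={spec.d}, alpha={spec.alpha}, "
                        f"phi={spec.dihedral_phi}): clash {na}...{nb}")

    if ACCEPTOR_CONTEXTS[spec.acceptor_context][2] == "S":
        for sg in (sg_a, sg_b):
            if float(np.linalg.norm(nu - sg)) <= _SS_MAX + 0.1:
                raise InfeasibleSpecError(
                    "sulfur acceptor would be mistaken for a disulphide partner")

    # only the prescribed (donor SG, Nu) contact may come near the criteria
    donors = [(sg_a, [cb_a, sg_b], donor), (sg_b, [cb_b, sg_a], partner)]
    shell = _VDW["S"] + _VDW["S"] + _DIST_TOL + 0.05
    for s_pos, partners, own_group in donors:
        own_names = {id(p) for _, _, p in own_group}
        for grp in groups:
            for name, elem, pos in grp:
                if elem not in ("O", "S"):
                    continue
                if id(pos) in own_names or any(pos is q for q in partners):
                    continue
                if pos is nu and s_pos is sg_a:
                    continue  # the intended contact
                d, alpha_min = _direct_geometry(pos, s_pos, partners)
                if d <= shell and alpha_min <= _ALPHA_MAX + 2.0:
                    raise InfeasibleSpecError(
                        f"spec admits a second near-detectable contact "
                        f"({name} at d={d:.2f}, alpha={alpha_min:.1f})")


def perturb_structure(structure: Structure, sigma: float, seed: int,
                      plddt: float = 95.0) -> Structure:
    """Predicted-model counterpart: isotropic Gaussian coordinate noise.

    Every coordinate of every atom receives independent zero-mean noise of
    standard deviation ``sigma`` (Angstrom); deterministic given ``seed``.
    The copy is relabelled as a predicted model with a constant pLDDT in the
    B-factor column and, like AlphaFold-style files, carries no SSBOND
    records or crystallographic metadata.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = structure.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
            atom.bfactor = plddt
    out.metadata.source = PREDICTED
    out.metadata.method = None
    out.metadata.resolution = None
    out.metadata.temperature = None
    out.metadata.ssbond_records = []
    return out


def generate_paired_dataset(spec: PairedDatasetSpec
                            ) -> tuple[list[Structure], list[Structure], pd.DataFrame]:
    """Toy survey: n paired entries plus a generator-side ground-truth table.

    The truth table records, per entry, the geometry measured directly from
    the raw coordinates (independent of the detection module) before and
    after perturbation, whether each side passes the default criteria, and
    ``recovered_truth`` = both sides pass.
    """
    rng = np.random.default_rng(spec.seed)
    res_name, nu_name, nu_elem = ACCEPTOR_CONTEXTS[spec.acceptor_context]
    exps: list[Structure] = []
    models: list[Structure] = []
    rows = []
    for i in range(spec.n_entries):
        toy_spec = ToyGeometrySpec(
            d=float(rng.uniform(*spec.d_range)),
            alpha=float(rng.uniform(*spec.alpha_range)),
            dihedral_phi=float(rng.uniform(*spec.phi_range)),
            acceptor_element=nu_elem,
            acceptor_context=spec.acceptor_context,
        )
        entry_id = f"SYN{i + 1:04d}"
        exp = build_toy_chb(toy_spec, entry_id=entry_id,
                            accession=f"SYNTH{i + 1:04d}")
        model = perturb_structure(exp, spec.noise_sigma,
                                  seed=int(rng.integers(2 ** 31)))
        exps.append(exp)
        models.append(model)
        rows.append(_truth_row(entry_id, exp, model, nu_name, nu_elem))
    return exps, models, pd.DataFrame(rows)


def _truth_row(entry_id: str, exp: Structure, model: Structure,
               nu_name: str, nu_elem: str) -> dict:
    def measure(st: Structure) -> tuple[float, float, bool]:
        donor = st.get_residue("A", 1)
        partner = st.get_residue("A", 10)
        acc = st.get_residue("A", 20)
        sg_a, cb_a = donor.get_atom("SG").coords, donor.get_atom("CB").coords
        sg_b = partner.get_atom("SG").coords
        nu = acc.get_atom(nu_name).coords
        d, alpha_min = _direct_geometry(nu, sg_a, [cb_a, sg_b])
        intact = float(np.linalg.norm(sg_a - sg_b)) <= _SS_MAX
        return d, alpha_min, intact and _chb_pass(d, alpha_min, nu_elem)

    d_true, alpha_true, exp_pass = measure(exp)
    d_pert, alpha_pert, model_pass = measure(model)
    return {
        "entry_id": entry_id,
        "d_true": d_true,
        "alpha_true": alpha_true,
        "d_perturbed": d_pert,
        "alpha_perturbed": alpha_pert,
        "exp_pass": exp_pass,
        "model_pass": model_pass,
        "recovered_truth": exp_pass and model_pass,
    }


_RANDOM_RES = (
    ("GLY", (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))),
    ("SER", (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O"))),
    ("ALA", (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))),
    ("MET", (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("SD", "S"))),
)


def random_structure(n_residues: int = 80, n_disulphides: int = 3,
                     seed: int = 0, box: float = 18.0) -> Structure:
    """Random atom soup (with planted disulphides) for detector stress tests.

    Geometry is deliberately unphysical apart from the planted CYS pairs;
    the fixture exists to compare detection routes on identical coordinates,
    not to resemble a protein.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    serial = itertools.count(1)
    seq = itertools.count(1)

    def rand_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for _ in range(n_disulphides):
        center = rng.uniform(2.0, box - 2.0, size=3)
        sg1 = center
        sg2 = center + 2.05 * rand_unit()
        for sg in (sg1, sg2):
            cb = sg + 1.81 * rand_unit()
            ca = cb + 1.52 * rand_unit()
            atoms = [Atom(next(serial), "N", "N", "", ca + 1.46 * rand_unit()),
                     Atom(next(serial), "CA", "C", "", ca),
                     Atom(next(serial), "CB", "C", "", cb),
                     Atom(next(serial), "SG", "S", "", sg)]
            residues.append(Residue("A", next(seq), "", "CYS", atoms))
    for _ in range(max(n_residues - 2 * n_disulphides, 0)):
        name, template = _RANDOM_RES[int(rng.integers(len(_RANDOM_RES)))]
        anchor = rng.uniform(0.0, box, size=3)
        atoms = [Atom(next(serial), aname, elem, "",
                      anchor + rng.uniform(-1.5, 1.5, size=3))
                 for aname, elem in template]
        residues.append(Residue("A", next(seq), "", name, atoms))
    metadata = StructureMetadata(entry_id="RND", source=EXPERIMENTAL,
                                 method="X-RAY DIFFRACTION", resolution=1.0,
                                 temperature=100.0)
    return Structure(metadata=metadata, residues=residues)
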