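"""Experimental-vs-predicted comparison of chalcogen bonds.

Residues are mapped between an experimental entry and its predicted model
through the DBREF numbering offsets (predicted models are single chains
numbered in sequence-database coordinates), each experimental ChB is
re-measured in the model through internal coordinates only (no
superposition), and the model-minus-experimental differences Delta-d and
Delta-alpha are recorded together with a recovery flag: whether the model
geometry still satisfies the same detection criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import ChalcogenBond, ChBParams, chb_geometry, find_disulphides
from .errors import UnpairableError
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

ABSENT_NONE = None
ABSENT_RESIDUE_UNMAPPED = "residue-unmapped"
ABSENT_ATOM_MISSING = "atom-missing"
ABSENT_DISULPHIDE_BROKEN = "disulphide-broken"


@dataclass
class ResidueMap:
    """One-to-one map (exp chain, exp author seq) -> model seq number."""

    pairs: dict[tuple[str, int], int]
    accession: str
    unmapped: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class MatchedChB:
    exp_chb: ChalcogenBond
    model_d: Optional[float] = None
    model_alphas: Optional[dict[str, float]] = None
    model_alpha_min: Optional[float] = None
    delta_d: Optional[float] = None          # model - experimental, Angstrom
    delta_alpha: Optional[float] = None      # model - experimental, degrees
    recovered: bool = False
    mean_plddt: Optional[float] = None
    absent_reason: Optional[str] = ABSENT_NONE


def build_residue_map(exp: Structure, model: Structure) -> ResidueMap:
    """Map experimental author numbering onto model (database) numbering.

    For every experimental chain with a DBREF to the shared accession,
    ``model_seq = exp_seq - seq_begin + db_begin``.  Mapped residues must
    agree on residue name in both structures; disagreements and residues
    with insertion codes go to ``unmapped``.
    """
    exp_refs = [r for r in exp.metadata.dbrefs if r.accession]
    if not exp_refs:
        raise UnpairableError(f"{exp.metadata.entry_id}: no DBREF accession")
    model_accessions = {r.accession for r in model.metadata.dbrefs if r.accession}
    shared = [r for r in exp_refs if not model_accessions or r.accession in model_accessions]
    if not shared:
        raise UnpairableError(
            f"{exp.metadata.entry_id}: no accession shared with the model")
    accession = shared[0].accession
    refs = [r for r in shared if r.accession == accession]

    model_chain = model.chains()[0] if model.chains() else None
    model_index = {res.seq_number: res for res in model.residues
                   if res.chain_id == model_chain and not res.icode}

    pairs: dict[tuple[str, int], int] = {}
    unmapped: list[tuple[str, int, str]] = []
    for ref in refs:
        for res in exp.residues:
            if res.chain_id != ref.chain_id:
                continue
            if not ref.seq_begin <= res.seq_number <= ref.seq_end:
                continue
            if res.icode:
                logger.info("%s %s%d%s: insertion-code residue excluded from mapping",
                            exp.metadata.entry_id, res.chain_id, res.seq_number, res.icode)
                unmapped.append(res.key)
                continue
            model_seq = res.seq_number - ref.seq_begin + ref.db_begin
            model_res = model_index.get(model_seq)
            if model_res is None or model_res.res_name != res.res_name:
                if model_res is not None:
                    logger.info("%s %s%d: residue-name mismatch %s vs %s",
                                exp.metadata.entry_id, res.chain_id, res.seq_number,
                                res.res_name, model_res.res_name)
                unmapped.append(res.key)
                continue
            pairs[(res.chain_id, res.seq_number)] = model_seq
    return ResidueMap(pairs=pairs, accession=accession, unmapped=unmapped)


def _model_residue(model: Structure, seq_number: int) -> Optional[Residue]:
    chain = model.chains()[0] if model.chains() else None
    for res in model.residues:
        if res.chain_id == chain and res.seq_number == seq_number and not res.icode:
            return res
    return None


def match_chbs(exp_chbs: Sequence[ChalcogenBond], exp: Structure, model: Structure,
               residue_map: ResidueMap, params: Optional[ChBParams] = None
               ) -> list[MatchedChB]:
    """Locate each experimental ChB's counterpart geometry in the model.

    The donor SG and the same-named acceptor atom are found through the
    residue map.  A model donor cysteine that is no longer part of a
    disulphide (the bridge is broken or the region unstructured) yields
    ``absent_reason = "disulphide-broken"`` with no geometry.  Otherwise d
    and alpha are recomputed with the model's own covalent partners and
    ``recovered`` applies the identical criteria.
    """
    params = params or ChBParams()
    model_bridges = find_disulphides(model, params)
    partner_of: dict[tuple[str, int, str], tuple[Residue, object]] = {}
    for b in model_bridges:
        partner_of[b.res_a.key] = (b.res_b, b.sg_b)
        partner_of[b.res_b.key] = (b.res_a, b.sg_a)

    matched: list[MatchedChB] = []
    for chb in exp_chbs:
        m = MatchedChB(exp_chb=chb)
        donor_seq = residue_map.pairs.get(chb.donor_residue[:2])
        acc_seq = residue_map.pairs.get(chb.acceptor_residue[:2])
        if donor_seq is None or acc_seq is None or chb.donor_residue[2] or chb.acceptor_residue[2]:
            m.absent_reason = ABSENT_RESIDUE_UNMAPPED
            matched.append(m)
            continue
        donor_res = _model_residue(model, donor_seq)
        acc_res = _model_residue(model, acc_seq)
        if donor_res is None or acc_res is None:
            m.absent_reason = ABSENT_RESIDUE_UNMAPPED
            matched.append(m)
            continue
        donor_sg = donor_res.get_atom("SG")
        acceptor = acc_res.get_atom(chb.acceptor_atom)
        if donor_sg is None or acceptor is None:
            m.absent_reason = ABSENT_ATOM_MISSING
            matched.append(m)
            continue
        m.mean_plddt = float(np.mean([donor_res.mean_bfactor(), acc_res.mean_bfactor()]))
        if donor_res.key not in partner_of:
            m.absent_reason = ABSENT_DISULPHIDE_BROKEN
            matched.append(m)
            continue
        _, partner_sg = partner_of[donor_res.key]
        partners: list[tuple[str, np.ndarray]] = []
        cb = donor_res.get_atom("CB")
        if cb is not None:
            partners.append(("CB", cb.coords))
        else:
            logger.info("model donor %s lacks CB; alpha from the S-S axis only",
                        donor_res.key)
        partners.append(("SG", partner_sg.coords))
        d, alphas, alpha_min = chb_geometry(acceptor.coords, donor_sg.coords,
                                            [p for _, p in partners])
        m.model_d = d
        m.model_alphas = {name: a for (name, _), a in zip(partners, alphas)}
        m.model_alpha_min = alpha_min
        m.delta_d = d - chb.d
        m.delta_alpha = alpha_min - chb.alpha_min
        m.recovered = (d <= chb.vdw_sum + params.distance_tolerance
                       and alpha_min <= params.alpha_max)
        matched.append(m)
    return matched


def recovery_fraction(matched: Sequence[MatchedChB]) -> float:
    """Fraction of experimental ChBs whose model geometry still passes."""
    if not matched:
        raise ValueError("recovery fraction is undefined for an empty collection")
    return sum(m.recovered for m in matched) / len(matched)


def mainchain_contact_control(exp: Structure, model: Structure,
                              residue_map: ResidueMap,
                              chb_residues: set[tuple[str, int, str]],
                              cutoff: float = 3.5,
                              adjacency_exclusion: int = 1) -> list[float]:
    """|Delta d| of main-chain O...N contacts around the ChB-forming residues.

    Hydrogen-bond-like contacts (O...N < ``cutoff``, strict) touching at
    least one ChB residue serve as an internal accuracy control: these
    distances are predicted far better than the ChB geometry itself.
    Same-residue and sequence-adjacent pairs (|dseq| <= ``adjacency_exclusion``
    on the same chain) are covalently constrained and excluded.
    """
    o_atoms = [(res, res.get_atom("O")) for res in exp.residues
               if res.is_standard_aa and res.get_atom("O") is not None]
    n_atoms = [(res, res.get_atom("N")) for res in exp.residues
               if res.is_standard_aa and res.get_atom("N") is not None]

    deltas: list[float] = []
    for res_o, atom_o in o_atoms:
        for res_n, atom_n in n_atoms:
            if res_o.key == res_n.key:
                continue
            if (res_o.chain_id == res_n.chain_id
                    and abs(res_o.seq_number - res_n.seq_number) <= adjacency_exclusion):
                continue
            if res_o.key not in chb_residues and res_n.key not in chb_residues:
                continue
            d_exp = float(np.linalg.norm(atom_o.coords - atom_n.coords))
            if d_exp >= cutoff:
                continue
            seq_o = residue_map.pairs.get(res_o.key[:2])
            seq_n = residue_map.pairs.get(res_n.key[:2])
            if seq_o is None or seq_n is None or res_o.icode or res_n.icode:
                logger.info("control contact %s-%s skipped: unmapped residue",
                            res_o.key, res_n.key)
                continue
            model_o = _model_residue(model, seq_o)
            model_n = _model_residue(model, seq_n)
            if model_o is None or model_n is None:
                continue
            atom_mo, atom_mn = model_o.get_atom("O"), model_n.get_atom("N")
            if atom_mo is None or atom_mn is None:
                logger.info("control contact %s-%s skipped: atom missing in model",
                            res_o.key, res_n.key)
                continue
            d_model = float(np.linalg.norm(atom_mo.coords - atom_mn.coords))
            deltas.append(abs(d_model - d_exp))
    return deltas


def plddt_band(mean_plddt: float) -> str:
    """Confidence band: 'low' (<50), 'high' (>90), 'medium' otherwise."""
    if not 0.0 <= mean_plddt <= 100.0:
        raise ValueError(f"pLDDT {mean_plddt} outside [0, 100]")
    if mean_plddt < 50.0:
        return "low"
    if mean_plddt > 90.0:
        return "high"
    return "medium"
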