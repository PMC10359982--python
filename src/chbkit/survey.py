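"""End-to-end drivers: compare one experimental/model pair, or a whole survey."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .detection import ChalcogenBond, ChBParams, detect_chbs
from .pairing import (
    MatchedChB,
    ResidueMap,
    build_residue_map,
    mainchain_contact_control,
    match_chbs,
)
from .report import ComparisonSummary, SurveyReport, pool_summaries, summarize_comparison
from .structure import Structure


@dataclass
class PairResult:
    exp_chbs: list[ChalcogenBond]
    residue_map: ResidueMap
    matched: list[MatchedChB]
    control_deltas: list[float]
    summary: ComparisonSummary


def compare_pair(exp: Structure, model: Structure,
                 params: Optional[ChBParams] = None,
                 control_cutoff: float = 3.5) -> PairResult:
    """Detect ChBs in the experimental entry and re-measure them in the model."""
    params = params or ChBParams()
    exp_chbs = detect_chbs(exp, params)
    residue_map = build_residue_map(exp, model)
    matched = match_chbs(exp_chbs, exp, model, residue_map, params)
    chb_residues = {c.donor_residue for c in exp_chbs} | {c.acceptor_residue
                                                          for c in exp_chbs}
    control = mainchain_contact_control(exp, model, residue_map, chb_residues,
                                        cutoff=control_cutoff)
    summary = summarize_comparison(matched, control, entry_id=exp.metadata.entry_id)
    return PairResult(exp_chbs=exp_chbs, residue_map=residue_map, matched=matched,
                      control_deltas=control, summary=summary)


def run_survey(pairs: Sequence[tuple[Structure, Structure]],
               params: Optional[ChBParams] = None,
               seed: Optional[int] = None) -> SurveyReport:
    """Compare every (experimental, model) pair and pool the statistics."""
    params = params or ChBParams()
    summaries = [compare_pair(exp, model, params).summary for exp, model in pairs]
    return pool_summaries(summaries, chb_params=params, seed=seed)
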