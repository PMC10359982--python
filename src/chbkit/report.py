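"""Aggregation of per-pair comparisons into survey-level statistics.

Uncertainties on means are standard errors of the mean (sample standard
deviation with the n-1 denominator, divided by sqrt(n)); output headers
label them "sem" explicitly.  Pooled statistics concatenate the per-ChB
values across entries rather than averaging per-entry means, so counts
stay additive; the per-entry rows are kept alongside so either convention
can be recomputed.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import CurationPolicy
from .detection import ChBParams
from .pairing import MatchedChB, plddt_band

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def mean_and_stderr(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (n-1 denominator).

    A single value has, by convention, a standard error of 0 (logged).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_and_stderr requires at least one value")
    if arr.size == 1:
        logger.info("mean_and_stderr: single value, standard error set to 0 by convention")
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass
class ComparisonSummary:
    """Per-pair comparison statistics, with raw per-ChB values for pooling."""

    entry_id: str = ""
    n_exp_chbs: int = 0
    n_recovered: int = 0
    recovery_fraction: Optional[float] = None
    mean_abs_delta_d: Optional[float] = None
    sem_abs_delta_d: Optional[float] = None
    mean_abs_delta_alpha: Optional[float] = None
    sem_abs_delta_alpha: Optional[float] = None
    control_mean_abs_delta_d: Optional[float] = None
    control_sem_abs_delta_d: Optional[float] = None
    n_control_contacts: int = 0
    plddt_band_counts: dict[str, int] = field(
        default_factory=lambda: {"low": 0, "medium": 0, "high": 0})
    # raw values retained for exact pooling
    abs_delta_d_values: list[float] = field(default_factory=list)
    abs_delta_alpha_values: list[float] = field(default_factory=list)
    control_abs_delta_d_values: list[float] = field(default_factory=list)


def summarize_comparison(matched: Sequence[MatchedChB],
                         control_deltas: Sequence[float] = (),
                         entry_id: str = "") -> ComparisonSummary:
    """Build a :class:`ComparisonSummary` from matched ChBs and control contacts."""
    s = ComparisonSummary(entry_id=entry_id)
    s.n_exp_chbs = len(matched)
    s.n_recovered = sum(m.recovered for m in matched)
    if matched:
        s.recovery_fraction = s.n_recovered / s.n_exp_chbs
    s.abs_delta_d_values = [abs(m.delta_d) for m in matched if m.delta_d is not None]
    s.abs_delta_alpha_values = [abs(m.delta_alpha) for m in matched
                                if m.delta_alpha is not None]
    if s.abs_delta_d_values:
        s.mean_abs_delta_d, s.sem_abs_delta_d = mean_and_stderr(s.abs_delta_d_values)
    if s.abs_delta_alpha_values:
        s.mean_abs_delta_alpha, s.sem_abs_delta_alpha = mean_and_stderr(
            s.abs_delta_alpha_values)
    s.control_abs_delta_d_values = list(control_deltas)
    s.n_control_contacts = len(s.control_abs_delta_d_values)
    if s.control_abs_delta_d_values:
        s.control_mean_abs_delta_d, s.control_sem_abs_delta_d = mean_and_stderr(
            s.control_abs_delta_d_values)
    for m in matched:
        if m.mean_plddt is not None:
            s.plddt_band_counts[plddt_band(m.mean_plddt)] += 1
    return s


@dataclass
class SurveyReport:
    """Survey-level aggregation over entry pairs."""

    per_entry: list[ComparisonSummary]
    n_exp_chbs: int
    n_recovered: int
    recovery_fraction: Optional[float]
    mean_abs_delta_d: Optional[float]
    sem_abs_delta_d: Optional[float]
    mean_abs_delta_alpha: Optional[float]
    sem_abs_delta_alpha: Optional[float]
    control_mean_abs_delta_d: Optional[float]
    control_sem_abs_delta_d: Optional[float]
    n_control_contacts: int
    plddt_band_counts: dict[str, int]
    run_metadata: dict


def pool_summaries(per_entry: Sequence[ComparisonSummary],
                   chb_params: Optional[ChBParams] = None,
                   curation_policy: Optional[CurationPolicy] = None,
                   seed: Optional[int] = None) -> SurveyReport:
    """Pool per-entry summaries over the concatenated per-ChB values."""
    if not per_entry:
        raise ValueError("pool_summaries requires at least one entry")
    all_dd = [v for s in per_entry for v in s.abs_delta_d_values]
    all_da = [v for s in per_entry for v in s.abs_delta_alpha_values]
    all_ctrl = [v for s in per_entry for v in s.control_abs_delta_d_values]
    n_chbs = sum(s.n_exp_chbs for s in per_entry)
    n_rec = sum(s.n_recovered for s in per_entry)
    bands = {"low": 0, "medium": 0, "high": 0}
    for s in per_entry:
        for band, count in s.plddt_band_counts.items():
            bands[band] += count

    def stats(values: list[float]) -> tuple[Optional[float], Optional[float]]:
        return mean_and_stderr(values) if values else (None, None)

    mean_dd, sem_dd = stats(all_dd)
    mean_da, sem_da = stats(all_da)
    mean_ctrl, sem_ctrl = stats(all_ctrl)
    params = chb_params or ChBParams()
    metadata = {
        "chb_params": _params_dict(params),
        "curation_policy": dataclasses.asdict(curation_policy) if curation_policy else None,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
    }
    return SurveyReport(
        per_entry=list(per_entry),
        n_exp_chbs=n_chbs,
        n_recovered=n_rec,
        recovery_fraction=(n_rec / n_chbs) if n_chbs else None,
        mean_abs_delta_d=mean_dd,
        sem_abs_delta_d=sem_dd,
        mean_abs_delta_alpha=mean_da,
        sem_abs_delta_alpha=sem_da,
        control_mean_abs_delta_d=mean_ctrl,
        control_sem_abs_delta_d=sem_ctrl,
        n_control_contacts=sum(s.n_control_contacts for s in per_entry),
        plddt_band_counts=bands,
        run_metadata=metadata,
    )


def _params_dict(params: ChBParams) -> dict:
    d = dataclasses.asdict(params)
    d["acceptor_elements"] = sorted(d["acceptor_elements"])
    return d


def matched_to_table(matched: Sequence[MatchedChB], entry_id: str = "") -> pd.DataFrame:
    """Per-ChB comparison rows (d at 3 decimals, alpha at 2)."""
    rows = []
    for m in matched:
        c = m.exp_chb
        rows.append({
            "entry_id": entry_id,
            "donor_chain": c.donor_residue[0],
            "donor_resnum": c.donor_residue[1],
            "acceptor_chain": c.acceptor_residue[0],
            "acceptor_resnum": c.acceptor_residue[1],
            "acceptor_atom": c.acceptor_atom,
            "exp_d": round(c.d, 3),
            "exp_alpha_min": round(c.alpha_min, 2),
            "model_d": round(m.model_d, 3) if m.model_d is not None else None,
            "model_alpha_min": (round(m.model_alpha_min, 2)
                                if m.model_alpha_min is not None else None),
            "delta_d": round(m.delta_d, 3) if m.delta_d is not None else None,
            "delta_alpha": round(m.delta_alpha, 2) if m.delta_alpha is not None else None,
            "recovered": m.recovered,
            "mean_plddt": round(m.mean_plddt, 2) if m.mean_plddt is not None else None,
            "absent_reason": m.absent_reason,
        })
    return pd.DataFrame(rows)


def write_matched_tsv(matched: Sequence[MatchedChB], path, entry_id: str = "") -> None:
    matched_to_table(matched, entry_id).to_csv(path, sep="\t", index=False)


def report_to_table(report: SurveyReport) -> pd.DataFrame:
    """Per-entry summary rows followed by a pooled row."""
    rows = []
    for s in report.per_entry + [None]:
        if s is None:
            src, label = report, "POOLED"
        else:
            src, label = s, s.entry_id
        rows.append({
            "entry_id": label,
            "n_exp_chbs": src.n_exp_chbs,
            "n_recovered": src.n_recovered,
            "recovery_fraction": src.recovery_fraction,
            "mean_abs_delta_d_A": src.mean_abs_delta_d,
            "sem_abs_delta_d_A": src.sem_abs_delta_d,
            "mean_abs_delta_alpha_deg": src.mean_abs_delta_alpha,
            "sem_abs_delta_alpha_deg": src.sem_abs_delta_alpha,
            "control_mean_abs_delta_d_A": src.control_mean_abs_delta_d,
            "control_sem_abs_delta_d_A": src.control_sem_abs_delta_d,
            "n_control_contacts": src.n_control_contacts,
            "plddt_low": src.plddt_band_counts["low"],
            "plddt_medium": src.plddt_band_counts["medium"],
            "plddt_high": src.plddt_band_counts["high"],
        })
    return pd.DataFrame(rows)


def write_report_csv(report: SurveyReport, path) -> None:
    report_to_table(report).to_csv(path, index=False)
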