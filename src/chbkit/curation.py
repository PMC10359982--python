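"""Selection filters for the experimental survey set.

The survey keeps only single-model X-ray structures refined at <= 1.5 A
resolution, collected at cryogenic temperature (90-110 K), with at most 5%
of atoms that are neither protein nor water, and reduces sequence redundancy
to <= 40% pairwise identity.  Redundancy reduction is an interface to an
external clustering executable (CD-HIT); when none is configured a
documented greedy stand-in based on global pairwise alignment is applied.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .errors import ToolInvocationError
from .structure import Structure, nonprotein_fraction

logger = logging.getLogger(__name__)


@dataclass
class CurationPolicy:
    max_resolution: float = 1.5  # Angstrom
    temp_range: tuple[float, float] = (90.0, 110.0)  # Kelvin, inclusive
    max_nonprotein_fraction: float = 0.05
    require_single_model: bool = True
    require_xray: bool = True
    max_seq_identity: float = 40.0  # percent, redundancy stage

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        if self.temp_range[0] > self.temp_range[1]:
            raise ValueError("temp_range must be ordered")
        if not 0 <= self.max_nonprotein_fraction <= 1:
            raise ValueError("max_nonprotein_fraction must be in [0, 1]")


@dataclass
class CurationVerdict:
    entry_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)


def apply_curation(structure: Structure, policy: Optional[CurationPolicy] = None
                   ) -> CurationVerdict:
    """Evaluate every selection rule independently and report all failures.

    Missing metadata required by a rule fails that rule: curation is
    conservative by design.
    """
    policy = policy or CurationPolicy()
    meta = structure.metadata
    failed: list[str] = []

    if policy.require_xray:
        if meta.method is None or "X-RAY" not in meta.method.upper():
            failed.append("method")
    if meta.resolution is None or meta.resolution > policy.max_resolution:
        failed.append("resolution")
    if (meta.temperature is None
            or not policy.temp_range[0] <= meta.temperature <= policy.temp_range[1]):
        failed.append("temperature")
    if policy.require_single_model and meta.n_models != 1:
        failed.append("single_model")
    if nonprotein_fraction(structure) > policy.max_nonprotein_fraction:
        failed.append("nonprotein_fraction")

    return CurationVerdict(entry_id=meta.entry_id, passed=not failed, failed_rules=failed)


def has_pairable_accession(structure: Structure) -> tuple[bool, Optional[str]]:
    """Whether any DBREF names a sequence-database accession usable for pairing."""
    for ref in structure.metadata.dbrefs:
        if ref.accession:
            return True, ref.accession
    return False, None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity on a global alignment: matches / alignment length * 100."""
    if not seq_a or not seq_b:
        return 0.0
    alignment = _make_aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    return 100.0 * matches / len(row_a)


def redundancy_filter(entries: Sequence[tuple[str, str]], max_identity: float = 40.0,
                      clustering_exe: Optional[str] = None) -> list[str]:
    """Retain one representative per sequence-identity cluster.

    When ``clustering_exe`` points at a CD-HIT-style executable it is run on
    a temporary FASTA file and its representatives are returned.  Otherwise a
    greedy stand-in is used: entries are visited by descending sequence
    length and kept unless their global-alignment identity to an already
    retained sequence exceeds ``max_identity`` percent.
    """
    if clustering_exe is not None:
        return _external_cluster(entries, max_identity, clustering_exe)

    logger.info("redundancy_filter: external clustering not configured; "
                "using the greedy alignment-identity stand-in")
    order = sorted(range(len(entries)), key=lambda i: -len(entries[i][1]))
    retained: list[int] = []
    for i in order:
        _, seq = entries[i]
        if all(pairwise_identity(seq, entries[j][1]) <= max_identity for j in retained):
            retained.append(i)
    retained.sort()
    return [entries[i][0] for i in retained]


def _external_cluster(entries: Sequence[tuple[str, str]], max_identity: float,
                      exe: str) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "input.fasta"
        out = Path(tmp) / "clustered"
        fasta.write_text("".join(f">{eid}\n{seq}\n" for eid, seq in entries))
        cmd = [exe, "-i", str(fasta), "-o", str(out), "-c", f"{max_identity / 100:.2f}"]
        try:
            subprocess.run(cmd, check=True, capture_output=True)
        except (OSError, subprocess.CalledProcessError) as exc:
            raise ToolInvocationError(f"clustering tool failed: {exc}") from exc
        ids = [line[1:].split()[0] for line in out.read_text().splitlines()
               if line.startswith(">")]
    return ids
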