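"""Reading and writing structure files.

Reading is backed by gemmi (PDB and mmCIF).  DBREF records and the
REMARK 200 temperature field are recovered from the raw PDB records,
which gemmi keeps but does not expose as typed objects.  Writing emits
a narrow, fixed-column PDB subset (REMARK 2/200, EXPDTA, DBREF, SSBOND,
ATOM/HETATM) sufficient for round-tripping every field this pipeline
consumes.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional

import gemmi

from .errors import EmptyStructureError, FormatError, SerializationError
from .structure import (
    EXPERIMENTAL,
    PREDICTED,
    STANDARD_AA,
    Atom,
    DBRef,
    Residue,
    SSBondRecord,
    Structure,
    StructureMetadata,
)

logger = logging.getLogger(__name__)

_TEMP_RE = re.compile(r"REMARK 200\s+TEMPERATURE\s+\(KELVIN\)\s*:\s*([0-9.]+)")


def _parse_dbref_line(line: str) -> Optional[DBRef]:
    # PDB v3 fixed columns; fall back to whitespace tokens for lenient input.
    try:
        chain = line[12].strip()
        seq_begin = int(line[14:18])
        seq_end = int(line[20:24])
        db_name = line[26:32].strip()
        accession = line[33:41].strip()
        db_begin = int(line[55:60])
        db_end = int(line[62:67])
        return DBRef(chain, db_name, accession, seq_begin, seq_end, db_begin, db_end)
    except (ValueError, IndexError):
        pass
    tokens = line.split()
    if len(tokens) >= 10:
        try:
            return DBRef(
                tokens[2], tokens[5], tokens[6],
                int(tokens[3]), int(tokens[4]), int(tokens[8]), int(tokens[9]),
            )
        except ValueError:
            return None
    return None


def _parse_pdb_header_records(text: str) -> tuple[list[DBRef], Optional[float]]:
    dbrefs: list[DBRef] = []
    temperature: Optional[float] = None
    for line in text.splitlines():
        if line.startswith("DBREF "):
            ref = _parse_dbref_line(line)
            if ref is not None:
                dbrefs.append(ref)
            else:
                logger.warning("unparseable DBREF record skipped: %r", line)
        elif temperature is None and line.startswith("REMARK 200"):
            m = _TEMP_RE.search(line)
            if m:
                temperature = float(m.group(1))
    return dbrefs, temperature


def read_structure(path, format: str = "auto", source: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model's coordinates are loaded; ``metadata.n_models``
    reflects the whole file.  Hydrogens are dropped; alternate locations
    other than blank/"A" are discarded (logged).  ``source`` forces the
    provenance label; by default a file without a crystallographic
    resolution is labelled a predicted model.
    """
    path = Path(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.remove_hydrogens()

    dbrefs: list[DBRef] = []
    temperature: Optional[float] = None
    if st.input_format == gemmi.CoorFormat.Pdb:
        dbrefs, temperature = _parse_pdb_header_records(path.read_text())

    resolution = st.resolution if st.resolution > 0 else None
    info = dict(st.info)
    method = info.get("_exptl.method") or None
    if source is None:
        source = EXPERIMENTAL if resolution is not None else PREDICTED

    ssbonds = []
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            p1, p2 = con.partner1, con.partner2
            ssbonds.append(SSBondRecord(
                p1.chain_name, p1.res_id.seqid.num, p1.res_id.seqid.icode.strip(),
                p2.chain_name, p2.res_id.seqid.num, p2.res_id.seqid.icode.strip(),
            ))

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    residues: list[Residue] = []
    n_discarded_alt = 0
    for chain in st[0]:
        for res in chain:
            atoms: list[Atom] = []
            for atom in res:
                alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                if alt not in ("", "A"):
                    n_discarded_alt += 1
                    continue
                atoms.append(Atom(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    altloc=alt,
                    coords=[atom.pos.x, atom.pos.y, atom.pos.z],
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    bfactor=atom.b_iso,
                ))
            if atoms:
                residues.append(Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    atoms=atoms,
                ))
    if n_discarded_alt:
        logger.info("%s: discarded %d alternate-location atoms (kept blank/'A')",
                    path.name, n_discarded_alt)
    if not any(r.res_name in STANDARD_AA for r in residues):
        raise EmptyStructureError(f"{path}: no protein atoms")

    metadata = StructureMetadata(
        entry_id=st.name or info.get("_entry.id", ""),
        source=source,
        method=method,
        resolution=resolution,
        temperature=temperature,
        n_models=max(len(st), 1),
        dbrefs=dbrefs,
        ssbond_records=ssbonds,
    )
    structure = Structure(metadata=metadata, residues=residues)
    _check_ssbond_resolvable(structure)
    return structure


def _check_ssbond_resolvable(structure: Structure) -> None:
    index = structure.residue_index()
    for rec in structure.metadata.ssbond_records:
        for chain, seq, icode in ((rec.chain_1, rec.seq_1, rec.icode_1),
                                  (rec.chain_2, rec.seq_2, rec.icode_2)):
            if (chain, seq, icode) not in index:
                logger.warning("%s: SSBOND residue %s %s%s not in coordinates",
                               structure.metadata.entry_id, chain, seq, icode)


def _format_coord(value: float) -> str:
    out = f"{value:8.3f}"
    if len(out) != 8:
        raise SerializationError(f"coordinate {value} exceeds PDB column width")
    return out


def _atom_name_field(name: str) -> str:
    # Single-letter element atom names start in column 14 by PDB convention.
    if len(name) < 4:
        return f" {name:<3s}"
    return name[:4]


def write_structure(structure: Structure, path) -> None:
    """Write a :class:`Structure` as fixed-column PDB text.

    Coordinates are quantized to the format's 3-decimal precision, so
    ``read_structure(write_structure(s))`` reproduces them to 0.001 A.
    """
    meta = structure.metadata
    lines: list[str] = []
    if meta.method:
        lines.append(f"EXPDTA    {meta.method}")
    if meta.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {meta.resolution:7.2f} ANGSTROMS.")
    if meta.temperature is not None:
        lines.append(f"REMARK 200  TEMPERATURE           (KELVIN) : {meta.temperature:g}")
    for ref in meta.dbrefs:
        lines.append(
            f"DBREF  {meta.entry_id[:4]:<4s} {ref.chain_id:1s} "
            f"{ref.seq_begin:4d}  {ref.seq_end:4d}  {ref.db_name:<6s} "
            f"{ref.accession:<8s} {'':<12s} {ref.db_begin:5d}  {ref.db_end:5d}"
        )
    for i, rec in enumerate(meta.ssbond_records, start=1):
        lines.append(
            f"SSBOND {i:3d} CYS {rec.chain_1:1s} {rec.seq_1:4d}{rec.icode_1 or ' '}"
            f"   CYS {rec.chain_2:1s} {rec.seq_2:4d}{rec.icode_2 or ' '}"
        )
    serial = 0
    for res in structure.residues:
        record = "ATOM  " if (res.is_standard_aa or res.is_water) else "HETATM"
        for atom in res.atoms:
            serial += 1
            if serial > 99999:
                raise SerializationError("more than 99999 atoms")
            x, y, z = (_format_coord(v) for v in atom.coords)
            lines.append(
                f"{record}{serial:5d} {_atom_name_field(atom.name)}{atom.altloc or ' '}"
                f"{res.res_name:<3s} {res.chain_id:1s}{res.seq_number:4d}{res.icode or ' '}"
                f"   {x}{y}{z}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
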