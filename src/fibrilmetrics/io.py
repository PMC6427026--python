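"""File I/O: structures (PDB/mmCIF via gemmi), traces (CSV), sequences
(FASTA via Biopython).

Altloc policy on reading: for each (residue, atom name) the highest-
occupancy alternate location is kept; ties keep the first.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError
from .mechanics import FibrilTrace
from .structure import ATOM_COLUMNS, AtomicModel

logger = logging.getLogger("fibrilmetrics")

TRACE_COLUMNS = ["fibril_id", "vertex_index", "x_nm", "y_nm"]


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def read_structure(path) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Uses the first model; keeps the highest-occupancy altloc per atom.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no model")
    rows = []
    n_alt_dropped = 0
    for chain in st[0]:
        for residue in chain:
            best: dict[str, tuple[float, tuple]] = {}
            for atom in residue:
                row = (chain.name, residue.seqid.num, residue.name.strip(),
                       atom.name.strip(), atom.element.name.upper(),
                       atom.pos.x, atom.pos.y, atom.pos.z)
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = (atom.occ, row)
                else:
                    n_alt_dropped += 1
                    if atom.occ > prev[0]:
                        best[atom.name] = (atom.occ, row)
            rows.extend(row for _, row in best.values())
    if not rows:
        raise FormatError(f"{path} contains no atoms")
    if n_alt_dropped:
        logger.info("dropped %d alternate locations reading %s",
                    n_alt_dropped, path)
    return AtomicModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def write_structure(model: AtomicModel, path) -> None:
    """Write a model as PDB (.pdb) or mmCIF (.cif/.mmcif)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    gm = gemmi.Model("1")
    for chain_label in model.chains:
        chain = gemmi.Chain(str(chain_label))
        sub = model.select_chain(chain_label).atoms
        for (res_seq, res_name), grp in sub.groupby(["res_seq", "res_name"],
                                                    sort=False):
            res = gemmi.Residue()
            res.name = str(res_name)
            res.seqid = gemmi.SeqId(int(res_seq), " ")
            for row in grp.itertuples():
                atom = gemmi.Atom()
                atom.name = str(row.name)
                atom.element = gemmi.Element(str(row.element))
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        st.write_pdb(str(path))
    elif suffix in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise FormatError(f"unsupported structure extension {suffix!r}")


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def write_traces(traces: list[FibrilTrace], path) -> None:
    """Write traces as CSV with columns fibril_id, vertex_index, x_nm, y_nm."""
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "fibril_id": t.fibril_id,
            "vertex_index": np.arange(len(t.vertices)),
            "x_nm": t.vertices[:, 0],
            "y_nm": t.vertices[:, 1],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[FibrilTrace]:
    """Read traces from the CSV dialect written by :func:`write_traces`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks columns {missing}")
    traces = []
    for fid, grp in df.groupby("fibril_id", sort=False):
        grp = grp.sort_values("vertex_index")
        traces.append(FibrilTrace(grp[["x_nm", "y_nm"]].to_numpy(float),
                                  fibril_id=str(fid)))
    if not traces:
        raise FormatError(f"{path} contains no traces")
    return traces


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (order-preserving)."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"{path} contains no FASTA records")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
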