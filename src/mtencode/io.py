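"""Format round-trips: pattern CSV, lattice PDB export, JSON configs.

Pattern CSV dialect: comma-separated, mandatory header
``site_index,protofilament,axial,state``, UTF-8, LF endings.  PDB export
writes one pseudo-atom per tubulin monomer (coordinates in Angstrom,
chain per protofilament, residue name ALA, B-factor column carrying the
phosphorylation state 0/1/2 when a pattern is attached).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from .encoding import LatticePhospho, PhosphoPattern, get_scheme
from .errors import ParameterError
from .lattice import MTLattice, Patch

__all__ = [
    "pattern_to_csv",
    "pattern_from_csv",
    "lattice_to_pdb",
    "pdb_roundtrip_coordinates",
]

PATTERN_COLUMNS = ["site_index", "protofilament", "axial", "state"]

# chain identifiers for up to 26 protofilaments
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def pattern_to_csv(pattern: PhosphoPattern, path, patch: Optional[Patch] = None) -> None:
    """Write a pattern to CSV; protofilament/axial columns come from the
    bound patch when given, else -1 placeholders."""
    rows = []
    for i, state in enumerate(pattern.site_states):
        if patch is not None:
            p, a = patch.peripheral[i].index
        else:
            p, a = -1, -1
        rows.append({"site_index": i, "protofilament": p, "axial": a, "state": state})
    df = pd.DataFrame(rows, columns=PATTERN_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def pattern_from_csv(path, scheme) -> PhosphoPattern:
    """Read a pattern CSV back; malformed rows raise a parse error naming
    the offending line number (header = line 1)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParameterError(f"cannot parse pattern CSV: {exc}") from exc
    if list(df.columns) != PATTERN_COLUMNS:
        raise ParameterError(
            f"pattern CSV must have header {','.join(PATTERN_COLUMNS)}"
        )
    s = get_scheme(scheme)
    digits = [0] * s.n_sites
    for row_pos, row in enumerate(df.itertuples(index=False)):
        line_no = row_pos + 2  # header is line 1
        try:
            idx, state = int(row.site_index), int(row.state)
        except (TypeError, ValueError):
            raise ParameterError(
                f"line {line_no}: site_index and state must be integers"
            ) from None
        if not 0 <= idx < s.n_sites:
            raise ParameterError(
                f"line {line_no}: site_index {idx} outside [0, {s.n_sites})"
            )
        if not 0 <= state < s.states_per_site:
            raise ParameterError(
                f"line {line_no}: state {state} outside "
                f"[0, {s.states_per_site})"
            )
        digits[idx] = state
    return PhosphoPattern(s, tuple(digits))


def lattice_to_pdb(
    lattice: MTLattice, path, phospho: Optional[LatticePhospho] = None
) -> None:
    """Export the lattice as pseudo-atoms, one CA per monomer.

    Coordinates convert nm -> Angstrom; each protofilament becomes a chain;
    the B-factor column records the dimer's phosphorylation state.
    """
    if lattice.spec.n_protofilaments > len(_CHAIN_IDS):
        raise ParameterError("PDB export supports at most 26 protofilaments")
    builder = StructureBuilder()
    builder.init_structure("MT")
    builder.init_model(0)
    for p in range(lattice.spec.n_protofilaments):
        builder.init_chain(_CHAIN_IDS[p])
        builder.init_seg("    ")
        resseq = 0
        for a in range(lattice.spec.n_dimer_rings):
            site = lattice.site(p, a)
            state = float(phospho.state(site)) if phospho is not None else 0.0
            for mono, coord in (("alpha", site.alpha_center), ("beta", site.beta_center)):
                resseq += 1
                builder.init_residue("ALA", " ", resseq, " ")
                builder.init_atom(
                    "CA",
                    [c * 10.0 for c in coord],  # nm -> Angstrom
                    state,
                    1.0,
                    " ",
                    " CA ",
                    resseq,
                    element="C",
                )
    out = PDBIO()
    out.set_structure(builder.get_structure())
    out.save(str(path))


def pdb_roundtrip_coordinates(path):
    """Parse an exported PDB back into an (n_atoms, 3) Angstrom array."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("MT", str(path))
    import numpy as np

    return np.array([atom.coord for atom in structure.get_atoms()], dtype=float)
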