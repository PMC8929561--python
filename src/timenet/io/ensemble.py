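"""Multi-model PDB structure ensembles.

An ensemble is a fixed atom roster plus one coordinate set per frame --
each MODEL of a multi-model PDB file (e.g. an NMR bundle or extracted MD
snapshots) becomes one frame.  Parsing is delegated to biotite, whose
``AtomArrayStack`` enforces the constant-roster invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure import infer_elements
from biotite.structure.io.pdb import PDBFile

__all__ = ["StructureEnsemble", "read_pdb_ensemble", "write_pdb_ensemble"]


@dataclass
class StructureEnsemble:
    """Atom table plus (n_frames, n_atoms, 3) coordinates in Angstrom.

    The atom table has columns chain, res_id, ins_code, res_name,
    atom_name, element; atom identifiers render as
    ``chain:res_id[ins_code]:res_name:atom_name``.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} != "
                f"atom table length {len(self.atoms)}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_ids(self) -> list[str]:
        out = []
        for row in self.atoms.itertuples(index=False):
            resnum = f"{row.res_id}{row.ins_code}".strip()
            out.append(f"{row.chain}:{resnum}:{row.res_name}:{row.atom_name}")
        return out

    def residue_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for aid in self.atom_ids():
            seen[":".join(aid.split(":")[:3])] = None
        return list(seen)

    def first_frame(self) -> "StructureEnsemble":
        return StructureEnsemble(self.atoms, self.coords[:1], source=self.source)


def _stack_to_ensemble(stack: AtomArrayStack, source: str) -> StructureEnsemble:
    elements = np.asarray(stack.element)
    blank = np.char.strip(elements.astype(str)) == ""
    if blank.any():
        inferred = np.asarray(infer_elements(stack.atom_name))
        elements = np.where(blank, inferred, elements)
    atoms = pd.DataFrame(
        {
            "chain": [c if c.strip() else "_" for c in stack.chain_id],
            "res_id": stack.res_id.astype(int),
            "ins_code": [i.strip() for i in stack.ins_code],
            "res_name": [r.strip() for r in stack.res_name],
            "atom_name": [a.strip() for a in stack.atom_name],
            "element": [e.strip().upper() for e in elements],
        }
    )
    return StructureEnsemble(atoms, stack.coord.copy(), source=source)


def read_pdb_ensemble(
    path: str | Path, first_model_only: bool = False
) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into an ensemble.

    One frame per MODEL; a file without MODEL records yields a single
    frame.  ``first_model_only`` keeps only MODEL 1, the convention for
    treating an NMR bundle as a single structure.  Files whose models
    disagree on the atom roster are rejected.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors
        raise ValueError(f"{path}: cannot parse PDB file: {exc}") from exc
    if first_model_only:
        atoms = pdb.get_structure(model=1)
        stack = AtomArrayStack(1, atoms.array_length())
        for category in atoms.get_annotation_categories():
            stack.set_annotation(category, atoms.get_annotation(category))
        stack.coord[0] = atoms.coord
    else:
        try:
            stack = pdb.get_structure()
        except Exception as exc:  # noqa: BLE001
            raise ValueError(
                f"{path}: inconsistent atom rosters across models: {exc}"
            ) from exc
    return _stack_to_ensemble(stack, source=path.name)


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    n = ensemble.n_atoms
    stack = AtomArrayStack(ensemble.n_frames, n)
    stack.coord[:] = ensemble.coords
    stack.set_annotation(
        "chain_id",
        np.array(
            [c if c != "_" else "A" for c in ensemble.atoms["chain"]], dtype="U4"
        ),
    )
    stack.set_annotation("res_id", ensemble.atoms["res_id"].to_numpy())
    stack.set_annotation(
        "ins_code", ensemble.atoms["ins_code"].to_numpy().astype("U1")
    )
    stack.set_annotation(
        "res_name", ensemble.atoms["res_name"].to_numpy().astype("U5")
    )
    stack.set_annotation(
        "atom_name", ensemble.atoms["atom_name"].to_numpy().astype("U6")
    )
    stack.set_annotation(
        "element", ensemble.atoms["element"].to_numpy().astype("U2")
    )
    stack.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
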