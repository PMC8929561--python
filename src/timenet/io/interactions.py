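"""Geometric extraction of contact and hydrogen-bond timelines.

Contacts follow the carbon-contact convention: a binary interaction exists
in a frame when two carbon atoms of different residues are within the
distance cutoff (5 Angstrom by default).  Hydrogen bonds use the common
geometric criterion of heavy-atom donor-acceptor distance <= 3.5 Angstrom
and donor-H-acceptor angle >= 135 degrees; for ensembles without explicit
hydrogens (typical crystal structures) detection falls back to the
distance criterion alone and the records are flagged ``distance-only``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..network import Timeline, TimelineRecord
from .ensemble import StructureEnsemble

__all__ = ["extract_contacts", "extract_hbonds", "DONOR_ATOMS", "ACCEPTOR_ATOMS"]

_AA = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()

# Fixed donor/acceptor chemistry for the standard amino acids.  Backbone N
# (except proline) donates, backbone O and terminal OXT accept; residues not
# listed here contribute contacts only.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

DONOR_ATOMS = {
    res: ({"N"} if res != "PRO" else set()) | _SIDECHAIN_DONORS.get(res, set())
    for res in _AA
}
ACCEPTOR_ATOMS = {
    res: {"O", "OXT"} | _SIDECHAIN_ACCEPTORS.get(res, set()) for res in _AA
}

_H_COVALENT_CUTOFF = 1.25  # Angstrom, donor-hydrogen attachment distance


def _residue_keys(ensemble: StructureEnsemble) -> np.ndarray:
    atoms = ensemble.atoms
    return (
        atoms["chain"].astype(str)
        + ":"
        + atoms["res_id"].astype(str)
        + atoms["ins_code"].astype(str)
    ).to_numpy()


def extract_contacts(
    ensemble: StructureEnsemble,
    cutoff: float = 5.0,
    selection: Callable[[dict], bool] | None = None,
    exclude_neighbors: int = 0,
) -> list[TimelineRecord]:
    """Binary carbon-contact timelines for every inter-residue carbon pair.

    A pair is in contact in a frame when its Euclidean distance is within
    ``cutoff``; pairs never in contact are omitted.  ``selection`` further
    restricts the carbon atoms (a predicate over atom-table rows as dicts).
    ``exclude_neighbors`` drops same-chain pairs within that many residues
    in sequence (0 = only intra-residue pairs excluded, the default).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = ensemble.atoms
    mask = (atoms["element"] == "C").to_numpy()
    if selection is not None:
        rows = atoms.to_dict("records")
        mask &= np.array([bool(selection(r)) for r in rows])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("contact atom selection is empty")

    ids = np.array(ensemble.atom_ids())[idx]
    res_keys = _residue_keys(ensemble)[idx]
    chains = atoms["chain"].to_numpy()[idx]
    res_nums = atoms["res_id"].to_numpy()[idx]
    coords = ensemble.coords[:, idx, :]  # (T, m, 3)

    diff = coords[:, :, None, :] - coords[:, None, :, :]
    within = (np.sqrt((diff**2).sum(axis=-1)) <= cutoff)  # (T, m, m)

    records = []
    m = idx.size
    for a in range(m):
        for b in range(a + 1, m):
            if res_keys[a] == res_keys[b]:
                continue
            if (
                exclude_neighbors > 0
                and chains[a] == chains[b]
                and abs(int(res_nums[a]) - int(res_nums[b])) <= exclude_neighbors
            ):
                continue
            series = within[:, a, b]
            if series.any():
                # canonical endpoint order: independent of atom enumeration
                u, v = sorted((str(ids[a]), str(ids[b])))
                records.append(
                    TimelineRecord(u, v, "contact", Timeline(series.astype(int)))
                )
    return records


def _attached_hydrogens(ensemble: StructureEnsemble) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of covalently attached hydrogens.

    Attachment is geometric (first frame, same residue, within 1.25 A)."""
    atoms = ensemble.atoms
    res_keys = _residue_keys(ensemble)
    h_idx = np.flatnonzero((atoms["element"] == "H").to_numpy())
    heavy_idx = np.flatnonzero((atoms["element"] != "H").to_numpy())
    coords0 = ensemble.coords[0]
    attached: dict[int, list[int]] = {}
    for h in h_idx:
        same_res = heavy_idx[res_keys[heavy_idx] == res_keys[h]]
        if same_res.size == 0:
            continue
        d = np.linalg.norm(coords0[same_res] - coords0[h], axis=1)
        nearest = same_res[int(np.argmin(d))]
        if d.min() <= _H_COVALENT_CUTOFF:
            attached.setdefault(int(nearest), []).append(int(h))
    return attached


def extract_hbonds(
    ensemble: StructureEnsemble,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 135.0,
) -> list[TimelineRecord]:
    """Binary hydrogen-bond timelines between donor and acceptor atoms.

    Donors/acceptors come from a fixed table for the standard amino acids
    (N/O/S chemistry).  A bond exists in a frame when the heavy-atom
    donor-acceptor distance is within ``dist_cutoff`` and some attached
    hydrogen gives a donor-H-acceptor angle >= ``angle_cutoff``.  Without
    any hydrogens in the ensemble the angle test is skipped and every
    record is flagged ``distance-only``.  Intra-residue pairs are skipped.
    """
    if dist_cutoff <= 0:
        raise ValueError("distance cutoff must be positive")
    if not 0 < angle_cutoff <= 180:
        raise ValueError("angle cutoff must be in (0, 180] degrees")
    atoms = ensemble.atoms
    res_keys = _residue_keys(ensemble)
    ids = np.array(ensemble.atom_ids())

    donors, acceptors = [], []
    for i, row in enumerate(atoms.itertuples(index=False)):
        table_d = DONOR_ATOMS.get(row.res_name, set())
        table_a = ACCEPTOR_ATOMS.get(row.res_name, set())
        if row.atom_name in table_d:
            donors.append(i)
        if row.atom_name in table_a:
            acceptors.append(i)

    has_hydrogens = bool((atoms["element"] == "H").any())
    attached = _attached_hydrogens(ensemble) if has_hydrogens else {}
    coords = ensemble.coords
    flags = () if has_hydrogens else ("distance-only",)

    records = []
    for d in donors:
        hydrogens = attached.get(d, [])
        if has_hydrogens and not hydrogens:
            continue  # donor without a proton cannot donate
        for a in acceptors:
            if a == d or res_keys[a] == res_keys[d]:
                continue
            dist = np.linalg.norm(coords[:, d] - coords[:, a], axis=1)
            present = dist <= dist_cutoff
            if has_hydrogens and present.any():
                angle_ok = np.zeros(ensemble.n_frames, dtype=bool)
                for h in hydrogens:
                    v1 = coords[:, d] - coords[:, h]
                    v2 = coords[:, a] - coords[:, h]
                    cosang = np.sum(v1 * v2, axis=1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    angle_ok |= angle >= angle_cutoff
                present &= angle_ok
            if present.any():
                records.append(
                    TimelineRecord(
                        str(ids[d]), str(ids[a]), "hbond", Timeline(present.astype(int)), flags
                    )
                )
    return records
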