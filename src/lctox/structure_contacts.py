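"""Residue contact maps from a homodimeric light-chain structure.

Two residues are in contact when their Cβ atoms (Cα for glycine) lie
strictly closer than a distance threshold, 7.5 Å by default.  Contacts
within a chain form the monomeric pair set; contacts across the two chains
of the dimer form the dimeric pair set.  Pairs are expressed in progressive
scheme positions via a PDB-residue-to-scheme map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 7.5


@dataclass(frozen=True)
class ContactMap:
    """Monomeric and dimeric position-pair sets at a Cβ distance threshold.

    ``monomeric_pairs`` holds unordered within-chain pairs ``(i, j)`` with
    ``i < j``; ``dimeric_pairs`` holds chain-crossing pairs ``(i, j)`` with
    ``i <= j`` (a position may contact its two-fold symmetric mate).
    """

    monomeric_pairs: frozenset[tuple[int, int]]
    dimeric_pairs: frozenset[tuple[int, int]]
    threshold_angstrom: float
    structure_id: str
    chain_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.threshold_angstrom <= 0:
            raise ValueError("threshold must be positive")
        if any(i >= j for i, j in self.monomeric_pairs):
            raise ValueError("monomeric pairs must satisfy i < j")
        if any(i > j for i, j in self.dimeric_pairs):
            raise ValueError("dimeric pairs must satisfy i <= j")


def load_structure_cbeta(pdb_path, chain_ids: tuple[str, str] | None = None
                         ) -> dict[str, dict[int, np.ndarray]]:
    """Per-chain mapping from residue number to Cβ coordinate.

    Glycine (or any residue lacking a Cβ atom) falls back to Cα.  Alternate
    locations are resolved by highest occupancy, ties alphabetically by
    altloc identifier.  Only ATOM records contribute; water and hetero
    residues are skipped.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", pdb_path)
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chain_ids is None:
        chain_ids = tuple(available[:2])
    missing = [c for c in chain_ids if c not in available]
    if missing:
        raise ValueError(f"chains {missing} not in structure (has {available})")

    out: dict[str, dict[int, np.ndarray]] = {}
    for cid in chain_ids:
        coords: dict[int, np.ndarray] = {}
        for residue in model[cid]:
            hetflag, resseq, _icode = residue.id
            if hetflag.strip():
                continue
            atom = _pick_atom(residue, "CB") or _pick_atom(residue, "CA")
            if atom is None:
                raise ValueError(
                    f"residue {residue.get_resname()} {cid}:{resseq} has "
                    "neither CB nor CA"
                )
            coords[resseq] = np.asarray(atom.get_coord(), dtype=float)
        out[cid] = coords
        logger.debug("chain %s: %d residue coordinates", cid, len(coords))
    return out


def _pick_atom(residue, name: str):
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        children.sort(key=lambda a: (-a.get_occupancy(), a.get_altloc()))
        return children[0]
    return atom


def build_contact_map(coords_chain1: Mapping[int, np.ndarray],
                      coords_chain2: Mapping[int, np.ndarray],
                      pdb_to_scheme_map: Mapping[tuple[str, int], int],
                      threshold: float = DEFAULT_THRESHOLD,
                      structure_id: str = "structure",
                      chain_pair: tuple[str, str] = ("A", "B")) -> ContactMap:
    """Derive monomeric and dimeric contact pairs in scheme positions.

    The map keys are ``(chain_id, pdb_resnum)``.  Every residue present in
    the coordinate sets must be mapped; unmapped residues abort with the
    full list so numbering problems surface immediately.  Distances are
    compared strictly (< threshold).
    """
    chains = (dict(coords_chain1), dict(coords_chain2))
    unmapped = [(cid, r) for cid, coords in zip(chain_pair, chains)
                for r in coords if (cid, r) not in pdb_to_scheme_map]
    if unmapped:
        raise ValueError(f"residues without a scheme position: {sorted(unmapped)}")

    def positions_and_xyz(cid, coords):
        res = sorted(coords)
        pos = np.array([pdb_to_scheme_map[(cid, r)] for r in res])
        xyz = np.array([coords[r] for r in res], dtype=float).reshape(len(res), 3)
        return pos, xyz

    p1, x1 = positions_and_xyz(chain_pair[0], chains[0])
    p2, x2 = positions_and_xyz(chain_pair[1], chains[1])

    monomeric: set[tuple[int, int]] = set()
    for pos, xyz in ((p1, x1), (p2, x2)):
        if len(pos) == 0:
            continue
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        ii, jj = np.nonzero(d < threshold)
        for a, b in zip(ii, jj):
            if pos[a] < pos[b]:
                monomeric.add((int(pos[a]), int(pos[b])))

    dimeric: set[tuple[int, int]] = set()
    if len(p1) and len(p2):
        d = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=-1)
        ii, jj = np.nonzero(d < threshold)
        for a, b in zip(ii, jj):
            i, j = sorted((int(p1[a]), int(p2[b])))
            dimeric.add((i, j))

    logger.info("contact map %s: %d monomeric, %d dimeric pairs (< %.2f A)",
                structure_id, len(monomeric), len(dimeric), threshold)
    return ContactMap(frozenset(monomeric), frozenset(dimeric),
                      float(threshold), structure_id, tuple(chain_pair))


def contact_map_from_pdb(pdb_path, pdb_to_scheme_map,
                         chain_ids: tuple[str, str] | None = None,
                         threshold: float = DEFAULT_THRESHOLD,
                         structure_id: str | None = None) -> ContactMap:
    """Convenience wrapper: parse a PDB file and build its contact map."""
    coords = load_structure_cbeta(pdb_path, chain_ids)
    cids = tuple(coords)
    return build_contact_map(coords[cids[0]], coords[cids[1]], pdb_to_scheme_map,
                             threshold=threshold,
                             structure_id=structure_id or str(pdb_path),
                             chain_pair=cids)
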