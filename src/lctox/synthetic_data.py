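"""Synthetic light-chain repertoires with known ground truth.

Every other module is testable offline through this generator: it draws
labelled sequences from a small bundled set of synthetic germlines (the
names, e.g. ``SYNV1*01``, make the artificial origin explicit), applies
background somatic mutations at a uniform per-position rate, plants
class-discriminative mutations with known class-conditional probabilities,
and can emit a toy two-chain structure whose contact map is known by
construction.

Background substitutions are uniform over the 19 non-germline residues;
no hypermutation-hotspot or transition bias is modelled — the downstream
method only consumes amino-acid differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, DatasetRecord, GermlineRecord
from .germline_align import (label_universe, number_germline,
                             renumber_progressive)

logger = logging.getLogger(__name__)


def _kc_labels(length: int, insertions: Mapping[int, int]) -> tuple[str, ...]:
    """Kabat-Chothia labels 1..N with ``insertions[num]`` lettered inserts after num."""
    labels: list[str] = []
    num = 1
    while len(labels) < length:
        labels.append(str(num))
        for k in range(insertions.get(num, 0)):
            if len(labels) < length:
                labels.append(f"{num}{chr(ord('A') + k)}")
        num += 1
    return tuple(labels[:length])


def _germline(gid: str, seq: str, insertions: Mapping[int, int]) -> GermlineRecord:
    return GermlineRecord(gid, seq, _kc_labels(len(seq), insertions))


# Hand-written synthetic lambda-like V+J germlines (~108 residues each);
# two carry CDR insertion labels so progressive renumbering is exercised.
TOY_GERMLINES: tuple[GermlineRecord, ...] = (
    _germline(
        "SYNV1*01-SYNJ1*01",
        "SYVLTQPPSVSVAPGQTARITCGGNNIGSKSVHWYQQKPGQAPVLVVYDDSDRPSGIPERFSGSNSGNTATLTISRVEAGDEADYYCQVWDSSSDHVVFGGGTKLTVL",
        {},
    ),
    _germline(
        "SYNV2*01-SYNJ2*01",
        "QSVLTQPPSASGTPGQRVTISCSGSSSNIGSNTVNWYQQLPGTAPKLLIYSNNQRPSGVPDRFSGSKSGTSASLAISGLQSEDEADYYCAAWDDSLNGVVFGGGTQLTVL",
        {30: 2},
    ),
    _germline(
        "SYNV3*01-SYNJ1*01",
        "SSELTQDPAVSVALGQTVRITCQGDSLRSYYASWYQQKPGQAPVLVIYGKNNRPSGIPDRFSGSSSGNTASLTITGAQAEDEADYYCNSRDSSGNHVVFGGGTKLTVL",
        {95: 1},
    ),
)


@dataclass(frozen=True)
class PlantedEffect:
    """One class-discriminative somatic mutation: (position, aa) with
    per-class probabilities of being present."""

    position: int
    amino_acid: str
    p_tox: float
    p_nox: float


@dataclass(frozen=True)
class PlantedPairEffect:
    """A planted token pair at two positions, e.g. ``A-X`` plants alanine at
    the first position and restores the germline residue at the second."""

    positions: tuple[int, int]
    token_pair: str
    p_tox: float
    p_nox: float


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic repertoire; generation is a pure
    function of this object (the seed included).

    Defaults mirror the scale of the training collection the method was
    developed on: 428 toxic and 647 non-toxic sequences with a background
    somatic-mutation rate of 0.03 per position (roughly 3 substitutions
    per ~110-residue variable domain).
    """

    germline_set: tuple[GermlineRecord, ...] = TOY_GERMLINES
    n_tox: int = 428
    n_nox: int = 647
    background_sm_rate: float = 0.03
    planted_effects: tuple[PlantedEffect, ...] = ()
    pair_effects: tuple[PlantedPairEffect, ...] = ()
    germline_usage_skew: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_sm_rate <= 1:
            raise ValueError("background_sm_rate must be in [0, 1]")
        for e in self.planted_effects:
            if not (0 <= e.p_tox <= 1 and 0 <= e.p_nox <= 1):
                raise ValueError("effect probabilities must be in [0, 1]")


def toy_scheme(germlines: Sequence[GermlineRecord] = TOY_GERMLINES
               ) -> dict[str, int]:
    """The progressive scheme of the bundled germline set."""
    return renumber_progressive(
        label_universe({g.germline_id: g for g in germlines}))


def generate_repertoire(spec: SimSpec
                        ) -> tuple[list[DatasetRecord], pd.DataFrame]:
    """Draw a labelled repertoire; returns records plus the ground-truth table.

    Per sequence: a germline is drawn from the class-conditional usage
    distribution, background substitutions hit each position independently,
    then planted effects fire with their class probability (overriding the
    background).  The truth table lists every planted effect.
    """
    rng = np.random.default_rng(spec.seed)
    germlines = {g.germline_id: g for g in spec.germline_set}
    scheme = toy_scheme(spec.germline_set)
    numbered = {gid: number_germline(g, scheme) for gid, g in germlines.items()}

    for e in spec.planted_effects:
        for gid, ng in numbered.items():
            if ng.residue_by_position.get(e.position) == e.amino_acid:
                raise ValueError(
                    f"planted residue {e.amino_acid} at position {e.position} "
                    f"equals the germline residue of {gid}"
                )

    gids = sorted(germlines)
    records: list[DatasetRecord] = []
    for label, n in (("tox", spec.n_tox), ("nox", spec.n_nox)):
        usage = None
        if spec.germline_usage_skew is not None:
            usage = np.asarray(spec.germline_usage_skew[label], dtype=float)
            usage = usage / usage.sum()
        for i in range(n):
            gid = gids[int(rng.choice(len(gids), p=usage))]
            base = numbered[gid].residue_by_position
            residues = dict(base)
            for pos in sorted(residues):
                if rng.random() < spec.background_sm_rate:
                    others = [a for a in AMINO_ACIDS if a != base[pos]]
                    residues[pos] = others[int(rng.integers(len(others)))]
            p_attr = "p_tox" if label == "tox" else "p_nox"
            for e in spec.planted_effects:
                if rng.random() < getattr(e, p_attr) and e.position in residues:
                    residues[e.position] = e.amino_acid
            for pe in spec.pair_effects:
                fire = rng.random() < getattr(pe, p_attr)
                if fire and all(p in residues for p in pe.positions):
                    for pos, tok in zip(pe.positions, pe.token_pair.split("-")):
                        residues[pos] = base[pos] if tok == "X" else tok
            seq = "".join(residues[p] for p in sorted(residues))
            records.append(DatasetRecord(f"{label}{i:05d}", seq, gid, label))

    truth = pd.DataFrame(
        [{"kind": "amp", "positions": str(e.position), "tokens": e.amino_acid,
          "p_tox": e.p_tox, "p_nox": e.p_nox} for e in spec.planted_effects]
        + [{"kind": "pair", "positions": f"{pe.positions[0]}-{pe.positions[1]}",
            "tokens": pe.token_pair, "p_tox": pe.p_tox, "p_nox": pe.p_nox}
           for pe in spec.pair_effects],
        columns=["kind", "positions", "tokens", "p_tox", "p_nox"])
    logger.info("generated %d tox / %d nox sequences (seed %d)",
                spec.n_tox, spec.n_nox, spec.seed)
    return records, truth


# ---------------------------------------------------------------------------
# toy structure

_PDB_ATOM = ("ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{resseq:4d}"
             "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {elem:>2s}\n")


def generate_toy_structure(positions: Sequence[int],
                           interface_positions: Sequence[int] = (),
                           monomer_pairs: Sequence[tuple[int, int]] = (),
                           chain_ids: tuple[str, str] = ("A", "B"),
                           ) -> tuple[str, dict[tuple[str, int], int]]:
    """A two-chain PDB text whose contact map is known by construction.

    Designated interface positions sit < 7.5 Å across chains (each facing
    its own symmetric mate), designated monomer pairs sit < 7.5 Å within
    each chain, and every other residue pair is kept > 9 Å apart; the
    residue numbers double as scheme positions.  Raises when the requested
    geometry cannot be realised under the layout used here.
    """
    positions = sorted(positions)
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    if not set(interface_positions) <= set(positions):
        raise ValueError("interface positions must be among positions")
    for i, j in monomer_pairs:
        if i not in positions or j not in positions:
            raise ValueError(f"monomer pair ({i},{j}) outside positions")

    idx = {p: k for k, p in enumerate(positions)}
    coords = {cid: {} for cid in chain_ids}
    for p, k in idx.items():
        coords[chain_ids[0]][p] = np.array([10.0 * k, 0.0, 0.0])
        coords[chain_ids[1]][p] = np.array([10.0 * k, 0.0, 20.0])
    for i, j in monomer_pairs:
        for cid in chain_ids:
            coords[cid][j] = coords[cid][i] + np.array([0.0, 6.0, 0.0])
    for p in interface_positions:
        coords[chain_ids[1]][p][2] = coords[chain_ids[0]][p][2] + 5.0

    # feasibility: designated pairs close, all others comfortably apart
    wanted_mono = {tuple(sorted(pr)) for pr in monomer_pairs}
    wanted_dim = {(p, p) for p in interface_positions}
    for c1 in chain_ids:
        for c2 in chain_ids:
            if c1 > c2:
                continue
            for p in positions:
                for q in positions:
                    if c1 == c2 and q <= p:
                        continue
                    d = float(np.linalg.norm(coords[c1][p] - coords[c2][q]))
                    pair = tuple(sorted((p, q)))
                    wanted = (pair in wanted_mono) if c1 == c2 else (pair in wanted_dim)
                    if wanted and d >= 7.5:
                        raise ValueError(f"cannot place pair {pair} in contact")
                    if not wanted and d <= 9.0:
                        raise ValueError(
                            f"geometric infeasibility: undesignated pair {pair} "
                            f"({c1}/{c2}) at {d:.1f} A")

    lines = []
    serial = 1
    for cid in chain_ids:
        for p in positions:
            x, y, z = coords[cid][p]
            lines.append(_PDB_ATOM.format(serial=serial, name="CA", alt=" ",
                                          res="ALA", chain=cid, resseq=p,
                                          icode=" ", x=x, y=y, z=z + 0.5,
                                          occ=1.0, b=0.0, elem="C"))
            serial += 1
            lines.append(_PDB_ATOM.format(serial=serial, name="CB", alt=" ",
                                          res="ALA", chain=cid, resseq=p,
                                          icode=" ", x=x, y=y, z=z,
                                          occ=1.0, b=0.0, elem="C"))
            serial += 1
        lines.append(f"TER   {serial:5d}      ALA {cid}{positions[-1]:4d}\n")
        serial += 1
    lines.append("END\n")
    scheme_map = {(cid, p): p for cid in chain_ids for p in positions}
    return "".join(lines), scheme_map
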