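"""Categorical feature families from somatic-mutation encodings.

Three families describe each light chain:

* AMP — the amino acid at each mutated position (``X`` when unmutated),
  one column per scheme position;
* MAP — token pairs at monomeric structural contacts;
* DAP — token pairs at dimeric (interface) contacts;

plus an optional single GLVJ column holding the germline VJ rearrangement.
All values stay categorical strings; one-hot expansion happens only inside
the ML harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import MISSING
from .germline_align import SMutEncoding
from .structure_contacts import ContactMap

logger = logging.getLogger(__name__)

FAMILIES = ("AMP", "MAP", "DAP", "GLVJ")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature column (or a one-hot level of it, when ``token`` is set).

    Column-level descriptors name the attribute (``AMP:49``,
    ``MAP:56-59``); value-level descriptors name a (position, token)
    combination in the field's style: ``49-A`` for a mutation to alanine at
    position 49, ``56X-59X`` for an unmutated contact pair.
    """

    family: str
    positions: tuple[int, ...]
    name: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        want = {"AMP": 1, "MAP": 2, "DAP": 2, "GLVJ": 0}[self.family]
        if len(self.positions) != want:
            raise ValueError(f"{self.family} descriptor needs {want} positions")


def amp_descriptor(position: int) -> FeatureDescriptor:
    return FeatureDescriptor("AMP", (position,), f"AMP:{position}")


def pair_descriptor(family: str, i: int, j: int) -> FeatureDescriptor:
    return FeatureDescriptor(family, (i, j), f"{family}:{i}-{j}")


def value_level_name(desc: FeatureDescriptor, value: str) -> str:
    """Canonical name of one categorical level, e.g. ``49-A`` or ``56X-59X``."""
    if desc.family == "AMP":
        return f"{desc.positions[0]}-{value}"
    if desc.family in ("MAP", "DAP"):
        ti, tj = value.split("-")
        return f"{desc.positions[0]}{ti}-{desc.positions[1]}{tj}"
    return value  # GLVJ: the rearrangement string is the level name


@dataclass
class FeatureMatrix:
    """Labelled categorical design matrix: rows = sequences, columns = features."""

    data: pd.DataFrame
    labels: pd.Series
    descriptors: dict[str, FeatureDescriptor]

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels indices differ")
        missing = [c for c in self.data.columns if c not in self.descriptors]
        if missing:
            raise ValueError(f"columns without descriptors: {missing}")

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.data.columns:
            fam = self.descriptors[c].family
            if fam not in seen:
                seen.append(fam)
        return tuple(seen)

    def training_view(self) -> "FeatureMatrix":
        """Rows with a known phenotype (label ``unknown`` excluded)."""
        keep = self.labels.isin(["tox", "nox"])
        return FeatureMatrix(self.data.loc[keep], self.labels.loc[keep],
                             self.descriptors)

    def select_families(self, families: Sequence[str]) -> "FeatureMatrix":
        cols = [c for c in self.data.columns
                if self.descriptors[c].family in families]
        if not cols:
            raise ValueError(f"no columns for families {families}")
        return FeatureMatrix(self.data[cols], self.labels,
                             {c: self.descriptors[c] for c in cols})


def extract_amp(encoding: SMutEncoding, position_universe: Iterable[int]
                ) -> dict[int, str]:
    """AMP row: the somatic-mutation token at every scheme position."""
    tokens = encoding.token_by_position
    stray = set(tokens) - set(position_universe)
    if stray:
        raise ValueError(f"encoding positions outside the universe: {sorted(stray)}")
    return {pos: tokens.get(pos, MISSING) for pos in position_universe}


def extract_pair_family(encoding: SMutEncoding,
                        pair_set: Iterable[tuple[int, int]]) -> dict[tuple[int, int], str]:
    """MAP/DAP row: joined token pair ``t_i-t_j`` for each contact pair (i < j)."""
    tokens = encoding.token_by_position
    out = {}
    for i, j in pair_set:
        out[(i, j)] = f"{tokens.get(i, MISSING)}-{tokens.get(j, MISSING)}"
    return out


def assemble_matrix(encodings: Sequence[SMutEncoding],
                    families_selected: Sequence[str],
                    contact_map: ContactMap | None = None,
                    germline_ids: Mapping[str, str] | None = None,
                    labels: Mapping[str, str] | None = None,
                    position_universe: Sequence[int] | None = None) -> FeatureMatrix:
    """Assemble the labelled categorical design matrix, one block per family.

    Column order is stable: AMP by position, MAP then DAP by sorted pair,
    GLVJ last.  Label ``unknown`` rows are kept (callers training a model
    use :meth:`FeatureMatrix.training_view`).
    """
    families_selected = list(families_selected)
    if not families_selected or any(f not in FAMILIES for f in families_selected):
        raise ValueError(f"families must be a non-empty subset of {FAMILIES}")
    if {"MAP", "DAP"} & set(families_selected) and contact_map is None:
        raise ValueError("MAP/DAP features need a contact map")
    if position_universe is None:
        position_universe = sorted({p for e in encodings for p in e.token_by_position})

    ids = [e.sequence_id for e in encodings]
    columns: dict[str, list[str]] = {}
    descriptors: dict[str, FeatureDescriptor] = {}

    def add_block(names_descs, rows):
        for (name, desc), values in zip(names_descs, zip(*rows)) if rows else ():
            columns[name] = list(values)
            descriptors[name] = desc

    if "AMP" in families_selected:
        descs = [(amp_descriptor(p).name, amp_descriptor(p)) for p in position_universe]
        rows = [[extract_amp(e, position_universe)[p] for p in position_universe]
                for e in encodings]
        add_block(descs, rows)
    for fam, pair_attr in (("MAP", "monomeric_pairs"), ("DAP", "dimeric_pairs")):
        if fam in families_selected:
            pairs = sorted(getattr(contact_map, pair_attr))
            descs = [(pair_descriptor(fam, i, j).name, pair_descriptor(fam, i, j))
                     for i, j in pairs]
            rows = [[extract_pair_family(e, pairs)[p] for p in pairs]
                    for e in encodings]
            add_block(descs, rows)
    if "GLVJ" in families_selected:
        if germline_ids is None:
            germline_ids = {e.sequence_id: e.germline_id for e in encodings}
        desc = FeatureDescriptor("GLVJ", (), "GLVJ")
        columns["GLVJ"] = [germline_ids[i] for i in ids]
        descriptors["GLVJ"] = desc

    data = pd.DataFrame(columns, index=pd.Index(ids, name="sequence_id"))
    if labels is None:
        labels = {}
    label_series = pd.Series([labels.get(i, "unknown") for i in ids],
                             index=data.index, name="label")
    logger.info("assembled feature matrix: %d rows x %d columns (%s)",
                len(data), data.shape[1], "+".join(families_selected))
    return FeatureMatrix(data, label_series, descriptors)
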