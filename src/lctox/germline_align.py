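"""Germline alignment, Kabat-Chothia numbering transfer and S_mut encoding.

A mature light chain (LC) is aligned globally to its germline precursor,
each LC residue inherits a Kabat-Chothia label from the aligned germline
residue (insertions get the preceding label plus the next insertion
letter), labels are renumbered progressively to contiguous integer scheme
positions, and finally the LC is encoded position-by-position as its
somatic-mutation difference from the germline: ``X`` where identical, the
LC residue where mutated, and a missing token where the LC does not cover
a germline position.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np

from .io_formats import MISSING, GermlineRecord, kabat_key

logger = logging.getLogger(__name__)

#: default linear-gap scoring: (match, mismatch, gap)
DEFAULT_SCORING = (1, -1, -2)


@dataclass(frozen=True)
class AlignedPair:
    """A global LC-vs-germline alignment; ``-`` marks gaps."""

    lc_aligned: str
    gl_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.lc_aligned) != len(self.gl_aligned):
            raise ValueError("aligned rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.lc_aligned, self.gl_aligned)):
            raise ValueError("alignment column with gaps in both rows")


@dataclass(frozen=True)
class NumberedSequence:
    """An LC's residues mapped onto integer scheme positions."""

    sequence_id: str
    residue_by_position: Mapping[int, str]
    germline_id: str

    @property
    def coverage(self) -> frozenset[int]:
        return frozenset(self.residue_by_position)


@dataclass(frozen=True)
class SMutEncoding:
    """Per-position somatic-mutation tokens for one LC.

    Token semantics: ``X`` = identical to germline, an amino acid = the
    somatically mutated residue, :data:`~lctox.io_formats.MISSING` = the
    germline covers the position but the LC does not.
    """

    sequence_id: str
    token_by_position: Mapping[int, str]
    germline_id: str

    @cached_property
    def n_sm(self) -> int:
        return sum(1 for t in self.token_by_position.values()
                   if t != "X" and t != MISSING)

    def sm_positions(self) -> list[int]:
        """Scheme positions carrying a somatic mutation, ascending."""
        return sorted(p for p, t in self.token_by_position.items()
                      if t != "X" and t != MISSING)


# ---------------------------------------------------------------------------
# global alignment

def _nw_matrix_python(a: np.ndarray, b: np.ndarray, match: int,
                      mismatch: int, gap: int) -> np.ndarray:
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    for i in range(n + 1):
        H[i, 0] = i * gap
    for j in range(m + 1):
        H[0, j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            if up > best:
                best = up
            left = H[i, j - 1] + gap
            if left > best:
                best = left
            H[i, j] = best
    return H


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _nw_matrix = njit(cache=True)(_nw_matrix_python)
except ImportError:  # pragma: no cover
    _nw_matrix = _nw_matrix_python


def global_align(lc_seq: str, gl_seq: str,
                 scoring: tuple[int, int, int] = DEFAULT_SCORING) -> AlignedPair:
    """Optimal Needleman-Wunsch global alignment with linear gap penalties.

    Traceback ties are broken deterministically: a match/mismatch step is
    preferred over a gap in the LC row, which is preferred over a gap in
    the germline row.
    """
    if not lc_seq or not gl_seq:
        raise ValueError("global_align requires two non-empty sequences")
    match, mismatch, gap = scoring
    a = np.frombuffer(lc_seq.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(gl_seq.encode("ascii"), dtype=np.uint8)
    H = _nw_matrix(a, b, match, mismatch, gap)

    lc_row: list[str] = []
    gl_row: list[str] = []
    i, j = len(lc_seq), len(gl_seq)
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if lc_seq[i - 1] == gl_seq[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                lc_row.append(lc_seq[i - 1])
                gl_row.append(gl_seq[j - 1])
                i -= 1
                j -= 1
                continue
        # gap in the LC row (germline residue unmatched)
        if j > 0 and H[i, j] == H[i, j - 1] + gap:
            lc_row.append("-")
            gl_row.append(gl_seq[j - 1])
            j -= 1
            continue
        # gap in the germline row (LC insertion)
        lc_row.append(lc_seq[i - 1])
        gl_row.append("-")
        i -= 1
    return AlignedPair("".join(reversed(lc_row)), "".join(reversed(gl_row)),
                       float(H[len(lc_seq), len(gl_seq)]))


# ---------------------------------------------------------------------------
# numbering

def transfer_numbering(pair: AlignedPair, germline: GermlineRecord) -> list[str]:
    """Kabat-Chothia labels for the LC residues of a global alignment.

    LC residues aligned to a germline residue inherit its label; residues in
    insertion columns get the preceding label with the next insertion letter;
    germline-only columns produce no LC label.
    """
    if pair.gl_aligned.replace("-", "") != germline.sequence:
        raise ValueError("germline row of alignment does not match germline record")
    labels: list[str] = []
    gi = 0
    last_label: str | None = None
    for lc_c, gl_c in zip(pair.lc_aligned, pair.gl_aligned):
        if gl_c != "-":
            last_label = germline.kc_labels[gi]
            gi += 1
            if lc_c != "-":
                labels.append(last_label)
        else:
            if last_label is None:
                raise ValueError("LC insertion before the first germline residue")
            num, ins = kabat_key(last_label)
            if ins == "Z":
                raise ValueError(f"insertion letters exhausted after label {last_label!r}")
            nxt = "A" if not ins else string.ascii_uppercase[
                string.ascii_uppercase.index(ins) + 1]
            last_label = f"{num}{nxt}"
            labels.append(last_label)
    return labels


def renumber_progressive(kc_labels_universe: Sequence[str]) -> dict[str, int]:
    """Bijective, Kabat-order-preserving map from labels to positions 1..N.

    E.g. a universe containing 30, 30A..30F, 31 maps the insertions onto
    the integers directly after 30's position, shifting everything later.
    """
    keys = [kabat_key(l) for l in kc_labels_universe]
    if len(set(keys)) != len(keys):
        seen: set[tuple[int, str]] = set()
        dupes = [lab for lab, k in zip(kc_labels_universe, keys)
                 if k in seen or seen.add(k)]
        raise ValueError(f"duplicate labels in universe: {dupes}")
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    return {kc_labels_universe[i]: rank + 1 for rank, i in enumerate(order)}


def label_universe(germlines: Mapping[str, GermlineRecord],
                   extra_labels: Sequence[str] = ()) -> list[str]:
    """Sorted union of Kabat-Chothia labels across germlines plus dataset insertions."""
    labels = {l for g in germlines.values() for l in g.kc_labels}
    labels.update(extra_labels)
    return sorted(labels, key=kabat_key)


def number_sequence(sequence_id: str, sequence: str, germline: GermlineRecord,
                    scheme: Mapping[str, int],
                    scoring: tuple[int, int, int] = DEFAULT_SCORING) -> NumberedSequence:
    """Align an LC to its germline and place residues on scheme positions."""
    pair = global_align(sequence, germline.sequence, scoring)
    kc = transfer_numbering(pair, germline)
    residues = pair.lc_aligned.replace("-", "")
    by_pos: dict[int, str] = {}
    for res, lab in zip(residues, kc):
        if lab not in scheme:
            raise KeyError(
                f"{sequence_id!r}: Kabat-Chothia label {lab!r} absent from the "
                "progressive scheme; rebuild the scheme with dataset insertions"
            )
        by_pos[scheme[lab]] = res
    return NumberedSequence(sequence_id, by_pos, germline.germline_id)


def number_germline(germline: GermlineRecord,
                    scheme: Mapping[str, int]) -> NumberedSequence:
    by_pos = {scheme[lab]: res for res, lab in zip(germline.sequence, germline.kc_labels)}
    return NumberedSequence(germline.germline_id, by_pos, germline.germline_id)


# ---------------------------------------------------------------------------
# encoding

def encode_smut(lc: NumberedSequence, gl: NumberedSequence) -> SMutEncoding:
    """Encode an LC as its somatic-mutation difference from the germline.

    Germline positions absent from the LC become the missing token; an LC
    position absent from the germline flags a numbering inconsistency.
    """
    stray = lc.coverage - gl.coverage
    if stray:
        raise ValueError(
            f"{lc.sequence_id!r} covers positions absent from germline "
            f"{gl.sequence_id!r}: {sorted(stray)}"
        )
    tokens: dict[int, str] = {}
    for pos in sorted(gl.residue_by_position):
        lc_res = lc.residue_by_position.get(pos)
        if lc_res is None:
            tokens[pos] = MISSING
        elif lc_res == gl.residue_by_position[pos]:
            tokens[pos] = "X"
        else:
            tokens[pos] = lc_res
    return SMutEncoding(lc.sequence_id, tokens, gl.sequence_id)


def decode_smut(encoding: SMutEncoding, gl: NumberedSequence) -> dict[int, str]:
    """Reconstruct the LC's residues over covered positions from its encoding."""
    out: dict[int, str] = {}
    for pos, tok in encoding.token_by_position.items():
        if tok == MISSING:
            continue
        out[pos] = gl.residue_by_position[pos] if tok == "X" else tok
    return out


def encode_dataset(records, germlines: Mapping[str, GermlineRecord],
                   scheme: Mapping[str, int] | None = None
                   ) -> tuple[list[SMutEncoding], dict[str, int]]:
    """Number and encode a whole dataset against its germline reference.

    Returns the encodings plus the progressive scheme used.  When no scheme
    is given it is derived from the germline label universe, extended with
    any insertion labels the dataset introduces.
    """
    if scheme is None:
        extra: set[str] = set()
        for rec in records:
            gl = germlines[rec.germline_id]
            pair = global_align(rec.sequence, gl.sequence)
            extra.update(transfer_numbering(pair, gl))
        scheme = renumber_progressive(label_universe(germlines, sorted(extra)))
    numbered_gl = {gid: number_germline(g, scheme) for gid, g in germlines.items()}
    encodings = []
    for rec in records:
        lc = number_sequence(rec.sequence_id, rec.sequence,
                             germlines[rec.germline_id], scheme)
        encodings.append(encode_smut(lc, numbered_gl[rec.germline_id]))
        logger.debug("encoded %s: %d somatic mutations", rec.sequence_id,
                     encodings[-1].n_sm)
    logger.info("encoded %d sequences over %d scheme positions",
                len(encodings), len(scheme))
    return encodings, dict(scheme)
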