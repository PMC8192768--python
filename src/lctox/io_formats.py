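"""Readers and writers for on-disk artifacts.

All other modules consume the in-memory types produced here.  File formats
are deliberately plain text: FASTA for sequences, tab-separated tables for
labels and Kabat-Chothia sidecars, JSON for contact maps and reversion
plans.  Coordinates in files are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: the 20 standard one-letter amino-acid codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: token used for positions covered by the germline but not the light chain
MISSING = "."

#: allowed phenotype labels
VALID_LABELS = ("tox", "nox", "unknown")


@dataclass(frozen=True)
class DatasetRecord:
    """One light chain: sequence, its germline assignment and phenotype label."""

    sequence_id: str
    sequence: str
    germline_id: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"invalid label {self.label!r} for {self.sequence_id!r}; "
                f"expected one of {VALID_LABELS}"
            )
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in AMINO_ACIDS]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"sequence {self.sequence_id!r} contains non-standard residue "
                f"{char!r} at position {pos}"
            )


@dataclass(frozen=True)
class GermlineRecord:
    """An unmutated V+J germline sequence with per-residue Kabat-Chothia labels."""

    germline_id: str
    sequence: str
    kc_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.kc_labels) != len(self.sequence):
            raise ValueError(
                f"germline {self.germline_id!r}: {len(self.kc_labels)} labels "
                f"for {len(self.sequence)} residues"
            )
        keys = [kabat_key(l) for l in self.kc_labels]
        for a, b in zip(keys, keys[1:]):
            if not a < b:
                raise ValueError(
                    f"germline {self.germline_id!r}: Kabat-Chothia labels not "
                    f"strictly increasing around {self.kc_labels[keys.index(b)]!r}"
                )


def kabat_key(label: str) -> tuple[int, str]:
    """Sort key for a Kabat-Chothia label: numeric part, then insertion letter."""
    num = label.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    ins = label[len(num):]
    if not num.isdigit() or len(ins) > 1:
        raise ValueError(f"malformed Kabat-Chothia label {label!r}")
    return int(num), ins


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Sequences are upper-cased and validated against the 20 standard codes;
    gap characters and empty records are rejected with the record index.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        idx = len(records) + 1
        if not header:
            raise ValueError(f"FASTA record {idx}: empty header")
        if not seq:
            raise ValueError(f"FASTA record {idx} ({header!r}): empty sequence")
        for i, c in enumerate(seq):
            if c not in AMINO_ACIDS:
                raise ValueError(
                    f"FASTA record {idx} ({header!r}): invalid character "
                    f"{c!r} at position {i + 1}"
                )
        records.append((header, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError("FASTA parse error: sequence data before first header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# labels and germline reference

def read_labels(path) -> dict[str, tuple[str, str | None]]:
    """Read the 2- or 3-column label table.

    Columns: sequence_id, label, and optionally germline_id.  Returns
    ``{sequence_id: (label, germline_id_or_None)}``.
    """
    out: dict[str, tuple[str, str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
            sid, label = parts[0], parts[1]
            gl = parts[2] if len(parts) == 3 else None
            if label not in VALID_LABELS:
                raise ValueError(
                    f"{path}:{lineno}: unknown label token {label!r} "
                    f"(expected one of {VALID_LABELS})"
                )
            if sid in out:
                raise ValueError(f"{path}:{lineno}: duplicate sequence_id {sid!r}")
            out[sid] = (label, gl)
    return out


def read_germline_reference(fasta_path, kc_path) -> dict[str, GermlineRecord]:
    """Load germline sequences plus their Kabat-Chothia sidecar table.

    The sidecar is a 3-column TSV: germline_id, residue_index (1-based),
    kc_label.
    """
    seqs = dict(read_fasta(fasta_path))
    labels: dict[str, dict[int, str]] = {}
    with open(kc_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{kc_path}:{lineno}: expected 3 columns")
            gid, idx, lab = parts
            labels.setdefault(gid, {})[int(idx)] = lab
    out: dict[str, GermlineRecord] = {}
    for gid, seq in seqs.items():
        if gid not in labels:
            raise ValueError(f"germline {gid!r} has no Kabat-Chothia labels in {kc_path}")
        by_idx = labels[gid]
        if sorted(by_idx) != list(range(1, len(seq) + 1)):
            raise ValueError(f"germline {gid!r}: label indices do not cover 1..{len(seq)}")
        out[gid] = GermlineRecord(gid, seq, tuple(by_idx[i] for i in range(1, len(seq) + 1)))
    extra = set(labels) - set(seqs)
    if extra:
        raise ValueError(f"Kabat-Chothia labels for unknown germlines: {sorted(extra)}")
    return out


def write_germline_reference(germlines: Mapping[str, GermlineRecord],
                             fasta_path, kc_path) -> None:
    write_fasta([(g.germline_id, g.sequence) for g in germlines.values()], fasta_path)
    with open(kc_path, "w") as fh:
        for g in germlines.values():
            for i, lab in enumerate(g.kc_labels, 1):
                fh.write(f"{g.germline_id}\t{i}\t{lab}\n")


def read_dataset(fasta_path, labels_path, germline_fasta, germline_kc
                 ) -> tuple[list[DatasetRecord], dict[str, GermlineRecord]]:
    """Join the sequence FASTA with the label table and germline reference.

    Every labelled id must exist in the FASTA.  A missing germline_id column
    triggers nearest-identity assignment against the reference (logged).
    """
    germlines = read_germline_reference(germline_fasta, germline_kc)
    seqs = read_fasta(fasta_path)
    seq_ids = [sid for sid, _ in seqs]
    if len(set(seq_ids)) != len(seq_ids):
        dupes = sorted({s for s in seq_ids if seq_ids.count(s) > 1})
        raise ValueError(f"duplicate sequence ids in {fasta_path}: {dupes}")
    labels = read_labels(labels_path)
    dangling = sorted(set(labels) - set(seq_ids))
    if dangling:
        raise ValueError(f"label rows reference ids absent from FASTA: {dangling}")
    records: list[DatasetRecord] = []
    for sid, seq in seqs:
        if sid not in labels:
            raise ValueError(f"sequence {sid!r} has no label row")
        label, gid = labels[sid]
        if gid is None:
            gid = assign_germline(seq, germlines)
            logger.info("assigned germline %s to %s by nearest identity", gid, sid)
        elif gid not in germlines:
            raise ValueError(f"sequence {sid!r}: germline {gid!r} not in reference")
        records.append(DatasetRecord(sid, seq, gid, label))
    logger.info("read dataset: %d sequences, %d germlines", len(records), len(germlines))
    return records, germlines


def assign_germline(sequence: str, germlines: Mapping[str, GermlineRecord]) -> str:
    """Nearest-identity germline assignment (explicit fallback, logged upstream)."""
    from .germline_align import global_align

    best_id, best_score = None, None
    for gid in sorted(germlines):
        score = global_align(sequence, germlines[gid].sequence).score
        if best_score is None or score > best_score:
            best_id, best_score = gid, score
    assert best_id is not None
    return best_id


# ---------------------------------------------------------------------------
# contact maps

def write_contact_map_json(cmap, path) -> None:
    payload = {
        "structure_id": cmap.structure_id,
        "chain_pair": list(cmap.chain_pair),
        "threshold": cmap.threshold_angstrom,
        "monomeric": sorted(map(list, cmap.monomeric_pairs)),
        "dimeric": sorted(map(list, cmap.dimeric_pairs)),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_contact_map_json(path):
    from .structure_contacts import ContactMap

    with open(path) as fh:
        d = json.load(fh)
    return ContactMap(
        monomeric_pairs=frozenset(tuple(p) for p in d["monomeric"]),
        dimeric_pairs=frozenset(tuple(p) for p in d["dimeric"]),
        threshold_angstrom=float(d["threshold"]),
        structure_id=d["structure_id"],
        chain_pair=tuple(d["chain_pair"]),
    )


# ---------------------------------------------------------------------------
# experiment reports

#: column order for the per-experiment report table
REPORT_COLUMNS = [
    "families", "algorithm", "smote", "folds", "seed",
    "auc", "sensitivity", "specificity", "accuracy", "balanced_accuracy", "f1",
    "tp", "fp", "tn", "fn",
    "youden_threshold", "youden_j", "youden_se", "youden_sp",
]


def reports_to_frame(reports: Sequence) -> pd.DataFrame:
    rows = []
    for r in reports:
        c = r.config
        yt, yj, yse, ysp = r.youden
        tp, fp, tn, fn = r.confusion
        rows.append({
            "families": "+".join(c.families), "algorithm": c.algorithm,
            "smote": c.smote, "folds": c.folds, "seed": c.seed,
            "auc": r.auc, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "accuracy": r.accuracy,
            "balanced_accuracy": r.balanced_accuracy, "f1": r.f1,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "youden_threshold": yt, "youden_j": yj, "youden_se": yse, "youden_sp": ysp,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(reports: Sequence, path) -> None:
    """Write one TSV row per experiment configuration, deterministic column order."""
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG = {
    "contact_threshold": 7.5,
    "info_gain_cutoff": 0.01,
    "cv_folds": 10,
    "smote": False,
    "classifier": "random_forest",
}


def load_config(path=None) -> dict:
    """Key-value YAML config; missing keys fall back to defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None and Path(path).exists():
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg.update(user)
    return cfg
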