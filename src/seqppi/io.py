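"""Readers and writers for the formats the pipeline touches.

FASTA proteomes, tab-separated pair tables, and self-describing TSV
feature matrices.  Parsing is strict: unresolved identifiers, duplicate
ids, non-binary labels and malformed records raise ``ValueError`` with a
message naming the offender, so problems surface at the boundary rather
than deep inside an encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: substitutions applied under the "map" non-standard residue policy
AMBIGUOUS_MAP = {"U": "C", "B": "D", "Z": "E"}

PAIR_COLUMNS = ("id_a", "id_b", "label")

_LABEL_ALIASES = {
    "1": 1,
    "0": 0,
    "interacting": 1,
    "non-interacting": 0,
    "noninteracting": 0,
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    ``sequence`` is uppercase and restricted to the 20 standard
    amino-acid letters after sanitization.
    """

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _sanitize(rec_id: str, seq: str, on_nonstandard: str) -> str | None:
    """Return the cleaned sequence, or None if the record is dropped."""
    seq = seq.upper()
    bad = sorted(set(seq) - STANDARD_AA)
    if not bad:
        return seq
    if on_nonstandard == "map":
        seq = "".join(AMBIGUOUS_MAP.get(c, c) for c in seq)
        bad = sorted(set(seq) - STANDARD_AA)
        if not bad:
            return seq
    warnings.warn(
        f"dropping record {rec_id!r}: non-standard residue(s) {''.join(bad)}",
        stacklevel=3,
    )
    return None


def read_fasta(path, on_nonstandard: str = "reject") -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into an id -> :class:`ProteinRecord` map.

    Parameters
    ----------
    path : path-like
        FASTA file, wrapped or unwrapped lines, one record per header.
    on_nonstandard : {"reject", "map"}
        Policy for residues outside the 20-letter alphabet.  "reject"
        drops the record with a warning.  "map" first substitutes
        U->C, B->D, Z->E and then drops records that still contain
        non-standard letters (e.g. X).
    """
    if on_nonstandard not in ("reject", "map"):
        raise ValueError(f"unknown non-standard residue policy {on_nonstandard!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if text_head and not text_head.startswith(">"):
        raise ValueError(f"malformed FASTA: first record line does not start with '>' in {path}")

    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        clean = _sanitize(rec.id, seq, on_nonstandard)
        if clean is not None:
            proteome[rec.id] = ProteinRecord(rec.id, clean)
    return proteome


def write_fasta(path, proteome: Mapping[str, ProteinRecord], width: int = 60) -> None:
    """Write an id -> record map to FASTA with fixed-width wrapping."""
    with open(path, "w") as fh:
        for rec in proteome.values():
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_pair_table(
    path,
    proteome: Mapping[str, ProteinRecord],
    require_label: bool = True,
) -> pd.DataFrame:
    """Read a tab-separated pair table (idA, idB, label).

    Lines starting with '#' and blank lines are ignored; row order is
    preserved.  Every id must resolve against ``proteome``; labels are
    parsed to {0, 1} ("interacting"/"non-interacting" accepted as
    aliases).  With ``require_label=False`` a 2-column table is
    accepted and the label column is filled with -1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair table not found: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2 and not require_label:
                id_a, id_b = fields
                label = -1
            elif len(fields) == 3:
                id_a, id_b, raw = fields
                raw = raw.strip().lower()
                if raw not in _LABEL_ALIASES:
                    raise ValueError(
                        f"{path}:{lineno}: non-binary label {fields[2]!r}"
                    )
                label = _LABEL_ALIASES[raw]
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            for pid in (id_a, id_b):
                if pid not in proteome:
                    raise ValueError(f"{path}:{lineno}: unknown protein id {pid!r}")
            rows.append((id_a, id_b, label))
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


def write_pair_table(path, pairs: pd.DataFrame) -> None:
    """Write a pair table as TSV (idA, idB, label), no header."""
    pairs.to_csv(path, sep="\t", header=False, index=False, columns=list(PAIR_COLUMNS))


def filter_min_length(
    proteome: Mapping[str, ProteinRecord],
    pairs: pd.DataFrame,
    min_length: int = 50,
) -> pd.DataFrame:
    """Drop pairs containing a protein shorter than ``min_length`` residues.

    This is the dataset-assembly length floor (50 residues by default);
    it is deliberately not applied at parse time.
    """
    keep = [
        len(proteome[a]) >= min_length and len(proteome[b]) >= min_length
        for a, b in zip(pairs["id_a"], pairs["id_b"])
    ]
    return pairs.loc[keep].reset_index(drop=True)


def write_feature_matrix(
    path,
    matrix: np.ndarray,
    row_ids: Sequence[str],
    layout: Sequence[tuple[str, int]],
) -> None:
    """Write a feature matrix as TSV with a self-describing header.

    The header records the named block layout (e.g. ``AC_A=180``) so a
    reader can recover which columns belong to which descriptor.  Values
    are written with 17 significant digits, enough to round-trip IEEE
    doubles exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if matrix.shape[0] != len(row_ids):
        raise ValueError(
            f"row count {matrix.shape[0]} does not match id count {len(row_ids)}"
        )
    width = sum(w for _, w in layout)
    if matrix.shape[0] > 0 and matrix.shape[1] != width:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but layout declares {width}"
        )
    with open(path, "w") as fh:
        fh.write("# seqppi feature matrix v1\n")
        fh.write("# blocks: " + " ".join(f"{n}={w}" for n, w in layout) + "\n")
        for rid, row in zip(row_ids, matrix):
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_feature_matrix(path) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Returns ``(matrix, row_ids, layout)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix not found: {path}")
    layout: list[tuple[str, int]] = []
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# blocks:"):
                    for tok in line[len("# blocks:") :].split():
                        name, w = tok.split("=")
                        layout.append((name, int(w)))
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    width = sum(w for _, w in layout)
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, width))
    return matrix, ids, layout
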