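"""Sequence encoding for the two network branches.

A guide sequence (default length ``l = 21``) is first mapped to its
Watson-Crick complement base-by-base (no reversal), then one-hot encoded
with the fixed column order ``(A, T, G, C)``:

    A -> [1,0,0,0]   T -> [0,1,0,0]   G -> [0,0,1,0]   C -> [0,0,0,1]

The resulting binary image ``X_oh`` (l x 4) feeds the spatial branch; a
trainable embedding table ``E_m`` (4 x m) turns it into the dense matrix
``X_e = X_oh @ E_m`` that feeds the temporal branch.  Because each row of
``X_oh`` is an indicator, the matrix product is exactly a per-position
row lookup into ``E_m`` -- both views are implemented and tested.

Positions are reported 1-based, 5'->3'.  ``U`` on input is normalized to
``T`` (guides are RNA; the model works in DNA letters).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidAlphabetError, LengthMismatchError, MalformedMatrixError

DEFAULT_LENGTH = 21

#: canonical column order of every l x 4 matrix in the package
BASES = "ATGC"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: column permutation that relabels a complement-space l x 4 matrix into
#: original-base space (A<->T, G<->C under the (A,T,G,C) column order)
COMPLEMENT_COLUMN_PERM = np.array([1, 0, 3, 2])


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate the alphabet.

    Raises :class:`InvalidAlphabetError` naming the first offending
    1-based position.
    """
    s = str(seq).strip().upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in BASE_INDEX:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} at position {i + 1} in sequence {seq!r}"
            )
    return s


def complement_sequence(seq: str) -> str:
    """Per-position Watson-Crick complement (A<->T, G<->C), no reversal."""
    s = normalize_sequence(seq)
    return "".join(COMPLEMENT[ch] for ch in s)


def one_hot_encode(seq: str, length: int = DEFAULT_LENGTH) -> np.ndarray:
    """Encode a guide as the l x 4 binary image of its complement.

    The complement convention is applied here, so callers pass original
    guide sequences throughout the package.
    """
    s = normalize_sequence(seq)
    if len(s) != length:
        raise LengthMismatchError(
            f"sequence length {len(s)} != configured model length {length}"
        )
    comp = complement_sequence(s)
    oh = np.zeros((length, 4), dtype=np.float64)
    for i, ch in enumerate(comp):
        oh[i, BASE_INDEX[ch]] = 1.0
    return oh


def one_hot_decode(oh: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`, returning the original guide."""
    oh = np.asarray(oh, dtype=np.float64)
    if oh.ndim != 2 or oh.shape[1] != 4:
        raise MalformedMatrixError(f"expected an l x 4 matrix, got shape {oh.shape}")
    if not np.all(np.isin(oh, (0.0, 1.0))):
        raise MalformedMatrixError("one-hot entries must be exactly 0 or 1")
    sums = oh.sum(axis=1)
    bad = np.nonzero(sums != 1.0)[0]
    if bad.size:
        raise MalformedMatrixError(f"row {bad[0] + 1} sums to {sums[bad[0]]}, expected 1")
    comp = "".join(BASES[j] for j in oh.argmax(axis=1))
    return "".join(COMPLEMENT[ch] for ch in comp)


def encode_batch(seqs, length: int = DEFAULT_LENGTH) -> np.ndarray:
    """Stack one-hot images for a sequence collection into (n, l, 4)."""
    return np.stack([one_hot_encode(s, length) for s in seqs])


def embed(oh: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Dense embedding ``X_e = X_oh @ E_m`` (equivalently row lookup)."""
    oh = np.asarray(oh, dtype=np.float64)
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] != 4:
        raise ValueError(f"embedding table must be 4 x m, got shape {table.shape}")
    if oh.shape[-1] != 4:
        raise ValueError(f"one-hot matrix must have 4 columns, got shape {oh.shape}")
    return oh @ table


# ---------------------------------------------------------------------------
# dataset I/O


def read_sequences(path: str | Path, length: int | None = None) -> pd.DataFrame:
    """Read guides from CSV/TSV (column ``sequence``, optional ``activity``)
    or FASTA (by extension: .fa/.fasta/.fna).  Sequences are normalized;
    activities, when present, are validated to lie in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        from Bio import SeqIO

        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        df = pd.DataFrame(records, columns=["id", "sequence"])
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        if "sequence" not in df.columns:
            raise ValueError(f"{path} has no 'sequence' column")
    df["sequence"] = df["sequence"].map(normalize_sequence)
    if length is not None:
        bad = df.index[df["sequence"].str.len() != length]
        if len(bad):
            raise LengthMismatchError(
                f"row {bad[0]} has length {len(df.loc[bad[0], 'sequence'])}, expected {length}"
            )
    if "activity" in df.columns:
        act = df["activity"].astype(float)
        if ((act < 0) | (act > 1)).any():
            raise ValueError("activity values must lie in [0, 1]")
        df["activity"] = act
    return df


def write_matrix_tsv(
    values: np.ndarray,
    path: str | Path,
    columns=tuple(BASES),
    index_name: str = "position",
) -> None:
    """Write a matrix as TSV with 1-based position index rows."""
    values = np.asarray(values)
    df = pd.DataFrame(values, columns=list(columns))
    df.insert(0, index_name, np.arange(1, values.shape[0] + 1))
    df.to_csv(path, sep="\t", index=False)
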