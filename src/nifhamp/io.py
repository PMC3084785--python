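"""Plain-text I/O: FASTA, TSV tables, Newick trees, alignment profiles.

All sequence files are uncompressed FASTA; wrapped input is accepted and
records are always written unwrapped (one sequence line per record) so that
re-runs are byte-comparable.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd


class FastaFormatError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(header, sequence), ...]``.

    Wrapped and unwrapped records are accepted.  Raises
    :class:`FastaFormatError` with a line number when sequence data precedes
    the first header or a record has an empty sequence.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise FastaFormatError(
                            f"{path}: record at line {header_line} has no sequence"
                        )
                    records.append((header, "".join(chunks)))
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
    if header is not None:
        if not chunks:
            raise FastaFormatError(
                f"{path}: record at line {header_line} has no sequence"
            )
        records.append((header, "".join(chunks)))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(header, sequence)`` pairs as unwrapped FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame, index: bool = True) -> None:
    """Write a DataFrame as TSV with a header row."""
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_newick(path: str | os.PathLike, tree) -> None:
    """Write a scikit-bio ``TreeNode`` as a Newick file with branch lengths."""
    tree.write(str(path), format="newick")
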