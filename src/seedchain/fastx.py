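"""FASTA reading/writing (multi-record, wrapped lines, optional gzip)."""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import InputError

__all__ = ["read_fasta", "write_fasta"]


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (record id up to first whitespace, uppercase sequence) pairs."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq).upper()
    except (OSError, ValueError) as exc:
        raise InputError(f"malformed FASTA {path}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
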