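"""PAF (Pairwise mApping Format) records: the 12 mandatory columns.

Lines are tab-separated and newline-terminated; query coordinates of
reverse-strand hits are reported on the original read orientation, as the
format requires.  A ``tp:A:P``/``tp:A:S`` tag flags primary vs secondary.
"""

from __future__ import annotations

import dataclasses

from .errors import InputError

__all__ = ["PafRecord", "parse_paf_line"]


@dataclasses.dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"bad query interval {self.qstart}-{self.qend} (len {self.qlen})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"bad target interval {self.tstart}-{self.tend} (len {self.tlen})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.mapq <= 60):
            raise ValueError(f"mapq out of range: {self.mapq}")

    @property
    def is_primary(self) -> bool:
        return "tp:A:S" not in self.tags

    def core_fields(self) -> tuple:
        """The 12 mandatory columns (the comparison surface of verify mode)."""
        return (
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.matches, self.block_len, self.mapq,
        )

    def to_line(self) -> str:
        cols = [str(c) for c in self.core_fields()] + list(self.tags)
        return "\t".join(cols) + "\n"


def parse_paf_line(line: str) -> PafRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise InputError(f"PAF line has {len(parts)} columns, need >= 12")
    try:
        return PafRecord(
            parts[0], int(parts[1]), int(parts[2]), int(parts[3]), parts[4],
            parts[5], int(parts[6]), int(parts[7]), int(parts[8]),
            int(parts[9]), int(parts[10]), int(parts[11]),
            tuple(parts[12:]),
        )
    except ValueError as exc:
        raise InputError(f"malformed PAF line: {exc}") from exc
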