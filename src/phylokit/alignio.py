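"""Multiple sequence alignment model and FASTA/Phylip/Clustal/Nexus I/O.

The in-memory model is deliberately simple: an :class:`Alignment` is an
ordered list of (name, sequence) pairs of equal length over a nucleotide or
amino-acid alphabet, stored uppercase.  ``U`` is normalized to ``T`` for
nucleotide data so a single code path serves the distance estimators.  A
looser :class:`SequenceSet` (lengths may differ) models unaligned input
such as coding sequences destined for codon alignment.

Reading goes through Biopython's parsers for Clustal and Nexus; FASTA and
Phylip (relaxed names, sequential and interleaved) are parsed directly so
both Phylip dialects and precise error reporting are available.  All
writers are local so the output format is deterministic.  gzip input is
detected by magic bytes.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Union

from .tree import PhyloError

__all__ = [
    "Alignment",
    "SequenceSet",
    "read_alignment",
    "write_alignment",
    "align_stats",
    "AlignStats",
]

NT_CHARS = set("ACGTUN")
GAP = "-"
# IUPAC nucleotide ambiguity codes plus missing-data symbols
NT_AMBIG = set("RYSWKMBDHVNX?")
AA_AMBIG = set("BZJUOX?")


class SequenceSet:
    """Named sequences of possibly different lengths (unaligned)."""

    def __init__(self, records, alphabet: str = "auto") -> None:
        self.records: list[tuple[str, str]] = []
        seen = set()
        for name, seq in records:
            if not name:
                raise PhyloError("empty sequence name")
            if name in seen:
                raise PhyloError(f"duplicate sequence name: {name!r}")
            seen.add(name)
            self.records.append((name, seq.upper()))
        if alphabet == "auto":
            alphabet = detect_alphabet(s for _, s in self.records)
        if alphabet not in ("nucleotide", "amino-acid"):
            raise PhyloError(f"unknown alphabet: {alphabet!r}")
        self.alphabet = alphabet
        if alphabet == "nucleotide":
            self.records = [(n, s.replace("U", "T")) for n, s in self.records]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    def sequence(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise PhyloError(f"no sequence named {name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SequenceSet)
            and self.records == other.records
            and self.alphabet == other.alphabet
        )


class Alignment(SequenceSet):
    """Equal-length named sequences over a declared alphabet."""

    def __init__(self, records, alphabet: str = "auto") -> None:
        super().__init__(records, alphabet)
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise PhyloError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        self.length = lengths.pop() if lengths else 0

    def column(self, i: int) -> str:
        return "".join(s[i] for _, s in self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.records == other.records
            and self.alphabet == other.alphabet
        )


def detect_alphabet(seqs) -> str:
    """Nucleotide iff >=90% of non-gap characters are in ACGTUN."""
    counts = Counter()
    for s in seqs:
        counts.update(s)
    total = sum(v for k, v in counts.items() if k not in "-?.*")
    if total == 0:
        return "nucleotide"
    nt = sum(v for k, v in counts.items() if k in NT_CHARS)
    return "nucleotide" if nt / total >= 0.9 else "amino-acid"


# ---------------------------------------------------------------------------
# reading


def _decode(stream: Union[str, bytes, IO]) -> str:
    if isinstance(stream, str):
        return stream
    if isinstance(stream, bytes):
        data = stream
    else:
        data = stream.read()
        if isinstance(data, str):
            return data
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8")


def _sniff_format(text: str) -> str:
    head = text.lstrip()
    if head.startswith(">"):
        return "fasta"
    if head.upper().startswith("#NEXUS"):
        return "nexus"
    if head.upper().startswith("CLUSTAL"):
        return "clustal"
    if head[:1].isdigit():
        return "phylip"
    raise PhyloError("cannot auto-detect alignment format")


def _read_fasta(text: str) -> list[tuple[str, str]]:
    records = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if line[1:].strip() else ""
            chunks = []
        else:
            if name is None:
                raise PhyloError("FASTA data before first '>' header")
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise PhyloError("empty FASTA input")
    return records


def _read_phylip(text: str) -> list[tuple[str, str]]:
    lines = [ln.rstrip() for ln in text.splitlines()]
    while lines and not lines[0].strip():
        lines.pop(0)
    if not lines:
        raise PhyloError("empty Phylip input")
    header = lines[0].split()
    if len(header) < 2 or not header[0].isdigit() or not header[1].isdigit():
        raise PhyloError(f"malformed Phylip header: {lines[0]!r}")
    n_seq, n_col = int(header[0]), int(header[1])
    body = [ln for ln in lines[1:]]
    # first block: n_seq lines carrying names
    first = [ln for ln in body if ln.strip()][:n_seq]
    if len(first) < n_seq:
        raise PhyloError(f"Phylip header says {n_seq} sequences, fewer found")
    names = []
    seqs = []
    for ln in first:
        parts = ln.split(None, 1)
        names.append(parts[0])
        seqs.append(parts[1].replace(" ", "") if len(parts) > 1 else "")
    if all(len(s) >= n_col for s in seqs):
        pass  # sequential with full rows
    else:
        # sequential with wrapped rows, or interleaved continuation blocks
        rest = [ln for ln in body if ln.strip()][n_seq:]
        if _phylip_is_interleaved(seqs, rest, n_seq, n_col):
            idx = 0
            for ln in rest:
                seqs[idx % n_seq] += ln.replace(" ", "")
                idx += 1
        else:  # sequential: keep appending to the current sequence
            idx = 0
            for ln in rest:
                while len(seqs[idx]) >= n_col:
                    idx += 1
                    if idx >= n_seq:
                        raise PhyloError("extra Phylip data after last sequence")
                seqs[idx] += ln.replace(" ", "")
    bad = [n for n, s in zip(names, seqs) if len(s) != n_col]
    if bad:
        raise PhyloError(
            f"Phylip sequences with length != {n_col}: {', '.join(bad)}"
        )
    return list(zip(names, seqs))


def _phylip_is_interleaved(seqs, rest, n_seq, n_col) -> bool:
    if not rest:
        return False
    if len(rest) % n_seq != 0:
        return False
    # interleaved blocks advance all sequences in lock step
    per_block = [len(rest[i].replace(" ", "")) for i in range(min(n_seq, len(rest)))]
    return len(set(per_block)) == 1 and len(seqs[0]) < n_col


def _read_with_biopython(text: str, fmt: str) -> list[tuple[str, str]]:
    from Bio import AlignIO

    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except Exception as exc:  # normalize Bio's error types
        raise PhyloError(f"failed to parse {fmt} alignment: {exc}") from exc
    return [(rec.id, str(rec.seq)) for rec in aln]


def read_alignment(
    stream: Union[str, bytes, IO],
    format: str = "auto",
    alphabet: str = "auto",
) -> Alignment:
    """Read an alignment; ``format='auto'`` sniffs by leading bytes."""
    text = _decode(stream)
    if format == "auto":
        format = _sniff_format(text)
    if format == "fasta":
        records = _read_fasta(text)
    elif format == "phylip":
        records = _read_phylip(text)
    elif format in ("clustal", "nexus"):
        records = _read_with_biopython(text, format)
    else:
        raise PhyloError(f"unknown alignment format: {format!r}")
    return Alignment(records, alphabet)


def read_sequences(stream: Union[str, bytes, IO], alphabet: str = "auto") -> SequenceSet:
    """Read possibly-unaligned FASTA sequences."""
    return SequenceSet(_read_fasta(_decode(stream)), alphabet)


def read_alignment_path(path: str, format: str = "auto") -> Alignment:
    with open(path, "rb") as fh:
        return read_alignment(fh, format)


# ---------------------------------------------------------------------------
# writing


def _wrap(seq: str, width: int) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)]


def write_alignment(aln: Alignment, format: str = "fasta") -> str:
    """Serialize an alignment; round-trips through :func:`read_alignment`."""
    if format == "fasta":
        out = []
        for name, seq in aln:
            out.append(">" + name)
            out.extend(_wrap(seq, 80))
        return "\n".join(out) + "\n"
    if format == "phylip":
        if len(aln) == 0:
            raise PhyloError("cannot write an empty alignment as Phylip")
        lines = [f" {len(aln)} {aln.length}"]
        for name, seq in aln:
            lines.append(f"{name}  {seq}")
        return "\n".join(lines) + "\n"
    if format == "clustal":
        width = 60
        lines = ["CLUSTAL W multiple sequence alignment", ""]
        namew = max((len(n) for n, _ in aln), default=0)
        for start in range(0, max(aln.length, 1), width):
            for name, seq in aln:
                lines.append(f"{name.ljust(namew)}  {seq[start:start + width]}")
            lines.append("")
        return "\n".join(lines) + "\n"
    if format == "nexus":
        if len(aln) == 0:
            raise PhyloError("cannot write an empty alignment as Nexus")
        dtype = "dna" if aln.alphabet == "nucleotide" else "protein"
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(aln)} NCHAR={aln.length};",
            f"  FORMAT DATATYPE={dtype} MISSING=? GAP=-;",
            "  MATRIX",
        ]
        namew = max(len(n) for n, _ in aln)
        for name, seq in aln:
            lines.append(f"    {name.ljust(namew)}  {seq}")
        lines.extend(["  ;", "END;"])
        return "\n".join(lines) + "\n"
    raise PhyloError(f"unknown alignment format: {format!r}")


# ---------------------------------------------------------------------------
# statistics


@dataclass
class AlignStats:
    length: int
    n_sequences: int
    char_freqs: dict = field(default_factory=dict)
    gap_fraction: float = 0.0
    n_constant: int = 0
    n_variable: int = 0


def align_stats(aln: Alignment) -> AlignStats:
    """Length, counts, character frequencies, gap fraction, constant sites.

    Frequencies are over non-gap characters.  A column is constant when all
    its unambiguous non-gap characters are identical and at least one
    exists; other columns with any unambiguous variation are variable.
    """
    counts = Counter()
    for _, seq in aln:
        counts.update(seq)
    n_gap = counts.pop(GAP, 0)
    total = sum(counts.values())
    freqs = {c: v / total for c, v in sorted(counts.items())} if total else {}
    cells = aln.length * len(aln)
    ambig = NT_AMBIG if aln.alphabet == "nucleotide" else AA_AMBIG
    n_constant = n_variable = 0
    for i in range(aln.length):
        col = {c for c in aln.column(i) if c != GAP and c not in ambig and c != "*"}
        if len(col) == 1:
            n_constant += 1
        elif len(col) > 1:
            n_variable += 1
    return AlignStats(
        length=aln.length,
        n_sequences=len(aln),
        char_freqs=freqs,
        gap_fraction=n_gap / cells if cells else 0.0,
        n_constant=n_constant,
        n_variable=n_variable,
    )
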