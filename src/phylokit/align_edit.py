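"""Alignment modification commands: clean, rename, mask, extract, concat,
translate, codon alignment and bootstrap replicates.

Coordinates are 0-based half-open throughout the API; the command line
accepts the 1-based inclusive convention and converts.  Gap-fraction
cutoffs are compared strictly (``>``): a cutoff of 0.5 keeps columns that
are exactly half gaps, and ambiguity characters count as non-gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .alignio import GAP, Alignment, SequenceSet
from .tree import PhyloError

__all__ = [
    "RenameMap",
    "GENETIC_CODES",
    "clean_sites",
    "clean_seqs",
    "rename_seqs",
    "sanitize_names",
    "mask",
    "extract",
    "concat",
    "translate",
    "codon_align",
    "seqboot",
]


class RenameMap:
    """Ordered old-name → new-name pairs forming a bijection."""

    def __init__(self, pairs) -> None:
        self.pairs: list[tuple[str, str]] = list(pairs)
        olds = [o for o, _ in self.pairs]
        news = [n for _, n in self.pairs]
        if len(set(olds)) != len(olds):
            raise PhyloError("duplicate old names in rename map")
        if len(set(news)) != len(news):
            raise PhyloError("duplicate new names in rename map")
        self.mapping = dict(self.pairs)

    @classmethod
    def from_text(cls, text: str) -> "RenameMap":
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PhyloError(f"rename map line is not two tab-separated fields: {line!r}")
            pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def to_text(self) -> str:
        return "".join(f"{o}\t{n}\n" for o, n in self.pairs)

    def inverted(self) -> "RenameMap":
        return RenameMap((n, o) for o, n in self.pairs)


# ---------------------------------------------------------------------------
# genetic codes (NCBI translation tables 1 and 2)

_STANDARD_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASES = "TCAG"


def _build_code(aas: str) -> dict:
    table = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    name: str
    table: dict

    def translate_codon(self, codon: str) -> str:
        if codon == "---":
            return GAP
        aa = self.table.get(codon)
        return aa if aa is not None else "X"


_VMITO_AAS = (
    "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
)

GENETIC_CODES = {
    "standard": GeneticCode("standard", _build_code(_STANDARD_AAS)),
    "vertebrate-mito": GeneticCode("vertebrate-mito", _build_code(_VMITO_AAS)),
}


# ---------------------------------------------------------------------------
# cleaning


def _check_cutoff(cutoff: float) -> None:
    if not 0.0 <= cutoff <= 1.0:
        raise PhyloError(f"cutoff must be in [0, 1], got {cutoff}")


def clean_sites(aln: Alignment, cutoff: float = 0.5):
    """Drop columns whose gap fraction exceeds ``cutoff`` (strictly).

    Returns ``(alignment, n_removed)``; kept columns stay in order.
    """
    _check_cutoff(cutoff)
    n = len(aln)
    keep = [
        i
        for i in range(aln.length)
        if aln.column(i).count(GAP) / n <= cutoff
    ]
    result = Alignment(
        [(name, "".join(seq[i] for i in keep)) for name, seq in aln],
        aln.alphabet,
    )
    return result, aln.length - len(keep)


def clean_seqs(aln: Alignment, cutoff: float = 0.5):
    """Drop sequences whose gap fraction exceeds ``cutoff`` (strictly)."""
    _check_cutoff(cutoff)
    kept = [
        (name, seq)
        for name, seq in aln
        if aln.length == 0 or seq.count(GAP) / aln.length <= cutoff
    ]
    return Alignment(kept, aln.alphabet), len(aln) - len(kept)


# ---------------------------------------------------------------------------
# renaming


def rename_seqs(aln, rename_map: RenameMap, allow_missing: bool = False):
    """Rename sequences by map; unmapped names are kept unchanged."""
    present = set(aln.names)
    if not allow_missing:
        missing = [o for o in rename_map.mapping if o not in present]
        if missing:
            raise PhyloError(
                f"rename map entries match no sequence: {', '.join(missing)}"
            )
    records = [
        (rename_map.mapping.get(name, name), seq) for name, seq in aln
    ]
    cls = Alignment if isinstance(aln, Alignment) else SequenceSet
    return cls(records, aln.alphabet)


_BAD_NAME_CHARS = re.compile(r"[^A-Za-z0-9_.\-]")


def sanitize_names(aln):
    """Replace non ``[A-Za-z0-9_.-]`` characters by ``_`` and deduplicate.

    Returns ``(alignment, map)`` where the map sends old names to the
    sanitized ones (invert it to restore the originals).
    """
    new_names: list[str] = []
    used: set[str] = set()
    for name in aln.names:
        base = _BAD_NAME_CHARS.sub("_", name)
        cand = base
        suffix = 2
        while cand in used:
            cand = f"{base}_{suffix}"
            suffix += 1
        used.add(cand)
        new_names.append(cand)
    rmap = RenameMap(zip(aln.names, new_names))
    return rename_seqs(aln, rmap), rmap


# ---------------------------------------------------------------------------
# masking / extraction / concatenation


def mask(aln: Alignment, start: int, length: int, fill: str | None = None) -> Alignment:
    """Replace columns [start, start+length) by the fill character.

    Gaps inside the window are preserved.  Default fill is ``N`` for
    nucleotide and ``X`` for amino-acid alignments.
    """
    if start < 0 or length < 0 or start + length > aln.length:
        raise PhyloError(
            f"mask window [{start}, {start + length}) outside alignment of length {aln.length}"
        )
    if fill is None:
        fill = "N" if aln.alphabet == "nucleotide" else "X"
    records = []
    for name, seq in aln:
        window = "".join(
            GAP if c == GAP else fill for c in seq[start : start + length]
        )
        records.append((name, seq[:start] + window + seq[start + length :]))
    return Alignment(records, aln.alphabet)


def extract(aln: Alignment, ranges) -> Alignment:
    """Concatenate the column blocks given as sorted, non-overlapping
    0-based half-open ranges."""
    ranges = list(ranges)
    if not ranges:
        raise PhyloError("no ranges given to extract")
    prev_end = 0
    for start, end in ranges:
        if start < prev_end:
            raise PhyloError(f"ranges overlap or are unsorted at [{start}, {end})")
        if start < 0 or end > aln.length or start >= end:
            raise PhyloError(
                f"range [{start}, {end}) invalid for alignment of length {aln.length}"
            )
        prev_end = end
    records = [
        (name, "".join(seq[s:e] for s, e in ranges)) for name, seq in aln
    ]
    return Alignment(records, aln.alphabet)


def concat(alns, fill_missing: bool = False) -> Alignment:
    """Join alignments column-wise by sequence name.

    The result's name set is the union of all blocks' names (in order of
    first appearance); a name absent from a block is an error unless
    ``fill_missing`` is set, in which case that segment becomes gaps.
    """
    alns = list(alns)
    if not alns:
        raise PhyloError("concat needs at least one alignment")
    alphabets = {a.alphabet for a in alns}
    if len(alphabets) > 1:
        raise PhyloError(f"mixed alphabets in concat: {sorted(alphabets)}")
    all_names: list[str] = []
    for a in alns:
        for n in a.names:
            if n not in all_names:
                all_names.append(n)
    if not fill_missing:
        for i, a in enumerate(alns):
            missing = [n for n in all_names if n not in set(a.names)]
            if missing:
                raise PhyloError(
                    f"alignment {i + 1} is missing sequences: {', '.join(missing)}"
                )
    parts = {n: [] for n in all_names}
    for a in alns:
        have = dict(a.records)
        for n in all_names:
            parts[n].append(have.get(n, GAP * a.length))
    return Alignment(
        [(n, "".join(parts[n])) for n in all_names], alphabets.pop()
    )


# ---------------------------------------------------------------------------
# translation and codon alignment


def translate(seqs, phase: int = 0, code: GeneticCode | None = None):
    """Translate nucleotide sequences to amino acids.

    Drops ``phase`` leading characters.  Codon ``---`` gives ``-``; a codon
    containing a gap or ambiguity otherwise gives ``X``; stops give ``*``.
    Returns ``(translated, n_trailing_dropped)`` where the count covers the
    1–2 characters of any incomplete trailing codon summed over sequences.
    """
    if code is None:
        code = GENETIC_CODES["standard"]
    if phase not in (0, 1, 2):
        raise PhyloError(f"phase must be 0, 1 or 2, got {phase}")
    if seqs.alphabet != "nucleotide":
        raise PhyloError("translate requires a nucleotide alphabet")
    records = []
    dropped = 0
    for name, seq in seqs:
        s = seq[phase:]
        dropped += len(s) % 3
        aa = "".join(
            code.translate_codon(s[i : i + 3]) for i in range(0, len(s) - len(s) % 3, 3)
        )
        records.append((name, aa))
    cls = Alignment if isinstance(seqs, Alignment) else SequenceSet
    return cls(records, "amino-acid"), dropped


def codon_align(prot_aln: Alignment, cds: SequenceSet, code: GeneticCode | None = None) -> Alignment:
    """Back-translate a protein alignment using its coding sequences.

    Each protein residue column expands to the matching codon; each protein
    gap expands to ``---``.  The CDS must translate (ignoring a trailing
    stop codon) to the ungapped protein sequence.
    """
    if code is None:
        code = GENETIC_CODES["standard"]
    if prot_aln.alphabet != "amino-acid":
        raise PhyloError("codon_align expects an amino-acid alignment")
    if set(prot_aln.names) != set(cds.names):
        only_p = sorted(set(prot_aln.names) - set(cds.names))
        only_c = sorted(set(cds.names) - set(prot_aln.names))
        raise PhyloError(
            f"name mismatch between protein alignment and CDS: "
            f"protein-only={only_p}, cds-only={only_c}"
        )
    records = []
    for name, prot in prot_aln:
        nt = cds.sequence(name)
        if len(nt) % 3 == 0 and len(nt) >= 3 and code.table.get(nt[-3:]) == "*":
            nt = nt[:-3]  # tolerate a trailing stop codon
        n_res = sum(1 for c in prot if c != GAP)
        if len(nt) != 3 * n_res:
            raise PhyloError(
                f"{name}: CDS length {len(nt)} does not give {n_res} codons"
            )
        out = []
        pos = 0
        for res_i, c in enumerate(prot):
            if c == GAP:
                out.append("---")
                continue
            codon = nt[pos : pos + 3]
            trans = code.translate_codon(codon)
            if trans != c and c not in ("X", "?") and trans != "X":
                raise PhyloError(
                    f"{name}: codon {codon} translates to {trans}, "
                    f"protein has {c} at residue {res_i + 1}"
                )
            out.append(codon)
            pos += 3
        records.append((name, "".join(out)))
    return Alignment(records, "nucleotide")


# ---------------------------------------------------------------------------
# bootstrap replicates


def seqboot(aln: Alignment, n_replicates: int, seed: int) -> list[Alignment]:
    """Bootstrap pseudo-alignments: columns drawn with replacement.

    Replicate ``r`` uses an independent random stream derived from
    ``(seed, r)``, so any replicate is reproducible on its own.
    """
    if n_replicates <= 0:
        raise PhyloError("number of replicates must be positive")
    if aln.length < 1:
        raise PhyloError("cannot bootstrap an empty alignment")
    out = []
    seqs = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in aln]
    names = aln.names
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, aln.length, size=aln.length)
        records = [
            (name, arr[cols].tobytes().decode()) for name, arr in zip(names, seqs)
        ]
        out.append(Alignment(records, aln.alphabet))
    return out
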