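"""Deterministic synthetic inputs: simulated sequence pairs under the
implemented substitution models, random alignments, and a catalog of small
hand-derived worked examples.

Randomness is always seeded; per-case streams are derived from
``(seed, case)`` pairs so no result depends on generator call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignio import Alignment
from .distances import get_protein_model
from .tree import PhyloError

__all__ = [
    "SimSpec",
    "simulate_pair",
    "random_alignment",
    "jc_expected_mismatch",
    "WorkedExample",
    "worked_examples",
]

_NT = "ACGT"
_AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SimSpec:
    model: str
    d: float
    length: int
    seed: int

    def __post_init__(self) -> None:
        if self.d < 0:
            raise PhyloError("distance must be non-negative")
        if self.length < 1:
            raise PhyloError("length must be at least 1")


def jc_expected_mismatch(d: float) -> float:
    """Expected mismatch proportion at distance d under Jukes-Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _jc_transition_matrix(d: float) -> np.ndarray:
    same = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
    diff = (1.0 - same) / 3.0
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def simulate_pair(spec: SimSpec) -> Alignment:
    """Two sequences separated by distance d: ancestor drawn from the
    model's equilibrium frequencies, descendant site-wise from P(d)."""
    rng = np.random.default_rng([spec.seed, 2024])
    model = spec.model.lower()
    if model == "jc":
        pi = np.full(4, 0.25)
        P = _jc_transition_matrix(spec.d)
        letters = _NT
    else:
        pm = get_protein_model(model)
        pi = pm.pi
        P = pm.transition_matrix(spec.d)
        P = P / P.sum(axis=1, keepdims=True)
        letters = _AA_LETTERS
    anc = rng.choice(len(pi), size=spec.length, p=pi)
    cum = np.cumsum(P, axis=1)
    u = rng.random(spec.length)
    desc = np.array(
        [np.searchsorted(cum[a], x) for a, x in zip(anc, u)], dtype=int
    )
    desc = np.clip(desc, 0, len(pi) - 1)
    return Alignment(
        [
            ("anc", "".join(letters[i] for i in anc)),
            ("desc", "".join(letters[i] for i in desc)),
        ],
        "nucleotide" if model == "jc" else "amino-acid",
    )


def random_alignment(
    n_seqs: int, length: int, alphabet: str = "nucleotide", seed: int = 0,
    gap_fraction: float = 0.0,
) -> Alignment:
    """IID random alignment, optionally sprinkled with gaps."""
    rng = np.random.default_rng([seed, 777])
    letters = _NT if alphabet == "nucleotide" else _AA_LETTERS
    records = []
    for i in range(n_seqs):
        chars = rng.choice(list(letters), size=length)
        if gap_fraction > 0:
            gaps = rng.random(length) < gap_fraction
            chars = np.where(gaps, "-", chars)
        records.append((f"seq{i + 1}", "".join(chars)))
    return Alignment(records, alphabet)


# ---------------------------------------------------------------------------
# worked examples: tiny hand-derived cases used across the test suite


@dataclass
class WorkedExample:
    name: str
    operation: str
    args: dict
    expected: object
    note: str = ""


def worked_examples() -> list:
    """Static catalog of small cases with hand-derived expected outputs."""
    return [
        WorkedExample(
            "newick-roundtrip",
            "parse_write_newick",
            {"text": "((A:1,B:2):3,C:4);"},
            "((A:1,B:2):3,C:4);",
            "default formatting is byte-stable",
        ),
        WorkedExample(
            "newick-sum-lengths",
            "newick_total_length",
            {"text": "((A:1,B:2):3,C:4);"},
            10.0,
        ),
        WorkedExample(
            "prune-path-merge",
            "prune_remove",
            {"text": "((A:1,B:2):3,C:4);", "remove": ["B"]},
            "(A:4,C:4);",
            "edge lengths 1 and 3 merge",
        ),
        WorkedExample(
            "clean-sites-half",
            "clean_sites",
            {
                "records": [("s1", "A-A"), ("s2", "AA-"), ("s3", "A-A")],
                "cutoff": 0.5,
            },
            [("s1", "AA"), ("s2", "A-"), ("s3", "AA")],
            "column 2 at 2/3 gaps removed, column 3 at 1/3 kept",
        ),
        WorkedExample(
            "mask-keeps-gaps",
            "mask",
            {"records": [("s1", "A-GT")], "start": 1, "length": 2},
            [("s1", "A-NT")],
        ),
        WorkedExample(
            "translate-gap-codon",
            "translate",
            {"records": [("s1", "ATG---AAA")], "phase": 0},
            [("s1", "M-K")],
        ),
        WorkedExample(
            "codon-align-gap-expansion",
            "codon_align",
            {
                "prot": [("s1", "M-K"), ("s2", "MLK")],
                "cds": [("s1", "ATGAAA"), ("s2", "ATGCTGAAA")],
            },
            [("s1", "ATG---AAA"), ("s2", "ATGCTGAAA")],
        ),
        WorkedExample(
            "rf-quartet-pair",
            "rf_distance",
            {"ref": "((A,B),(C,D));", "comp": "((A,C),(B,D));"},
            2,
            "disjoint singleton split sets",
        ),
        WorkedExample(
            "rf-binary-vs-star",
            "rf_distance",
            {"ref": "((A,B),(C,D));", "comp": "(A,B,C,D);"},
            1,
        ),
        WorkedExample(
            "collapse-low-support",
            "collapse_support",
            {"text": "((A,B)0.3:1,(C,D)0.9:1,E);", "cutoff": 0.7},
            "(A,B,(C,D)0.9:1,E);",
        ),
        WorkedExample(
            "colless-caterpillar-5",
            "colless_caterpillar",
            {"n": 5},
            6,
            "(n-1)(n-2)/2",
        ),
        WorkedExample(
            "cherries-quartet",
            "count_cherries",
            {"text": "((A,B),(C,D));"},
            2,
        ),
        WorkedExample(
            "patristic-triplet",
            "patristic",
            {"text": "((A:1,B:2):3,C:4);"},
            {("A", "B"): 3.0, ("A", "C"): 8.0, ("B", "C"): 9.0},
        ),
        WorkedExample(
            "jc-at-p-0.3",
            "jc_from_p",
            {"p": 0.3},
            -0.75 * math.log(0.6),
            "-(3/4) ln(1 - 4p/3)",
        ),
        WorkedExample(
            "k2p-closed-form",
            "k2p_from_pq",
            {"P": 0.1, "Q": 0.05},
            -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1),
        ),
        WorkedExample(
            "tbe-cherry-is-fbp",
            "tbe_equals_fbp_on_cherry",
            {
                "ref": "((A,B),(C,(D,E)));",
                "boots": ["((A,B),(C,(D,E)));", "((A,C),(B,(D,E)));"],
            },
            None,
            "p=2 edges: per-tree transfer contribution is 0 or 1",
        ),
    ]
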