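"""Evolutionary distances from alignments.

Nucleotide distances use the classical closed-form estimators (JC, K2P,
F81, F84, TN93, plus the uncorrected ``pdist``/``raw``), computed from the
pairwise proportions of transitions and transversions with pairwise
deletion of gap/ambiguity sites.  Base frequencies, where a model needs
them, are estimated once from the whole alignment rather than per pair,
which stabilizes the frequency-aware estimators on short sequences.

Amino-acid distances are maximum-likelihood estimates under an empirical
replacement model (DAYHOFF, JTT, MTREV, LG, WAG): for a pair at distance d
the log-likelihood is sum over compared sites of log(pi_a * P_ab(d)), with
P(d) = expm(Q d) and Q the model's rate matrix normalized to one expected
substitution per unit distance.  The 1-D likelihood is maximized by
bounded scalar optimization on [1e-9, 20].

Saturated pairs (a non-positive logarithm argument) yield +Inf rather than
an error; the Phylip matrix writer substitutes a sentinel of 20.0 so the
matrix remains usable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import _empirical_matrices as _emp
from .alignio import Alignment
from .tree import PhyloError

__all__ = [
    "PairCounts",
    "DistanceMatrix",
    "pair_counts",
    "nt_distance",
    "nt_distance_matrix",
    "prot_distance_matrix",
    "base_frequencies",
    "ProteinModel",
    "get_protein_model",
    "NT_MODELS",
    "PROTEIN_MODELS",
]

NT_MODELS = ("jc", "k2p", "f81", "f84", "tn93", "pdist", "raw")
PROTEIN_MODELS = ("dayhoff", "jtt", "mtrev", "lg", "wag")

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}
_AA = _emp.AA_ORDER
_AA_INDEX = {c: i for i, c in enumerate(_AA)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# distance matrix container


class DistanceMatrix:
    """Symmetric named distance matrix (+Inf marks saturated pairs)."""

    def __init__(self, names, matrix) -> None:
        self.names = list(names)
        self.matrix = np.asarray(matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise PhyloError("distance matrix shape does not match names")

    def __getitem__(self, pair):
        i = self.names.index(pair[0])
        j = self.names.index(pair[1])
        return self.matrix[i, j]

    def to_phylip(self) -> str:
        """Phylip square format; +Inf written as the sentinel 20.0."""
        lines = [f"   {len(self.names)}"]
        for name, row in zip(self.names, self.matrix):
            vals = " ".join(
                f"{(20.0 if not math.isfinite(v) else v):.8f}" for v in row
            )
            lines.append(f"{name}  {vals}")
        return "\n".join(lines) + "\n"

    @property
    def n_saturated(self) -> int:
        return int(np.sum(~np.isfinite(self.matrix)) // 2)


# ---------------------------------------------------------------------------
# pairwise site counts


@dataclass
class PairCounts:
    """Pairwise-deletion site counts for one sequence pair.

    p is the overall mismatch proportion; P1 and P2 the A<->G and C<->T
    transition proportions; Q the transversion proportion; freqs the joint
    base counts over compared sites (rows = seq1, cols = seq2, ACGT).
    """

    n: int
    p: float
    P1: float
    P2: float
    Q: float
    freqs: np.ndarray

    @property
    def P(self) -> float:
        return self.P1 + self.P2


def pair_counts(seq1: str, seq2: str) -> PairCounts:
    """Count compared sites and substitution proportions for a pair.

    Sites where either sequence carries a gap or an ambiguity code are
    excluded entirely (pairwise deletion, no fractional matching).
    """
    if len(seq1) != len(seq2):
        raise PhyloError("sequences have different lengths")
    joint = np.zeros((4, 4))
    n = 0
    for a, b in zip(seq1, seq2):
        i = _NT_INDEX.get(a)
        j = _NT_INDEX.get(b)
        if i is None or j is None:
            continue
        joint[i, j] += 1
        n += 1
    if n == 0:
        raise PhyloError("no comparable sites between the two sequences")
    mismatch = n - np.trace(joint)
    p1 = joint[0, 2] + joint[2, 0]  # A<->G
    p2 = joint[1, 3] + joint[3, 1]  # C<->T
    q = mismatch - p1 - p2
    return PairCounts(
        n=n, p=mismatch / n, P1=p1 / n, P2=p2 / n, Q=q / n, freqs=joint
    )


def base_frequencies(aln: Alignment) -> np.ndarray:
    """Global ACGT frequencies over unambiguous non-gap characters."""
    counts = np.zeros(4)
    for _, seq in aln:
        for c in seq:
            i = _NT_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise PhyloError("alignment holds no unambiguous nucleotides")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# closed-form nucleotide estimators


def _safe_log(x: float) -> float:
    """log with saturation semantics: non-positive argument -> -inf."""
    if x <= 0:
        return -math.inf
    return math.log(x)


def _d_jc(c: PairCounts, pi) -> float:
    return -0.75 * _safe_log(1.0 - 4.0 * c.p / 3.0)


def _d_k2p(c: PairCounts, pi) -> float:
    return -0.5 * _safe_log(1.0 - 2.0 * c.P - c.Q) - 0.25 * _safe_log(
        1.0 - 2.0 * c.Q
    )


def _d_f81(c: PairCounts, pi) -> float:
    b = 1.0 - float(np.sum(np.square(pi)))
    if b <= 0:
        raise PhyloError("degenerate base frequencies for F81")
    return -b * _safe_log(1.0 - c.p / b)


def _d_f84(c: PairCounts, pi) -> float:
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    if min(pr, py) <= 0 or pa * pg == 0 or pc * pt == 0:
        raise PhyloError("degenerate base frequencies for F84")
    a = pa * pg / pr + pc * pt / py
    b = pa * pg + pc * pt
    cc = pr * py
    P, Q = c.P, c.Q
    return -2.0 * a * _safe_log(
        1.0 - P / (2.0 * a) - (a - b) * Q / (2.0 * a * cc)
    ) + 2.0 * (a - b - cc) * _safe_log(1.0 - Q / (2.0 * cc))


def _d_tn93(c: PairCounts, pi) -> float:
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    if pa * pg == 0 or pc * pt == 0 or pr * py == 0:
        raise PhyloError("degenerate base frequencies for TN93")
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pc * pt / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1.0 - c.P1 / k1 - c.Q / (2.0 * pr)
    w2 = 1.0 - c.P2 / k2 - c.Q / (2.0 * py)
    w3 = 1.0 - c.Q / (2.0 * pr * py)
    return -k1 * _safe_log(w1) - k2 * _safe_log(w2) - k3 * _safe_log(w3)


_NT_ESTIMATORS = {
    "jc": _d_jc,
    "k2p": _d_k2p,
    "f81": _d_f81,
    "f84": _d_f84,
    "tn93": _d_tn93,
}


def nt_distance(seq1: str, seq2: str, model: str, pi=None) -> float:
    """Closed-form nucleotide distance for one pair.

    ``pi`` (ACGT frequencies) is required by f81/f84/tn93; pass the global
    alignment frequencies from :func:`base_frequencies`.  Saturation gives
    +Inf.  ``pdist`` returns the mismatch proportion, ``raw`` the mismatch
    count divided by compared sites (identical by construction, kept as
    distinct names mirroring common usage).
    """
    model = model.lower()
    c = pair_counts(seq1, seq2)
    if model in ("pdist", "raw"):
        return c.p
    if model not in _NT_ESTIMATORS:
        raise PhyloError(f"unknown nucleotide model: {model!r}")
    if model in ("f81", "f84", "tn93"):
        if pi is None:
            raise PhyloError(f"model {model} needs base frequencies")
        pi = np.asarray(pi, dtype=float)
    d = _NT_ESTIMATORS[model](c, pi)
    if d == -0.0:
        return 0.0
    if math.isinf(d) or d != d:
        return math.inf
    return max(d, 0.0)


def nt_distance_matrix(aln: Alignment, model: str) -> DistanceMatrix:
    """All-pairs nucleotide distances (each unordered pair computed once)."""
    if aln.alphabet != "nucleotide":
        raise PhyloError("nucleotide distance matrix needs nucleotide data")
    if len(aln) < 2:
        raise PhyloError("need at least two sequences")
    pi = (
        base_frequencies(aln)
        if model.lower() in ("f81", "f84", "tn93")
        else None
    )
    n = len(aln)
    mat = np.zeros((n, n))
    seqs = [s for _, s in aln]
    for i in range(n):
        for j in range(i + 1, n):
            d = nt_distance(seqs[i], seqs[j], model, pi)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(aln.names, mat)


# ---------------------------------------------------------------------------
# maximum-likelihood protein distances


class ProteinModel:
    """Empirical replacement model with precomputed spectral decomposition.

    The rate matrix is Q_ij = s_ij pi_j (i != j) with the diagonal set to
    minus the row sum, normalized so that -sum_i pi_i Q_ii = 1.  Transition
    probabilities P(d) = expm(Q d) are computed through the symmetric
    matrix B = D^{1/2} Q D^{-1/2} (D = diag(pi)), whose eigendecomposition
    is exact and stable for reversible models.
    """

    def __init__(self, name: str, rates, freqs) -> None:
        self.name = name
        s = np.zeros((20, 20))
        k = 0
        for j in range(20):  # column-major lower triangle
            for i in range(j + 1, 20):
                s[i, j] = s[j, i] = rates[k]
                k += 1
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        q /= scale
        self.pi = pi
        self.Q = q
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, np.newaxis]) / sqrt_pi[np.newaxis, :]
        b = (b + b.T) / 2.0
        self._eigval, self._eigvec = np.linalg.eigh(b)
        self._left = self._eigvec / sqrt_pi[:, np.newaxis]
        self._right = self._eigvec * sqrt_pi[:, np.newaxis]

    def transition_matrix(self, d: float) -> np.ndarray:
        p = self._left @ np.diag(np.exp(self._eigval * d)) @ self._right.T
        return np.clip(p, 1e-300, None)


def uniform_protein_model() -> ProteinModel:
    """Equal exchangeabilities and frequencies (20-state Poisson model)."""
    return ProteinModel("uniform", np.ones(190), np.full(20, 0.05))


_MODEL_CACHE: dict[str, ProteinModel] = {}


def get_protein_model(name: str) -> ProteinModel:
    key = name.lower()
    if key in _MODEL_CACHE:
        return _MODEL_CACHE[key]
    if key == "uniform":
        model = uniform_protein_model()
    elif key in PROTEIN_MODELS:
        upper = key.upper()
        model = ProteinModel(
            upper,
            getattr(_emp, f"{upper}_RATES"),
            getattr(_emp, f"{upper}_FREQS"),
        )
    else:
        raise PhyloError(f"unknown protein model: {name!r}")
    _MODEL_CACHE[key] = model
    return model


def _aa_pair_counts(seq1: str, seq2: str) -> np.ndarray:
    joint = np.zeros((20, 20))
    for a, b in zip(seq1, seq2):
        i = _AA_INDEX.get(a)
        j = _AA_INDEX.get(b)
        if i is None or j is None:
            continue
        joint[i, j] += 1
    return joint


def ml_protein_distance(seq1: str, seq2: str, model: ProteinModel) -> float:
    """Maximize the pairwise likelihood over d in [1e-9, 20]."""
    joint = _aa_pair_counts(seq1, seq2)
    if joint.sum() == 0:
        raise PhyloError("no comparable sites between the two sequences")
    if np.trace(joint) == joint.sum():
        return 0.0
    log_pi = np.log(model.pi)

    def neg_loglik(d: float) -> float:
        p = model.transition_matrix(d)
        return -float(np.sum(joint * (log_pi[:, np.newaxis] + np.log(p))))

    res = minimize_scalar(
        neg_loglik, bounds=(1e-9, 20.0), method="bounded",
        options={"xatol": 1e-8},
    )
    d = float(res.x)
    return 0.0 if d <= 2e-9 else d


def prot_distance_matrix(aln: Alignment, model: str) -> DistanceMatrix:
    """All-pairs ML distances under an empirical amino-acid model."""
    if aln.alphabet != "amino-acid":
        raise PhyloError("protein distance matrix needs amino-acid data")
    if len(aln) < 2:
        raise PhyloError("need at least two sequences")
    pm = get_protein_model(model)
    n = len(aln)
    mat = np.zeros((n, n))
    seqs = [s for _, s in aln]
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_protein_distance(seqs[i], seqs[j], pm)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(aln.names, mat)
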