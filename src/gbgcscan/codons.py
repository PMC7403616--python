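"""Genetic-code machinery shared by the simulator and the estimator.

This module provides the 61-state sense-codon space under the standard
genetic code, the weak/strong classification of single-nucleotide codon
changes, GC-content statistics (GC, GC12, GC3), and the YN98(F3X4) codon
rate matrix with an optional weak-to-strong bias multiplier used to emulate
GC-biased gene conversion (gBGC) in forward simulations.

Conventions
-----------
* Bases A and T are "weak" (W), G and C are "strong" (S).  A single
  nucleotide change is classified by the (from, to) base classes into one
  of WS, SW, WW, SS, crossed with synonymous/nonsynonymous for eight
  mutational categories in total.
* Only the 61 sense codons of the standard code are modelled; stop codons
  are outside the state space.  Codons containing ``N`` or ``-`` are
  treated as unscored and excluded from counts.
* Rate matrices are scaled so that the expected number of substitutions
  per codon site per unit branch length is 1 at ``ws_bias = 1``; the bias
  multiplier is applied *after* scaling, so biased branches have a higher
  realized substitution rate (all categories elevated, WS most).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "CATEGORY_LABELS",
    "MutationCategory",
    "YN98Params",
    "CodonError",
    "AmbiguousCodonError",
    "StopCodonError",
    "NotSingleChangeError",
    "CodingLengthError",
    "classify_change",
    "gc_content",
    "codon_frequencies",
    "build_rate_matrix",
    "stationary_distribution",
    "category_matrix",
    "opportunity_matrix",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))

#: The 61 sense codons of the standard genetic code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STANDARD_TABLE.stop_codons
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(
    _STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS
)

WEAK_BASES = frozenset("AT")
STRONG_BASES = frozenset("GC")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

BASE_CLASSES = ("WS", "SW", "WW", "SS")
CODING_CLASSES = ("synonymous", "nonsynonymous")
#: Column labels for the eight per-category rates, dS first.
CATEGORY_LABELS = (
    "dS_WS", "dS_SW", "dS_WW", "dS_SS",
    "dN_WS", "dN_SW", "dN_WW", "dN_SS",
)


class CodonError(ValueError):
    """Base class for codon-level input errors."""


class AmbiguousCodonError(CodonError):
    """Codon contains N or gap characters and cannot be scored."""


class StopCodonError(CodonError):
    """Codon is a stop codon, outside the sense-codon state space."""


class NotSingleChangeError(CodonError):
    """Codon pair does not differ at exactly one position."""


class CodingLengthError(CodonError):
    """Sequence length is not a multiple of three (gene must be excluded)."""


@dataclass(frozen=True)
class MutationCategory:
    """One of the eight mutational categories of a single-nucleotide codon
    change: base class (WS/SW/WW/SS) x coding class (synonymous or not)."""

    base_class: str
    coding_class: str

    def __post_init__(self) -> None:
        if self.base_class not in BASE_CLASSES:
            raise ValueError(f"unknown base class {self.base_class!r}")
        if self.coding_class not in CODING_CLASSES:
            raise ValueError(f"unknown coding class {self.coding_class!r}")

    @property
    def label(self) -> str:
        prefix = "dS" if self.coding_class == "synonymous" else "dN"
        return f"{prefix}_{self.base_class}"

    @property
    def index(self) -> int:
        return CATEGORY_LABELS.index(self.label)


def _base_class(from_base: str, to_base: str) -> str:
    w_from = from_base in WEAK_BASES
    w_to = to_base in WEAK_BASES
    if w_from and not w_to:
        return "WS"
    if not w_from and w_to:
        return "SW"
    if w_from and w_to:
        return "WW"
    return "SS"


def _check_sense(codon: str) -> None:
    if len(codon) != 3:
        raise CodonError(f"codon must have length 3, got {codon!r}")
    if any(b not in "ACGT" for b in codon):
        raise AmbiguousCodonError(f"codon {codon!r} contains ambiguous characters")
    if codon in _STANDARD_TABLE.stop_codons:
        raise StopCodonError(f"{codon!r} is a stop codon")


def classify_change(from_codon: str, to_codon: str) -> MutationCategory:
    """Classify a single-nucleotide change between two sense codons.

    Raises :class:`NotSingleChangeError` if the codons differ at zero or
    more than one position, :class:`StopCodonError` /
    :class:`AmbiguousCodonError` for codons outside the state space.
    """
    _check_sense(from_codon)
    _check_sense(to_codon)
    diff = [p for p in range(3) if from_codon[p] != to_codon[p]]
    if len(diff) != 1:
        raise NotSingleChangeError(
            f"{from_codon!r} -> {to_codon!r} differs at {len(diff)} positions"
        )
    pos = diff[0]
    base_class = _base_class(from_codon[pos], to_codon[pos])
    syn = (
        _STANDARD_TABLE.forward_table[from_codon]
        == _STANDARD_TABLE.forward_table[to_codon]
    )
    return MutationCategory(base_class, "synonymous" if syn else "nonsynonymous")


class GCContent(NamedTuple):
    gc: float
    gc12: float
    gc3: float


def gc_content(seq: str) -> GCContent:
    """GC fraction overall, at first+second, and at third codon positions.

    Fractions are computed over unambiguous (A/C/G/T) bases only; gaps and
    N are ignored.  A sequence whose length is not a multiple of three
    raises :class:`CodingLengthError` so callers exclude the gene rather
    than silently truncating.  Position classes with no unambiguous base
    yield ``nan``.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise CodingLengthError(
            f"sequence length {len(seq)} is not a multiple of three"
        )
    counts = np.zeros(3)   # unambiguous bases per codon position
    gc = np.zeros(3)
    for i, base in enumerate(seq):
        if base in "ACGT":
            pos = i % 3
            counts[pos] += 1
            if base in "GC":
                gc[pos] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        total = gc.sum() / counts.sum() if counts.sum() else float("nan")
        gc12 = gc[:2].sum() / counts[:2].sum() if counts[:2].sum() else float("nan")
        gc3 = gc[2] / counts[2] if counts[2] else float("nan")
    return GCContent(float(total), float(gc12), float(gc3))


def _default_pi() -> np.ndarray:
    return np.full((3, 4), 0.25)


@dataclass
class YN98Params:
    """Parameters of the YN98(F3X4) codon model.

    kappa
        Transition/transversion rate ratio (> 0).
    omega
        Nonsynonymous/synonymous rate ratio dN/dS (> 0).
    pi
        3x4 matrix of position-specific nucleotide frequencies in A, C, G,
        T order (F3X4); each row sums to 1.
    ws_bias
        Multiplier applied to all weak-to-strong changes (>= 1; 1 means no
        gBGC).  This is a forward-simulation extension; the fitted model
        always uses ``ws_bias = 1``.
    """

    kappa: float = 2.0
    omega: float = 0.2
    pi: np.ndarray = field(default_factory=_default_pi)
    ws_bias: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError("kappa must be finite and > 0")
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise ValueError("omega must be finite and > 0")
        if not (np.isfinite(self.ws_bias) and self.ws_bias >= 1):
            raise ValueError("ws_bias must be finite and >= 1")
        if self.pi.shape != (3, 4):
            raise ValueError("pi must be a 3x4 matrix (positions x ACGT)")
        if np.any(self.pi < 0) or not np.allclose(self.pi.sum(axis=1), 1.0):
            raise ValueError("each row of pi must be non-negative and sum to 1")


_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def codon_frequencies(pi: np.ndarray) -> np.ndarray:
    """F3X4 stationary codon frequencies: products of positional nucleotide
    frequencies, renormalized over the 61 sense codons."""
    pi = np.asarray(pi, dtype=float)
    freqs = np.array(
        [
            pi[0, _BASE_TO_COL[c[0]]]
            * pi[1, _BASE_TO_COL[c[1]]]
            * pi[2, _BASE_TO_COL[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("positional frequencies give zero mass to sense codons")
    return freqs / total


def _single_change_pairs():
    """Yield (i, j, pos, from_base, to_base) for ordered sense-codon pairs
    differing at exactly one position."""
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) == 1:
                p = diff[0]
                yield i, j, p, ci[p], cj[p]


def _build_static_tables():
    n = len(SENSE_CODONS)
    cat = np.full((n, n), -1, dtype=np.int8)
    is_ws = np.zeros((n, n), dtype=bool)
    is_transition = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    opp = np.zeros((n, 8))
    for i, j, _pos, b_from, b_to in _single_change_pairs():
        base_class = _base_class(b_from, b_to)
        syn = AMINO_ACIDS[i] == AMINO_ACIDS[j]
        label = ("dS_" if syn else "dN_") + base_class
        k = CATEGORY_LABELS.index(label)
        cat[i, j] = k
        is_ws[i, j] = base_class == "WS"
        is_transition[i, j] = (b_from, b_to) in _TRANSITIONS
        is_syn[i, j] = syn
        # Nei-Gojobori-style opportunity: each codon position offers three
        # alternative bases; each sense alternative contributes 1/3 site to
        # its category.
        opp[i, k] += 1.0 / 3.0
    return cat, is_ws, is_transition, is_syn, opp


_CAT_MATRIX, _WS_MASK, _TS_MASK, _SYN_MASK, _OPPORTUNITY = _build_static_tables()


def category_matrix() -> np.ndarray:
    """61x61 int matrix giving the category index (0..7 into
    :data:`CATEGORY_LABELS`) of each single-position sense change, -1 for
    pairs that are not single-nucleotide neighbours."""
    return _CAT_MATRIX.copy()


def opportunity_matrix() -> np.ndarray:
    """61x8 matrix of per-codon mutational-opportunity sites per category
    (number of single-nucleotide sense neighbours in the category / 3)."""
    return _OPPORTUNITY.copy()


def build_rate_matrix(params: YN98Params) -> np.ndarray:
    """Build the 61x61 YN98(F3X4) rate matrix.

    The off-diagonal entry for a single-nucleotide change i->j is
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]`` (pi_j the F3X4
    stationary frequency of the target codon); multi-position changes have
    rate zero; the diagonal makes rows sum to zero.  The matrix is scaled
    to one expected substitution per codon site per unit time at
    ``ws_bias = 1``; the weak-to-strong multiplier is applied after
    scaling (so bias raises the realized rate).
    """
    freqs = codon_frequencies(params.pi)
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    neighbour = _CAT_MATRIX >= 0
    q[neighbour] = np.broadcast_to(freqs, (n, n))[neighbour]
    q[_TS_MASK] *= params.kappa
    q[neighbour & ~_SYN_MASK] *= params.omega
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(q))
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    q /= scale
    if params.ws_bias != 1.0:
        q[_WS_MASK] *= params.ws_bias
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (left null vector of Q,
    normalized to sum 1)."""
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
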