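"""Length-stratified local protein alignment with Karlin–Altschul statistics.

Queries are routed to PAM30 (<30 aa), PAM70 (30–70 aa) or BLOSUM62 (>70 aa)
the way short-query protein BLAST searches are, aligned with full affine-gap
Smith–Waterman dynamic programming (Bio.Align.PairwiseAligner in local mode —
no heuristic seeding, which is fine at the scales this package targets), and
scored for significance with E = K·m·n·exp(−λS) where n is the concatenated
length of the target panel, matching database-style BLAST semantics.

The 30/70 boundaries are assigned inclusively to the middle class and are
configurable. Gap penalties follow the community defaults for each matrix
(BLOSUM62 11/1, PAM70 10/1, PAM30 9/1); λ and K are shipped per-matrix
constants approximating the gapped values used by BLAST — hit/no-hit
decisions at the 1e-5 cutoff are insensitive to their exact values here.
'X' scores 0 against every residue; any other letter outside the 20-letter
alphabet is an input error. No low-complexity masking is applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Protocol, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .models import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"

#: matrix -> (gap_open, gap_extend, lambda, K); gap of length k costs
#: |gap_open| + k*|gap_extend|
MATRIX_PARAMS: dict[str, tuple[int, int, float, float]] = {
    "BLOSUM62": (-11, -1, 0.267, 0.041),
    "PAM70": (-10, -1, 0.310, 0.100),
    "PAM30": (-9, -1, 0.294, 0.110),
}

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_LENGTH_BOUNDS = (30, 70)


@dataclass(frozen=True)
class ScoringScheme:
    """A substitution matrix with affine gap penalties and E-value parameters."""

    matrix_name: str
    matrix: object  # substitution_matrices.Array
    gap_open: int
    gap_extend: int
    lambda_: float
    K: float

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_frac: float
    query_range: tuple[int, int]
    target_range: tuple[int, int]
    matrix_name: str


def _restricted_matrix(name: str):
    base = substitution_matrices.load(name)
    arr = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            arr[a, b] = 0.0 if (a == "X" or b == "X") else base[a, b]
    return arr


@lru_cache(maxsize=None)
def scoring_scheme(matrix_name: str) -> ScoringScheme:
    if matrix_name not in MATRIX_PARAMS:
        raise ValueError(f"unknown matrix {matrix_name!r}; options: {sorted(MATRIX_PARAMS)}")
    go, ge, lam, k = MATRIX_PARAMS[matrix_name]
    return ScoringScheme(
        matrix_name=matrix_name, matrix=_restricted_matrix(matrix_name),
        gap_open=go, gap_extend=ge, lambda_=lam, K=k,
    )


@lru_cache(maxsize=None)
def _aligner(matrix_name: str) -> PairwiseAligner:
    scheme = scoring_scheme(matrix_name)
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = scheme.matrix
    # PairwiseAligner charges open_gap_score for the first gap position and
    # extend_gap_score thereafter; BLAST-style open+k*extend needs the shift.
    a.open_gap_score = scheme.gap_open + scheme.gap_extend
    a.extend_gap_score = scheme.gap_extend
    return a


def validate_sequence(seq: str, label: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"{label} contains letters outside the amino-acid alphabet: {sorted(bad)}")
    return seq


def select_matrix(
    query_length_aa: int, bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
) -> str:
    """Route a query to PAM30/PAM70/BLOSUM62 by length; both bounds fall in
    the middle (PAM70) class."""
    if query_length_aa < 1:
        raise ValueError(f"query length must be >= 1, got {query_length_aa}")
    lo, hi = bounds
    if query_length_aa < lo:
        return "PAM30"
    if query_length_aa <= hi:
        return "PAM70"
    return "BLOSUM62"


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    if m < 1 or n < 1:
        raise ValueError("sequence and database lengths must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lambda_ * raw_score)


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    return (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2.0)


def local_score(query: str, target: str, scheme: ScoringScheme) -> float:
    """Optimal local affine-gap alignment score (0 when nothing positive)."""
    return _aligner(scheme.matrix_name).score(query, target)


def smith_waterman(
    query: ProteinRecord,
    target: ProteinRecord,
    scheme: ScoringScheme,
    n_database: int | None = None,
) -> AlignmentHit | None:
    """Optimal local alignment of two proteins; None when no alignment
    scores above zero. ``n_database`` overrides the target length used for
    the E-value (database-style search statistics)."""
    qseq = validate_sequence(query.sequence, f"query {query.id!r}")
    tseq = validate_sequence(target.sequence, f"target {target.id!r}")
    aligner = _aligner(scheme.matrix_name)
    score = aligner.score(qseq, tseq)
    if score <= 0:
        return None
    aln = aligner.align(qseq, tseq)[0]
    counts = aln.counts()
    identity = counts.identities / aln.length if aln.length else 0.0
    qblocks, tblocks = aln.aligned
    n = n_database if n_database is not None else len(tseq)
    return AlignmentHit(
        query_id=query.id,
        target_id=target.id,
        raw_score=int(round(score)),
        bit_score=bit_score(score, scheme),
        e_value=evalue(score, len(qseq), n, scheme),
        identity_frac=identity,
        query_range=(int(qblocks[0][0]), int(qblocks[-1][1])),
        target_range=(int(tblocks[0][0]), int(tblocks[-1][1])),
        matrix_name=scheme.matrix_name,
    )


class HitProvider(Protocol):
    """Anything that can answer panel hit queries for a protein."""

    def best_evalue(self, query: ProteinRecord, panel: Sequence[ProteinRecord],
                    cutoff: float) -> float | None: ...

    def has_hit(self, query: ProteinRecord, panel: Sequence[ProteinRecord],
                cutoff: float) -> bool: ...


class InternalAligner:
    """Hit decisions from the internal Smith–Waterman search."""

    def __init__(self, length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS):
        self.length_bounds = length_bounds

    def _scheme(self, query: ProteinRecord) -> ScoringScheme:
        return scoring_scheme(select_matrix(query.length_aa, self.length_bounds))

    def best_evalue(self, query, panel, cutoff=DEFAULT_EVALUE_CUTOFF):
        if not panel:
            return None
        scheme = self._scheme(query)
        qseq = validate_sequence(query.sequence, f"query {query.id!r}")
        n_total = sum(t.length_aa for t in panel)
        best = None
        for target in panel:
            s = local_score(qseq, target.sequence.upper(), scheme)
            e = evalue(s, len(qseq), n_total, scheme)
            if best is None or e < best:
                best = e
        return best

    def has_hit(self, query, panel, cutoff=DEFAULT_EVALUE_CUTOFF):
        if not panel:
            return False
        scheme = self._scheme(query)
        qseq = validate_sequence(query.sequence, f"query {query.id!r}")
        n_total = sum(t.length_aa for t in panel)
        # minimal raw score reaching the cutoff; E is monotone in S
        min_score = math.log(scheme.K * len(qseq) * n_total / cutoff) / scheme.lambda_
        for target in panel:
            if local_score(qseq, target.sequence.upper(), scheme) >= min_score:
                return True
        return False


class HitTableProvider:
    """Hit decisions taken from a precomputed BLAST-style table.

    The table is an "outfmt 6"-compatible subset with columns
    (query_id, target_id, identity_pct, align_len, e_value, bit_score);
    panel membership is decided by which panel contains the target id.
    """

    def __init__(self, table) -> None:
        import pandas as pd  # local import keeps module import light

        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(
                table, sep="\t", header=None,
                names=["query_id", "target_id", "identity_pct", "align_len",
                       "e_value", "bit_score"],
            )
        self._by_query: dict[str, list[tuple[str, float]]] = {}
        for q, t, e in zip(table["query_id"], table["target_id"], table["e_value"]):
            self._by_query.setdefault(str(q), []).append((str(t), float(e)))

    def best_evalue(self, query, panel, cutoff=DEFAULT_EVALUE_CUTOFF):
        ids = {t.id for t in panel}
        rows = [e for t, e in self._by_query.get(query.id, []) if t in ids]
        return min(rows) if rows else None

    def has_hit(self, query, panel, cutoff=DEFAULT_EVALUE_CUTOFF):
        e = self.best_evalue(query, panel, cutoff)
        return e is not None and e <= cutoff


def has_hit(
    query: ProteinRecord,
    panel: Iterable[ProteinRecord],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> bool:
    """True iff any panel protein aligns to the query with E <= cutoff under
    the matrix selected by query length. An empty panel never hits."""
    return InternalAligner(length_bounds).has_hit(query, list(panel), cutoff)
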