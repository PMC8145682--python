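"""Global pairwise protein alignment with affine gap penalties.

Implements the Needleman-Wunsch / Gotoh dynamic programme and reports the
EMBOSS Needle percentage statistics: identity, similarity (columns whose
residue pair scores > 0 under the substitution matrix) and gaps, all over the
full alignment length including terminal gaps.

The DP is row-vectorised with numpy.  The in-row gap state (a gap in the
first sequence, consuming the second) normally carries a within-row
dependency; it is resolved in closed form with a running prefix maximum,
because ``E[j] = max_{k<j} (G[k] - open - (j-k) * extend)`` can be rewritten
as ``-open - j*extend + cummax(G[k] + k*extend)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SubstitutionMatrix",
    "GapPenalties",
    "AlignmentResult",
    "read_fasta",
    "write_fasta",
    "needleman_wunsch",
    "percent_stats",
]

NEG_INF = float("-inf")


class SubstitutionMatrix:
    """Symmetric residue-pair scores backed by a dense numpy lookup table.

    Residues absent from the matrix alphabet score ``default_score``
    against everything (EMBOSS behaviour for unknown codes without a
    matrix row).
    """

    def __init__(self, alphabet: str, scores: np.ndarray, *, name: str = "custom",
                 default_score: float = -1.0):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score table shape does not match alphabet")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.alphabet = alphabet
        self.name = name
        self.default_score = float(default_score)
        # extra trailing row/column holds the default score for unknowns
        n = len(alphabet)
        table = np.full((n + 1, n + 1), self.default_score, dtype=float)
        table[:n, :n] = scores
        self._table = table
        self._index = np.full(128, n, dtype=np.intp)
        for i, ch in enumerate(alphabet):
            self._index[ord(ch)] = i

    @classmethod
    def from_biopython(cls, array, *, name: str = "custom",
                       default_score: float = -1.0) -> "SubstitutionMatrix":
        alphabet = "".join(array.alphabet)
        return cls(alphabet, np.asarray(array, dtype=float), name=name,
                   default_score=default_score)

    @classmethod
    def load(cls, name: str = "BLOSUM62", *, default_score: float = -1.0) -> "SubstitutionMatrix":
        """Load a named matrix shipped with Biopython (BLOSUM62, PAM250, ...)."""
        return cls.from_biopython(substitution_matrices.load(name.upper()),
                                  name=name.upper(), default_score=default_score)

    @classmethod
    def read(cls, path: str | Path, *, default_score: float = -1.0) -> "SubstitutionMatrix":
        """Read a matrix in NCBI/EMBOSS text format."""
        with open(path) as fh:
            array = substitution_matrices.read(fh)
        return cls.from_biopython(array, name=Path(path).stem, default_score=default_score)

    @classmethod
    def identity(cls, alphabet: str = "ACDEFGHIKLMNPQRSTVWY", match: float = 1.0,
                 mismatch: float = 0.0) -> "SubstitutionMatrix":
        n = len(alphabet)
        scores = np.full((n, n), mismatch, dtype=float)
        np.fill_diagonal(scores, match)
        return cls(alphabet, scores, name="identity")

    def encode(self, seq: str) -> np.ndarray:
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return self._index[codes]

    def score(self, a: str, b: str) -> float:
        return float(self._table[self._index[ord(a)], self._index[ord(b)]])

    def pair_scores(self, a: str, b: str) -> np.ndarray:
        """len(a) x len(b) table of pair scores."""
        return self._table[np.ix_(self.encode(a), self.encode(b))]


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap cost: a gap of length L costs ``open + L * extend``.

    Defaults mirror EMBOSS Needle for proteins (open 10.0, extend 0.5,
    terminal gaps unpenalised).
    """

    open: float = 10.0
    extend: float = 0.5
    penalize_end_gaps: bool = False

    def __post_init__(self):
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass(frozen=True)
class AlignmentResult:
    """One global alignment with its score and EMBOSS percent statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    alignment_length: int
    n_identical: int
    n_similar: int
    n_gap_positions: int
    pct_identity: float
    pct_similarity: float
    pct_gaps: float


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs, sequences upper-cased.

    Raises ``ValueError`` naming the file for an empty file or a file whose
    first non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}")
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _dp_matrices(sub: np.ndarray, gaps: GapPenalties):
    """Fill the Gotoh matrices M (match), F (gap in b / vertical) and
    E (gap in a / horizontal) for sequences of length m, n."""
    m, n = sub.shape
    go, ge = gaps.open, gaps.extend
    M = np.full((m + 1, n + 1), NEG_INF)
    E = np.full((m + 1, n + 1), NEG_INF)
    F = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    j = np.arange(1, n + 1, dtype=float)
    i = np.arange(1, m + 1, dtype=float)
    if gaps.penalize_end_gaps:
        E[0, 1:] = -(go + j * ge)
        F[1:, 0] = -(go + i * ge)
    else:
        E[0, 1:] = 0.0
        F[1:, 0] = 0.0
    jj = np.arange(n + 1, dtype=float)
    for r in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], E[r - 1]), F[r - 1])
        M[r, 1:] = prev_best[:-1] + sub[r - 1]
        F[r, 1:] = np.maximum(np.maximum(M[r - 1, 1:], E[r - 1, 1:]) - go,
                              F[r - 1, 1:]) - ge
        # horizontal state via prefix max; opening allowed from M or F,
        # extension folds into the running maximum of G[k] + k*extend
        G = np.maximum(M[r], F[r])
        run = np.maximum.accumulate(G + jj * ge)
        E[r, 1:] = -go + run[:-1] - jj[1:] * ge
    return M, E, F


def _choose_end(M, E, F, gaps: GapPenalties):
    """Pick the termination cell and state; with free end gaps the best score
    may sit anywhere on the last row/column, with trailing gaps appended."""
    m = M.shape[0] - 1
    n = M.shape[1] - 1

    def best_at(i, j):
        vals = (M[i, j], F[i, j], E[i, j])
        states = ("M", "F", "E")
        k = int(np.argmax(vals))
        # preference M > F > E on exact ties
        best = vals[k]
        for s, v in zip(states, vals):
            if v == best:
                return v, s
        return best, states[k]

    if gaps.penalize_end_gaps:
        v, s = best_at(m, n)
        return (m, n), s, v
    candidates = [(m, n)]
    candidates += [(i, n) for i in range(m - 1, -1, -1)]
    candidates += [(m, j) for j in range(n - 1, -1, -1)]
    best_cell, best_state, best_val = None, None, NEG_INF
    for (i, j) in candidates:
        v, s = best_at(i, j)
        if v > best_val:
            best_cell, best_state, best_val = (i, j), s, v
    return best_cell, best_state, best_val


def _traceback(a: str, b: str, sub: np.ndarray, M, E, F, cell, state,
               gaps: GapPenalties) -> tuple[str, str]:
    go, ge = gaps.open, gaps.extend
    i, j = cell
    m, n = len(a), len(b)
    cols_a: list[str] = []
    cols_b: list[str] = []
    # trailing free end gaps
    cols_a.extend("-" * (n - j))
    cols_b.extend(reversed(b[j:]))
    cols_a.extend(reversed(a[i:]))
    cols_b.extend("-" * (m - i))

    def close(x, y):
        return abs(x - y) <= 1e-9 or (x == y)

    while i > 0 or j > 0:
        if i == 0:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            continue
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j]), ("F", F[i, j]), ("E", E[i, j])):
                if close(v, target):
                    state = s
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M state")
        elif state == "F":  # gap in b, consume a
            cols_a.append(a[i - 1])
            cols_b.append("-")
            target = F[i, j] + ge
            i -= 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j] - go), ("F", F[i, j]), ("E", E[i, j] - go)):
                if close(v, target):
                    state = s
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in F state")
        else:  # E: gap in a, consume b
            cols_a.append("-")
            cols_b.append(b[j - 1])
            target = E[i, j] + ge
            j -= 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j] - go), ("F", F[i, j] - go), ("E", E[i, j])):
                if close(v, target):
                    state = s
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in E state")
    return "".join(reversed(cols_a)), "".join(reversed(cols_b))


def needleman_wunsch(a: str, b: str, matrix: SubstitutionMatrix | None = None,
                     gaps: GapPenalties | None = None) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Parameters
    ----------
    a, b : str
        Ungapped sequences (non-empty).
    matrix : SubstitutionMatrix, optional
        Defaults to BLOSUM62.
    gaps : GapPenalties, optional
        Defaults to open 10.0 / extend 0.5 with free terminal gaps, the
        EMBOSS Needle protein defaults.

    Ties in the traceback are broken by preferring a match/mismatch column,
    then a gap in the second sequence, then a gap in the first.  Distinct
    co-optimal alignments can differ in length (and hence in percent
    statistics), so the computation runs on a canonical argument order
    (lexicographically smaller sequence first) and swaps the gapped strings
    back: score and all percent statistics are therefore symmetric in the
    argument order.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = matrix if matrix is not None else SubstitutionMatrix.load("BLOSUM62")
    gaps = gaps if gaps is not None else GapPenalties()
    a, b = a.upper(), b.upper()
    if not (a.isascii() and b.isascii()):
        raise ValueError("sequences must be ASCII residue strings")
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    sub = matrix.pair_scores(x, y)
    M, E, F = _dp_matrices(sub, gaps)
    cell, state, score = _choose_end(M, E, F, gaps)
    aligned_x, aligned_y = _traceback(x, y, sub, M, E, F, cell, state, gaps)
    if swapped:
        aligned_x, aligned_y = aligned_y, aligned_x
    return _finalise(aligned_x, aligned_y, float(score), matrix)


def _finalise(aligned_a: str, aligned_b: str, score: float,
              matrix: SubstitutionMatrix) -> AlignmentResult:
    length = len(aligned_a)
    n_ident = n_sim = n_gap = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            n_gap += 1
            continue
        identical = x == y
        if identical:
            n_ident += 1
        if identical or matrix.score(x, y) > 0:
            n_sim += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        alignment_length=length,
        n_identical=n_ident,
        n_similar=n_sim,
        n_gap_positions=n_gap,
        pct_identity=100.0 * n_ident / length,
        pct_similarity=100.0 * n_sim / length,
        pct_gaps=100.0 * n_gap / length,
    )


def percent_stats(result: AlignmentResult) -> tuple[float, float, float]:
    """Return ``(pct_identity, pct_similarity, pct_gaps)`` of an alignment.

    Identity counts columns with equal residues; similarity counts columns
    whose pair scores positively under the matrix (identities included); gap
    columns are never similar.  Denominator is the full alignment length,
    terminal gaps included — the convention of EMBOSS Needle's report.
    """
    return result.pct_identity, result.pct_similarity, result.pct_gaps


def format_alignment(result: AlignmentResult, name_a: str = "a", name_b: str = "b",
                     width: int = 60) -> str:
    """EMBOSS-like block rendering of an alignment (for CLI output)."""
    lines = [
        f"# Length: {result.alignment_length}",
        f"# Identity: {result.n_identical}/{result.alignment_length} ({result.pct_identity:.1f}%)",
        f"# Similarity: {result.n_similar}/{result.alignment_length} ({result.pct_similarity:.1f}%)",
        f"# Gaps: {result.n_gap_positions}/{result.alignment_length} ({result.pct_gaps:.1f}%)",
        f"# Score: {result.score:.1f}",
        "",
    ]
    for i in range(0, result.alignment_length, width):
        sa = result.aligned_a[i:i + width]
        sb = result.aligned_b[i:i + width]
        mid = "".join("|" if x == y and x != "-" else
                      ("." if x != "-" and y != "-" else " ")
                      for x, y in zip(sa, sb))
        lines += [f"{name_a:<10} {sa}", f"{'':<10} {mid}", f"{name_b:<10} {sb}", ""]
    return "\n".join(lines)
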