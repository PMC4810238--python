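"""Raw alignment scores and normalized similarity.

The clustering is driven by the *normalized similarity*

    s(p, q) = 2 * s0(p, q) / (s0(p, p) + s0(q, q))

where s0 is the raw (unnormalized) local-alignment score.  It equals 1 for
identical proteins.  Raw scores come either from an external all-vs-all
search in tabular format (the raw score, not the bit score, is used) or
from the built-in Smith–Waterman scorer (BLOSUM62, affine gaps with
open 11 / extend 1 in the usual search-tool convention: a gap of length k
costs 11 + k).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

from .io import Proteome, ProteinRecord

__all__ = [
    "AlgorithmParams",
    "RawScoreTable",
    "normalized_similarity",
    "BuiltinScorer",
    "builtin_raw_score",
    "builtin_expect",
    "compute_scores",
    "parse_search_tabular",
    "write_scores",
    "load_scores",
]

log = logging.getLogger("plastclust")

# Karlin–Altschul parameters for gapped BLOSUM62 with open 11 / extend 1,
# used to attach a stand-in expect value to built-in scores (search space
# taken as the product of the two sequence lengths).
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class AlgorithmParams:
    """Clustering parameters.

    H: partition threshold on normalized similarity — trees whose minimum
       edge falls below H are candidates for splitting.
    E: expect-value threshold for base-graph edges.
    L: floor on normalized similarity for sparse-graph edges.
    scorer: ``builtin_local`` (Smith–Waterman BLOSUM62/11/1) or
       ``external_tabular`` (raw scores parsed from search output).

    Defaults: H = 0.60, E = 0.001, L = 0.
    """

    H: float = 0.60
    E: float = 0.001
    L: float = 0.0
    scorer: str = "builtin_local"

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise ValueError(f"H must be in [0, 1], got {self.H}")
        if self.E <= 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")
        if self.scorer not in ("builtin_local", "external_tabular"):
            raise ValueError(f"unknown scorer {self.scorer!r}")


def normalized_similarity(s0_pair: float, s0_self1: float, s0_self2: float) -> float:
    """2·s0(p,q) / (s0(p,p) + s0(q,q)); peaks at 1 for identical proteins."""
    if s0_self1 <= 0 or s0_self2 <= 0:
        raise ValueError(
            f"self scores must be positive, got {s0_self1} and {s0_self2}"
        )
    if s0_pair < 0:
        raise ValueError(f"pair score must be non-negative, got {s0_pair}")
    return 2.0 * s0_pair / (s0_self1 + s0_self2)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class RawScoreTable:
    """Symmetric store of raw scores and expect values for protein pairs.

    ``entries`` maps the sorted id pair to ``(raw_score, expect)``;
    ``self_scores`` maps each protein id to its self-comparison raw score.
    ``n_dropped_no_self`` counts pairs discarded because one endpoint had
    no self-hit (normalization would be undefined).
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    self_scores: dict[str, float] = field(default_factory=dict)
    n_dropped_no_self: int = 0

    def add_pair(self, a: str, b: str, raw: float, expect: float) -> None:
        if a == b:
            raise ValueError("use add_self for self comparisons")
        key = _pair_key(a, b)
        prev = self.entries.get(key)
        if prev is None:
            self.entries[key] = (raw, expect)
        else:
            # keep the best raw score; expect = minimum of the directions
            self.entries[key] = (max(prev[0], raw), min(prev[1], expect))

    def add_self(self, a: str, raw: float) -> None:
        if raw <= 0:
            raise ValueError(f"self score for {a!r} must be positive, got {raw}")
        self.self_scores[a] = max(raw, self.self_scores.get(a, 0.0))

    def get(self, a: str, b: str) -> tuple[float, float] | None:
        return self.entries.get(_pair_key(a, b))

    def similarity(self, a: str, b: str) -> float:
        """Normalized similarity of a stored pair."""
        raw, _ = self.entries[_pair_key(a, b)]
        return normalized_similarity(raw, self.self_scores[a], self.self_scores[b])

    def drop_pairs_without_self_scores(self) -> int:
        """Remove pairs whose endpoints lack a self score; return the count."""
        bad = [
            k
            for k in self.entries
            if k[0] not in self.self_scores or k[1] not in self.self_scores
        ]
        for k in bad:
            del self.entries[k]
        self.n_dropped_no_self += len(bad)
        if bad:
            log.warning("dropped %d pairs lacking a self-hit", len(bad))
        return len(bad)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Built-in Smith–Waterman scorer
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = set(_BLOSUM62.alphabet)


def _sanitize(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet: U→C, anything else→X."""
    out = []
    for c in seq.upper():
        if c in _MATRIX_ALPHABET and c != "*":
            out.append(c)
        elif c == "U":
            out.append("C")
        else:
            out.append("X")
    return "".join(out)


class BuiltinScorer:
    """Smith–Waterman local alignment raw score (BLOSUM62, gaps 11/1).

    A gap of length k costs 11 + k, matching default protein-search
    settings; selenocysteine (U) is scored as cysteine and any residue
    outside the matrix alphabet as X.
    """

    def __init__(self) -> None:
        self._aligner = PairwiseAligner(
            substitution_matrix=_BLOSUM62,
            mode="local",
            open_gap_score=-12.0,
            extend_gap_score=-1.0,
        )

    def raw_score(self, seq1: str, seq2: str) -> float:
        return float(self._aligner.score(_sanitize(seq1), _sanitize(seq2)))


_default_scorer: BuiltinScorer | None = None


def builtin_raw_score(p1: ProteinRecord | str, p2: ProteinRecord | str) -> float:
    """Raw score of two proteins (or raw sequences) under the builtin scorer."""
    global _default_scorer
    if _default_scorer is None:
        _default_scorer = BuiltinScorer()
    s1 = p1.sequence if isinstance(p1, ProteinRecord) else p1
    s2 = p2.sequence if isinstance(p2, ProteinRecord) else p2
    return _default_scorer.raw_score(s1, s2)


def builtin_expect(raw: float, len1: int, len2: int) -> float:
    """Karlin–Altschul expect value for a builtin raw score.

    E = K·m·n·exp(−λ·S) with the gapped BLOSUM62/11/1 constants and the
    product of the sequence lengths as search space.  A stand-in for a real
    search tool's database-wide statistics, adequate for thresholding.
    """
    return _KA_K * len1 * len2 * math.exp(-_KA_LAMBDA * raw)


def compute_scores(proteomes: Iterable[Proteome]) -> RawScoreTable:
    """All-vs-all raw scores with the builtin scorer.

    Every self score is computed; a non-self pair is stored only when its
    local-alignment score is positive (no local alignment ⇒ no hit).
    """
    scorer = BuiltinScorer()
    proteins = [p for pm in proteomes for p in pm]
    table = RawScoreTable()
    seqs = {p.protein_id: _sanitize(p.sequence) for p in proteins}
    for p in proteins:
        table.add_self(p.protein_id, scorer.raw_score(p.sequence, p.sequence))
    n = len(proteins)
    for i in range(n):
        pi = proteins[i]
        si = seqs[pi.protein_id]
        for j in range(i + 1, n):
            pj = proteins[j]
            raw = float(scorer._aligner.score(si, seqs[pj.protein_id]))
            if raw > 0:
                expect = builtin_expect(raw, len(si), len(seqs[pj.protein_id]))
                table.add_pair(pi.protein_id, pj.protein_id, raw, expect)
    return table


# ---------------------------------------------------------------------------
# External tabular search output
# ---------------------------------------------------------------------------

def parse_search_tabular(
    path: str | Path,
    id_map: Mapping[str, str],
    evalue_column: int = 10,
    score_column: int = 12,
    delimiter: str = "\t",
) -> RawScoreTable:
    """Parse all-vs-all tabular search output into a :class:`RawScoreTable`.

    Column indices are 0-based; the defaults fit the common 12-column
    tabular layout extended with a raw-score column appended as column 13
    (index 12).  ``id_map`` translates the search tool's sequence ids to
    global protein ids; every id must resolve.

    Per ordered query/subject pair the single best (highest raw score) hit
    is kept; the two directions are symmetrized by taking the maximum raw
    score and the minimum expect.  Self-hits populate the self scores.
    Pairs for which either endpoint lacks a self-hit are dropped (counted
    in ``n_dropped_no_self``).
    """
    table = RawScoreTable()
    best: dict[tuple[str, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split(delimiter)
            if len(cols) <= max(evalue_column, score_column):
                raise ValueError(
                    f"{path}:{lineno}: expected at least "
                    f"{max(evalue_column, score_column) + 1} columns, got {len(cols)}"
                )
            q_raw, s_raw = cols[0], cols[1]
            try:
                q, s = id_map[q_raw], id_map[s_raw]
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unresolvable sequence id {exc.args[0]!r}"
                ) from None
            try:
                expect = float(cols[evalue_column])
                raw = float(cols[score_column])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric expect/raw-score field"
                ) from None
            key = (q, s)
            prev = best.get(key)
            if prev is None or raw > prev[0]:
                best[key] = (raw, expect)
    for (q, s), (raw, expect) in best.items():
        if q == s:
            table.add_self(q, raw)
    for (q, s), (raw, expect) in best.items():
        if q != s:
            table.add_pair(q, s, raw, expect)
    table.drop_pairs_without_self_scores()
    return table


# ---------------------------------------------------------------------------
# Score-table persistence (intermediate TSV)
# ---------------------------------------------------------------------------

def write_scores(table: RawScoreTable, path: str | Path) -> None:
    """Persist a score table as TSV (self scores are rows with equal ids)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\traw_score\texpect\n")
        for pid in sorted(table.self_scores):
            fh.write(f"{pid}\t{pid}\t{table.self_scores[pid]:g}\t0\n")
        for (a, b) in sorted(table.entries):
            raw, expect = table.entries[(a, b)]
            fh.write(f"{a}\t{b}\t{raw:g}\t{expect:g}\n")


def load_scores(path: str | Path) -> RawScoreTable:
    """Load a score table written by :func:`write_scores`."""
    table = RawScoreTable()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein1"):
            raise ValueError(f"{path}: not a score table")
        for line in fh:
            a, b, raw, expect = line.rstrip("\n").split("\t")
            if a == b:
                table.add_self(a, float(raw))
            else:
                table.add_pair(a, b, float(raw), float(expect))
    table.drop_pairs_without_self_scores()
    return table
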