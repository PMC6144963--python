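"""Semiglobal pairwise identity between amplicon inserts and barcode references.

Identity is the criterion used for direct taxonomic assignment (default
threshold 0.97) and for OTU clustering/profiling.  The alignment is
semiglobal: terminal gaps on the *reference* are free, so a short insert
contained in a full-length barcode scores 1.0 when identical.  Identity is
matches / aligned columns, where the aligned span excludes the free
terminal gaps.
"""

from __future__ import annotations

import math
import re

import edlib

from .primers import IUPAC_SETS, is_iupac

# let degenerate reference bases count as matches to their expansions
_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_SETS.items()
    if len(bases) > 1
    for base in bases
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    if not is_iupac(seq):
        bad = sorted({c for c in seq.upper() if c not in IUPAC_SETS})
        raise ValueError(f"{what} contains non-IUPAC characters: {bad}")


def _identity_from_result(res: dict) -> float:
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (cols - res["editDistance"]) / cols


def pairwise_identity(query: str, reference: str) -> float:
    """Fraction of matching columns in the best semiglobal alignment.

    Raises ``ValueError`` for empty or non-IUPAC input.
    """
    _check_dna(query, "query")
    _check_dna(reference, "reference")
    res = edlib.align(
        query.upper(), reference.upper(), mode="HW", task="path",
        additionalEqualities=_EQUALITIES,
    )
    return _identity_from_result(res)


def max_edit_distance(query_len: int, min_identity: float) -> int:
    """Edit-distance band guaranteeing no alignment at >= min_identity is missed.

    identity = (cols - d)/cols with cols <= len(query) + d, so any hit at
    identity >= t satisfies d <= (1 - t) * L / t.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    return int(math.floor((1.0 - min_identity) * query_len / min_identity)) + 1


def banded_distance(query: str, reference: str, k: int) -> int:
    """Edit distance if <= k, else -1 (edlib early exit)."""
    return edlib.align(
        query.upper(), reference.upper(), mode="HW", task="distance", k=k,
        additionalEqualities=_EQUALITIES,
    )["editDistance"]


class ReferenceIndex:
    """Pigeonhole substring index for banded search against a reference set.

    If a query is within k edits of a reference, then splitting the query
    into k+1 contiguous pieces leaves at least one piece untouched, and
    that piece occurs verbatim somewhere in the reference.  Candidate
    references are therefore the union of exact-substring hits over the
    pieces; alignment is only run on candidates.  The filter is exact (no
    missed hits within the band).
    """

    def __init__(self, references: list[tuple[str, str]]):
        self.references = [(lab, seq.upper()) for lab, seq in references]
        # references with degenerate bases can't be exact-substring filtered
        self._always = [i for i, (_, s) in enumerate(self.references)
                        if any(c not in "ACGT" for c in s)]
        self._by_piece_len: dict[int, dict[str, list[int]]] = {}

    def _index(self, plen: int) -> dict[str, list[int]]:
        idx = self._by_piece_len.get(plen)
        if idx is None:
            idx = {}
            for i, (_, seq) in enumerate(self.references):
                seen = set()
                for s in range(len(seq) - plen + 1):
                    piece = seq[s: s + plen]
                    if piece not in seen:
                        idx.setdefault(piece, []).append(i)
                        seen.add(piece)
            self._by_piece_len[plen] = idx
        return idx

    def candidates(self, query: str, k: int) -> list[int] | None:
        """Reference indices possibly within k edits; None = filter unusable."""
        L = len(query)
        n_pieces = k + 1
        if L // n_pieces < 8:  # pieces too short to discriminate
            return None
        bounds = [round(j * L / n_pieces) for j in range(n_pieces + 1)]
        hits: set[int] = set(self._always)
        for a, b in zip(bounds, bounds[1:]):
            piece = query[a:b]
            hits.update(self._index(b - a).get(piece, ()))
        return sorted(hits)


def best_hits(
    query: str,
    references: list[tuple[str, str]],
    min_identity: float = 0.80,
    index: ReferenceIndex | None = None,
) -> tuple[float, list[int]]:
    """Best identity of ``query`` against labelled references.

    Parameters
    ----------
    references
        list of (label, sequence); labels need not be unique (several
        records may carry the same species).
    min_identity
        reporting floor — hits below it are ignored (keeps the edlib band
        narrow).

    Returns
    -------
    (best_identity, indices) where ``indices`` are the reference positions
    attaining the best identity; ``(0.0, [])`` when nothing reaches the
    floor.
    """
    _check_dna(query, "query")
    q = query.upper()
    k = max_edit_distance(len(q), min_identity)
    scan = range(len(references))
    if index is not None:
        cands = index.candidates(q, k)
        if cands is not None:
            scan = cands
    dmin = k + 1
    cand: list[int] = []
    for i in scan:
        d = edlib.align(q, references[i][1].upper(), mode="HW", task="distance",
                        k=dmin, additionalEqualities=_EQUALITIES)["editDistance"]
        if d < 0:
            continue
        if d < dmin:
            dmin, cand = d, [i]
        elif d == dmin:
            cand.append(i)
    if not cand:
        return 0.0, []
    # resolve exact identities (column counts) only for the minimal-distance set
    idents = []
    for i in cand:
        res = edlib.align(q, references[i][1].upper(), mode="HW", task="path",
                          additionalEqualities=_EQUALITIES)
        idents.append(_identity_from_result(res))
    best = max(idents)
    if best < min_identity:
        return 0.0, []
    winners = [i for i, ident in zip(cand, idents) if abs(ident - best) < 1e-12]
    return best, winners
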