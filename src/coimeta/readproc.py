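"""Quality trimming, pair merging and degenerate-primer amplicon splitting.

The stage chain mirrors a standard amplicon pipeline: sliding-window
quality trim, overlap-merge of each mate pair (minimum overlap 30 nt,
consensus takes the higher-quality base), then anchored IUPAC-aware primer
identification at both ends of the merged read.  A merged read is kept
only when the forward primer and the reverse-complemented reverse primer
of the *same* marker are found and the primer-stripped insert is at least
270 nt.

Scalar functions (`quality_trim`, `merge_pair`, `split_read`) are the
readable reference implementations; the `*_batch` variants are vectorized
over uniform-length read matrices and are what the pipeline uses.  Both
routes are tested against each other.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .primers import PrimerDefinition, mismatch_count, primer_bits, read_bits

DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_MISMATCH_FRAC = 0.25
DEFAULT_MIN_INSERT_LEN = 270

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMP_LUT[a] = b


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    quality: np.ndarray
    overlap_len: int
    n_overlap_mismatches: int
    marker_id: str | None = None
    insert_seq: str | None = None


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------

def quality_trim(
    quality: np.ndarray,
    window_len: int = 4,
    mean_q_threshold: float = 20.0,
    min_len: int = 100,
) -> int:
    """Return the kept prefix length (0 = discard).

    The read is cut where the first ``window_len`` sliding window has mean
    quality below threshold; bases after the cut point are kept one by one
    while they individually stay at or above the threshold (the behaviour
    of the conventional sliding-window trimmer).  Reads shorter than
    ``min_len`` after trimming are discarded.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    q = np.asarray(quality, dtype=float)
    n = q.size
    if n >= window_len:
        means = np.convolve(q, np.ones(window_len), mode="valid") / window_len
        fail = np.flatnonzero(means < mean_q_threshold)
        if fail.size:
            cut = int(fail[0])
            while cut < n and q[cut] >= mean_q_threshold:
                cut += 1
            n = cut
    return n if n >= min_len else 0


def quality_trim_batch(
    quals: np.ndarray,
    window_len: int = 4,
    mean_q_threshold: float = 20.0,
    min_len: int = 100,
) -> np.ndarray:
    """Vectorized `quality_trim` over an (n_reads, read_len) matrix."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    q = np.asarray(quals, dtype=float)
    n_reads, L = q.shape
    if L < window_len:
        lens = np.full(n_reads, L)
    else:
        csum = np.concatenate(
            [np.zeros((n_reads, 1)), np.cumsum(q, axis=1)], axis=1
        )
        means = (csum[:, window_len:] - csum[:, :-window_len]) / window_len
        failing = means < mean_q_threshold
        any_fail = failing.any(axis=1)
        first = np.where(any_fail, failing.argmax(axis=1), L)
        lens = first.copy()
        # extend past the window start over individually good bases; a failing
        # window always contains a base below threshold, so <= window_len steps
        for _ in range(window_len):
            can = (lens < L) & any_fail
            good = np.zeros(n_reads, dtype=bool)
            good[can] = q[np.flatnonzero(can), lens[can]] >= mean_q_threshold
            if not good.any():
                break
            lens[good] += 1
    return np.where(lens >= min_len, lens, 0)


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

def merge_pair(
    fwd_seq: str,
    fwd_qual: np.ndarray,
    rev_seq: str,
    rev_qual: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    read_id: str = "",
) -> MergedRead | None:
    """Merge one mate pair; None when no overlap >= min_overlap qualifies.

    The reverse mate is reverse-complemented; among overlaps of at least
    ``min_overlap`` the one minimizing the mismatch fraction wins, ties
    going to the longer overlap.  At overlap mismatches the consensus
    takes the base with the higher quality (the forward base on quality
    ties).
    """
    if not fwd_seq or not rev_seq:
        raise ValueError("zero-length mate")
    f = np.frombuffer(fwd_seq.upper().encode(), dtype=np.uint8)
    r = np.frombuffer(rev_seq.upper().encode(), dtype=np.uint8)
    rc = _COMP_LUT[r[::-1]]
    rcq = np.asarray(rev_qual)[::-1]
    fq = np.asarray(fwd_qual)
    lf, lr = f.size, rc.size

    best = None  # (frac, -overlap, overlap, mismatches)
    for o in range(min_overlap, min(lf, lr) + 1):
        mm = int(np.count_nonzero(f[lf - o:] != rc[:o]))
        frac = mm / o
        if frac > max_mismatch_frac:
            continue
        key = (frac, -o)
        if best is None or key < best[0]:
            best = (key, o, mm)
    if best is None:
        return None
    _, o, mm = best

    head_s, head_q = f[: lf - o], fq[: lf - o]
    tail_s, tail_q = rc[o:], rcq[o:]
    ov_f, ov_r = f[lf - o:], rc[:o]
    ovq_f, ovq_r = fq[lf - o:], rcq[:o]
    take_rev = ov_r != ov_f
    take_rev &= ovq_r > ovq_f
    ov_s = np.where(take_rev, ov_r, ov_f)
    ov_q = np.maximum(ovq_f, ovq_r)
    seq = np.concatenate([head_s, ov_s, tail_s])
    qual = np.concatenate([head_q, ov_q, tail_q])
    return MergedRead(read_id, seq.tobytes().decode("ascii"), qual, o, mm)


def merge_batch(
    fwd_seq: np.ndarray,
    rev_seq: np.ndarray,
    fwd_qual: np.ndarray,
    rev_qual: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[np.ndarray | None], np.ndarray, np.ndarray]:
    """Vectorized merge over uniform-length read matrices.

    Parameters are (n, L) uint8 ASCII matrices; quality may be (L,) shared
    or (n, L).  Returns (merged sequences as list of uint8 arrays or None,
    overlap lengths (0 = unmerged), mismatch counts).
    """
    f = np.asarray(fwd_seq)
    rc = _COMP_LUT[np.asarray(rev_seq)[:, ::-1]]
    n, lf = f.shape
    lr = rc.shape[1]
    fq = np.broadcast_to(np.asarray(fwd_qual), f.shape)
    rcq = np.broadcast_to(np.asarray(rev_qual), rev_seq.shape)[:, ::-1]

    best_key_frac = np.full(n, np.inf)
    best_o = np.zeros(n, dtype=np.int64)
    best_mm = np.zeros(n, dtype=np.int64)
    for o in range(min_overlap, min(lf, lr) + 1):
        mm = np.count_nonzero(f[:, lf - o:] != rc[:, :o], axis=1)
        frac = mm / o
        ok = frac <= max_mismatch_frac
        better = ok & (frac <= best_key_frac)  # <= prefers longer overlap on ties
        best_key_frac[better] = frac[better]
        best_o[better] = o
        best_mm[better] = mm[better]

    merged: list[np.ndarray | None] = [None] * n
    for o in np.unique(best_o):
        if o == 0:
            continue
        sel = np.flatnonzero(best_o == o)
        head = f[sel, : lf - o]
        tail = rc[sel, o:]
        ov_f, ov_r = f[sel, lf - o:], rc[sel, :o]
        qf, qr = fq[sel, lf - o:], rcq[sel, :o]
        take_rev = (ov_r != ov_f) & (qr > qf)
        ov = np.where(take_rev, ov_r, ov_f)
        block = np.concatenate([head, ov, tail], axis=1)
        for k, i in enumerate(sel):
            merged[i] = block[k]
    return merged, best_o, best_mm


# ---------------------------------------------------------------------------
# primer splitting
# ---------------------------------------------------------------------------

def _anchored_match(
    seq_bits: np.ndarray, pbits: np.ndarray, max_mm: int, slack: int, at_end: bool
) -> int | None:
    """Offset of the best anchored primer match within ±slack, else None."""
    L, k = seq_bits.size, pbits.size
    best = None
    for off in range(0, slack + 1):
        if at_end:
            s = L - k - off
            if s < 0:
                continue
            window = seq_bits[s: s + k]
        else:
            if off + k > L:
                continue
            window = seq_bits[off: off + k]
        mm = int(mismatch_count(pbits, window))
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (off, mm)
    return best[0] if best else None


def split_read(
    merged_seq: str,
    primer_defs: dict[str, PrimerDefinition],
    max_mismatches: int = 0,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    slack: int = 2,
    strict_n: bool = True,
) -> tuple[str | None, str | None, str]:
    """Assign one merged read to a marker and strip its primers.

    Returns (marker_id, insert_seq, status) with status one of
    ``assigned``, ``no_primer``, ``ambiguous_marker``, ``too_short``.
    Both the forward primer (5' end) and the reverse-complemented reverse
    primer (3' end) must match the same marker within ``max_mismatches``
    under IUPAC-aware comparison, anchored with ±``slack`` nt.
    """
    if not primer_defs:
        raise ValueError("primer_defs is empty")
    sb = read_bits(
        np.frombuffer(merged_seq.upper().encode(), dtype=np.uint8), strict_n=strict_n
    )
    fwd_hits, rev_hits, complete = {}, {}, []
    for mid, pdef in primer_defs.items():
        fo = _anchored_match(sb, primer_bits(pdef.forward_seq), max_mismatches,
                             slack, at_end=False)
        ro = _anchored_match(sb, primer_bits(pdef.reverse_rc), max_mismatches,
                             slack, at_end=True)
        if fo is not None:
            fwd_hits[mid] = fo
        if ro is not None:
            rev_hits[mid] = ro
        if fo is not None and ro is not None:
            complete.append((mid, fo, ro))
    if len(complete) > 1:
        return None, None, "ambiguous_marker"
    if not complete:
        if fwd_hits and rev_hits and set(fwd_hits) != set(rev_hits):
            return None, None, "ambiguous_marker"
        return None, None, "no_primer"
    mid, fo, ro = complete[0]
    pdef = primer_defs[mid]
    start = fo + len(pdef.forward_seq)
    end = len(merged_seq) - len(pdef.reverse_seq) - ro
    insert = merged_seq[start:end].upper()
    if len(insert) < min_insert_len:
        return mid, None, "too_short"
    return mid, insert, "assigned"


def split_batch(
    merged: list[np.ndarray | None],
    primer_defs: dict[str, PrimerDefinition],
    max_mismatches: int = 0,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    slack: int = 2,
    strict_n: bool = True,
) -> tuple[list[str | None], list[str | None], list[str]]:
    """Vectorized primer split, grouping merged reads by length.

    ``None`` entries (unmerged pairs) pass through with status
    ``unmerged``.  Returns (markers, inserts, statuses) aligned with the
    input list.
    """
    n = len(merged)
    markers: list[str | None] = [None] * n
    inserts: list[str | None] = [None] * n
    status: list[str] = ["unmerged"] * n

    by_len: dict[int, list[int]] = {}
    for i, seq in enumerate(merged):
        if seq is not None:
            by_len.setdefault(len(seq), []).append(i)

    pinfo = {
        mid: (primer_bits(p.forward_seq), primer_bits(p.reverse_rc),
              len(p.forward_seq), len(p.reverse_seq))
        for mid, p in primer_defs.items()
    }
    for L, idx in by_len.items():
        block = np.vstack([merged[i] for i in idx])
        bits = read_bits(block, strict_n=strict_n)
        m = len(idx)
        fwd_off = {mid: np.full(m, -1) for mid in primer_defs}
        rev_off = {mid: np.full(m, -1) for mid in primer_defs}
        for mid, (fb, rb, lf, lr) in pinfo.items():
            best_f = np.full(m, np.iinfo(np.int64).max)
            best_r = np.full(m, np.iinfo(np.int64).max)
            for off in range(slack + 1):
                if off + lf <= L:
                    mm = mismatch_count(fb, bits[:, off: off + lf])
                    hit = (mm <= max_mismatches) & (mm < best_f)
                    fwd_off[mid][hit] = off
                    best_f = np.minimum(best_f, np.where(mm <= max_mismatches, mm,
                                                         best_f))
                s = L - lr - off
                if s >= 0:
                    mm = mismatch_count(rb, bits[:, s: s + lr])
                    hit = (mm <= max_mismatches) & (mm < best_r)
                    rev_off[mid][hit] = off
                    best_r = np.minimum(best_r, np.where(mm <= max_mismatches, mm,
                                                         best_r))
        mids = list(primer_defs)
        comp = np.stack([(fwd_off[mid] >= 0) & (rev_off[mid] >= 0) for mid in mids])
        any_f = np.stack([fwd_off[mid] >= 0 for mid in mids]).any(axis=0)
        any_r = np.stack([rev_off[mid] >= 0 for mid in mids]).any(axis=0)
        n_complete = comp.sum(axis=0)
        for k, i in enumerate(idx):
            if n_complete[k] > 1:
                status[i] = "ambiguous_marker"
            elif n_complete[k] == 0:
                mixed = any_f[k] and any_r[k] and not any(
                    (fwd_off[mid][k] >= 0) and (rev_off[mid][k] >= 0) for mid in mids
                ) and {mid for mid in mids if fwd_off[mid][k] >= 0} != {
                    mid for mid in mids if rev_off[mid][k] >= 0
                }
                status[i] = "ambiguous_marker" if mixed else "no_primer"
            else:
                mid = mids[int(np.argmax(comp[:, k]))]
                fb, rb, lf, lr = pinfo[mid]
                s = int(fwd_off[mid][k]) + lf
                e = L - lr - int(rev_off[mid][k])
                ins = block[k, s:e].tobytes().decode("ascii")
                if len(ins) < min_insert_len:
                    markers[i] = mid
                    status[i] = "too_short"
                else:
                    markers[i] = mid
                    inserts[i] = ins
                    status[i] = "assigned"
    return markers, inserts, status


# ---------------------------------------------------------------------------
# FASTQ IO and the per-sample stage driver
# ---------------------------------------------------------------------------

def read_fastq_pair(path_r1, path_r2) -> tuple[list[str], np.ndarray, np.ndarray,
                                               np.ndarray, np.ndarray]:
    """Load a gzipped (or plain) FASTQ mate pair into uniform-length arrays.

    Raises ValueError naming the record for malformed input.  Reads must
    share one length per file (the synthetic generator guarantees this).
    """
    def load(path):
        opener = gzip.open if str(path).endswith(".gz") else open
        ids, seqs, quals = [], [], []
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                plus = fh.readline()
                qual = fh.readline().rstrip("\n")
                if not header.startswith("@") or not plus.startswith("+") \
                        or len(seq) != len(qual) or not seq:
                    raise ValueError(f"malformed FASTQ record {header.strip()!r} in {path}")
                rid = header[1:].split()[0]
                if rid.endswith(("/1", "/2")):
                    rid = rid[:-2]
                ids.append(rid)
                seqs.append(seq)
                quals.append(qual)
        if not seqs:  # a negative control can legitimately be empty
            return ids, np.zeros((0, 0), dtype=np.uint8), np.zeros((0, 0), dtype=np.uint8)
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError(f"variable read lengths in {path}")
        smat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
        qmat = np.vstack([
            np.frombuffer(q.encode(), dtype=np.uint8) - 33 for q in quals
        ])
        return ids, smat, qmat

    ids1, s1, q1 = load(path_r1)
    ids2, s2, q2 = load(path_r2)
    if len(ids1) != len(ids2):
        raise ValueError("mate files differ in read count")
    return ids1, s1, q1, s2, q2


@dataclass
class StageCounts:
    """Per-sample read-fate bookkeeping; the partition invariant is
    input = assigned(COI1)+assigned(COI2)+rejected+unmerged."""

    n_input: int
    n_trim_discarded: int
    n_unmerged: int
    n_no_primer: int
    n_ambiguous: int
    n_too_short: int
    n_assigned: dict

    def check_partition(self) -> bool:
        return self.n_input == (
            self.n_trim_discarded + self.n_unmerged + self.n_no_primer
            + self.n_ambiguous + self.n_too_short + sum(self.n_assigned.values())
        )


def process_sample(
    fwd_seq: np.ndarray,
    rev_seq: np.ndarray,
    fwd_qual: np.ndarray,
    rev_qual: np.ndarray,
    primer_defs: dict[str, PrimerDefinition],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    primer_mismatches: int = 0,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    trim_window: int = 4,
    trim_threshold: float = 20.0,
    trim_min_len: int = 100,
) -> tuple[dict[str, Counter], StageCounts]:
    """Trim → merge → split one sample; returns per-marker insert Counters.

    Trimming is applied as a read-pair filter: pairs where either mate
    would be trimmed below ``trim_min_len`` are discarded whole (merging
    requires full-length mates in this amplicon setting).
    """
    n = fwd_seq.shape[0]
    counts = {mid: Counter() for mid in primer_defs}
    if n == 0:
        return counts, StageCounts(0, 0, 0, 0, 0, 0,
                                   {mid: 0 for mid in primer_defs})
    fq = np.broadcast_to(np.asarray(fwd_qual), fwd_seq.shape)
    rq = np.broadcast_to(np.asarray(rev_qual), rev_seq.shape)
    keep_f = quality_trim_batch(fq, trim_window, trim_threshold, trim_min_len)
    keep_r = quality_trim_batch(rq, trim_window, trim_threshold, trim_min_len)
    full = (keep_f == fwd_seq.shape[1]) & (keep_r == rev_seq.shape[1])
    n_trim = int(n - full.sum())

    merged, overlaps, _ = merge_batch(
        fwd_seq[full], rev_seq[full], fq[full], rq[full],
        min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
    )
    markers, inserts, status = split_batch(
        merged, primer_defs, max_mismatches=primer_mismatches,
        min_insert_len=min_insert_len,
    )
    tall = Counter(status)
    for mid, ins, st in zip(markers, inserts, status):
        if st == "assigned":
            counts[mid][ins] += 1
    sc = StageCounts(
        n_input=n,
        n_trim_discarded=n_trim,
        n_unmerged=tall.get("unmerged", 0),
        n_no_primer=tall.get("no_primer", 0),
        n_ambiguous=tall.get("ambiguous_marker", 0),
        n_too_short=tall.get("too_short", 0),
        n_assigned={mid: sum(counts[mid].values()) for mid in primer_defs},
    )
    return counts, sc
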