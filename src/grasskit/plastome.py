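"""Chloroplast genome finishing: seed-and-extend gap closure and structure QC.

The finishing strategy mirrors manual plastome curation: contig ends are
trimmed to drop potentially misassembled bases, terminal k-mers are used to
fish matching raw reads (both strands), contigs are extended by the consensus
of the bases those reads contribute beyond the end, overlapping ends are
merged until a single circle remains, and the circle is rotated/flipped into
the canonical quadripartite representation LSC + IRb + SSC + IRa.  A k-mer
coverage track over the finished assembly provides the final sanity check:
single-copy regions sit at one modal abundance level, inverted repeats at
twice that level, and everything else is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import kmers as _kmers
from ._seq import circular_slice, encode, revcomp
from .errors import (
    ContigTooShortError,
    InvalidSpecError,
    NoQuadripartiteStructureError,
    UnresolvedGapError,
)

DEFAULT_K = 20


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A contig under curation.  ``trimmed_by`` records end-trim provenance."""

    id: str
    sequence: str
    trimmed_by: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise InvalidSpecError(f"contig {self.id!r} has empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise InvalidSpecError(f"contig {self.id!r} has invalid bases {bad}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class PlastomePartition:
    """Lengths and canonical intervals of the quadripartite plastome.

    Intervals are 0-based half-open on the canonical linearization
    (origin at the LSC start).
    """

    lsc_len: int
    irb_len: int
    ssc_len: int
    ira_len: int

    def __post_init__(self):
        if self.ira_len != self.irb_len:
            raise InvalidSpecError("IRa and IRb must have equal length")
        if min(self.lsc_len, self.ssc_len, self.irb_len) <= 0:
            raise InvalidSpecError("all partition lengths must be positive")

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.irb_len

    @property
    def boundaries(self) -> dict[str, tuple[int, int]]:
        l, r, s = self.lsc_len, self.irb_len, self.ssc_len
        return {
            "LSC": (0, l),
            "IRb": (l, l + r),
            "SSC": (l + r, l + r + s),
            "IRa": (l + r + s, l + 2 * r + s),
        }

    def to_frame(self):
        import pandas as pd

        rows = [
            (name, start, end, end - start)
            for name, (start, end) in self.boundaries.items()
        ]
        return pd.DataFrame(rows, columns=["region", "start", "end", "length"])


@dataclass
class CoverageTrack:
    """Per-position k-mer abundance over an assembly plus windowed means."""

    k: int
    abundance: np.ndarray
    window: int
    window_starts: np.ndarray = field(repr=False)
    window_means: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# read k-mer index
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer integer codes of a base-code array; validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.uint64)
    for t in range(k):
        out = out * np.uint64(4) + np.minimum(codes[t : t + n], 3).astype(np.uint64)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return out, valid


def _encode_kmer(kmer: str) -> int:
    code = 0
    for c in encode(kmer):
        if c >= 4:
            raise InvalidSpecError(f"k-mer {kmer!r} contains non-ACGT base")
        code = code * 4 + int(c)
    return code


class ReadKmerIndex:
    """Sorted array index from forward k-mer code to (read, offset) pairs.

    Queries report matches of a query k-mer on the forward strand and of its
    reverse complement (i.e. reads drawn from the opposite strand).
    """

    def __init__(self, reads, k: int = DEFAULT_K):
        if k <= 0 or k > 32:
            raise InvalidSpecError("k must be in 1..32 for the read index")
        self.k = k
        self.reads = list(reads)
        codes_parts, read_parts, off_parts = [], [], []
        for i, read in enumerate(self.reads):
            c, valid = _kmer_codes(encode(read), k)
            idx = np.nonzero(valid)[0]
            codes_parts.append(c[idx])
            read_parts.append(np.full(len(idx), i, dtype=np.int32))
            off_parts.append(idx.astype(np.int32))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._read_ids = (
            np.concatenate(read_parts)[order] if read_parts else np.empty(0, np.int32)
        )
        self._offsets = (
            np.concatenate(off_parts)[order] if off_parts else np.empty(0, np.int32)
        )

    def _lookup(self, code: int):
        lo = np.searchsorted(self._codes, np.uint64(code), side="left")
        hi = np.searchsorted(self._codes, np.uint64(code), side="right")
        return [
            (int(self._read_ids[i]), int(self._offsets[i])) for i in range(lo, hi)
        ]

    def query(self, kmer: str):
        """All occurrences of ``kmer`` in the reads, on either strand.

        Returns a list of ``(read_index, offset, strand)`` where ``offset`` is
        the position of the match in the read as stored (forward coordinates)
        and ``strand`` is '+' when the read contains the k-mer itself, '-'
        when it contains its reverse complement.
        """
        if len(kmer) != self.k:
            raise InvalidSpecError(f"query k-mer length {len(kmer)} != k={self.k}")
        kmer = kmer.upper()
        hits = [(r, o, "+") for r, o in self._lookup(_encode_kmer(kmer))]
        rc = revcomp(kmer)
        if rc != kmer:
            hits += [(r, o, "-") for r, o in self._lookup(_encode_kmer(rc))]
        return hits

    def support(self, kmer: str) -> int:
        return len(self.query(kmer))


def find_matching_reads(end_kmer: str, reads, k: int | None = None, index=None):
    """Reads containing ``end_kmer`` or its reverse complement, with offsets.

    The search is exact, emulating a grep of the raw reads with the terminal
    sequence and, separately, with its reverse complement.
    """
    k = k or len(end_kmer)
    if len(end_kmer) != k:
        raise InvalidSpecError("end_kmer length must equal k")
    if index is None:
        index = ReadKmerIndex(reads, k=k)
    return index.query(end_kmer)


# ---------------------------------------------------------------------------
# trimming and extension
# ---------------------------------------------------------------------------

def trim_ends(contig: Contig, n: int = 100) -> Contig:
    """Drop ``n`` bases from both contig ends (misassembly guard)."""
    if n < 0:
        raise InvalidSpecError("trim length must be non-negative")
    if n == 0:
        return replace(contig)
    if len(contig) <= 2 * n:
        raise ContigTooShortError(
            f"contig {contig.id!r} ({len(contig)} bp) too short to trim {n} bp "
            "from each end"
        )
    return Contig(contig.id, contig.sequence[n:-n], contig.trimmed_by + n)


def _consensus_tail(tails, min_support):
    """Column-wise strict-majority consensus of the read tails.

    Returns (consensus string, stop reason or None). Stops at the first
    column with no coverage, support below ``min_support``, or a tie.
    """
    out = []
    col = 0
    while True:
        counts: dict[str, int] = {}
        for t in tails:
            if len(t) > col:
                b = t[col]
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            return "".join(out), "no-matching-reads" if col == 0 else None
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        best, best_n = ranked[0]
        if best_n < min_support:
            return "".join(out), "insufficient-support" if col == 0 else None
        if len(ranked) > 1 and ranked[1][1] == best_n:
            return "".join(out), "ambiguous" if col == 0 else None
        if best == "N":
            return "".join(out), "ambiguous" if col == 0 else None
        out.append(best)
        col += 1


def _extend_right_once(seq, index, min_support):
    """One extension round at the 3' end; returns (new bases, reason|None)."""
    k = index.k
    term = seq[-k:]
    tails = []
    for rid, off, strand in index.query(term):
        read = index.reads[rid]
        if strand == "+":
            tails.append(read[off + k :])
        else:
            oriented = revcomp(read)
            pos = len(read) - k - off
            tails.append(oriented[pos + k :])
    tails = [t for t in tails if t]
    if not tails:
        return "", "no-matching-reads"
    return _consensus_tail(tails, min_support)


def extend_contig(
    contig: Contig,
    reads=None,
    k: int = DEFAULT_K,
    min_support: int = 2,
    max_rounds: int = 1000,
    index: ReadKmerIndex | None = None,
) -> tuple[Contig, dict]:
    """Greedy consensus extension of both contig ends.

    Each round anchors on the terminal k-mer, collects every read containing
    it (either strand), and appends the strict-majority consensus of the
    bases those reads contribute beyond the end.  Extension of an end stops
    when no read reaches past it, when consensus support drops below
    ``min_support``, when the top two bases tie, or at ``max_rounds``.
    """
    if len(contig) < k:
        raise InvalidSpecError("contig shorter than k")
    if index is None:
        index = ReadKmerIndex(reads, k=k)
    reasons = {}
    seq = contig.sequence
    # right end, then left end via reverse complement
    for end in ("right", "left"):
        work = seq if end == "right" else revcomp(seq)
        reason = None
        for _ in range(max_rounds):
            added, reason = _extend_right_once(work, index, min_support)
            work = work + added
            if reason is not None:
                break
            if not added:
                reason = "no-progress"
                break
        else:
            reason = "max-rounds"
        reasons[end] = reason
        seq = work if end == "right" else revcomp(work)
    return Contig(contig.id, seq, contig.trimmed_by), reasons


# ---------------------------------------------------------------------------
# gap closure
# ---------------------------------------------------------------------------

def _junction_support(seq, pos, index, circular_len=None):
    """Number of reads whose sequence spans position ``pos`` via the k-mer
    centred on it."""
    k = index.k
    start = pos - k // 2
    if circular_len is not None:
        kmer = circular_slice(seq, start % circular_len, k)
    else:
        if start < 0 or start + k > len(seq):
            return 0
        kmer = seq[start : start + k]
    return index.support(kmer)


def _try_merge(a: str, b: str, k: int, index, min_support):
    """Merge contig b onto the right end of a if their ends overlap >= k.

    Tries b in both orientations.  Returns merged string or None."""
    term = a[-k:]
    for seq_b in (b, revcomp(b)):
        p = seq_b.find(term)
        while p != -1:
            overlap = p + k
            if overlap <= len(a) and overlap <= len(seq_b):
                if a[-overlap:] == seq_b[:overlap]:
                    merged = a + seq_b[overlap:]
                    if (
                        _junction_support(merged, len(a), index) >= min_support
                    ):
                        return merged
            p = seq_b.find(term, p + 1)
    return None


def _try_circularize(a: str, k: int, index, min_support):
    """If the two ends of a single contig overlap by >= k, close the circle."""
    term = a[-k:]
    p = a.find(term)
    while p != -1 and p + k < len(a):
        overlap = p + k
        if overlap < len(a) and a[-overlap:] == a[:overlap]:
            circ = a[: len(a) - overlap]
            if (
                _junction_support(circ, 0, index, circular_len=len(circ))
                >= min_support
            ):
                return circ
        p = a.find(term, p + 1)
    return None


def close_gaps(
    contigs,
    reads=None,
    k: int = DEFAULT_K,
    min_support: int = 2,
    max_rounds: int = 2000,
    index: ReadKmerIndex | None = None,
) -> tuple[str, dict]:
    """Extend and merge contigs until one circular sequence remains.

    Alternates one consensus-extension round on every open contig end with a
    merge sweep that joins any two contigs whose ends agree exactly over at
    least ``k`` bases; each junction must additionally be spanned by at least
    ``min_support`` reads.  Raises :class:`UnresolvedGapError` when no
    further progress is possible or ``max_rounds`` is exhausted.
    """
    if not contigs:
        raise InvalidSpecError("no contigs supplied")
    if index is None:
        index = ReadKmerIndex(reads, k=k)
    seqs = [c.sequence if isinstance(c, Contig) else str(c) for c in contigs]
    report = {"merges": 0, "rounds": 0, "junctions": []}

    for _ in range(max_rounds):
        report["rounds"] += 1
        # merge sweep
        merged_any = True
        while merged_any and len(seqs) > 1:
            merged_any = False
            out = []
            used = [False] * len(seqs)
            for i in range(len(seqs)):
                if used[i]:
                    continue
                cur = seqs[i]
                for j in range(len(seqs)):
                    if j == i or used[j]:
                        continue
                    m = _try_merge(cur, seqs[j], k, index, min_support)
                    if m is None:
                        m = _try_merge(seqs[j], cur, k, index, min_support)
                    if m is not None:
                        report["merges"] += 1
                        report["junctions"].append(len(cur))
                        cur = m
                        used[j] = True
                        merged_any = True
                used[i] = True
                out.append(cur)
            seqs = out
        if len(seqs) == 1:
            circ = _try_circularize(seqs[0], k, index, min_support)
            if circ is not None:
                report["junctions"].append(0)
                return circ, report
        # extension round on all ends
        progressed = False
        new_seqs = []
        for s in seqs:
            grown, reasons = extend_contig(
                Contig("tmp", s), k=k, min_support=min_support, max_rounds=1,
                index=index,
            )
            if len(grown) > len(s):
                progressed = True
            new_seqs.append(grown.sequence)
        seqs = new_seqs
        if not progressed:
            open_ends = [(s[:k], s[-k:]) for s in seqs]
            raise UnresolvedGapError(
                f"gap closure stalled with {len(seqs)} contig(s)",
                contigs=[Contig(f"partial_{i}", s) for i, s in enumerate(seqs)],
                open_ends=open_ends,
            )
    raise UnresolvedGapError(
        f"max_rounds={max_rounds} exhausted with {len(seqs)} contig(s)",
        contigs=[Contig(f"partial_{i}", s) for i, s in enumerate(seqs)],
        open_ends=[(s[:k], s[-k:]) for s in seqs],
    )


# ---------------------------------------------------------------------------
# quadripartite structure
# ---------------------------------------------------------------------------

def _longest_rc_repeat(seq: str, min_ir: int, anchor_k: int = 31):
    """Longest pair of disjoint reverse-complement repeats on a circle.

    Anchors exact-matching ``anchor_k``-mers between the sequence and its
    reverse complement, chains them along anti-diagonals, and extends each
    candidate base-by-base around the circle.  Returns
    ((startA, length), (startB, length)) in forward coordinates, or None.
    """
    n = len(seq)
    if n < 2 * min_ir:
        return None
    doubled = seq + seq[: anchor_k - 1]
    codes = encode(doubled)
    fwd, valid_f = _kmer_codes(codes, anchor_k)
    fwd = fwd[:n]
    # reverse-complement k-mer codes at each circular position
    comp = np.where(codes < 4, 3 - codes.astype(np.int64), 4).astype(np.uint8)
    rc = np.zeros(n + anchor_k - 1 - anchor_k + 1, dtype=np.uint64)
    m = len(rc)
    for t in range(anchor_k):
        rc = rc * np.uint64(4) + np.minimum(
            comp[anchor_k - 1 - t : anchor_k - 1 - t + m], 3
        ).astype(np.uint64)
    rc = rc[:n]

    order = np.argsort(fwd, kind="stable")
    sorted_f = fwd[order]
    lo = np.searchsorted(sorted_f, rc, side="left")
    hi = np.searchsorted(sorted_f, rc, side="right")
    js = np.nonzero(hi > lo)[0]
    hits = []
    for j in js:
        for t in range(lo[j], hi[j]):
            hits.append((int(order[t]), int(j)))
    if not hits:
        return None

    # group by anti-diagonal (i + j) mod n and take one anchor per run
    by_diag: dict[int, list[int]] = {}
    for i, j in hits:
        by_diag.setdefault((i + j) % n, []).append(i)
    best = None
    seen = set()
    for d, ivals in by_diag.items():
        ivals.sort()
        runs = [[ivals[0], ivals[0]]]
        for i in ivals[1:]:
            if i == runs[-1][1] + 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for i0, i1 in runs:
            # run covers A=[i0, i1+k); matching B interval starts at d - i1
            j0 = (d - i1) % n
            res = _extend_rc_pair(seq, i0, j0, anchor_k + (i1 - i0))
            if res is None:
                continue
            a_start, b_start, L = res
            key = tuple(sorted([(a_start, L), (b_start, L)]))
            if key in seen:
                continue
            seen.add(key)
            if L >= min_ir and (best is None or L > best[2]):
                if _disjoint_on_circle(a_start, L, b_start, L, n):
                    best = (a_start, b_start, L)
    if best is None:
        return None
    a_start, b_start, L = best
    return (a_start, L), (b_start, L)


def _extend_rc_pair(seq: str, i0: int, j0: int, core: int):
    """Maximally extend an exact reverse-complement match on the circle.

    The anchor asserts seq[i0:i0+core] == revcomp(seq[j0:j0+core]) circularly.
    Extension grows the A interval left/right (and the B interval oppositely)
    while bases remain complementary, capped at half the circle.
    """
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    cap = n // 2

    def base(p):
        return seq[p % n]

    # verify anchor
    for t in range(core):
        if base(i0 + t) != comp.get(base(j0 + core - 1 - t), "?"):
            return None
    left = 0
    while core + left < cap and base(i0 - left - 1) == comp.get(
        base(j0 + core + left), "?"
    ):
        left += 1
    right = 0
    while core + left + right < cap and base(i0 + core + right) == comp.get(
        base(j0 - right - 1), "?"
    ):
        right += 1
    a_start = (i0 - left) % n
    b_start = (j0 - right) % n
    return a_start, b_start, core + left + right


def _disjoint_on_circle(a, la, b, lb, n):
    """True when circular intervals [a,a+la) and [b,b+lb) do not overlap."""
    if la + lb > n:
        return False
    gap1 = (b - (a + la)) % n
    gap2 = (a - (b + lb)) % n
    return gap1 + gap2 == n - la - lb


def detect_quadripartite(
    assembly: str, min_ir: int = 1000
) -> tuple[PlastomePartition, str]:
    """Locate the inverted-repeat pair and canonicalize the plastome.

    Finds the longest pair of disjoint, exactly reverse-complement-identical
    repeats of at least ``min_ir`` bases on the circle; the longer intervening
    single-copy arc is labelled LSC and the shorter SSC.  The sequence is
    rotated (and flipped if needed, choosing the lexicographically smaller of
    the two strand representations) so that the emitted string reads
    LSC + IRb + SSC + IRa with the origin at the LSC start.
    """
    if min_ir < 100:
        raise InvalidSpecError("min_ir must be >= 100")
    assembly = assembly.upper()
    pair = _longest_rc_repeat(assembly, min_ir)
    if pair is None:
        raise NoQuadripartiteStructureError(
            f"no disjoint reverse-complement repeat pair >= {min_ir} bp found"
        )
    (a_start, L), (b_start, _) = pair
    n = len(assembly)
    a_end, b_end = (a_start + L) % n, (b_start + L) % n
    arc1 = (b_start - a_end) % n  # from end of A to start of B
    arc2 = (a_start - b_end) % n  # from end of B to start of A
    if arc1 >= arc2:
        lsc_len, ssc_len = arc1, arc2
        lsc_start, irb_start = a_end, b_start
    else:
        lsc_len, ssc_len = arc2, arc1
        lsc_start, irb_start = b_end, a_start
    canon = circular_slice(assembly, lsc_start, n)
    part = PlastomePartition(
        lsc_len=lsc_len, irb_len=L, ssc_len=ssc_len, ira_len=L
    )
    # strand choice: compare with the complementary-strand canonical form
    l, r, s = lsc_len, L, ssc_len
    lsc, irb = canon[:l], canon[l : l + r]
    ssc, ira = canon[l + r : l + r + s], canon[l + r + s :]
    flipped = revcomp(lsc) + irb + revcomp(ssc) + ira
    if flipped < canon:
        canon = flipped
    return part, canon


# ---------------------------------------------------------------------------
# coverage QC
# ---------------------------------------------------------------------------

def coverage_track(
    assembly: str,
    reads,
    k: int = DEFAULT_K,
    window: int = 500,
    ir_intervals=None,
    tolerance_factor: float = 1.75,
    circular: bool = True,
) -> tuple[CoverageTrack, list]:
    """k-mer abundance of the reads along the assembly, with anomaly flags.

    Each assembly position is assigned the strand-canonical count, in the
    reads, of the k-mer starting there.  Windowed means are compared with the
    modal single-copy level; windows off by more than ``tolerance_factor``
    are flagged, except that windows overlapping the supplied inverted-repeat
    intervals are compared against twice the modal level.
    """
    if len(assembly) < k:
        raise InvalidSpecError("assembly shorter than k")
    read_list = list(reads)
    max_rl = max((len(r) for r in read_list), default=0)
    if read_list and k > max_rl:
        raise InvalidSpecError(f"k={k} exceeds read length {max_rl}")
    counts = _kmers.count_kmers(read_list, k) if read_list else None
    if counts is None or counts.n_distinct == 0:
        warnings.warn("empty read set: coverage track is all zero")
    seq = assembly.upper() + (assembly.upper()[: k - 1] if circular else "")
    codes = encode(seq)
    fwd, valid = _kmer_codes(codes, k)
    # canonical codes
    comp = np.where(codes < 4, 3 - codes.astype(np.int64), 4).astype(np.uint8)
    m = len(fwd)
    rc = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        rc = rc * np.uint64(4) + np.minimum(comp[k - 1 - t : k - 1 - t + m], 3).astype(
            np.uint64
        )
    canonical = np.minimum(fwd, rc)
    if counts is None or counts.n_distinct == 0:
        abundance = np.zeros(m, dtype=np.int64)
    else:
        abundance = counts.lookup(canonical)
    abundance[~valid] = 0

    n_pos = len(abundance)
    starts = np.arange(0, n_pos, window)
    means = np.array(
        [abundance[s : min(s + window, n_pos)].mean() for s in starts]
    )
    track = CoverageTrack(
        k=k, abundance=abundance, window=window, window_starts=starts,
        window_means=means,
    )
    # expected copy multiplier per position: 2 where the k-mer lies fully
    # inside an inverted repeat (it occurs at both IR copies), else 1
    multiplier = np.ones(n_pos)
    for a, b in ir_intervals or []:
        lo, hi = max(int(a), 0), min(int(b) - k + 1, n_pos)
        if hi > lo:
            multiplier[lo:hi] = 2.0
    pure_single = np.array([
        multiplier[s : min(s + window, n_pos)].max() == 1.0 for s in starts
    ])
    if pure_single.any():
        level = float(np.median(means[pure_single]))
    else:
        level = float(np.median(means) / 2.0)
    anomalies = []
    for s, mu in zip(starts, means):
        expected = level * float(multiplier[s : min(s + window, n_pos)].mean())
        if expected <= 0:
            continue
        ratio = mu / expected
        if ratio > tolerance_factor or ratio < 1.0 / tolerance_factor:
            anomalies.append(
                {"start": int(s), "end": int(min(s + window, n_pos)),
                 "mean": float(mu), "expected": float(expected)}
            )
    return track, anomalies


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def finish_plastome(
    contigs,
    reads,
    k: int = DEFAULT_K,
    trim: int = 100,
    min_support: int = 2,
    min_ir: int = 1000,
    window: int = 500,
    max_rounds: int = 2000,
):
    """Full finishing pipeline: trim, extend/merge, orient, QC.

    Returns ``(canonical sequence, PlastomePartition, CoverageTrack,
    anomalies, report)``.
    """
    trimmed = [trim_ends(c, trim) if trim else c for c in contigs]
    read_list = list(reads)
    index = ReadKmerIndex(read_list, k=k)
    circle, report = close_gaps(
        trimmed, k=k, min_support=min_support, max_rounds=max_rounds, index=index
    )
    partition, canonical = detect_quadripartite(circle, min_ir=min_ir)
    ir_iv = [partition.boundaries["IRb"], partition.boundaries["IRa"]]
    track, anomalies = coverage_track(
        canonical, read_list, k=k, window=window, ir_intervals=ir_iv
    )
    return canonical, partition, track, anomalies, report
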