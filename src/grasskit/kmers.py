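"""k-mer counting, abundance histograms, and genome-size estimation.

Single-copy sequence produces a distinctive peak in the k-mer abundance
histogram centred at the average sequencing depth; sequence present twice in
the genome forms a second peak at twice that depth, and so on.  The total
k-mer mass above the error region divided by the depth of the single-copy
peak estimates total genome size, while the number of distinct k-mers under
the first peak estimates the single-copy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, encode
from .errors import EstimationFailedError, InvalidSpecError

_CHUNK_BASES = 20_000_000


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-canonical k-mer integer codes for one base-code array.

    Windows containing non-ACGT bases are dropped.  Requires k <= 32.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    four = np.uint64(4)
    c64 = np.minimum(codes, 3).astype(np.uint64)
    comp64 = np.uint64(3) - c64
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for t in range(k):
        fwd *= four
        fwd += c64[t : t + n]
        rc *= four
        rc += comp64[k - 1 - t : k - 1 - t + n]
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    np.minimum(fwd, rc, out=fwd)
    return fwd[valid]


def _decode_code(code: int, k: int) -> str:
    out = np.empty(k, dtype=np.uint8)
    for t in range(k - 1, -1, -1):
        out[t] = code & 3
        code >>= 2
    return decode(out)


@dataclass
class KmerCounts:
    """Multiplicity table of canonical k-mers, stored as sorted code arrays."""

    k: int
    codes: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    @property
    def n_distinct(self) -> int:
        return len(self.codes)

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())

    def lookup(self, query_codes: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        pos = np.searchsorted(self.codes, query_codes)
        pos = np.minimum(pos, max(len(self.codes) - 1, 0))
        out = np.zeros(len(query_codes), dtype=np.int64)
        if len(self.codes):
            hit = self.codes[pos] == query_codes
            out[hit] = self.counts[pos[hit]]
        return out

    def get(self, kmer: str) -> int:
        codes = _canonical_codes(encode(kmer.upper()), self.k)
        if len(codes) != 1:
            raise InvalidSpecError("get() expects a single valid k-mer")
        return int(self.lookup(codes)[0])

    def to_dict(self) -> dict[str, int]:
        """Decode to a {canonical k-mer string: count} dict (small tables)."""
        return {
            _decode_code(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }


def count_kmers(reads, k: int) -> KmerCounts:
    """Strand-canonical k-mer counts over a collection of read strings."""
    if k <= 0:
        raise InvalidSpecError("k must be positive")
    if k > 32:
        raise InvalidSpecError("k must be <= 32")
    parts = []
    buf, buf_len = [], 0

    def _flush():
        nonlocal buf, buf_len
        if not buf:
            return
        # 'N' separators break k-mer windows across read joins
        arr = encode("N".join(buf).upper())
        parts.append(_canonical_codes(arr, k))
        buf, buf_len = [], 0

    for read in reads:
        s = str(read)
        if len(s) < k:
            continue
        buf.append(s)
        buf_len += len(s) + 1
        if buf_len >= _CHUNK_BASES:
            _flush()
    _flush()
    if not parts:
        return KmerCounts(k, np.empty(0, np.uint64), np.empty(0, np.int64))
    allc = np.concatenate(parts)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerCounts(k, codes, counts.astype(np.int64))


@dataclass
class KmerHistogram:
    """Abundance histogram: entries[m] = number of distinct k-mers seen m times."""

    k: int
    multiplicity: np.ndarray
    count: np.ndarray

    def as_dict(self) -> dict[int, int]:
        return {int(m): int(c) for m, c in zip(self.multiplicity, self.count)}

    @property
    def total_mass(self) -> int:
        return int((self.multiplicity.astype(np.int64) * self.count).sum())

    def dense(self) -> np.ndarray:
        """Entries on a dense 1..max multiplicity grid (index 0 = mult 1)."""
        out = np.zeros(int(self.multiplicity.max()), dtype=np.int64)
        out[self.multiplicity - 1] = self.count
        return out

    @classmethod
    def from_dict(cls, entries: dict[int, int], k: int = 21) -> "KmerHistogram":
        ms = np.array(sorted(entries), dtype=np.int64)
        return cls(k, ms, np.array([entries[int(m)] for m in ms], dtype=np.int64))


def build_histogram(counts: KmerCounts) -> KmerHistogram:
    if counts.n_distinct == 0:
        raise InvalidSpecError("empty k-mer table")
    mult, n = np.unique(counts.counts, return_counts=True)
    return KmerHistogram(counts.k, mult.astype(np.int64), n.astype(np.int64))


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Genome size derived from the k-mer histogram peak structure."""

    coverage_peak: float
    total_bp: float
    single_copy_bp: float
    error_cutoff: int


def _smooth(x: np.ndarray, width: int = 3) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    pad = width // 2
    xp = np.concatenate([np.repeat(x[:1], pad), x, np.repeat(x[-1:], pad)])
    return np.convolve(xp, np.ones(width) / width, mode="valid")


def estimate_genome_size(
    hist: KmerHistogram, smooth_width: int = 3
) -> GenomeSizeEstimate:
    """Estimate total and single-copy genome size from the histogram.

    The error cutoff is the first local minimum of the (smoothed) entries as
    multiplicity increases; the coverage peak is the count-weighted mode
    above that cutoff; total size is the k-mer mass above the cutoff divided
    by the peak depth; single-copy size is the number of distinct k-mers with
    multiplicity in [cutoff, 1.5 x peak), the midpoint between the 1x and 2x
    peaks.
    """
    dense = hist.dense().astype(float)
    if len(dense) < 3:
        # e.g. an idealized single-multiplicity histogram
        m = int(hist.multiplicity[np.argmax(hist.count)])
        mass = hist.total_mass
        sc = int(hist.count[hist.multiplicity < 1.5 * m].sum())
        return GenomeSizeEstimate(float(m), mass / m, float(sc), 0)
    sm = _smooth(dense, smooth_width)
    # first local minimum: first index where the smoothed series starts rising
    cutoff = None
    for m in range(1, len(sm)):
        if sm[m] > sm[m - 1]:
            cutoff = m  # multiplicity value of the minimum position (1-based-1)
            break
    if cutoff is None:
        raise EstimationFailedError(
            "histogram is monotone decreasing: no coverage peak separable "
            "from the error slope",
            diagnostics={"max_multiplicity": len(dense)},
        )
    above = sm[cutoff:]
    if not len(above) or above.max() <= 0:
        raise EstimationFailedError("no mass above the error cutoff")
    m0 = cutoff + int(np.argmax(above)) + 1  # multiplicity of the smoothed mode
    # count-weighted mean over the first peak's support [0.5 m0, 1.5 m0):
    # 1.5x the mode is the midpoint between the single- and two-copy peaks
    lo, hi = max(cutoff + 1, int(np.ceil(0.5 * m0))), int(np.ceil(1.5 * m0))
    ms = np.arange(lo, min(hi, len(dense) + 1))
    w = dense[ms - 1]
    if w.sum() <= 0:
        raise EstimationFailedError("empty peak window")
    c = float((ms * w).sum() / w.sum())
    mult = hist.multiplicity.astype(float)
    sel = mult > cutoff
    mass = float((mult[sel] * hist.count[sel]).sum())
    total_bp = mass / c
    sc_sel = (mult > cutoff) & (mult < 1.5 * c)
    single_copy_bp = float(hist.count[sc_sel].sum())
    return GenomeSizeEstimate(c, total_bp, single_copy_bp, int(cutoff))


def ratio_percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage ratio rounded as printed in assembly summaries."""
    if denominator == 0:
        raise InvalidSpecError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, ndigits if ndigits else None)
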