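"""piRNA signature statistics on mapped small-RNA reads.

Length classification (27-32 nt inclusive), the opposite-strand 5'-overlap
profile diagnostic of ping-pong biogenesis, fixed-width genomic window
densities, the cumulative coverage curve, and the permutation clustering
ratio (windows needed for 90% of shuffled positions divided by windows
needed for the observed positions).

Overlap convention: reads are 0-based half-open; a plus-read 5' end is its
start, a minus-read 5' end is end - 1.  For an opposite-strand pair whose
spans intersect, the tabulated overlap is the width of the span
intersection, which for 5'-staggered pairs equals
(minus 5') - (plus 5') + 1 and makes the profile symmetric under swapping
all strand labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import ReadInterval

PIRNA_MIN_LENGTH = 27
PIRNA_MAX_LENGTH = 32


class PirnaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# length classification
# ---------------------------------------------------------------------------

def classify_length(
    reads: Iterable[ReadInterval],
    min_length: int = PIRNA_MIN_LENGTH,
    max_length: int = PIRNA_MAX_LENGTH,
) -> tuple[list[ReadInterval], list[ReadInterval]]:
    """Partition reads into (putative piRNAs, other reads), preserving order."""
    pirnas: list[ReadInterval] = []
    other: list[ReadInterval] = []
    for read in reads:
        (pirnas if min_length <= read.length <= max_length else other).append(read)
    return pirnas, other


def length_histogram(reads: Iterable[ReadInterval]) -> dict[int, int]:
    """Exact integer histogram of read lengths."""
    return dict(sorted(Counter(r.length for r in reads).items()))


# ---------------------------------------------------------------------------
# ping-pong profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PingPongProfile:
    counts: dict[int, int]  # overlap (nt) -> pair count, 1..max_overlap
    max_overlap: int

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def modal_overlap(self) -> int | None:
        if not self.total_pairs:
            return None
        return max(self.counts, key=lambda o: (self.counts[o], -o))

    def to_payload(self) -> dict:
        return {
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "modal_overlap": self.modal_overlap,
            "total_pairs": self.total_pairs,
            "max_overlap": self.max_overlap,
        }


def pingpong_profile(
    reads: Iterable[ReadInterval], max_overlap: int = 25
) -> PingPongProfile:
    """Tabulate span overlaps of every intersecting plus/minus read pair.

    Input is expected to be length-filtered already (putative piRNAs).
    Pairs whose overlap falls in [1, max_overlap] are counted.
    """
    by_contig: dict[str, tuple[list[ReadInterval], list[ReadInterval]]] = {}
    for read in reads:
        plus, minus = by_contig.setdefault(read.contig, ([], []))
        (plus if read.strand == "+" else minus).append(read)

    counts: Counter[int] = Counter()
    for plus, minus in by_contig.values():
        if not plus or not minus:
            continue
        minus.sort(key=lambda r: r.start)
        m_starts = np.array([r.start for r in minus])
        max_minus_len = max(r.length for r in minus)
        for p in plus:
            # candidates: minus reads with start in (p.start - L_minus, p.end)
            lo = int(np.searchsorted(m_starts, p.start - max_minus_len, side="left"))
            hi = int(np.searchsorted(m_starts, p.end, side="left"))
            for m in minus[lo:hi]:
                overlap = min(p.end, m.end) - max(p.start, m.start)
                if 1 <= overlap <= max_overlap:
                    counts[overlap] += 1
    return PingPongProfile(counts=dict(sorted(counts.items())), max_overlap=max_overlap)


# ---------------------------------------------------------------------------
# window densities
# ---------------------------------------------------------------------------

@dataclass
class WindowCounts:
    """Per-window putative-piRNA counts; windows tile each contig from 0."""

    window: int
    counts: dict[str, np.ndarray]  # contig -> counts per window index

    @property
    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def flat(self) -> list[tuple[str, int, int]]:
        """(contig, window index, count) triples in deterministic order."""
        out: list[tuple[str, int, int]] = []
        for contig in sorted(self.counts):
            for idx, count in enumerate(self.counts[contig]):
                out.append((contig, idx, int(count)))
        return out

    def to_payload(self) -> dict:
        return {
            "window": self.window,
            "total": self.total,
            "n_windows": sum(len(c) for c in self.counts.values()),
        }


def window_counts(
    reads: Iterable[ReadInterval],
    contig_lengths: Mapping[str, int],
    window: int = 2000,
) -> WindowCounts:
    """Assign each read to the window containing its start coordinate."""
    if window < 1:
        raise PirnaError("window must be >= 1")
    counts = {
        contig: np.zeros(-(-length // window), dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    for read in reads:
        if read.contig not in counts:
            raise PirnaError(f"read on unknown contig {read.contig!r}")
        if read.end > contig_lengths[read.contig]:
            raise PirnaError(
                f"read [{read.start}, {read.end}) beyond contig "
                f"{read.contig!r} (length {contig_lengths[read.contig]})"
            )
        counts[read.contig][read.start // window] += 1
    return WindowCounts(window=window, counts=counts)


def dense_windows(
    counts: WindowCounts, min_count: int = 1000
) -> list[tuple[str, int, int]]:
    """Windows holding at least *min_count* putative piRNAs."""
    return [t for t in counts.flat() if t[2] >= min_count]


def cumulative_coverage_curve(counts: WindowCounts) -> np.ndarray:
    """Cumulative fraction of reads as windows are added by decreasing count."""
    total = counts.total
    if total == 0:
        raise PirnaError("no reads in any window")
    values = np.sort(
        np.concatenate([c for c in counts.counts.values()])
    )[::-1]
    return np.cumsum(values) / total


def windows_to_cover(counts: WindowCounts, fraction: float = 0.9) -> int:
    """Smallest number of top windows whose cumulative count reaches
    fraction * total.  Ties at the boundary are broken by (contig, index)."""
    if not 0 < fraction <= 1:
        raise PirnaError("fraction must be in (0, 1]")
    total = counts.total
    if total == 0:
        raise PirnaError("windows_to_cover undefined for zero reads")
    flat = sorted(counts.flat(), key=lambda t: (-t[2], t[0], t[1]))
    target = fraction * total
    acc = 0
    for i, (_contig, _idx, count) in enumerate(flat, start=1):
        acc += count
        if acc >= target:
            return i
    return len(flat)  # pragma: no cover (acc == total >= target)


# ---------------------------------------------------------------------------
# clustering ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusteringResult:
    windows_real_90: int
    windows_shuffled_90: float  # mean over shuffles
    n_shuffles: int
    seed: int
    fraction: float
    window: int

    @property
    def clustering_ratio(self) -> float:
        return self.windows_shuffled_90 / self.windows_real_90

    def to_payload(self) -> dict:
        return {
            "windows_real_90": self.windows_real_90,
            "windows_shuffled_90": self.windows_shuffled_90,
            "clustering_ratio": self.clustering_ratio,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "fraction": self.fraction,
            "window": self.window,
        }


def clustering_ratio(
    reads: Sequence[ReadInterval],
    contig_lengths: Mapping[str, int],
    window: int = 2000,
    fraction: float = 0.9,
    n_shuffles: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """Permutation clustering statistic.

    The real windows-to-cover value comes from the observed starts; the
    shuffled value is the mean over *n_shuffles* of windows-to-cover after
    drawing each read a uniform start on its own contig (length and strand
    preserved).  Ratio > 1 indicates genomic clustering.
    """
    reads = list(reads)
    if not reads:
        raise PirnaError("clustering_ratio requires at least one read")
    if n_shuffles < 1:
        raise PirnaError("n_shuffles must be >= 1")
    real = windows_to_cover(window_counts(reads, contig_lengths, window), fraction)
    rng = np.random.default_rng(seed)
    shuffled_values: list[int] = []
    by_contig: dict[str, np.ndarray] = {}
    for contig in sorted({r.contig for r in reads}):
        lengths = np.array([r.length for r in reads if r.contig == contig])
        by_contig[contig] = lengths
    n_win = {c: -(-l // window) for c, l in contig_lengths.items()}
    for _ in range(n_shuffles):
        counts = {c: np.zeros(n, dtype=np.int64) for c, n in n_win.items()}
        for contig, lengths in by_contig.items():
            limit = contig_lengths[contig]
            starts = rng.integers(0, limit - lengths + 1)
            np.add.at(counts[contig], starts // window, 1)
        shuffled_values.append(
            windows_to_cover(WindowCounts(window=window, counts=counts), fraction)
        )
    return ClusteringResult(
        windows_real_90=real,
        windows_shuffled_90=float(np.mean(shuffled_values)),
        n_shuffles=n_shuffles,
        seed=seed,
        fraction=fraction,
        window=window,
    )
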