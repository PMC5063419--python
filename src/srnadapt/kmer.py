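"""k-mer counting, filtering and suffix-prefix assembly.

The adapter-prediction core rests on one assumption: in an unprocessed
small RNA library most reads run into the 3' adapter, so the adapter's
k-mers are by far the most frequent.  This module counts every k-length
window over a read sample, discards low-complexity k-mers (homopolymer
runs) and infrequent k-mers (frequency-ratio filter), then chains the
survivors by perfect (k-1)-overlap into candidate adapter sequences, each
scored by the fraction of all windows its member k-mers account for.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from srnadapt.fastq_io import SequenceRead


class EmptyTableError(ValueError):
    """No k-mer window could be counted (k exceeds every read length)."""


@dataclass(slots=True)
class KmerTable:
    """k-mer frequencies over one counting run.

    ``total_windows`` is the total number of counted windows *before any
    filtering* and stays fixed through the filters: normalizing candidate
    scores by the per-run window total is what makes scores comparable
    across different k in iterative mode.  Windows containing N are never
    counted and do not enter ``total_windows``.
    """

    k: int
    counts: dict[str, int]
    total_windows: int


@dataclass(frozen=True, slots=True)
class AdapterCandidate:
    """An assembled putative adapter.

    ``members`` are the (k-mer, count) pairs of the chain in 5'->3' order;
    ``score`` is the summed member count divided by the generating table's
    ``total_windows``, hence in (0, 1].
    """

    sequence: str
    score: float
    members: tuple[tuple[str, int], ...]

    @property
    def member_count_sum(self) -> int:
        return sum(n for _, n in self.members)


def count_kmers(reads: Sequence[SequenceRead], k: int) -> KmerTable:
    """Count every k-length window of every read.

    Windows containing N are skipped entirely (excluded from counts *and*
    from the window total) so that N-rich libraries do not deflate
    candidate scores.  Raises :class:`EmptyTableError` when k exceeds every
    read length.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not reads:
        raise ValueError("reads must be nonempty")
    counts: Counter[str] = Counter()
    total = 0
    for read in reads:
        seq = read.bases
        n = len(seq) - k + 1
        if n <= 0:
            continue
        if "N" in seq:
            windows = [seq[i : i + k] for i in range(n) if "N" not in seq[i : i + k]]
        else:
            windows = [seq[i : i + k] for i in range(n)]
        counts.update(windows)
        total += len(windows)
    if total == 0:
        raise EmptyTableError(f"k={k} exceeds every read length; no window counted")
    return KmerTable(k=k, counts=dict(counts), total_windows=total)


def filter_low_complexity(table: KmerTable) -> KmerTable:
    """Remove k-mers containing a homopolymer run of length >= floor(k/2).

    Poly(A) stretches and other homopolymer artifacts recur across reads as
    strongly as a real adapter would and must not seed candidates.  The
    threshold floor(k/2) (k=9 -> runs of 4) is deliberately strict; see the
    methods note.  ``total_windows`` is left unchanged -- score
    normalization always uses the unfiltered window total of the run.
    """
    m = table.k // 2
    patterns = tuple(b * m for b in "ACGT")
    kept = {
        s: c
        for s, c in table.counts.items()
        if not any(p in s for p in patterns)
    }
    return KmerTable(k=table.k, counts=kept, total_windows=table.total_windows)


def filter_by_ratio(table: KmerTable, ratio: float) -> KmerTable:
    """Keep k-mers whose frequency is within ``ratio`` of the most abundant.

    With f(S) the count of the most abundant surviving k-mer S, a k-mer s
    is kept iff f(S)/f(s) <= ratio; the boundary is inclusive (a k-mer
    exactly at the ratio survives) and S itself always survives.  An empty
    table passes through empty.
    """
    if ratio <= 1.0:
        raise ValueError("ratio threshold must be > 1.0")
    if not table.counts:
        return KmerTable(k=table.k, counts={}, total_windows=table.total_windows)
    f_top = max(table.counts.values())
    kept = {s: c for s, c in table.counts.items() if f_top / c <= ratio}
    return KmerTable(k=table.k, counts=kept, total_windows=table.total_windows)


def score_normalize(
    members: Iterable[tuple[str, int]], total_windows: int
) -> float:
    """Summed member frequency divided by the run's total window count."""
    if total_windows <= 0:
        raise ValueError("total_windows must be positive to define a score")
    return sum(n for _, n in members) / total_windows


def assemble(table: KmerTable) -> list[AdapterCandidate]:
    """Chain surviving k-mers by perfect (k-1) suffix-prefix overlap.

    Greedy chain extension: seed at the highest-count unused k-mer, extend
    rightward while some unused k-mer's (k-1)-prefix equals the current
    chain suffix (highest count first, then lexicographic), then extend
    leftward symmetrically; repeat until every k-mer is used.  Each k-mer
    joins at most one chain, so overlap cycles terminate.  On overlap
    graphs that are disjoint unions of simple paths -- the expected shape
    when the k-mers come from a single adapter -- this recovers exactly the
    path merges.

    Candidates are returned sorted by score descending, ties broken by
    higher summed member count and then lexicographically by sequence.
    """
    counts = table.counts
    if not counts:
        return []
    prefix_index: dict[str, list[str]] = {}
    suffix_index: dict[str, list[str]] = {}
    for s in counts:
        prefix_index.setdefault(s[:-1], []).append(s)
        suffix_index.setdefault(s[1:], []).append(s)

    unused = set(counts)
    seed_order = sorted(counts, key=lambda s: (-counts[s], s))
    pick = lambda opts: min(opts, key=lambda s: (-counts[s], s))  # noqa: E731

    candidates: list[AdapterCandidate] = []
    for seed in seed_order:
        if seed not in unused:
            continue
        unused.discard(seed)
        chain: deque[str] = deque([seed])
        while True:
            opts = [s for s in prefix_index.get(chain[-1][1:], ()) if s in unused]
            if not opts:
                break
            nxt = pick(opts)
            chain.append(nxt)
            unused.discard(nxt)
        while True:
            opts = [s for s in suffix_index.get(chain[0][:-1], ()) if s in unused]
            if not opts:
                break
            prv = pick(opts)
            chain.appendleft(prv)
            unused.discard(prv)
        members = tuple((s, counts[s]) for s in chain)
        sequence = chain[0] + "".join(s[-1] for s in list(chain)[1:])
        score = score_normalize(members, table.total_windows)
        candidates.append(AdapterCandidate(sequence, score, members))

    candidates.sort(key=lambda c: (-c.score, -c.member_count_sum, c.sequence))
    return candidates
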