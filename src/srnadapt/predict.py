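"""Single-setting and iterative (grid-tallied) adapter prediction.

``predict_single`` runs the full pipeline -- count, homopolymer filter,
ratio filter, assembly -- for one (k, R) setting and ranks the assembled
candidates; the top candidate is the putative 3' adapter.  A single
setting occasionally ranks the true adapter second.  ``predict_iterative``
therefore runs the pipeline over a small (k, R) grid and re-ranks
candidates by the *sum* of their normalized scores across runs; because
each run's scores are normalized by that run's total window count, scores
from different k are commensurable and the tally rewards sequences that
rank highly under many settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from srnadapt.fastq_io import SequenceRead
from srnadapt.kmer import (
    assemble,
    count_kmers,
    filter_by_ratio,
    filter_low_complexity,
)

#: Best-performing single-mode setting.
DEFAULT_K = 9
DEFAULT_R = 1.4
#: Default grid for iterative and exhaustive modes.
DEFAULT_KS = (9, 11)
DEFAULT_RS = (1.2, 1.3, 1.4)

#: Minimum prefix agreement for two adapters to count as the same adapter.
MIN_MATCH_OVERLAP = 9


@dataclass(frozen=True, slots=True)
class PredictionResult:
    """Ranked adapter candidates and the settings that produced them.

    ``candidates`` holds (sequence, score) pairs, strictly ordered by score
    descending with lexicographic tie-break.  In single mode the score is
    the normalized assembly score; in iterative mode it is the tallied sum
    over runs (bounded by the number of runs).
    """

    candidates: tuple[tuple[str, float], ...]
    params: tuple[tuple[int, float], ...]
    sampled_reads: int

    @property
    def top(self) -> str | None:
        """The putative adapter, or None when every k-mer was filtered out."""
        return self.candidates[0][0] if self.candidates else None


def predict_single(
    reads: Sequence[SequenceRead],
    k: int = DEFAULT_K,
    ratio: float = DEFAULT_R,
) -> PredictionResult:
    """Predict the 3' adapter with one (k, R) setting.

    An empty candidate list (every k-mer filtered out) is a legitimate
    outcome -- e.g. an already-processed library of short reads -- and is
    reported as an empty result, distinct from any parse error.
    """
    table = filter_by_ratio(filter_low_complexity(count_kmers(reads, k)), ratio)
    candidates = assemble(table)
    return PredictionResult(
        candidates=tuple((c.sequence, c.score) for c in candidates),
        params=((k, ratio),),
        sampled_reads=len(reads),
    )


def predict_iterative(
    reads: Sequence[SequenceRead],
    ks: Iterable[int] = DEFAULT_KS,
    ratios: Iterable[float] = DEFAULT_RS,
) -> PredictionResult:
    """Predict the 3' adapter by tallying scores over a (k, R) grid.

    For every distinct assembled sequence (exact string identity; sequences
    of different length are distinct even when one is a prefix of the
    other) the tallied score is the sum of its normalized scores over all
    runs in which it appears.  With a singleton grid this reduces exactly
    to :func:`predict_single`.
    """
    ks = sorted(set(ks))
    ratios = sorted(set(ratios))
    if not ks or not ratios:
        raise ValueError("ks and ratios must be nonempty")
    tally: dict[str, float] = {}
    params: list[tuple[int, float]] = []
    for k in ks:
        base = filter_low_complexity(count_kmers(reads, k))
        for r in ratios:
            params.append((k, r))
            for cand in assemble(filter_by_ratio(base, r)):
                tally[cand.sequence] = tally.get(cand.sequence, 0.0) + cand.score
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return PredictionResult(
        candidates=tuple(ordered),
        params=tuple(params),
        sampled_reads=len(reads),
    )


def adapters_match(
    predicted: str, truth: str, min_overlap: int = MIN_MATCH_OVERLAP
) -> bool:
    """Whether a predicted adapter agrees with a reference adapter.

    True iff the shorter of the two is a prefix of the longer and is at
    least ``min_overlap`` long.  Prefix agreement is the operative notion:
    clipping only ever uses a short prefix of the adapter, so a prediction
    that extends or truncates the reference 3' end clips identically.
    """
    if len(predicted) > len(truth):
        predicted, truth = truth, predicted
    return len(predicted) >= min_overlap and truth.startswith(predicted)
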