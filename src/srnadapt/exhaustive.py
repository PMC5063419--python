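"""Exhaustive mode: adapter selection by genome-mapping rate.

After the correct 3' adapter is removed, the remaining inserts are genuine
small RNAs and should map to the reference genome at a high rate, so the
mapping rate is a model-selection criterion that needs no metadata.  This
module clips the reads with every candidate adapter from a (k, R) grid,
maps each clipped set (and the raw, unclipped reads) with a user-defined
mapper command, and reports:

* the **optimal adapter** -- the clipped candidate with the highest mapped
  fraction,
* a **quality flag** -- a library whose optimal mapping rate is below 20%
  is flagged as poor,
* an **already-processed verdict** -- when raw reads map at least as well
  as the best clipped candidate (and clear the 20% line), the adapters
  were evidently removed upstream and the library is ready to map.

The mapper is any shell command template with ``{input}`` (FASTQ in) and
``{output}`` (SAM out) placeholders; mapping strictness (e.g. "no
mismatches") lives inside the user's template.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from srnadapt.fastq_io import SequenceRead, write_fastq
from srnadapt.kmer import assemble, count_kmers, filter_by_ratio, filter_low_complexity
from srnadapt.predict import DEFAULT_KS, DEFAULT_RS

#: Label used for the unclipped (raw reads) evaluation.
RAW_LABEL = "RAW"

#: Mapping rate below which a library is flagged as poor quality.
QUALITY_CUTOFF = 0.20

#: Adapter occurrences are located by this prefix length.
CLIP_PREFIX_LEN = 7

#: Shortest insert worth mapping (typical small RNAs are >= 16 nt).
DEFAULT_MIN_INSERT = 16


class MapperError(RuntimeError):
    """The user-defined mapper exited nonzero or produced unreadable SAM."""


@dataclass(frozen=True, slots=True)
class MapperSpec:
    """A user-defined read-mapping command.

    ``command_template`` must contain the placeholders ``{input}`` and
    ``{output}`` exactly once each; they are substituted with the clipped
    FASTQ path and the SAM output path and the result is run through the
    shell.
    """

    command_template: str

    def __post_init__(self) -> None:
        for ph in ("{input}", "{output}"):
            n = self.command_template.count(ph)
            if n != 1:
                raise ValueError(
                    f"command template must contain {ph} exactly once (found {n})"
                )

    def render(self, input_path: str | Path, output_path: str | Path) -> str:
        return self.command_template.replace("{input}", str(input_path)).replace(
            "{output}", str(output_path)
        )


@dataclass(frozen=True, slots=True)
class CandidateEvaluation:
    """Clipped and mapped fractions for one candidate adapter.

    Both fractions share the same denominator -- the number of sampled
    input reads -- so "mapped <= clipped" holds whenever only clipped
    reads are submitted to the mapper.  For the RAW evaluation
    ``clipped_fraction`` is None (not applicable).
    """

    adapter: str
    mapped_fraction: float
    clipped_fraction: float | None = None

    @property
    def is_raw(self) -> bool:
        return self.adapter == RAW_LABEL


@dataclass(frozen=True, slots=True)
class ExhaustiveReport:
    """Outcome of an exhaustive-mode run."""

    evaluations: tuple[CandidateEvaluation, ...]
    optimal_adapter: str | None
    quality_ok: bool
    already_processed: bool
    sampled_reads: int = 0
    params: tuple[tuple[int, float], ...] = field(default=())

    @property
    def optimal_evaluation(self) -> CandidateEvaluation | None:
        for ev in self.evaluations:
            if ev.adapter == self.optimal_adapter and not ev.is_raw:
                return ev
        return None

    @property
    def raw_evaluation(self) -> CandidateEvaluation | None:
        for ev in self.evaluations:
            if ev.is_raw:
                return ev
        return None


def clip_adapter(
    reads: Sequence[SequenceRead],
    adapter: str,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> tuple[list[SequenceRead], float]:
    """Clip an adapter by exact search for its 7-mer prefix.

    For each read the leftmost exact occurrence of ``adapter[:7]`` at
    position p marks the adapter junction; the insert is the first p bases
    (with the matching quality prefix).  Reads without an occurrence are
    excluded from the clipped output, as are inserts shorter than
    ``min_insert`` -- too short to map informatively (this includes
    adapter-dimer reads, where p == 0).  The returned ``clipped_fraction``
    counts every read with an occurrence, regardless of insert length,
    over all input reads.
    """
    if len(adapter) < CLIP_PREFIX_LEN:
        raise ValueError(
            f"adapter must be at least {CLIP_PREFIX_LEN} nt (got {len(adapter)})"
        )
    if min_insert < 1:
        raise ValueError("min_insert must be >= 1")
    key = adapter[:CLIP_PREFIX_LEN]
    hits = 0
    clipped: list[SequenceRead] = []
    for read in reads:
        p = read.bases.find(key)
        if p < 0:
            continue
        hits += 1
        if p >= min_insert:
            clipped.append(SequenceRead(read.read_id, read.bases[:p], read.quals[:p]))
    return clipped, hits / len(reads) if reads else 0.0


def count_fastq_records(path: str | Path) -> int:
    """Number of records in a (possibly gzipped) FASTQ file."""
    from srnadapt.fastq_io import _open_maybe_gzip

    with _open_maybe_gzip(path) as fh:
        return sum(1 for _ in fh) // 4


def run_mapper(
    spec: MapperSpec,
    reads_path: str | Path,
    sam_path: str | Path | None = None,
) -> tuple[int, int]:
    """Run the mapper command and count mapped primary SAM records.

    Returns ``(mapped, submitted)`` where ``submitted`` is the number of
    reads in ``reads_path`` and ``mapped`` counts SAM records that are
    neither unmapped nor secondary/supplementary.  A nonzero exit status
    raises :class:`MapperError` carrying the captured stderr.
    """
    reads_path = Path(reads_path)
    if not reads_path.exists():
        raise FileNotFoundError(reads_path)
    submitted = count_fastq_records(reads_path)
    own_tmp = sam_path is None
    if own_tmp:
        tmp = tempfile.NamedTemporaryFile(suffix=".sam", delete=False)
        tmp.close()
        sam_path = tmp.name
    sam_path = Path(sam_path)
    try:
        cmd = spec.render(reads_path, sam_path)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise MapperError(
                f"mapper exited with status {proc.returncode}: {cmd}\n"
                f"stderr:\n{proc.stderr.strip()}"
            )
        try:
            with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
                mapped = sum(
                    1
                    for rec in sam
                    if not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary)
                )
        except (ValueError, OSError) as exc:
            raise MapperError(f"could not parse mapper SAM output: {exc}") from exc
    finally:
        if own_tmp:
            Path(sam_path).unlink(missing_ok=True)
    return mapped, submitted


def _grid_top_candidates(
    reads: Sequence[SequenceRead],
    ks: Iterable[int],
    ratios: Iterable[float],
) -> tuple[list[str], list[tuple[int, float]]]:
    """Top-1 assembled sequence of every (k, R) run, deduplicated in order."""
    seen: list[str] = []
    params: list[tuple[int, float]] = []
    for k in sorted(set(ks)):
        base = filter_low_complexity(count_kmers(reads, k))
        for r in sorted(set(ratios)):
            params.append((k, r))
            cands = assemble(filter_by_ratio(base, r))
            if cands and cands[0].sequence not in seen:
                if len(cands[0].sequence) >= CLIP_PREFIX_LEN:
                    seen.append(cands[0].sequence)
    return seen, params


def exhaustive_search(
    reads: Sequence[SequenceRead],
    mapper: MapperSpec,
    ks: Iterable[int] = DEFAULT_KS,
    ratios: Iterable[float] = DEFAULT_RS,
    min_insert: int = DEFAULT_MIN_INSERT,
    workdir: str | Path | None = None,
) -> ExhaustiveReport:
    """Select the optimal adapter by genome-mapping rate.

    Runs single-mode prediction for every (k, R) setting, deduplicates the
    per-run top candidates, evaluates each by clip -> map, and also maps
    the raw, unclipped reads.  Fractions are over the sampled input reads.
    The optimal adapter is the clipped candidate with the highest mapped
    fraction (ties: higher clipped fraction, then lexicographic);
    ``quality_ok`` applies the 20% rule to the governing mapping rate, and
    ``already_processed`` is True when RAW maps at least as well as the
    best clipped candidate and itself clears 20%.
    """
    if not reads:
        raise ValueError("reads must be nonempty")
    candidates, params = _grid_top_candidates(reads, ks, ratios)
    n = len(reads)
    evaluations: list[CandidateEvaluation] = []
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        tdir = Path(td)
        for i, adapter in enumerate(candidates):
            clipped, cfrac = clip_adapter(reads, adapter, min_insert)
            if clipped:
                fq = tdir / f"clipped_{i}.fastq"
                write_fastq(clipped, fq)
                mapped, _ = run_mapper(mapper, fq, tdir / f"clipped_{i}.sam")
            else:
                mapped = 0
            evaluations.append(
                CandidateEvaluation(
                    adapter=adapter,
                    mapped_fraction=mapped / n,
                    clipped_fraction=cfrac,
                )
            )
        raw_fq = tdir / "raw.fastq"
        write_fastq(reads, raw_fq)
        raw_mapped, _ = run_mapper(mapper, raw_fq, tdir / "raw.sam")
        raw_eval = CandidateEvaluation(
            adapter=RAW_LABEL, mapped_fraction=raw_mapped / n, clipped_fraction=None
        )
        evaluations.append(raw_eval)

    clipped_evals = [ev for ev in evaluations if not ev.is_raw]
    if clipped_evals:
        best = max(
            clipped_evals,
            key=lambda ev: (ev.mapped_fraction, ev.clipped_fraction, ev.adapter),
        )
        optimal: str | None = best.adapter
        governing = best.mapped_fraction
        already = (
            raw_eval.mapped_fraction >= best.mapped_fraction
            and raw_eval.mapped_fraction >= QUALITY_CUTOFF
        )
        if already:
            governing = raw_eval.mapped_fraction
    else:
        optimal = None
        governing = raw_eval.mapped_fraction
        already = raw_eval.mapped_fraction >= QUALITY_CUTOFF
    return ExhaustiveReport(
        evaluations=tuple(evaluations),
        optimal_adapter=optimal,
        quality_ok=governing >= QUALITY_CUTOFF,
        already_processed=already,
        sampled_reads=n,
        params=tuple(params),
    )


def assess_quality(report: ExhaustiveReport) -> str | None:
    """Return a structured warning string for a poor library, else None.

    The governing mapping rate is the optimal clipped candidate's (or
    RAW's for a processed / candidate-free library); below 20% the library
    is flagged.  Pure function of the report.
    """
    if report.quality_ok:
        return None
    ev = report.optimal_evaluation
    if report.already_processed or ev is None:
        ev = report.raw_evaluation
    rate = ev.mapped_fraction if ev is not None else 0.0
    return (
        f"QUALITY-WARNING\tmapping rate {rate:.1%} is below "
        f"{QUALITY_CUTOFF:.0%}; the input library is likely of poor quality"
    )
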