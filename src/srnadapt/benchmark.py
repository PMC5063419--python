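"""Reproducible evaluation batches over seeded synthetic libraries.

These helpers define the package's standard self-evaluation conditions --
library depth, read length, insert range, adapter fraction, contamination
scenarios -- in one place, so the test suite and the reproduction script
measure exactly the same thing.  Each library in a batch gets its own
genome and its own distinct random adapter, all derived deterministically
from a base seed.

Problem sizes: recovery batches use 50,000-read libraries (the predictor's
sampling window); mapping-based batches use 20,000-read libraries, which
keeps a full exhaustive run (grid prediction + clipping + mapping of every
candidate) to a couple of seconds per library without changing any
per-read statistic.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from srnadapt.exhaustive import assess_quality, exhaustive_search
from srnadapt.fastq_io import SequenceRead
from srnadapt.predict import adapters_match, predict_iterative, predict_single
from srnadapt.simulate import (
    LibrarySpec,
    make_exact_match_mapper,
    make_genome,
    make_library,
    random_adapter,
)

_MOD = 2**31

GENOME_LENGTH = 10_000
RECOVERY_DEPTH = 50_000
MAPPING_DEPTH = 20_000
ADAPTER_LENGTH = 20
BARCODE_LENGTH = 4


def _seed(base: int, salt: int) -> int:
    return (base * 10_007 + salt) % _MOD


def make_recovery_library(
    base_seed: int,
    index: int,
    *,
    barcoded: bool = False,
    abundant_fraction: float = 0.0,
    adapter_fraction: float = 0.8,
    n_reads: int = RECOVERY_DEPTH,
) -> tuple[list[SequenceRead], str]:
    """One seeded library plus its ground-truth (possibly barcoded) adapter."""
    s = _seed(base_seed, index)
    genome = make_genome(GENOME_LENGTH, seed=_seed(s, 1))
    adapter = random_adapter(ADAPTER_LENGTH, seed=_seed(s, 2))
    barcode = random_adapter(BARCODE_LENGTH, seed=_seed(s, 3)) if barcoded else None
    spec = LibrarySpec(
        adapter=adapter,
        barcode=barcode,
        n_reads=n_reads,
        adapter_fraction=adapter_fraction,
        abundant_rna_fraction=abundant_fraction,
        seed=_seed(s, 4),
    )
    reads, _ = make_library(spec, genome)
    return reads, spec.full_adapter


@dataclass(frozen=True)
class RecoveryResult:
    """Hit counts over a batch of libraries (a hit = >= 9-nt prefix match)."""

    single_hits: int
    iterative_hits: int
    n_libraries: int


def recovery_batch(
    base_seed: int,
    n_libraries: int = 20,
    *,
    barcoded: bool = False,
    abundant_fraction: float = 0.0,
    adapter_fraction: float = 0.8,
    modes: tuple[str, ...] = ("single", "iterative"),
) -> RecoveryResult:
    """Adapter-recovery hit counts for single and/or iterative mode."""
    single_hits = iterative_hits = 0
    for i in range(n_libraries):
        reads, truth = make_recovery_library(
            base_seed,
            i,
            barcoded=barcoded,
            abundant_fraction=abundant_fraction,
            adapter_fraction=adapter_fraction,
        )
        if "single" in modes:
            top = predict_single(reads).top
            single_hits += top is not None and adapters_match(top, truth)
        if "iterative" in modes:
            top = predict_iterative(reads).top
            iterative_hits += top is not None and adapters_match(top, truth)
    return RecoveryResult(single_hits, iterative_hits, n_libraries)


@dataclass(frozen=True)
class ProcessedDetectionResult:
    correct: int
    n_fixtures: int


def processed_detection_batch(
    base_seed: int,
    n_each: int = 10,
    n_reads: int = MAPPING_DEPTH,
) -> ProcessedDetectionResult:
    """Classify adapter-free vs adapter-bearing fixtures with the stub mapper.

    Adapter-free fixtures are full-cycle genomic reads (the shape of a
    library whose adapters were removed upstream); adapter-bearing
    fixtures carry the adapter in 90% of reads.  A fixture is scored
    correct when ``already_processed`` matches its construction.
    """
    correct = 0
    with tempfile.TemporaryDirectory() as td:
        tdir = Path(td)
        for i in range(2 * n_each):
            s = _seed(base_seed, 1000 + i)
            truth_processed = i % 2 == 0
            genome_fa = tdir / f"g{i}.fa"
            genome = make_genome(GENOME_LENGTH, seed=_seed(s, 1), fasta_path=genome_fa)
            mapper = make_exact_match_mapper(genome_fa, tdir / f"map{i}.py")
            if truth_processed:
                spec = LibrarySpec(
                    adapter="", adapter_fraction=0.0, n_reads=n_reads, seed=_seed(s, 4)
                )
            else:
                spec = LibrarySpec(
                    adapter=random_adapter(ADAPTER_LENGTH, seed=_seed(s, 2)),
                    adapter_fraction=0.9,
                    n_reads=n_reads,
                    seed=_seed(s, 4),
                )
            reads, _ = make_library(spec, genome)
            report = exhaustive_search(reads, mapper, workdir=td)
            correct += report.already_processed == truth_processed
    return ProcessedDetectionResult(correct, 2 * n_each)


@dataclass(frozen=True)
class QualityProbeResult:
    """Mapping rates and warnings for a poor and a good library."""

    poor_mapped_fraction: float
    poor_warned: bool
    good_mapped_fraction: float
    good_warned: bool
    n_reads: int


def quality_probe(base_seed: int, n_reads: int = MAPPING_DEPTH) -> QualityProbeResult:
    """Exercise the 20% quality rule.

    The poor library has no genomic origin: its inserts come from a
    different random genome than the mapper's reference, so however the
    adapter is clipped almost nothing maps.  The good library's inserts
    come from the reference itself.
    """
    with tempfile.TemporaryDirectory() as td:
        tdir = Path(td)
        genome_fa = tdir / "ref.fa"
        ref = make_genome(GENOME_LENGTH, seed=_seed(base_seed, 11), fasta_path=genome_fa)
        mapper = make_exact_match_mapper(genome_fa, tdir / "map.py")
        foreign = make_genome(GENOME_LENGTH, seed=_seed(base_seed, 12))

        def probe(genome: str, salt: int):
            spec = LibrarySpec(
                adapter=random_adapter(ADAPTER_LENGTH, seed=_seed(base_seed, salt)),
                adapter_fraction=0.9,
                n_reads=n_reads,
                seed=_seed(base_seed, salt + 1),
            )
            reads, _ = make_library(spec, genome)
            report = exhaustive_search(reads, mapper, workdir=td)
            ev = report.optimal_evaluation or report.raw_evaluation
            return ev.mapped_fraction, assess_quality(report) is not None

        poor_rate, poor_warned = probe(foreign, 21)
        good_rate, good_warned = probe(ref, 31)
    return QualityProbeResult(poor_rate, poor_warned, good_rate, good_warned, n_reads)
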