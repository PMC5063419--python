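"""Seeded synthetic small RNA libraries and toy genomes with known truth.

The generator emulates the read classes seen in public small RNA
libraries so every pipeline stage is testable offline:

* **adapter** reads: a genomic insert (16-30 nt scale) followed by the 3'
  adapter, optionally preceded by a de-multiplexing barcode retained at
  the adapter's 5' end;
* **abundant** reads: one fixed, highly sequenced small RNA species
  (a known confounder for frequency-based prediction);
* **dimer** reads: pure adapter concatenations -- ligation products with
  no insert, as seen in immunoprecipitation controls;
* **genomic** reads: full-cycle genomic sequence with no adapter in reach,
  modelling both already-processed libraries and long-insert dropout.

All randomness flows from a single NumPy generator seeded by the library
spec, so identical specs produce byte-identical FASTQ and manifests.
Class counts follow a largest-remainder quota, exact to within one read.
"""

from __future__ import annotations

import shlex
import stat
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from srnadapt.exhaustive import MapperSpec
from srnadapt.fastq_io import SequenceRead, write_fastq

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CLASS_ADAPTER = "adapter"
CLASS_ABUNDANT = "abundant"
CLASS_DIMER = "dimer"
CLASS_GENOMIC = "genomic"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class QualityModel:
    """Per-cycle Phred means declining linearly along the read.

    Defaults (38 -> 30, sd 2) describe a decent modern run; early-platform
    libraries can be emulated by lowering the means.  Scores are clamped
    to [2, 40] and encoded at offset 33.
    """

    start_mean: float = 38.0
    end_mean: float = 30.0
    noise_sd: float = 2.0


@dataclass(frozen=True, slots=True)
class LibrarySpec:
    """Ground-truth recipe for one synthetic library."""

    adapter: str
    n_reads: int = 50_000
    read_length: int = 36
    insert_length_range: tuple[int, int] = (18, 26)
    barcode: str | None = None
    adapter_fraction: float = 1.0
    abundant_rna_fraction: float = 0.0
    dimer_fraction: float = 0.0
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.adapter_fraction, self.abundant_rna_fraction, self.dimer_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-9:
            raise ValueError("class fractions must jointly be <= 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        lo, hi = self.insert_length_range
        if not (1 <= lo <= hi <= self.read_length):
            raise ValueError("insert length bounds must satisfy 1 <= lo <= hi <= read_length")
        needs_adapter = self.adapter_fraction > 0 or self.abundant_rna_fraction > 0 or self.dimer_fraction > 0
        if needs_adapter and not self.adapter:
            raise ValueError("adapter must be nonempty when adapter-bearing classes are requested")

    @property
    def full_adapter(self) -> str:
        """The sequence actually ligated 3' of the insert (barcode + adapter)."""
        return (self.barcode or "") + self.adapter


@dataclass(frozen=True, slots=True)
class ManifestEntry:
    """Per-read ground truth: class and genomic insert coordinates.

    ``insert_start``/``insert_end`` are 0-based half-open genome
    coordinates of the insert (−1 for dimer reads, which have none);
    ``strand`` is '+', '-' or '.' for dimers.
    """

    read_id: str
    read_class: str
    insert_start: int
    insert_end: int
    strand: str


def make_genome(
    length: int, seed: int, fasta_path: str | Path | None = None, name: str = "toygenome"
) -> str:
    """Uniform random A/C/G/T genome, optionally written as one-record FASTA."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    genome = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    if fasta_path is not None:
        SeqIO.write([SeqRecord(Seq(genome), id=name, description="")], str(fasta_path), "fasta")
    return genome


def random_adapter(length: int, seed: int, max_run: int = 3) -> str:
    """A random adapter-like oligo with no homopolymer run above ``max_run``.

    Real adapter oligos are designed sequences screened for complexity;
    unconstrained random strings would contain long runs that no vendor
    adapter has, so runs are capped (default 3, below the floor(k/2)=4
    threshold of the low-complexity filter at k=9).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    run = 0
    for _ in range(length):
        if run >= max_run:
            choices = [b for b in _BASES if b != out[-1]]
            b = choices[rng.integers(0, len(choices))]
        else:
            b = _BASES[rng.integers(0, 4)]
        run = run + 1 if out and b == out[-1] else 1
        out.append(b)
    return "".join(out)


def _class_counts(spec: LibrarySpec) -> dict[str, int]:
    """Largest-remainder allocation of reads to classes (exact to ±1)."""
    fracs = {
        CLASS_ADAPTER: spec.adapter_fraction,
        CLASS_ABUNDANT: spec.abundant_rna_fraction,
        CLASS_DIMER: spec.dimer_fraction,
    }
    fracs[CLASS_GENOMIC] = max(0.0, 1.0 - sum(fracs.values()))
    exact = {c: f * spec.n_reads for c, f in fracs.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = spec.n_reads - sum(counts.values())
    for c in sorted(exact, key=lambda c: (exact[c] - counts[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def make_library(
    spec: LibrarySpec,
    genome: str,
    fastq_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[SequenceRead], list[ManifestEntry]]:
    """Generate a synthetic library from a genome string.

    Every read is built as insert + barcode + adapter per its class,
    truncated to ``read_length`` and padded with random downstream bases
    when shorter (the sequencer keeps reading past short fragments).
    Returns the reads and the per-read ground-truth manifest; optionally
    writes FASTQ and a tab-separated manifest.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    lo, hi = spec.insert_length_range
    counts = _class_counts(spec)
    labels = np.array(
        [CLASS_ADAPTER] * counts[CLASS_ADAPTER]
        + [CLASS_ABUNDANT] * counts[CLASS_ABUNDANT]
        + [CLASS_DIMER] * counts[CLASS_DIMER]
        + [CLASS_GENOMIC] * counts[CLASS_GENOMIC]
    )
    rng.shuffle(labels)

    # one fixed abundant species per library, drawn once
    ab_len = int(rng.integers(lo, hi + 1))
    ab_start = int(rng.integers(0, len(genome) - ab_len + 1))
    ab_strand = "+" if rng.integers(0, 2) == 0 else "-"
    ab_insert = genome[ab_start : ab_start + ab_len]
    if ab_strand == "-":
        ab_insert = reverse_complement(ab_insert)

    qm = spec.quality_model
    means = np.linspace(qm.start_mean, qm.end_mean, L)
    qmat = np.clip(
        np.rint(means + rng.normal(0.0, qm.noise_sd, size=(spec.n_reads, L))), 2, 40
    ).astype(np.int64)

    full_adapter = spec.full_adapter
    dimer_body = (full_adapter * (L // max(1, len(full_adapter)) + 2))[:L] if full_adapter else ""

    reads: list[SequenceRead] = []
    manifest: list[ManifestEntry] = []
    for i, label in enumerate(labels):
        if label == CLASS_DIMER:
            seq = dimer_body
            start = end = -1
            strand = "."
        elif label == CLASS_GENOMIC:
            start = int(rng.integers(0, len(genome) - L + 1))
            end = start + L
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            seq = genome[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
        else:
            if label == CLASS_ABUNDANT:
                ilen, start, strand = ab_len, ab_start, ab_strand
                insert = ab_insert
            else:
                ilen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, len(genome) - ilen + 1))
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                insert = genome[start : start + ilen]
                if strand == "-":
                    insert = reverse_complement(insert)
            end = start + ilen
            seq = (insert + full_adapter)[:L]
            if len(seq) < L:
                pad = "".join(_BASES[j] for j in rng.integers(0, 4, size=L - len(seq)))
                seq += pad
        quals = "".join(chr(q + 33) for q in qmat[i])
        read_id = f"sim_{i:06d}"
        reads.append(SequenceRead(read_id, seq, quals))
        manifest.append(ManifestEntry(read_id, str(label), start, end, strand))

    if fastq_path is not None:
        write_fastq(reads, fastq_path, gzip_out=str(fastq_path).endswith(".gz"))
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write("read_id\tclass\tinsert_start\tinsert_end\tstrand\n")
            for m in manifest:
                fh.write(
                    f"{m.read_id}\t{m.read_class}\t{m.insert_start}\t"
                    f"{m.insert_end}\t{m.strand}\n"
                )
    return reads, manifest


_STUB_TEMPLATE = '''#!/usr/bin/env python3
"""Synthetic exact-match read mapper (test stub).

Reports a read as mapped iff its sequence -- or its reverse complement --
occurs exactly in the reference genome, and emits minimal valid SAM.
Usage: exact_match_mapper.py GENOME_FASTA READS_FASTQ OUT_SAM
"""
import sys

def read_fasta(path):
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is None:
                    name = line[1:].split()[0]
                continue
            parts.append(line.upper())
    return name or "ref", "".join(parts)

def revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]

def main(genome_fa, fastq, out_sam):
    name, genome = read_fasta(genome_fa)
    with open(fastq) as fh, open(out_sam, "w") as out:
        out.write("@HD\\tVN:1.6\\tSO:unsorted\\n")
        out.write(f"@SQ\\tSN:{name}\\tLN:{len(genome)}\\n")
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip().upper()
            fh.readline()
            qual = fh.readline().strip() or "*"
            qname = h[1:].split()[0].strip()
            pos = genome.find(seq) if seq else -1
            flag = 0
            if pos < 0 and seq:
                rc = revcomp(seq)
                pos = genome.find(rc)
                flag = 16
            if pos < 0 or not seq:
                out.write(f"{qname}\\t4\\t*\\t0\\t0\\t*\\t*\\t0\\t0\\t{seq or '*'}\\t{qual}\\n")
            else:
                out.write(
                    f"{qname}\\t{flag}\\t{name}\\t{pos + 1}\\t42\\t{len(seq)}M"
                    f"\\t*\\t0\\t0\\t{seq}\\t{qual}\\n"
                )

if __name__ == "__main__":
    if len(sys.argv) != 4:
        sys.exit("usage: exact_match_mapper.py GENOME_FASTA READS_FASTQ OUT_SAM")
    main(*sys.argv[1:])
'''


def make_exact_match_mapper(
    genome_fasta: str | Path, script_path: str | Path
) -> MapperSpec:
    """Write a self-contained exact-match mapper stub and return its spec.

    The stub plays the role of a strict aligner (perfect matches only,
    both strands) in tests and offline runs; the returned
    :class:`MapperSpec` invokes it through the current Python interpreter.
    """
    script_path = Path(script_path)
    script_path.write_text(_STUB_TEMPLATE)
    script_path.chmod(script_path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP)
    template = (
        f"{shlex.quote(sys.executable)} {shlex.quote(str(script_path))} "
        f"{shlex.quote(str(genome_fasta))} {{input}} {{output}}"
    )
    return MapperSpec(command_template=template)
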