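"""Small-RNA read QC and mature-miRNA counting.

Reads are 3'-adapter trimmed (longest suffix matching a prefix of the
adapter, exact, with a minimum overlap), then kept when 18-30 nt long
with mean Phred strictly above 20.  Clean reads are assigned to mature
miRNA sequences: exact sequence identity first; failing that, equal
length at Hamming distance 1 (no indels).  A read matching several
mature ids — miRBase lists distinct ids with identical mature
sequences, e.g. let-7 family members — increments all of them, while
the assigned-read statistic counts it once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import QCParams, log

__all__ = [
    "MatureSet",
    "QCStats",
    "read_mature_fasta",
    "trim_adapter",
    "filter_reads",
    "assign_reads",
    "quantify_library",
]

_DNA = set("ACGTN")


@dataclass(frozen=True)
class MatureSet:
    """Mature miRNA catalogue: id -> uppercase DNA sequence (U normalized to T).

    Distinct ids may share a sequence.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty mature set")
        for mid, seq in self.sequences.items():
            if not set(seq) <= _DNA:
                raise ValueError(f"{mid}: non-DNA characters in {seq!r}")

    def by_sequence(self) -> dict[str, list[str]]:
        table: dict[str, list[str]] = defaultdict(list)
        for mid, seq in self.sequences.items():
            table[seq].append(mid)
        return dict(table)


@dataclass
class QCStats:
    total_reads: int = 0
    passed_reads: int = 0
    assigned_reads: int = 0
    perfect_match_reads: int = 0
    one_mismatch_reads: int = 0
    unassigned_reads: int = 0
    discarded_length: int = 0
    discarded_quality: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"statistic": k, "value": v} for k, v in vars(self).items()]
        )


def read_mature_fasta(path) -> MatureSet:
    """Load mature sequences from FASTA; RNA alphabets are normalized to DNA."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return MatureSet(seqs)


def trim_adapter(
    seq: str, qual: str, adapter: str, min_overlap: int = 6
) -> tuple[str, str]:
    """Remove the 3' adapter and everything downstream of it.

    The match is the leftmost position where the read continues as a
    prefix of the adapter (full adapter if it fits, otherwise the
    adapter's own prefix running off the read's end), exact and at least
    ``min_overlap`` long.  No match leaves the read unchanged; quality is
    trimmed in lockstep.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        span = min(len(adapter), n - i)
        if seq[i : i + span] == adapter[:span]:
            return seq[:i], qual[:i]
    return seq, qual


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def filter_reads(fastq_path, qc: QCParams) -> tuple[list[str], QCStats]:
    """Adapter-trim and quality-filter a FASTQ file.

    Returns the clean read sequences and a QCStats with assignment
    fields still zero.  Malformed records raise with the 1-based record
    index.
    """
    stats = QCStats()
    clean: list[str] = []
    idx = 0
    try:
        with open(fastq_path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                idx += 1
                if len(seq) != len(qual):
                    raise ValueError("sequence/quality length mismatch")
                stats.total_reads += 1
                seq = seq.upper()
                if qc.trim_5prime and qc.adapter_5prime:
                    # same rule mirrored onto the 5' end
                    rs, rq = trim_adapter(
                        seq[::-1], qual[::-1], qc.adapter_5prime[::-1],
                        qc.min_adapter_overlap,
                    )
                    seq, qual = rs[::-1], rq[::-1]
                seq, qual = trim_adapter(seq, qual, qc.adapter, qc.min_adapter_overlap)
                if not (qc.min_len <= len(seq) <= qc.max_len):
                    stats.discarded_length += 1
                    continue
                if not _mean_phred(qual) > qc.min_mean_phred:
                    stats.discarded_quality += 1
                    continue
                stats.passed_reads += 1
                clean.append(seq)
    except ValueError as err:
        raise ValueError(f"malformed FASTQ record #{idx + 1} in {fastq_path}: {err}") from err
    log.info(
        "filter_reads %s: %d total, %d passed (%d short/long, %d low-quality)",
        fastq_path, stats.total_reads, stats.passed_reads,
        stats.discarded_length, stats.discarded_quality,
    )
    return clean, stats


def _hamming1_ids(read: str, by_seq: dict[str, list[str]]) -> list[str]:
    """Mature ids at Hamming distance exactly 1 from the read (equal length)."""
    ids: list[str] = []
    seen: set[str] = set()
    for pos in range(len(read)):
        orig = read[pos]
        for base in "ACGT":
            if base == orig:
                continue
            variant = read[:pos] + base + read[pos + 1 :]
            if variant in by_seq and variant not in seen:
                seen.add(variant)
                ids.extend(by_seq[variant])
    return ids


def assign_reads(
    reads: list[str], mature: MatureSet, max_mismatch: int = 1,
    stats: QCStats | None = None,
) -> tuple[pd.Series, QCStats]:
    """Count clean reads against the mature catalogue.

    Exact matches take strict priority; only a read with no exact match
    is considered at Hamming distance 1 (when ``max_mismatch`` >= 1).
    Each read adds 1 to *every* mature id it matches, so duplicated
    mature sequences under distinct ids receive identical counts.
    """
    if stats is None:
        stats = QCStats(passed_reads=len(reads), total_reads=len(reads))
    by_seq = mature.by_sequence()
    counts = {mid: 0 for mid in mature.sequences}
    for read in reads:
        ids = by_seq.get(read)
        if ids is not None:
            stats.perfect_match_reads += 1
        elif max_mismatch >= 1:
            ids = _hamming1_ids(read, by_seq) or None
            if ids is not None:
                stats.one_mismatch_reads += 1
        if ids is None:
            stats.unassigned_reads += 1
            continue
        for mid in ids:
            counts[mid] += 1
    stats.assigned_reads = stats.perfect_match_reads + stats.one_mismatch_reads
    return pd.Series(counts, name="count"), stats


def quantify_library(
    fastq_path, mature: MatureSet, qc: QCParams, max_mismatch: int = 1
) -> tuple[pd.Series, QCStats]:
    """filter_reads then assign_reads for one library."""
    clean, stats = filter_reads(fastq_path, qc)
    return assign_reads(clean, mature, max_mismatch=max_mismatch, stats=stats)
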