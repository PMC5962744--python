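"""Read quality control: 3' quality trimming, length and low-complexity
filters, and exact-duplicate removal, with a per-rule audit report.

The filter chain runs in a fixed order — trim, minimum length, low
complexity, duplicates — and each removed read is counted under the first
rule that fired, so the report columns always sum back to the input count.
Low complexity is measured as Shannon entropy of the empirical k-mer
distribution (``N`` counts as a fifth symbol so runs of ``N`` cannot score
as complex sequence).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import SequenceRead

#: Removal-rule keys, in the order the rules fire.
QC_RULES = ("empty_after_trim", "short", "low_complexity", "duplicate")

DEFAULT_MIN_LEN = 34
DEFAULT_TRIM_WINDOW = 5
DEFAULT_TRIM_Q = 15
DEFAULT_ENTROPY_K = 3
DEFAULT_ENTROPY_MIN = 1.5


@dataclass
class QCReport:
    """Audit of a filtering run: every input read is either kept, counted
    under exactly one removal rule, or (if shortened but retained) counted
    as trimmed."""

    input_count: int = 0
    kept_count: int = 0
    trimmed_count: int = 0
    removed_by_rule: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in QC_RULES}
    )

    @property
    def removed_total(self) -> int:
        return sum(self.removed_by_rule.values())

    def check(self) -> None:
        if self.input_count != self.kept_count + self.removed_total:
            raise AssertionError(
                f"QC conservation violated: {self.input_count} in != "
                f"{self.kept_count} kept + {self.removed_total} removed"
            )


def trim_quality(
    read: SequenceRead,
    window: int = DEFAULT_TRIM_WINDOW,
    q_threshold: float = DEFAULT_TRIM_Q,
) -> SequenceRead:
    """Trim low-quality bases from the 3' end.

    Repeatedly removes the terminal base while either the terminal base
    quality is below *q_threshold* or the mean quality over the terminal
    window of size ``min(window, remaining length)`` is below it.  The
    trailing-base condition guarantees the kept read never ends in a base
    below the threshold, which a pure window mean would permit.  May return
    an empty read.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    quals = read.qualities
    end = len(quals)
    while end > 0:
        w = min(window, end)
        tail = quals[end - w:end]
        if quals[end - 1] < q_threshold or sum(tail) / w < q_threshold:
            end -= 1
        else:
            break
    return SequenceRead(read.read_id, read.bases[:end], quals[:end])


def sequence_entropy(bases: str, k: int = DEFAULT_ENTROPY_K) -> float:
    """Shannon entropy (bits) of the empirical k-mer distribution of *bases*.

    ``N`` (or any non-ACGT symbol) is treated as an ordinary fifth symbol.
    Raises ``ValueError`` when the sequence is shorter than *k*.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_kmers = len(bases) - k + 1
    if n_kmers < 1:
        raise ValueError(f"sequence of length {len(bases)} shorter than k={k}")
    counts = Counter(bases[i:i + k] for i in range(n_kmers))
    ent = 0.0
    for c in counts.values():
        p = c / n_kmers
        ent -= p * math.log2(p)
    return ent


def filter_reads(
    reads: Iterable[SequenceRead],
    min_len: int = DEFAULT_MIN_LEN,
    entropy_k: int = DEFAULT_ENTROPY_K,
    entropy_threshold: float = DEFAULT_ENTROPY_MIN,
    trim_window: int = DEFAULT_TRIM_WINDOW,
    trim_q: float = DEFAULT_TRIM_Q,
    dedupe: bool = True,
) -> tuple[list[SequenceRead], QCReport]:
    """Run the full QC chain over *reads* and return kept reads plus report.

    Rule order is fixed: 3' quality trim; drop if empty after trim; drop if
    shorter than *min_len*; drop if k-mer entropy is below
    *entropy_threshold*; drop exact sequence duplicates keeping the first
    occurrence.  Reads shorter than *entropy_k* (only reachable when
    ``min_len < entropy_k``) count as low complexity.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    report = QCReport()
    kept: list[SequenceRead] = []
    seen: set[str] = set()
    for read in reads:
        report.input_count += 1
        trimmed = trim_quality(read, window=trim_window, q_threshold=trim_q)
        if len(trimmed) == 0:
            report.removed_by_rule["empty_after_trim"] += 1
            continue
        if len(trimmed) < min_len:
            report.removed_by_rule["short"] += 1
            continue
        if len(trimmed) < entropy_k or sequence_entropy(trimmed.bases, entropy_k) < entropy_threshold:
            report.removed_by_rule["low_complexity"] += 1
            continue
        if dedupe:
            if trimmed.bases in seen:
                report.removed_by_rule["duplicate"] += 1
                continue
            seen.add(trimmed.bases)
        if len(trimmed) < len(read):
            report.trimmed_count += 1
        kept.append(trimmed)
        report.kept_count += 1
    report.check()
    return kept, report


def write_qc_report(report: QCReport, path) -> None:
    """Write the QC report as a two-column rule/count TSV."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#rule\tcount\n")
        fh.write(f"input\t{report.input_count}\n")
        for rule in QC_RULES:
            fh.write(f"{rule}\t{report.removed_by_rule[rule]}\n")
        fh.write(f"trimmed_kept\t{report.trimmed_count}\n")
        fh.write(f"kept\t{report.kept_count}\n")
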