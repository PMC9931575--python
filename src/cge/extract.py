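"""Turn amplicon FASTQ reads into per-sample sequence-tag count tables.

Pipeline per read: (1) assign to a locus by exact match of the first 20 nt
of the read to a locus-specific amplicon prefix; (2) locate the first exact
occurrence of the original or mutant variant sequence and cut out the
flanking 5+5 nt as the candidate tag (a 16-nt window for a 6-nt variant);
(3) accept the read iff the candidate tag is within ``max_subs``
substitutions of the reference flank. The matching is substitution-only —
the window has fixed length, so an indel in the flank shifts the extracted
bases and is rejected through the resulting mismatch pile-up, mirroring
agrep with prohibitive insertion/deletion costs (-I5 -D5).

Base qualities are ignored; reads are scanned in the sequenced (forward)
orientation unless a reverse-complement scan is requested.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import reverse_complement

from .design import LocusDesign

#: default acceptance radius for the paired-lineage analysis
MAX_SUBS_PAIR = 2
#: default acceptance radius for the editing-efficiency decomposition
MAX_SUBS_EFFICIENCY = 5

REJECT_REASONS = ("no_center", "truncated", "too_many_subs", "ambiguous_center")


class ConfigError(ValueError):
    """Inconsistent locus design collection (e.g. duplicate prefixes)."""


@dataclass(frozen=True)
class WindowMatch:
    """One accepted variant-anchored window from one read."""

    variant_label: str  # "original" | "mutant"
    tag: str
    n_flank_mutations: int
    read_id: str = ""


@dataclass
class TagCountTable:
    """Raw per-(variant, tag) read counts for one sample at one locus."""

    sample_id: str
    locus_name: str
    counts: Counter = field(default_factory=Counter)  # (variant_label, tag) -> count
    total_reads_assigned: int = 0
    reject_reasons: Counter = field(default_factory=Counter)

    def count(self, variant_label: str, tag: str) -> int:
        return self.counts.get((variant_label, tag), 0)

    @property
    def n_accepted(self) -> int:
        return sum(self.counts.values())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def validate_designs(designs: Iterable[LocusDesign]) -> list[LocusDesign]:
    """Check mutual distinctness of locus-assignment prefixes."""
    designs = list(designs)
    seen: dict[str, str] = {}
    for d in designs:
        if d.prefix in seen:
            raise ConfigError(
                f"loci {seen[d.prefix]!r} and {d.locus_name!r} share the prefix {d.prefix}"
            )
        seen[d.prefix] = d.locus_name
    return designs


def assign_locus(read_sequence: str, designs: Iterable[LocusDesign]) -> str | None:
    """Locus whose prefix matches the read start exactly, else None.

    Only the prefix is examined; the remainder of the read may be arbitrary.
    """
    for d in designs:
        if read_sequence.startswith(d.prefix):
            return d.locus_name
    return None


def extract_window(
    read_sequence: str,
    design: LocusDesign,
    max_subs: int = MAX_SUBS_PAIR,
    read_id: str = "",
) -> WindowMatch | None:
    """Extract and validate the tagged window around the first variant hit.

    Returns None (with no side effects) when the read has no exact variant
    occurrence, the window would run off the read, both variant sequences
    occur, or the candidate tag exceeds ``max_subs`` substitutions.
    Use :func:`extract_window_verbose` when the reject reason is needed.
    """
    match, _ = extract_window_verbose(read_sequence, design, max_subs, read_id)
    return match


def extract_window_verbose(
    read_sequence: str,
    design: LocusDesign,
    max_subs: int = MAX_SUBS_PAIR,
    read_id: str = "",
) -> tuple[WindowMatch | None, str | None]:
    """As :func:`extract_window` but also returns the reject reason."""
    read_sequence = read_sequence.upper()
    i_orig = read_sequence.find(design.original_seq)
    i_mut = read_sequence.find(design.mutant_seq)
    if i_orig >= 0 and i_mut >= 0:
        return None, "ambiguous_center"
    if i_orig < 0 and i_mut < 0:
        return None, "no_center"
    if i_orig >= 0:
        variant_label, pos, center = "original", i_orig, design.original_seq
    else:
        variant_label, pos, center = "mutant", i_mut, design.mutant_seq

    f = design.flank_len
    lo, hi = pos - f, pos + len(center) + f
    if lo < 0 or hi > len(read_sequence):
        return None, "truncated"
    tag = read_sequence[lo:pos] + read_sequence[pos + len(center) : hi]
    n_mut = hamming(tag, design.reference_flank)
    if n_mut > max_subs:
        return None, "too_many_subs"
    return WindowMatch(variant_label, tag, n_mut, read_id), None


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(source) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path/handle; tolerates gzip."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as handle:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(handle, "fastq"))
    else:
        yield from ((r.id, str(r.seq)) for r in SeqIO.parse(source, "fastq"))


def count_tags(
    fastq_source,
    designs: Iterable[LocusDesign],
    sample_id: str = "sample",
    max_subs: int = MAX_SUBS_PAIR,
    scan_reverse_complement: bool = False,
) -> dict[str, TagCountTable]:
    """Count reads per unique (variant, tag) for every locus in one sample.

    ``fastq_source`` may be a FASTQ(.gz) path, an open handle, or an
    iterable of (read_id, sequence) pairs. Counts are raw — the +1
    pseudocount belongs to ratio formation downstream, not here. Reads
    failing prefix assignment are tallied under the pseudo-locus
    ``__unassigned__``; per-table reject reasons record window attrition.
    """
    designs = validate_designs(designs)
    by_name = {d.locus_name: d for d in designs}
    tables = {
        name: TagCountTable(sample_id=sample_id, locus_name=name) for name in by_name
    }
    n_unassigned = 0

    if isinstance(fastq_source, (str, Path)) or hasattr(fastq_source, "read"):
        reads: Iterable[tuple[str, str]] = iter_fastq(fastq_source)
    else:
        reads = fastq_source

    n_malformed = 0
    reads_iter = iter(reads)
    while True:
        try:
            read_id, seq = next(reads_iter)
        except StopIteration:
            break
        except ValueError as exc:  # malformed FASTQ record aborts the parser
            warnings.warn(f"malformed FASTQ record in {sample_id}: {exc}", stacklevel=2)
            n_malformed += 1
            break
        seq = seq.upper()
        locus = assign_locus(seq, designs)
        if locus is None and scan_reverse_complement:
            rc = reverse_complement(seq)
            locus = assign_locus(rc, designs)
            if locus is not None:
                seq = rc
        if locus is None:
            n_unassigned += 1
            continue
        table = tables[locus]
        table.total_reads_assigned += 1
        match, reason = extract_window_verbose(seq, by_name[locus], max_subs, read_id)
        if match is None:
            table.reject_reasons[reason] += 1
        else:
            table.counts[(match.variant_label, match.tag)] += 1

    for t in tables.values():
        t.reject_reasons["no_prefix_total_sample"] = n_unassigned
        if n_malformed:
            t.reject_reasons["malformed_total_sample"] = n_malformed
    return tables


def count_exact_variants(fastq_source, variant_sequences: Iterable[str]) -> Counter:
    """Exact-substring counts of full tagged template sequences per read.

    Used for coding-region (degenerate codon) libraries, where each template
    variant is a fully specified sequence and the read either contains it
    verbatim or not. A read increments every listed sequence it contains;
    in a well-formed library the variants are mutually exclusive.
    """
    variant_sequences = [v.upper() for v in variant_sequences]
    counts: Counter = Counter({v: 0 for v in variant_sequences})
    if isinstance(fastq_source, (str, Path)) or hasattr(fastq_source, "read"):
        reads: Iterable[tuple[str, str]] = iter_fastq(fastq_source)
    else:
        reads = fastq_source
    for _read_id, seq in reads:
        seq = seq.upper()
        for v in variant_sequences:
            if v in seq:
                counts[v] += 1
    return counts
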