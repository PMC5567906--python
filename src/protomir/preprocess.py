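"""Raw small-RNA read cleaning with a per-category accounting ledger.

Every raw read is assigned to exactly one category by the first failing
test in a fixed order (low quality -> 3' adapter missing -> empty insert
-> 5' adapter contaminant -> too short -> poly-A -> clean), mirroring the
read-accounting summaries that BGI-style sRNA pipelines print.  Clean
inserts are collapsed into a unique-sequence count profile, the central
count-bearing object of the downstream stages.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import normalize

#: ledger category keys, in assignment (precedence) order
CATEGORIES = (
    "low_quality",
    "no_3adapter",
    "insert_null",
    "contaminant_5adapter",
    "shorter_than_18",
    "poly_a",
    "clean",
)


@dataclass
class ReadLedger:
    """Per-category read counts for one library.

    ``clean_reads`` is derived, never stored: it must always equal
    high-quality reads minus the sum of the removal categories, and
    ``validate`` enforces that every category is bounded by the totals.
    """

    total_reads: int = 0
    high_quality: int = 0
    no_3adapter: int = 0
    insert_null: int = 0
    contaminant_5adapter: int = 0
    shorter_than_18: int = 0
    poly_a: int = 0

    @property
    def removed(self) -> int:
        return (
            self.no_3adapter
            + self.insert_null
            + self.contaminant_5adapter
            + self.shorter_than_18
            + self.poly_a
        )

    @property
    def clean_reads(self) -> int:
        return self.high_quality - self.removed

    @property
    def clean_pct(self) -> float:
        """Clean reads as a percentage of high-quality reads, 2 decimals."""
        if self.high_quality == 0:
            return 0.0
        return round(100.0 * self.clean_reads / self.high_quality, 2)

    @property
    def low_quality(self) -> int:
        return self.total_reads - self.high_quality

    def validate(self) -> None:
        for name in (
            "no_3adapter",
            "insert_null",
            "contaminant_5adapter",
            "shorter_than_18",
            "poly_a",
        ):
            v = getattr(self, name)
            if v < 0 or v > self.high_quality:
                raise ValueError(f"ledger category {name}={v} out of bounds")
        if not (0 <= self.high_quality <= self.total_reads):
            raise ValueError("high_quality must be between 0 and total_reads")
        if self.clean_reads < 0:
            raise ValueError("removal categories exceed high-quality reads")

    def as_dict(self) -> dict[str, int | float]:
        d = dataclasses.asdict(self)
        d["low_quality"] = self.low_quality
        d["clean_reads"] = self.clean_reads
        d["clean_pct"] = self.clean_pct
        return d


@dataclass
class LibraryProfile:
    """Collapsed unique insert sequences with read counts for one library."""

    condition: str
    seq_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_clean(self) -> int:
        return sum(self.seq_counts.values())

    @property
    def unique_count(self) -> int:
        return len(self.seq_counts)

    def validate(self, min_len: int = 18, max_len: int = 30) -> None:
        for seq, n in self.seq_counts.items():
            if n <= 0:
                raise ValueError(f"non-positive count for {seq}")
            if not (min_len <= len(seq) <= max_len):
                raise ValueError(f"sequence length {len(seq)} outside window")


def find_adapter3(
    read: str,
    adapter3: str,
    min_overlap: int = 6,
    max_mismatch: int = 1,
    max_insert: int = 30,
) -> int | None:
    """Locate the 3' adapter; return the insert length (match start) or None.

    The earliest position where a >=min_overlap prefix of the adapter
    matches with at most ``max_mismatch`` mismatches wins.  Matches that
    would leave an insert longer than ``max_insert`` are not usable (the
    adapter is then effectively absent from the sequenced window).
    """
    n = len(read)
    limit = min(n - min_overlap, max_insert)
    # fast path: exact hit of a 10-nt adapter prefix bounds the fuzzy scan
    probe = adapter3[: min(10, len(adapter3))]
    p_exact = read.find(probe)
    if not (0 <= p_exact <= limit):
        p_exact = None
    scan_end = limit if p_exact is None else p_exact - 1
    for pos in range(0, scan_end + 1):
        k = min(len(adapter3), n - pos)
        if k < min_overlap:
            break
        mm = 0
        for a, b in zip(read[pos : pos + k], adapter3):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return pos
    return p_exact


def _matches_5adapter(insert: str, adapter5: str, min_overlap: int = 8,
                      max_mismatch: int = 1) -> bool:
    """True if the insert starts with a 5' adapter prefix (ligation dimer)."""
    k = min(len(insert), len(adapter5))
    if k < min_overlap:
        return False
    mm = sum(1 for a, b in zip(insert, adapter5) if a != b)
    return mm <= max_mismatch


def _is_poly_a(insert: str, frac: float = 0.8) -> bool:
    return insert.count("A") >= frac * len(insert)


def _is_low_quality(seq: str, qual: str | None, min_mean_phred: float) -> bool:
    if "N" in seq or not set(seq) <= set("ACGTU"):
        return True
    if qual:
        mean = sum(ord(c) - 33 for c in qual) / len(qual)
        if mean < min_mean_phred:
            return True
    return False


def clean_reads(
    reads: Iterable,
    adapter3: str,
    adapter5: str | None = None,
    min_len: int = 18,
    max_len: int = 30,
    min_mean_phred: float = 20.0,
    condition: str = "library",
) -> tuple[LibraryProfile, ReadLedger]:
    """Clean raw reads into a collapsed profile plus category ledger.

    ``reads`` yields sequences, ``(seq, qual)`` pairs, or
    ``(seq, qual, count)`` triples (count > 1 for pre-collapsed input).
    Each read lands in exactly one ledger category; the ledger
    conservation invariant holds on return.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    ledger = ReadLedger()
    counts: Counter[str] = Counter()
    for rec in reads:
        if isinstance(rec, str):
            seq, qual, n = rec, None, 1
        elif len(rec) == 2:
            (seq, qual), n = rec, 1
        else:
            seq, qual, n = rec
        seq = seq.upper()
        ledger.total_reads += n
        if _is_low_quality(seq, qual, min_mean_phred):
            continue
        ledger.high_quality += n
        seq = normalize(seq)
        pos = find_adapter3(seq, normalize(adapter3), max_insert=max_len)
        if pos is None:
            ledger.no_3adapter += n
            continue
        if pos == 0:
            ledger.insert_null += n
            continue
        insert = seq[:pos]
        if adapter5 and _matches_5adapter(insert, normalize(adapter5)):
            ledger.contaminant_5adapter += n
            continue
        if len(insert) < min_len:
            ledger.shorter_than_18 += n
            continue
        if _is_poly_a(insert):
            ledger.poly_a += n
            continue
        counts[insert] += n
    ledger.validate()
    profile = LibraryProfile(condition=condition, seq_counts=dict(counts))
    assert profile.total_clean == ledger.clean_reads
    return profile, ledger


def length_distribution(profile: LibraryProfile) -> dict[int, tuple[int, float]]:
    """Read-count-weighted length histogram: length -> (count, fraction)."""
    counts: Counter[int] = Counter()
    for seq, n in profile.seq_counts.items():
        counts[len(seq)] += n
    total = sum(counts.values())
    if total == 0:
        return {}
    return {L: (c, c / total) for L, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# I/O

def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (sequence, quality) pairs from a Phred33 FASTQ file."""
    with open(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            yield seq, qual


def read_collapsed_fasta(path: str | Path) -> Iterator[tuple[str, None, int]]:
    """Yield (sequence, None, count) from a `>id_xCOUNT` collapsed FASTA."""
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    yield "".join(chunks), None, _collapsed_count(name)
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield "".join(chunks), None, _collapsed_count(name)


def _collapsed_count(header: str) -> int:
    tail = header.rsplit("_x", 1)
    if len(tail) == 2 and tail[1].isdigit():
        return int(tail[1])
    return 1


def write_collapsed_fasta(profile: LibraryProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(
            sorted(profile.seq_counts.items(), key=lambda kv: (-kv[1], kv[0])), 1
        ):
            fh.write(f">{profile.condition}_{i}_x{n}\n{seq}\n")


def write_ledger_tsv(ledgers: dict[str, ReadLedger], path: str | Path) -> None:
    """Write a read-accounting table, one column per library."""
    conds = list(ledgers)
    rows = [
        ("total_reads", "total_reads"),
        ("high_quality", "high_quality"),
        ("no_3adapter", "3' adaptor null"),
        ("insert_null", "insert null"),
        ("contaminant_5adapter", "5' adaptor contaminants"),
        ("shorter_than_18", "smaller than 18 nt"),
        ("poly_a", "poly A"),
        ("clean_reads", "clean reads"),
        ("clean_pct", "clean reads % of high quality"),
    ]
    with open(path, "w") as fh:
        fh.write("category\t" + "\t".join(conds) + "\n")
        for attr, label in rows:
            vals = [str(getattr(ledgers[c], attr)) for c in conds]
            fh.write(label + "\t" + "\t".join(vals) + "\n")
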