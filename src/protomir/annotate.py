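"""Hierarchical annotation of clean unique sequences.

Each unique sequence receives the FIRST matching category in the fixed
priority order rRNA > tRNA > snRNA > snoRNA > known miRNA > exon (sense,
antisense) > intron (sense, antisense) > unannotated, so the categories
partition the profile.  Matching is exact: ncRNA classes by verbatim
containment in a reference sequence, mature miRNAs by full-length
equality (case- and U/T-insensitive), genome placement by exact
substring search on both strands.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from ._seq import normalize, revcomp
from .preprocess import LibraryProfile

log = logging.getLogger(__name__)

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

CATEGORY_ORDER = NCRNA_CLASSES + (
    "known_miRNA",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
)


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]    # 0-based half-open, sorted
    introns: list[tuple[int, int]]


@dataclass
class MirnaRecord:
    """A known mature miRNA with per-library read counts."""

    name: str
    family: str
    sequence: str
    count_calli: int = 0
    count_protoplasts: int = 0
    tpm_calli: float | None = None
    tpm_protoplasts: float | None = None


@dataclass
class AnnotationTable:
    """Per-sequence categories plus the per-category count summary."""

    condition: str
    seq_category: dict[str, str]
    category_reads: dict[str, int]
    category_unique: dict[str, int]
    total_clean: int
    total_unique: int
    mapped_unique: int
    seq_loci: dict[str, list[Locus]] = field(default_factory=dict)

    @property
    def mapped_pct(self) -> float:
        """Genome-mapped unique sequences as % of unique sequences, 2 dp."""
        if self.total_unique == 0:
            return 0.0
        return round(100.0 * self.mapped_unique / self.total_unique, 2)

    def validate(self) -> None:
        if sum(self.category_reads.values()) != self.total_clean:
            raise ValueError("category read counts do not partition the profile")
        if sum(self.category_unique.values()) != self.total_unique:
            raise ValueError("category unique counts do not partition the profile")

    def sequences_in(self, category: str) -> list[str]:
        return [s for s, c in self.seq_category.items() if c == category]


def map_to_genome(
    seq: str, genome: str, chrom: str = "chr1", max_hits: int = 25
) -> tuple[list[Locus], bool]:
    """All exact-match loci of ``seq`` on both strands of ``genome``.

    Returns (loci, overflowed); the list is capped at ``max_hits``.
    """
    s = normalize(seq)
    loci: list[Locus] = []
    overflow = False
    for query, strand in ((s, "+"), (revcomp(s), "-")):
        p = genome.find(query)
        while p != -1:
            if len(loci) >= max_hits:
                overflow = True
                break
            loci.append(Locus(chrom, p, p + len(s), strand))
            p = genome.find(query, p + 1)
        if overflow:
            break
    return loci, overflow


def _gene_feature(locus: Locus, genes: list[GeneModel]) -> tuple[str, str] | None:
    """Best-overlap gene feature for a locus: ('exon'|'intron', gene strand).

    Majority overlap decides exon vs intron; ties go to exon.
    """
    best = None  # (overlap, 0 if exon else 1, feature, strand)
    for g in genes:
        for kind_rank, kind, ivals in ((0, "exon", g.exons), (1, "intron", g.introns)):
            for s, e in ivals:
                ov = min(locus.end, e) - max(locus.start, s)
                if ov > 0:
                    key = (-ov, kind_rank)
                    if best is None or key < best[0]:
                        best = (key, kind, g.strand)
    if best is None:
        return None
    return best[1], best[2]


def classify(
    profile: LibraryProfile,
    refs,
    max_hits: int = 25,
) -> AnnotationTable:
    """Assign every unique sequence its first matching category.

    ``refs`` needs ``ncrna_sets`` (dict class -> list of sequences),
    ``mature_mirnas`` (dict name -> sequence; known catalog), ``genome``
    (string) and ``gene_models`` (list of GeneModel).
    """
    for cls in NCRNA_CLASSES:
        if cls not in refs.ncrna_sets:
            raise KeyError(f"missing ncRNA reference set: {cls}")
    ncrna = {c: [normalize(x) for x in refs.ncrna_sets[c]] for c in NCRNA_CLASSES}
    mature = {normalize(s): n for n, s in refs.mature_mirnas.items()}
    genome = normalize(refs.genome)

    seq_category: dict[str, str] = {}
    seq_loci: dict[str, list[Locus]] = {}
    reads = {c: 0 for c in CATEGORY_ORDER}
    unique = {c: 0 for c in CATEGORY_ORDER}
    mapped = 0

    for seq, n in profile.seq_counts.items():
        s = normalize(seq)
        loci, _ = map_to_genome(s, genome, max_hits=max_hits)
        if loci:
            mapped += 1
            seq_loci[seq] = loci
        cat = None
        for cls in NCRNA_CLASSES:
            if any(s in ref for ref in ncrna[cls]):
                cat = cls
                break
        if cat is None and s in mature:
            cat = "known_miRNA"
        if cat is None and loci:
            feat = _gene_feature(loci[0], refs.gene_models)
            if feat is not None:
                kind, gstrand = feat
                orient = "sense" if loci[0].strand == gstrand else "antisense"
                cat = f"{kind}_{orient}"
        if cat is None:
            cat = "unannotated"
        seq_category[seq] = cat
        reads[cat] += n
        unique[cat] += 1

    table = AnnotationTable(
        condition=profile.condition,
        seq_category=seq_category,
        category_reads=reads,
        category_unique=unique,
        total_clean=profile.total_clean,
        total_unique=profile.unique_count,
        mapped_unique=mapped,
        seq_loci=seq_loci,
    )
    table.validate()
    return table


_FAMILY_RE = re.compile(r"(miR[0-9]+)", re.IGNORECASE)


def mirna_family(name: str) -> str:
    """Family stem of a miRNA name (``crt-miR166e*`` -> ``miR166``)."""
    m = _FAMILY_RE.search(name)
    return m.group(1) if m else name.rstrip("*")


def identify_known_mirnas(
    profiles: dict[str, LibraryProfile] | LibraryProfile,
    mature_ref: dict[str, str],
) -> list[MirnaRecord]:
    """Quantify known miRNAs by exact full-length match to the catalog.

    ``profiles`` maps condition ('calli'/'protoplasts') to its profile; a
    single profile is treated as the calli library.  Duplicate mature
    sequences under different names collapse to the first name seen.
    """
    if not mature_ref:
        raise ValueError("mature miRNA reference is empty")
    if isinstance(profiles, LibraryProfile):
        profiles = {profiles.condition: profiles}
    seq_to_name: dict[str, str] = {}
    for name, seq in mature_ref.items():
        s = normalize(seq)
        if s in seq_to_name:
            log.warning(
                "duplicate mature sequence for %s (already named %s); keeping first",
                name, seq_to_name[s],
            )
            continue
        seq_to_name[s] = name
    records: dict[str, MirnaRecord] = {}
    for name, seq in mature_ref.items():
        s = normalize(seq)
        if seq_to_name[s] != name:
            continue
        records[name] = MirnaRecord(name=name, family=mirna_family(name), sequence=s)
    for cond, profile in profiles.items():
        for seq, n in profile.seq_counts.items():
            name = seq_to_name.get(normalize(seq))
            if name is None:
                continue
            rec = records[name]
            if cond == "protoplasts":
                rec.count_protoplasts += n
            else:
                rec.count_calli += n
    return list(records.values())


def write_mirna_catalog(records: list[MirnaRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tfamily\tsequence\tcount_calli\tcount_protoplasts\n")
        for r in records:
            fh.write(f"{r.name}\t{r.family}\t{r.sequence}\t"
                     f"{r.count_calli}\t{r.count_protoplasts}\n")


def read_mirna_catalog(path) -> list[MirnaRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(MirnaRecord(
                name=row["name"], family=row.get("family", ""),
                sequence=row.get("sequence", ""),
                count_calli=int(row.get("count_calli", 0)),
                count_protoplasts=int(row.get("count_protoplasts", 0)),
            ))
    return records


def write_annotation_tsv(tables: dict[str, AnnotationTable], path) -> None:
    """Category summary table (reads and unique counts per library)."""
    conds = list(tables)
    with open(path, "w") as fh:
        fh.write("category\t" + "\t".join(
            f"{c}_reads\t{c}_unique" for c in conds) + "\n")
        for cat in ("total",) + CATEGORY_ORDER + ("mapped_to_genome",):
            cells = []
            for c in conds:
                t = tables[c]
                if cat == "total":
                    cells += [str(t.total_clean), str(t.total_unique)]
                elif cat == "mapped_to_genome":
                    cells += ["-", f"{t.mapped_unique} ({t.mapped_pct}%)"]
                else:
                    cells += [str(t.category_reads[cat]), str(t.category_unique[cat])]
            fh.write(cat + "\t" + "\t".join(cells) + "\n")
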