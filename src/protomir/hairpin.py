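"""Novel miRNA prediction from unannotated genome-mapped reads.

Candidate precursors are excised around each mapped read, folded, and
screened with plant-miRNA hairpin criteria in fixed order:

(a) the candidate mature read (the most abundant read in the window)
    lies entirely on one stem arm, never spanning the terminal loop;
(b) the mature/star duplex has at most ``max_duplex_mismatch`` unpaired
    mature positions and at most ``max_bulge`` asymmetrically bulged
    nucleotides;
(c) the precursor folds below the MFE ceiling (default -18 kcal/mol);
(d) the mature length is within 20-24 nt;
(e) the mature read is supported by at least ``min_reads`` reads summed
    over libraries.

Rejection reports the first criterion that failed.  Accepted candidates
are deduplicated by mature sequence and named ``novel_mir_1..N`` in a
stable (locus, mature) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import normalize, revcomp
from .annotate import AnnotationTable, Locus, map_to_genome
from .thermo import get_engine, pair_table


@dataclass
class HairpinThresholds:
    mfe_max: float = -18.0          # kcal/mol ceiling (criterion c)
    mature_min_len: int = 20
    mature_max_len: int = 24
    max_duplex_mismatch: int = 4    # unpaired mature positions (criterion b)
    max_bulge: int = 2              # asymmetric bulged nucleotides (criterion b)
    min_reads: int = 5              # summed over libraries (criterion e)
    flank: int = 150
    read_flank: int = 20


@dataclass
class PrecursorWindow:
    chrom: str
    start: int       # genomic, 0-based half-open, forward coordinates
    end: int
    strand: str
    sequence: str    # transcribed orientation (revcomp for '-' strand)


@dataclass
class HairpinCandidate:
    locus: Locus
    precursor: str
    structure: str
    mfe: float
    mature: str
    mature_interval: tuple[int, int]   # within precursor
    star_interval: tuple[int, int]
    arm: str                           # '5p' or '3p'
    counts: dict[str, int]
    duplex_mismatches: int
    name: str | None = None
    loci: list[Locus] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class Rejection:
    reason: str  # first failed criterion: arm|duplex|mfe|length|reads
    detail: str = ""


def excise_candidates(
    locus: Locus, genome: str, flank: int = 150, read_flank: int = 20
) -> list[PrecursorWindow]:
    """Candidate precursor windows around a mapped read.

    One full window extends ``flank`` nt on each side of the read; two
    read-anchored sub-windows put the read near the 5p or 3p arm.
    Windows are clipped at contig bounds and strand-corrected so the
    returned sequence is the transcribed (folding) orientation.
    """
    n = len(genome)
    if locus.start < 0 or locus.end > n:
        raise IndexError(f"locus {locus} outside genome of length {n}")
    spans = [
        (locus.start - flank, locus.end + flank),       # read central
        (locus.start - read_flank, locus.end + flank),  # read on 5' side
        (locus.start - flank, locus.end + read_flank),  # read on 3' side
    ]
    out = []
    seen = set()
    for s, e in spans:
        s, e = max(0, s), min(n, e)
        if (s, e) in seen:
            continue
        seen.add((s, e))
        seq = genome[s:e]
        if locus.strand == "-":
            seq = revcomp(seq)
        out.append(PrecursorWindow(locus.chrom, s, e, locus.strand, seq))
    return out


def evaluate_hairpin(
    window: PrecursorWindow,
    reads: dict[str, dict[str, int]],
    engine=None,
    thresholds: HairpinThresholds | None = None,
) -> HairpinCandidate | Rejection:
    """Fold a window and test the plant-miRNA criteria.

    ``reads`` maps read sequence -> per-library counts for the reads
    attributable to this window; the most abundant sequence found in the
    window sequence is taken as the mature candidate.
    """
    th = thresholds or HairpinThresholds()
    engine = engine or get_engine()
    wseq = normalize(window.sequence)

    best = None
    for seq, counts in reads.items():
        s = normalize(seq)
        pos = wseq.find(s)
        if pos == -1:
            continue
        total = sum(counts.values())
        if best is None or total > best[2]:
            best = (s, pos, total, counts)
    if best is None:
        return Rejection("arm", "no read maps inside the window")
    mature, m0, total, counts = best
    m1 = m0 + len(mature)

    structure, mfe = engine.fold(wseq)
    table = pair_table(structure)

    # (a) mature entirely on one stem arm
    region = structure[m0:m1]
    has_open, has_close = "(" in region, ")" in region
    if (has_open and has_close) or not (has_open or has_close):
        return Rejection("arm", "mature read spans the loop or is unpaired")
    arm = "5p" if has_open else "3p"

    # (b) mature/star duplex quality
    partners = [table[i] for i in range(m0, m1) if table[i] is not None]
    mismatches = (m1 - m0) - len(partners)
    if mismatches > th.max_duplex_mismatch:
        return Rejection("duplex", f"{mismatches} unpaired mature positions")
    star_lo, star_hi = min(partners), max(partners) + 1
    paired_span = (
        max(i for i in range(m0, m1) if table[i] is not None)
        - min(i for i in range(m0, m1) if table[i] is not None) + 1
    )
    bulge = abs((star_hi - star_lo) - paired_span)
    if bulge > th.max_bulge:
        return Rejection("duplex", f"{bulge} asymmetric bulged nucleotides")

    # (c) folding energy
    if mfe > th.mfe_max:
        return Rejection("mfe", f"MFE {mfe:.1f} above {th.mfe_max}")

    # (d) mature length
    if not (th.mature_min_len <= len(mature) <= th.mature_max_len):
        return Rejection("length", f"mature length {len(mature)}")

    # (e) read support
    if total < th.min_reads:
        return Rejection("reads", f"{total} reads < {th.min_reads}")

    locus = Locus(window.chrom, window.start, window.end, window.strand)
    return HairpinCandidate(
        locus=locus,
        precursor=wseq,
        structure=structure,
        mfe=mfe,
        mature=mature,
        mature_interval=(m0, m1),
        star_interval=(star_lo, star_hi),
        arm=arm,
        counts=dict(counts),
        duplex_mismatches=mismatches,
    )


def name_novel(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Deduplicate by mature sequence and assign stable novel_mir_N names.

    Candidates sharing a mature sequence collapse to one catalog entry
    (the first by locus order) carrying all loci; ordering is by locus,
    then mature sequence, so naming is reproducible.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.locus.chrom, c.locus.start, c.locus.end,
                       c.locus.strand, c.mature),
    )
    by_mature: dict[str, HairpinCandidate] = {}
    for c in ordered:
        kept = by_mature.get(c.mature)
        if kept is None:
            c.loci = [c.locus]
            by_mature[c.mature] = c
        elif c.locus not in kept.loci:
            kept.loci.append(c.locus)
    catalog = list(by_mature.values())
    for i, c in enumerate(catalog, 1):
        c.name = f"novel_mir_{i}"
    return catalog


def find_novel_mirnas(
    tables: dict[str, AnnotationTable],
    profiles: dict,
    genome: str,
    engine=None,
    thresholds: HairpinThresholds | None = None,
    max_hits: int = 25,
) -> list[HairpinCandidate]:
    """Full novel-miRNA scan over the unannotated fraction of the libraries.

    Unannotated sequences of plausible mature length with enough summed
    read support are mapped to the genome (repeat-derived reads at
    >= max_hits loci are skipped), candidate precursors excised around
    each locus, and the first accepted hairpin per sequence kept.
    """
    th = thresholds or HairpinThresholds()
    engine = engine or get_engine()
    genome = normalize(genome)

    counts_by_seq: dict[str, dict[str, int]] = {}
    for cond, table in tables.items():
        prof = profiles[cond]
        for seq in table.sequences_in("unannotated"):
            n = prof.seq_counts.get(seq, 0)
            if n:
                counts_by_seq.setdefault(normalize(seq), {})[cond] = n

    accepted: list[HairpinCandidate] = []
    for seq, counts in sorted(counts_by_seq.items()):
        if not (th.mature_min_len <= len(seq) <= th.mature_max_len):
            continue
        if sum(counts.values()) < th.min_reads:
            continue
        loci = None
        for table in tables.values():
            if seq in table.seq_loci:
                loci = table.seq_loci[seq]
                break
        if loci is None:
            loci, overflow = map_to_genome(seq, genome, max_hits=max_hits)
        if not loci or len(loci) >= max_hits:
            continue
        for locus in loci:
            hit = None
            for window in excise_candidates(locus, genome, th.flank, th.read_flank):
                res = evaluate_hairpin(window, {seq: counts}, engine, th)
                if isinstance(res, HairpinCandidate):
                    hit = res
                    break
            if hit is not None:
                accepted.append(hit)
                break
    return name_novel(accepted)


def write_novel_catalog(catalog: list[HairpinCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tmature\tarm\tmfe_kcal_mol\tduplex_mismatches\t"
                 "count_calli\tcount_protoplasts\tlocus\tprecursor\tstructure\n")
        for c in catalog:
            loci = ";".join(f"{l.chrom}:{l.start}-{l.end}({l.strand})" for l in c.loci)
            fh.write(
                f"{c.name}\t{c.mature}\t{c.arm}\t{c.mfe:.2f}\t{c.duplex_mismatches}\t"
                f"{c.counts.get('calli', 0)}\t{c.counts.get('protoplasts', 0)}\t"
                f"{loci}\t{c.precursor}\t{c.structure}\n"
            )
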