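"""Fully ground-truthed synthetic reference bundle and raw sRNA libraries.

The generator builds a toy chromosome with planted miRNA hairpin loci
(perfect inverted-repeat stems, so the mature/star duplex provably
satisfies the hairpin screen), a known-miRNA catalog covering a subset
of the planted matures (the rest are discoverable as novel), ncRNA
reference sets, exon/intron gene models, and transcripts carrying
target sites verified against the target-rule filter at construction
time.

``simulate_library`` then emits adapter-ligated reads for the two
conditions ("calli", "protoplasts"): miRNA insert counts are drawn
negative-binomially around per-miRNA abundances, planted log2 effects
multiply the protoplast means, defective reads (missing 3' adapter,
empty insert, 5' adapter dimers, short inserts, poly-A, low quality)
are injected by category, and genome-derived degradation fragments
absorb the remaining read mass.  Every read's category is known by
construction, so the cleaning ledger and the annotation category
counts have an exact truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import normalize, random_seq, revcomp
from .annotate import GeneModel, Locus, _gene_feature
from .preprocess import find_adapter3
from .target import apply_rules, duplex_align

CONDITIONS = ("calli", "protoplasts")

# standard Illumina TruSeq small-RNA adapters
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass
class SimParams:
    """Study conditions for the synthetic experiment.

    Defect fractions default to the per-category rates of a deeply
    sequenced sRNA library (order 1e-4..1e-3 of high-quality reads);
    ncRNA and degradation mass dominate the clean fraction, with the
    remainder carrying the miRNA signal.
    """

    seed: int = 1
    n_reads_per_library: int = 100_000
    read_length: int = 50
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    frac_low_quality: float = 0.002
    frac_no_3adapter: float = 0.0006
    frac_insert_null: float = 0.0001
    frac_5adapter_contaminant: float = 0.0005
    frac_short: float = 0.003
    frac_polya: float = 0.0002
    frac_ncrna: float = 0.05
    frac_degradation: float = 0.55
    # overdispersion of counts around the planted abundances; the two
    # libraries are technical preparations of one pool each, so this
    # sits between pure Poisson and biological-replicate variability
    expression_dispersion: float = 0.05
    planted_log2_effects: dict[str, float] | None = None
    n_mirnas: int = 30
    n_known: int = 20
    genome_length: int = 100_000

    def contamination_fracs(self) -> list[float]:
        return [
            self.frac_low_quality, self.frac_no_3adapter, self.frac_insert_null,
            self.frac_5adapter_contaminant, self.frac_short, self.frac_polya,
            self.frac_ncrna, self.frac_degradation,
        ]

    def validate(self) -> None:
        if self.n_reads_per_library <= 0:
            raise ValueError("n_reads_per_library must be positive")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        fr = self.contamination_fracs()
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fr) >= 1:
            raise ValueError("contamination fractions must sum to < 1")
        if self.expression_dispersion <= 0:
            raise ValueError("expression_dispersion must be positive")
        if not (0 < self.n_known <= self.n_mirnas):
            raise ValueError("need 0 < n_known <= n_mirnas")


@dataclass
class PlantedMirna:
    name: str
    family: str
    sequence: str
    known: bool
    arm: str                  # which precursor arm carries the mature
    locus: Locus              # precursor interval on the toy chromosome
    precursor: str
    weight: float             # relative abundance
    log2_effect: float = 0.0


@dataclass
class ReferenceBundle:
    genome: str
    mature_mirnas: dict[str, str]          # known catalog: name -> sequence
    precursor_loci: list[Locus]
    ncrna_sets: dict[str, list[str]]
    gene_models: list[GeneModel]
    transcripts: dict[str, str]
    mirnas: list[PlantedMirna] = field(default_factory=list)
    target_truth: list[tuple[str, str, int]] = field(default_factory=list)
    params: SimParams | None = None

    @property
    def truth(self) -> pd.DataFrame:
        """Per-miRNA expected abundances and planted effects."""
        rows = []
        for m in self.mirnas:
            rows.append({
                "name": m.name, "sequence": m.sequence, "family": m.family,
                "known": m.known, "arm": m.arm, "chrom": m.locus.chrom,
                "start": m.locus.start, "end": m.locus.end,
                "strand": m.locus.strand, "weight": m.weight,
                "log2_effect": m.log2_effect,
            })
        return pd.DataFrame(rows)


@dataclass
class SimulatedLibrary:
    condition: str
    reads: list[tuple[str, str, str]]      # (id, sequence, quality)
    ledger_truth: dict[str, int]
    annotate_truth: dict[str, int]         # category -> clean read count
    mirna_counts: dict[str, int]           # realized per-miRNA clean counts

    @property
    def n_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# reference generation

_MATURE_LENGTHS = (20, 21, 21, 21, 22, 22, 23, 24)


def _draw_mature(rng: np.random.Generator, adapter3: str,
                 existing: set[str]) -> str:
    while True:
        seq = random_seq(rng, int(rng.choice(_MATURE_LENGTHS)))
        if seq in existing or revcomp(seq) in existing:
            continue
        # the mature must survive adapter trimming intact
        read = seq + adapter3 + adapter3
        if find_adapter3(read, adapter3) == len(seq):
            return seq


def _mirna_names(n_known: int, n_novel: int) -> list[tuple[str, str, bool]]:
    """(name, family, known) triples; known names pair into families and
    include one star entry."""
    out = []
    for i in range(n_known):
        fam = f"miR{101 + i // 2}"
        letter = "ab"[i % 2]
        name = f"sim-{fam}{letter}"
        if i == 5:  # one passenger-strand catalog entry
            name += "*"
        out.append((name, fam, True))
    for j in range(n_novel):
        out.append((f"planted_novel_{j + 1:02d}", f"novel{j + 1}", False))
    return out


def _build_precursor(rng: np.random.Generator, mature: str, arm: str) -> tuple[str, int]:
    """Perfect inverted-repeat hairpin hosting the mature on one arm.

    Returns (precursor, mature offset within precursor).
    """
    f5 = random_seq(rng, int(rng.integers(6, 11)))
    f3 = random_seq(rng, int(rng.integers(6, 11)))
    loop = random_seq(rng, int(rng.integers(8, 13)))
    embedded = mature if arm == "5p" else revcomp(mature)
    stem5 = f5 + embedded + f3
    precursor = stem5 + loop + revcomp(stem5)
    if arm == "5p":
        offset = len(f5)
    else:
        offset = len(stem5) + len(loop) + len(f3)
    assert precursor[offset : offset + len(mature)] == mature
    return precursor, offset


def _default_effects(mirnas: list[PlantedMirna]) -> dict[str, float]:
    """Planted contrasts: alternating-sign effects on mid-abundance
    known and novel miRNAs (published DEMs sit in the mid-TPM range;
    the most abundant species are typically stable housekeeping-like
    miRNAs, and perturbing them would distort library composition).
    Only species holding 0.4-3% of the miRNA read mass carry effects:
    a contrast on a near-zero-count miRNA is unobservable at realistic
    depth, and one on a dominant species would visibly distort the
    composition of the whole library."""
    wsum = sum(m.weight for m in mirnas)
    effects = {}
    pattern = (3.0, -3.0, 2.0, -2.0, 3.0, -2.0)
    for known in (True, False):
        ranked = [m.name for m in sorted(mirnas, key=lambda m: -m.weight)
                  if m.known is known and 0.004 <= m.weight / wsum <= 0.03]
        for name, eff in zip(ranked, pattern):
            effects[name] = eff
    return effects


def generate_reference(params: SimParams) -> ReferenceBundle:
    """Deterministically build the toy reference bundle for ``params``."""
    params.validate()
    rng = np.random.default_rng([params.seed, 101])
    adapter3 = normalize(params.adapter3)
    n_novel = params.n_mirnas - params.n_known

    matures: list[str] = []
    seen: set[str] = set()
    for _ in range(params.n_mirnas):
        seq = _draw_mature(rng, adapter3, seen)
        matures.append(seq)
        seen.add(seq)

    names = _mirna_names(params.n_known, n_novel)
    # log-uniform abundance grid; the top species holds ~10% of the
    # miRNA read mass, as the dominant conserved family does in real
    # plant sRNA libraries
    weights = 10.0 ** rng.uniform(0.8, 2.2, size=params.n_mirnas)

    # plant hairpins on a random chromosome at well-separated slots
    genome = list(random_seq(rng, params.genome_length))
    spacing = params.genome_length // (params.n_mirnas + 2)
    mirnas: list[PlantedMirna] = []
    precursor_loci: list[Locus] = []
    for i, ((name, fam, known), mature) in enumerate(zip(names, matures)):
        arm = "5p" if rng.random() < 0.5 else "3p"
        precursor, _ = _build_precursor(rng, mature, arm)
        strand = "+" if rng.random() < 0.5 else "-"
        start = spacing * (i + 1) + int(rng.integers(0, spacing // 4))
        end = start + len(precursor)
        inserted = precursor if strand == "+" else revcomp(precursor)
        genome[start:end] = list(inserted)
        locus = Locus("chr1", start, end, strand)
        precursor_loci.append(locus)
        mirnas.append(PlantedMirna(
            name=name, family=fam, sequence=mature, known=known, arm=arm,
            locus=locus, precursor=precursor, weight=float(weights[i]),
        ))
    genome_str = "".join(genome)

    # each mature (and its complement arm) must be unique on the chromosome
    for m in mirnas:
        occ = genome_str.count(m.sequence) + genome_str.count(revcomp(m.sequence))
        if occ != 2:  # one mature arm + one star arm
            raise RuntimeError(
                f"planted mature {m.name} occurs {occ} times; "
                "regenerate with a different seed"
            )

    gene_models = _plant_genes(rng, precursor_loci, params.genome_length)
    ncrna_sets = _make_ncrna_sets(rng, {m.sequence for m in mirnas})

    # planted log2 effects: user-specified or the default contrast plan
    effects = (params.planted_log2_effects
               if params.planted_log2_effects is not None
               else _default_effects(mirnas))
    known_names = {m.name for m in mirnas}
    for name in effects:
        if name not in known_names:
            raise ValueError(f"planted effect for unknown miRNA {name!r}")
    for m in mirnas:
        m.log2_effect = float(effects.get(m.name, 0.0))

    transcripts, target_truth = _plant_transcripts(rng, mirnas, effects)

    bundle = ReferenceBundle(
        genome=genome_str,
        mature_mirnas={m.name: m.sequence for m in mirnas if m.known},
        precursor_loci=precursor_loci,
        ncrna_sets=ncrna_sets,
        gene_models=gene_models,
        transcripts=transcripts,
        mirnas=mirnas,
        target_truth=target_truth,
        params=dataclasses.replace(params),
    )
    return bundle


def _plant_genes(rng, precursor_loci: list[Locus], genome_len: int,
                 n_genes: int = 6) -> list[GeneModel]:
    """Exon/intron gene models in the gaps between hairpin slots."""
    genes = []
    occupied = sorted((l.start, l.end) for l in precursor_loci)
    step = max(1, len(occupied) // n_genes)
    for gi in range(n_genes):
        idx = gi * step
        if idx + 1 >= len(occupied):
            break
        gap_lo = occupied[idx][1] + 150
        gap_hi = occupied[idx + 1][0] - 150
        if gap_hi - gap_lo < 1400:
            continue
        pos = gap_lo
        exons, introns = [], []
        for elen, ilen in ((320, 210), (260, 160), (240, 0)):
            exons.append((pos, pos + elen))
            pos += elen
            if ilen:
                introns.append((pos, pos + ilen))
                pos += ilen
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{gi + 1}", strand, exons, introns))
    return genes


_NCRNA_PLAN = {"rRNA": (3, 150), "tRNA": (5, 75), "snRNA": (4, 110),
               "snoRNA": (4, 95)}


def _make_ncrna_sets(rng, matures: set[str]) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for cls, (count, length) in _NCRNA_PLAN.items():
        seqs = []
        while len(seqs) < count:
            s = random_seq(rng, length)
            if any(m in s for m in matures):
                continue
            seqs.append(s)
        sets[cls] = seqs
    return sets


def _plant_transcripts(
    rng, mirnas: list[PlantedMirna], effects: dict[str, float],
    n_transcripts: int = 16,
) -> tuple[dict[str, str], list[tuple[str, str, int]]]:
    """Random mRNAs, some carrying target sites for the effect-carrying
    miRNAs (checked against the duplex rule filter at construction)."""
    transcripts = {
        f"tx{i + 1:02d}": random_seq(rng, int(rng.integers(300, 601)))
        for i in range(n_transcripts)
    }
    ids = list(transcripts)
    truth: list[tuple[str, str, int]] = []
    with_sites = [m for m in mirnas if effects.get(m.name)] \
        + [m for m in mirnas if m.known and not effects.get(m.name)][:4]
    for k, m in enumerate(with_sites):
        tid = ids[k % len(ids)]
        site = _make_site(rng, m.sequence)
        tx = transcripts[tid]
        pos = int(rng.integers(30, len(tx) - len(site) - 30))
        transcripts[tid] = tx[:pos] + site + tx[pos + len(site):]
        truth.append((m.name, tid, pos))
    # construction check: every planted site passes rules 1-5 with score 0/0.5
    for name, tid, pos in truth:
        seq = next(m.sequence for m in mirnas if m.name == name)
        alns = [a for a in duplex_align(seq, transcripts[tid], name, tid)
                if a.window_start == pos]
        assert alns and all(apply_rules(a)[:5] == [True] * 5 for a in alns[:1])
    return transcripts, truth


def _make_site(rng, mature: str) -> str:
    """Reverse-complement target site, sometimes with one G·U wobble in
    the 3' half (outside miRNA positions 1-12)."""
    site = revcomp(mature)
    L = len(mature)
    if rng.random() < 0.5:
        # a miRNA G at position >= 14 pairs target C; C->T makes a G·U
        gu_ok = [i for i in range(13, L - 1) if mature[i] == "G"]
        if gu_ok:
            i = int(rng.choice(gu_ok))          # 0-based miRNA position
            sidx = L - 1 - i                    # antiparallel site index
            assert site[sidx] == "C"
            site = site[:sidx] + "T" + site[sidx + 1:]
    return site


# ---------------------------------------------------------------------------
# library simulation

_COND_SALT = {"calli": 211, "protoplasts": 223}


def simulate_library(
    bundle: ReferenceBundle, params: SimParams, condition: str
) -> SimulatedLibrary:
    """Emit one library of adapter-ligated reads with exact category truth."""
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng([params.seed, _COND_SALT[condition]])
    n = params.n_reads_per_library
    a3 = normalize(params.adapter3)
    a5 = normalize(params.adapter5)
    genome = normalize(bundle.genome)

    fracs = params.contamination_fracs()
    labels = ["low_quality", "no_3adapter", "insert_null",
              "contaminant_5adapter", "shorter_than_18", "poly_a",
              "ncrna", "degradation"]
    probs = fracs + [1.0 - sum(fracs)]
    cat_counts = dict(zip(labels + ["mirna_pool"],
                          rng.multinomial(n, probs)))

    # negative-binomial miRNA counts around the planted abundances
    mirna_mass = n * (1.0 - sum(fracs))
    wsum = sum(m.weight for m in bundle.mirnas)
    disp = params.expression_dispersion
    r = 1.0 / disp
    mirna_counts: dict[str, int] = {}
    for m in bundle.mirnas:
        mean = mirna_mass * m.weight / wsum
        if condition == "protoplasts":
            mean *= 2.0 ** m.log2_effect
        c = int(rng.negative_binomial(r, r / (r + mean)))
        mirna_counts[m.name] = c
    total_mirna = sum(mirna_counts.values())
    pool = int(cat_counts["degradation"]) + int(cat_counts["mirna_pool"])
    if total_mirna > pool:
        raise RuntimeError("miRNA counts exceed available read mass; "
                           "lower abundances or raise n_reads_per_library")
    n_degradation = pool - total_mirna

    reads: list[tuple[str, str]] = []  # (category-tag, full read)
    qual = "I" * params.read_length

    def finish(insert: str) -> str:
        return (insert + a3 + a3 + "A" * params.read_length)[: params.read_length]

    # defective categories
    for _ in range(int(cat_counts["low_quality"])):
        s = random_seq(rng, params.read_length)
        reads.append(("low_quality", s[:5] + "N" + s[6:]))
    for _ in range(int(cat_counts["no_3adapter"])):
        while True:
            s = random_seq(rng, params.read_length)
            if find_adapter3(s, a3) is None:
                break
        reads.append(("no_3adapter", s))
    for _ in range(int(cat_counts["insert_null"])):
        reads.append(("insert_null", finish("")))
    for _ in range(int(cat_counts["contaminant_5adapter"])):
        insert = a5[: int(rng.integers(18, min(27, len(a5) + 1)))]
        assert find_adapter3(finish(insert), a3) == len(insert)
        reads.append(("contaminant_5adapter", finish(insert)))
    short_extra = 0
    for _ in range(int(cat_counts["shorter_than_18"])):
        insert = _safe_insert(rng, a3, int(rng.integers(10, 18)))
        reads.append(("shorter_than_18", finish(insert)))
    for _ in range(int(cat_counts["poly_a"])):
        insert = "A" * int(rng.integers(20, 29))
        assert find_adapter3(finish(insert), a3) == len(insert)
        reads.append(("poly_a", finish(insert)))

    # ncRNA contamination: verbatim fragments of the reference sets
    mature_set = {m.sequence for m in bundle.mirnas}
    ncrna_truth: dict[str, int] = {c: 0 for c in bundle.ncrna_sets}
    classes = list(bundle.ncrna_sets)
    class_w = np.array([0.5, 0.2, 0.15, 0.15])[: len(classes)]
    class_w = class_w / class_w.sum()
    for _ in range(int(cat_counts["ncrna"])):
        cls = classes[int(rng.choice(len(classes), p=class_w))]
        ref = bundle.ncrna_sets[cls][int(rng.integers(len(bundle.ncrna_sets[cls])))]
        while True:
            ln = int(rng.integers(18, 31))
            st = int(rng.integers(0, len(ref) - ln + 1))
            frag = normalize(ref[st : st + ln])
            if frag in mature_set or find_adapter3(finish(frag), a3) != ln:
                continue
            break
        ncrna_truth[cls] += 1
        reads.append((cls, finish(frag)))

    # mature miRNA reads
    for m in bundle.mirnas:
        tag = "known_miRNA" if m.known else "unannotated"
        read = finish(m.sequence)
        reads.extend((tag, read) for _ in range(mirna_counts[m.name]))

    # degradation fragments: unique random genome substrings, 15-30 nt
    feature_truth = {"exon_sense": 0, "exon_antisense": 0,
                     "intron_sense": 0, "intron_antisense": 0,
                     "unannotated": 0}
    for _ in range(n_degradation):
        while True:
            ln = int(rng.integers(15, 31))
            st = int(rng.integers(0, len(genome) - ln))
            frag = genome[st : st + ln]
            strand = "+" if rng.random() < 0.5 else "-"
            seq = frag if strand == "+" else revcomp(frag)
            if seq in mature_set or revcomp(seq) in mature_set:
                continue
            if genome.count(frag) + genome.count(revcomp(frag)) != 1:
                continue  # must map uniquely so truth is unambiguous
            if find_adapter3(finish(seq), a3) != ln:
                continue
            break
        if ln < 18:
            short_extra += 1
            reads.append(("shorter_than_18", finish(seq)))
            continue
        feat = _gene_feature(Locus("chr1", st, st + ln, strand),
                             bundle.gene_models)
        if feat is None:
            cat = "unannotated"
        else:
            kind, gstrand = feat
            cat = f"{kind}_{'sense' if strand == gstrand else 'antisense'}"
        feature_truth[cat] += 1
        reads.append((cat, finish(seq)))

    order = rng.permutation(len(reads))
    shuffled = [
        (f"{condition}_{i + 1}|{reads[j][0]}", reads[j][1], qual)
        for i, j in enumerate(order)
    ]

    ledger_truth = {
        "total_reads": n,
        "high_quality": n - int(cat_counts["low_quality"]),
        "low_quality": int(cat_counts["low_quality"]),
        "no_3adapter": int(cat_counts["no_3adapter"]),
        "insert_null": int(cat_counts["insert_null"]),
        "contaminant_5adapter": int(cat_counts["contaminant_5adapter"]),
        "shorter_than_18": int(cat_counts["shorter_than_18"]) + short_extra,
        "poly_a": int(cat_counts["poly_a"]),
    }
    ledger_truth["clean_reads"] = ledger_truth["high_quality"] - (
        ledger_truth["no_3adapter"] + ledger_truth["insert_null"]
        + ledger_truth["contaminant_5adapter"]
        + ledger_truth["shorter_than_18"] + ledger_truth["poly_a"]
    )

    known_reads = sum(c for m, c in mirna_counts.items()
                      if next(x.known for x in bundle.mirnas if x.name == m))
    annotate_truth = dict(ncrna_truth)
    annotate_truth["known_miRNA"] = known_reads
    for cat, c in feature_truth.items():
        annotate_truth[cat] = c
    annotate_truth["unannotated"] += total_mirna - known_reads

    return SimulatedLibrary(
        condition=condition,
        reads=shuffled,
        ledger_truth=ledger_truth,
        annotate_truth=annotate_truth,
        mirna_counts=mirna_counts,
    )


def _safe_insert(rng, a3: str, length: int) -> str:
    """Random insert that trims back to itself in front of the adapter."""
    while True:
        s = random_seq(rng, length)
        if find_adapter3((s + a3 + a3 + "A" * 60)[:60], a3) == length:
            return s


# ---------------------------------------------------------------------------
# file output

def write_fastq(lib: SimulatedLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in lib.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_bundle(bundle: ReferenceBundle, outdir: str | Path) -> None:
    """FASTA/GFF3/TSV serialization of the reference bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(outdir / "genome.fa", {"chr1": bundle.genome})
    _write_fasta(outdir / "mature.fa", bundle.mature_mirnas)
    for cls, seqs in bundle.ncrna_sets.items():
        _write_fasta(outdir / f"ncrna_{cls}.fa",
                     {f"{cls}_{i + 1}": s for i, s in enumerate(seqs)})
    _write_fasta(outdir / "transcripts.fa", bundle.transcripts)
    with open(outdir / "genes.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.gene_models:
            lo = min(s for s, _ in g.exons)
            hi = max(e for _, e in g.exons)
            fh.write(f"chr1\tprotomir\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"chr1\tprotomir\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "target_truth.tsv", "w") as fh:
        fh.write("mirna\ttranscript\tsite_start\n")
        for name, tid, pos in bundle.target_truth:
            fh.write(f"{name}\t{tid}\t{pos}\n")


def _write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_bundle(refdir: str | Path) -> ReferenceBundle:
    """Reload a reference bundle written by ``write_bundle``.

    Truth metadata (planted miRNA table, target sites) is not required
    to be present; the loaded bundle is sufficient for annotation,
    novel discovery and target prediction on real or simulated reads.
    """
    refdir = Path(refdir)
    genome = _read_fasta(refdir / "genome.fa")
    ncrna_sets = {}
    for cls in _NCRNA_PLAN:
        path = refdir / f"ncrna_{cls}.fa"
        ncrna_sets[cls] = list(_read_fasta(path).values()) if path.exists() else []
    import gffutils

    gene_models: list[GeneModel] = []
    gff = refdir / "genes.gff"
    if gff.exists():
        db = gffutils.create_db(str(gff), ":memory:", force=True,
                                merge_strategy="create_unique")
        for gene in db.features_of_type("gene"):
            exons = sorted((f.start - 1, f.end) for f in
                           db.children(gene, featuretype="exon"))
            introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])
                       if s2 > e1]
            gene_models.append(GeneModel(gene.id, gene.strand, exons, introns))
    return ReferenceBundle(
        genome=next(iter(genome.values())),
        mature_mirnas=_read_fasta(refdir / "mature.fa"),
        precursor_loci=[],
        ncrna_sets=ncrna_sets,
        gene_models=gene_models,
        transcripts=_read_fasta(refdir / "transcripts.fa"),
    )
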