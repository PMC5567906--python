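"""Rule-based plant miRNA target prediction.

A miRNA is aligned antiparallel against every transcript window; each
miRNA position (1-based from the 5' end) is classed as WC pair ('W'),
G·U wobble ('G'), mismatch ('M') or bulge ('B').  Candidate duplexes
are screened with six rules:

1. total mismatch score <= 4, where G·U weighs 0.5 and a mismatch or
   bulge weighs 1;
2. no run of more than 2 consecutive non-WC positions anywhere;
3. no two adjacent non-WC positions within miRNA positions 2-12;
4. positions 10 and 11 both Watson-Crick paired;
5. mismatch score restricted to positions 1-12 <= 2.5;
6. duplex MFE at least 75% of the MFE of the miRNA bound to its exact
   complement (computed with the shared fold engine).

G·U counts as a mismatch *event* for the positional rules 2-4 (strict
reading; switchable) while contributing only 0.5 to the scores.  At
most one single-nucleotide bulge is allowed, weighted 1.0 and
prohibited within positions 2-12; target-side bulges are recorded
against the 5'-flanking miRNA position.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import normalize, revcomp
from .thermo import get_engine

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # miRNA G : target U, miRNA U : target G

WEIGHTS = {"W": 0.0, "G": 0.5, "M": 1.0, "B": 1.0}


def _pair_class(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "W"
    if (m, t) in _GU:
        return "G"
    return "M"


@dataclass
class DuplexAlignment:
    """Antiparallel miRNA/target pairing with per-miRNA-position classes."""

    mirna: str                      # 5'->3'
    mirna_name: str
    transcript_id: str
    window_start: int               # 0-based half-open on the transcript
    window_end: int
    target_window: str              # transcript strand, 5'->3'
    classes: str                    # length == len(mirna), chars WGMB
    bulge: tuple[str, int] | None = None  # ('mirna'|'target', miRNA position)

    @property
    def mismatch_score(self) -> float:
        return sum(WEIGHTS[c] for c in self.classes)


@dataclass
class TargetHit:
    alignment: DuplexAlignment
    duplex_mfe: float
    perfect_mfe: float
    mfe_ratio: float
    rule_flags: tuple[bool, bool, bool, bool, bool, bool]

    @property
    def accepted(self) -> bool:
        return all(self.rule_flags)


def _align_classes(mirna: str, window: str, bulge: tuple[str, int] | None,
                   max_score: float = float("inf")) -> str | None:
    """Per-position classes for one alignment variant, or None once the
    accumulated score exceeds ``max_score``.  miRNA position i pairs the
    window antiparallel from its 3' end, with at most one single-nt
    bulge on either strand."""
    L, K = len(mirna), len(window)
    if bulge is None:
        b, off_lo, off_hi = L + 1, 0, 0  # never bulged
        if K != L:
            raise ValueError("ungapped alignment needs equal lengths")
    elif bulge[0] == "mirna":
        b, off_lo, off_hi = bulge[1], -1, 0
        if K != L - 1:
            raise ValueError("miRNA bulge needs a window one nt shorter")
    else:  # target-side bulge between miRNA positions b and b+1
        b, off_lo, off_hi = bulge[1], +1, 0
        if K != L + 1:
            raise ValueError("target bulge needs a window one nt longer")
    classes = []
    score = 0.0
    for i in range(1, L + 1):
        if i == b and bulge is not None:
            c = "B"
        elif i < b:
            c = _pair_class(mirna[i - 1], window[L + off_lo - i])
        else:
            c = _pair_class(mirna[i - 1], window[L + off_hi - i])
        score += WEIGHTS[c]
        if score > max_score:
            return None
        classes.append(c)
    return "".join(classes)


def _bulge_positions(L: int, kind: str, forbidden_lo: int = 2,
                     forbidden_hi: int = 12) -> list[int]:
    # recorded position must sit outside the seed-proximal 2..12 window
    lo = 1 if kind == "target" else 2
    return [b for b in range(lo, L)
            if not (forbidden_lo <= b <= forbidden_hi)]


def duplex_align(
    mirna: str,
    transcript: str,
    mirna_name: str = "miRNA",
    transcript_id: str = "transcript",
    max_score: float = 4.0,
    allow_bulge: bool = True,
) -> list[DuplexAlignment]:
    """All transcript windows whose best antisense alignment scores
    <= ``max_score``; one alignment (the best-scoring variant) per
    distinct window."""
    m = normalize(mirna)
    t = normalize(transcript)
    if not set(m) <= set("ACGT") or not set(t) <= set("ACGT"):
        raise ValueError("sequences must be nucleotide (ACGT/U)")
    L, n = len(m), len(t)
    if n < L:
        return []
    variants: list[tuple[int, tuple[str, int] | None]] = [(L, None)]
    if allow_bulge:
        variants += [(L - 1, ("mirna", b)) for b in _bulge_positions(L, "mirna")]
        variants += [(L + 1, ("target", b)) for b in _bulge_positions(L, "target")]
    hits: dict[tuple[int, int], DuplexAlignment] = {}
    for K, bulge in variants:
        for s in range(0, n - K + 1):
            window = t[s : s + K]
            classes = _align_classes(m, window, bulge, max_score)
            if classes is None:
                continue
            score = sum(WEIGHTS[c] for c in classes)
            key = (s, s + K)
            prev = hits.get(key)
            if prev is None or score < prev.mismatch_score:
                hits[key] = DuplexAlignment(
                    mirna=m, mirna_name=mirna_name, transcript_id=transcript_id,
                    window_start=s, window_end=s + K, target_window=window,
                    classes=classes, bulge=bulge,
                )
    return [hits[k] for k in sorted(hits)]


def apply_rules(
    alignment: DuplexAlignment,
    max_total: float = 4.0,
    max_run: int = 2,
    seed_lo: int = 2,
    seed_hi: int = 12,
    max_5p_score: float = 2.5,
    gu_is_mismatch_event: bool = True,
) -> list[bool]:
    """Evaluate positional rules 1-5; rule 6 (energy) is filled by the
    caller and returned here as True placeholder."""
    cls = alignment.classes
    weights = [WEIGHTS[c] for c in cls]
    event = [c != "W" if gu_is_mismatch_event else c in "MB" for c in cls]

    flag1 = sum(weights) <= max_total
    run = best_run = 0
    for e in event:
        run = run + 1 if e else 0
        best_run = max(best_run, run)
    flag2 = best_run <= max_run
    flag3 = not any(
        event[i - 1] and event[i]
        for i in range(seed_lo, min(seed_hi, len(cls)))
    )
    flag4 = len(cls) >= 11 and cls[9] == "W" and cls[10] == "W"
    flag5 = sum(weights[0:12]) <= max_5p_score
    return [flag1, flag2, flag3, flag4, flag5, True]


def duplex_energy(
    mirna: str, target_window: str, engine=None
) -> tuple[float, float, float]:
    """(duplex_mfe, perfect_mfe, ratio) for a miRNA against one window.

    perfect_mfe is the miRNA bound to its exact complement with the same
    engine; a non-negative duplex energy yields ratio 0.
    """
    engine = engine or get_engine()
    m = normalize(mirna)
    perfect = engine.duplex(m, revcomp(m))
    if perfect >= 0:
        raise ArithmeticError("perfect-complement duplex has no negative MFE")
    d = engine.duplex(m, normalize(target_window))
    ratio = 0.0 if d >= 0 else d / perfect
    return d, perfect, ratio


def evaluate_hit(
    alignment: DuplexAlignment,
    engine=None,
    mfe_ratio_min: float = 0.75,
    **rule_kwargs,
) -> TargetHit:
    flags = apply_rules(alignment, **rule_kwargs)
    d, perfect, ratio = duplex_energy(
        alignment.mirna, alignment.target_window, engine
    )
    flags[5] = ratio >= mfe_ratio_min
    return TargetHit(
        alignment=alignment, duplex_mfe=d, perfect_mfe=perfect,
        mfe_ratio=ratio, rule_flags=tuple(flags),
    )


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    engine=None,
    max_score: float = 4.0,
    mfe_ratio_min: float = 0.75,
    **rule_kwargs,
) -> tuple[list[TargetHit], list[str]]:
    """Accepted hits (all six rules true) for every miRNA x transcript,
    plus the list of target-less miRNA names."""
    if not mirnas or not transcripts:
        raise ValueError("miRNA and transcript catalogs must be non-empty")
    engine = engine or get_engine()
    hits: list[TargetHit] = []
    targetless: list[str] = []
    for name, mseq in mirnas.items():
        found = False
        for tid, tseq in transcripts.items():
            for aln in duplex_align(mseq, tseq, name, tid, max_score):
                hit = evaluate_hit(aln, engine, mfe_ratio_min, **rule_kwargs)
                if hit.accepted:
                    hits.append(hit)
                    found = True
        if not found:
            targetless.append(name)
    return hits, targetless


def write_hits_tsv(hits: list[TargetHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("miRNA\ttranscript\twindow_start\twindow_end\t"
                 "alignment_classes\tmismatch_score\tduplex_mfe\tmfe_ratio\n")
        for h in hits:
            a = h.alignment
            fh.write(
                f"{a.mirna_name}\t{a.transcript_id}\t{a.window_start}\t"
                f"{a.window_end}\t{a.classes}\t{a.mismatch_score:g}\t"
                f"{h.duplex_mfe:.2f}\t{h.mfe_ratio:.3f}\n"
            )
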