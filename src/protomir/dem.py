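"""Differential expression between two unreplicated count libraries.

Counts are normalised to transcripts per million (TPM = 1e6 * count /
library total, with a 0.01 TPM floor so absent miRNAs keep a finite
fold change), effect size is log2(TPM_protoplasts / TPM_calli), and the
p-value is the exact conditional count test for two library totals
(Audic-Claverie style): given x reads in library 1,

    P(Y = y | X = x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

with a two-sided p obtained by doubling the smaller tail and capping at
1.  A miRNA is called up (down) when log2 fold change > 1 (< -1) and
p <= 0.01; both cutoffs are parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

TPM_FLOOR = 0.01


@dataclass
class DemRecord:
    name: str
    x: int | None            # count in calli (None when built from TPMs)
    y: int | None            # count in protoplasts
    tpm_calli: float
    tpm_protoplasts: float
    fc: float                # log2(protoplasts/calli)
    p: float
    status: str              # up | down | unchanged


def normalize_tpm(count: float, library_total: int, floor: float = TPM_FLOOR) -> float:
    """TPM with a low-expression floor (absent -> ``floor``)."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    tpm = 1e6 * count / library_total
    return floor if tpm < floor else tpm


def log2_fold_change(tpm_protoplasts: float, tpm_calli: float) -> float:
    return math.log2(tpm_protoplasts / tpm_calli)


def _log_pmf(y: np.ndarray, x: int, ratio: float) -> np.ndarray:
    """log P(Y=y | X=x) for library-size ratio N2/N1."""
    return (
        y * math.log(ratio)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(ratio)
    )


def exact_count_pvalue(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided exact test of equal per-read rates in two libraries.

    The smaller of P(Y<=y|x) and P(Y>=y|x) is doubled and capped at 1;
    tails are direct summations of the conditional mass function in
    log space, so no factorial overflows and no catastrophic 1-minus
    cancellation for extreme counts.
    """
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be non-negative integers")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    ratio = N2 / N1
    lower = float(np.exp(_log_pmf(np.arange(y + 1), x, ratio)).sum())
    # upper tail: sum upward from y until the remaining geometric-like
    # mass is negligible relative to what is accumulated
    upper = 0.0
    start, block = y, 256
    while True:
        ys = np.arange(start, start + block)
        terms = np.exp(_log_pmf(ys, x, ratio))
        upper += float(terms.sum())
        start += block
        # term ratio -> ratio/(1+ratio) < 1; stop once the block tail is dust
        if terms[-1] < 1e-18 * max(upper, 1e-300):
            break
        block = min(block * 2, 65536)
    return min(1.0, 2.0 * min(lower, upper))


def classify_status(fc: float, p: float, fc_cut: float = 1.0,
                    p_cut: float = 0.01) -> str:
    """Strict fold-change inequality, inclusive p cutoff."""
    if p <= p_cut:
        if fc > fc_cut:
            return "up"
        if fc < -fc_cut:
            return "down"
    return "unchanged"


def call_dems(
    catalog,
    N1: int,
    N2: int,
    fc_cut: float = 1.0,
    p_cut: float = 0.01,
    floor: float = TPM_FLOOR,
) -> list[DemRecord]:
    """One DemRecord per catalog entry, sorted up block then down block
    (each by descending |fc|), then the unchanged remainder.

    ``catalog`` entries need ``name``, ``count_calli``, ``count_protoplasts``
    attributes (known-miRNA records) or ``name``/``counts`` (hairpin
    candidates).
    """
    out = []
    for rec in catalog:
        if hasattr(rec, "count_calli"):
            x, y = rec.count_calli, rec.count_protoplasts
        else:
            x = rec.counts.get("calli", 0)
            y = rec.counts.get("protoplasts", 0)
        tpm_c = normalize_tpm(x, N1, floor)
        tpm_p = normalize_tpm(y, N2, floor)
        fc = log2_fold_change(tpm_p, tpm_c)
        p = exact_count_pvalue(x, y, N1, N2)
        out.append(DemRecord(
            name=rec.name, x=x, y=y, tpm_calli=tpm_c, tpm_protoplasts=tpm_p,
            fc=fc, p=p, status=classify_status(fc, p, fc_cut, p_cut),
        ))
    return sort_dem_report(out)


def call_dems_from_tpm(
    rows: list[tuple[str, float, float, float]],
    fc_cut: float = 1.0,
    p_cut: float = 0.01,
) -> list[DemRecord]:
    """Classify from pre-normalised (name, tpm_calli, tpm_protoplasts, p)
    rows, bypassing raw counts (replaying a published expression table)."""
    out = []
    for name, tpm_c, tpm_p, p in rows:
        fc = log2_fold_change(tpm_p, tpm_c)
        out.append(DemRecord(
            name=name, x=None, y=None, tpm_calli=tpm_c, tpm_protoplasts=tpm_p,
            fc=fc, p=p, status=classify_status(fc, p, fc_cut, p_cut),
        ))
    return sort_dem_report(out)


def sort_dem_report(records: list[DemRecord]) -> list[DemRecord]:
    rank = {"up": 0, "down": 1, "unchanged": 2}
    return sorted(records, key=lambda r: (rank[r.status], -abs(r.fc), r.name))


def write_dem_tsv(records: list[DemRecord], path) -> None:
    """Report table: TPM and log2 fold change to 2 decimals, p in
    scientific notation."""
    with open(path, "w") as fh:
        fh.write("miRNA\ttpm_calli\ttpm_protoplasts\tlog2_fold_change\t"
                 "p_value\tstatus\n")
        for r in records:
            fh.write(
                f"{r.name}\t{r.tpm_calli:.2f}\t{r.tpm_protoplasts:.2f}\t"
                f"{r.fc:.2f}\t{r.p:.2E}\t{r.status}\n"
            )
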