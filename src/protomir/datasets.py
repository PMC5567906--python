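"""Bundled reference datasets from a published citrus callus/protoplast
small-RNA experiment, for replaying the ledger arithmetic and the
differential-expression calls on real reported values."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .preprocess import ReadLedger


def _read(name: str) -> pd.DataFrame:
    with resources.files("protomir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def citrus_ledgers() -> dict[str, ReadLedger]:
    """Published per-category read counts as ReadLedger objects."""
    df = _read("citrus_ledger.tsv").set_index("category")
    out = {}
    for cond in ("calli", "protoplasts"):
        col = df[cond]
        out[cond] = ReadLedger(
            total_reads=int(col["total_reads"]),
            high_quality=int(col["high_quality"]),
            no_3adapter=int(col["no_3adapter"]),
            insert_null=int(col["insert_null"]),
            contaminant_5adapter=int(col["contaminant_5adapter"]),
            shorter_than_18=int(col["shorter_than_18"]),
            poly_a=int(col["poly_a"]),
        )
        out[cond].validate()
    return out


def citrus_unique_mapping() -> dict[str, tuple[int, int]]:
    """(mapped unique, total unique) per condition from the same study."""
    df = _read("citrus_ledger.tsv").set_index("category")
    return {
        cond: (int(df[cond]["mapped_unique"]), int(df[cond]["unique_srnas"]))
        for cond in ("calli", "protoplasts")
    }


def citrus_dem_table() -> list[tuple[str, float, float, float]]:
    """Published (miRNA, TPM calli, TPM protoplasts, p) rows."""
    df = _read("citrus_dem_tpm.tsv")
    return [
        (r.mirna, float(r.tpm_calli), float(r.tpm_protoplasts), float(r.p_value))
        for r in df.itertuples()
    ]
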