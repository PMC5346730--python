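"""Plain-text TSV readers/writers for every pipeline interchange table.

All intermediates are headered, diff-able TSV; the trait table encodes
tissue as ``tumor``/``normal`` and receptor status as 0/1 with ``NA`` for
missing, mirroring how clinical annotation tables usually arrive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_data import TRAITS, CohortData


def write_cohort(path: str | Path, expression: pd.DataFrame) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_traits(path: str | Path, traits: pd.DataFrame) -> None:
    out = traits.copy()
    out.insert(0, "tissue", out.pop("tumor").map({1.0: "tumor", 0.0: "normal"}))
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_traits(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    traits = pd.DataFrame(index=raw.index)
    traits["tumor"] = raw["tissue"].map({"tumor": 1.0, "normal": 0.0})
    for col in TRAITS[1:]:
        traits[col] = raw[col].astype(float)
    return traits


def write_survival(path: str | Path, survival: pd.DataFrame) -> None:
    survival.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_transcripts(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_transcripts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort_data(outdir: str | Path, cohort: CohortData) -> None:
    outdir = Path(outdir)
    write_cohort(outdir / "cohort.tsv", cohort.expression)
    write_traits(outdir / "traits.tsv", cohort.traits)
    if cohort.survival is not None:
        write_survival(outdir / "survival.tsv", cohort.survival)


def write_table(path: str | Path, table: pd.DataFrame, index_label: str | None = None) -> None:
    if index_label is None:
        table.to_csv(path, sep="\t", index=False)
    else:
        table.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
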