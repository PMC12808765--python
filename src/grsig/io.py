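"""Plain-text readers and writers for the pipeline's tables.

Counts are gene-rows x sample-columns TSV; sample sheets, cohorts, gene
annotations, truth tables and plates are column-oriented TSV; peaks are
BED3 plus named numeric columns; gene-set collections are GMT.
"""

from __future__ import annotations

import pandas as pd


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index_label="patient_id")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient_id")


def write_peaks(peaks: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [c for c in peaks.columns
                                        if c not in ("chrom", "start", "end")]
    peaks[cols].to_csv(path, sep="\t", index=False)


def read_peaks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(collection: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
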