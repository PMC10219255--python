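"""Readers and writers for the pipeline's plain-text table formats.

Counts travel as TSV (gene_id index plus one column per sample), sample
sheets and lifespan/CT tables as CSV, annotations as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, SurvivalCohort


def read_counts(counts_tsv, samples_csv) -> CountMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col="gene_id")
    meta = pd.read_csv(samples_csv, index_col="sample")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_tsv, samples_csv=None) -> None:
    cm.counts.to_csv(counts_tsv, sep="\t", index_label="gene_id")
    if samples_csv is not None:
        cm.sample_meta.to_csv(samples_csv, index_label="sample")


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneAnnotation(table["length_nt"])


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.lengths.rename("length_nt").to_csv(path, sep="\t", index_label="gene_id")


def read_lifespans(path) -> dict:
    """CSV with columns group, lifespan_days -> dict of SurvivalCohort."""
    table = pd.read_csv(path)
    col = "lifespan_days" if "lifespan_days" in table.columns else "day"
    return {
        g: SurvivalCohort(str(g), sub[col].to_numpy())
        for g, sub in table.groupby("group", sort=False)
    }


def write_lifespans(cohorts, path) -> None:
    rows = [
        {"group": c.group, "lifespan_days": int(d)}
        for c in cohorts
        for d in np.sort(c.lifespans)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path, index_label=None) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=index_label is not None,
                 index_label=index_label)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
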