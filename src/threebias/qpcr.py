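"""ddCT relative quantification and RNA-seq concordance.

Classic ddCT with amplification efficiency fixed at 2: technical
replicates are averaged first, then per-sample dCT = CT_reference -
CT_target (averaged over reference genes when several are given), then
-ddCT = mean dCT(treated) - mean dCT(control).  Under perfect efficiency
-ddCT estimates the log2 fold change, so it is directly comparable to
RNA-seq Log2FC values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "technical_rep", "ct")


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return table


def delta_ct(
    table: pd.DataFrame,
    target: str,
    references,
) -> pd.DataFrame:
    """Per-sample dCT = CT_reference - CT_target for one target gene.

    Technical replicates are averaged before differencing.  With several
    reference genes the per-reference dCT values are retained (one column
    each, ``dct_<ref>``) and combined by arithmetic mean into ``dct``.
    Samples missing the target or any reference are dropped with a
    warning.
    """
    references = [references] if isinstance(references, str) else list(references)
    if not references:
        raise ValueError("need at least one reference gene")
    table = _validate_ct_table(table)
    genes = [target, *references]
    sub = table[table["gene_id"].isin(genes)]
    # technical replicates averaged first
    mean_ct = (
        sub.groupby(["sample_id", "group", "gene_id"], sort=False)["ct"]
        .mean()
        .unstack("gene_id")
        .reset_index()
    )
    present = [g for g in genes if g in mean_ct.columns]
    absent = set(genes) - set(present)
    if absent:
        raise ValueError(f"genes absent from CT table: {sorted(absent)}")
    complete = mean_ct.dropna(subset=genes)
    n_dropped = len(mean_ct) - len(complete)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sample(s) missing target or reference CTs",
            stacklevel=2,
        )
    if complete.empty:
        raise ValueError("no sample has complete CT data for target and references")
    out = complete[["sample_id", "group"]].copy()
    for ref in references:
        out[f"dct_{ref}"] = complete[ref] - complete[target]
    out["dct"] = out[[f"dct_{ref}" for ref in references]].mean(axis=1)
    return out.reset_index(drop=True)


def neg_delta_delta_ct(
    delta_cts: pd.DataFrame,
    treated: str = "torin",
    control: str = "control",
    column: str = "dct",
) -> float:
    """-ddCT = mean dCT(treated) - mean dCT(control); estimates log2 FC."""
    for group in (treated, control):
        if (delta_cts["group"] == group).sum() == 0:
            raise ValueError(f"group {group!r} has no samples")
    mean_t = delta_cts.loc[delta_cts["group"] == treated, column].mean()
    mean_c = delta_cts.loc[delta_cts["group"] == control, column].mean()
    return float(mean_t - mean_c)


def concordance(
    neg_ddct: dict,
    log2fc: dict,
) -> pd.DataFrame:
    """Compare qPCR -ddCT against RNA-seq log2 fold changes per group.

    Both inputs map group keys (e.g. "male_6w") to values.  Keys must
    match.  Reports the difference (-ddCT minus Log2FC) and whether the
    signs agree; zeros agree with anything by convention (a zero estimate
    carries no directional claim).
    """
    if set(neg_ddct) != set(log2fc):
        raise ValueError(
            f"group keys differ: {sorted(set(neg_ddct) ^ set(log2fc))}"
        )
    rows = []
    for key in sorted(neg_ddct):
        q, r = float(neg_ddct[key]), float(log2fc[key])
        agree = q == 0 or r == 0 or np.sign(q) == np.sign(r)
        rows.append(
            {
                "group": key,
                "neg_ddct": q,
                "log2fc_rnaseq": r,
                "difference": q - r,
                "signs_agree": bool(agree),
            }
        )
    return pd.DataFrame(rows)
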