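"""Age-trend statistics, group-exclusive set logic, and overrepresentation.

The age-associated fold change summarizes a gene's trajectory over three
equally spaced ages (2, 4, 6 weeks, coded x = 0, 1, 2): it is ``2**(2*b)``
where b is the OLS slope of log2 expression on x -- i.e. the fitted
old-over-young expression ratio.  A value of 4 means expression in old
individuals is 4-fold that of young ones (and 2-fold that of middle-aged).

Genes are classified as age-associated (up/down) by joint thresholds on
the young-vs-old test p-value and the magnitude of the log2 age fold
change; per-group classifications are then partitioned into the full Venn
lattice so that, e.g., genes age-associated exclusively in treated males
can be isolated.  Overrepresentation of any selection against GMT gene-set
collections uses the one-sided hypergeometric upper tail with BH FDR.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import CountMatrix
from .de import bh_fdr, cpm

AGES_WEEKS = (2, 4, 6)
#: pseudo-expression added before log2 when building trajectories
TRAJECTORY_PRIOR = 0.5


def age_trajectories(
    counts: CountMatrix,
    sex: str,
    diet: str,
) -> pd.DataFrame:
    """Mean log2(CPM + 0.5) per age for one (sex, diet) group.

    Returns a genes x 3 DataFrame with columns 2, 4, 6 (weeks), averaging
    replicates within each age.
    """
    meta = counts.sample_meta
    cols = {}
    for age in AGES_WEEKS:
        samples = meta.index[
            (meta["sex"] == sex) & (meta["diet"] == diet) & (meta["age_weeks"] == age)
        ]
        if len(samples) == 0:
            raise ValueError(f"no samples for sex={sex!r} diet={diet!r} age={age}")
        cols[age] = np.log2(cpm(counts)[samples] + TRAJECTORY_PRIOR).mean(axis=1)
    return pd.DataFrame(cols)


def aa_fold_change(trajectory, scale: str = "log2") -> float | pd.Series:
    """Age-associated fold change from a 3-point expression trajectory.

    ``trajectory`` holds expression at ages coded x = 0, 1, 2 -- either a
    length-3 sequence (one gene) or a genes x 3 DataFrame.  The OLS slope
    b of log2 expression on x is fitted and ``2**(2*b)`` -- the fitted
    old/young ratio on the linear scale -- is returned.  For 3 equally
    spaced points the slope is simply ``(y2 - y0) / 2`` of the log2
    values, so a gene with linear-scale expression 1, 2, 4 gives exactly
    4, and constant expression gives 1.

    ``scale`` declares the input scale: ``"log2"`` (the
    :func:`age_trajectories` output) or ``"linear"`` (raw expression,
    logged here; values must be positive).
    """
    arr = np.asarray(trajectory, dtype=float)
    if scale == "linear":
        if (arr <= 0).any():
            raise ValueError("linear-scale expression must be positive")
        arr = np.log2(arr)
    elif scale != "log2":
        raise ValueError("scale must be 'log2' or 'linear'")
    if arr.ndim == 1:
        if arr.shape != (3,):
            raise ValueError("trajectory must have exactly 3 timepoints")
        if not np.isfinite(arr).all():
            raise ValueError("trajectory values must be finite")
        return float(2.0 ** (arr[2] - arr[0]))
    if arr.shape[1] != 3:
        raise ValueError("trajectory matrix must have exactly 3 columns")
    if not np.isfinite(arr).all():
        raise ValueError("trajectory values must be finite")
    out = 2.0 ** (arr[:, 2] - arr[:, 0])
    if isinstance(trajectory, pd.DataFrame):
        return pd.Series(out, index=trajectory.index, name="aa_fold_change")
    return out


def classify_age_associated(
    p_values: pd.Series,
    aa_fc: pd.Series,
    p_threshold: float = 0.05,
    logfc_threshold: float = 0.3,
) -> pd.DataFrame:
    """Threshold classification of age-associated genes.

    ``p_values`` come from the young-vs-old consensus contrast; ``aa_fc``
    is the linear-scale age fold change.  direction is ``up`` iff
    ``p < p_threshold`` and ``log2(aa_fc) > logfc_threshold``; ``down``
    with the opposite strict inequality; ``none`` otherwise (boundary
    values are not associated).
    """
    p_values = pd.Series(p_values, dtype=float)
    aa_fc = pd.Series(aa_fc, dtype=float)
    if not p_values.index.equals(aa_fc.index):
        if set(p_values.index) != set(aa_fc.index):
            raise ValueError("p-value and fold-change gene sets differ")
        aa_fc = aa_fc.loc[p_values.index]
    log2_fc = np.log2(aa_fc)
    sig = p_values < p_threshold
    direction = np.where(
        sig & (log2_fc > logfc_threshold),
        "up",
        np.where(sig & (log2_fc < -logfc_threshold), "down", "none"),
    )
    return pd.DataFrame(
        {"aa_fold_change": aa_fc, "p_value": p_values, "direction": direction}
    )


def exclusive_sets(memberships: dict) -> dict:
    """Full Venn partition of per-group gene sets.

    ``memberships`` maps group name to an iterable of genes (e.g. the genes
    classified up in that group).  Returns a dict keyed by frozenset of
    group names -- every non-empty region of the inclusion-exclusion
    lattice -- whose values are the genes belonging to exactly those
    groups.  Regions are disjoint and their union is the union of the
    inputs; a gene present in all groups appears only in the all-groups
    region.
    """
    if len(memberships) < 2:
        raise ValueError("need at least two groups")
    sets = {g: frozenset(m) for g, m in memberships.items()}
    regions: dict[frozenset, set] = {}
    for gene in frozenset().union(*sets.values()):
        key = frozenset(g for g, s in sets.items() if gene in s)
        regions.setdefault(key, set()).add(gene)
    return regions


def venn_region_table(regions: dict) -> pd.DataFrame:
    """Flatten a Venn partition into a tidy (region, n_genes, genes) table."""
    rows = [
        {
            "region": "&".join(sorted(key)),
            "n_genes": len(genes),
            "genes": ",".join(sorted(genes)),
        }
        for key, genes in sorted(regions.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "n_genes", "genes"])


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    gene_sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        gene_sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return gene_sets


def ora(
    selected,
    universe,
    gene_sets: dict,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation analysis over gene sets.

    For each set S (intersected with the universe), with universe size N,
    selection size n and |S| = K, the p-value is the upper tail
    ``P(X >= overlap)`` for X hypergeometric(N, K, n).  BH FDR is applied
    across sets.  ``selected`` must be a subset of ``universe``.
    """
    universe = frozenset(universe)
    selected = frozenset(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not selected:
        warnings.warn("empty selection; all ORA p-values are 1", stacklevel=2)
    big_n, n = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        k_set = len(members)
        overlap = len(members & selected)
        p = float(hypergeom.sf(overlap - 1, big_n, k_set, n)) if selected else 1.0
        rows.append(
            {
                "gene_set": name,
                "set_size": k_set,
                "overlap": overlap,
                "p_value": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"]) if len(out) else []
    return out


def all_region_keys(groups) -> list:
    """Every non-empty subset of groups, for exhaustive region enumeration."""
    groups = list(groups)
    keys = []
    for r in range(1, len(groups) + 1):
        keys.extend(frozenset(c) for c in itertools.combinations(groups, r))
    return keys
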