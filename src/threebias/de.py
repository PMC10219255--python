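"""Self-contained negative-binomial differential-expression engine.

Implements the classic count-based two-group workflow from its published
formulas: counts-per-million filtering, trimmed-mean-of-M-values (TMM)
between-sample normalization, common-dispersion estimation by conditional
maximum likelihood on library-size-equalized pseudo-counts, the conditional
NB exact test, and Benjamini-Hochberg FDR.

The engine deliberately re-implements these steps rather than shelling out
to an external tool so the 3'-bias correction layer can drive it with
arbitrary (windowed, per-bin-renormalized) count inputs and so every step
has a closed-form or enumeration oracle in the test suite.

Normalization convention: M-values are log2 ratios of *raw* counts against
the reference sample, so a sample's factor absorbs both sequencing depth
and composition; the effective library size is proportional to the factor
itself (factors are rescaled to geometric mean 1).  This is equivalent to
the proportion-based formulation, where the factor multiplies the library
size, up to a constant common to all samples -- which the library-size
equalization step removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

#: prior added to normalized group means before taking log2, avoiding infinities
LOGFC_PRIOR = 0.125


@dataclass
class DEResult:
    """Per-gene two-group differential expression results.

    ``table`` is indexed by gene id with columns ``log_fc`` (log2, treated
    vs control), ``p_value``, ``fdr`` and ``mean_cpm``.
    """

    table: pd.DataFrame
    contrast: tuple = ("treated", "control")
    dispersion: float = float("nan")

    def __post_init__(self) -> None:
        required = {"log_fc", "p_value", "fdr", "mean_cpm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def log_fc(self) -> pd.Series:
        return self.table["log_fc"]

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``1e6 * y_gs / sum_g y_gs`` per sample."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return mat * (1e6 / lib)


def filter_by_cpm(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    threshold: float = 1.0,
    min_fraction: float = 0.5,
) -> CountMatrix:
    """Keep genes expressed above ``threshold`` CPM in enough samples.

    A gene is kept iff the number of samples with CPM strictly greater than
    ``threshold`` is at least ``ceil(min_fraction * n)`` where n is the size
    of the smallest group.  ``groups`` defaults to the (sex, age, diet)
    cells of the sample sheet.
    """
    if groups is None:
        groups = counts.group_labels()
    groups = pd.Series(groups).loc[counts.sample_ids]
    sizes = groups.value_counts()
    if sizes.empty or (sizes == 0).any():
        raise ValueError("every group must contain at least one sample")
    required = int(np.ceil(min_fraction * sizes.min()))
    n_above = (cpm(counts) > threshold).sum(axis=1)
    keep = n_above >= required
    if not keep.any():
        warnings.warn("CPM filter removed every gene", stacklevel=2)
    return counts.subset_genes(counts.gene_ids[keep])


def _choose_reference(mat: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper quartile."""
    lib = mat.sum(axis=0)
    uq = np.array(
        [np.quantile(mat[:, j][mat[:, j] > 0] / lib[j], 0.75) if (mat[:, j] > 0).any()
         else 0.0 for j in range(mat.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample against a reference sample, per-gene log2 raw-count
    ratios (M) and average log2 abundances (A) are computed over genes
    expressed in both samples; the most extreme ``m_trim`` tails of M and
    ``a_trim`` tails of A are dropped and the surviving M values averaged
    with inverse delta-method-variance weights.  The factor is 2 to that
    weighted mean, rescaled so factors have geometric mean 1.  Two samples
    with identical composition but doubled depth get factors
    (1/sqrt(2), sqrt(2)); identical samples all get 1.
    """
    mat_df = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat_df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = mat_df.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    ref = _choose_reference(mat)

    log_factors = np.zeros(mat.shape[1])
    yr = mat[:, ref]
    nr = lib[ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        yj = mat[:, j]
        nj = lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() == 0:
            warnings.warn(
                f"no genes shared with reference for sample {mat_df.columns[j]}; "
                "factor 1",
                stacklevel=2,
            )
            continue
        m = np.log2(yj[ok] / yr[ok])
        a = 0.5 * np.log2(yj[ok] * yr[ok])
        # delta-method variance of M under binomial sampling
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        keep = np.ones(m.size, dtype=bool)
        for v, trim in ((m, m_trim), (a, a_trim)):
            lo, hi = np.quantile(v, [trim, 1.0 - trim])
            keep &= (v >= lo) & (v <= hi)
        if keep.sum() == 0:
            warnings.warn(
                f"trimming removed all genes for sample {mat_df.columns[j]}; factor 1",
                stacklevel=2,
            )
            continue
        with np.errstate(divide="ignore"):
            inv = np.where(w[keep] > 0, 1.0 / w[keep], 0.0)
        if inv.sum() == 0:
            log_factors[j] = m[keep].mean()
        else:
            log_factors[j] = np.sum(m[keep] * inv) / inv.sum()

    log_factors -= log_factors.mean()  # geometric mean of factors is 1
    return pd.Series(2.0 ** log_factors, index=mat_df.columns, name="tmm_factor")


def _equalize(mat: np.ndarray, rel_scale: np.ndarray) -> np.ndarray:
    """Integer pseudo-counts on a common scale.

    ``rel_scale`` is each sample's relative size (TMM factors, or raw
    library sizes when unnormalized); counts are divided by it, rescaled to
    its geometric mean, and rounded.  An approximation to full quantile
    adjustment that keeps counts integral for the conditional likelihood.
    """
    common = np.exp(np.mean(np.log(rel_scale)))
    return np.rint(mat * (common / rel_scale)).astype(np.int64)


def _relative_scales(
    mat: np.ndarray, sample_ids, factors: pd.Series | None
) -> np.ndarray:
    if factors is not None:
        return factors.loc[sample_ids].to_numpy(dtype=float)
    return mat.sum(axis=0)


def _cml_loglik(pseudo: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Conditional log-likelihood of a common dispersion, summed over genes.

    Within each group the vector of counts given its total is
    Dirichlet-multinomial with shape r = 1/phi per sample; library sizes
    are assumed equal (hence the pseudo-count adjustment).
    """
    r = 1.0 / phi
    total = 0.0
    for gname in np.unique(groups):
        y = pseudo[:, groups == gname]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            - np.sum(gammaln(z + n * r)) + z.size * gammaln(n * r)
        )
    return total


def estimate_dispersion(
    counts: CountMatrix,
    groups: pd.Series,
    factors: pd.Series | None = None,
    pre_equalized: bool = False,
) -> float:
    """Common NB dispersion by conditional maximum likelihood, clipped at 0.

    Counts are rescaled to a common effective library size (skipped when
    ``pre_equalized``), then the conditional likelihood given per-gene,
    per-group totals is maximized over log dispersion.  Groups with a
    single replicate contribute nothing; if no group has replication the
    dispersion is unidentifiable and an error is raised.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    groups = pd.Series(groups).loc[counts.sample_ids]
    garr = groups.to_numpy()
    if max(np.sum(garr == g) for g in np.unique(garr)) < 2:
        raise ValueError("dispersion unidentifiable: no group has >=2 replicates")
    if pre_equalized:
        pseudo = np.rint(mat).astype(np.int64)
    else:
        pseudo = _equalize(mat, _relative_scales(mat, counts.sample_ids, factors))
    pseudo = pseudo[pseudo.sum(axis=1) > 0]

    res = minimize_scalar(
        lambda lp: -_cml_loglik(pseudo, garr, np.exp(lp)),
        bounds=(np.log(1e-6), np.log(10.0)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    # boundary solution: the Poisson limit fits at least as well
    if phi <= 1.2e-6:
        return 0.0
    return phi


def _exact_nb_pvalue(za: int, zb: int, ra: float, rb: float) -> float:
    """Two-sided conditional NB exact p-value for one gene.

    Conditional on the total z = za + zb, the group-A sum follows the
    NB-split law P(x) proportional to C(x+ra-1, x) C(z-x+rb-1, z-x); the
    p-value sums the probabilities of all splits no more likely than the
    observed one.
    """
    z = za + zb
    if z == 0:
        return 1.0
    x = np.arange(z + 1)
    logp = (
        gammaln(x + ra) - gammaln(x + 1)
        + gammaln(z - x + rb) - gammaln(z - x + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    # tie tolerance 1e-8 absorbs gammaln round-off at very large shape r
    return float(min(1.0, p[p <= p[za] * (1 + 1e-8)].sum()))


def _binom_split_pvalue(za: int, zb: int, prop_a: float) -> float:
    """Poisson-limit split test: exact binomial, minimum-likelihood two-sided."""
    z = za + zb
    if z == 0:
        return 1.0
    pmf = binom.pmf(np.arange(z + 1), z, prop_a)
    return float(min(1.0, pmf[pmf <= pmf[za] * (1 + 1e-10)].sum()))


def exact_test(
    counts: CountMatrix,
    groups: pd.Series,
    dispersion: float,
    contrast: tuple[str, str] = ("torin", "control"),
    factors: pd.Series | None = None,
    pre_equalized: bool = False,
) -> DEResult:
    """Conditional NB exact test between two groups of samples.

    ``contrast = (treated, control)``: log_fc is log2(treated / control) of
    normalized group means with a prior count of 0.125.  Counts are first
    rescaled to a common effective library size (TMM factors if given, raw
    library sizes otherwise; skipped when ``pre_equalized``); the per-gene
    two-sided p-value conditions on the gene's total.  In the Poisson limit
    (dispersion 0) the split test is exact binomial.
    """
    groups = pd.Series(groups).loc[counts.sample_ids]
    treated, control = contrast
    for gname in contrast:
        if (groups == gname).sum() == 0:
            raise ValueError(f"contrast group {gname!r} has no samples")
    use = groups.isin(contrast)
    sub = counts.subset_samples(counts.sample_ids[use])
    garr = groups[use].to_numpy()

    mat = sub.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size in contrast samples")
    if pre_equalized:
        pseudo = np.rint(mat).astype(np.int64)
    else:
        pseudo = _equalize(mat, _relative_scales(mat, sub.sample_ids, factors))

    is_a = garr == treated
    na, nb = int(is_a.sum()), int((~is_a).sum())
    za = pseudo[:, is_a].sum(axis=1)
    zb = pseudo[:, ~is_a].sum(axis=1)

    if dispersion > 0:
        r = 1.0 / dispersion
        pvals = np.array(
            [_exact_nb_pvalue(a, b, na * r, nb * r) for a, b in zip(za, zb)]
        )
    else:
        prop = na / (na + nb)
        pvals = np.array([_binom_split_pvalue(a, b, prop) for a, b in zip(za, zb)])

    mean_a = za / na
    mean_b = zb / nb
    log_fc = np.log2(mean_a + LOGFC_PRIOR) - np.log2(mean_b + LOGFC_PRIOR)
    mean_cpm = cpm(sub.counts).mean(axis=1)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_cpm": mean_cpm.to_numpy(),
        },
        index=sub.gene_ids,
    )
    return DEResult(table=table, contrast=contrast, dispersion=dispersion)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    contrast: tuple[str, str] = ("torin", "control"),
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.5,
) -> DEResult:
    """Full two-group pipeline: CPM filter -> TMM -> dispersion -> exact test.

    ``groups`` defaults to the ``diet`` column of the sample sheet.  The
    filter's smallest-group rule is evaluated on the contrast samples only.
    """
    if groups is None:
        groups = counts.sample_meta["diet"]
    groups = pd.Series(groups).loc[counts.sample_ids]
    use = groups.isin(contrast)
    if use.sum() == 0:
        raise ValueError("no samples match the contrast")
    sub = counts.subset_samples(counts.sample_ids[use])
    sub_groups = groups[use]

    filtered = filter_by_cpm(sub, sub_groups, cpm_threshold, min_fraction)
    if filtered.counts.shape[0] == 0:
        empty = pd.DataFrame(columns=["log_fc", "p_value", "fdr", "mean_cpm"])
        return DEResult(table=empty, contrast=contrast)
    factors = tmm_factors(filtered)
    phi = estimate_dispersion(filtered, sub_groups, factors)
    return exact_test(filtered, sub_groups, phi, contrast, factors)
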