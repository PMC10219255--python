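"""Synthetic experiments with known truth for pipeline verification.

The generator emulates a two-sex, three-age, drug-vs-control fly RNA-seq
design (36 libraries at 3 replicates per cell) with negative-binomial
counts, a per-sample 3'-coverage-decay bias, and optional injected
treatment and age effects.  Its point is that it can *create* the
length-correlated fold-change artifact the correction layer removes:
coverage decays exponentially from the 3' end with a per-sample scale tau,
so the captured fraction of a transcript of length L is

    B(L, tau) = (tau / L) * (1 - exp(-L / tau)),

monotone decreasing in L.  When tau differs between groups, the ratio of
capture fractions depends on L and a spurious length-correlated log
fold change appears in uncorrected differential expression.

Lifespan cohorts follow a Gompertz hazard ``h(t) = a * effect * exp(b t)``
with deaths recorded daily (integer days, no censoring), and qPCR CT
tables are built by construction so that the downstream -ddCT chain
recovers an injected log2 fold change exactly in the noise-free limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, SurvivalCohort

AGE_CODE = {2: 0, 4: 1, 6: 2}  # weeks -> uniformly spaced age index

DEFAULT_DESIGN = tuple(
    itertools.product(("male", "female"), (2, 4, 6), ("torin", "control"))
)


def capture_fraction(length, tau):
    """Fraction of a transcript captured under exponential 3' coverage decay.

    ``B(L, tau) = (tau/L) * (1 - exp(-L/tau))``: 1 in the no-bias limit
    (tau >> L), ~tau/L for heavily degraded libraries (tau << L).

    Parameters
    ----------
    length
        Transcript length in nt (scalar or array), must be positive.
    tau
        Decay scale in nt (scalar or array), must be positive.
    """
    L = np.asarray(length, dtype=float)
    t = np.asarray(tau, dtype=float)
    if (L <= 0).any():
        raise ValueError("transcript length must be positive")
    if (t <= 0).any():
        raise ValueError("bias scale tau must be positive")
    out = (t / L) * (-np.expm1(-L / t))
    if out.ndim == 0:
        return float(out)
    return out


def window_fraction(length, window, tau):
    """Expected fraction of a transcript's reads falling in its 3'-terminal window.

    With coverage density proportional to ``exp(-d/tau)`` at distance d from
    the 3' end, the terminal ``min(L, W)`` nt hold
    ``(1 - exp(-min(L,W)/tau)) / (1 - exp(-L/tau))`` of the reads.
    """
    L = np.asarray(length, dtype=float)
    t = np.asarray(tau, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    w_eff = np.minimum(L, window)
    frac = (-np.expm1(-w_eff / t)) / (-np.expm1(-L / t))
    return np.clip(frac, 0.0, 1.0)


@dataclass
class SimConfig:
    """Parameters of a synthetic 3'-biased RNA-seq experiment.

    Attributes
    ----------
    n_genes, n_reps
        Number of genes and replicates per design cell.
    design
        Cells as (sex, age_weeks, diet) triples; ages must be in {2, 4, 6}
        weeks and are coded 0/1/2 for trend effects.
    baseline_mean_log, baseline_sd_log
        Location/scale of the natural-log of relative gene abundance.
    dispersion
        NB dispersion phi >= 0 (variance = mu + phi mu^2); 0 gives Poisson.
    length_log10_range
        (min, max) of log10 transcript length in nt; lengths are drawn
        log-uniformly.
    bias_tau
        3' decay scale in nt: a single value for all samples, or a mapping
        from diet label to tau for group-dependent bias.
    de_fraction, de_logfc
        Fraction of genes carrying a true treatment effect and its log2
        magnitude delta.
    age_slope_fraction, age_slope
        Fraction of genes with a true per-timepoint log2 age slope b and
        its value.
    age_slope_groups
        Optional collection of (sex, diet) pairs to which age slopes are
        restricted; None applies them in every group.
    lib_size
        Expected library size in the no-bias limit.
    window_nt
        3' window W used for the windowed companion counts.
    seed
        RNG seed; runs are bit-reproducible.
    """

    n_genes: int = 2000
    n_reps: int = 3
    design: Sequence[tuple] = DEFAULT_DESIGN
    baseline_mean_log: float = 3.0
    baseline_sd_log: float = 1.2
    dispersion: float = 0.1
    length_log10_range: tuple = (2.5, 4.5)
    bias_tau: float | Mapping[str, float] = 2000.0
    de_fraction: float = 0.0
    de_logfc: float = 0.0
    age_slope_fraction: float = 0.0
    age_slope: float = 0.0
    age_slope_groups: Sequence[tuple] | None = None
    lib_size: float = 1e6
    window_nt: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("n_genes and n_reps must be >= 1")
        if len(self.design) == 0:
            raise ValueError("design must contain at least one cell")
        for cell in self.design:
            if len(cell) != 3 or cell[1] not in AGE_CODE:
                raise ValueError(f"bad design cell {cell!r}; age must be 2/4/6 weeks")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.length_log10_range
        if not (0 < lo <= hi):
            raise ValueError("length_log10_range must be positive and ordered")
        for frac in (self.de_fraction, self.age_slope_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        taus = (
            list(self.bias_tau.values())
            if isinstance(self.bias_tau, Mapping)
            else [self.bias_tau]
        )
        if any(t <= 0 for t in taus):
            raise ValueError("bias_tau must be positive")
        if self.lib_size <= 0 or self.window_nt <= 0:
            raise ValueError("lib_size and window_nt must be positive")

    def tau_for(self, diet: str) -> float:
        if isinstance(self.bias_tau, Mapping):
            return float(self.bias_tau[diet])
        return float(self.bias_tau)


@dataclass
class SimulatedExperiment:
    """Output of :func:`simulate_counts`: counts, windowed counts, and truth."""

    counts: CountMatrix
    windowed_counts: CountMatrix
    annotation: GeneAnnotation
    truth: pd.DataFrame  # per gene: delta, age_slope, is_de
    bias: pd.Series  # per sample: tau
    config: SimConfig = field(repr=False, default=None)


def simulate_counts(config: SimConfig) -> SimulatedExperiment:
    """Draw a full synthetic experiment under the coverage-decay bias model.

    Counts are NB with mean
    ``mu_gs = s * e_g * B(L_g, tau_s) * 2^(x_s * delta_g + a_s * b_g)``
    where ``x_s`` indicates treatment, ``a_s`` in {0,1,2} is the age index,
    and ``s`` scales the expected no-bias library to ``lib_size``.  The 3'
    windowed companion matrix is a per-entry Binomial thinning of the full
    counts with the window fraction, so ``windowed <= counts`` element-wise.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    gene_ids = pd.Index([f"g{i:05d}" for i in range(g)], name="gene_id")
    lo, hi = config.length_log10_range
    lengths = 10 ** rng.uniform(lo, hi, size=g)
    abundance = np.exp(rng.normal(config.baseline_mean_log, config.baseline_sd_log, g))

    delta = np.zeros(g)
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    delta[de_idx] = config.de_logfc

    slope = np.zeros(g)
    n_slope = int(round(config.age_slope_fraction * g))
    slope_idx = rng.choice(g, size=n_slope, replace=False)
    slope[slope_idx] = config.age_slope

    scale = config.lib_size / abundance.sum()

    sample_rows = []
    for sex, age, diet in config.design:
        for rep in range(1, config.n_reps + 1):
            sample_rows.append(
                {
                    "sample": f"{sex}_{age}w_{diet}_r{rep}",
                    "sex": sex,
                    "age_weeks": age,
                    "diet": diet,
                    "replicate": rep,
                }
            )
    meta = pd.DataFrame(sample_rows).set_index("sample")

    counts = np.empty((g, len(meta)), dtype=np.int64)
    windowed = np.empty_like(counts)
    taus = []
    for j, (sample, row) in enumerate(meta.iterrows()):
        tau = config.tau_for(row["diet"])
        taus.append(tau)
        x = 1.0 if row["diet"] == "torin" else 0.0
        a = AGE_CODE[row["age_weeks"]]
        slopes_apply = config.age_slope_groups is None or (
            (row["sex"], row["diet"]) in {tuple(g) for g in config.age_slope_groups}
        )
        mu = (
            scale
            * abundance
            * capture_fraction(lengths, tau)
            * 2.0 ** (x * delta + (a * slope if slopes_apply else 0.0))
        )
        if config.dispersion == 0:
            y = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            y = rng.negative_binomial(r, r / (r + mu))
        w = window_fraction(lengths, config.window_nt, tau)
        counts[:, j] = y
        windowed[:, j] = rng.binomial(y, w)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta.index)
    windowed_df = pd.DataFrame(windowed, index=gene_ids, columns=meta.index)
    truth = pd.DataFrame(
        {"delta": delta, "age_slope": slope, "is_de": delta != 0}, index=gene_ids
    )
    return SimulatedExperiment(
        counts=CountMatrix(counts_df, meta),
        windowed_counts=CountMatrix(windowed_df, meta),
        annotation=GeneAnnotation(pd.Series(lengths, index=gene_ids, name="length_nt")),
        truth=truth,
        bias=pd.Series(taus, index=meta.index, name="tau"),
        config=config,
    )


def gompertz_lifespans(
    n: int, a: float, b: float, effect: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer day-of-death draws under hazard ``a * effect * exp(b t)``.

    Uses the closed-form inverse survival function
    ``T = (1/b) * ln(1 - b ln(U) / (a * effect))`` and rounds deaths up to
    the day they are observed (daily collection).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if a <= 0 or b <= 0 or effect <= 0:
        raise ValueError("Gompertz parameters and effect must be positive")
    u = rng.uniform(size=n)
    t = np.log1p(-b * np.log(u) / (a * effect)) / b
    return np.maximum(1, np.ceil(t).astype(int))


def simulate_lifespans(
    n_per_group: int,
    gompertz_a: float = 1e-4,
    gompertz_b: float = 0.12,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Control and treated lifespan cohorts under the Gompertz law.

    The control hazard is ``a * exp(b t)``; the treated hazard is multiplied
    by ``effect`` (< 1 extends lifespan).  Returns (control, treated).
    """
    rng = np.random.default_rng(seed)
    control = gompertz_lifespans(n_per_group, gompertz_a, gompertz_b, 1.0, rng)
    treated = gompertz_lifespans(n_per_group, gompertz_a, gompertz_b, effect, rng)
    return SurvivalCohort("control", control), SurvivalCohort("treated", treated)


def gompertz_median(a: float, b: float, effect: float = 1.0) -> float:
    """Median of the continuous Gompertz lifespan distribution (oracle)."""
    return np.log1p(b * np.log(2.0) / (a * effect)) / b


def simulate_qpcr(
    true_log2fc: Mapping[str, float],
    ct_noise_sd: float = 0.25,
    n_biological: int = 3,
    references: Sequence[str] = ("eIF4A", "RpL32"),
    groups: Sequence[str] = ("control", "torin"),
    sex: str = "male",
    age_weeks: int = 4,
    baseline_delta_ct: float = 2.0,
    n_technical: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format CT table for target genes against reference genes.

    Each biological sample gets a plate/loading offset shared by all its
    wells; each well (technical replicate) gets independent Gaussian noise
    of sd ``ct_noise_sd``.  Target CTs are built as
    ``CT_ref - dCT`` with ``dCT = baseline + log2fc`` in the treated group,
    so the noise-free -ddCT chain returns ``log2fc`` exactly.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if n_biological < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >= 1")
    if len(references) == 0 or len(true_log2fc) == 0:
        raise ValueError("need at least one reference and one target gene")

    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        treated = group != groups[0]
        for b in range(1, n_biological + 1):
            sample = f"{sex}_{age_weeks}w_{group}_b{b}"
            plate_offset = rng.normal(0.0, 0.5)
            ref_base = {ref: 20.0 + plate_offset for ref in references}
            for ref in references:
                for tech in range(1, n_technical + 1):
                    rows.append(
                        (sample, group, sex, age_weeks, ref, tech,
                         ref_base[ref] + rng.normal(0.0, ct_noise_sd))
                    )
            mean_ref = np.mean(list(ref_base.values()))
            for target, lfc in true_log2fc.items():
                dct = baseline_delta_ct + (lfc if treated else 0.0)
                for tech in range(1, n_technical + 1):
                    rows.append(
                        (sample, group, sex, age_weeks, target, tech,
                         mean_ref - dct + rng.normal(0.0, ct_noise_sd))
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "sex", "age_weeks", "gene_id",
            "technical_rep", "ct",
        ],
    )
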