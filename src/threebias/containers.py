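"""Core data containers shared across the pipeline.

These are thin, validated wrappers around pandas objects: a gene x sample
count matrix with a sample sheet, a per-gene annotation carrying transcript
lengths, and an uncensored lifespan cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sample-sheet columns every CountMatrix carries
SAMPLE_META_COLUMNS = ("sex", "age_weeks", "diet", "replicate")


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.
    sample_meta
        DataFrame indexed by sample id with columns ``sex``, ``age_weeks``,
        ``diet`` and ``replicate``, covering every count column.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta missing samples: {sorted(missing)}")
        for col in SAMPLE_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        # align meta rows to count columns
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.sample_meta)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.sample_meta.loc[samples])

    def group_labels(self, keys=("sex", "age_weeks", "diet")) -> pd.Series:
        """Group label per sample, joining the given metadata keys."""
        meta = self.sample_meta
        return meta[list(keys)].astype(str).agg("_".join, axis=1)


@dataclass
class GeneAnnotation:
    """Per-gene average transcript length in nucleotides."""

    lengths: pd.Series  # indexed by gene id, values in nt

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=float)
        if self.lengths.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.lengths.index

    def log10_lengths(self) -> pd.Series:
        return np.log10(self.lengths)

    def for_genes(self, genes) -> pd.Series:
        missing = set(genes) - set(self.lengths.index)
        if missing:
            raise KeyError(f"annotation missing lengths for {len(missing)} genes")
        return self.lengths.loc[genes]


@dataclass
class SurvivalCohort:
    """Uncensored lifespans (integer days) for one group of individuals.

    Deaths are recorded once per day, so heavy ties are expected and every
    individual has an observed event.
    """

    group: str
    lifespans: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.lifespans = np.asarray(self.lifespans, dtype=int)
        if self.lifespans.size == 0:
            raise ValueError("cohort must contain at least one individual")
        if (self.lifespans < 1).any():
            raise ValueError("lifespans must be >= 1 day")

    @property
    def n(self) -> int:
        return int(self.lifespans.size)

    @property
    def median(self) -> float:
        return float(np.median(self.lifespans))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.lifespans, q))
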