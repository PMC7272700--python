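"""Count normalization and expression summaries.

Implements the pre-processing stage shared by the mRNA and miRNA arms of
the pipeline: median-of-ratios size factors, per-sample fold changes
against the control-group mean, CPM/RPKM conversion, the raw-count
expression filter applied to miRNAs, and quartile-based abundance classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

#: pseudo-count (normalized-count units) guarding zeros in fold changes
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CountMatrix:
    """Raw integer counts, features x samples, with a two-group design.

    Parameters
    ----------
    counts
        Non-negative integer matrix with feature ids as index and sample
        ids as columns.
    groups
        Mapping of sample id to ``"control"`` or ``"case"`` covering every
        column of ``counts``.
    feature_lengths
        Optional per-feature lengths in bp, required only for RPKM.
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = pd.Series(self.groups)
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.counts.columns)]
        bad = set(self.groups.unique()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (CONTROL, CASE):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"group {g!r} has no samples")
        if self.feature_lengths is not None:
            self.feature_lengths = pd.Series(self.feature_lengths).loc[
                self.counts.index
            ]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(samples)], self.groups.loc[list(samples)],
            self.feature_lengths,
        )

    def subset_features(self, features) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(features)], self.groups, self.feature_lengths
        )


@dataclass
class NormalizedMatrix:
    """Counts divided column-wise by positive size factors."""

    normalized: pd.DataFrame
    size_factors: pd.Series
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sf = np.asarray(self.size_factors, float)
        if not np.all(np.isfinite(sf)) or (sf <= 0).any():
            raise ValueError("size factors must be finite and > 0")


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median, over features with nonzero
    counts in every sample, of ``count / geometric mean across samples``.

    Raises
    ------
    ValueError
        If no feature is nonzero in all samples; pre-filter the matrix to
        expressed features first.
    """
    x = cm.counts.values
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "pre-filter to expressed features before normalization"
        )
    logx = np.log(x[allpos])
    log_geo = logx.mean(axis=1, keepdims=True)
    ratios = np.exp(logx - log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalize(cm: CountMatrix, size_factors: pd.Series | None = None) -> NormalizedMatrix:
    """Divide counts column-wise by (estimated) size factors."""
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    norm = cm.counts.div(size_factors, axis=1)
    return NormalizedMatrix(norm, size_factors, cm.groups)


def per_sample_fold_change(
    nm: NormalizedMatrix,
    reference_group: str = CONTROL,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold change of each sample against the reference-group mean.

    ``FC[g, s] = (norm[g, s] + eps) / (mean of norm[g, reference] + eps)``
    with ``eps = pseudocount`` bounding ratios at zero counts.
    """
    if nm.groups is None:
        raise ValueError("NormalizedMatrix carries no group labels")
    ref = nm.groups.index[nm.groups == reference_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = nm.normalized[list(ref)].mean(axis=1)
    return nm.normalized.add(pseudocount).div(ref_mean + pseudocount, axis=0)


def to_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads: ``count * 1e6 / column sum``."""
    libsize = cm.counts.sum(axis=0)
    return cm.counts.mul(1e6).div(libsize, axis=1)


def to_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: ``count * 1e9 / (column sum * length)``."""
    if cm.feature_lengths is None:
        raise ValueError("feature_lengths required for RPKM")
    libsize = cm.counts.sum(axis=0)
    return cm.counts.mul(1e9).div(libsize, axis=1).div(cm.feature_lengths, axis=0)


def filter_expressed_mirnas(cm: CountMatrix, threshold: int = 32) -> list[str]:
    """Features with raw count strictly above ``threshold`` in >=1 sample.

    The default reproduces the expressed-in-muscle filter (mapped reads
    > 32 in at least one sequenced sample).
    """
    keep = (cm.counts > threshold).any(axis=1)
    return list(cm.counts.index[keep])


def abundance_class(values: pd.Series) -> pd.Series:
    """Quartile-based abundance classes: low (< Q1), high (> Q3), else medium.

    Quartiles use linear interpolation (numpy default, type 7) on the
    supplied per-feature abundances.
    """
    v = pd.Series(values).astype(float)
    q1, q3 = np.quantile(v.values, [0.25, 0.75])
    out = pd.Series("medium", index=v.index, name="abundance_class")
    out[v < q1] = "low"
    out[v > q3] = "high"
    return out
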