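"""Variability filtering and the binary gene-pair transform.

The core representation of this method: instead of absolute expression,
each covariate is the within-sample comparison of two genes.  A pair
(IRG1, IRG2) takes value 1 in a sample when IRG1's expression strictly
exceeds IRG2's, else 0 (ties included).  Because the indicator depends
only on the within-sample ordering, it is invariant to any strictly
increasing per-sample transform of the data — the property that lets a
signature trained on RNA-seq FPKM transfer to microarray intensities
without cross-platform normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "PairMatrix",
    "mad_filter",
    "build_pairs",
    "build_pair_matrix",
    "filter_pairs",
]

PAIR_SEP = "|"


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the per-cohort MAD variability filter.

    ``gene_mad`` holds the unscaled MAD of every candidate gene in every
    cohort (NaN where the gene is absent).  A gene is kept only if it is
    present in every cohort and exceeds the threshold in each.
    """

    gene_mad: pd.DataFrame  # genes x cohorts
    kept: set[str]
    dropped: set[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.kept & self.dropped:
            raise ValueError("kept and dropped gene sets overlap")


@dataclass(frozen=True)
class PairMatrix:
    """Binary pair-by-sample matrix of gene-pair indicators.

    ``data`` rows are labelled ``"IRG1|IRG2"``; entry (p, s) is 1 iff the
    first gene of p out-expresses the second in sample s.
    """

    pairs: tuple[tuple[str, str], ...]
    data: pd.DataFrame  # pairs x samples, values in {0, 1}

    def __post_init__(self) -> None:
        if len(self.pairs) != self.data.shape[0]:
            raise ValueError("pair list and matrix row count disagree")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("pair matrix values must be binary")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def frequencies(self) -> pd.Series:
        """Across-sample frequency of value 1 per pair."""
        return self.data.mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "pair"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        pairs = tuple(tuple(str(ix).split(PAIR_SEP, 1)) for ix in data.index)
        return cls(pairs=pairs, data=data.astype(np.int8))


def _unscaled_mad(values: np.ndarray) -> np.ndarray:
    """Row-wise median absolute deviation, no consistency constant."""
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def mad_filter(
    cohorts: ExpressionMatrix | Sequence[ExpressionMatrix],
    genes: Iterable[str],
    threshold: float = 0.5,
    cohort_names: Sequence[str] | None = None,
) -> FilterReport:
    """Keep genes whose unscaled MAD exceeds ``threshold`` in every cohort.

    The statistic is computed per cohort; the decision is the intersection:
    a gene absent from any cohort, or at or below the threshold in any
    cohort, is dropped.
    """
    if isinstance(cohorts, ExpressionMatrix):
        cohorts = [cohorts]
    if threshold < 0:
        raise ValueError("MAD threshold must be non-negative")
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty candidate gene set")
    if cohort_names is None:
        cohort_names = [f"cohort_{i}" for i in range(len(cohorts))]
    mad = pd.DataFrame(index=genes, columns=list(cohort_names), dtype=float)
    for name, cohort in zip(cohort_names, cohorts):
        present = [g for g in genes if g in cohort.data.index]
        if not present:
            raise ValueError(f"no candidate genes found in {name}")
        mad.loc[present, name] = _unscaled_mad(
            cohort.data.loc[present].to_numpy(dtype=float)
        )
    passing = (mad > threshold).all(axis=1) & mad.notna().all(axis=1)
    kept = set(mad.index[passing])
    dropped = set(genes) - kept
    if not kept:
        raise ValueError(
            f"no genes pass MAD > {threshold} in all cohorts; lower the threshold"
        )
    logger.info("MAD filter kept %d of %d genes", len(kept), len(genes))
    return FilterReport(gene_mad=mad, kept=kept, dropped=dropped, threshold=threshold)


def build_pairs(expr: ExpressionMatrix, genes: Iterable[str]) -> PairMatrix:
    """All C(n, 2) binary gene-pair indicators over ``genes``.

    Orientation is fixed lexicographically; value = 1 iff the first gene's
    expression strictly exceeds the second's, so a tie scores 0.  Any fixed
    orientation is equivalent for screening and fitting, since the model
    sees both directions through the 0/1 coding.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least two genes to form pairs")
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    arr = expr.data.loc[genes].to_numpy(dtype=float)
    i_idx, j_idx = np.triu_indices(len(genes), k=1)
    values = (arr[i_idx] > arr[j_idx]).astype(np.int8)
    pairs = tuple((genes[i], genes[j]) for i, j in zip(i_idx, j_idx))
    index = [f"{a}{PAIR_SEP}{b}" for a, b in pairs]
    data = pd.DataFrame(values, index=index, columns=expr.sample_ids)
    return PairMatrix(pairs=pairs, data=data)


def build_pair_matrix(
    expr: ExpressionMatrix, pairs: Sequence[tuple[str, str]]
) -> PairMatrix:
    """Binary indicators for an explicit, ordered list of gene pairs.

    Unlike :func:`build_pairs`, orientation is taken as given — used to
    evaluate a fixed signature or a hand-picked candidate set.
    """
    if not pairs:
        raise ValueError("empty pair list")
    genes = {g for p in pairs for g in p}
    missing = sorted(genes - set(expr.data.index))
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    g1 = expr.data.loc[[p[0] for p in pairs]].to_numpy(dtype=float)
    g2 = expr.data.loc[[p[1] for p in pairs]].to_numpy(dtype=float)
    values = (g1 > g2).astype(np.int8)
    index = [f"{a}{PAIR_SEP}{b}" for a, b in pairs]
    data = pd.DataFrame(values, index=index, columns=expr.sample_ids)
    return PairMatrix(pairs=tuple(tuple(p) for p in pairs), data=data)


def filter_pairs(pm: PairMatrix, low: float = 0.2, high: float = 0.8) -> PairMatrix:
    """Drop pairs with small variation or imbalanced distribution.

    Retains pairs whose across-sample frequency of value 1 lies in
    [``low``, ``high``]; constant and near-constant pairs carry no
    information and destabilize downstream fits.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("require 0 <= low < high <= 1")
    freq = pm.frequencies().to_numpy()
    keep = (freq >= low) & (freq <= high)
    if not keep.any():
        raise ValueError("all pairs removed by the frequency filter")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("frequency filter removed %d of %d pairs", n_drop, pm.n_pairs)
    pairs = tuple(p for p, k in zip(pm.pairs, keep) if k)
    return PairMatrix(pairs=pairs, data=pm.data.loc[keep])
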