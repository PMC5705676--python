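"""Quantifiable-protein filtering and S0-moderated differential abundance.

The test statistic is a SAM-style moderated Welch statistic

    d = (mean(x) - mean(y)) / (s0 + sqrt(var(x)/n_x + var(y)/n_y))

with sample variances (n-1 denominator) and a non-negative fudge factor
``s0`` added to the unequal-variance standard error.  ``s0 = 0`` recovers
the classical Welch t statistic; ``s0 > 0`` de-emphasises proteins whose
variance is accidentally tiny.  Missing intensities (non-detections) are
excluded before computing counts, means and variances -- never imputed.

Significance is assessed by a symmetric permutation FDR: group labels are
reshuffled (exhaustively when few enough relabelings exist, otherwise by
seeded random draws), |d| is recomputed under each relabeling, and for
candidate cutoffs taken at the observed |d| values

    FDR(c) = mean over permutations of #{|d*| >= c} / max(1, #{|d| >= c})

clipped to [0, 1] and made monotone non-increasing in c.  The chosen cutoff
is the smallest c with FDR(c) <= alpha.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TestConfig:
    """Settings for filtering and testing.

    Defaults are the workflow's standard operating point: ``s0 = 1``, a
    permutation FDR threshold of 0.05, a 60% per-group valid-value
    requirement, and 250 permutations.
    """

    s0: float = 1.0
    alpha: float = 0.05
    min_valid_frac: float = 0.6
    n_permutations: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if not 0 < self.min_valid_frac <= 1:
            raise ValueError("min_valid_frac must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class GroupDesign:
    """Assignment of samples to the two compared conditions.

    ``group1``/``group2`` fix the direction of the contrast
    (``d > 0`` means higher in ``group1``); when not given they default to
    the sorted pair of distinct labels.
    """

    assignments: dict[str, str]
    group1: str | None = None
    group2: str | None = None

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"design must have exactly 2 groups, got {labels}")
        if self.group1 is None or self.group2 is None:
            self.group1, self.group2 = labels
        if {self.group1, self.group2} != set(labels):
            raise ValueError("group1/group2 do not match the design labels")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group1: str | None = None,
                   group2: str | None = None) -> "GroupDesign":
        """Build from a two-column table (sample_id, group)."""
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))),
                   group1=group1, group2=group2)


def log_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """log2-transform raw intensities; zeros and non-detections become
    missing.  Negative input is an error."""
    values = raw.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("raw intensities must be non-negative")
    out = np.full_like(values, np.nan)
    pos = values > 0
    out[pos] = np.log2(values[pos])
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def _required_valid(frac: float, n: int) -> int:
    # small epsilon guards against float fuzz in frac * n at exact integers
    return math.ceil(frac * n - 1e-9)


def filter_quantifiable(
    matrix: pd.DataFrame,
    design: GroupDesign,
    cfg: TestConfig | None = None,
) -> pd.DataFrame:
    """Retain proteins with enough valid values in EACH group.

    A protein is quantifiable when it has at least
    ``ceil(min_valid_frac * n_g)`` non-missing values in every group (for
    5 vs 5 at 60% that is 3 out of 5 in both conditions).
    """
    cfg = cfg or TestConfig()
    keep = pd.Series(True, index=matrix.index)
    for group in (design.group1, design.group2):
        cols = [c for c in matrix.columns if design.assignments.get(c) == group]
        if not cols:
            raise ValueError(f"no samples of group {group!r} in the matrix")
        required = _required_valid(cfg.min_valid_frac, len(cols))
        keep &= matrix[cols].notna().sum(axis=1) >= required
    return matrix.loc[keep]


def sam_welch_d(x, y, s0: float = 1.0) -> float:
    """Moderated Welch statistic for one protein (missing values dropped).

    Requires at least two valid values per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 valid values per group")
    se = math.sqrt(np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y))
    return float((x.mean() - y.mean()) / (s0 + se))


def _d_vector(values: np.ndarray, idx1, idx2, s0: float) -> np.ndarray:
    """Vectorised d over a proteins x samples matrix with NaN missing.

    Proteins with fewer than two valid values in either group get NaN.
    """
    out = []
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # permuted groups may have < 2 valid values; those rows become NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        for idx in (idx1, idx2):
            sub = values[:, idx]
            n = np.sum(np.isfinite(sub), axis=1)
            mean = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=1)
            var = np.nanvar(np.where(np.isfinite(sub), sub, np.nan), axis=1, ddof=1)
            out.append((n, mean, var))
    (n1, m1, v1), (n2, m2, v2) = out
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m2) / (s0 + np.sqrt(v1 / n1 + v2 / n2))
    d[(n1 < 2) | (n2 < 2)] = np.nan
    return d


@dataclass
class DiffResult:
    """Differential-abundance outcome.

    ``table`` has one row per tested protein; ``cutoff`` is the chosen |d|
    threshold (inf when no cutoff satisfies the FDR target).
    """

    table: pd.DataFrame
    cutoff: float
    fdr_at_cutoff: float
    n_significant: int
    config: TestConfig
    n_permutations_used: int
    exhaustive: bool
    fdr_curve: pd.DataFrame = field(repr=False, default=None)


def _relabelings(n: int, n1: int, cfg: TestConfig) -> tuple[list[tuple[int, ...]], bool]:
    """Index sets forming permuted group 1, excluding the identity.

    All distinct relabelings are enumerated when their count (minus the
    identity) is at most ``n_permutations``; otherwise that many random
    draws are taken, seed-deterministically.
    """
    identity = tuple(range(n1))
    total = math.comb(n, n1)
    if total - 1 <= cfg.n_permutations:
        return [c for c in itertools.combinations(range(n), n1) if c != identity], True
    rng = np.random.default_rng(cfg.seed)
    draws: list[tuple[int, ...]] = []
    while len(draws) < cfg.n_permutations:
        pick = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if pick != identity:
            draws.append(pick)
    return draws, False


def permutation_fdr(
    matrix: pd.DataFrame,
    design: GroupDesign,
    cfg: TestConfig | None = None,
) -> DiffResult:
    """Permutation-FDR thresholding of the moderated Welch statistic.

    The matrix should already be filtered with :func:`filter_quantifiable`;
    columns are reordered internally so that group-1 samples come first and
    relabelings draw new group-1 index sets from all samples.
    """
    cfg = cfg or TestConfig()
    cols1 = [c for c in matrix.columns if design.assignments.get(c) == design.group1]
    cols2 = [c for c in matrix.columns if design.assignments.get(c) == design.group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs >= 2 samples")
    unassigned = [c for c in matrix.columns if c not in cols1 + cols2]
    if unassigned:
        raise ValueError(f"samples not in the design: {unassigned}")

    values = matrix[cols1 + cols2].to_numpy(dtype=float)
    n1, n = len(cols1), len(cols1) + len(cols2)
    idx1 = list(range(n1))
    idx2 = list(range(n1, n))
    obs_d = _d_vector(values, idx1, idx2, cfg.s0)
    obs_abs = np.abs(obs_d)
    obs_sorted = np.sort(obs_abs[np.isfinite(obs_abs)])

    relabelings, exhaustive = _relabelings(n, n1, cfg)
    pool = []
    for pick in relabelings:
        other = [i for i in range(n) if i not in pick]
        d_star = _d_vector(values, list(pick), other, cfg.s0)
        pool.append(np.abs(d_star[np.isfinite(d_star)]))
    pool = np.sort(np.concatenate(pool)) if pool else np.array([])
    n_perm = len(relabelings)

    candidates = np.unique(obs_sorted)
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, candidates, side="left")
    n_perm_ge = (len(pool) - np.searchsorted(pool, candidates, side="left")) / max(1, n_perm)
    fdr = np.clip(n_perm_ge / np.maximum(1, n_obs_ge), 0.0, 1.0)
    fdr_mono = np.minimum.accumulate(fdr) if len(fdr) else fdr

    passing = np.nonzero(fdr_mono <= cfg.alpha)[0]
    if len(passing):
        cutoff = float(candidates[passing[0]])
        fdr_at = float(fdr_mono[passing[0]])
    else:
        cutoff, fdr_at = math.inf, math.nan

    significant = np.isfinite(obs_abs) & (obs_abs >= cutoff)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(np.where(np.isfinite(values[:, idx1]), values[:, idx1], np.nan), axis=1)
        m2 = np.nanmean(np.where(np.isfinite(values[:, idx2]), values[:, idx2], np.nan), axis=1)
    table = pd.DataFrame(
        {
            "n_valid_g1": np.sum(np.isfinite(values[:, idx1]), axis=1),
            "n_valid_g2": np.sum(np.isfinite(values[:, idx2]), axis=1),
            "mean_g1": m1,
            "mean_g2": m2,
            "log2_difference": m1 - m2,
            "d_statistic": obs_d,
            "significant": significant,
        },
        index=matrix.index,
    )
    return DiffResult(
        table=table,
        cutoff=cutoff,
        fdr_at_cutoff=fdr_at,
        n_significant=int(significant.sum()),
        config=cfg,
        n_permutations_used=n_perm,
        exhaustive=exhaustive,
        fdr_curve=pd.DataFrame({"cutoff": candidates, "fdr": fdr_mono}),
    )
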