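"""Correlation and over-representation statistics.

Spearman rank-correlation matrices link the DDR pathway activity block to
the immune feature block (and DDR pathways to each other), with two-sided
p-values — a t-approximation for n >= 10, exhaustive permutation enumeration
below — and Benjamini-Hochberg q-values over the whole matrix as one family.
The proteomics-style over-representation analysis is a two-tailed Fisher's
exact test on the usual 2x2 in-set/out-of-set x foreground/background table,
plus fold-change quartile grouping of upregulated proteins.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "bh_fdr",
    "ORAResult",
    "fisher_ora",
    "fisher_ora_collection",
    "quantile_groups",
]


@dataclass
class CorrelationMatrix:
    """Aligned rho / p / q matrices (rows x columns of features)."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = (
            self.rho.stack(future_stack=True).rename("rho").reset_index()
            .rename(columns={"level_0": "row", "level_1": "column"})
        )
        long["p"] = self.p.to_numpy().ravel()
        long["q"] = self.q.to_numpy().ravel()
        return long


def _rank_columns(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, values)


def _standardize(ranks: np.ndarray) -> np.ndarray:
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norm


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all orderings of one rank vector."""
    n = len(rx)
    sx = _standardize(rx.reshape(-1, 1)).ravel()
    sy = _standardize(ry.reshape(-1, 1)).ravel()
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (sy[perms] * sx).sum(axis=1)
    hits = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
    return hits / len(perms)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho_c) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


def spearman_matrix(A: pd.DataFrame, B: pd.DataFrame) -> CorrelationMatrix:
    """Spearman rho between every column of A and every column of B.

    Both frames are samples x features and must share the same sample index
    in the same order, with at least 4 samples.  Ties get average ranks.
    Constant columns yield undefined (NaN) cells, reported as missing rather
    than zero.  q-values are BH over all defined cells jointly.
    """
    if not A.index.equals(B.index):
        raise ValueError("A and B must share the same samples in the same order")
    n = A.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples for correlation, got {n}")
    ra = _rank_columns(A.to_numpy(dtype=float))
    rb = _rank_columns(B.to_numpy(dtype=float))
    sa = _standardize(ra)
    sb = _standardize(rb)
    const_a = ~np.isfinite(sa).all(axis=0)
    const_b = ~np.isfinite(sb).all(axis=0)
    for label in A.columns[const_a]:
        logger.warning("column %r constant; correlations undefined", label)
    for label in B.columns[const_b]:
        logger.warning("column %r constant; correlations undefined", label)
    rho = np.nan_to_num(sa).T @ np.nan_to_num(sb)
    rho[const_a, :] = np.nan
    rho[:, const_b] = np.nan
    rho = np.clip(rho, -1.0, 1.0, out=rho)

    if n >= 10:
        p = _t_approx_p(rho, n)
    else:
        p = np.full_like(rho, np.nan)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                if np.isfinite(rho[i, j]):
                    p[i, j] = _exact_perm_p(ra[:, i], rb[:, j], rho[i, j])

    q = bh_fdr(p.ravel()).reshape(p.shape)
    mk = lambda m: pd.DataFrame(m, index=A.columns, columns=B.columns)
    return CorrelationMatrix(rho=mk(rho), p=mk(p), q=mk(q))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through as NaN."""
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if ((flat[ok] < 0) | (flat[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return q.reshape(p.shape)


@dataclass(frozen=True)
class ORAResult:
    """Fisher's exact over-representation result for one gene set."""

    set_name: str
    a: int  # in set, foreground
    b: int  # out of set, foreground
    c: int  # in set, background rest
    d: int  # out of set, background rest
    odds_ratio: float
    p_two_tailed: float


def fisher_ora(foreground, background, gene_set: GeneSet) -> ORAResult:
    """Two-tailed Fisher's exact test for over-representation of `gene_set`
    among `foreground` relative to `background`.

    The two-tailed p sums every hypergeometric outcome whose probability is
    at most that of the observed table.  The odds ratio is (a*d)/(b*c), with
    infinity when b*c = 0 and a*d > 0, and NaN for the fully degenerate
    0/0 case.
    """
    fg = {str(x).upper() for x in foreground}
    bg = {str(x).upper() for x in background}
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    members = set(gene_set.members) & bg
    rest = bg - fg
    a = len(members & fg)
    b = len(fg) - a
    c = len(members & rest)
    d = len(rest) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return ORAResult(set_name=gene_set.name, a=a, b=b, c=c, d=d,
                     odds_ratio=odds, p_two_tailed=float(min(p, 1.0)))


def fisher_ora_collection(
    foreground, background, collection: GeneSetCollection
) -> pd.DataFrame:
    """ORA over a whole collection, with BH q-values across its sets."""
    rows = [fisher_ora(foreground, background, s) for s in collection]
    df = pd.DataFrame(
        dict(
            set_name=[r.set_name for r in rows],
            a=[r.a for r in rows], b=[r.b for r in rows],
            c=[r.c for r in rows], d=[r.d for r in rows],
            odds_ratio=[r.odds_ratio for r in rows],
            p=[r.p_two_tailed for r in rows],
        )
    )
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def quantile_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Assign fold-change quartile groups Q1..Q4 to upregulated proteins.

    Expects columns ``protein`` and ``fold_change`` (> 0, tumor/normal).
    Proteins with fold change > 1 are split into ascending quartiles (Q4 =
    strongest upregulation); boundary ties go to the lower group via
    minimum-rank assignment.  Downregulated proteins keep an empty group.
    Adds/overwrites ``direction`` and ``quantile_group`` columns.
    """
    if "fold_change" not in table.columns:
        raise ValueError("table must have a fold_change column")
    fc = table["fold_change"].to_numpy(dtype=float)
    if (fc <= 0).any() or not np.isfinite(fc).all():
        raise ValueError("fold changes must be positive and finite")
    out = table.copy()
    out["direction"] = np.where(fc > 1.0, "up", "down")
    up = fc > 1.0
    n_up = int(up.sum())
    if n_up < 4:
        raise ValueError(f"need at least 4 upregulated proteins, got {n_up}")
    ranks = stats.rankdata(fc[up], method="min")
    groups = np.ceil(ranks * 4.0 / n_up).astype(int)
    groups = np.clip(groups, 1, 4)
    labels = np.full(len(out), "", dtype=object)
    labels[np.flatnonzero(up)] = [f"Q{g}" for g in groups]
    out["quantile_group"] = labels
    return out
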