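"""Per-sample pre-ranked gene-set enrichment.

The pipeline converts a bulk expression matrix into a samples x pathways
activity matrix: each gene is median-centered across samples, each sample's
genes are ranked by their centered value, and a weighted Kolmogorov-Smirnov
running-sum enrichment score (ES) is computed per gene set against that
ranking.  ES values are calibrated to normalized enrichment scores (NES) and
nominal p-values against a gene-label permutation null (random same-size
sets), with Benjamini-Hochberg FDR per sample across pathways.

The running-sum statistic: walking down the ranked list, a gene in the set
adds |score|^weight normalized by the summed |score|^weight over set members;
a gene outside the set subtracts 1/(N - N_hits).  The ES is the running-sum
value of maximal absolute deviation from zero.  When every member score is
zero the hit increments fall back to a uniform 1/N_hits.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, filter_gene_sets

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentScore",
    "EnrichmentParams",
    "CohortScores",
    "median_center",
    "rank_transform",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "normalize_es",
    "score_cohort",
    "cluster_matrix",
]


def median_center(expr: pd.DataFrame, mode: str = "subtract") -> pd.DataFrame:
    """Center (or scale) each gene by its median across samples.

    ``subtract`` (default) removes the per-gene median, appropriate for
    log-space data; ``divide`` divides by it (genes with median 0 are
    left unscaled, with a warning).
    """
    if expr.shape[1] < 2:
        raise ValueError("median centering needs at least 2 samples")
    med = expr.median(axis=1)
    if mode == "subtract":
        return expr.sub(med, axis=0)
    if mode == "divide":
        denom = med.replace(0.0, np.nan)
        n_zero = int((med == 0).sum())
        if n_zero:
            logger.warning("median_center(divide): %d genes have median 0, left unscaled", n_zero)
        return expr.div(denom, axis=0).fillna(expr)
    raise ValueError(f"unknown mode {mode!r}")


def rank_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene's values by centered integer ranks across samples.

    Alternative ranking metric: per gene, samples are ranked (average ties)
    and centered so the metric keeps a sign, mirroring rank-based rather than
    magnitude-based scoring.
    """
    n = expr.shape[1]
    ranks = np.apply_along_axis(rankdata, 1, expr.to_numpy())
    return pd.DataFrame(ranks - (n + 1) / 2.0, index=expr.index, columns=expr.columns)


@dataclass(frozen=True)
class RankedList:
    """A sample's genes ordered by descending ranking metric.

    Ties in the metric are broken by ascending gene symbol so the ordering
    is deterministic.
    """

    sample_id: str
    genes: np.ndarray  # ordered gene symbols
    scores: np.ndarray  # non-increasing ranking metric

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def rank_genes(centered: pd.DataFrame, sample_id: str) -> RankedList:
    """Order one sample's genes by descending centered value, symbols break ties."""
    if sample_id not in centered.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    scores = centered[sample_id].to_numpy(dtype=float)
    genes = centered.index.to_numpy(dtype=object)
    order = np.lexsort((genes, -scores))
    return RankedList(sample_id=sample_id, genes=genes[order], scores=scores[order])


class EnrichmentScore(NamedTuple):
    es: float
    running_sum: np.ndarray
    peak_index: int


def _hit_increments(weights: np.ndarray) -> np.ndarray:
    """Normalized hit increments; uniform fallback when all member scores are 0."""
    total = weights.sum()
    if total == 0:
        return np.full(len(weights), 1.0 / len(weights))
    return weights / total


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> EnrichmentScore:
    """Weighted KS running-sum enrichment score of `gene_set` in `ranked`.

    Returns the signed ES, the full running sum (one value per list
    position), and the position of maximal absolute deviation.  Requires at
    least one member in the list, and at least one non-member.
    """
    raw = gene_set.members if hasattr(gene_set, "members") else gene_set
    members = {str(g).upper() for g in raw}
    n = len(ranked)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == n:
        raise ValueError("gene set equals the gene universe; misses are undefined")
    w = np.abs(ranked.scores[hits]) ** weight
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[hits] = _hit_increments(w)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return EnrichmentScore(es=float(running[peak]), running_sum=running, peak_index=peak)


def _es_batch(abs_weighted: np.ndarray, hit_idx: np.ndarray, return_peaks: bool = False):
    """Enrichment scores for many same-size gene sets against one ranked list.

    `abs_weighted` is |score|^weight in ranked order (length N);
    `hit_idx` is (m, k) member positions.  Exploits that the running sum is
    piecewise linear between hits, so each extremum is attained either at a
    hit position or immediately before the next hit: O(m k log k) instead
    of O(m N).
    """
    n = abs_weighted.shape[0]
    m, k = hit_idx.shape
    if not (1 <= k < n):
        raise ValueError("set size must be in [1, N-1]")
    idx = np.sort(hit_idx, axis=1)
    w = abs_weighted[idx]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        denom = w.sum(axis=1, keepdims=True)
    hit_cum = np.cumsum(w / denom, axis=1)
    miss_step = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    # running sum at each hit position, and at the position just before it
    at_hit = hit_cum - (idx + 1 - i) * miss_step
    before_hit = np.concatenate(
        [np.zeros((m, 1)), hit_cum[:, :-1]], axis=1
    ) - (idx - (i - 1)) * miss_step
    # interleave (before, at) per hit so ties resolve to the earliest
    # list position, matching the full running-sum argmax
    cand = np.empty((m, 2 * k))
    cand[:, 0::2] = before_hit
    cand[:, 1::2] = at_hit
    positions = np.empty((m, 2 * k), dtype=np.intp)
    positions[:, 0::2] = idx - 1
    positions[:, 1::2] = idx
    best = np.argmax(np.abs(cand), axis=1)
    es = cand[np.arange(m), best]
    if not return_peaks:
        return es
    return es, positions[np.arange(m), best]


def _es_from_positions(abs_weighted: np.ndarray, hit_pos: np.ndarray):
    """Exact running-sum ES from member positions (cumsum path, O(N))."""
    n = abs_weighted.shape[0]
    k = len(hit_pos)
    w = abs_weighted[hit_pos]
    steps = np.full(n, -1.0 / (n - k))
    steps[hit_pos] = _hit_increments(w)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def _sample_subsets(
    rng: np.random.Generator, n: int, k: int, m: int
) -> np.ndarray:
    """(m, k) uniform random k-subsets of range(n), as index rows.

    For k far below n, draws with replacement and redraws the few rows with
    collisions; otherwise falls back to per-row sampling without
    replacement.
    """
    if n < 100 or k > n // 4:
        out = np.empty((m, k), dtype=np.intp)
        for j in range(m):
            out[j] = rng.choice(n, size=k, replace=False)
        return out
    idx = rng.integers(0, n, size=(m, k))
    while True:
        bad = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null ES distribution from random gene subsets of `set_size` (gene-label
    permutation), reproducible given the seed."""
    n = len(ranked)
    if not (1 <= set_size < n):
        raise ValueError("set_size must satisfy 1 <= set_size < N")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _sample_subsets(rng, n, set_size, n_perm)
    absw = np.abs(ranked.scores) ** weight
    return _es_batch(absw, idx)


class NormalizedScore(NamedTuple):
    nes: float
    p_nominal: float


def normalize_es(es: float, null: np.ndarray) -> NormalizedScore:
    """NES = ES divided by the mean |ES| of same-sign null values; the nominal
    p-value comes from the same-sign null tail with add-one smoothing.

    Returns (nan, nan) when the null contains no same-sign value; callers
    flag and exclude such cells rather than zero-filling them.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if es == 0.0:
        return NormalizedScore(nes=0.0, p_nominal=1.0)
    same = null[np.sign(null) == np.sign(es)]
    if same.size == 0:
        return NormalizedScore(nes=float("nan"), p_nominal=float("nan"))
    nes = es / np.mean(np.abs(same))
    p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
    return NormalizedScore(nes=float(nes), p_nominal=float(p))


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs for cohort scoring.

    weight: exponent on |score| in the hit increments (1 = classic weighted
    statistic).  n_perm: permutations per null.  min_size/max_size: set-size
    bounds after intersection with measured genes.  ranking_metric:
    ``centered`` uses the median-centered value, ``rank`` uses centered
    integer ranks across samples.  center_mode: subtract or divide the
    per-gene median.
    """

    weight: float = 1.0
    n_perm: int = 1000
    min_size: int = 5
    max_size: int = 500
    seed: int = 0
    ranking_metric: str = "centered"
    center_mode: str = "subtract"


@dataclass
class CohortScores:
    """samples x pathways NES matrix plus the long per-cell result table."""

    nes: pd.DataFrame
    results: pd.DataFrame
    params: EnrichmentParams = field(default_factory=EnrichmentParams)


def _sample_seed(root_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Per-sample seed derived from the root seed and the sample identifier,
    so results do not depend on sample order."""
    return np.random.SeedSequence([root_seed, zlib.crc32(str(sample_id).encode())])


def score_cohort(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> CohortScores:
    """Score every (sample, pathway) pair: ES, NES, nominal p and BH q.

    Null distributions are gene-label permutations, cached per (sample,
    set size).  A sample whose centered profile is all zero cannot be ranked
    meaningfully; its row is filled with NaN and flagged in the result table.
    """
    params = params or EnrichmentParams()
    surviving = filter_gene_sets(collection, expr, params.min_size, params.max_size)
    centered = median_center(expr, mode=params.center_mode)
    if params.ranking_metric == "rank":
        centered = rank_transform(centered)
    elif params.ranking_metric != "centered":
        raise ValueError(f"unknown ranking_metric {params.ranking_metric!r}")

    pathway_names = surviving.names
    records: list[dict] = []
    nes_rows: list[np.ndarray] = []
    for sample_id in expr.columns:
        ranked = rank_genes(centered, sample_id)
        if np.all(ranked.scores == 0):
            logger.warning("sample %s: degenerate (all-zero) ranking; row flagged", sample_id)
            nes_rows.append(np.full(len(pathway_names), np.nan))
            for name in pathway_names:
                records.append(
                    dict(sample=sample_id, pathway=name, es=np.nan, nes=np.nan,
                         p_nominal=np.nan, fdr_q=np.nan, n_hits=0, peak_index=-1,
                         flag="degenerate_sample")
                )
            continue
        rng = np.random.default_rng(_sample_seed(params.seed, sample_id))
        absw = np.abs(ranked.scores) ** params.weight
        pos_of = {g: i for i, g in enumerate(ranked.genes)}
        null_cache: dict[int, np.ndarray] = {}
        row = np.empty(len(pathway_names))
        sample_records = []
        for j, gene_set in enumerate(surviving):
            hit_idx = np.fromiter(
                (pos_of[g] for g in gene_set.members), dtype=np.intp, count=len(gene_set)
            )
            es_val, peak = _es_from_positions(absw, hit_idx)
            k = len(gene_set)
            if k not in null_cache:
                idx = _sample_subsets(rng, len(ranked), k, params.n_perm)
                null_cache[k] = _es_batch(absw, idx)
            nes, p = normalize_es(es_val, null_cache[k])
            if np.isnan(nes):
                logger.warning(
                    "sample %s, pathway %s: no same-sign null ES; cell undefined",
                    sample_id, gene_set.name,
                )
            row[j] = nes
            sample_records.append(
                dict(sample=sample_id, pathway=gene_set.name, es=es_val, nes=nes,
                     p_nominal=p, fdr_q=np.nan, n_hits=k, peak_index=peak,
                     flag="" if np.isfinite(nes) else "undefined_nes")
            )
        pvals = np.array([r["p_nominal"] for r in sample_records])
        ok = np.isfinite(pvals)
        if ok.any():
            q = np.full(len(pvals), np.nan)
            q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            for r, qv in zip(sample_records, q):
                r["fdr_q"] = qv
        nes_rows.append(row)
        records.extend(sample_records)

    nes = pd.DataFrame(np.vstack(nes_rows), index=expr.columns, columns=pathway_names)
    nes.index.name = "sample"
    results = pd.DataFrame.from_records(records)
    return CohortScores(nes=nes, results=results, params=params)


@dataclass
class ClusterResult:
    """Leaf orderings and merge trees from hierarchical clustering."""

    row_order: list | None = None
    col_order: list | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.row_order is not None:
            out["row_order"] = [str(x) for x in self.row_order]
            out["row_linkage"] = self.row_linkage.tolist()
        if self.col_order is not None:
            out["col_order"] = [str(x) for x in self.col_order]
            out["col_linkage"] = self.col_linkage.tolist()
        return out


def _cluster_axis(values: np.ndarray, labels, distance: str, method: str):
    if values.shape[0] < 2:
        raise ValueError("need at least 2 items on the clustered axis")
    d = pdist(values, metric=distance)
    if not np.isfinite(d).all():
        bad = np.argwhere(~np.isfinite(squareform(d)))
        i, j = bad[0]
        raise ValueError(f"non-finite distance between {labels[i]!r} and {labels[j]!r}")
    link = hierarchy.linkage(d, method=method)
    order = hierarchy.leaves_list(link)
    return [labels[i] for i in order], link


def cluster_matrix(
    matrix: pd.DataFrame,
    axis: str = "both",
    distance: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Hierarchically cluster rows and/or columns of an activity matrix.

    Undefined cells (NaN) are imputed to 0 for distance computation, with a
    log entry.  Merge-distance ties are resolved by SciPy's deterministic
    smaller-index rule, so orderings are reproducible.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows|columns|both, got {axis!r}")
    values = matrix.to_numpy(dtype=float)
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        logger.info("cluster_matrix: %d undefined cells imputed to 0 for distances", n_nan)
        values = np.nan_to_num(values, nan=0.0)
    out = ClusterResult()
    if axis in ("rows", "both"):
        out.row_order, out.row_linkage = _cluster_axis(
            values, list(matrix.index), distance, method
        )
    if axis in ("columns", "both"):
        out.col_order, out.col_linkage = _cluster_axis(
            values.T, list(matrix.columns), distance, method
        )
    return out
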