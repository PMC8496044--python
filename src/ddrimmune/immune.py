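"""Per-sample immune features: content score, immune pathway activity, and
signature-based cell-type deconvolution.

The immune content score is the mean across-sample z-score of a curated
immune-specific gene list — a scalar infiltration proxy per sample.  Cell
fractions come from regressing each sample's profile on a genes x cell-types
signature matrix, either by non-negative least squares (default,
deterministic) or by linear nu-support-vector regression over a small nu
grid with the lowest-RMSE fit retained; negative coefficients are clipped
and fractions renormalized to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .enrichment import EnrichmentParams, score_cohort
from .io import GeneSetCollection, validate_signature

logger = logging.getLogger(__name__)

__all__ = [
    "immune_content_score",
    "DeconvolutionResult",
    "deconvolve",
    "deconvolve_cohort",
    "ImmuneFeatures",
    "build_immune_features",
]

FEATURE_KINDS = ("content_score", "pathway", "cell_fraction")


def immune_content_score(expr: pd.DataFrame, immune_genes: Sequence[str]) -> pd.Series:
    """Mean across-sample z-score of the immune genes present in `expr`.

    Each immune gene is standardized across samples (population sd);
    constant genes are dropped with a warning.  The resulting scores have
    cohort mean ~0.  Raises if no immune gene is measured, and warns when
    fewer than half of the list is found.
    """
    wanted = [g.upper() for g in immune_genes]
    present = [g for g in wanted if g in expr.index]
    if not present:
        missing = ", ".join(wanted[:10])
        raise ValueError(f"no immune genes found in the expression matrix (looked for {missing} ...)")
    if len(present) < 0.5 * len(wanted):
        logger.warning(
            "only %d of %d immune genes found in the expression matrix",
            len(present), len(wanted),
        )
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d immune genes constant across samples, dropped", int((~keep).sum()))
    sub = sub.loc[keep]
    if sub.empty:
        raise ValueError("all immune genes are constant across samples; score undefined")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    score = z.mean(axis=0)
    score.name = "immune_content_score"
    return score


@dataclass(frozen=True)
class DeconvolutionResult:
    """Cell-type fractions for one sample (non-negative, summing to 1)."""

    sample_id: str
    fractions: pd.Series
    rmse: float
    method: str
    nu_selected: float | None = None

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must be non-negative and sum to 1")


def _shared_z(sample_expr: pd.Series, signature: pd.DataFrame):
    """Restrict both to shared genes and standardize with the mixture's moments.

    Because true fractions sum to one, applying the mixture's own (mean, sd)
    affinely to the signature columns preserves the linear mixing relation
    exactly, so noiseless mixtures remain exactly recoverable.
    """
    shared = signature.index.intersection(sample_expr.index)
    n_types = signature.shape[1]
    threshold = max(10, 2 * n_types)
    if len(shared) < threshold:
        raise ValueError(
            f"only {len(shared)} genes shared between sample and signature; need >= {threshold}"
        )
    m = sample_expr.loc[shared].to_numpy(dtype=float)
    s = signature.loc[shared].to_numpy(dtype=float)
    mu, sd = m.mean(), m.std()
    if sd == 0:
        raise ValueError("sample expression constant over signature genes; cannot deconvolve")
    return (m - mu) / sd, (s - mu) / sd, shared


def _check_degenerate(signature: pd.DataFrame) -> None:
    cols = signature.to_numpy().T
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.allclose(cols[i], cols[j]):
                logger.warning(
                    "signature columns %r and %r are (near-)identical; fractions may be unstable",
                    signature.columns[i], signature.columns[j],
                )
                return


def deconvolve(
    sample_expr: pd.Series,
    signature: pd.DataFrame,
    method: str = "nnls",
    nu_grid: Sequence[float] = (0.25, 0.5, 0.75),
) -> DeconvolutionResult:
    """Estimate cell-type fractions for one sample against a signature matrix."""
    validate_signature(signature)
    _check_degenerate(signature)
    mz, sz, _shared = _shared_z(sample_expr, signature)
    nu_selected: float | None = None
    if method == "nnls":
        coef, _res = nnls(sz, mz)
    elif method == "nu_svr":
        best = None
        for nu in nu_grid:
            svr = NuSVR(kernel="linear", nu=nu, C=1.0)
            svr.fit(sz, mz)
            raw = svr.coef_.ravel()
            clipped = np.clip(raw, 0.0, None)
            rmse_nu = float(np.sqrt(np.mean((sz @ clipped - mz) ** 2)))
            if best is None or rmse_nu < best[0]:
                best = (rmse_nu, clipped, nu)
        _, coef, nu_selected = best
    else:
        raise ValueError(f"unknown deconvolution method {method!r}")
    rmse = float(np.sqrt(np.mean((sz @ coef - mz) ** 2)))
    total = coef.sum()
    if total == 0:
        logger.warning(
            "sample %s: all deconvolution coefficients zero; uniform fractions returned",
            sample_expr.name,
        )
        fractions = np.full(signature.shape[1], 1.0 / signature.shape[1])
    else:
        fractions = coef / total
    return DeconvolutionResult(
        sample_id=str(sample_expr.name),
        fractions=pd.Series(fractions, index=signature.columns),
        rmse=rmse,
        method=method,
        nu_selected=nu_selected,
    )


def deconvolve_cohort(
    expr: pd.DataFrame,
    signature: pd.DataFrame,
    method: str = "nnls",
    nu_grid: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Fractions for every sample: samples x cell_types DataFrame."""
    rows = [
        deconvolve(expr[s], signature, method=method, nu_grid=nu_grid).fractions
        for s in expr.columns
    ]
    out = pd.DataFrame(rows, index=expr.columns)
    out.index.name = "sample"
    return out


@dataclass
class ImmuneFeatures:
    """samples x immune-features matrix with a kind tag per feature."""

    values: pd.DataFrame
    kinds: pd.Series  # feature -> kind in FEATURE_KINDS

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.kinds.index):
            raise ValueError("feature labels and kind tags out of sync")
        bad = set(self.kinds) - set(FEATURE_KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")

    def write_tsv(self, path) -> None:
        """TSV with a second header row tagging each feature's kind."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample\t" + "\t".join(map(str, self.values.columns)) + "\n")
            fh.write("#kind\t" + "\t".join(self.kinds) + "\n")
            for sample, row in self.values.iterrows():
                fh.write(str(sample) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def build_immune_features(
    expr: pd.DataFrame,
    immune_genes: Sequence[str],
    immune_sets: GeneSetCollection | None = None,
    signature: pd.DataFrame | None = None,
    enrichment_params: EnrichmentParams | None = None,
    deconv_method: str = "nnls",
) -> ImmuneFeatures:
    """Assemble the per-sample immune feature block: content score, immune
    pathway NES, and deconvolved cell fractions (the latter two optional)."""
    columns: list[pd.Series | pd.DataFrame] = []
    kinds: list[tuple[str, str]] = []

    score = immune_content_score(expr, immune_genes)
    columns.append(score)
    kinds.append((str(score.name), "content_score"))

    if immune_sets is not None and len(immune_sets) > 0:
        scores = score_cohort(expr, immune_sets, enrichment_params)
        columns.append(scores.nes)
        kinds.extend((str(c), "pathway") for c in scores.nes.columns)

    if signature is not None:
        fracs = deconvolve_cohort(expr, signature, method=deconv_method)
        columns.append(fracs)
        kinds.extend((str(c), "cell_fraction") for c in fracs.columns)

    values = pd.concat(columns, axis=1)
    values.index.name = "sample"
    constant = values.columns[values.nunique(dropna=True) <= 1]
    for c in constant:
        logger.warning("immune feature %r is constant across samples; correlations undefined", c)
    kind_series = pd.Series(dict(kinds)).reindex(values.columns)
    return ImmuneFeatures(values=values, kinds=kind_series)
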