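"""Synthetic bulk-expression cohorts with planted pathway and immune structure.

The generator emulates the statistical structure the analysis assumes:

* each planted pathway has a per-sample latent activity (standard normal)
  that shifts its member genes' log2 expression;
* an immune-infiltration latent scales immune-gene expression and tilts the
  per-sample cell-type mixture toward immune cell types;
* the designated pathway latent and the immune latent are drawn from a
  Gaussian copula whose Pearson parameter 2*sin(pi*rho/6) targets a chosen
  Spearman correlation (typically negative);
* cell-type marker genes are linear mixtures of a block-structured signature
  matrix weighted by the sample's Dirichlet cell fractions.

Expression is simulated directly in log2 space with Gaussian noise; the
analysis is rank-based, so count-level realism adds nothing testable.  A
count mode (Poisson sampling of 2^x then log2(x+1)) is available as a flag.
Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .io import (
    GeneSet,
    GeneSetCollection,
    write_expression,
    write_gene_list,
    write_gmt,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_signature",
    "generate_mixture_set",
    "generate_protein_table",
    "write_bundle",
]

DEFAULT_CELL_TYPES = ("T_CELL", "B_CELL", "NK_CELL", "MYELOID", "STROMAL")
#: cell types counted as immune when tilting fractions (all but the stromal one)
NON_IMMUNE_TYPES = ("STROMAL",)


@dataclass(frozen=True)
class CohortConfig:
    """Conditions for a synthetic tumor cohort.

    effect_size is the log2 shift per unit latent activity; noise_sd the
    per-gene Gaussian noise in log2 units.  target_rho is the Spearman
    correlation planted between the designated pathway's latent and the
    immune latent.
    """

    n_samples: int = 80
    n_genes: int = 12000
    designated_pathway: str = "HOMOLOGOUS_DNA_PAIRING_AND_STRAND_EXCHANGE"
    target_rho: float = -0.6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_cell_types: int = 5
    markers_per_type: int = 8
    immune_gene_count: int = 60
    fraction_tilt: float = 0.8
    baseline_log_mean: float = 1.2
    baseline_log_sd: float = 0.4
    count_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if not -1.0 < self.target_rho < 1.0:
            raise ValueError("target_rho must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 2 <= self.n_cell_types <= len(DEFAULT_CELL_TYPES):
            raise ValueError(f"n_cell_types must be in [2, {len(DEFAULT_CELL_TYPES)}]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expr: pd.DataFrame
    truth_latents: pd.DataFrame  # samples x (pathway names + 'immune')
    truth_fractions: pd.DataFrame  # samples x cell types
    immune_genes: list[str]
    signature: pd.DataFrame
    collection: GeneSetCollection
    immune_sets: GeneSetCollection
    realized_rho: float
    config: CohortConfig = field(repr=False, default=None)


def _copula_pair(rng: np.random.Generator, n: int, target_rho: float):
    """Bivariate normals whose rank correlation targets `target_rho`."""
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    return z[:, 0], z[:, 1]


def generate_signature(
    cell_types: Sequence[str],
    markers_per_type: int,
    baseline: np.ndarray,
    rng: np.random.Generator,
    marker_high: float = 4.0,
) -> pd.DataFrame:
    """Block-structured genes x cell-types signature: each cell type's marker
    genes sit `marker_high` log2 units above a shared baseline."""
    genes = [
        f"MK_{ct}_{i + 1}" for ct in cell_types for i in range(markers_per_type)
    ]
    values = np.tile(baseline[:, None], (1, len(cell_types)))
    for c, _ct in enumerate(cell_types):
        block = slice(c * markers_per_type, (c + 1) * markers_per_type)
        values[block, c] += marker_high + rng.normal(0.0, 0.3, markers_per_type)
    values += rng.normal(0.0, 0.1, values.shape)
    values = np.clip(values, 0.0, None)
    return pd.DataFrame(values, index=genes, columns=list(cell_types))


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort under `config`.

    Gene universe = planted pathway genes + immune-responsive genes +
    cell-type marker genes + inert filler genes up to n_genes.  A gene
    belonging to several planted pathways is driven by one primary pathway
    (the designated pathway if it contains the gene, else the first pathway
    in collection order), so overlapping sets intercorrelate through shared
    members without diluting the designated pathway's own latent.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    collection = datasets.load_ddr_collection()
    immune_sets = datasets.load_immune_collection()
    if config.designated_pathway not in collection.names:
        raise ValueError(f"designated pathway {config.designated_pathway!r} not in collection")

    immune_genes = datasets.load_immune_genes()
    if config.immune_gene_count <= len(immune_genes):
        immune_genes = immune_genes[: config.immune_gene_count]
    else:
        immune_genes = immune_genes + [
            f"IMMG{i:03d}" for i in range(config.immune_gene_count - len(immune_genes))
        ]

    cell_types = list(DEFAULT_CELL_TYPES[: config.n_cell_types - 1]) + [
        DEFAULT_CELL_TYPES[-1]
    ]
    # primary pathway per gene: designated first, then collection order
    primary: dict[str, str] = {}
    for g in collection[config.designated_pathway].members:
        primary[g] = config.designated_pathway
    for s in collection:
        for g in s.members:
            primary.setdefault(g, s.name)

    immune_strength: dict[str, float] = {}
    for s in immune_sets:
        for g in s.members:
            immune_strength[g] = 0.8
    for g in immune_genes:
        immune_strength[g] = 1.0

    baseline_for = lambda size: rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size
    )
    marker_baseline = baseline_for(config.markers_per_type * len(cell_types))
    signature = generate_signature(
        cell_types, config.markers_per_type, marker_baseline, rng
    )

    universe: list[str] = []
    seen: set[str] = set()
    for g in [*primary, *immune_strength, *signature.index]:
        if g not in seen:
            universe.append(g)
            seen.add(g)
    n_structured = len(universe)
    if n_structured > config.n_genes:
        raise ValueError(
            f"structured genes ({n_structured}) exceed n_genes ({config.n_genes})"
        )
    universe += [f"GENE{i:05d}" for i in range(config.n_genes - n_structured)]

    n, m = config.n_samples, config.n_genes
    samples = [f"S{i + 1:03d}" for i in range(n)]

    designated_latent, immune_latent = _copula_pair(rng, n, config.target_rho)
    latents = {name: rng.standard_normal(n) for name in collection.names}
    latents[config.designated_pathway] = designated_latent

    # Dirichlet fractions tilted so the immune share rises with the latent
    alpha = np.full((n, len(cell_types)), 1.0)
    for c, ct in enumerate(cell_types):
        sign = -1.0 if ct in NON_IMMUNE_TYPES else 1.0
        alpha[:, c] = np.exp(sign * config.fraction_tilt * immune_latent)
    gammas = rng.gamma(shape=alpha)
    fractions = gammas / gammas.sum(axis=1, keepdims=True)

    baseline = baseline_for(m)
    expr = np.tile(baseline[:, None], (1, n))
    marker_pos = {g: i for i, g in enumerate(signature.index)}
    sig_values = signature.to_numpy()
    mixed = sig_values @ fractions.T  # markers x samples
    for gi, g in enumerate(universe):
        if g in primary:
            expr[gi] += config.effect_size * latents[primary[g]]
        if g in immune_strength:
            expr[gi] += config.effect_size * immune_strength[g] * immune_latent
        if g in marker_pos:
            expr[gi] = mixed[marker_pos[g]]
    expr += rng.normal(0.0, config.noise_sd, expr.shape)

    if config.count_mode:
        counts = rng.poisson(np.clip(2.0 ** expr, 0.0, 1e9))
        expr = np.log2(counts + 1.0)

    expr_df = pd.DataFrame(expr, index=universe, columns=samples)
    truth_latents = pd.DataFrame(
        {**{k: v for k, v in latents.items()}, "immune": immune_latent}, index=samples
    )
    truth_fractions = pd.DataFrame(fractions, index=samples, columns=cell_types)
    realized_rho = float(stats.spearmanr(designated_latent, immune_latent).statistic)

    return SyntheticCohort(
        expr=expr_df,
        truth_latents=truth_latents,
        truth_fractions=truth_fractions,
        immune_genes=immune_genes,
        signature=signature,
        collection=collection,
        immune_sets=immune_sets,
        realized_rho=realized_rho,
        config=config,
    )


def generate_mixture_set(
    signature: pd.DataFrame,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulated bulk mixtures of the signature's cell types.

    Fractions are Dirichlet(1, ..., 1); each mixture column is
    signature @ fractions plus Gaussian noise.  Returns (genes x samples
    expression, samples x cell-types truth fractions).
    """
    rng = np.random.default_rng(seed)
    k = signature.shape[1]
    fractions = rng.dirichlet(np.ones(k), size=n_samples)
    mix = signature.to_numpy() @ fractions.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, mix.shape)
    samples = [f"M{i + 1:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(mix, index=signature.index, columns=samples)
    truth = pd.DataFrame(fractions, index=samples, columns=signature.columns)
    return expr, truth


def generate_protein_table(
    n_proteins: int = 500,
    frac_up: float = 0.4,
    seed: int = 0,
    planted_size: int = 40,
    planted_odds: float = 5.0,
):
    """Synthetic protein fold-change table with one planted enriched set.

    Members of the planted set are upregulated with boosted odds
    (`planted_odds` vs the background odds implied by `frac_up`), so a
    Fisher over-representation test should flag the set.  Returns
    (table, planted GeneSet, truth dict).
    """
    if not 0.0 < frac_up < 1.0:
        raise ValueError("frac_up must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = [f"PROT{i + 1:04d}" for i in range(n_proteins)]
    planted = list(rng.choice(ids, size=min(planted_size, n_proteins), replace=False))
    odds_bg = frac_up / (1.0 - frac_up)
    p_planted = planted_odds * odds_bg / (1.0 + planted_odds * odds_bg)
    planted_set = set(planted)
    p_up = np.where([i in planted_set for i in ids], p_planted, frac_up)
    up = rng.random(n_proteins) < p_up
    log2fc = np.where(
        up,
        np.abs(rng.normal(1.2, 0.8, n_proteins)) + 0.05,
        -np.abs(rng.normal(1.2, 0.8, n_proteins)) - 0.05,
    )
    table = pd.DataFrame(
        dict(protein=ids, fold_change=2.0 ** log2fc)
    )
    table["direction"] = np.where(up, "up", "down")
    gene_set = (
        GeneSet("PLANTED_SET", "synthetic planted enriched set", tuple(planted))
        if planted
        else None
    )
    truth = dict(planted_members=planted, p_up_planted=float(p_planted), frac_up=frac_up)
    return table, gene_set, truth


def write_bundle(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the complete input bundle for a pipeline run: expression TSV,
    DDR and immune GMTs, immune gene list, signature TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "ddr_gmt": outdir / "ddr.gmt",
        "immune_gmt": outdir / "immune.gmt",
        "immune_genes": outdir / "immune_genes.txt",
        "signature": outdir / "signature.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expr, paths["expression"])
    write_gmt(cohort.collection, paths["ddr_gmt"])
    write_gmt(cohort.immune_sets, paths["immune_gmt"])
    write_gene_list(cohort.immune_genes, paths["immune_genes"])
    write_expression(cohort.signature, paths["signature"])
    truth = dict(
        realized_rho=cohort.realized_rho,
        designated_pathway=cohort.config.designated_pathway,
        target_rho=cohort.config.target_rho,
        latents={c: cohort.truth_latents[c].tolist() for c in cohort.truth_latents},
        fractions={c: cohort.truth_fractions[c].tolist() for c in cohort.truth_fractions},
        samples=list(cohort.expr.columns),
    )
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
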