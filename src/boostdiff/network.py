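"""Differential network assembly.

Fits one boosted ensemble per target gene across a pair of expression
matrices, extracts regulator importances, filters targets by the
prediction-error difference, and merges the two sub-analyses (each
condition in turn taken as the target condition) into the final directed
differential network.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .boosting import (
    BoostedEnsemble,
    BoostParams,
    fit_boosted_ensemble,
    fit_cart_forest,
    mean_error_difference,
)
from .difftree import BASELINE, TARGET, LearningSet, iter_nodes

__all__ = [
    "GeneModelResult",
    "EdgeRecord",
    "RunConfig",
    "SUBANALYSIS_A",
    "SUBANALYSIS_B",
    "scale_targets_unit_variance",
    "compute_vim",
    "run_subanalysis",
    "filter_by_error_percentile",
    "build_differential_network",
    "run_pipeline",
    "differential_genie3_baseline",
]

logger = logging.getLogger(__name__)

SUBANALYSIS_A = "condition_A_target"
SUBANALYSIS_B = "condition_B_target"


@dataclass
class GeneModelResult:
    """Per-target-gene outcome of one sub-analysis."""

    target_gene: str
    importances: Dict[str, float]
    error_difference: float
    n_fitted: int


@dataclass(frozen=True)
class EdgeRecord:
    """One directed edge of a differential network."""

    regulator: str
    target: str
    weight: float
    subanalysis: str


@dataclass
class RunConfig:
    """Configuration of a full differential-network run.

    ``error_percentile`` is the lower-tail percentile of the
    prediction-error-difference distribution used to keep the most
    differentially predicted target genes (default 3).
    ``regulators`` restricts the candidate-regulator universe (e.g. to a
    transcription-factor list); ``"all"`` uses every gene.
    """

    boost_params: BoostParams = field(default_factory=BoostParams)
    regulators: Union[str, Sequence[str]] = "all"
    error_percentile: float = 3.0
    top_k_per_subanalysis: int = 500
    rng_seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.error_percentile <= 100.0:
            raise ValueError("error_percentile must be in (0, 100]")
        if self.top_k_per_subanalysis < 1:
            raise ValueError("top_k_per_subanalysis must be >= 1")


# ---------------------------------------------------------------------------
# Scaling and importances
# ---------------------------------------------------------------------------

def scale_targets_unit_variance(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale every gene row to unit sample variance (means untouched).

    Scaling the response removes the edge-ranking bias toward highly
    variable target genes.  Zero-variance genes are dropped with a warning:
    they admit no regression target.
    """
    sd = expr.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "dropping %d zero-variance gene(s): %s",
            int(zero.sum()),
            ", ".join(expr.index[zero][:10]),
        )
        expr = expr.loc[~zero]
        sd = sd[~zero]
    return expr.div(sd, axis=0)


def compute_vim(ens: BoostedEnsemble) -> Dict[str, float]:
    """Variable importance of every regulator in a fitted ensemble.

    ``VIM(g') = sum_m alpha_m * sum_{nodes split on g'} VarRed_target`` —
    only the target-condition variance reduction counts, weighted by the
    boosting tree weight.  Regulators never used as a split have VIM 0.
    """
    if ens.n_fitted == 0:
        raise ValueError("cannot compute importances of an empty ensemble")
    vim = np.zeros(len(ens.regulator_ids))
    for alpha, tree in zip(ens.alphas, ens.trees):
        for node in iter_nodes(tree):
            if not node.is_leaf:
                vim[node.split.feature_index] += alpha * node.split.varred_target
    return dict(zip(ens.regulator_ids, vim.tolist()))


# ---------------------------------------------------------------------------
# Per-gene fitting
# ---------------------------------------------------------------------------

def _gene_seed(base_seed: int, gene: str, stream: int) -> int:
    """Stable per-gene RNG seed, independent of gene order in the matrix."""
    digest = zlib.crc32(gene.encode("utf-8"))
    ss = np.random.SeedSequence([base_seed, digest, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def _resolve_regulators(
    expr: pd.DataFrame, regulators: Union[str, Sequence[str]]
) -> List[str]:
    # canonical (sorted) order keeps results invariant to matrix row order
    if isinstance(regulators, str) and regulators == "all":
        return sorted(expr.index)
    known = sorted(set(r for r in regulators if r in expr.index))
    unknown = sorted(set(regulators) - set(expr.index))
    if unknown:
        logger.warning(
            "dropping %d unknown regulator id(s): %s",
            len(unknown),
            ", ".join(unknown[:10]),
        )
    if not known:
        raise ValueError("no known regulator identifiers remain")
    return known


def _fit_one_gene(
    gene: str,
    regs: List[str],
    design_t: np.ndarray,
    design_b: np.ndarray,
    resp_t: np.ndarray,
    resp_b: np.ndarray,
    boost_params: BoostParams,
    seed: int,
) -> GeneModelResult:
    params = replace(boost_params, rng_seed=seed, tree_params=boost_params.tree_params)
    ls_t = LearningSet(design_t, resp_t, regs, TARGET)
    ls_b = LearningSet(design_b, resp_b, regs, BASELINE)
    ens = fit_boosted_ensemble(ls_t, ls_b, params, target_gene=gene)
    if ens.n_fitted == 0:
        return GeneModelResult(gene, {}, np.nan, 0)
    return GeneModelResult(
        target_gene=gene,
        importances=compute_vim(ens),
        error_difference=mean_error_difference(ens, ls_t, ls_b),
        n_fitted=ens.n_fitted,
    )


def run_subanalysis(
    expr_target_cond: pd.DataFrame,
    expr_baseline_cond: pd.DataFrame,
    config: RunConfig,
    seed_stream: int = 0,
) -> List[GeneModelResult]:
    """Fit one boosted differential ensemble per target gene.

    Responses are the unit-variance-scaled expression of the target gene in
    each condition; predictor columns are used unscaled.  Each gene gets an
    RNG stream derived from ``config.rng_seed`` and a hash of its
    identifier, so results do not depend on gene order or parallelism.
    """
    if set(expr_target_cond.index) != set(expr_baseline_cond.index):
        only_t = sorted(set(expr_target_cond.index) - set(expr_baseline_cond.index))
        only_b = sorted(set(expr_baseline_cond.index) - set(expr_target_cond.index))
        raise ValueError(
            f"gene sets differ between conditions: only in target {only_t[:5]}, "
            f"only in baseline {only_b[:5]}"
        )
    if expr_target_cond.shape[1] < 2 or expr_baseline_cond.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")
    expr_b = expr_baseline_cond.loc[expr_target_cond.index]
    # response scaling uses the pooled (cross-condition) standard deviation:
    # a shared factor removes the bias toward highly variable target genes
    # while keeping prediction errors comparable between conditions, which
    # the error-difference filter depends on
    pooled_sd = pd.concat([expr_target_cond, expr_b], axis=1).std(axis=1, ddof=1)
    keep = pooled_sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance target gene(s)", int((~keep).sum()))
    scaled_t = expr_target_cond.loc[keep].div(pooled_sd[keep], axis=0)
    scaled_b = expr_b.loc[keep].div(pooled_sd[keep], axis=0)
    targets = [g for g in expr_target_cond.index if keep.get(g, False)]
    universe = _resolve_regulators(expr_target_cond, config.regulators)

    tasks = []
    for gene in targets:
        regs = [r for r in universe if r != gene]
        if not regs:
            continue
        tasks.append(
            delayed(_fit_one_gene)(
                gene,
                regs,
                expr_target_cond.loc[regs].to_numpy().T,
                expr_b.loc[regs].to_numpy().T,
                scaled_t.loc[gene].to_numpy(),
                scaled_b.loc[gene].to_numpy(),
                config.boost_params,
                _gene_seed(config.rng_seed, gene, seed_stream),
            )
        )
    results = Parallel(n_jobs=config.n_jobs)(tasks)
    n_skipped = sum(r.n_fitted == 0 for r in results)
    if n_skipped:
        logger.info("%d of %d target genes yielded no usable ensemble", n_skipped, len(results))
    return list(results)


# ---------------------------------------------------------------------------
# Filtering, ranking, merging
# ---------------------------------------------------------------------------

def filter_by_error_percentile(
    results: Sequence[GeneModelResult],
    percentile: float,
) -> List[GeneModelResult]:
    """Keep target genes in the lower tail of the error-difference distribution.

    Retains results whose ``error_difference`` is <= the given percentile of
    the empirical distribution (computed over fitted genes only): the genes
    whose expression the ensemble predicts best in the target condition
    relative to the baseline.  With tied values at the threshold, every tied
    gene is retained (the <= convention).
    """
    fitted = [r for r in results if r.n_fitted > 0]
    if not fitted:
        logger.warning("no fitted gene models to filter")
        return []
    errs = np.array([r.error_difference for r in fitted])
    threshold = np.percentile(errs, percentile)
    kept = [r for r in fitted if r.error_difference <= threshold]
    logger.info(
        "error-difference filter at percentile %g (threshold %.4g): kept %d / %d genes",
        percentile,
        threshold,
        len(kept),
        len(fitted),
    )
    return kept


def _ranked_edges(
    results: Sequence[GeneModelResult], tag: str, top_k: int
) -> List[EdgeRecord]:
    edges = [
        EdgeRecord(reg, r.target_gene, w, tag)
        for r in results
        for reg, w in r.importances.items()
        if w > 0.0
    ]
    edges.sort(key=lambda e: (-e.weight, e.regulator, e.target))
    return edges[:top_k]


def build_differential_network(
    results_A: Sequence[GeneModelResult],
    results_B: Sequence[GeneModelResult],
    config: RunConfig,
) -> List[EdgeRecord]:
    """Merge the top edges of the two (already filtered) sub-analyses.

    Within each sub-analysis, edges are ranked by importance (ties broken
    lexicographically by regulator then target) and the top
    ``top_k_per_subanalysis`` are kept.  An edge appearing in both
    sub-analyses is kept twice, distinguished by its tag.
    """
    k = config.top_k_per_subanalysis
    return _ranked_edges(results_A, SUBANALYSIS_A, k) + _ranked_edges(
        results_B, SUBANALYSIS_B, k
    )


def run_pipeline(
    expr_A: pd.DataFrame,
    expr_B: pd.DataFrame,
    config: RunConfig,
) -> List[EdgeRecord]:
    """Full differential-network inference on a pair of condition matrices.

    Runs the two sub-analyses (condition A as target vs B as baseline, then
    the roles reversed), filters each by the error-difference percentile,
    and merges the top edges.
    """
    results_A = run_subanalysis(expr_A, expr_B, config, seed_stream=0)
    results_B = run_subanalysis(expr_B, expr_A, config, seed_stream=1)
    kept_A = filter_by_error_percentile(results_A, config.error_percentile)
    kept_B = filter_by_error_percentile(results_B, config.error_percentile)
    return build_differential_network(kept_A, kept_B, config)


# ---------------------------------------------------------------------------
# Differential-GENIE3 baseline
# ---------------------------------------------------------------------------

def _condition_importances(
    expr: pd.DataFrame,
    universe: List[str],
    config: RunConfig,
) -> Dict[str, Dict[str, float]]:
    """GENIE3-style importances from a bagged variance-reduction forest."""
    scaled = scale_targets_unit_variance(expr)
    out: Dict[str, Dict[str, float]] = {}
    for gene in expr.index:
        if gene not in scaled.index:
            continue
        regs = [r for r in universe if r != gene]
        if not regs:
            continue
        ls = LearningSet(expr.loc[regs].to_numpy().T, scaled.loc[gene].to_numpy(), regs)
        ens = fit_cart_forest(
            ls,
            config.boost_params.n_estimators,
            config.boost_params.tree_params,
            rng_seed=_gene_seed(config.rng_seed, gene, 2),
            target_gene=gene,
        )
        out[gene] = compute_vim(ens)
    return out


def differential_genie3_baseline(
    expr_A: pd.DataFrame,
    expr_B: pd.DataFrame,
    config: RunConfig,
) -> List[EdgeRecord]:
    """Edge weight subtraction between per-condition static forests.

    Fits a standard variance-reduction tree ensemble separately per
    condition and ranks edges by the weight difference A-B (tagged as the
    A-target sub-analysis) and B-A (the reverse), taking the top
    ``top_k_per_subanalysis`` of each.  The per-gene RNG seed is shared
    between the two condition fits, so identical inputs give exactly zero
    differences.
    """
    if set(expr_A.index) != set(expr_B.index):
        raise ValueError("gene sets differ between conditions")
    universe = _resolve_regulators(expr_A, config.regulators)
    w_A = _condition_importances(expr_A, universe, config)
    w_B = _condition_importances(expr_B.loc[expr_A.index], universe, config)
    k = config.top_k_per_subanalysis
    edges: List[EdgeRecord] = []
    for tag, first, second in ((SUBANALYSIS_A, w_A, w_B), (SUBANALYSIS_B, w_B, w_A)):
        diffs = [
            EdgeRecord(reg, gene, first[gene][reg] - second.get(gene, {}).get(reg, 0.0), tag)
            for gene in first
            for reg in first[gene]
        ]
        diffs.sort(key=lambda e: (-e.weight, e.regulator, e.target))
        edges.extend(diffs[:k])
    return edges
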