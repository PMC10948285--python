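"""Differential regression trees.

A differential tree is a binary regression tree grown jointly on two
expression datasets — a *target* condition (e.g. disease) and a *baseline*
condition (e.g. control) — for a single target gene.  Instead of the usual
variance-reduction impurity criterion, splits are chosen by the
*differential variance improvement* (DVI):

    DVI(g') = max_tau VarRed(g', tau, S_target) - max_tau VarRed(g', tau, S_baseline)

where ``VarRed`` is the weighted decrease in mean squared deviation of the
target gene's expression obtained by thresholding candidate regulator ``g'``
at ``tau``, and the two maxima are taken independently over each condition's
own samples.  A split gene with a large positive DVI is much more predictive
of the target gene in the target condition than in the baseline condition —
exactly the signature of a condition-specific regulatory dependency.

Each internal node keeps two thresholds, one per condition, so that both
conditions' samples are partitioned on their own expression scale.  Using a
single shared threshold would skew the split: one side would fill with
target-condition samples and the other with baseline samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LearningSet",
    "SplitResult",
    "DiffTreeNode",
    "TreeParams",
    "mse_from_mean",
    "variance_reduction",
    "best_threshold",
    "compute_dvi",
    "grow_tree",
    "predict_target",
]

TARGET = "target"
BASELINE = "baseline"


@dataclass
class LearningSet:
    """One condition's regression problem for a single target gene.

    Parameters
    ----------
    design
        Samples x regulators matrix of candidate-regulator expression.
    response
        Target-gene expression, one value per sample (row of ``design``).
    regulator_ids
        Identifiers for the design columns, excluding the target gene.
    condition_label
        ``"target"`` or ``"baseline"``.
    """

    design: np.ndarray
    response: np.ndarray
    regulator_ids: Sequence[str]
    condition_label: str = TARGET

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if self.design.ndim != 2:
            raise ValueError("design must be a 2-D samples x regulators matrix")
        if self.design.shape[0] != self.response.shape[0]:
            raise ValueError(
                f"design has {self.design.shape[0]} rows but response has "
                f"{self.response.shape[0]} values"
            )
        if len(set(self.regulator_ids)) != len(self.regulator_ids):
            raise ValueError("regulator_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.design.shape[1]

    def subset(self, rows: np.ndarray) -> "LearningSet":
        """Learning set restricted to (or resampled at) the given rows."""
        return LearningSet(
            self.design[rows], self.response[rows], self.regulator_ids, self.condition_label
        )


@dataclass
class SplitResult:
    """Outcome of evaluating one candidate split feature at a node."""

    feature_index: int
    tau_target: float
    tau_baseline: float
    varred_target: float
    varred_baseline: float
    dvi: float


@dataclass
class DiffTreeNode:
    """Node of a differential tree.

    Internal nodes carry a :class:`SplitResult` with ``dvi > 0`` and two
    children; the target-condition samples are partitioned by
    ``split.tau_target`` and the baseline samples by ``split.tau_baseline``.
    Leaves carry the condition-wise mean responses of the samples that
    reached them (``leaf_prediction_baseline`` is ``None`` when no baseline
    sample reached the leaf).
    """

    samples_target: np.ndarray
    samples_baseline: np.ndarray
    split: Optional[SplitResult] = None
    left: Optional["DiffTreeNode"] = None
    right: Optional["DiffTreeNode"] = None
    leaf_prediction_target: Optional[float] = None
    leaf_prediction_baseline: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class TreeParams:
    """Differential-tree growth hyperparameters.

    ``max_depth`` defaults to 2: shallow differential trees (stumps and near
    stumps) keep the variable-importance measure interpretable, because each
    node already combines two independent thresholds.
    ``n_candidate_features`` is the number of regulators sampled per node
    (random-forest style).  The default ``None`` considers every candidate
    regulator at every node: ensemble diversity then comes entirely from the
    paired bootstraps, and the split search never misses a genuinely
    differential regulator in favour of a correlated proxy.  Subsampling
    (e.g. ``ceil(sqrt(p))``) trades that guarantee for extra decorrelation
    and speed on large regulator sets.
    """

    max_depth: int = 2
    min_samples_per_condition: int = 2
    n_candidate_features: Optional[int] = None
    rng_seed: int = 0

    def resolve_n_features(self, n_regulators: int) -> int:
        if self.n_candidate_features is None:
            return n_regulators
        return min(self.n_candidate_features, n_regulators)


# ---------------------------------------------------------------------------
# Split criterion
# ---------------------------------------------------------------------------

def mse_from_mean(values: np.ndarray) -> float:
    """Mean squared deviation from the sample mean (population form, /n).

    The population divisor makes the weighted impurity decomposition exact,
    so variance reduction is guaranteed nonnegative.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("mse_from_mean of an empty vector is undefined")
    return float(np.mean((values - values.mean()) ** 2))


def variance_reduction(
    feature: np.ndarray,
    response: np.ndarray,
    sample_set: np.ndarray,
    tau: float,
) -> float:
    """Impurity decrease of splitting ``sample_set`` at ``feature <= tau``.

    Returns ``MSE(y[S]) - |S_L|/|S| MSE(y[S_L]) - |S_R|/|S| MSE(y[S_R])``.
    An empty side contributes a reduction of 0 by convention (no useful
    split), so the value is defined for every threshold.
    """
    sample_set = np.asarray(sample_set, dtype=np.intp)
    if sample_set.size == 0:
        raise ValueError("variance_reduction over an empty sample set")
    f = np.asarray(feature, dtype=np.float64)[sample_set]
    y = np.asarray(response, dtype=np.float64)[sample_set]
    left = f <= tau
    if not left.any() or left.all():
        return 0.0
    n = y.size
    n_l = int(left.sum())
    red = (
        mse_from_mean(y)
        - n_l / n * mse_from_mean(y[left])
        - (n - n_l) / n * mse_from_mean(y[~left])
    )
    return max(red, 0.0)


def _threshold_scan(f: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Variance reduction at every candidate threshold, vectorized.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values.  Returns ``(taus, varreds)`` in increasing tau order
    (both empty when fewer than two distinct feature values exist).
    """
    n = f.size
    if n < 2:
        return np.empty(0), np.empty(0)
    order = np.argsort(f, kind="stable")
    fs = f[order]
    ys = y[order] - y.mean()  # centering improves conditioning; invariant
    distinct = np.flatnonzero(fs[1:] != fs[:-1]) + 1  # left-block sizes
    if distinct.size == 0:
        return np.empty(0), np.empty(0)
    c1 = np.cumsum(ys)
    c2 = np.cumsum(ys * ys)
    tot1, tot2 = c1[-1], c2[-1]
    n_l = distinct.astype(np.float64)
    n_r = n - n_l
    s1_l = c1[distinct - 1]
    s2_l = c2[distinct - 1]
    mse_tot = tot2 / n - (tot1 / n) ** 2
    mse_l = s2_l / n_l - (s1_l / n_l) ** 2
    mse_r = (tot2 - s2_l) / n_r - ((tot1 - s1_l) / n_r) ** 2
    varred = mse_tot - (n_l / n) * mse_l - (n_r / n) * mse_r
    taus = (fs[distinct - 1] + fs[distinct]) / 2.0
    return taus, np.maximum(varred, 0.0)


def _scan_all_features(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best threshold and variance reduction for every feature at once.

    Vectorized counterpart of :func:`best_threshold` over the columns of
    ``F`` (node samples x features).  Returns ``(taus, varreds)`` of length
    ``n_features``; features with no valid split get ``(nan, 0.0)``.
    Numerically identical to the per-feature scan: same centered prefix
    sums, same smallest-tau tie-break.
    """
    n, p = F.shape
    taus = np.full(p, np.nan)
    varreds = np.zeros(p)
    if n < 2:
        return taus, varreds
    order = np.argsort(F, axis=0, kind="stable")
    Fs = np.take_along_axis(F, order, axis=0)
    Ys = (y - y.mean())[order]
    c1 = np.cumsum(Ys, axis=0)
    c2 = np.cumsum(Ys * Ys, axis=0)
    tot1, tot2 = c1[-1], c2[-1]
    n_l = np.arange(1, n, dtype=np.float64)[:, None]
    n_r = n - n_l
    s1_l, s2_l = c1[:-1], c2[:-1]
    mse_tot = tot2 / n - (tot1 / n) ** 2
    mse_l = s2_l / n_l - (s1_l / n_l) ** 2
    mse_r = (tot2 - s2_l) / n_r - ((tot1 - s1_l) / n_r) ** 2
    varred = mse_tot - (n_l / n) * mse_l - (n_r / n) * mse_r
    valid = Fs[1:] != Fs[:-1]
    varred = np.where(valid, np.maximum(varred, 0.0), -1.0)
    best = np.argmax(varred, axis=0)  # first max = smallest tau on ties
    cols = np.arange(p)
    best_vr = varred[best, cols]
    has_split = valid.any(axis=0)
    varreds[has_split] = np.maximum(best_vr[has_split], 0.0)
    mid = (Fs[best, cols] + Fs[best + 1, cols]) / 2.0
    taus[has_split] = mid[has_split]
    return taus, varreds


def best_threshold(
    feature: np.ndarray,
    response: np.ndarray,
    sample_set: np.ndarray,
) -> tuple[Optional[float], float]:
    """Threshold maximizing the variance reduction over ``sample_set``.

    Ties are broken toward the smallest tau.  Returns ``(None, 0.0)`` when
    no valid split exists (fewer than two samples or all feature values
    identical).
    """
    sample_set = np.asarray(sample_set, dtype=np.intp)
    f = np.asarray(feature, dtype=np.float64)[sample_set]
    y = np.asarray(response, dtype=np.float64)[sample_set]
    taus, varreds = _threshold_scan(f, y)
    if taus.size == 0:
        return None, 0.0
    i = int(np.argmax(varreds))  # first max = smallest tau on ties
    return float(taus[i]), float(varreds[i])


def compute_dvi(
    feature_index: int,
    ls_target: LearningSet,
    ls_baseline: LearningSet,
    samples_target: np.ndarray,
    samples_baseline: np.ndarray,
) -> SplitResult:
    """Evaluate one candidate split feature at a node.

    The two per-condition maxima are optimized independently, each over its
    own condition's node samples.  When the baseline side admits no
    informative split (``varred_baseline == 0``, including degenerate
    cases), the baseline routing threshold falls back to the target
    threshold, so baseline samples follow the target partition.
    """
    tau_t, vr_t = best_threshold(
        ls_target.design[:, feature_index], ls_target.response, samples_target
    )
    if samples_baseline.size >= 2:
        tau_b, vr_b = best_threshold(
            ls_baseline.design[:, feature_index], ls_baseline.response, samples_baseline
        )
    else:
        tau_b, vr_b = None, 0.0
    if vr_b == 0.0 or tau_b is None:
        tau_b = tau_t
        vr_b = 0.0
    return SplitResult(
        feature_index=int(feature_index),
        tau_target=np.nan if tau_t is None else tau_t,
        tau_baseline=np.nan if tau_b is None else tau_b,
        varred_target=vr_t,
        varred_baseline=vr_b,
        dvi=vr_t - vr_b,
    )


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def grow_tree(
    ls_target: LearningSet,
    ls_baseline: LearningSet,
    params: TreeParams,
    rng: Optional[np.random.Generator] = None,
    sample_weights_target: Optional[np.ndarray] = None,
) -> DiffTreeNode:
    """Grow one differential tree by recursive binary partitioning.

    At each node, ``n_candidate_features`` regulators are drawn without
    replacement; the split gene is the DVI argmax among them (ties: lowest
    feature index, then smallest threshold).  Recursion stops at
    ``max_depth``, when either condition's sample count at a node falls
    below ``min_samples_per_condition``, or when no candidate achieves a
    positive DVI.

    ``sample_weights_target`` is accepted for interface symmetry with the
    boosting loop but is not consulted here: adaptive weighting enters only
    through the caller's weighted bootstrap of the target rows.
    """
    del sample_weights_target  # resampling is the caller's job
    if ls_target.n_samples == 0 or ls_baseline.n_samples == 0:
        raise ValueError("both learning sets must be nonempty")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n_feat = params.resolve_n_features(ls_target.n_regulators)

    def make_leaf(st: np.ndarray, sb: np.ndarray) -> DiffTreeNode:
        pred_b = float(ls_baseline.response[sb].mean()) if sb.size else None
        return DiffTreeNode(
            samples_target=st,
            samples_baseline=sb,
            leaf_prediction_target=float(ls_target.response[st].mean()),
            leaf_prediction_baseline=pred_b,
        )

    def _grow(st: np.ndarray, sb: np.ndarray, depth: int) -> DiffTreeNode:
        if (
            depth >= params.max_depth
            or st.size < params.min_samples_per_condition
            or sb.size < params.min_samples_per_condition
        ):
            return make_leaf(st, sb)
        feats = np.sort(rng.choice(ls_target.n_regulators, size=n_feat, replace=False))
        # batch split search; numerically identical to compute_dvi per feature
        taus_t, vr_t = _scan_all_features(
            ls_target.design[np.ix_(st, feats)], ls_target.response[st]
        )
        if sb.size >= 2:
            taus_b, vr_b = _scan_all_features(
                ls_baseline.design[np.ix_(sb, feats)], ls_baseline.response[sb]
            )
        else:
            taus_b, vr_b = np.full(feats.size, np.nan), np.zeros(feats.size)
        fallback = (vr_b == 0.0) | np.isnan(taus_b)
        taus_b = np.where(fallback, taus_t, taus_b)
        vr_b = np.where(fallback, 0.0, vr_b)
        dvi = vr_t - vr_b
        # lowest feature index wins among candidates tied with the max;
        # the 1e-12 band absorbs last-ulp noise so exact mathematical ties
        # (e.g. two-sample nodes, where any separating feature attains the
        # full reduction) break deterministically
        i = int(np.flatnonzero(dvi >= dvi.max() - 1e-12)[0])
        best = SplitResult(
            feature_index=int(feats[i]),
            tau_target=float(taus_t[i]),
            tau_baseline=float(taus_b[i]),
            varred_target=float(vr_t[i]),
            varred_baseline=float(vr_b[i]),
            dvi=float(dvi[i]),
        )
        if best.dvi <= 0.0 or not np.isfinite(best.tau_target):
            return make_leaf(st, sb)
        f_t = ls_target.design[st, best.feature_index]
        f_b = ls_baseline.design[sb, best.feature_index]
        left_t, right_t = st[f_t <= best.tau_target], st[f_t > best.tau_target]
        left_b, right_b = sb[f_b <= best.tau_baseline], sb[f_b > best.tau_baseline]
        node = DiffTreeNode(samples_target=st, samples_baseline=sb, split=best)
        node.left = _grow(left_t, left_b, depth + 1)
        node.right = _grow(right_t, right_b, depth + 1)
        return node

    return _grow(
        np.arange(ls_target.n_samples, dtype=np.intp),
        np.arange(ls_baseline.n_samples, dtype=np.intp),
        0,
    )


def predict_target(
    root: DiffTreeNode,
    rows: np.ndarray,
    condition: str = TARGET,
) -> np.ndarray:
    """Route design rows through the tree and return leaf means.

    ``condition="target"`` routes by the target thresholds and returns the
    target-condition leaf means — the tree's actual prediction.
    ``condition="baseline"`` routes by the baseline thresholds and returns
    baseline leaf means, falling back to the target mean at leaves that no
    baseline training sample reached; it exists to support the
    prediction-error-difference filter.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    out = np.empty(rows.shape[0])
    use_target = condition == TARGET
    if not use_target and condition != BASELINE:
        raise ValueError(f"unknown condition {condition!r}")
    for i, row in enumerate(rows):
        node = root
        while not node.is_leaf:
            tau = node.split.tau_target if use_target else node.split.tau_baseline
            node = node.left if row[node.split.feature_index] <= tau else node.right
        if use_target or node.leaf_prediction_baseline is None:
            out[i] = node.leaf_prediction_target
        else:
            out[i] = node.leaf_prediction_baseline
    return out


def iter_nodes(root: DiffTreeNode):
    """Yield all nodes in depth-first (node, left, right) order."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        if not node.is_leaf:
            stack.append(node.right)
            stack.append(node.left)
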