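"""Top-k precision/recall/F1 scoring of predicted differential networks.

Tree-based methods emit directed edges; most differential-coexpression
methods do not.  For comparability, predicted and truth edge sets are
collapsed to undirected pairs before scoring, each pair keeping the larger
of its two directed weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

from .network import EdgeRecord

__all__ = ["EvalResult", "to_undirected", "top_k", "score"]

Pair = Tuple[str, str]


@dataclass
class EvalResult:
    k: int
    precision: float
    recall: float
    f1: float
    n_truth: int


def _as_triples(edges: Iterable) -> List[Tuple[str, str, float]]:
    out = []
    for e in edges:
        if isinstance(e, EdgeRecord):
            out.append((e.regulator, e.target, e.weight))
        else:
            r, t = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            out.append((r, t, w))
    return out


def to_undirected(edges: Iterable) -> Dict[Pair, float]:
    """Collapse directed edges to unordered pairs, keeping the max weight.

    Accepts :class:`EdgeRecord` objects or ``(regulator, target[, weight])``
    tuples.  Self-loops are dropped defensively.
    """
    pairs: Dict[Pair, float] = {}
    for r, t, w in _as_triples(edges):
        if r == t:
            continue
        key: Pair = (r, t) if r <= t else (t, r)
        if key not in pairs or w > pairs[key]:
            pairs[key] = w
    return pairs


def top_k(edges: Union[Mapping[Pair, float], Iterable], k: int):
    """The k highest-weight edges with deterministic lexicographic tie-breaks.

    On a mapping of undirected pairs, returns a pair -> weight dict; on a
    directed edge list, returns a list in rank order.  Returns fewer than
    ``k`` items only when the input is shorter.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(edges, Mapping):
        ranked = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))
        return dict(ranked[:k])
    edges = list(edges)
    if edges and isinstance(edges[0], EdgeRecord):
        ranked = sorted(edges, key=lambda e: (-e.weight, e.regulator, e.target))
    else:
        ranked = sorted(_as_triples(edges), key=lambda e: (-e[2], e[0], e[1]))
    return ranked[:k]


def _as_pair_set(edges) -> Set[Pair]:
    if isinstance(edges, Mapping):
        return set(edges.keys())
    return {
        ((r, t) if r <= t else (t, r))
        for r, t, _ in _as_triples(edges)
        if r != t
    }


def score(predicted_topk, truth_edges) -> EvalResult:
    """Precision, recall and F1 of a predicted edge set against the truth.

    Both arguments are interpreted as undirected pair sets.  An empty truth
    set makes the task ill-posed and raises.
    """
    pred = _as_pair_set(predicted_topk)
    truth = _as_pair_set(truth_edges)
    if not truth:
        raise ValueError("scoring against an empty truth set is ill-posed")
    hits = len(pred & truth)
    precision = hits / len(pred) if pred else 0.0
    recall = hits / len(truth)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalResult(
        k=len(pred), precision=precision, recall=recall, f1=f1, n_truth=len(truth)
    )
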