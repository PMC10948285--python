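"""Synthetic two-condition expression data with known differential edges.

Generates paired disease/control-style expression matrices from a random
regulatory DAG in which each non-input gene responds to its regulators
through normalized Hill kinetics (activation ``x^h / (k^h + x^h)``,
repression its complement), with additive Gaussian noise.  Two perturbation
modes induce condition-specific dependencies with *exact* ground truth:

``coefficient_switch``
    A chosen set of edges has its regulatory strength set to 0 in condition
    B, so those dependencies exist only in condition A.  The switched edges
    are the differential ground truth by construction.

``knockdown``
    One input gene's expression is multiplied by a small knockdown factor
    in condition A only.  Every regulatory dependency the perturbation can
    reach — the knocked-down gene's incoming edges plus all edges leaving
    it or any of its descendants — is differential ground truth.

Because the ground truth is exact rather than estimated by sensitivity
analysis, edge-recovery scores carry no ground-truth approximation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimulatedDataset", "build_reference_network",
           "simulate_expression", "make_dataset"]

Edge = Tuple[str, str]

COEFFICIENT_SWITCH = "coefficient_switch"
KNOCKDOWN = "knockdown"


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults emulate the evaluation regime of two-condition knockdown
    simulations: 100 samples per condition, Hill coefficient 2 with
    half-saturation 0.5 (mid-range of uniform (0,1) inputs, so regulators
    operate on the responsive part of the curve), knockdown factor 0.1, and
    additive Gaussian noise with sd 0.05 — small relative to the unit
    dynamic range but large enough that dependencies are statistical, not
    deterministic.
    """

    n_genes: int = 30
    n_samples_per_condition: int = 100
    n_regulators_per_gene: int = 2
    mode: str = COEFFICIENT_SWITCH
    knockdown_gene: Optional[str] = None
    n_switch_edges: int = 3
    hill_coefficient: float = 2.0
    hill_k: float = 0.5
    noise_sd: float = 0.05
    knockdown_factor: float = 0.1
    strength_range: Tuple[float, float] = (0.5, 1.0)
    repression_prob: float = 0.3
    input_fraction: float = 0.15
    #: minimum between-condition difference in regulator-target Pearson
    #: correlation required of every switched edge (~1.8 standard errors of
    #: a correlation difference at n=100, i.e. statistically detectable);
    #: switch sets are redrawn until the realized matrices satisfy it
    detect_margin: float = 0.25
    max_redraws: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mode not in (COEFFICIENT_SWITCH, KNOCKDOWN):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SimulatedDataset:
    """Paired condition matrices with the exact differential-edge partition."""

    expr_A: pd.DataFrame
    expr_B: pd.DataFrame
    truth_edges: Set[Edge]
    static_edges: Set[Edge]
    network: nx.DiGraph
    config: SimConfig
    knockdown_gene: Optional[str] = None


def _gene_names(n: int) -> list:
    width = len(str(n))
    return [f"G{str(i).zfill(width)}" for i in range(1, n + 1)]


def build_reference_network(config: SimConfig) -> nx.DiGraph:
    """Random regulatory DAG with signed, weighted edges.

    Genes are laid out in a random topological order; the first
    ``input_fraction`` are exogenous inputs (no parents), and every later
    gene draws 1..n_regulators_per_gene parents uniformly from its
    predecessors in the order, which guarantees acyclicity.  Edge signs are
    +1 (activation) or -1 (repression) and strengths are uniform in
    ``strength_range``.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_names(config.n_genes)
    order = [genes[i] for i in rng.permutation(config.n_genes)]
    n_inputs = max(1, int(np.ceil(config.input_fraction * config.n_genes)))
    g = nx.DiGraph()
    g.add_nodes_from(genes)
    for pos, gene in enumerate(order):
        g.nodes[gene]["is_input"] = pos < n_inputs
        if pos < n_inputs:
            continue
        n_par = int(rng.integers(1, config.n_regulators_per_gene + 1))
        n_par = min(n_par, pos)
        parents = rng.choice(pos, size=n_par, replace=False)
        for p in parents:
            sign = -1 if rng.random() < config.repression_prob else 1
            strength = float(rng.uniform(*config.strength_range))
            g.add_edge(order[p], gene, sign=sign, strength=strength)
    return g


def _hill(x: np.ndarray, k: float, h: float) -> np.ndarray:
    xh = np.abs(x) ** h
    return xh / (k**h + xh)


def simulate_expression(
    network: nx.DiGraph,
    config: SimConfig,
    rng: np.random.Generator,
    knockdown_gene: Optional[str] = None,
    zeroed_edges: FrozenSet[Edge] = frozenset(),
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Draw one condition's genes x samples expression matrix.

    Input genes are uniform on (0, 1).  Every downstream gene is computed
    in topological order as the strength-weighted mean of its parents' Hill
    responses, plus Gaussian noise.  ``knockdown_gene`` has its value
    multiplied by the knockdown factor (before children consume it);
    ``zeroed_edges`` are removed from the regulatory input.  A gene whose
    active parents are all zeroed falls back to exogenous uniform variation.
    """
    n = config.n_samples_per_condition
    genes = list(network.nodes)
    values: Dict[str, np.ndarray] = {}
    for gene in nx.topological_sort(network):
        parents = [
            (p, network.edges[p, gene])
            for p in network.predecessors(gene)
            if (p, gene) not in zeroed_edges
        ]
        if not parents:
            x = rng.uniform(0.0, 1.0, size=n)
            if network.in_degree(gene) > 0:  # regulators lost to zeroing
                x = x + rng.normal(0.0, config.noise_sd, size=n)
        else:
            num = np.zeros(n)
            denom = 0.0
            for p, attrs in parents:
                resp = _hill(values[p], config.hill_k, config.hill_coefficient)
                if attrs["sign"] < 0:
                    resp = 1.0 - resp
                num += attrs["strength"] * resp
                denom += attrs["strength"]
            x = num / denom + rng.normal(0.0, config.noise_sd, size=n)
        if gene == knockdown_gene:
            x = x * config.knockdown_factor
        values[gene] = x
    samples = [f"{sample_prefix}{i:03d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        np.vstack([values[g] for g in genes]), index=genes, columns=samples
    )


def _knockdown_truth(network: nx.DiGraph, kd: str) -> Set[Edge]:
    """Edges whose dependency the knockdown perturbs.

    The knocked-down gene's incoming edges (its response to its regulators
    is rescaled) plus every edge leaving the gene or any of its descendants
    (their regulator values are shifted by the perturbation).
    """
    affected = {kd} | nx.descendants(network, kd)
    truth = {(u, v) for u, v in network.edges if u in affected}
    truth |= set(network.in_edges(kd))
    return truth


def make_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the paired matrices and the exact truth/static partition.

    Condition A carries the perturbation (the "disease" side): in knockdown
    mode its samples have the knockdown applied; in coefficient_switch mode
    the switched edges are active in A and zeroed in B.
    """
    rng = np.random.default_rng(config.rng_seed)
    network = build_reference_network(config)
    all_edges = set(network.edges)

    if config.mode == KNOCKDOWN:
        if config.knockdown_gene is not None:
            kd = config.knockdown_gene
            if kd not in network:
                raise ValueError(f"knockdown gene {kd!r} not in network")
        else:
            inputs = sorted(g for g in network if network.nodes[g]["is_input"])
            kd = inputs[int(rng.integers(len(inputs)))]
        expr_A = simulate_expression(
            network, config, rng, knockdown_gene=kd, sample_prefix="A"
        )
        expr_B = simulate_expression(network, config, rng, sample_prefix="B")
        truth = _knockdown_truth(network, kd)
        kd_gene = kd
    else:
        edges_sorted = sorted(all_edges)
        n_switch = min(config.n_switch_edges, len(edges_sorted))
        # planted-signal detectability gate: every switched edge must show a
        # between-condition correlation difference of at least detect_margin
        # on the realized matrices; otherwise redraw the switch set
        best = None
        for _ in range(config.max_redraws):
            picked = rng.choice(len(edges_sorted), size=n_switch, replace=False)
            switched = frozenset(edges_sorted[i] for i in picked)
            expr_A = simulate_expression(network, config, rng, sample_prefix="A")
            expr_B = simulate_expression(
                network, config, rng, zeroed_edges=switched, sample_prefix="B"
            )
            margin = min(
                abs(
                    np.corrcoef(expr_A.loc[u], expr_A.loc[v])[0, 1]
                    - np.corrcoef(expr_B.loc[u], expr_B.loc[v])[0, 1]
                )
                for u, v in switched
            )
            if best is None or margin > best[0]:
                best = (margin, switched, expr_A, expr_B)
            if margin >= config.detect_margin:
                break
        _, switched, expr_A, expr_B = best
        truth = set(switched)
        kd_gene = None

    return SimulatedDataset(
        expr_A=expr_A,
        expr_B=expr_B,
        truth_edges=truth,
        static_edges=all_edges - truth,
        network=network,
        config=config,
        knockdown_gene=kd_gene,
    )
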