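"""Thermodynamics-enriched network analysis.

A solved flux distribution orients the active subnetwork (every reaction
rewritten so its flux is positive), side compounds are stripped, the
remaining substrate-to-product relations become an unweighted directed
metabolite graph, and PageRank on that graph yields a measurement-priority
list: highly central metabolites constrain the thermodynamic problem most,
so they are the ones worth quantifying first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .model import MetabolicModel

DEFAULT_DAMPING = 0.85
DEFAULT_PR_TOL = 1e-8
DEFAULT_PR_MAX_ITER = 200
DEFAULT_QUANTILE_CUTS = (0.10, 0.30, 0.50)


class CentralityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# orientation and graph building
# ---------------------------------------------------------------------------

@dataclass
class OrientedSubnetwork:
    """Active reactions with flux-direction-corrected stoichiometry."""

    stoichiometry: Dict[str, Dict[str, float]]  # reaction -> species -> coeff
    fluxes: Dict[str, float]  # all >= 0 after orientation
    species: List[str]


def simplify_and_orient(
    model: MetabolicModel,
    fluxes: Mapping[str, float],
    tolerance: float = 1e-6,
) -> OrientedSubnetwork:
    """Keep reactions with |v| > tolerance, negate the stoichiometry of
    backward-running ones so every retained flux is positive, and drop
    species left without any retained reaction."""
    stoich: Dict[str, Dict[str, float]] = {}
    oriented_flux: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        v = fluxes.get(rid, 0.0)
        if abs(v) <= tolerance:
            continue
        sign = 1.0 if v > 0 else -1.0
        stoich[rid] = {sid: sign * c for sid, c in rxn.stoichiometry.items()}
        oriented_flux[rid] = abs(v)
    species = sorted({sid for st in stoich.values() for sid in st})
    return OrientedSubnetwork(stoichiometry=stoich, fluxes=oriented_flux,
                              species=species)


def build_adjacency(
    subnet: OrientedSubnetwork,
    side_compounds: Iterable[str] = (),
) -> nx.DiGraph:
    """Directed metabolite graph: one edge substrate -> product for every
    substrate/product pair of every oriented reaction, with side compounds
    excluded from both roles.  Edges are unweighted; duplicates collapse."""
    side = set(side_compounds)
    graph = nx.DiGraph()
    for st in subnet.stoichiometry.values():
        substrates = [s for s, c in st.items() if c < 0 and s not in side]
        products = [s for s, c in st.items() if c > 0 and s not in side]
        graph.add_nodes_from(substrates)
        graph.add_nodes_from(products)
        for s in substrates:
            for p in products:
                if s != p:
                    graph.add_edge(s, p)
    return graph


# ---------------------------------------------------------------------------
# PageRank
# ---------------------------------------------------------------------------

def compute_pagerank(
    graph: nx.DiGraph,
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_PR_TOL,
    max_iter: int = DEFAULT_PR_MAX_ITER,
) -> Dict[str, float]:
    """PageRank by dense power iteration with uniform teleportation.

    Dangling nodes redistribute their mass uniformly; iteration stops when
    the L1 change drops below ``tol``.  Scores sum to 1.
    """
    if graph.number_of_nodes() == 0:
        raise CentralityError("empty graph")
    if not 0.0 < damping < 1.0:
        raise CentralityError("damping must be in (0, 1)")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    # column-stochastic link matrix
    M = np.zeros((n, n))
    dangling = np.zeros(n, dtype=bool)
    for node in nodes:
        out = list(graph.successors(node))
        j = index[node]
        if out:
            for succ in out:
                M[index[succ], j] = 1.0 / len(out)
        else:
            dangling[j] = True
    x = np.full(n, 1.0 / n)
    teleport = np.full(n, 1.0 / n)
    for iteration in range(max_iter):
        dangling_mass = x[dangling].sum()
        x_new = damping * (M @ x + dangling_mass * teleport) + (1 - damping) * teleport
        delta = np.abs(x_new - x).sum()
        x = x_new
        if delta < tol:
            return {node: float(x[index[node]]) for node in nodes}
    raise CentralityError(
        f"PageRank did not converge in {max_iter} iterations (L1 change {delta:.3e})"
    )


# ---------------------------------------------------------------------------
# priority report
# ---------------------------------------------------------------------------

@dataclass
class PriorityReport:
    """PageRank-ranked metabolites in quantile bins with measured flags."""

    table: pd.DataFrame  # rank, species_id, score, quantile_bin, measured
    excluded_measured: List[str] = field(default_factory=list)

    def bin_counts(self, measured_only: bool = True) -> Dict[str, int]:
        df = self.table
        if measured_only:
            df = df[df["measured"]]
        return df.groupby("quantile_bin", observed=True).size().to_dict()

    def measured_in_top(self, fraction: float = 0.5) -> int:
        cutoff = math.ceil(fraction * len(self.table))
        top = self.table[self.table["rank"] <= cutoff]
        return int(top["measured"].sum())


def prioritize_metabolites(
    scores: Mapping[str, float],
    measured: Iterable[str] = (),
    quantile_cuts: Tuple[float, ...] = DEFAULT_QUANTILE_CUTS,
) -> PriorityReport:
    """Rank species by PageRank score (descending, ties broken by id),
    assign rank-position quantile bins (top 10%, 30%, 50%, below) and flag
    species with an experimental measurement.  Measured species that are
    not in the graph (side compounds or inactive) are listed separately."""
    if not scores:
        raise CentralityError("no scores to rank")
    measured = set(measured)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ordered)
    cut_ranks = [math.ceil(q * n) for q in quantile_cuts]
    labels = [f"{int(q * 100)}%" for q in quantile_cuts]

    def bin_of(rank: int) -> str:
        for cut, label in zip(cut_ranks, labels):
            if rank <= cut:
                return label
        return "below"

    rows = [
        {
            "rank": i + 1,
            "species_id": sid,
            "score": score,
            "quantile_bin": bin_of(i + 1),
            "measured": sid in measured,
        }
        for i, (sid, score) in enumerate(ordered)
    ]
    excluded = sorted(measured - set(scores))
    return PriorityReport(table=pd.DataFrame(rows), excluded_measured=excluded)
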