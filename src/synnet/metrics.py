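"""Network parameter panel: degrees, path length, clustering, density,
centralization.

Definitions (for a simple undirected graph with N vertices, M edges):

* average degree  <k> = (1/N) sum_i k_i = 2M/N
* average path length  L = mean shortest-path distance over unordered
  vertex pairs; by default only reachable pairs enter the mean (the
  all-pairs and largest-component variants are selectable)
* local clustering  C_i = 2 E_i / (k_i (k_i - 1)), with C_i = 0 for
  degree < 2; global C is the unweighted mean of C_i over all N vertices
* density  ND = M / (N (N-1) / 2)
* degree centralization  NC = (N/(N-1)) (k_max/(N-1) - ND), with the
  approximate form k_max/N - ND available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.sparse import csgraph

from synnet.errors import ValidationError
from synnet.network import SyntacticNetwork
from synnet.treebank import CorpusMeta

LMode = Literal["reachable", "all-pairs", "largest-component"]
NCForm = Literal["exact", "approximate"]


@dataclass(frozen=True)
class DegreeStats:
    """Per-vertex degrees with mean and maximum."""

    degrees: dict[str, int]
    k_mean: float
    k_max: int

    @property
    def sample(self) -> np.ndarray:
        return np.array(sorted(self.degrees.values()), dtype=np.int64)


@dataclass(frozen=True)
class PathStats:
    """Shortest-path summary of a network.

    ``matrix`` holds all pairwise BFS distances (np.inf for unreachable
    pairs) indexed by ``vertex_order``; it is kept so callers can look up
    individual geodesics without recomputing.
    """

    L: float
    reachable_pairs: int
    unreachable_pairs: int
    component_count: int
    largest_component_fraction: float
    vertex_order: tuple[str, ...] = field(repr=False)
    matrix: np.ndarray = field(repr=False)

    def distance(self, u: str, v: str) -> float:
        i = self.vertex_order.index(u)
        j = self.vertex_order.index(v)
        return float(self.matrix[i, j])


@dataclass(frozen=True)
class ClusteringStats:
    """Local clustering coefficients, neighbor-edge counts, and their mean."""

    local: dict[str, float]
    neighbor_edges: dict[str, int]
    C: float


@dataclass(frozen=True)
class CentralityStats:
    ND: float
    NC: float
    k_max: int
    form_used: NCForm


@dataclass(frozen=True)
class MetricsRow:
    """One network's full parameter panel (one row of the study table)."""

    label: str
    modality: str
    level: int | str
    N: int
    M: int
    token_count: int | None
    gamma_prime: float | None
    fit_R2: float | None
    k_mean: float
    C: float
    L: float
    ND: float
    NC: float

    #: serialization order of the panel columns
    COLUMNS = (
        "label",
        "modality",
        "level",
        "N",
        "M",
        "token_count",
        "gamma_prime",
        "fit_R2",
        "k_mean",
        "C",
        "L",
        "ND",
        "NC",
    )

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def degree_stats(network: SyntacticNetwork) -> DegreeStats:
    """Degrees count distinct incident edges; multiplicity is ignored."""
    if network.N == 0:
        raise ValidationError("network is empty")
    degs = network.degrees()
    values = np.fromiter(degs.values(), dtype=np.int64, count=len(degs))
    return DegreeStats(
        degrees=degs,
        k_mean=float(values.mean()),
        k_max=int(values.max()),
    )


def _distance_matrix(network: SyntacticNetwork) -> tuple[np.ndarray, list[str]]:
    adj, order = network.adjacency_matrix()
    dist = csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)
    return dist, order


def average_path_length(
    network: SyntacticNetwork, *, mode: LMode = "reachable"
) -> PathStats:
    """Mean shortest-path distance over unordered vertex pairs.

    ``mode='reachable'`` (default) averages over pairs joined by some path;
    ``'all-pairs'`` divides by N(N-1)/2 and errors on disconnected input;
    ``'largest-component'`` restricts to the largest connected component.
    """
    if network.N < 2:
        raise ValidationError("need at least 2 vertices for path length")
    if network.M == 0:
        raise ValidationError("network has no edges")
    dist, order = _distance_matrix(network)
    n_comp, labels = csgraph.connected_components(
        network.adjacency_matrix()[0], directed=False
    )
    comp_sizes = np.bincount(labels)
    largest = int(comp_sizes.max())
    n = network.N
    iu = np.triu_indices(n, k=1)
    upper = dist[iu]
    finite = np.isfinite(upper)
    reachable = int(finite.sum())
    unreachable = int((~finite).sum())

    if mode == "all-pairs":
        if unreachable:
            raise ValidationError(
                f"network is disconnected ({n_comp} components); "
                "all-pairs L is infinite"
            )
        L = float(upper.mean())
    elif mode == "largest-component":
        big = int(comp_sizes.argmax())
        keep = labels == big
        sub = dist[np.ix_(keep, keep)]
        siu = np.triu_indices(largest, k=1)
        L = float(sub[siu].mean()) if largest > 1 else 0.0
    elif mode == "reachable":
        if reachable == 0:
            raise ValidationError("no reachable vertex pairs")
        L = float(upper[finite].sum() / reachable)
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode!r}")

    return PathStats(
        L=L,
        reachable_pairs=reachable,
        unreachable_pairs=unreachable,
        component_count=int(n_comp),
        largest_component_fraction=largest / n,
        vertex_order=tuple(order),
        matrix=dist,
    )


def clustering(network: SyntacticNetwork) -> ClusteringStats:
    """Local clustering via triangle counting among neighbor sets.

    Vertices of degree < 2 contribute C_i = 0 and stay in the mean, so the
    global coefficient is always an average over all N vertices.
    """
    if network.N == 0:
        raise ValidationError("network is empty")
    adj, order = network.adjacency_matrix()
    a = adj.astype(np.int64)
    # E_i = number of edges among neighbors of i = (A^2 ∘ A) row sum / 2
    tri = (a @ a).multiply(a).sum(axis=1)
    e_counts = np.asarray(tri).ravel() // 2
    k = np.asarray(a.sum(axis=1)).ravel()
    local: dict[str, float] = {}
    neighbor_edges: dict[str, int] = {}
    coeffs = np.zeros(len(order))
    for i, v in enumerate(order):
        ki = int(k[i])
        ei = int(e_counts[i])
        ci = 2.0 * ei / (ki * (ki - 1)) if ki >= 2 else 0.0
        local[v] = ci
        neighbor_edges[v] = ei
        coeffs[i] = ci
    return ClusteringStats(
        local=local,
        neighbor_edges=neighbor_edges,
        C=float(coeffs.mean()),
    )


def density_centralization(
    network: SyntacticNetwork, *, form: NCForm = "exact"
) -> CentralityStats:
    """Density ND = 2M/(N(N-1)) and degree centralization NC."""
    n, m = network.N, network.M
    if n < 2:
        raise ValidationError("need at least 2 vertices for density")
    rho = m / (n * (n - 1) / 2)
    k_max = max(network.degrees().values()) if n else 0
    if form == "exact":
        nc = (n / (n - 1)) * (k_max / (n - 1) - rho)
    elif form == "approximate":
        nc = k_max / n - rho
    else:  # pragma: no cover
        raise ValueError(f"unknown NC form {form!r}")
    return CentralityStats(ND=float(rho), NC=float(nc), k_max=k_max, form_used=form)


def compute_metrics_row(
    network: SyntacticNetwork,
    meta: CorpusMeta,
    fit=None,
    *,
    token_count: int | None = None,
    l_mode: LMode = "reachable",
    nc_form: NCForm = "exact",
) -> MetricsRow:
    """Assemble the full parameter panel for one network.

    ``fit`` may be a power-law fit result providing ``gamma_prime`` and
    ``R2``; pass None to leave the distribution columns empty. Values are
    kept at double precision; rounding happens only at serialization.
    """
    deg = degree_stats(network)
    path = average_path_length(network, mode=l_mode)
    clust = clustering(network)
    cent = density_centralization(network, form=nc_form)
    return MetricsRow(
        label=meta.label,
        modality=meta.modality,
        level=meta.level,
        N=network.N,
        M=network.M,
        token_count=token_count,
        gamma_prime=None if fit is None else float(fit.gamma_prime),
        fit_R2=None if fit is None else float(fit.R2),
        k_mean=deg.k_mean,
        C=clust.C,
        L=path.L,
        ND=cent.ND,
        NC=cent.NC,
    )
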