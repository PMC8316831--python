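"""Matched G(N, M) random baselines and the small-world decision rule.

A network is judged small-world when its clustering coefficient is at
least ``tau_c`` times the matched random-ensemble mean while its average
path length is at most ``tau_l`` times the ensemble mean. The closed
forms C_rand ~ <k>/N and L_rand ~ ln N / ln<k> are reported alongside the
Monte-Carlo summaries as sanity anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from synnet.errors import ValidationError
from synnet.metrics import (
    MetricsRow,
    average_path_length,
    clustering,
)
from synnet.network import SyntacticNetwork


@dataclass(frozen=True)
class RandomEnsembleStats:
    model: str
    N: int
    M: int
    reps: int
    seed: int
    L_mean: float
    L_sd: float
    C_mean: float
    C_sd: float
    L_closed_form: float
    C_closed_form: float


@dataclass(frozen=True)
class SmallWorldAssessment:
    c_ratio: float
    l_ratio: float
    is_small_world: bool
    tau_c: float
    tau_l: float


def generate_gnm(
    N: int, M: int, seed: int | np.random.Generator = 0
) -> SyntacticNetwork:
    """Uniform simple graph with exactly N vertices and M distinct edges.

    Edges are drawn without replacement from the N(N-1)/2 possible pairs,
    so the draw is exactly uniform over simple graphs with those counts.
    Vertex labels are ``v0``..``v{N-1}``.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    max_edges = N * (N - 1) // 2
    if not 0 <= M <= max_edges:
        raise ValidationError(f"M={M} outside 0..{max_edges} for N={N}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    net = SyntacticNetwork()
    for i in range(N):
        net.add_vertex(f"v{i}")
    if M == 0:
        return net
    chosen = np.sort(rng.choice(max_edges, size=M, replace=False))
    # linear index -> (i, j) with i < j over the upper triangle; exact
    # integer row offsets keep the decode free of float rounding issues
    rows = np.arange(N, dtype=np.int64)
    offsets = rows * N - rows * (rows + 1) // 2  # first index of row i
    i = np.searchsorted(offsets, chosen, side="right") - 1
    j = chosen - offsets[i] + i + 1
    for a, b in zip(i, j):
        net.add_edge(f"v{a}", f"v{b}")
    return net


def ensemble_metrics(
    N: int, M: int, reps: int = 30, seed: int = 0
) -> RandomEnsembleStats:
    """L and C summaries over a seeded G(N, M) ensemble.

    Per-replicate metrics use the same conventions as the observed-network
    panel (L over reachable pairs, C averaged over all vertices).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ls = np.empty(reps)
    cs = np.empty(reps)
    for r in range(reps):
        g = generate_gnm(N, M, rng)
        ls[r] = average_path_length(g).L
        cs[r] = clustering(g).C
    k_mean = 2 * M / N
    l_closed = float(np.log(N) / np.log(k_mean)) if k_mean > 1 else float("nan")
    return RandomEnsembleStats(
        model="gnm",
        N=N,
        M=M,
        reps=reps,
        seed=seed,
        L_mean=float(ls.mean()),
        L_sd=float(ls.std(ddof=1)) if reps > 1 else 0.0,
        C_mean=float(cs.mean()),
        C_sd=float(cs.std(ddof=1)) if reps > 1 else 0.0,
        L_closed_form=l_closed,
        C_closed_form=k_mean / N,
    )


def assess_small_world(
    obs: MetricsRow,
    ens: RandomEnsembleStats,
    tau_c: float = 5.0,
    tau_l: float = 1.2,
) -> SmallWorldAssessment:
    """Compare an observed panel row against its matched random ensemble."""
    if (obs.N, obs.M) != (ens.N, ens.M):
        raise ValidationError(
            f"ensemble (N={ens.N}, M={ens.M}) does not match observed "
            f"network (N={obs.N}, M={obs.M})"
        )
    if ens.C_mean <= 0 or ens.L_mean <= 0:
        raise ValidationError("degenerate ensemble summaries")
    c_ratio = obs.C / ens.C_mean
    l_ratio = obs.L / ens.L_mean
    return SmallWorldAssessment(
        c_ratio=float(c_ratio),
        l_ratio=float(l_ratio),
        is_small_world=bool(c_ratio >= tau_c and l_ratio <= tau_l),
        tau_c=tau_c,
        tau_l=tau_l,
    )
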