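"""Random walk with restart on the heterogeneous lncRNA-disease network.

The walk runs on nl + nd nodes (lncRNAs first, then diseases).  From a node
with both intra-network similarity neighbours and bipartite association
links, a step jumps across the bipartite links with probability
``lambda_jump`` and otherwise moves within its own similarity network; a
node missing one kind of link spends its whole step on the other; a node
with neither is dangling and its mass is returned to the restart seed.

Propagation iterates  p <- (1 - r) * (M^T p + dangling_mass * p0) + r * p0
to the stationary distribution.  Seeding at each disease node in turn yields
a score for every lncRNA-disease pair; unknown pairs in the low-score tail
are the candidate pool from which training negatives are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LAMBDA = 0.5
DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITERS = 10_000
DEFAULT_POOL_FRACTION = 0.5


@dataclass
class HeteroTransition:
    """Row-stochastic transition matrix over lncRNA + disease nodes."""

    matrix: np.ndarray
    lambda_jump: float
    n_lncrnas: int
    n_diseases: int
    dangling: np.ndarray  # bool mask of all-zero rows

    @property
    def size(self) -> int:
        return self.n_lncrnas + self.n_diseases


@dataclass
class PairScoreTable:
    """Stationary lncRNA-block probabilities per disease seed (nl x nd)."""

    scores: np.ndarray
    params: dict


def build_transition_matrix(
    llcm: np.ndarray,
    ddscm: np.ndarray,
    ldcm: np.ndarray,
    lambda_jump: float = DEFAULT_LAMBDA,
) -> HeteroTransition:
    llcm = np.asarray(llcm, float)
    ddscm = np.asarray(ddscm, float)
    ldcm = np.asarray(ldcm, float)
    nl, nd = ldcm.shape
    if llcm.shape != (nl, nl) or ddscm.shape != (nd, nd):
        raise ValueError("similarity matrix dimensions inconsistent with the association matrix")
    if not 0.0 <= lambda_jump <= 1.0:
        raise ValueError("lambda_jump must lie in [0, 1]")
    if llcm.min() < 0 or ddscm.min() < 0:
        raise ValueError("similarity matrices must be nonnegative")

    n = nl + nd
    m = np.zeros((n, n))

    def fill_block(rows, intra, bip, intra_offset, bip_offset):
        intra = intra.copy()
        np.fill_diagonal(intra, 0.0)  # self-weight excluded
        for i in range(rows):
            si, sb = intra[i].sum(), bip[i].sum()
            if si > 0 and sb > 0:
                m[intra_offset + i, intra_offset:intra_offset + intra.shape[1]] = (
                    (1 - lambda_jump) * intra[i] / si
                )
                m[intra_offset + i, bip_offset:bip_offset + bip.shape[1]] = (
                    lambda_jump * bip[i] / sb
                )
            elif si > 0:
                m[intra_offset + i, intra_offset:intra_offset + intra.shape[1]] = intra[i] / si
            elif sb > 0:
                m[intra_offset + i, bip_offset:bip_offset + bip.shape[1]] = bip[i] / sb

    fill_block(nl, llcm, ldcm, 0, nl)
    fill_block(nd, ddscm, ldcm.T, nl, 0)
    dangling = m.sum(axis=1) == 0.0
    return HeteroTransition(m, lambda_jump, nl, nd, dangling)


def rwrh_propagate(
    transition: HeteroTransition,
    seed_distribution: np.ndarray,
    restart_prob: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> np.ndarray:
    """Stationary distribution of the restart walk from one seed distribution."""
    p0 = np.asarray(seed_distribution, float)
    if p0.min() < 0 or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("seed distribution must be nonnegative and sum to 1")
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")
    mt = transition.matrix.T
    dangling = transition.dangling
    p = p0.copy()
    for _ in range(max_iters):
        dm = p[dangling].sum()
        p_next = (1.0 - restart_prob) * (mt @ p + dm * p0) + restart_prob * p0
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < tolerance:
            return p
    raise RuntimeError(
        f"random walk did not converge in {max_iters} iterations (residual {residual:.3e})"
    )


def score_all_pairs(
    llcm: np.ndarray,
    ddscm: np.ndarray,
    ldcm: np.ndarray,
    lambda_jump: float = DEFAULT_LAMBDA,
    restart_prob: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
    seed_known_lncrnas: bool = False,
) -> PairScoreTable:
    """Propagate from every disease seed; column j holds the lncRNA-block scores.

    By default the full seed mass sits on the disease node; with
    ``seed_known_lncrnas`` it is split ``lambda_jump``-style between the
    disease node and its known lncRNAs.
    """
    ldcm = np.asarray(ldcm, float)
    nl, nd = ldcm.shape
    transition = build_transition_matrix(llcm, ddscm, ldcm, lambda_jump)
    scores = np.zeros((nl, nd))
    for j in range(nd):
        p0 = np.zeros(nl + nd)
        known = np.flatnonzero(ldcm[:, j])
        if seed_known_lncrnas and known.size:
            p0[nl + j] = 1.0 - lambda_jump
            p0[known] = lambda_jump / known.size
        else:
            p0[nl + j] = 1.0
        p = rwrh_propagate(transition, p0, restart_prob, tolerance, max_iters)
        scores[:, j] = p[:nl]
    if not np.isfinite(scores).all():
        raise RuntimeError("random-walk scores contain NaN or Inf")
    params = {
        "lambda_jump": lambda_jump,
        "restart_prob": restart_prob,
        "tolerance": tolerance,
        "seed_known_lncrnas": seed_known_lncrnas,
    }
    return PairScoreTable(scores, params)


def sample_negatives(
    score_table: PairScoreTable | np.ndarray,
    positives: set[tuple[int, int]],
    ratio: float = 1.0,
    pool_fraction: float = DEFAULT_POOL_FRACTION,
    seed: int = 0,
    mode: str = "rwrh",
) -> list[tuple[int, int]]:
    """Draw negatives from the low-score tail of the unknown pairs.

    ``mode='rwrh'`` ranks unknown pairs by walk score ascending (ties broken
    by pair index) and keeps the lowest ``pool_fraction`` as the candidate
    pool; ``mode='uniform'`` pools all unknown pairs (the random-negative
    baseline).  ``ceil(ratio * len(positives))`` pairs are sampled without
    replacement, reproducibly for a given seed, and are disjoint from the
    positives by construction.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    scores = score_table.scores if isinstance(score_table, PairScoreTable) else np.asarray(score_table)
    nl, nd = scores.shape
    unknown = [(i, j) for i in range(nl) for j in range(nd) if (i, j) not in positives]
    if mode == "rwrh":
        unknown.sort(key=lambda ij: (scores[ij[0], ij[1]], ij[0], ij[1]))
        pool = unknown[: int(np.ceil(pool_fraction * len(unknown)))]
    elif mode == "uniform":
        pool = unknown
    else:
        raise ValueError(f"unknown sampling mode: {mode!r}")
    count = int(np.ceil(ratio * len(positives)))
    if count > len(pool):
        raise ValueError(
            f"candidate pool has {len(pool)} pairs but {count} negatives requested; "
            "increase pool_fraction"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=count, replace=False)
    return [pool[k] for k in sorted(chosen)]
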