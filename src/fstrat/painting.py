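"""First-coalescence chromosome painting and NNLS ancestry fits.

For each position of the genome, a subject haplotype is "painted" by the
reference population it coalesces with first in the local tree: walking
from the subject leaf toward the root, the first node whose other
descendants include reference samples defines the event.  If several
reference populations are involved at that node, the event weight is
split proportionally to their sample counts.  Span-weighted aggregation
over trees yields, per subject, a profile vector ``a`` of length k (one
entry per reference population) summing to 1 over the covered genome.

A target profile is then modelled as a non-negative mixture of source
profiles:

    min || a_target - A beta ||_2   subject to  beta >= 0, sum(beta) <= 1

This estimator is the genealogical idealization of haplotype-painting /
IBD-sharing mixture models; it is useful as a comparison point and is
known to be biased when a source has experienced strong drift since
admixture (which the simulation study reproduces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize

from fstrat.genealogy import GenealogySequence, PopulationAssignment

__all__ = [
    "CoalescenceProfile",
    "NNLSFit",
    "first_coalescence_profile",
    "coalescence_profiles",
    "population_profile",
    "nnls_admixture",
]


@dataclass
class CoalescenceProfile:
    """Fraction of the genome first-coalescing with each reference population.

    ``a`` is normalized over the covered span (so it sums to 1 whenever any
    of the genome is covered); ``coverage`` is the covered fraction.
    ``block_a``/``block_weights`` optionally retain the per-block breakdown
    for jackknifing.
    """

    subject: str
    reference_pops: list[str]
    a: np.ndarray
    coverage: float
    block_a: np.ndarray | None = None
    block_weights: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if np.any(self.a < -1e-12):
            raise ValueError("profile entries must be non-negative")
        if self.coverage > 0 and not math_isclose(self.a.sum(), 1.0):
            raise ValueError(f"profile must sum to 1 over covered span, got {self.a.sum()}")


def math_isclose(a, b, tol=1e-9):
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


@dataclass
class NNLSFit:
    """Result of the constrained mixture fit."""

    target: str
    sources: list[str]
    weights: np.ndarray
    residual: float
    identifiable: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-9) or w.sum() > 1 + 1e-9:
            raise ValueError("weights must satisfy beta >= 0 and sum(beta) <= 1")
        self.weights = np.clip(w, 0.0, None)


@njit(cache=True)
def _paint_kernel(
    num_nodes,
    edges_left,
    edges_right,
    edges_parent,
    edges_child,
    insertion,
    removal,
    L,
    leaf_label,  # (num_nodes,) int64, -1 if not a reference sample
    k,
    subjects,  # (S,) int64 sample node ids
    block_edges,  # (B+1,) float64
):
    S = len(subjects)
    B = len(block_edges) - 1
    parent = np.full(num_nodes, -1, dtype=np.int64)
    cnt = np.zeros((num_nodes, k))
    for u in range(num_nodes):
        lab = leaf_label[u]
        if lab >= 0:
            cnt[u, lab] = 1.0
    out = np.zeros((S, B, k))
    uncovered = np.zeros((S, B))
    M = len(insertion)
    j = 0
    l = 0
    pos = 0.0
    d = np.zeros(k)
    while pos < L:
        while l < M and edges_right[removal[l]] == pos:
            e = removal[l]
            l += 1
            c = edges_child[e]
            u = edges_parent[e]
            while u != -1:
                for q in range(k):
                    cnt[u, q] -= cnt[c, q]
                u = parent[u]
            parent[c] = -1
        while j < M and edges_left[insertion[j]] == pos:
            e = insertion[j]
            j += 1
            c = edges_child[e]
            p = edges_parent[e]
            parent[c] = p
            u = p
            while u != -1:
                for q in range(k):
                    cnt[u, q] += cnt[c, q]
                u = parent[u]
        right = L
        if j < M and edges_left[insertion[j]] < right:
            right = edges_left[insertion[j]]
        if l < M and edges_right[removal[l]] < right:
            right = edges_right[removal[l]]
        # paint the interval [pos, right) for each subject
        b0 = np.searchsorted(block_edges, pos, side="right") - 1
        for si in range(S):
            s = subjects[si]
            c = s
            u = parent[s]
            found = False
            while u != -1:
                tot = 0.0
                for q in range(k):
                    d[q] = cnt[u, q] - cnt[c, q]
                    tot += d[q]
                if tot > 0.0:
                    found = True
                    break
                c = u
                u = parent[u]
            b = b0
            lo = pos
            while lo < right and b < B:
                hi = min(right, block_edges[b + 1])
                span = hi - lo
                if found:
                    for q in range(k):
                        out[si, b, q] += span * d[q] / tot
                else:
                    uncovered[si, b] += span
                lo = hi
                b += 1
        pos = right
    return out, uncovered


def coalescence_profiles(
    g: GenealogySequence,
    subjects,
    reference_pops,
    pops: PopulationAssignment,
    blocks=None,
) -> list[CoalescenceProfile]:
    """Paint several subject samples in one pass over the trees.

    ``subjects`` are sample ids; a subject belonging to a reference
    population is automatically held out of its own painting (only other
    lineages can generate events).  ``blocks`` (optional bp size or
    boundary array) retains a per-block breakdown for jackknifing.
    """
    from fstrat.fstats import _resolve_blocks

    reference_pops = list(reference_pops)
    subjects = list(subjects)
    if not reference_pops:
        raise ValueError("need at least one reference population")
    ts = g.tree_sequence
    pops_r = pops.restrict(g.sample_ids)
    leaf_label = np.full(ts.num_nodes, -1, dtype=np.int64)
    for q, rp in enumerate(reference_pops):
        nodes = g.sample_nodes(pops_r.members(rp))
        if len(nodes) == 0:
            raise ValueError(f"reference population {rp!r} has no sample")
        leaf_label[nodes] = q
    subject_nodes = g.sample_nodes(subjects)
    edges = (
        np.array([0.0, ts.sequence_length])
        if blocks is None
        else _resolve_blocks(blocks, ts.sequence_length)
    )
    tab = ts.tables
    out, uncovered = _paint_kernel(
        ts.num_nodes,
        tab.edges.left,
        tab.edges.right,
        tab.edges.parent.astype(np.int64),
        tab.edges.child.astype(np.int64),
        tab.indexes.edge_insertion_order.astype(np.int64),
        tab.indexes.edge_removal_order.astype(np.int64),
        ts.sequence_length,
        leaf_label,
        len(reference_pops),
        subject_nodes.astype(np.int64),
        edges,
    )
    profiles = []
    for si, s in enumerate(subjects):
        covered = out[si].sum()
        total = covered + uncovered[si].sum()
        a = out[si].sum(axis=0)
        a = a / covered if covered > 0 else a
        block_w = out[si].sum(axis=1)
        block_a = np.divide(
            out[si], block_w[:, None], out=np.zeros_like(out[si]),
            where=block_w[:, None] > 0,
        )
        profiles.append(
            CoalescenceProfile(
                subject=s,
                reference_pops=reference_pops,
                a=a,
                coverage=covered / total if total > 0 else 0.0,
                block_a=block_a,
                block_weights=block_w,
            )
        )
        if covered == 0:
            warnings.warn(f"subject {s!r}: no tree had a reference coalescence")
    return profiles


def first_coalescence_profile(
    g: GenealogySequence,
    subject: str,
    reference_pops,
    pops: PopulationAssignment,
    blocks=None,
) -> CoalescenceProfile:
    """Paint a single subject sample (see :func:`coalescence_profiles`)."""
    if subject in reference_pops:
        raise ValueError("subject must be a sample id, not a reference population")
    return coalescence_profiles(g, [subject], reference_pops, pops, blocks)[0]


def population_profile(
    g: GenealogySequence,
    population: str,
    reference_pops,
    pops: PopulationAssignment,
    blocks=None,
) -> CoalescenceProfile:
    """Span-weighted average profile of all members of a population.

    Members belonging to a reference population are held out of their own
    painting, so a population may appear in ``reference_pops`` as well.
    """
    members = pops.restrict(g.sample_ids).members(population)
    profs = coalescence_profiles(g, members, reference_pops, pops, blocks)
    w = np.array([p.coverage for p in profs])
    if w.sum() == 0:
        raise ValueError(f"population {population!r}: nothing painted")
    a = np.average([p.a for p in profs], axis=0, weights=w)
    block_w = np.sum([p.block_weights for p in profs], axis=0)
    block_a = np.zeros_like(profs[0].block_a)
    num = np.sum([p.block_a * p.block_weights[:, None] for p in profs], axis=0)
    np.divide(num, block_w[:, None], out=block_a, where=block_w[:, None] > 0)
    return CoalescenceProfile(
        subject=population,
        reference_pops=list(reference_pops),
        a=a / a.sum(),
        coverage=float(np.mean([p.coverage for p in profs])),
        block_a=block_a,
        block_weights=block_w,
    )


def _solve_simplex_ls(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """min ||y - A b||, b >= 0, sum(b) <= 1, via NNLS then constrained QP."""
    b, _ = optimize.nnls(A, y)
    if b.sum() <= 1.0 + 1e-12:
        return b
    m = A.shape[1]
    res = optimize.minimize(
        lambda b: 0.5 * np.sum((y - A @ b) ** 2),
        x0=np.full(m, 1.0 / m),
        jac=lambda b: A.T @ (A @ b - y),
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0,
                      "jac": lambda b: np.ones(m)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    b = np.clip(res.x, 0.0, None)
    # polish: exact equality-constrained LS on the active face
    active = b > 1e-9
    if active.any():
        Aa = A[:, active]
        n_act = Aa.shape[1]
        K = np.zeros((n_act + 1, n_act + 1))
        K[:n_act, :n_act] = Aa.T @ Aa
        K[:n_act, n_act] = 1.0
        K[n_act, :n_act] = 1.0
        rhs = np.concatenate([Aa.T @ y, [1.0]])
        try:
            sol = np.linalg.solve(K, rhs)[:n_act]
            if np.all(sol >= -1e-12):
                cand = np.zeros_like(b)
                cand[active] = np.clip(sol, 0.0, None)
                if np.sum((y - A @ cand) ** 2) <= np.sum((y - A @ b) ** 2) + 1e-15:
                    b = cand
        except np.linalg.LinAlgError:
            pass
    b = b / max(b.sum(), 1.0)
    return b


def nnls_admixture(target, sources) -> NNLSFit:
    """Fit a target profile as a constrained mixture of source profiles.

    Parameters
    ----------
    target
        A :class:`CoalescenceProfile` or a bare length-k vector.
    sources
        List of source :class:`CoalescenceProfile` (over the same reference
        list) or a (k, m) matrix whose columns are source profiles.
    """
    if isinstance(target, CoalescenceProfile):
        y = target.a
        tname = target.subject
        refs = target.reference_pops
    else:
        y = np.asarray(target, dtype=float)
        tname, refs = "target", None
    if isinstance(sources, (list, tuple)) and sources and isinstance(
        sources[0], CoalescenceProfile
    ):
        names = [s.subject for s in sources]
        for s in sources:
            if refs is not None and s.reference_pops != refs:
                raise ValueError(
                    f"source {s.subject!r} uses different reference populations"
                )
        A = np.column_stack([s.a for s in sources])
    else:
        A = np.asarray(sources, dtype=float)
        names = [f"source{i}" for i in range(A.shape[1])]
    if A.shape[0] != len(y):
        raise ValueError("target and source profiles have different lengths")
    if np.any(np.all(A == 0, axis=0)):
        raise ValueError("all-zero source profile column")
    beta = _solve_simplex_ls(A, y)
    residual = float(np.linalg.norm(y - A @ beta))
    fit = NNLSFit(tname, names, beta, residual)
    if np.linalg.matrix_rank(A, tol=1e-10) < A.shape[1]:
        fit.identifiable = False
        fit.warnings.append(
            "source profile matrix is rank deficient; weights are not unique "
            "along its null space"
        )
    return fit
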