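"""qpWave rank tests, qpAdm mixture fits, model rotation, cladality
clustering and outgroup-f3 MDS.

All operations consume an :class:`~fstrat.fstats.F2BlockTensor`.  The
statistical core is the generalized-least-squares treatment of the matrix
of f4-statistics

    F_ij = f4(l_0, l_i; r_0, r_j)

between a "left" set (target/sources) and a "right" (reference) set, with
the error model given by the weighted block-jackknife covariance of the
entries.  qpWave tests rank(F) <= r (rank 0 between two groups means they
form a clade with respect to the references); qpAdm expresses a target as
a mixture of sources, estimating weights beta with sum(beta) = 1 and a
model-fit p-value from the corresponding rank condition.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from fstrat.fstats import F2BlockTensor, f3_blocks, f4_blocks
from fstrat.jackknife import jackknife_mean_and_cov

__all__ = [
    "AdmixtureFit",
    "qpwave_rank_test",
    "qpadm_fit",
    "rotational_qpadm",
    "pairwise_qpwave_pvalues",
    "pairwise_cladality_clustering",
    "outgroup_f3_mds",
]

#: eigenvalue floor for jackknife covariances, as a fraction of the trace;
#: makes small-block analyses deterministic instead of numerically singular
COV_FLOOR = 1e-12
#: condition number beyond which sources are flagged as collinear
COLLINEAR_CONDITION = 1e8


@dataclass
class AdmixtureFit:
    """A qpAdm model: weights, uncertainty, fit p-value, feasibility."""

    target: str
    sources: list[str]
    references: list[str]
    weights: np.ndarray
    se: np.ndarray
    p_value: float
    statistic: float
    dof: int
    log10_p: float = 0.0  # exact even where p_value underflows to 0
    collinear: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return bool(np.all((self.weights >= 0) & (self.weights <= 1)))

    @property
    def alpha(self) -> float | None:
        """Weight of the second source in a two-source fit."""
        return float(self.weights[1]) if len(self.sources) == 2 else None

    def __repr__(self):
        w = ", ".join(
            f"{s}={b:.3f}+/-{e:.3f}" for s, b, e in zip(self.sources, self.weights, self.se)
        )
        return f"qpAdm[{self.target} ~ {w}; p={self.p_value:.3g}]"


def _quadform_log10_sf(statistic: float, dof: int, n_blocks: int) -> float:
    """log10 tail probability of a GLS quadratic form.

    The covariance entering the statistic is itself estimated from
    ``n_blocks`` jackknife blocks, so the naive chi-square reference is
    anticonservative.  We use the Hotelling-type F reference,

        stat * (B - d) / (d * (B - 1))  ~  F(d, B - d),

    which is exact for a rank-0 test on Gaussian block means and an
    accurate approximation for the constrained fits; it converges to the
    chi-square as B grows, and is monotone in the statistic, so model
    rankings are unaffected.  Falls back to chi-square when B <= d + 1.
    """
    if n_blocks > dof + 1:
        scaled = statistic * (n_blocks - dof) / (dof * (n_blocks - 1))
        return float(stats.f.logsf(scaled, dof, n_blocks - dof)) / math.log(10)
    return float(stats.chi2.logsf(statistic, dof)) / math.log(10)


def _floored_inverse(cov: np.ndarray) -> np.ndarray:
    """Invert a covariance after flooring eigenvalues at COV_FLOOR * trace."""
    ev, U = linalg.eigh(cov)
    floor = max(COV_FLOOR * max(np.trace(cov), 0.0), 1e-300)
    ev = np.maximum(ev, floor)
    return (U / ev) @ U.T


def _f4_block_matrix(tensor: F2BlockTensor, left, right) -> np.ndarray:
    """Per-block f4(l0, li; r0, rj) entries, shape (B, (L-1)*(R-1))."""
    l0, r0 = left[0], right[0]
    cols = [
        f4_blocks(tensor, l0, li, r0, rj)
        for li in left[1:]
        for rj in right[1:]
    ]
    return np.column_stack(cols)


def qpwave_rank_test(
    tensor: F2BlockTensor, left, right, rank: int = 0
) -> tuple[float, float, int]:
    """Test rank(F) <= rank for the left x right f4 matrix.

    Returns ``(p_value, statistic, dof)`` with
    ``dof = (L - 1 - rank)(R - 1 - rank)``.  ``rank=0`` between two left
    groups is the cladality test: are they symmetrically related to every
    reference?  Positive ranks are fitted by alternating generalized least
    squares on the jackknife covariance.
    """
    left, right = list(left), list(right)
    if set(left) & set(right):
        raise ValueError("left and right sets must be disjoint")
    nl, nr = len(left) - 1, len(right) - 1
    if not 0 <= rank < min(nl, nr):
        raise ValueError(f"rank must be in [0, {min(nl, nr) - 1}] for this left/right")
    blocks = _f4_block_matrix(tensor, left, right)
    est, cov = jackknife_mean_and_cov(blocks, tensor.weights)
    if np.trace(cov) <= 0:
        if np.allclose(est, 0):
            # identically-zero f4 matrix: perfectly cladal, nothing to test
            dof = (nl - rank) * (nr - rank)
            return 1.0, 0.0, dof
        raise ValueError("singular f4 covariance; use more or longer blocks")
    cinv = _floored_inverse(cov)
    if rank == 0:
        statistic = float(est @ cinv @ est)
    else:
        F = est.reshape(nl, nr)
        U, s, Vt = np.linalg.svd(F)
        A = U[:, :rank] * s[:rank]
        Bm = Vt[:rank]
        statistic = np.inf
        for _ in range(200):
            # fix A, GLS-solve for B, then fix B, GLS-solve for A
            for which in ("B", "A"):
                if which == "B":
                    X = np.kron(A, np.eye(nr))  # vec(AB) = X vec(B)
                else:
                    X = np.kron(np.eye(nl), Bm.T)  # vec row-major: see below
                # operate on row-major vec: vec(F)[i*nr+j]
                M = X.T @ cinv @ X
                rhs = X.T @ cinv @ est
                sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
                if which == "B":
                    Bm = sol.reshape(rank, nr)
                else:
                    A = sol.reshape(nl, rank)
            resid = est - (A @ Bm).reshape(-1)
            new_stat = float(resid @ cinv @ resid)
            if abs(statistic - new_stat) < 1e-10 * (1 + abs(new_stat)):
                statistic = new_stat
                break
            statistic = new_stat
    dof = (nl - rank) * (nr - rank)
    p = float(10.0 ** _quadform_log10_sf(statistic, dof, tensor.num_blocks))
    return p, statistic, dof


def _qpadm_weights(est_mat: np.ndarray, cov: np.ndarray, n_iter: int = 5):
    """Constrained GLS for qpAdm weights.

    est_mat is the (S, R-1) matrix of f4(target, s_i; r_0, r_j); the model
    asserts a beta with sum(beta) = 1 and beta' est_mat = 0.  The error
    model for y = est_mat' beta is (beta x I)' Q (beta x I); since it
    depends on beta, the quadratic solve is iterated from uniform weights.
    """
    S, K = est_mat.shape
    Q = cov.reshape(S, K, S, K)
    beta = np.full(S, 1.0 / S)
    ones = np.ones(S)
    statistic = np.nan
    for _ in range(n_iter):
        cov_y = np.einsum("i,ikjl,j->kl", beta, Q, beta)
        cinv = _floored_inverse(cov_y)
        M = est_mat @ cinv @ est_mat.T
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            Minv = np.linalg.pinv(M)
        beta_new = Minv @ ones / (ones @ Minv @ ones)
        y = est_mat.T @ beta_new
        statistic = float(y @ cinv @ y)
        if np.allclose(beta_new, beta, atol=1e-12):
            beta = beta_new
            break
        beta = beta_new
    cond = np.linalg.cond(M)
    return beta, statistic, cond


def qpadm_fit(
    tensor: F2BlockTensor, target: str, sources, references
) -> AdmixtureFit:
    """Fit ``target`` as a mixture of ``sources`` given ``references``.

    Weights are normalized to sum to 1 but deliberately NOT clamped to
    [0, 1]: infeasibility must be observable (see ``feasible``).  Standard
    errors come from a delete-one-block jackknife of the whole fit; the
    model p-value is chi-square with ``len(references) - len(sources)``
    degrees of freedom.
    """
    sources = list(sources)
    references = list(references)
    if target in sources or target in references:
        raise ValueError("target must not appear among sources or references")
    if set(sources) & set(references):
        raise ValueError("sources and references must be disjoint")
    S, R = len(sources), len(references)
    if R < S + 1:
        raise ValueError(f"need at least {S + 1} references for {S} sources")
    r0 = references[0]
    cols = [
        f4_blocks(tensor, target, s, r0, rj)
        for s in sources
        for rj in references[1:]
    ]
    blocks = np.column_stack(cols)  # (B, S*(R-1))
    est, cov = jackknife_mean_and_cov(blocks, tensor.weights)
    est_mat = est.reshape(S, R - 1)
    beta, statistic, cond = _qpadm_weights(est_mat, cov)

    # jackknife of the weights: refit on delete-one-block means, reusing the
    # full covariance (the error model), as is standard for these fits
    W = tensor.weights
    tot = W @ blocks
    Wsum = W.sum()
    betas_del = np.empty((len(W), S))
    for b in range(len(W)):
        est_b = (tot - W[b] * blocks[b]) / (Wsum - W[b])
        betas_del[b] = _qpadm_weights(est_b.reshape(S, R - 1), cov)[0]
    h = Wsum / W
    theta_J = len(W) * beta - np.sum((1 - W / Wsum)[:, None] * betas_del, axis=0)
    tau = h[:, None] * beta[None, :] - (h - 1)[:, None] * betas_del
    se = np.sqrt(
        np.maximum(np.sum((tau - theta_J) ** 2 / (h - 1)[:, None], axis=0) / len(W), 0)
    )
    dof = R - S
    log10_p = _quadform_log10_sf(statistic, dof, tensor.num_blocks)
    fit = AdmixtureFit(
        target=target,
        sources=sources,
        references=references,
        weights=beta,
        se=se,
        p_value=float(10.0 ** log10_p),
        statistic=statistic,
        dof=dof,
        log10_p=log10_p,
        collinear=bool(cond > COLLINEAR_CONDITION),
    )
    if fit.collinear:
        fit.warnings.append(
            f"source f4 system is near-collinear (condition {cond:.2g}); "
            "weights are not well identified"
        )
    return fit


def rotational_qpadm(
    tensor: F2BlockTensor,
    target: str,
    source_pool,
    max_sources: int = 2,
    fixed_references=(),
    p_all: float = 0.05,
    p_best: float = 0.01,
) -> dict:
    """Rotating qpAdm model search.

    Every subset of ``source_pool`` of size 1..``max_sources`` is fitted
    with all unused pool members (plus ``fixed_references``) as references,
    which penalizes models that relegate a true source to the reference
    set.  Models with any weight outside [0, 1] are removed by the
    feasibility filter.  The ``accepted`` list reports either all feasible
    models with p > ``p_all``, or else the single best feasible model if it
    reaches p > ``p_best``.

    Returns a dict with ``fits`` (all fitted models, ranked by p-value),
    ``feasible``, ``accepted`` and ``diagnostics``.
    """
    pool = list(source_pool)
    if len(pool) < 2:
        raise ValueError("source pool must contain at least 2 groups")
    fits: list[AdmixtureFit] = []
    diagnostics: list[str] = []
    for size in range(1, max_sources + 1):
        for combo in itertools.combinations(pool, size):
            refs = list(fixed_references) + [g for g in pool if g not in combo]
            if len(refs) < size + 1:
                diagnostics.append(
                    f"skipped {combo}: only {len(refs)} references available"
                )
                continue
            try:
                fits.append(qpadm_fit(tensor, target, list(combo), refs))
            except (ValueError, np.linalg.LinAlgError) as e:
                diagnostics.append(f"model {combo} failed: {e}")
    fits.sort(key=lambda f: -f.log10_p)
    feasible = [f for f in fits if f.feasible]
    if not feasible:
        diagnostics.append("no feasible model (all weights outside [0, 1])")
    accepted = [f for f in feasible if f.p_value > p_all]
    if not accepted and feasible and feasible[0].p_value > p_best:
        accepted = [feasible[0]]
    return {
        "fits": fits,
        "feasible": feasible,
        "accepted": accepted,
        "diagnostics": diagnostics,
    }


def pairwise_qpwave_pvalues(
    tensor: F2BlockTensor, individuals, references
) -> pd.DataFrame:
    """Rank-0 qpWave p-value for every pair of individuals.

    Diagonal is 1 by convention; the matrix is symmetric.
    """
    individuals = list(individuals)
    P = pd.DataFrame(
        np.eye(len(individuals)) * 0 + 1.0, index=individuals, columns=individuals
    )
    for a, b in itertools.combinations(individuals, 2):
        p, _, _ = qpwave_rank_test(tensor, [a, b], list(references), rank=0)
        P.loc[a, b] = P.loc[b, a] = p
    return P


def pairwise_cladality_clustering(
    pvalues: pd.DataFrame,
    ages_years: dict[str, float] | None = None,
    p_cut: float = 0.01,
    age_window: float = 500.0,
    min_size: int = 3,
) -> pd.DataFrame:
    """UPGMA clustering of individuals from pairwise cladality p-values.

    Average-linkage (UPGMA) clustering on ``-log10 p`` dissimilarities, cut
    at height ``-log10(p_cut)``; clusters are then iteratively subdivided
    so that every member is within ``age_window`` years of its cluster's
    mean age (the farthest member is split off first, deterministically,
    and split-off members are re-clustered among themselves by the same
    rule).  Clusters smaller than ``min_size`` are flagged, mirroring the
    practice of only interpreting clusters of three or more.

    Returns a DataFrame indexed by individual with columns ``cluster``
    (int label), ``age`` and ``small`` (below min_size flag).
    """
    ids = list(pvalues.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    M = pvalues.to_numpy(dtype=float)
    if np.isnan(M).any():
        i, j = map(int, np.argwhere(np.isnan(M))[0])
        raise ValueError(f"missing pairwise p-value for ({ids[i]}, {ids[j]})")
    with np.errstate(divide="ignore"):
        D = -np.log10(np.clip(M, 1e-300, 1.0))
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=-math.log10(p_cut), criterion="distance")

    ages = {s: (ages_years or {}).get(s, 0.0) for s in ids}

    def subdivide(members: list[str]) -> list[list[str]]:
        members = sorted(members)
        removed: list[str] = []
        while len(members) > 1:
            mean_age = np.mean([ages[s] for s in members])
            dev = [(abs(ages[s] - mean_age), s) for s in members]
            worst = max(dev)  # ties resolved toward lexicographically later id
            if worst[0] <= age_window:
                break
            members.remove(worst[1])
            removed.append(worst[1])
        out = [members] if members else []
        if removed:
            out.extend(subdivide(removed))
        return out

    final: list[list[str]] = []
    for lab in sorted(set(labels)):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        final.extend(subdivide(members))
    final.sort(key=lambda ms: ms[0])
    rows = []
    for k, members in enumerate(final, start=1):
        for s in members:
            rows.append((s, k, ages[s], len(members) < min_size))
    df = pd.DataFrame(rows, columns=["individual", "cluster", "age", "small"])
    return df.set_index("individual").loc[ids]


def outgroup_f3_mds(
    tensor: F2BlockTensor, outgroup: str, k_dims: int = 2
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the 1 - f3(outgroup; i, j) matrix.

    Eigen-decomposition of the double-centred squared-dissimilarity matrix;
    coordinates are ordered by eigenvalue and scaled by sqrt(eigenvalue).
    Axes with negative eigenvalues (non-Euclidean part of the
    dissimilarity) are suppressed; a warning is issued if ``k_dims``
    exceeds the number of positive eigenvalues.
    """
    items = [g for g in tensor.groups if g != outgroup]
    if outgroup not in tensor.groups:
        raise KeyError(f"outgroup {outgroup!r} not in tensor")
    if len(items) < 3:
        raise ValueError("need at least 3 non-outgroup groups for an MDS")
    N = len(items)
    D = np.zeros((N, N))
    for i, a in enumerate(items):
        for j in range(i + 1, N):
            b = items[j]
            f3 = float(
                np.average(f3_blocks(tensor, outgroup, a, b), weights=tensor.weights)
            )
            D[i, j] = D[j, i] = 1.0 - f3
    J = np.eye(N) - np.ones((N, N)) / N
    Bmat = -0.5 * J @ (D**2) @ J
    ev, U = linalg.eigh(Bmat)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    n_pos = int(np.sum(ev > 1e-12 * max(ev.max(), 1)))
    if k_dims > n_pos:
        warnings.warn(
            f"requested {k_dims} dimensions but only {n_pos} positive "
            f"eigenvalues; truncating"
        )
        k_dims = n_pos
    coords = U[:, :k_dims] * np.sqrt(ev[:k_dims])
    out = pd.DataFrame(
        coords, index=items, columns=[f"dim{i + 1}" for i in range(k_dims)]
    )
    out.attrs["eigenvalues"] = ev
    out.attrs["negative_eigenvalues"] = ev[ev < 0]
    return out
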