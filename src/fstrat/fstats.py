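"""Block-partitioned f2-statistics under time stratification.

f2(A, B) measures the squared allele-frequency (or branch-weight)
difference between two groups.  On a genealogy, every branch contributes

    (w_A - w_B)^2 * mu * l_eff * span

where ``w_X`` is the fraction of group X's samples descending from the
branch and ``l_eff`` its length clipped to the ascertainment window
``[t_low, t_high)`` (a branch crossing a threshold contributes only the
portion inside the window).  Restricting to recent branches concentrates
the statistic on recent coalescences, which is where the power for recent
admixture lives.  With the Patterson et al. (2012) sample-size correction
the per-branch summary becomes

    (w_A - w_B)^2 - w_A(1-w_A)/(n_A-1) - w_B(1-w_B)/(n_B-1)

which makes the genotype-, mutation- and branch-mode estimators directly
comparable, and incidentally makes singleton tip branches contribute
exactly zero to cross-group f2.

All statistics are computed per genomic block; derived statistics
(f3/f4/f4-ratio) recombine per-block values and obtain standard errors
with a weighted block jackknife.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tskit

from fstrat.genealogy import GenealogySequence, GenotypeMatrix, PopulationAssignment
from fstrat.jackknife import block_jackknife

__all__ = [
    "AscertainmentSpec",
    "F2BlockTensor",
    "FStatEstimate",
    "make_blocks",
    "f2_blocks_from_genealogy",
    "f2_blocks_from_genotypes",
    "f3_from_f2",
    "f4_from_f2",
    "f4_ratio_alpha",
    "block_jackknife",
    "export_f2",
    "import_f2",
]


@dataclass(frozen=True)
class AscertainmentSpec:
    """How f2-statistics are ascertained.

    Attributes
    ----------
    t_high, t_low
        Upper/lower time cut-offs in generations, measured from the present
        (time 0).  The window is half-open ``[t_low, t_high)``.
    min_daf, max_daf
        Derived-allele-frequency window, computed across all samples of the
        tensor's group set (a single ascertainment per tensor).
    mode
        ``branch`` (clipped branch lengths x mu), ``mutation_age`` (mutations
        whose branch-age midpoint falls in the window) or ``genotype``
        (mutations regardless of age).
    mu
        Mutation rate per bp per generation; used to scale branch-mode f2
        onto the per-bp mutation scale.
    internal_only
        Exclude singleton tip branches (default, for robustness to sample
        age).  Under the sample-size correction these contribute zero to
        cross-group f2 anyway; the flag matters for uncorrected analyses.
    sample_size_correction
        Subtract the finite-sample heterozygosity terms p(1-p)/(n-1).
    """

    t_high: float = math.inf
    t_low: float = 0.0
    min_daf: float = 0.0
    max_daf: float = 1.0
    mode: str = "branch"
    mu: float = 1.25e-8
    internal_only: bool = True
    sample_size_correction: bool = True

    def __post_init__(self):
        if not 0 <= self.t_low < self.t_high:
            raise ValueError(f"need 0 <= t_low < t_high, got [{self.t_low}, {self.t_high})")
        if not 0 <= self.min_daf < 1:
            raise ValueError(f"min_daf must be in [0, 1), got {self.min_daf}")
        if not self.min_daf < self.max_daf <= 1:
            raise ValueError("need min_daf < max_daf <= 1")
        if self.mode not in ("branch", "mutation_age", "genotype"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "branch" and not self.mu > 0:
            raise ValueError("mu must be > 0 in branch mode")


@dataclass
class FStatEstimate:
    """A derived statistic with block-jackknife uncertainty."""

    value: float
    se: float
    n_blocks: int
    definition: str
    warnings: list[str] = field(default_factory=list)

    @property
    def z(self) -> float:
        return self.value / self.se if self.se > 0 else math.inf * np.sign(self.value)

    def __repr__(self):
        return (
            f"{self.definition} = {self.value:.6g} +/- {self.se:.3g} "
            f"(z={self.z:.2f}, blocks={self.n_blocks})"
        )


class F2BlockTensor:
    """Per-block pairwise f2 values for a set of groups.

    ``values`` has shape (P, P, B): per-block f2 between each group pair,
    normalized by block weight (per bp for genealogy tensors, per site for
    genotype tensors).  Each block slice is symmetric with zero diagonal.
    Provenance (the :class:`AscertainmentSpec`) is immutable.
    """

    def __init__(self, groups, values, weights, spec, block_intervals=None):
        self.groups = list(groups)
        self.values = np.asarray(values, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self._spec = spec
        self.block_intervals = (
            np.asarray(block_intervals, dtype=float)
            if block_intervals is not None
            else None
        )
        P, B = len(self.groups), len(self.weights)
        if self.values.shape != (P, P, B):
            raise ValueError(f"values shape {self.values.shape} != {(P, P, B)}")
        if np.any(self.weights <= 0):
            raise ValueError("block weights must be positive")
        if not np.allclose(self.values, self.values.transpose(1, 0, 2)):
            raise ValueError("per-block f2 slices must be symmetric")
        if np.any(np.abs(np.diagonal(self.values, axis1=0, axis2=1)) > 0):
            raise ValueError("per-block f2 diagonal must be zero")

    @property
    def spec(self) -> AscertainmentSpec:
        return self._spec

    @property
    def num_blocks(self) -> int:
        return len(self.weights)

    def index(self, group) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in tensor {self.groups}") from None

    def pair_blocks(self, a, b) -> np.ndarray:
        """Per-block f2 between groups ``a`` and ``b``, shape (B,)."""
        return self.values[self.index(a), self.index(b)]

    def f2(self, a, b) -> FStatEstimate:
        est, se = block_jackknife(self.pair_blocks(a, b), self.weights)
        return FStatEstimate(est, se, self.num_blocks, f"f2({a},{b})")

    def subset(self, groups) -> "F2BlockTensor":
        idx = [self.index(g) for g in groups]
        return F2BlockTensor(
            [self.groups[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.weights,
            self._spec,
            self.block_intervals,
        )


def make_blocks(sequence_length: float, block_size: float = 5e6) -> np.ndarray:
    """Contiguous physical block boundaries covering [0, L)."""
    edges = np.arange(0.0, sequence_length, block_size)
    return np.append(edges, sequence_length)


def blocks_from_rate_map(rate_map, cm_size: float = 5.0) -> np.ndarray:
    """Block boundaries of a given genetic size from an msprime RateMap."""
    L = rate_map.sequence_length
    total_cm = rate_map.get_cumulative_mass(L) * 100
    targets = np.arange(cm_size, total_cm, cm_size) / 100
    # invert the cumulative map by interpolation on its breakpoints
    cum = rate_map.get_cumulative_mass(rate_map.position)
    cuts = np.interp(targets, cum, rate_map.position)
    return np.unique(np.concatenate([[0.0], cuts, [L]]))


def _resolve_blocks(blocks, sequence_length) -> np.ndarray:
    if np.isscalar(blocks):
        return make_blocks(sequence_length, float(blocks))
    edges = np.asarray(blocks, dtype=float)
    if edges.ndim != 1 or len(edges) < 3 or np.any(np.diff(edges) <= 0):
        raise ValueError("block boundaries must be increasing with >=2 blocks")
    return edges


def _group_sample_sets(
    g: GenealogySequence, pops: PopulationAssignment
) -> tuple[list[str], list[np.ndarray]]:
    pops = pops.restrict(g.sample_ids)
    groups = pops.groups
    sets = [g.sample_nodes(pops.members(grp)) for grp in groups]
    for grp, s in zip(groups, sets):
        if len(s) == 0:
            raise ValueError(f"group {grp!r} has no sample in the genealogy")
    return groups, sets


def _pairs(P: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(P) for j in range(i + 1, P)]


def _to_tensor(groups, pair_vals, weights, spec, edges) -> F2BlockTensor:
    """Assemble a (P, P, B) tensor from per-pair per-block values."""
    P, B = len(groups), len(weights)
    values = np.zeros((P, P, B))
    for k, (i, j) in enumerate(_pairs(P)):
        values[i, j] = values[j, i] = pair_vals[k]
    intervals = np.column_stack([edges[:-1], edges[1:]])
    return F2BlockTensor(groups, values, weights, spec, intervals)


# ----------------------------------------------------------------------
# branch mode
# ----------------------------------------------------------------------

def _branch_f2_tskit(ts, sample_sets, spec, edges):
    """Fast path: tskit C branch f2 on a decapitated tree sequence.

    ``decapitate(t)`` truncates every branch crossing time ``t``, which is
    exactly the proportional-truncation rule; subtracting the same
    statistic decapitated at ``t_low`` implements the lower threshold
    (branch contributions are linear in clipped length).
    """
    idx = _pairs(len(sample_sets))

    def stat(threshold):
        tsc = ts if math.isinf(threshold) else ts.decapitate(threshold)
        return tsc.f2(
            sample_sets,
            indexes=idx,
            windows=edges,
            mode="branch",
            span_normalise=False,
        )

    vals = stat(spec.t_high)
    if spec.t_low > 0:
        vals = vals - stat(spec.t_low)
    return vals.T * spec.mu  # (n_pairs, B), per-branch-length -> per-mutation scale


def _interval_overlaps(a, b, edges):
    """bp overlap of [a, b) with each block, shape (B,)."""
    lo = np.maximum(a, edges[:-1])
    hi = np.minimum(b, edges[1:])
    return np.clip(hi - lo, 0.0, None)


def _branch_f2_reference(ts, sample_sets, spec, edges):
    """Per-tree reference implementation (any n, DAF ascertainment, no
    correction).  O(trees x nodes); intended for small inputs and as the
    independent cross-check of the fast path."""
    P = len(sample_sets)
    n = np.array([len(s) for s in sample_sets], dtype=float)
    onehot = np.zeros((ts.num_nodes, P))
    in_union = np.zeros(ts.num_nodes)
    for i, s in enumerate(sample_sets):
        onehot[s, i] = 1.0
        in_union[s] = 1.0
    n_union = in_union.sum()
    times = ts.nodes_time
    B = len(edges) - 1
    acc = np.zeros((len(_pairs(P)), B))
    loc = np.empty(ts.num_nodes, dtype=np.int64)
    pairs = _pairs(P)
    pi = np.array([i for i, _ in pairs])
    pj = np.array([j for _, j in pairs])
    for tree in ts.trees():
        span = _interval_overlaps(tree.interval.left, tree.interval.right, edges)
        if span.sum() == 0:
            continue
        order = tree.postorder()
        m = len(order)
        loc[order] = np.arange(m)
        parent_loc = np.asarray(tree.parent_array)[order]
        has_parent = parent_loc != tskit.NULL
        C = onehot[order].copy()
        U = in_union[order].copy()
        for i in range(m):  # postorder: children precede parents
            p = parent_loc[i]
            if p != tskit.NULL:
                C[loc[p]] += C[i]
                U[loc[p]] += U[i]
        p_times = np.where(has_parent, times[np.where(has_parent, parent_loc, 0)], 0.0)
        l_eff = np.clip(
            np.minimum(p_times, spec.t_high)
            - np.maximum(times[order], spec.t_low),
            0.0, None,
        )
        keep = has_parent & (l_eff > 0)
        if spec.internal_only:
            keep &= np.array([tree.num_samples(u) for u in order]) > 1
        daf = U / n_union
        keep &= (daf >= spec.min_daf) & (daf <= spec.max_daf)
        if not keep.any():
            continue
        w = C[keep] / n
        if spec.sample_size_correction:
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(n > 1, w * (1 - w) / np.maximum(n - 1, 1), 0.0)
        else:
            h = np.zeros_like(w)
        summary = (w[:, pi] - w[:, pj]) ** 2 - h[:, pi] - h[:, pj]
        dens = summary.T @ l_eff[keep]  # (n_pairs,)
        acc += np.outer(dens, span)
    return acc * spec.mu


# ----------------------------------------------------------------------
# mutation modes
# ----------------------------------------------------------------------

def _mutation_midpoint_ages(ts) -> np.ndarray:
    """Branch-age-interval midpoint of the (single) mutation at each site.

    Sites with several stacked mutations or with a mutation above a local
    root get NaN and are excluded from age-ascertained statistics.
    """
    ages = np.full(ts.num_sites, np.nan)
    times = ts.nodes_time
    parents = ts.edges_parent
    for site in ts.sites():
        if len(site.mutations) != 1:
            continue
        mut = site.mutations[0]
        if mut.edge == tskit.NULL:
            continue
        ages[site.id] = 0.5 * (times[mut.node] + times[parents[mut.edge]])
    return ages


def _site_f2_blocks(
    derived, valid_n, positions, groups_cols, edges, spec, site_mask, per_bp
):
    """Aggregate per-site corrected f2 into blocks.

    derived: (S, H) 0/1 with -1 missing; groups_cols: list of column arrays.
    """
    P = len(groups_cols)
    S = derived.shape[0]
    cnt = np.empty((S, P))
    n = np.empty((S, P))
    for i, cols in enumerate(groups_cols):
        sub = derived[:, cols]
        miss = sub < 0
        cnt[:, i] = np.where(miss, 0, sub).sum(axis=1)
        n[:, i] = sub.shape[1] - miss.sum(axis=1)
    ok = site_mask & np.all(n >= 1, axis=1)
    union_cols = np.concatenate(groups_cols)
    usub = derived[:, union_cols]
    umiss = usub < 0
    ucnt = np.where(umiss, 0, usub).sum(axis=1)
    un = usub.shape[1] - umiss.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(un > 0, ucnt / un, 0.0)
    ok &= (daf >= spec.min_daf) & (daf <= spec.max_daf)
    if spec.internal_only:
        ok &= ucnt != 1
    p = cnt / n
    if spec.sample_size_correction:
        for i in range(P):
            if np.any((n[:, i] < 2) & ok):
                nm = np.min(n[ok, i])
                raise ValueError(
                    f"sample-size correction needs n >= 2 haplotypes per group "
                    f"at every site; group index {i} has n = {int(nm)}"
                )
        h = p * (1 - p) / (n - 1)
    else:
        h = np.zeros_like(p)
    block_of = np.searchsorted(edges, positions, side="right") - 1
    B = len(edges) - 1
    in_range = (block_of >= 0) & (block_of < B)
    ok &= in_range
    pair_vals = np.zeros((len(_pairs(P)), B))
    counts_per_block = np.bincount(block_of[ok], minlength=B).astype(float)
    for k, (i, j) in enumerate(_pairs(P)):
        v = (p[:, i] - p[:, j]) ** 2 - h[:, i] - h[:, j]
        pair_vals[k] = np.bincount(block_of[ok], weights=v[ok], minlength=B)
    if per_bp:
        weights = np.diff(edges)
    else:
        weights = np.maximum(counts_per_block, 1e-300)
    return pair_vals / weights, np.diff(edges) if per_bp else counts_per_block


def f2_blocks_from_genealogy(
    g: GenealogySequence,
    pops: PopulationAssignment,
    spec: AscertainmentSpec | None = None,
    blocks=5e6,
) -> F2BlockTensor:
    """Compute the time-stratified per-block f2 tensor from a genealogy.

    In ``branch`` mode each branch contributes its clipped length times mu
    times span; in ``mutation_age`` mode a mutation contributes iff its
    branch-interval midpoint lies in ``[t_low, t_high)``; ``genotype`` mode
    uses all mutations.  Values are per bp, block weights are bp spans.
    """
    spec = spec or AscertainmentSpec()
    ts = g.tree_sequence
    groups, sample_sets = _group_sample_sets(g, pops)
    edges = _resolve_blocks(blocks, ts.sequence_length)

    # groups whose oldest sample is at/above t_high cannot contribute
    ages = {s: a for s, a in zip(g.sample_ids, g.sample_ages)}
    pops_r = pops.restrict(g.sample_ids)
    for grp in groups:
        oldest = max(ages[s] for s in pops_r.members(grp))
        if spec.t_high <= oldest:
            warnings.warn(
                f"group {grp!r}: oldest sample age {oldest:g} >= t_high "
                f"{spec.t_high:g}; the group may contribute nothing"
            )

    if spec.mode == "branch":
        fast = (
            spec.sample_size_correction
            and spec.min_daf == 0
            and spec.max_daf == 1
            and min(len(s) for s in sample_sets) >= 2
        )
        if fast:
            pair_vals = _branch_f2_tskit(ts, sample_sets, spec, edges)
        else:
            pair_vals = _branch_f2_reference(ts, sample_sets, spec, edges)
        weights = np.diff(edges)
        return _to_tensor(groups, pair_vals / weights, weights, spec, edges)

    # mutation-backed modes
    derived = (ts.genotype_matrix() > 0).astype(np.int8)
    positions = ts.sites_position
    if spec.mode == "mutation_age":
        ages_mid = _mutation_midpoint_ages(ts)
        site_mask = (
            np.isfinite(ages_mid)
            & (ages_mid >= spec.t_low)
            & (ages_mid < spec.t_high)
        )
    else:
        site_mask = np.ones(ts.num_sites, dtype=bool)
    sample_order = {int(s): i for i, s in enumerate(ts.samples())}
    group_cols = [
        np.array([sample_order[int(u)] for u in s]) for s in sample_sets
    ]
    pair_vals, weights = _site_f2_blocks(
        derived, None, positions, group_cols, edges, spec, site_mask, per_bp=True
    )
    return _to_tensor(groups, pair_vals, weights, spec, edges)


def f2_blocks_from_genotypes(
    genotypes: GenotypeMatrix,
    pops: PopulationAssignment,
    blocks=5e6,
    min_daf: float = 0.0,
    max_daf: float = 1.0,
    sample_size_correction: bool = True,
) -> F2BlockTensor:
    """Per-block f2 from a polarized haploid genotype matrix.

    Haplotype columns are matched to the assignment either directly by id
    or by stripping a trailing ``_<k>`` haplotype suffix.  Values are per
    site; block weights are per-block used-site counts.
    """
    spec = AscertainmentSpec(
        mode="genotype",
        min_daf=min_daf,
        max_daf=max_daf,
        internal_only=False,
        sample_size_correction=sample_size_correction,
    )

    def owner(hap_id):
        if hap_id in pops.sample_to_group:
            return pops.sample_to_group[hap_id]
        stem = hap_id.rsplit("_", 1)[0]
        return pops.sample_to_group.get(stem)

    col_group = [owner(h) for h in genotypes.haplotype_ids]
    groups = sorted({g for g in col_group if g is not None})
    if not groups:
        raise ValueError("no genotype column matches the population assignment")
    group_cols = [
        np.flatnonzero([cg == grp for cg in col_group]) for grp in groups
    ]
    for grp, cols in zip(groups, group_cols):
        if sample_size_correction and len(cols) < 2:
            raise ValueError(
                f"group {grp!r} has n = {len(cols)} haplotype(s); the sample "
                "size correction requires n >= 2"
            )
    L = float(genotypes.positions[-1]) + 1
    edges = _resolve_blocks(blocks, L)
    site_mask = np.ones(genotypes.matrix.shape[0], dtype=bool)
    pair_vals, weights = _site_f2_blocks(
        genotypes.matrix, None, genotypes.positions, group_cols, edges, spec,
        site_mask, per_bp=False,
    )
    keep = weights > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 blocks contain usable sites")
    P = len(groups)
    values = np.zeros((P, P, int(keep.sum())))
    for k, (i, j) in enumerate(_pairs(P)):
        values[i, j] = values[j, i] = pair_vals[k, keep]
    intervals = np.column_stack([edges[:-1], edges[1:]])[keep]
    return F2BlockTensor(groups, values, weights[keep], spec, intervals)


# ----------------------------------------------------------------------
# derived statistics
# ----------------------------------------------------------------------

def f3_blocks(tensor: F2BlockTensor, O, A, B) -> np.ndarray:
    """Per-block f3(O; A, B) = (f2(O,A) + f2(O,B) - f2(A,B)) / 2."""
    return 0.5 * (
        tensor.pair_blocks(O, A)
        + tensor.pair_blocks(O, B)
        - tensor.pair_blocks(A, B)
    )


def f4_blocks(tensor: F2BlockTensor, A, B, C, D) -> np.ndarray:
    """Per-block f4(A,B; C,D) = (f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)) / 2."""
    return 0.5 * (
        tensor.pair_blocks(A, D)
        + tensor.pair_blocks(B, C)
        - tensor.pair_blocks(A, C)
        - tensor.pair_blocks(B, D)
    )


def f3_from_f2(tensor: F2BlockTensor, O, A, B) -> FStatEstimate:
    est, se = block_jackknife(f3_blocks(tensor, O, A, B), tensor.weights)
    return FStatEstimate(est, se, tensor.num_blocks, f"f3({O};{A},{B})")


def f4_from_f2(tensor: F2BlockTensor, A, B, C, D) -> FStatEstimate:
    est, se = block_jackknife(f4_blocks(tensor, A, B, C, D), tensor.weights)
    return FStatEstimate(est, se, tensor.num_blocks, f"f4({A},{B};{C},{D})")


def f4_ratio_alpha(tensor: F2BlockTensor, PO, P1, P2, PI, PX) -> FStatEstimate:
    """Admixture proportion from the Patterson f4-ratio.

    For PX formed by a pulse of proportion alpha from P2 into P1, with PI a
    non-admixed sister of P1 and PO an outgroup:

        alpha = f4(PI, PO; P1, PX) / f4(PI, PO; P1, P2)

    The standard error is a delete-one-block jackknife of the ratio itself,
    matching the block structure of the underlying f2-statistics.
    """
    names = [PO, P1, P2, PI, PX]
    if len(set(names)) != 5:
        raise ValueError(f"the five groups must be distinct, got {names}")
    num = f4_blocks(tensor, PI, PO, P1, PX)
    den = f4_blocks(tensor, PI, PO, P1, P2)

    def ratio(vals, wts):
        m = wts @ vals / wts.sum()
        return m[0] / m[1]

    est, se = block_jackknife(np.column_stack([num, den]), tensor.weights, ratio)
    out = FStatEstimate(
        est, se, tensor.num_blocks, f"alpha[{PX}={P2}|{P1}; outgroup {PO}, sister {PI}]"
    )
    den_est, den_se = block_jackknife(den, tensor.weights)
    if den_se > 0 and abs(den_est / den_se) < 2:
        out.warnings.append(
            f"denominator f4(PI,PO;P1,P2) has |z| = {abs(den_est / den_se):.2f} < 2; "
            "the ratio is uninformative"
        )
    return out


# ----------------------------------------------------------------------
# on-disk layout: directory of per-pair block vectors + JSON sidecar
# ----------------------------------------------------------------------

_SIDE = "f2_meta.json"


def export_f2(tensor: F2BlockTensor, path) -> Path:
    """Write a tensor as per-pair TSV block vectors plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec_d = asdict(tensor.spec)
    spec_d = {k: (None if isinstance(v, float) and math.isinf(v) else v)
              for k, v in spec_d.items()}
    meta = {
        "format": "fstrat-f2-v1",
        "groups": tensor.groups,
        "weights": [f"{w:.17g}" for w in tensor.weights],
        "block_intervals": (
            tensor.block_intervals.tolist()
            if tensor.block_intervals is not None
            else None
        ),
        "spec": spec_d,
    }
    (path / _SIDE).write_text(json.dumps(meta, indent=1))
    for i, a in enumerate(tensor.groups):
        for j in range(i + 1, len(tensor.groups)):
            b = tensor.groups[j]
            np.savetxt(path / f"f2__{a}__{b}.tsv", tensor.values[i, j], fmt="%.17g")
    return path


def import_f2(path, expect_spec: AscertainmentSpec | None = None) -> F2BlockTensor:
    """Load a tensor written by :func:`export_f2` (lossless round-trip).

    ``expect_spec`` guards against mixing tensors with different
    ascertainment into one analysis: a provenance mismatch is an error.
    """
    path = Path(path)
    side = path / _SIDE
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if meta.get("format") != "fstrat-f2-v1":
        raise ValueError(f"unknown f2 export format {meta.get('format')!r}")
    spec_d = dict(meta["spec"])
    if spec_d.get("t_high") is None:
        spec_d["t_high"] = math.inf
    spec = AscertainmentSpec(**spec_d)
    if expect_spec is not None and spec != expect_spec:
        raise ValueError(
            f"provenance mismatch: stored spec {spec} != expected {expect_spec}"
        )
    groups = meta["groups"]
    weights = np.array([float(w) for w in meta["weights"]])
    P, B = len(groups), len(weights)
    values = np.zeros((P, P, B))
    for i, a in enumerate(groups):
        for j in range(i + 1, P):
            b = groups[j]
            v = np.loadtxt(path / f"f2__{a}__{b}.tsv", ndmin=1)
            values[i, j] = values[j, i] = v
    return F2BlockTensor(groups, values, weights, spec, meta["block_intervals"])
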