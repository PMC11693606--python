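"""Relate-style ``.anc``/``.mut`` text dialect.

Relate emits one marginal tree per line together with a table of mutations
mapped to branches.  Several minor dialect variants exist across versions;
this module reads and writes one documented layout and rejects anything
else loudly.

``.anc`` layout (whitespace separated)::

    NUM_HAPLOTYPES 4
    NUM_TREES 2
    SEQUENCE_LENGTH 1000000
    SAMPLE_AGES 0 0 0 0
    1: 5:(50.0) 5:(50.0) 6:(60.0) 6:(60.0) 7:(50.0) 7:(40.0) -1:(0)
    500001: ...

Each tree line starts with the 1-based bp position where the tree begins,
followed by one ``parent:(branch_length)`` entry per node.  The first
``NUM_HAPLOTYPES`` entries are the haploid samples (ages in generations from
the optional ``SAMPLE_AGES`` header, default 0); the remaining entries are
internal nodes ordered by increasing age.  Branch lengths are in
generations; the root has parent ``-1``.  A tree extends to the start of
the next tree (or ``SEQUENCE_LENGTH``).

``.mut`` layout (semicolon separated, one header line)::

    snp;pos_of_snp;tree;branch;is_mapped;age_begin;age_end;alleles
    0;74212;0;5;1;50.0;100.0;A/G

``branch`` is the node index (in the tree's ``.anc`` line) below the branch
carrying the mutation.  Mutations with ``is_mapped`` 0 (Relate's flag for
unmapped variants) are dropped and counted, since they cannot contribute to
branch-tagged statistics.  Positions are 1-based in both files and converted
to the package's 0-based half-open convention on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tskit

from fstrat.genealogy import GenealogySequence, GenealogyValidationError

_TIME_TOL = 1e-6


class RelateParseError(ValueError):
    """Malformed ``.anc``/``.mut`` content; the message names the line."""


def _resolve_paths(path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".anc":
        anc, mut = path, path.with_suffix(".mut")
    elif path.suffix == ".mut":
        anc, mut = path.with_suffix(".anc"), path
    else:
        anc, mut = path.with_suffix(".anc"), path.with_suffix(".mut")
    if not anc.exists():
        raise FileNotFoundError(anc)
    if not mut.exists():
        raise FileNotFoundError(mut)
    return anc, mut


def _parse_header(lines) -> tuple[dict, int]:
    header = {}
    i = 0
    while i < len(lines) and not lines[i].partition(":")[0].strip().isdigit():
        parts = lines[i].split()
        if len(parts) < 2:
            raise RelateParseError(f".anc line {i + 1}: malformed header {lines[i]!r}")
        header[parts[0]] = parts[1:]
        i += 1
    for key in ("NUM_HAPLOTYPES", "NUM_TREES", "SEQUENCE_LENGTH"):
        if key not in header:
            raise RelateParseError(f".anc header missing {key}")
    return header, i


def _parse_tree_line(line: str, lineno: int, num_haps: int):
    """Return (start_bp0, parents, lengths) for one `.anc` tree line."""
    head, sep, rest = line.partition(":")
    if not sep:
        raise RelateParseError(f".anc line {lineno}: missing 'pos:' prefix")
    try:
        start = int(head) - 1  # 1-based on disk
    except ValueError:
        raise RelateParseError(f".anc line {lineno}: bad start position {head!r}")
    entries = rest.split()
    if len(entries) < num_haps:
        raise RelateParseError(
            f".anc line {lineno}: {len(entries)} node entries for "
            f"{num_haps} haplotypes"
        )
    parents = np.empty(len(entries), dtype=np.int64)
    lengths = np.empty(len(entries), dtype=float)
    for j, ent in enumerate(entries):
        try:
            p, _, ln = ent.partition(":")
            parents[j] = int(p)
            if not (ln.startswith("(") and ln.endswith(")")):
                raise ValueError
            lengths[j] = float(ln[1:-1])
        except ValueError:
            raise RelateParseError(
                f".anc line {lineno}: malformed node entry {ent!r}"
            ) from None
    return start, parents, lengths


def _node_times(parents, lengths, sample_ages, lineno: int) -> np.ndarray:
    """Recover absolute node times from parent pointers and branch lengths."""
    n = len(parents)
    roots = np.flatnonzero(parents == -1)
    if len(roots) != 1:
        raise RelateParseError(f".anc line {lineno}: expected 1 root, got {len(roots)}")
    children: list[list[int]] = [[] for _ in range(n)]
    for u, p in enumerate(parents):
        if p >= 0:
            if p >= n:
                raise RelateParseError(f".anc line {lineno}: parent {p} out of range")
            children[p].append(u)
    depth = np.full(n, np.nan)
    depth[roots[0]] = 0.0
    stack = [int(roots[0])]
    while stack:
        u = stack.pop()
        for c in children[u]:
            depth[c] = depth[u] + lengths[c]
            stack.append(c)
    if np.isnan(depth).any():
        raise RelateParseError(f".anc line {lineno}: disconnected node(s)")
    nh = len(sample_ages)
    root_times = depth[:nh] + sample_ages
    t_root = root_times[0]
    if np.any(np.abs(root_times - t_root) > _TIME_TOL * max(1.0, abs(t_root))):
        raise GenealogyValidationError(
            f".anc line {lineno}: branch lengths inconsistent with sample ages"
        )
    times = t_root - depth
    if np.any(lengths[parents >= 0] <= 0):
        raise GenealogyValidationError(
            f".anc line {lineno}: non-positive branch length (child not younger "
            "than parent)"
        )
    return times


def read_relate(path) -> GenealogySequence:
    """Parse an ``.anc``/``.mut`` pair into a :class:`GenealogySequence`."""
    anc_path, mut_path = _resolve_paths(path)
    lines = [ln.rstrip("\n") for ln in open(anc_path) if ln.strip()]
    header, first_tree = _parse_header(lines)
    num_haps = int(header["NUM_HAPLOTYPES"][0])
    num_trees = int(header["NUM_TREES"][0])
    L = float(header["SEQUENCE_LENGTH"][0])
    ages = (
        np.array([float(x) for x in header["SAMPLE_AGES"]])
        if "SAMPLE_AGES" in header
        else np.zeros(num_haps)
    )
    if len(ages) != num_haps:
        raise RelateParseError(
            f".anc: {len(ages)} sample ages for {num_haps} haplotypes"
        )
    tree_lines = lines[first_tree:]
    if len(tree_lines) != num_trees:
        raise RelateParseError(
            f".anc: header declares {num_trees} trees, found {len(tree_lines)}"
        )

    tables = tskit.TableCollection(sequence_length=L)
    for i in range(num_haps):
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=ages[i])

    starts = []
    tree_node_maps = []  # dialect node index -> tskit node id, per tree
    parsed = []
    for k, line in enumerate(tree_lines):
        start, parents, lengths = _parse_tree_line(
            line, first_tree + k + 1, num_haps
        )
        starts.append(start)
        parsed.append((parents, lengths))
    starts.append(L)
    for k in range(num_trees):
        if starts[k + 1] <= starts[k]:
            raise RelateParseError(
                f".anc: tree start positions not strictly increasing at tree {k}"
            )
    if starts[0] != 0:
        raise RelateParseError(".anc: first tree must start at position 1")

    for k, (parents, lengths) in enumerate(parsed):
        times = _node_times(parents, lengths, ages, first_tree + k + 1)
        node_map = np.empty(len(parents), dtype=np.int64)
        node_map[:num_haps] = np.arange(num_haps)
        for j in range(num_haps, len(parents)):
            node_map[j] = tables.nodes.add_row(time=times[j])
        left, right = starts[k], starts[k + 1]
        for j, p in enumerate(parents):
            if p >= 0:
                tables.edges.add_row(left, right, int(node_map[p]), int(node_map[j]))
        tree_node_maps.append(node_map)

    # ---- mutations -----------------------------------------------------
    dropped = 0
    with open(mut_path) as fh:
        head = fh.readline().strip()
        expected = "snp;pos_of_snp;tree;branch;is_mapped;age_begin;age_end;alleles"
        if head != expected:
            raise RelateParseError(f".mut header {head!r} != {expected!r}")
        records = []
        for lineno, ln in enumerate(fh, start=2):
            if not ln.strip():
                continue
            parts = ln.strip().split(";")
            if len(parts) != 8:
                raise RelateParseError(f".mut line {lineno}: expected 8 fields")
            try:
                pos = int(parts[1]) - 1
                tree_idx = int(parts[2])
                branch = int(parts[3])
                mapped = int(parts[4]) == 1
                alleles = parts[7].split("/")
            except ValueError:
                raise RelateParseError(f".mut line {lineno}: malformed record") from None
            if not mapped or branch < 0:
                dropped += 1
                continue
            if len(alleles) != 2:
                raise RelateParseError(f".mut line {lineno}: bad alleles {parts[7]!r}")
            if not 0 <= pos < L:
                raise GenealogyValidationError(
                    f".mut line {lineno}: position {pos + 1} outside [1, {L:g}]"
                )
            if not 0 <= tree_idx < num_trees:
                raise RelateParseError(
                    f".mut line {lineno}: tree index {tree_idx} out of range "
                    f"(.anc has {num_trees} trees; .anc/.mut mismatch?)"
                )
            if not starts[tree_idx] <= pos < starts[tree_idx + 1]:
                raise GenealogyValidationError(
                    f".mut line {lineno}: position {pos + 1} outside the span of "
                    f"tree {tree_idx}"
                )
            node_map = tree_node_maps[tree_idx]
            if branch >= len(node_map):
                raise RelateParseError(
                    f".mut line {lineno}: branch {branch} out of range for tree "
                    f"{tree_idx} (.anc/.mut mismatch?)"
                )
            records.append((pos, int(node_map[branch]), alleles[0], alleles[1]))

    records.sort()
    last_pos = None
    for pos, node, anc, der in records:
        if pos != last_pos:
            site = tables.sites.add_row(position=pos, ancestral_state=anc)
            last_pos = pos
        tables.mutations.add_row(site=site, node=node, derived_state=der)

    tables.sort()
    try:
        tables.build_index()
        tables.compute_mutation_parents()
        ts = tables.tree_sequence()
    except tskit.LibraryError as e:  # pragma: no cover - defensive
        raise GenealogyValidationError(f"inconsistent genealogy tables: {e}") from e
    return GenealogySequence(
        ts, sample_ids=[str(i) for i in range(num_haps)], sample_ages=ages,
        dropped_mutations=dropped,
    )


def write_relate(g: GenealogySequence, prefix) -> tuple[Path, Path]:
    """Serialize a genealogy to the ``.anc``/``.mut`` dialect.

    Requires every marginal tree to have a single root and all samples
    present in all trees.  Internal nodes are renumbered per tree by
    increasing age (ties by node id), so round-tripping preserves topology,
    times and mutation placements but not tskit node ids.
    """
    prefix = Path(prefix)
    ts = g.tree_sequence
    nh = ts.num_samples
    samples = ts.samples()
    sample_pos = {int(s): i for i, s in enumerate(samples)}

    anc_path = prefix.with_suffix(".anc")
    mut_path = prefix.with_suffix(".mut")
    tree_of_site = np.searchsorted(
        ts.breakpoints(as_array=True), ts.sites_position, side="right"
    ) - 1
    mut_lines = []
    with open(anc_path, "w") as fh:
        fh.write(f"NUM_HAPLOTYPES {nh}\n")
        fh.write(f"NUM_TREES {ts.num_trees}\n")
        fh.write(f"SEQUENCE_LENGTH {ts.sequence_length:.10g}\n")
        fh.write("SAMPLE_AGES " + " ".join(f"{a:.10g}" for a in g.sample_ages) + "\n")
        node_maps = []
        for tree in ts.trees():
            if tree.num_roots != 1:
                raise ValueError(
                    f"tree at [{tree.interval.left:g}, {tree.interval.right:g}) has "
                    f"{tree.num_roots} roots; the dialect requires exactly one"
                )
            internal = sorted(
                (u for u in tree.nodes() if u not in sample_pos),
                key=lambda u: (ts.nodes_time[u], u),
            )
            local = dict(sample_pos)
            for j, u in enumerate(internal, start=nh):
                local[u] = j
            node_maps.append(local)
            entries = [None] * len(local)
            for u, j in local.items():
                p = tree.parent(u)
                if p == tskit.NULL:
                    entries[j] = "-1:(0)"
                else:
                    entries[j] = f"{local[p]}:({tree.branch_length(u):.10g})"
            fh.write(f"{int(tree.interval.left) + 1}: " + " ".join(entries) + "\n")

    for site in ts.sites():
        k = int(tree_of_site[site.id])
        for mut in site.mutations:
            mut_lines.append(
                f"{site.id};{int(site.position) + 1};{k};"
                f"{node_maps[k][mut.node]};1;"
                f"{ts.nodes_time[mut.node]:.10g};"
                f"{ts.nodes_time[ts.edges_parent[mut.edge]]:.10g};"
                f"{site.ancestral_state}/{mut.derived_state}"
            )
    with open(mut_path, "w") as fh:
        fh.write("snp;pos_of_snp;tree;branch;is_mapped;age_begin;age_end;alleles\n")
        fh.write("\n".join(mut_lines) + ("\n" if mut_lines else ""))
    return anc_path, mut_path
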