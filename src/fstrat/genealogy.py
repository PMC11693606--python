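"""Dated genealogies, population labels and genotype input.

The central container is :class:`GenealogySequence`, a thin wrapper around a
:class:`tskit.TreeSequence` carrying string sample identifiers and sample ages
in generations.  Both native ``.trees`` files and the Relate-style ``.anc`` /
``.mut`` text dialect (see :mod:`fstrat.relate`) are loaded into this one
representation; all downstream statistics consume it.

Conventions
-----------
* genomic coordinates are 0-based, half-open; the Relate dialect's 1-based
  positions are converted at the parsing boundary
* node times are in generations before present
* sample ages default to 0 (modern samples) when no metadata is available
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tskit

logger = logging.getLogger(__name__)

#: default years-per-generation used to convert sample ages given in years
YEARS_PER_GENERATION = 28.0


class GenealogyValidationError(ValueError):
    """A genealogy violated a structural invariant (times, spans, mutations)."""


@dataclass
class GenealogySequence:
    """Dated marginal trees with spans, mapped mutations and sample ages.

    Parameters
    ----------
    tree_sequence
        The underlying succinct tree sequence.  Node times are in
        generations; coordinates in bp, 0-based half-open.
    sample_ids
        One string identifier per sample node, in sample-node order.
    sample_ages
        Age of each sample in generations before present.  Defaults to the
        node times of the sample nodes.
    dropped_mutations
        Number of input mutations that could not be mapped to a branch
        (Relate's unmapped flag) and were discarded on read.
    """

    tree_sequence: tskit.TreeSequence
    sample_ids: list[str] = field(default_factory=list)
    sample_ages: np.ndarray | None = None
    dropped_mutations: int = 0

    def __post_init__(self):
        ts = self.tree_sequence
        if not self.sample_ids:
            self.sample_ids = [str(s) for s in ts.samples()]
        if len(self.sample_ids) != ts.num_samples:
            raise GenealogyValidationError(
                f"{len(self.sample_ids)} sample ids for {ts.num_samples} samples"
            )
        if self.sample_ages is None:
            self.sample_ages = ts.nodes_time[ts.samples()].copy()
        self.sample_ages = np.asarray(self.sample_ages, dtype=float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sequence_length(self) -> float:
        return self.tree_sequence.sequence_length

    @property
    def num_samples(self) -> int:
        return self.tree_sequence.num_samples

    @property
    def num_trees(self) -> int:
        return self.tree_sequence.num_trees

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def sample_nodes(self, sample_id_list) -> np.ndarray:
        """Map string sample ids to tskit sample node ids."""
        samples = self.tree_sequence.samples()
        return np.array(
            [samples[self.sample_index(s)] for s in sample_id_list], dtype=np.int32
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`GenealogyValidationError`."""
        ts = self.tree_sequence
        times = ts.nodes_time
        if np.any(times < 0):
            raise GenealogyValidationError("negative node time")
        ep, ec = ts.edges_parent, ts.edges_child
        if np.any(times[ep] <= times[ec]):
            bad = int(np.argmax(times[ep] <= times[ec]))
            raise GenealogyValidationError(
                f"edge {bad}: child (t={times[ec[bad]]}) is not younger than "
                f"parent (t={times[ep[bad]]})"
            )
        pos = ts.sites_position
        if pos.size and (pos.min() < 0 or pos.max() >= ts.sequence_length):
            raise GenealogyValidationError(
                f"mutation position outside [0, {ts.sequence_length:g})"
            )
        # tree spans tiling [0, L) is guaranteed by the tskit container itself
        if not np.all(np.isfinite(self.sample_ages)):
            raise GenealogyValidationError("non-finite sample age")

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"GenealogySequence(n={self.num_samples}, trees={self.num_trees}, "
            f"L={self.sequence_length:g} bp, sites={self.tree_sequence.num_sites})"
        )


@dataclass
class PopulationAssignment:
    """Map of samples to population groups, with per-sample ages.

    ``groups`` is ordered lexicographically so that any tensor built from an
    assignment has a deterministic group order.
    """

    sample_to_group: dict[str, str]
    ages_years: dict[str, float] = field(default_factory=dict)
    years_per_generation: float = YEARS_PER_GENERATION

    def __post_init__(self):
        if not self.sample_to_group:
            raise ValueError("empty population assignment")
        for s, a in self.ages_years.items():
            if not np.isfinite(a):
                raise ValueError(f"non-finite age for sample {s!r}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.sample_to_group.values()))

    def members(self, group: str) -> list[str]:
        out = [s for s, g in self.sample_to_group.items() if g == group]
        if not out:
            raise KeyError(f"empty or unknown group {group!r}")
        return sorted(out)

    def age_years(self, sample: str) -> float:
        return self.ages_years.get(sample, 0.0)

    def age_generations(self, sample: str) -> float:
        return self.age_years(sample) / self.years_per_generation

    def restrict(self, sample_ids) -> "PopulationAssignment":
        """Assignment restricted to samples present in ``sample_ids``."""
        keep = set(sample_ids)
        sub = {s: g for s, g in self.sample_to_group.items() if s in keep}
        if not sub:
            raise ValueError("no assigned sample present in the genealogy")
        return PopulationAssignment(
            sub,
            {s: a for s, a in self.ages_years.items() if s in sub},
            self.years_per_generation,
        )


def _derive_sample_ids(ts: tskit.TreeSequence) -> list[str]:
    """Stable string ids for sample nodes.

    When population metadata carries names (msprime output), samples are
    named ``<population>_h<k>`` with k counting haplotypes within the
    population — the same convention the simulation catalogue uses — so a
    population table written next to a ``.trees`` file stays valid across
    a round trip.  Without metadata, node ids are used.
    """
    names = {}
    for pop in ts.populations():
        md = pop.metadata if isinstance(pop.metadata, dict) else {}
        if isinstance(md, dict) and md.get("name"):
            names[pop.id] = md["name"]
    if not names:
        return [str(s) for s in ts.samples()]
    ids, counters = [], {}
    for s in ts.samples():
        pname = names.get(ts.node(s).population, f"pop{ts.node(s).population}")
        k = counters.get(pname, 0)
        counters[pname] = k + 1
        ids.append(f"{pname}_h{k}")
    return ids


def load_tree_sequence(path, format: str = "trees") -> GenealogySequence:
    """Load a dated genealogy from disk.

    Parameters
    ----------
    path
        For ``format="trees"`` a tskit ``.trees`` file; for
        ``format="relate"`` either the ``.anc`` file or the common prefix of
        the ``.anc``/``.mut`` pair.
    """
    path = Path(path)
    if format == "trees":
        if not path.exists():
            raise FileNotFoundError(path)
        ts = tskit.load(str(path))
        return GenealogySequence(ts, sample_ids=_derive_sample_ids(ts))
    if format == "relate":
        from fstrat import relate

        return relate.read_relate(path)
    raise ValueError(f"unknown genealogy format {format!r}")


def load_population_table(
    path, genealogy: GenealogySequence | None = None
) -> tuple[PopulationAssignment, list[str]]:
    """Read a ``sample<TAB>group<TAB>age`` table.

    ``age`` is in years before present (0 for modern samples).  When a
    genealogy is supplied, samples absent from it are reported in the second
    return value (and excluded from the assignment) rather than silently
    dropped.

    Returns
    -------
    (assignment, missing)
        ``missing`` lists table samples not found in the genealogy.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    required = {"sample", "group"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"population table must have columns sample, group[, age]; got "
            f"{list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in population table")
    ages = (
        dict(zip(df["sample"], df["age"].astype(float)))
        if "age" in df.columns
        else {}
    )
    assignment = PopulationAssignment(dict(zip(df["sample"], df["group"])), ages)
    missing: list[str] = []
    if genealogy is not None:
        present = set(genealogy.sample_ids)
        missing = [s for s in df["sample"] if s not in present]
        if missing:
            warnings.warn(
                f"{len(missing)} table sample(s) absent from the genealogy: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
            kept = assignment.restrict(present)
            for g in assignment.groups:
                if g not in kept.groups:
                    raise ValueError(
                        f"group {g!r} has no sample present in the genealogy"
                    )
            assignment = kept
    return assignment, missing


@dataclass
class GenotypeMatrix:
    """Polarized haploid derived-allele counts at biallelic sites.

    ``matrix`` has shape (num_sites, num_haplotypes) with entries 0/1 and
    ``-1`` flagging missing haploid genotypes (never imputed here).
    """

    matrix: np.ndarray
    positions: np.ndarray
    haplotype_ids: list[str]
    skipped_multiallelic: int = 0

    @property
    def missing(self) -> np.ndarray:
        return self.matrix < 0


def load_genotypes(path, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic genotypes from a VCF into a haplotype 0/1 matrix.

    Diploid entries contribute two haplotype columns (``<id>_0``,
    ``<id>_1``); haploid entries one.  Multi-allelic records are skipped
    (counted in ``skipped_multiallelic``); missing genotypes are flagged
    as -1.  The REF allele is taken as ancestral.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, samples=samples, gts012=False)
    if samples:
        found = set(vcf.samples)
        absent = [s for s in samples if s not in found]
        if absent:
            raise ValueError(f"samples not found in VCF: {absent}")
    rows = []
    positions = []
    skipped = 0
    ploidy = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        g = np.array(rec.genotype.array(), dtype=np.int16)  # (n, ploidy+1)
        alleles = g[:, :-1]
        if ploidy is None:
            ploidy = alleles.shape[1]
        row = alleles.reshape(-1).astype(np.int8)
        rows.append(row)
        positions.append(rec.POS - 1)  # VCF is 1-based
    if not rows:
        raise ValueError(f"no biallelic site in {path}")
    matrix = np.vstack(rows)
    matrix[matrix < 0] = -1
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("VCF site positions are not strictly increasing")
    hap_ids = [f"{s}_{k}" for s in vcf.samples for k in range(ploidy)]
    if skipped:
        logger.info("skipped %d multi-allelic site(s) in %s", skipped, path)
    return GenotypeMatrix(matrix, positions, hap_ids, skipped)
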