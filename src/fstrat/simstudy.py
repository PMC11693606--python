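"""Coalescent simulation catalogue and experiment harness.

Every scenario used to validate the estimators is generated here with
msprime, so the whole package is testable without external data.  The
catalogue covers:

* ``f4ratio`` (+ ``_bottleneck``/``_lowmu``/``_largeN`` variants): five
  populations PO, P1, P2, PI, PX; PO splits 10,000 generations ago, the
  proxy sources P1/P2 split 250 or 500 generations ago, PI splits from P1
  100 generations ago and PX is formed by a pulse between P1 and P2 50
  generations ago (P2 contributing proportion alpha).  Constant diploid
  size 5,000, hotspot-like recombination map, mu = 1.25e-8, 20 haploid
  sequences per population.
* ``qpadm_ref23`` (+ ``_div5``): a rotating-reference admixture model in
  which the sources split 1,200 generations ago and admixture occurs 40
  generations ago (all times divided by 5 in the ``_div5`` variant).
* ``stepping_stone``: nine populations on a 1D grid with symmetric
  adjacent migration (0.001 or 0.005).
* ``neanderthal_pulse`` / ``neanderthal_deep``: archaic admixture 2,000
  generations ago versus long-standing deep structure with symmetric
  migration until 3,000 generations ago; archaic/modern split 25,000,
  two archaic populations splitting 7,000 generations ago, archaic
  diploid size 3,000, modern 10,000.
* ``finescale_grid``: 25 demes on a 5x5 grid (deme size 500, migration
  0.01, structure emerging 100 generations ago from an ancestral
  population of 10,000), plus an outgroup panel splitting at the same
  time.
* ``panmictic`` and ``qpwave_calibration``: controls for closed-form
  diversity and null-calibration checks.

Default sequence length is 50 Mb with a deterministic hotspot-like
recombination map; experiments scale the length down further where the
scientific claim does not depend on it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from fstrat.fstats import (
    AscertainmentSpec,
    f2_blocks_from_genealogy,
    f4_from_f2,
    f4_ratio_alpha,
)
from fstrat.genealogy import GenealogySequence, GenotypeMatrix, PopulationAssignment

__all__ = [
    "ScenarioConfig",
    "ErrorModel",
    "CATALOG",
    "build_scenario",
    "simulate",
    "scenario_assignment",
    "genotypes_from_genealogy",
    "apply_error_model",
    "predicted_r2",
    "power_study",
    "summarize_power",
    "optimal_cutoff",
    "nnls_alpha",
    "stepping_stone_model_selection",
    "neanderthal_f4_contrast",
    "hotspot_recombination_map",
]

_SEED_MOD = 2**31 - 2


def subseed(seed: int, k: int) -> int:
    """Counter-based derivation of per-task seeds from one base seed."""
    return (seed * 1_000_003 + 7919 * k) % _SEED_MOD + 1


# ----------------------------------------------------------------------
# scenario configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved simulation scenario.

    Events are expressed in the coalescent (backward-time) convention:
    ``splits`` merge derived populations into an ancestral one at a time in
    generations; ``pulses`` are instantaneous admixture events; migrations
    are symmetric adjacent rates.  ``truth`` carries scenario ground truth
    (admixture proportion, split time, ...) for downstream experiments.
    """

    scenario: str
    populations: tuple[tuple[str, float], ...]  # (name, diploid size)
    splits: tuple[tuple[float, tuple[str, ...], str], ...]  # (time, derived, anc)
    pulses: tuple[tuple[float, str, tuple[str, ...], tuple[float, ...]], ...]
    #: pulses into a population that persists afterwards:
    #: (time, recipient, donor, proportion), forward-time reading
    mass_migrations: tuple[tuple[float, str, str, float], ...] = ()
    migrations: tuple[tuple[str, str, float], ...] = ()
    migration_changes: tuple[tuple[float, str, str, float], ...] = ()
    size_changes: tuple[tuple[float, str, float], ...] = ()
    samples: tuple[tuple[str, int, float], ...] = ()  # (pop, n_haploids, time)
    sequence_length: float = 50e6
    recombination: str = "hotspot"  # "uniform" | "hotspot"
    mutation_rate: float = 1.25e-8
    truth: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if not self.mutation_rate > 0:
            raise ValueError("mutation rate must be > 0 (branch mode needs mu)")
        if self.sequence_length <= 0:
            raise ValueError("sequence length must be positive")
        for t, *_ in self.splits:
            if t <= 0:
                raise ValueError("split times must be positive")
        for _, _, _, props in self.pulses:
            if not math.isclose(sum(props), 1.0):
                raise ValueError("pulse proportions must sum to 1")
            if any(not 0 <= p <= 1 for p in props):
                raise ValueError("pulse proportions must be in [0, 1]")
        if self.recombination not in ("uniform", "hotspot"):
            raise ValueError(f"unknown recombination map {self.recombination!r}")

    @property
    def truth_dict(self) -> dict[str, float]:
        return dict(self.truth)

    def demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name, size in self.populations:
            dem.add_population(name=name, initial_size=size)
        for a, b, rate in self.migrations:
            dem.set_symmetric_migration_rate([a, b], rate)
        for t, pop, size in self.size_changes:
            dem.add_population_parameters_change(
                time=t, population=pop, initial_size=size
            )
        for t, a, b, rate in self.migration_changes:
            dem.add_symmetric_migration_rate_change(
                time=t, populations=[a, b], rate=rate
            )
        for t, derived, anc_pops, props in self.pulses:
            dem.add_admixture(
                time=t, derived=derived, ancestral=list(anc_pops),
                proportions=list(props),
            )
        for t, recipient, donor, prop in self.mass_migrations:
            # forward-time pulse donor -> recipient; backward in time,
            # recipient lineages jump to the donor with this probability
            dem.add_mass_migration(
                time=t, source=recipient, dest=donor, proportion=prop
            )
        for t, derived, anc in self.splits:
            dem.add_population_split(time=t, derived=list(derived), ancestral=anc)
        dem.sort_events()
        return dem


def hotspot_recombination_map(
    sequence_length: float,
    mean_rate: float = 1.2e-8,
    hotspot_spacing: float = 60e3,
    hotspot_width: float = 2e3,
    hotspot_intensity: float = 12.0,
) -> msprime.RateMap:
    """Deterministic hotspot-like recombination map.

    A flat background punctuated by ~2 kb hotspots every ~60 kb with
    12x-elevated rate, mimicking the punctate structure of a human
    chromosome map; rescaled so the mean rate equals ``mean_rate``.  The
    layout is generated from a fixed internal seed so every simulation at
    a given length sees the same map.
    """
    rng = np.random.default_rng(987654321)
    edges = [0.0]
    rates = []
    pos = 0.0
    while pos < sequence_length:
        gap = rng.exponential(hotspot_spacing - hotspot_width)
        start = min(pos + gap, sequence_length)
        if start > pos:
            edges.append(start)
            rates.append(1.0)
            pos = start
        if pos >= sequence_length:
            break
        end = min(pos + hotspot_width, sequence_length)
        intensity = hotspot_intensity * rng.lognormal(0.0, 0.5)
        edges.append(end)
        rates.append(intensity)
        pos = end
    rates = np.array(rates)
    widths = np.diff(edges)
    rates *= mean_rate / np.average(rates, weights=widths)
    return msprime.RateMap(position=np.array(edges), rate=rates)


def _f4ratio(
    alpha=0.3,
    split_time=500.0,
    n_hap=20,
    Ne=5000.0,
    mu=1.25e-8,
    sequence_length=50e6,
    bottleneck=False,
    extra_outgroups=0,
    scenario="f4ratio",
) -> ScenarioConfig:
    # explicit ancestor chain: sampled populations are always leaves
    pops = [("PO", Ne), ("P1", Ne), ("P2", 1000.0 if bottleneck else Ne),
            ("PI", Ne), ("PX", Ne), ("A1", Ne), ("A12", Ne), ("ANC", Ne)]
    splits = [
        (100.0, ("P1", "PI"), "A1"),
        (split_time, ("A1", "P2"), "A12"),
        (10000.0, ("A12", "PO"), "ANC"),
    ]
    samples = [(p, n_hap, 0.0) for p in ("PO", "P1", "P2", "PI", "PX")]
    size_changes = [(50.0, "P2", Ne)] if bottleneck else []
    for i in range(extra_outgroups):
        name = f"O{i + 2}"
        anc = f"AO{i + 2}"
        pops.insert(-1, (name, Ne))
        pops.insert(-1, (anc, Ne))
        prev = "A12" if i == 0 else f"AO{i + 1}"
        # successively deeper outgroups along the main lineage
        splits[-1] = (splits[-1][0], (anc, "PO"), "ANC")
        splits.insert(-1, (4000.0 + 1500.0 * i, (prev, name), anc))
        samples.append((name, n_hap, 0.0))
    return ScenarioConfig(
        scenario=scenario,
        populations=tuple(pops),
        splits=tuple(splits),
        pulses=((50.0, "PX", ("P1", "P2"), (1 - alpha, alpha)),),
        size_changes=tuple(size_changes),
        samples=tuple(samples),
        sequence_length=sequence_length,
        mutation_rate=mu,
        truth=(("alpha", alpha), ("split_time", split_time),
               ("admixture_time", 50.0)),
    )


def _qpadm_ref23(factor=1.0, n_hap=20, Ne=5000.0, sequence_length=50e6):
    f = factor
    leaf = ["O", "R1", "R2", "R3", "R4", "R5", "S1", "S2", "T"]
    pops = [(p, Ne) for p in leaf]
    # ladder of ancestors up the main lineage leading to the sources
    splits = [(1200.0 / f, ("S1", "S2"), "AS")]
    prev = "AS"
    for t, r in [(1350.0, "R5"), (1500.0, "R4"), (1800.0, "R3"),
                 (2400.0, "R2"), (3000.0, "R1")]:
        anc = f"A{r}"
        splits.append((t / f, (prev, r), anc))
        prev = anc
    splits.append((6000.0 / f, (prev, "O"), "ANC"))
    pops += [(s[2], Ne) for s in splits]
    return ScenarioConfig(
        scenario="qpadm_ref23" if factor == 1 else "qpadm_ref23_div5",
        populations=tuple(pops),
        splits=tuple(splits),
        pulses=((40.0 / f, "T", ("S1", "S2"), (0.5, 0.5)),),
        samples=tuple((p, n_hap, 0.0) for p in leaf),
        sequence_length=sequence_length,
        truth=(("alpha", 0.5), ("admixture_time", 40.0 / f),
               ("split_time", 1200.0 / f)),
    )


def _stepping_stone(migration=0.001, n_demes=9, Ne=5000.0, split=2000.0,
                    n_hap=20, sequence_length=50e6):
    demes = [f"D{i}" for i in range(n_demes)]
    pops = [(d, Ne) for d in demes] + [("ANC", Ne)]
    migrations = [(demes[i], demes[i + 1], migration) for i in range(n_demes - 1)]
    return ScenarioConfig(
        scenario="stepping_stone",
        populations=tuple(pops),
        splits=((split, tuple(demes), "ANC"),),
        pulses=(),
        migrations=tuple(migrations),
        samples=tuple((d, n_hap, 0.0) for d in demes),
        sequence_length=sequence_length,
        truth=(("migration", migration), ("split_time", split)),
    )


def _neanderthal(deep=False, migration=1e-4, admix_prop=0.03,
                 sequence_length=50e6):
    """Archaic pulse vs deep-structure scenario.

    Both variants share: modern/archaic split 25,000 generations ago, two
    archaic populations (VIN closer to the admixing source, ALT) splitting
    7,000 generations ago, archaic diploid size 3,000, modern 10,000, and
    an outgroup OUT splitting 40,000 generations ago.  The pulse variant
    sends ``admix_prop`` from VIN into the non-African population NOA
    2,000 generations ago; the deep variant instead connects the two
    modern subgroups by symmetric migration from 30,000 until 3,000
    generations before present.
    """
    Nh, Nn = 10000.0, 3000.0
    pops = [("AFR", Nh), ("NOA", Nh), ("VIN", Nn), ("ALT", Nn), ("NEA", Nn),
            ("OUT", Nh), ("HUM", Nh), ("ANC", Nh), ("ROOT", Nh)]
    if deep:
        # NOA's lineage joins the NEA lineage at 25,000 via a founding
        # pulse (NEA emerges from NOA's subgroup); the two modern
        # subgroups exchange migrants between 3,000 and 30,000 gens BP
        splits = [
            (7000.0, ("VIN", "ALT"), "NEA"),
            (30000.0, ("AFR", "NOA"), "ANC"),
            (40000.0, ("ANC", "OUT"), "ROOT"),
        ]
        mass = ((25000.0, "NEA", "NOA", 1.0),)
        changes = ((3000.0, "AFR", "NOA", migration),)
    else:
        splits = [
            (3000.0, ("AFR", "NOA"), "HUM"),
            (7000.0, ("VIN", "ALT"), "NEA"),
            (25000.0, ("HUM", "NEA"), "ANC"),
            (40000.0, ("ANC", "OUT"), "ROOT"),
        ]
        mass = ((2000.0, "NOA", "VIN", admix_prop),)
        changes = ()
    return ScenarioConfig(
        scenario="neanderthal_deep" if deep else "neanderthal_pulse",
        populations=tuple(pops),
        splits=tuple(splits),
        pulses=(),
        mass_migrations=mass,
        migration_changes=changes,
        samples=(("AFR", 20, 0.0), ("NOA", 20, 0.0), ("VIN", 2, 1700.0),
                 ("ALT", 2, 4000.0), ("OUT", 4, 0.0)),
        sequence_length=sequence_length,
        truth=(("admix_prop", 0.0 if deep else admix_prop),
               ("migration", migration if deep else 0.0)),
    )


def _finescale(n_side=5, migration=0.01, deme_Ne=500.0, anc_Ne=10000.0,
               split=100.0, n_hap=4, n_out=200, sequence_length=50e6):
    demes = [f"G{i}{j}" for i in range(n_side) for j in range(n_side)]
    pops = [(d, deme_Ne) for d in demes] + [("OUTP", anc_Ne), ("ANC", anc_Ne)]
    migs = []
    for i in range(n_side):
        for j in range(n_side):
            if i + 1 < n_side:
                migs.append((f"G{i}{j}", f"G{i + 1}{j}", migration))
            if j + 1 < n_side:
                migs.append((f"G{i}{j}", f"G{i}{j + 1}", migration))
    return ScenarioConfig(
        scenario="finescale_grid",
        populations=tuple(pops),
        splits=((split, tuple(demes) + ("OUTP",), "ANC"),),
        pulses=(),
        migrations=tuple(migs),
        samples=tuple((d, n_hap, 0.0) for d in demes) + (("OUTP", n_out, 0.0),),
        sequence_length=sequence_length,
        truth=(("split_time", split), ("migration", migration)),
    )


def _panmictic(Ne=5000.0, n_hap=40, sequence_length=10e6):
    return ScenarioConfig(
        scenario="panmictic",
        populations=(("P", Ne),),
        splits=(),
        pulses=(),
        samples=(("P", n_hap, 0.0),),
        sequence_length=sequence_length,
        truth=(("Ne", Ne),),
    )


def _qpwave_calibration(Ne=5000.0, sequence_length=20e6):
    """One panmictic 'left' pool plus six diverged right groups."""
    rights = [f"R{i}" for i in range(1, 7)]
    pops = [("L", Ne)] + [(r, Ne) for r in rights]
    # each right group is founded from the left lineage at a staggered time
    mass = tuple(
        (2000.0 + 1000.0 * i, r, "L", 1.0) for i, r in enumerate(rights)
    )
    return ScenarioConfig(
        scenario="qpwave_calibration",
        populations=tuple(pops),
        splits=(),
        pulses=(),
        mass_migrations=mass,
        samples=(("L", 40, 0.0),) + tuple((r, 10, 0.0) for r in rights),
        sequence_length=sequence_length,
        truth=(),
    )


CATALOG = {
    "f4ratio": lambda **kw: _f4ratio(**kw),
    "f4ratio_bottleneck": lambda **kw: _f4ratio(
        bottleneck=True, scenario="f4ratio_bottleneck", **kw
    ),
    "f4ratio_lowmu": lambda **kw: _f4ratio(
        mu=4e-9, scenario="f4ratio_lowmu", **kw
    ),
    "f4ratio_largeN": lambda **kw: _f4ratio(
        n_hap=100, scenario="f4ratio_largeN", **kw
    ),
    "qpadm_ref23": lambda **kw: _qpadm_ref23(**kw),
    "qpadm_ref23_div5": lambda **kw: _qpadm_ref23(factor=5.0, **kw),
    "stepping_stone": lambda **kw: _stepping_stone(**kw),
    "neanderthal_pulse": lambda **kw: _neanderthal(deep=False, **kw),
    "neanderthal_deep": lambda **kw: _neanderthal(deep=True, **kw),
    "finescale_grid": lambda **kw: _finescale(**kw),
    "panmictic": lambda **kw: _panmictic(**kw),
    "qpwave_calibration": lambda **kw: _qpwave_calibration(**kw),
}


def build_scenario(catalog_id: str, **overrides) -> ScenarioConfig:
    """Materialize a catalogue scenario, optionally overriding parameters."""
    if catalog_id not in CATALOG:
        raise ValueError(
            f"unknown scenario {catalog_id!r}; catalogue: {sorted(CATALOG)}"
        )
    return CATALOG[catalog_id](**overrides)


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------

def simulate(config: ScenarioConfig, seed: int) -> GenealogySequence:
    """Simulate a scenario: genealogy with mutations, deterministic in seed."""
    dem = config.demography()
    sample_sets = []
    for pop, n_hap, time in config.samples:
        if n_hap % 2 == 0:
            sample_sets.append(
                msprime.SampleSet(n_hap // 2, population=pop, time=time, ploidy=2)
            )
        else:
            sample_sets.append(
                msprime.SampleSet(n_hap, population=pop, time=time, ploidy=1)
            )
    if config.recombination == "hotspot":
        kwargs = dict(
            recombination_rate=hotspot_recombination_map(config.sequence_length)
        )
    else:
        kwargs = dict(
            recombination_rate=1.2e-8, sequence_length=config.sequence_length
        )
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        random_seed=subseed(seed, 1),
        **kwargs,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, random_seed=subseed(seed, 2)
    )
    ids = []
    counters: dict[str, int] = {}
    pop_names = {p.id: p.name for p in dem.populations}
    for s in ts.samples():
        pname = pop_names[ts.node(s).population]
        k = counters.get(pname, 0)
        counters[pname] = k + 1
        ids.append(f"{pname}_h{k}")
    return GenealogySequence(ts, sample_ids=ids)


def scenario_assignment(
    g: GenealogySequence, per_individual: bool = False
) -> PopulationAssignment:
    """Population (or per-diploid-individual) labels for simulated samples."""
    mapping = {}
    for sid in g.sample_ids:
        pop, h = sid.rsplit("_h", 1)
        if per_individual:
            mapping[sid] = f"{pop}_i{int(h) // 2}"
        else:
            mapping[sid] = pop
    return PopulationAssignment(mapping)


def genotypes_from_genealogy(g: GenealogySequence) -> GenotypeMatrix:
    """Derived-allele haplotype matrix of all mutations in the genealogy."""
    ts = g.tree_sequence
    matrix = (ts.genotype_matrix() > 0).astype(np.int8)
    return GenotypeMatrix(
        matrix, ts.sites_position.astype(np.int64), list(g.sample_ids)
    )


# ----------------------------------------------------------------------
# genotype/phasing error model
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Symmetric haploid genotype flips plus optional phase-switch errors.

    Per diploid individual, a flip probability is drawn uniformly on
    ``[e_min, e_max]`` (errors per SNP per haplotype) and applied
    independently to every haploid genotype; this emulates the residual
    error of imputed ancient genomes.  With ``phase_switches=True`` the two
    haplotypes of each individual are re-phased with switch points at rate
    ``switch_rate_per_cm`` per cM (default one switch per 5 cM, a
    pessimistic stand-in for reference-free rephasing), using a uniform
    1 cM/Mb genetic map.
    """

    e_min: float = 1e-4
    e_max: float = 1e-3
    phase_switches: bool = False
    switch_rate_per_cm: float = 0.2

    def __post_init__(self):
        if not 0 <= self.e_min <= self.e_max <= 0.5:
            raise ValueError("need 0 <= e_min <= e_max <= 0.5")


def apply_error_model(
    genotypes: GenotypeMatrix, model: ErrorModel, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Apply the error model; returns the new matrix and drawn per-individual
    error rates (one per haplotype column, identical within a pair)."""
    rng = np.random.default_rng(subseed(seed, 11))
    M = genotypes.matrix.copy()
    S, H = M.shape
    e_hap = np.empty(H)
    for start in range(0, H - H % 2, 2):
        e_hap[start:start + 2] = rng.uniform(model.e_min, model.e_max)
    if H % 2:
        e_hap[-1] = rng.uniform(model.e_min, model.e_max)
    flips = rng.random((S, H)) < e_hap[None, :]
    valid = M >= 0
    M[valid & flips] = 1 - M[valid & flips]
    if model.phase_switches and H >= 2:
        cm_pos = genotypes.positions / 1e6  # 1 cM per Mb
        total_cm = cm_pos[-1] if len(cm_pos) else 0.0
        for start in range(0, H - H % 2, 2):
            n_sw = rng.poisson(model.switch_rate_per_cm * total_cm)
            if n_sw == 0:
                continue
            sw = np.sort(rng.uniform(0, total_cm, n_sw))
            phase = np.searchsorted(sw, cm_pos) % 2 == 1
            a, b = M[:, start].copy(), M[:, start + 1].copy()
            M[phase, start], M[phase, start + 1] = b[phase], a[phase]
    return (
        GenotypeMatrix(M, genotypes.positions, list(genotypes.haplotype_ids)),
        e_hap,
    )


def predicted_r2(e: float, maf: float) -> float:
    """Squared correlation between true and error-bearing haploid genotypes.

    For symmetric flips with probability e at allele frequency p:

        r^2 = p (1 - p) (1 - 2e)^2 / (q (1 - q)),   q = p(1-e) + (1-p)e
    """
    if not 0 <= e <= 0.5:
        raise ValueError("e must be in [0, 0.5]")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if e == 0.5:
        return 0.0
    p = maf
    q = p * (1 - e) + (1 - p) * e
    return p * (1 - p) * (1 - 2 * e) ** 2 / (q * (1 - q))


# ----------------------------------------------------------------------
# estimators and the power study
# ----------------------------------------------------------------------

def nnls_alpha(
    g: GenealogySequence, target_pop="PX", source_pops=("P1", "P2"),
    blocks=1e6,
) -> tuple[float, float]:
    """Admixture proportion of the second source via painting + NNLS.

    Paints the target and both sources against the sources as reference
    populations, fits the target profile as a mixture, and jackknifes the
    per-block profiles for a standard error.
    """
    from fstrat.painting import nnls_admixture, population_profile

    pops = scenario_assignment(g)
    refs = list(source_pops)
    profs = {
        p: population_profile(g, p, refs, pops, blocks=blocks)
        for p in [target_pop, *source_pops]
    }

    def fit_beta(avec_t, avec_s):
        A = np.column_stack(avec_s)
        return nnls_admixture(avec_t, A).weights[1]

    beta = fit_beta(profs[target_pop].a, [profs[p].a for p in source_pops])
    # delete-one-block jackknife over painting blocks
    bw = profs[target_pop].block_weights
    keep = bw > 0
    B = int(keep.sum())
    if B < 2:
        return float(beta), float("nan")

    def del_profile(prof, b_idx):
        w = prof.block_weights[keep]
        av = prof.block_a[keep]
        num = (av * w[:, None]).sum(axis=0) - av[b_idx] * w[b_idx]
        return num / (w.sum() - w[b_idx])

    betas = np.array([
        fit_beta(
            del_profile(profs[target_pop], b),
            [del_profile(profs[p], b) for p in source_pops],
        )
        for b in range(B)
    ])
    # weighted pseudo-value jackknife on the delete-one-block refits
    w = profs[target_pop].block_weights[keep]
    W = w.sum()
    h = W / w
    theta_J = B * beta - np.sum((1 - w / W) * betas)
    tau = h * beta - (h - 1) * betas
    var = np.sum((tau - theta_J) ** 2 / (h - 1)) / B
    return float(beta), float(np.sqrt(max(var, 0.0)))


_ESTIMATORS = (
    "genotype",
    "twigstats_branch",
    "twigstats_mutation",
    "rare_variant",
    "nnls",
)


def _alpha_from_tensor(tensor):
    est = f4_ratio_alpha(tensor, "PO", "P1", "P2", "PI", "PX")
    return est.value, est.se


def power_study(
    config: ScenarioConfig,
    cutoff_grid,
    estimators=("genotype", "twigstats_branch"),
    replicates: int = 20,
    seed: int = 1,
    block_size: float = 1e6,
) -> pd.DataFrame:
    """Admixture-proportion estimation across estimators and time cut-offs.

    Returns a tidy frame with one row per (replicate, estimator, cutoff):
    columns ``alpha_hat``, ``se`` (block jackknife) and ``flagged`` (cutoff
    below the admixture time, the expected-bias regime).  Cut-offs are
    ignored by the cutoff-independent estimators (genotype, rare_variant,
    nnls), which appear once per replicate with cutoff NaN.
    """
    unknown = set(estimators) - set(_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator(s) {sorted(unknown)}")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    cutoff_grid = [float(c) for c in cutoff_grid]
    admix_time = config.truth_dict.get("admixture_time", 0.0)
    rows = []
    for rep in range(replicates):
        g = simulate(config, subseed(seed, 100 + rep))
        pops = scenario_assignment(g)
        for est_name in estimators:
            if est_name == "genotype":
                spec = AscertainmentSpec(mode="genotype")
                a, s = _alpha_from_tensor(
                    f2_blocks_from_genealogy(g, pops, spec, blocks=block_size)
                )
                rows.append((rep, est_name, np.nan, a, s, False))
            elif est_name == "rare_variant":
                spec = AscertainmentSpec(mode="genotype", max_daf=0.05)
                a, s = _alpha_from_tensor(
                    f2_blocks_from_genealogy(g, pops, spec, blocks=block_size)
                )
                rows.append((rep, est_name, np.nan, a, s, False))
            elif est_name == "nnls":
                a, s = nnls_alpha(g, blocks=block_size)
                rows.append((rep, est_name, np.nan, a, s, False))
            else:
                mode = "branch" if est_name == "twigstats_branch" else "mutation_age"
                for cutoff in cutoff_grid:
                    spec = AscertainmentSpec(
                        t_high=cutoff, mode=mode, mu=config.mutation_rate
                    )
                    a, s = _alpha_from_tensor(
                        f2_blocks_from_genealogy(g, pops, spec, blocks=block_size)
                    )
                    rows.append(
                        (rep, est_name, cutoff, a, s, cutoff < admix_time)
                    )
    return pd.DataFrame(
        rows,
        columns=["rep", "estimator", "cutoff", "alpha_hat", "se", "flagged"],
    )


def summarize_power(table: pd.DataFrame) -> pd.DataFrame:
    """Per (estimator, cutoff) means and fold improvement vs genotype mode."""
    grp = table.groupby(["estimator", "cutoff"], dropna=False)
    out = grp.agg(
        mean_alpha=("alpha_hat", "mean"),
        mean_se=("se", "mean"),
        sd_alpha=("alpha_hat", "std"),
        n=("alpha_hat", "size"),
    ).reset_index()
    base = out.loc[out.estimator == "genotype", "mean_se"]
    if len(base):
        out["fold_improvement"] = float(base.iloc[0]) / out["mean_se"]
    else:
        out["fold_improvement"] = np.nan
    return out


def optimal_cutoff(summary: pd.DataFrame, estimator="twigstats_branch"):
    """Cut-off with minimal mean s.e. (ties toward the smaller cut-off).

    Input is the output of :func:`summarize_power` (needs >= 3 finite
    cut-offs).  Returns ``(cutoff, fold_improvement)``; if the minimum sits
    on the grid boundary a warning is attached (no interior minimum).
    """
    sub = summary[
        (summary.estimator == estimator) & np.isfinite(summary.cutoff)
    ].sort_values("cutoff")
    if len(sub) < 3:
        raise ValueError("need at least 3 cut-off grid points")
    i = int(np.argmin(sub.mean_se.to_numpy()))  # argmin takes first = smallest
    row = sub.iloc[i]
    if i in (0, len(sub) - 1):
        warnings.warn(
            "s.e. minimum on the grid boundary; no interior optimum found"
        )
    return float(row.cutoff), float(row.fold_improvement)


# ----------------------------------------------------------------------
# stepping-stone model selection & archaic contrast
# ----------------------------------------------------------------------

def stepping_stone_model_selection(
    migration: float,
    replicates: int = 10,
    seed: int = 1,
    mode: str | tuple = "genotype",
    t_high: float = 1000.0,
    sequence_length: float = 50e6,
    block_size: float = 1e6,
    target: str = "D3",
) -> dict:
    """Rotational qpAdm over all source pairs in the 1D stepping-stone model.

    Fits the target population with every pair of the remaining demes as
    sources (unused demes as references) and scores a replicate as correct
    when the model using the two immediately adjacent demes attains the
    highest p-value.  Following the rotational protocol, models with
    weights outside [0, 1] are removed before ranking: in a 1D gradient,
    bracketing pairs fit the target by linear extrapolation with
    infeasible weights and would otherwise rank spuriously well.  Ranking
    uses the log scale, which stays exact where every model is strongly
    rejected.

    ``mode`` is ``genotype`` (plain f-statistics), ``branch``
    (time-stratified at ``t_high``), or a tuple of both — the modes then
    share the same simulated replicates.  Returns a dict per mode (or the
    single mode's dict) with ``fraction_correct`` and per-replicate detail.
    """
    from fstrat.admixture import rotational_qpadm

    modes = (mode,) if isinstance(mode, str) else tuple(mode)
    config = build_scenario(
        "stepping_stone", migration=migration, sequence_length=sequence_length
    )
    idx = int(target[1:])
    adjacent = {f"D{idx - 1}", f"D{idx + 1}"}
    per_rep = {m: [] for m in modes}
    for rep in range(replicates):
        g = simulate(config, subseed(seed, 300 + rep))
        pops = scenario_assignment(g)
        pool = [p for p in pops.groups if p != target]
        for m in modes:
            if m == "genotype":
                spec = AscertainmentSpec(mode="genotype")
            else:
                spec = AscertainmentSpec(mode="branch", t_high=t_high,
                                         mu=config.mutation_rate)
            tensor = f2_blocks_from_genealogy(g, pops, spec, blocks=block_size)
            res = rotational_qpadm(tensor, target, pool, max_sources=2)
            pair_fits = [f for f in res["fits"] if len(f.sources) == 2]
            feasible = [f for f in pair_fits if f.feasible] or pair_fits
            best = max(feasible, key=lambda f: f.log10_p, default=None)
            correct = best is not None and set(best.sources) == adjacent
            adj = next(
                (f for f in pair_fits if set(f.sources) == adjacent), None
            )
            per_rep[m].append(
                {
                    "rep": rep,
                    "best_sources": tuple(best.sources) if best else None,
                    "best_p": best.p_value if best else np.nan,
                    "best_log10_p": best.log10_p if best else np.nan,
                    "adjacent_log10_p": adj.log10_p if adj else np.nan,
                    "correct": bool(correct),
                }
            )
    out = {
        m: {
            "migration": migration,
            "mode": m,
            "fraction_correct": float(np.mean([r["correct"] for r in per_rep[m]])),
            "replicates": per_rep[m],
        }
        for m in modes
    }
    return out[modes[0]] if isinstance(mode, str) else out


def neanderthal_f4_contrast(
    deep: bool, seed: int, sequence_length: float = 50e6,
    t_recent: float = 10000.0, block_size: float = 1e6,
) -> dict:
    """Archaic-affinity f4 in a recent stratum versus genome-wide.

    Computes f4(AFR, NOA; VIN, OUT) on branches restricted to
    ``[0, t_recent)`` and unrestricted.  Under a genuine archaic pulse the
    signal survives restriction to recent strata (introgressed lineages
    coalesce into the archaic clade soon after the pulse); under deep
    structure all shared drift predates the modern/archaic split and the
    recent stratum is empty of signal.
    """
    config = build_scenario(
        "neanderthal_deep" if deep else "neanderthal_pulse",
        sequence_length=sequence_length,
    )
    g = simulate(config, seed)
    pops = scenario_assignment(g)
    out = {}
    for label, spec in [
        ("recent", AscertainmentSpec(mode="branch", t_high=t_recent,
                                     mu=config.mutation_rate)),
        ("all", AscertainmentSpec(mode="branch", mu=config.mutation_rate)),
    ]:
        tensor = f2_blocks_from_genealogy(g, pops, spec, blocks=block_size)
        est = f4_from_f2(tensor, "AFR", "NOA", "VIN", "OUT")
        out[label] = {"f4": est.value, "se": est.se, "z": est.z}
    out["recent_fraction"] = (
        out["recent"]["f4"] / out["all"]["f4"] if out["all"]["f4"] != 0 else np.nan
    )
    return out
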