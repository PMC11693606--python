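"""f2 engine: closed forms, stratification, jackknife, derived statistics."""

import math

import numpy as np
import pytest

from fstrat.fstats import (
    AscertainmentSpec,
    F2BlockTensor,
    _branch_f2_reference,
    _branch_f2_tskit,
    export_f2,
    f2_blocks_from_genealogy,
    f2_blocks_from_genotypes,
    f3_from_f2,
    f4_blocks,
    f4_from_f2,
    f4_ratio_alpha,
    import_f2,
    make_blocks,
)
from fstrat.genealogy import GenotypeMatrix, PopulationAssignment
from fstrat.jackknife import block_jackknife, jackknife_mean_and_cov

MU = 1.25e-8


def uncorrected(**kw):
    kw.setdefault("mu", MU)
    kw.setdefault("sample_size_correction", False)
    kw.setdefault("internal_only", False)
    return AscertainmentSpec(**kw)


class TestBranchClosedForms:
    """Two haploid lineages with TMRCA T: f2 = 2 mu min(T, t_high) per bp."""

    @pytest.mark.parametrize(
        "t_high,internal_only,expected",
        [
            (math.inf, False, 2 * MU * 100),
            (50.0, False, 2 * MU * 50),  # proportional truncation
            (math.inf, True, 0.0),  # both branches are singleton tips
        ],
    )
    def test_two_leaf(self, two_leaf, two_pop_assignment, t_high,
                      internal_only, expected):
        spec = uncorrected(t_high=t_high, internal_only=internal_only)
        tensor = f2_blocks_from_genealogy(
            two_leaf, two_pop_assignment, spec, blocks=5e5
        )
        assert tensor.f2("A", "B").value == pytest.approx(expected, rel=1e-12)

    def test_lower_threshold_subtracts(self, two_leaf, two_pop_assignment):
        spec = uncorrected(t_low=30.0, t_high=80.0)
        tensor = f2_blocks_from_genealogy(
            two_leaf, two_pop_assignment, spec, blocks=5e5
        )
        assert tensor.f2("A", "B").value == pytest.approx(2 * MU * 50, rel=1e-12)

    def test_balanced_four_grouping(self, balanced_four):
        # groups = the two cherries; only internal branches u (50..100) and
        # v (60..100) separate them with weight difference 1
        pops = PopulationAssignment(
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        )
        spec = uncorrected(internal_only=True)
        tensor = f2_blocks_from_genealogy(balanced_four, pops, spec, blocks=5e5)
        assert tensor.f2("A", "B").value == pytest.approx(
            MU * (50 + 40), rel=1e-12
        )


class TestDualRouteEquivalence:
    """The tskit fast path and the per-tree reference path must agree."""

    @pytest.mark.parametrize("t_high", [math.inf, 700.0, 150.0])
    def test_fast_vs_reference(self, f4ratio_tiny_sim, t_high):
        _, g, pops = f4ratio_tiny_sim
        ts = g.tree_sequence
        groups = pops.groups
        sets = [g.sample_nodes(pops.members(x)) for x in groups]
        edges = make_blocks(ts.sequence_length, 5e5)
        spec = AscertainmentSpec(t_high=t_high, mu=MU)
        fast = _branch_f2_tskit(ts, sets, spec, edges)
        ref = _branch_f2_reference(ts, sets, spec, edges)
        assert np.allclose(fast, ref, rtol=1e-9, atol=1e-18)

    def test_monotone_in_time_window(self, f4ratio_sim):
        _, g, pops = f4ratio_sim
        vals = []
        for t_high in [200.0, 500.0, 1000.0, math.inf]:
            spec = AscertainmentSpec(t_high=t_high, mu=MU)
            tensor = f2_blocks_from_genealogy(g, pops, spec, blocks=5e6)
            vals.append(tensor.pair_blocks("P1", "P2").mean())
        assert np.all(np.diff(vals) >= 0)
        lowcut = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(t_low=200.0, mu=MU), blocks=5e6
        ).pair_blocks("P1", "P2").mean()
        assert lowcut <= vals[-1]

    def test_branch_matches_mutation_oracle(self, f4ratio_sim):
        """Branch-mode f2 * mu equals mutation-count f2 in expectation."""
        _, g, pops = f4ratio_sim
        tb = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mu=MU), blocks=2e6
        )
        tm = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="genotype"), blocks=2e6
        )
        for a, b in [("P1", "P2"), ("PO", "PX"), ("PI", "P2")]:
            eb = tb.f2(a, b)
            em = tm.f2(a, b)
            se = math.hypot(eb.se, em.se)
            assert abs(eb.value - em.value) < 3 * se

    def test_genotype_mode_equals_matrix_route(self, f4ratio_sim):
        """mode='genotype' on the genealogy and the GenotypeMatrix route see
        the same sites; per-block normalization differs (bp span vs site
        count), so block totals match exactly and ratios near-exactly."""
        from fstrat.simstudy import genotypes_from_genealogy

        _, g, pops = f4ratio_sim
        t1 = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="genotype"), blocks=5e6
        )
        t2 = f2_blocks_from_genotypes(
            genotypes_from_genealogy(g), pops, blocks=5e6
        )
        # identical per-block totals once un-normalized
        tot1 = t1.values * t1.weights  # per-bp values x bp weights
        tot2 = t2.values * t2.weights  # per-site values x site counts
        assert np.allclose(tot1, tot2, rtol=1e-9)
        a1 = f4_ratio_alpha(t1, "PO", "P1", "P2", "PI", "PX")
        a2 = f4_ratio_alpha(t2, "PO", "P1", "P2", "PI", "PX")
        assert a1.value == pytest.approx(a2.value, abs=0.02)


class TestGenotypeMode:
    def test_fixated_difference_gives_f2_one(self):
        # two sites in two blocks, A fixed derived, B fixed ancestral
        matrix = np.zeros((2, 20), dtype=np.int8)
        matrix[:, :10] = 1
        gm = GenotypeMatrix(matrix, np.array([10, 150]), [f"h{i}" for i in range(20)])
        pops = PopulationAssignment(
            {f"h{i}": ("A" if i < 10 else "B") for i in range(20)}
        )
        tensor = f2_blocks_from_genotypes(gm, pops, blocks=100.0)
        est = tensor.f2("A", "B")
        assert est.value == pytest.approx(1.0)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_same_source_frequencies_give_zero(self):
        """Two independent samples from one frequency vector: corrected f2
        is unbiased around 0."""
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.05, 0.95, size=2000)
        matrix = (rng.random((2000, 40)) < freqs[:, None]).astype(np.int8)
        gm = GenotypeMatrix(
            matrix, np.sort(rng.choice(10**6, 2000, replace=False)),
            [f"h{i}" for i in range(40)],
        )
        pops = PopulationAssignment(
            {f"h{i}": ("A" if i < 20 else "B") for i in range(40)}
        )
        tensor = f2_blocks_from_genotypes(gm, pops, blocks=1e5)
        est = tensor.f2("A", "B")
        assert abs(est.value) < 3 * est.se

    def test_n1_with_correction_is_error(self):
        matrix = np.ones((4, 3), dtype=np.int8)
        gm = GenotypeMatrix(matrix, np.arange(4) * 100, ["a", "b", "c"])
        pops = PopulationAssignment({"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError, match="'B'"):
            f2_blocks_from_genotypes(gm, pops, blocks=150.0)

    def test_rare_variant_ascertainment_drops_common_sites(self, f4ratio_sim):
        _, g, pops = f4ratio_sim
        t_all = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="genotype"), blocks=5e6
        )
        t_rare = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="genotype", max_daf=0.05), blocks=5e6
        )
        # rare-variant f2 is computed from far fewer sites, hence smaller
        assert t_rare.pair_blocks("P1", "P2").mean() < (
            t_all.pair_blocks("P1", "P2").mean()
        )


class TestMutationAgeMode:
    def test_age_window_partitions_signal(self, f4ratio_sim):
        _, g, pops = f4ratio_sim
        young = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="mutation_age", t_high=500.0),
            blocks=5e6,
        )
        old = f2_blocks_from_genealogy(
            g, pops,
            AscertainmentSpec(mode="mutation_age", t_low=500.0), blocks=5e6,
        )
        full = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(mode="mutation_age"), blocks=5e6
        )
        total = young.values + old.values
        # midpoint dating excludes multi-mutation sites in all three the
        # same way, so the two windows partition the full statistic
        assert np.allclose(total, full.values, rtol=1e-9, atol=1e-15)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            AscertainmentSpec(t_low=100, t_high=50)
        with pytest.raises(ValueError):
            AscertainmentSpec(min_daf=1.2)
        with pytest.raises(ValueError):
            AscertainmentSpec(mode="branch", mu=0.0)
        with pytest.raises(ValueError):
            AscertainmentSpec(mode="nope")


class TestJackknife:
    def test_two_block_closed_form(self):
        est, se = block_jackknife(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert (est, se) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_blocks(self):
        est, se = block_jackknife(np.full(7, 3.5), np.arange(1.0, 8.0))
        assert est == pytest.approx(3.5)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=12)
        w = rng.uniform(0.5, 2.0, size=12)
        a = block_jackknife(v, w)
        b = block_jackknife(v, 10 * w)
        assert a == pytest.approx(b)

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife(np.array([1.0]), np.array([1.0]))

    def test_vector_cov_matches_scalar(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(20, 3))
        w = rng.uniform(0.5, 2.0, size=20)
        est, cov = jackknife_mean_and_cov(v, w)
        for k in range(3):
            e1, s1 = block_jackknife(v[:, k], w)
            assert est[k] == pytest.approx(e1)
            assert math.sqrt(cov[k, k]) == pytest.approx(s1)


def synthetic_tensor(groups, pair_value, n_blocks=4, noise=0.0, seed=0):
    """Constant (or jittered) tensor with f2(a, b) = pair_value[(a, b)]."""
    rng = np.random.default_rng(seed)
    P = len(groups)
    values = np.zeros((P, P, n_blocks))
    for i in range(P):
        for j in range(i + 1, P):
            key = (groups[i], groups[j])
            v = pair_value.get(key, pair_value.get(key[::-1]))
            row = v + noise * rng.normal(size=n_blocks)
            values[i, j] = values[j, i] = row
    return F2BlockTensor(
        groups, values, np.ones(n_blocks), AscertainmentSpec(mode="genotype")
    )


class TestDerivedStatistics:
    def test_f3_outgroup_formula(self):
        tensor = synthetic_tensor(
            ["O", "X1", "X2"],
            {("O", "X1"): 0.2, ("O", "X2"): 0.4, ("X1", "X2"): 0.1},
        )
        est = f3_from_f2(tensor, "O", "X1", "X2")
        assert est.value == pytest.approx(0.25)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_identity_cases(self):
        tensor = synthetic_tensor(
            ["O", "A", "C", "D"],
            {p: v for p, v in zip(
                [("A", "C"), ("A", "D"), ("A", "O"), ("C", "D"), ("C", "O"),
                 ("D", "O")], [0.3, 0.5, 0.7, 0.2, 0.4, 0.6])},
            noise=0.01, seed=3,
        )
        assert f3_from_f2(tensor, "O", "A", "A").value == pytest.approx(
            tensor.f2("O", "A").value
        )
        assert f4_from_f2(tensor, "A", "A", "C", "D").value == pytest.approx(0.0)

    def test_f4_symmetries_exact(self):
        tensor = synthetic_tensor(
            ["A", "B", "C", "D"],
            {p: v for p, v in zip(
                [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
                 ("C", "D")], [0.11, 0.23, 0.31, 0.17, 0.29, 0.13])},
            noise=0.05, seed=4,
        )
        ab_cd = f4_blocks(tensor, "A", "B", "C", "D")
        assert np.allclose(ab_cd, -f4_blocks(tensor, "A", "B", "D", "C"), rtol=1e-12)
        assert np.allclose(ab_cd, f4_blocks(tensor, "C", "D", "A", "B"), rtol=1e-12)
        assert np.allclose(ab_cd, -f4_blocks(tensor, "B", "A", "C", "D"), rtol=1e-12)

    def test_f4_ratio_copy_endpoints(self, f4ratio_sim):
        """Relabelling halves of a source as the 'admixed' group pins alpha
        at 0 (for P1) or 1 (for P2)."""
        _, g, _ = f4ratio_sim

        def relabelled(split_pop):
            mapping = {}
            for sid in g.sample_ids:
                pop, h = sid.rsplit("_h", 1)
                if pop == "PX":
                    continue  # drop the real admixed group
                if pop == split_pop and int(h) >= 10:
                    mapping[sid] = "PX"
                else:
                    mapping[sid] = pop
            return PopulationAssignment(mapping)

        spec = AscertainmentSpec(mu=MU)
        t1 = f2_blocks_from_genealogy(g, relabelled("P1"), spec, blocks=2e6)
        est0 = f4_ratio_alpha(t1, "PO", "P1", "P2", "PI", "PX")
        assert abs(est0.value - 0.0) < 2 * est0.se + 0.02
        t2 = f2_blocks_from_genealogy(g, relabelled("P2"), spec, blocks=2e6)
        est1 = f4_ratio_alpha(t2, "PO", "P1", "P2", "PI", "PX")
        assert abs(est1.value - 1.0) < 2 * est1.se + 0.02

    def test_f4_ratio_recovers_truth(self, f4ratio_sim):
        cfg, g, pops = f4ratio_sim
        tensor = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(t_high=700.0, mu=MU), blocks=1e6
        )
        est = f4_ratio_alpha(tensor, "PO", "P1", "P2", "PI", "PX")
        truth = cfg.truth_dict["alpha"]
        assert abs(est.value - truth) < 3 * est.se

    def test_distinctness_required(self, f4ratio_sim):
        _, _, pops = f4ratio_sim
        tensor = synthetic_tensor(
            ["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1}
        )
        with pytest.raises(ValueError, match="distinct"):
            f4_ratio_alpha(tensor, "A", "B", "C", "A", "B")


class TestExportImport:
    def test_round_trip_bitwise(self, f4ratio_sim, tmp_path):
        _, g, pops = f4ratio_sim
        tensor = f2_blocks_from_genealogy(
            g, pops, AscertainmentSpec(t_high=500.0, mu=MU), blocks=5e6
        )
        export_f2(tensor, tmp_path / "f2dir")
        back = import_f2(tmp_path / "f2dir")
        assert back.groups == tensor.groups
        assert np.array_equal(back.values, tensor.values)
        assert np.array_equal(back.weights, tensor.weights)
        assert back.spec == tensor.spec

    def test_layout_three_groups(self, tmp_path):
        tensor = synthetic_tensor(
            ["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 2, ("B", "C"): 3}
        )
        out = export_f2(tensor, tmp_path / "d")
        pair_files = sorted(p.name for p in out.glob("f2__*.tsv"))
        assert pair_files == ["f2__A__B.tsv", "f2__A__C.tsv", "f2__B__C.tsv"]
        assert (out / "f2_meta.json").exists()

    def test_missing_sidecar_errors(self, tmp_path):
        tensor = synthetic_tensor(["A", "B"], {("A", "B"): 1})
        out = export_f2(tensor, tmp_path / "d")
        (out / "f2_meta.json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            import_f2(out)

    def test_provenance_mismatch_errors(self, tmp_path):
        tensor = synthetic_tensor(["A", "B"], {("A", "B"): 1})
        out = export_f2(tensor, tmp_path / "d")
        with pytest.raises(ValueError, match="provenance"):
            import_f2(out, expect_spec=AscertainmentSpec(t_high=100.0))
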