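"""Generator correctness: family births, sequence evolution, counts, reads."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirevol.analysis import stage_correlation
from mirevol.divergence import p_distance
from mirevol.expression import map_reads, count_to_hairpins
from mirevol.simulate import (
    ContaminantSpec,
    SimulationConfig,
    emit_reads,
    evolve_ortholog_pair,
    evolve_sequence,
    random_hairpin,
    simulate_dataset,
    simulate_expression,
    simulate_families,
)


class TestSimulateFamilies:
    def test_terminal_branch_births_all_rank_1(self):
        cfg = SimulationConfig(n_families=40, birth_rates={"N1": 1.0}, seed=3)
        fams, presence, tree = simulate_families(cfg)
        assert (fams.age_rank == 1).all()
        assert set(presence.columns[presence.iloc[0] == 1]) == {
            "D.virilis", "D.melanogaster"}

    def test_root_births_present_everywhere(self):
        cfg = SimulationConfig(n_families=40, birth_rates={"N7": 1.0}, seed=3)
        fams, presence, tree = simulate_families(cfg)
        assert (fams.age_rank == 7).all()
        assert (presence == 1).all().all()

    def test_zero_birth_rate_rejected(self):
        cfg = SimulationConfig(birth_rates={"N1": 0.0})
        with pytest.raises(ValueError):
            simulate_families(cfg)

    def test_branch_counts_within_multinomial_3sigma(self):
        n = 1000
        cfg = SimulationConfig(n_families=n, seed=11)
        fams, _, _ = simulate_families(cfg)
        total = sum(cfg.birth_rates.values())
        counts = fams.origin_node.str.split("|").str[0].value_counts()
        for name, rate in cfg.birth_rates.items():
            p = rate / total
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(name, 0) - n * p) <= 3 * sigma


class TestEvolveOrtholog:
    def test_zero_rates_identity(self, rng):
        cfg = SimulationConfig(region_rates={"seed": 0, "mature": 0, "outside": 0})
        hp = random_hairpin(90, rng)
        ortholog, true = evolve_ortholog_pair(hp, cfg.regions(), cfg, rng)
        assert ortholog == hp
        assert all(v == 0 for v in true.values())

    def test_saturation_approaches_three_quarters(self, rng):
        """At 10 subs/site the chain is fully randomized: expected mismatch
        fraction is 0.75 (Jukes-Cantor-style saturation)."""
        a = random_hairpin(4000, rng)
        b = evolve_sequence(a, 10.0, 2.0, rng)
        p, _, _ = p_distance(a, b)
        assert p == pytest.approx(0.75, abs=0.03)

    def test_seed_slower_than_loop_over_replicates(self, rng):
        cfg = SimulationConfig()  # seed rate 0.06 < outside rate 0.35
        regions = cfg.regions()
        seed_ps, out_ps = [], []
        from mirevol.divergence import region_slice
        seed_mask = region_slice(regions, "seed")
        out_mask = region_slice(regions, "outside_mature")
        for _ in range(500):
            hp = random_hairpin(cfg.hairpin_length, rng)
            ortholog, _ = evolve_ortholog_pair(hp, regions, cfg, rng)
            seed_ps.append(p_distance(hp, ortholog, seed_mask)[0])
            out_ps.append(p_distance(hp, ortholog, out_mask)[0])
        assert np.mean(seed_ps) < np.mean(out_ps)

    def test_true_distances_reported_per_region(self, rng):
        cfg = SimulationConfig()
        hp = random_hairpin(cfg.hairpin_length, rng)
        _, true = evolve_ortholog_pair(hp, cfg.regions(), cfg, rng, rate_scale=0.5)
        assert true["seed"] == pytest.approx(0.03)
        assert true["outside_mature"] == pytest.approx(0.175)
        assert true["seed"] < true["mature"] < true["outside_mature"]
        # hairpin rate is the length-weighted mean of the per-site rates
        n, n_mat, n_seed = cfg.hairpin_length, 44, 12
        hp_rate = (0.03 * n_seed + 0.06 * (n_mat - n_seed) + 0.175 * (n - n_mat)) / n
        assert true["hairpin"] == pytest.approx(hp_rate)


class TestSimulateExpression:
    def _truth(self, n, rng):
        return pd.DataFrame(
            {"true_hairpin_rate": rng.uniform(0.02, 0.4, size=n)},
            index=[f"m{i}" for i in range(n)])

    def test_null_association_near_zero(self, rng):
        cfg = SimulationConfig(assoc_strength=0.0, conservation_bias=0.0,
                               library_depth=200_000, seed=5)
        truth = self._truth(200, rng)
        matrix, _ = simulate_expression(truth, cfg, np.random.default_rng(5))
        rhos = [stage_correlation(matrix, truth.true_hairpin_rate, s)[0]
                for s in matrix.stages]
        assert max(abs(r) for r in rhos) < 0.2  # ~ 2.8 sigma at n=200

    def test_early_bias_least_negative_at_first_stage(self, default_dataset):
        ds = default_dataset
        div = ds.truth["true_hairpin_rate"]
        rhos = {s: stage_correlation(ds.matrix, div, s)[0] for s in ds.matrix.stages}
        assert max(rhos, key=rhos.get) == ds.matrix.stages[0]

    def test_mean_zero_mirna_absent_everywhere(self, rng):
        cfg = SimulationConfig(library_depth=50_000, seed=9)
        truth = self._truth(50, rng)
        matrix, means = simulate_expression(
            truth, cfg, np.random.default_rng(9), mean_zero={"m0"})
        assert (matrix.counts.loc["m0"] == 0).all()
        assert (means.loc["m0"] == 0).all()

    def test_library_totals_near_depth(self, default_dataset):
        # library totals fluctuate around the target depth with a CV set by
        # the NB dispersion over the handful of dominant microRNAs
        totals = default_dataset.matrix.mirna_mapped
        depth = default_dataset.config.library_depth
        assert ((totals - depth).abs() / depth < 0.35).all()
        assert abs(totals.mean() - depth) / depth < 0.15

    def test_genome_mapped_exceeds_mirna_mapped(self, default_dataset):
        m = default_dataset.matrix
        assert (m.genome_mapped > m.mirna_mapped).all()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=-0.1).validate()


class TestEmitReads:
    def test_single_mirna_seven_reads(self):
        counts = pd.DataFrame({"lib1": [7]}, index=["m1"])
        from mirevol.expression import ExpressionMatrix
        matrix = ExpressionMatrix(counts=counts.astype(float))
        libs, decoys = emit_reads(matrix, {"m1": "ACGTACGTACGTACGTACGTAC"})
        assert libs["lib1"] == ["ACGTACGTACGTACGTACGTAC"] * 7
        assert decoys == {}

    def test_mature_length_validated(self):
        counts = pd.DataFrame({"lib1": [1]}, index=["m1"])
        from mirevol.expression import ExpressionMatrix
        matrix = ExpressionMatrix(counts=counts.astype(float))
        with pytest.raises(ValueError):
            emit_reads(matrix, {"m1": "ACGT"})  # 4 nt < 19

    def test_round_trip_recovers_matrix(self, rng):
        cfg = SimulationConfig(n_families=25, library_depth=3000, seed=21)
        ds = simulate_dataset(cfg)
        libs, _ = emit_reads(ds.matrix, ds.mature, rng)
        records = {s: map_reads(reads, ds.loci_ref) for s, reads in libs.items()}
        rebuilt = count_to_hairpins(records, ds.loci_ref,
                                    stages=list(ds.matrix.counts.columns))
        pd.testing.assert_frame_equal(
            rebuilt.counts, ds.matrix.counts, check_dtype=False)

    def test_contaminants_sized_by_fraction(self, rng):
        counts = pd.DataFrame({"lib1": [100]}, index=["m1"])
        from mirevol.expression import ExpressionMatrix
        matrix = ExpressionMatrix(counts=counts.astype(float))
        spec = ContaminantSpec(frac_short=0.1, frac_long=0.05, frac_multimap=0.02)
        libs, decoys = emit_reads(matrix, {"m1": "A" * 22}, rng, spec)
        lens = pd.Series([len(r) for r in libs["lib1"]]).value_counts()
        assert lens[18] == 10 and lens[30] == 5
        assert len(decoys) == 5  # multimap bait present in 5 decoy loci
        assert lens[22] == 100 + 2


def test_dataset_is_seed_deterministic():
    a = simulate_dataset(SimulationConfig(n_families=30, library_depth=10_000, seed=4))
    b = simulate_dataset(SimulationConfig(n_families=30, library_depth=10_000, seed=4))
    assert a.loci_ref == b.loci_ref
    assert a.loci_partner == b.loci_partner
    pd.testing.assert_frame_equal(a.matrix.counts, b.matrix.counts)
    pd.testing.assert_frame_equal(a.truth, b.truth)
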