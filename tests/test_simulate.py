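import numpy as np
import pytest

import uvtx
from uvtx.genome import ParameterError
from uvtx.lesions import StateError, expected_readthrough, lesion_density, place_lesions
from uvtx.repair import assign_removal_times, genotype_presets
from uvtx.simulate import (
    SimulationConfig,
    arrest_position,
    sample_reads,
    simulate_bru_window,
    simulate_experiment,
)


def _assigned(gene, density, genotype, seed, **preset_kw):
    fld = place_lesions(gene, density, seed=seed)
    return assign_removal_times(fld, gene, genotype_presets(genotype, **preset_kw), seed=seed)


@pytest.fixture
def cfg():
    return SimulationConfig(reads_per_condition=100_000, tau_step=0.25)


class TestBruWindow:
    def test_undamaged_short_gene_covered_uniformly(self, cfg):
        # 30 kbp gene, 45 kbp of travel per window: steady-state coverage is
        # rate * window per bp, i.e. rate * window * bin_width mass per bin
        gene = uvtx.Gene("u", "chr1", 0, 30_000, "+", basal_rate=2.0)
        mass = simulate_bru_window(gene, _assigned(gene, 0.0, "NONE", 0), 0.0, cfg)
        expected = 2.0 * cfg.label_window * cfg.bin_width
        np.testing.assert_allclose(mass, expected, rtol=0.02)

    def test_permanent_arrest_truncates_coverage_at_the_lesion(self, cfg):
        # single unrepaired lesion at 10 kbp: full coverage before it
        # (every polymerase still crosses [0, 10k) inside some window),
        # zero strictly beyond
        gene = uvtx.Gene("l", "chr1", 0, 30_000, "+", basal_rate=1.0)
        fld = uvtx.LesionField("l", np.array([10_000.0]), np.array([]), 1e-5,
                               removal_assigned=True)
        mass = simulate_bru_window(gene, fld, 0.0, cfg)
        expected = 1.0 * cfg.label_window * cfg.bin_width
        np.testing.assert_allclose(mass[:20], expected, rtol=0.02)
        np.testing.assert_allclose(mass[20:], 0.0, atol=expected * 1e-9)

    def test_no_repair_means_no_recovery(self, cfg):
        gene = uvtx.Gene("n", "chr1", 0, 120_000, "+", basal_rate=1.0)
        fld = _assigned(gene, lesion_density(10.0), "NONE", 5)
        m0 = simulate_bru_window(gene, fld, 0.0, cfg)
        m24 = simulate_bru_window(gene, fld, 24.0, cfg)
        np.testing.assert_allclose(m24, m0, rtol=1e-9, atol=1e-9)

    def test_repaired_lesion_no_longer_blocks(self, cfg):
        # wave at 5 kbp/h clears a 5 kbp lesion by 1 h; at 2 h coverage is
        # indistinguishable from undamaged
        gene = uvtx.Gene("r", "chr1", 0, 30_000, "+", basal_rate=1.0)
        fld = uvtx.LesionField("r", np.array([5_000.0]), np.array([]), 1e-5)
        fld = assign_removal_times(fld, gene, genotype_presets("XPC", tc_wave_speed=5_000.0), 0)
        m = simulate_bru_window(gene, fld, 2.0, cfg)
        clean = simulate_bru_window(gene, uvtx.LesionField("r", [], [], 0.0, removal_assigned=True), 2.0, cfg)
        np.testing.assert_allclose(m, clean, rtol=1e-9)

    def test_silent_gene_has_no_mass(self, cfg):
        gene = uvtx.Gene("s", "chr1", 0, 30_000, "+", basal_rate=0.0)
        mass = simulate_bru_window(gene, _assigned(gene, 1e-4, "WT", 1), 0.0, cfg)
        assert np.all(mass == 0)

    def test_unassigned_removal_times_rejected(self, cfg, toy_gene):
        fld = place_lesions(toy_gene, 1e-4, seed=2)
        with pytest.raises(StateError):
            simulate_bru_window(toy_gene, fld, 0.0, cfg)

    def test_restart_incompetent_gene_stays_suppressed(self, cfg):
        gene = uvtx.Gene("slit2", "chr1", 0, 150_000, "+", basal_rate=1.0)
        fld = _assigned(gene, lesion_density(10.0), "WT", 3)
        late_ok = simulate_bru_window(gene, fld, 24.0, cfg, restart_competent=True)
        late_no = simulate_bru_window(gene, fld, 24.0, cfg, restart_competent=False)
        early = simulate_bru_window(gene, fld, 0.0, cfg, restart_competent=False)
        assert late_ok.sum() > 2 * late_no.sum()
        np.testing.assert_allclose(late_no, early, rtol=1e-9, atol=1e-9)


class TestArrestOracle:
    def test_pass_fraction_matches_target_theory(self):
        """Fraction of polymerases passing x at t=0 ~ exp(-d x)."""
        d = 1 / 14_000
        gene = uvtx.Gene("o", "chr1", 0, 60_000, "+", 1.0)
        rng = np.random.default_rng(12)
        n = 3_000
        stops = []
        for _ in range(n):
            fld = place_lesions(gene, d, seed=rng.integers(2**31))
            fld = assign_removal_times(fld, gene, genotype_presets("NONE"), seed=0)
            stops.append(arrest_position(fld, 0.0, 1_500.0))
        stops = np.array(stops)
        for x in (7_000.0, 14_000.0, 28_000.0):
            p = expected_readthrough(x, d)
            se = np.sqrt(p * (1 - p) / n)
            assert abs((stops >= x).mean() - p) < 3 * se


class TestSampleReads:
    def test_conservation_is_exact(self):
        masses = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([5.0])}
        counts = sample_reads(masses, 12_345, seed=0)
        assert sum(c.sum() for c in counts.values()) == 12_345

    def test_all_mass_in_one_bin_gets_all_reads(self):
        counts = sample_reads({"a": np.array([0.0, 4.0, 0.0])}, 999, seed=1)
        np.testing.assert_array_equal(counts["a"], [0, 999, 0])

    def test_law_of_large_numbers(self):
        masses = {"a": np.array([1.0, 2.0, 3.0, 4.0])}
        counts = sample_reads(masses, 1_000_000, seed=2)["a"]
        np.testing.assert_allclose(counts / 1e6, masses["a"] / 10.0, rtol=0.01)

    def test_fixed_seed_reproducible(self):
        m = {"a": np.arange(1.0, 20.0)}
        np.testing.assert_array_equal(
            sample_reads(m, 1000, seed=7)["a"], sample_reads(m, 1000, seed=7)["a"])

    def test_zero_mass_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero"):
            counts = sample_reads({"a": np.zeros(3)}, 10, seed=0)
        assert counts["a"].sum() == 0


class TestExperiment:
    def test_control_always_included_and_counts_conserved(self, sim):
        for gt in ("WT", "XPC", "CSB"):
            assert sim.control(gt) in sim.tracks
        for cond, tracks in sim.tracks.items():
            total = sum(t.total for t in tracks.values())
            assert total == sim.config.reads_per_condition

    def test_reproducible_from_config_and_seed(self, gene_set):
        cfg = SimulationConfig(doses=(10.0,), timepoints=(0.0,), genotypes=("WT",),
                               reads_per_condition=50_000, seed=9)
        a = simulate_experiment(gene_set, cfg)
        b = simulate_experiment(gene_set, cfg)
        assert a.rpkm.equals(b.rpkm)

    def test_duplicate_conditions_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(doses=(10.0, 10.0))

    def test_dose_monotonicity_of_body_to_5prime_ratio(self, sim, gene_set):
        """More UV, more 5' pile-up: body/5' coverage ratio of >20 kbp genes
        is non-increasing in dose at t = 0."""
        ratios = []
        for dose in (0.0, 10.0, 20.0):
            cond = sim.control("WT") if dose == 0 else sim.condition(dose, 0.0, "WT")
            tracks = sim.tracks[cond]
            head = body = 0.0
            for g in gene_set:
                if g.length <= 20_000 or g.basal_rate <= 0.5:
                    continue
                c = tracks[g.id].counts
                head += c[:10].mean()
                body += c[10:].mean()
            ratios.append(body / head)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_lesion_realization_shared_across_timepoints(self, gene_set):
        """Paired design: a NONE-genotype run must give identical expected
        coverage at every timepoint, so RPKM differs only by sampling."""
        cfg = SimulationConfig(doses=(10.0,), timepoints=(0.0, 24.0), genotypes=("NONE",),
                               reads_per_condition=200_000, seed=4)
        res = simulate_experiment(gene_set, cfg)
        c0 = np.array([res.tracks[res.condition(10, 0, "NONE")][g.id].total
                       for g in gene_set])
        c24 = np.array([res.tracks[res.condition(10, 24, "NONE")][g.id].total
                        for g in gene_set])
        big = c0 > 500  # genes sampled deeply enough for a tight ratio
        assert big.sum() > 20
        np.testing.assert_allclose(c24[big] / c0[big], 1.0, atol=0.2)
        assert np.corrcoef(c0, c24)[0, 1] > 0.99
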