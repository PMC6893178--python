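"""Pop-out simulation, passages, phenotype model, and the closed-form oracle."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tfg.geometry import VectorDesign, retention_probability
from tfg.library import (
    LibrarySpec,
    CloneGenotype,
    Mutation,
    generate_template,
    simulate_library,
)
from tfg.screen import (
    NULL,
    WILD,
    ScreenConfig,
    annotate_mutations,
    assign_phenotype,
    expected_mutant_fraction,
    sample_transformants,
    simulate_passages,
    simulate_popout,
    simulate_screen,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestSampleTransformants:
    def test_single_clone_receives_everything(self, rng):
        counts = sample_transformants(1, 500, rng)
        assert counts.tolist() == [500]

    def test_zero_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            sample_transformants(10, 0, rng)

    def test_unrepresented_clones_match_occupancy_formula(self, rng):
        # 10x oversampling leaves almost no clone unrepresented
        k, n, reps = 1_000, 10_000, 40
        expected = k * (1 - 1 / k) ** n  # ~0.045 per replicate
        missing = [np.sum(sample_transformants(k, n, rng) == 0) for _ in range(reps)]
        se = np.sqrt(max(np.var(missing, ddof=1), expected) / reps)
        assert abs(np.mean(missing) - expected) < 3 * max(se, 0.05)

    def test_sparse_sampling_yields_mostly_distinct_clones(self, rng):
        counts = sample_transformants(5_000, 100, rng)
        expected_distinct = 5_000 * (1 - (1 - 1 / 5_000) ** 100)
        assert abs(np.sum(counts > 0) - expected_distinct) < 3 * np.sqrt(100)


class TestSimulatePassages:
    def test_large_transfers_lose_no_clone(self, rng):
        cfg = ScreenConfig(
            n_transformants=10_000,
            cells_per_transfer=10_000_000,
            final_density_cells=300_000_000,
        )
        counts = np.full(200, 50)
        final, _ = simulate_passages(counts, cfg, rng)
        assert (final > 0).all()

    def test_zero_survival_clears_nontransformed_after_one_passage(self, rng):
        cfg = ScreenConfig(n_passages_selective=1, nontransformed_survival_per_passage=0.0)
        _, residual = simulate_passages(np.array([100, 100]), cfg, rng)
        assert residual == 0.0

    def test_single_clone_composition_unchanged(self, rng):
        cfg = ScreenConfig()
        final, _ = simulate_passages(np.array([164_000]), cfg, rng)
        assert final.sum() == final[0] > 0

    def test_residual_fraction_shrinks_with_passages(self, rng):
        counts = np.full(100, 1000)
        residuals = []
        for n_pass in (1, 2, 3):
            cfg = ScreenConfig(
                n_passages_selective=n_pass, nontransformed_survival_per_passage=0.5
            )
            _, r = simulate_passages(counts, cfg, np.random.default_rng(1))
            residuals.append(r)
        assert residuals[0] > residuals[1] > residuals[2]


class TestSimulatePopout:
    def test_non_recombinant_clone_rejected(self, rng, ade6_design):
        clone = CloneGenotype("bare", recombinant=False)
        with pytest.raises(ValueError, match="no tandem duplication"):
            simulate_popout(clone, ade6_design, rng)

    def test_outcome_partitions_the_mutation_set(self, rng, ade6_design):
        muts = tuple(Mutation(p, "A", "G") for p in (2600, 3100, 3600, 4100))
        clone = CloneGenotype("c", True, muts)
        for _ in range(500):
            o = simulate_popout(clone, ade6_design, rng)
            lost = tuple(m for m in muts if m not in o.retained)
            assert tuple(sorted(o.retained + lost)) == muts
            assert 0 < o.crossover_pos < ade6_design.total_homology

    def test_retained_sets_nest_toward_the_dsb(self, rng, ade6_design):
        # if a mutation far from the DSB is retained, every mutation nearer
        # the DSB (on the same side) is retained too
        muts = tuple(Mutation(p, "A", "G") for p in (2600, 3100, 3600, 4100))
        clone = CloneGenotype("c", True, muts)
        for _ in range(2_000):
            kept = {m.pos for m in simulate_popout(clone, ade6_design, rng).retained}
            if 2600 in kept:
                assert kept == {2600, 3100, 3600, 4100}
            if 3100 in kept:
                assert {3600, 4100} <= kept

    def test_crossover_positions_are_uniform(self, rng, ade6_design):
        clone = CloneGenotype("c", True, (Mutation(3000, "A", "G"),))
        L = ade6_design.total_homology
        xs = np.array(
            [simulate_popout(clone, ade6_design, rng).crossover_pos for _ in range(20_000)]
        )
        assert sps.kstest(xs / L, "uniform").pvalue > 1e-3

    def test_single_mutation_retention_matches_ratio(self, rng, ade6_design):
        n = 20_000
        for pos in (2600, 3500, 4400):
            clone = CloneGenotype("c", True, (Mutation(pos, "A", "G"),))
            kept = sum(
                bool(simulate_popout(clone, ade6_design, rng).retained)
                for _ in range(n)
            )
            p = retention_probability(ade6_design, pos)
            tol = 3 * math.sqrt(p * (1 - p) / n) + 0.5 / ade6_design.total_homology
            assert abs(kept / n - p) < tol


class TestAssignPhenotype:
    def _outcome(self, retained):
        from tfg.screen import PopoutOutcome

        return PopoutOutcome("c", 1.0, tuple(retained))

    def test_empty_retained_set_is_wild(self, rng):
        o = assign_phenotype(self._outcome(()), {}, {}, 0.11, rng)
        assert (o.phenotype, o.colony_color) == (WILD, "white")

    def test_retained_nonsense_without_hypomorphs_is_null(self, rng):
        m = Mutation(5, "A", "T")
        o = assign_phenotype(
            self._outcome([m]), {m: "nonsense"}, {m: True}, 0.0, rng
        )
        assert (o.phenotype, o.colony_color) == (NULL, "red")

    def test_unmarked_missense_stays_wild(self, rng):
        m = Mutation(5, "A", "T")
        o = assign_phenotype(
            self._outcome([m]), {m: "missense"}, {m: False}, 0.5, rng
        )
        assert o.phenotype == WILD

    def test_missing_annotation_rejected(self, rng):
        m = Mutation(5, "A", "T")
        with pytest.raises(ValueError, match="missing effect annotation"):
            assign_phenotype(self._outcome([m]), {}, {}, 0.1, rng)

    def test_marks_are_sticky_per_mutation(self):
        template, orf = generate_template(20, 300, 20, seed=5)
        spec = LibrarySpec(300, 1.0, 0.01, (20, 320), seed=6)
        clones = simulate_library(template, spec)
        r1 = np.random.default_rng(9)
        r2 = np.random.default_rng(9)
        _, marks1 = annotate_mutations(clones, template, orf, 0.3, r1)
        _, marks2 = annotate_mutations(clones, template, orf, 0.3, r2)
        assert marks1 == marks2


@pytest.fixture(scope="module")
def tiny_setup():
    template, orf = generate_template(200, 600, 200, seed=15)
    design = VectorDesign(200, 600, 200, dsb_pos=900, mutagenized_window=(220, 780))
    return template, orf, design


class TestSimulateScreen:
    def test_no_deleterious_no_background_means_no_mutants(self, tiny_setup):
        template, _, design = tiny_setup
        spec = LibrarySpec(100, 1.0, 0.0, design.mutagenized_window, seed=1)
        clones = simulate_library(template, spec)
        cfg = ScreenConfig(
            n_transformants=1_000,
            cells_per_transfer=100_000,
            final_density_cells=1_000_000,
            background_foar_fraction=0.0,
            deleterious_missense_prob=0.0,
            n_colonies_scored=500,
            seed=2,
        )
        result = simulate_screen(clones, template, design, cfg)
        assert result.mutant_fraction == 0.0
        assert all(o.colony_color == "white" for o in result.outcomes)

    def test_all_nonsense_single_mutation_clones_reduce_to_retention(self, tiny_setup):
        template, orf, design = tiny_setup
        # find a nonsense substitution inside the window
        from tfg.library import classify_effect, NONSENSE, BASES

        hit = None
        for pos in range(*design.coding_mutagenized_window):
            for alt in BASES:
                if alt != template[pos]:
                    m = Mutation(pos, template[pos], alt)
                    if classify_effect(template, orf, m) == NONSENSE:
                        hit = m
                        break
            if hit:
                break
        clones = [CloneGenotype(f"c{i}", True, (hit,)) for i in range(50)]
        cfg = ScreenConfig(
            n_transformants=500,
            cells_per_transfer=100_000,
            final_density_cells=1_000_000,
            background_foar_fraction=0.0,
            n_colonies_scored=20_000,
            seed=3,
        )
        result = simulate_screen(clones, template, design, cfg)
        p = retention_probability(design, hit.pos)
        tol = 3 * math.sqrt(p * (1 - p) / 20_000) + 1 / design.total_homology
        assert abs(result.mutant_fraction - p) < tol

    def test_background_colonies_are_flagged_wild(self, tiny_setup):
        template, _, design = tiny_setup
        spec = LibrarySpec(50, 1.0, 0.005, design.mutagenized_window, seed=4)
        clones = simulate_library(template, spec)
        cfg = ScreenConfig(
            n_transformants=500,
            cells_per_transfer=100_000,
            final_density_cells=1_000_000,
            background_foar_fraction=0.5,
            n_colonies_scored=2_000,
            seed=5,
        )
        result = simulate_screen(clones, template, design, cfg)
        n_bg = result.n_background
        assert abs(n_bg - 1_000) < 3 * math.sqrt(2_000 * 0.25)
        assert all(
            o.phenotype == WILD and math.isnan(o.crossover_pos)
            for o in result.outcomes
            if o.background
        )

    def test_deterministic_given_seed(self, tiny_setup):
        template, _, design = tiny_setup
        spec = LibrarySpec(80, 0.9, 0.005, design.mutagenized_window, seed=6)
        clones = simulate_library(template, spec)
        cfg = ScreenConfig(
            n_transformants=800,
            cells_per_transfer=100_000,
            final_density_cells=1_000_000,
            n_colonies_scored=300,
            seed=7,
        )
        r1 = simulate_screen(clones, template, design, cfg)
        r2 = simulate_screen(clones, template, design, cfg)
        assert r1.outcomes == r2.outcomes

    def test_colony_table_and_report_are_consistent(self, tiny_setup):
        template, _, design = tiny_setup
        spec = LibrarySpec(80, 0.9, 0.005, design.mutagenized_window, seed=6)
        clones = simulate_library(template, spec)
        cfg = ScreenConfig(
            n_transformants=800,
            cells_per_transfer=100_000,
            final_density_cells=1_000_000,
            n_colonies_scored=300,
            seed=8,
        )
        result = simulate_screen(clones, template, design, cfg)
        df = result.colony_frame()
        assert len(df) == 300
        report = result.aggregate_report(design)
        assert sum(report["phenotype_counts"].values()) == 300
        hist_total = sum(report["retained_position_histogram"].values())
        assert hist_total == df["n_retained"].sum()


class TestExpectedMutantFraction:
    def test_zero_deleterious_rate_gives_zero(self, ade6_design):
        assert expected_mutant_fraction(ade6_design, 0.0) == 0.0

    def test_single_deleterious_mutation_reduces_to_retention(self, ade6_design):
        pos = 3200
        lam = 1e-9  # conditional on >=1, effectively exactly one
        val = expected_mutant_fraction(ade6_design, lam, window=(pos, pos + 1))
        conditional = val / -math.expm1(-lam)
        expected = (pos + 0.5) / ade6_design.total_homology
        assert conditional == pytest.approx(expected, abs=1e-9)

    def test_strictly_increasing_in_rate(self, ade6_design):
        vals = [expected_mutant_fraction(ade6_design, lam) for lam in (0.1, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_background_scales_linearly(self, ade6_design):
        v0 = expected_mutant_fraction(ade6_design, 0.5, background=0.0)
        v2 = expected_mutant_fraction(ade6_design, 0.5, background=0.2)
        assert v2 == pytest.approx(0.8 * v0)

    def test_window_beyond_dsb_rejected(self, ade6_design):
        with pytest.raises(ValueError, match="5' side"):
            expected_mutant_fraction(ade6_design, 0.5, window=(4500, 4700))
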