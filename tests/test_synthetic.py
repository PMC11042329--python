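"""Generator contracts: determinism, model structure, statistical limits."""

import numpy as np
import pandas as pd
import pytest

from sedseq.exceptions import ConfigurationError, DomainError
from sedseq.scores import log_odds
from sedseq.synthetic import (
    CONTROL,
    ConditionSpec,
    make_catalog,
    simulate_experiment,
    simulate_fish_field,
    simulate_fraction_counts,
    simulate_polysome_experiment,
    simulate_true_psup,
)


class TestCatalog:
    def test_single_transcript_within_length_bounds(self):
        cat = make_catalog(1, seed=1)
        assert len(cat) == 1
        assert 200 <= cat.length_nt.iloc[0] <= 15000

    def test_median_length_matches_sampling_parameters(self):
        # log-mean ln(1300) should give an empirical median within 20% of 1300
        cat = make_catalog(5000, length_log_mean=np.log(1300), length_log_sd=0.6, seed=7)
        assert abs(cat.length_nt.median() / 1300 - 1) < 0.2

    def test_length_ceiling_accommodates_longest_yeast_mrnps(self):
        # the heaviest unstressed mRNP detected is the 12.4 kb dynein transcript
        cat = make_catalog(4000, length_log_mean=np.log(9000), length_log_sd=0.8, seed=3)
        assert cat.length_nt.max() >= 12400
        assert cat.length_nt.max() <= 15000

    def test_deterministic_given_seed(self):
        a = make_catalog(100, seed=5)
        b = make_catalog(100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invariants(self):
        cat = make_catalog(500, regulon_fractions={"induced": 0.1}, seed=2)
        assert (cat.length_nt >= 1).all()
        assert (cat.utr5_length_nt < cat.length_nt).all()
        assert cat.base_abundance.sum() == pytest.approx(1e6)
        assert set(cat.regulon) <= {"none", "induced"}

    def test_invalid_regulon_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            make_catalog(10, regulon_fractions={"a": 0.7, "b": 0.6}, seed=0)


class TestTruePsup:
    def test_control_matches_mass_law_exactly(self, catalog):
        cond = ConditionSpec("quiet", gene_noise_sd=0.0)
        psup = simulate_true_psup(catalog, cond, beta=1e-3, chi=0.8, seed=0)
        L = catalog.length_nt.to_numpy(float)
        expected = 1 - np.clip(1e-3 * L**0.8, None, 1 - 1e-6)
        np.testing.assert_allclose(psup.to_numpy(), expected, rtol=1e-9)

    def test_stress_scalar_formula(self):
        # single transcript: direct arithmetic of 1 - beta*L^chi*exp(mu)
        cat = pd.DataFrame(
            {
                "transcript_id": ["x"],
                "length_nt": [1000],
                "utr5_length_nt": [50],
                "regulon": ["none"],
                "base_abundance": [1.0],
            }
        )
        cond = ConditionSpec("s", mu=0.5, gene_noise_sd=0.0)
        psup = simulate_true_psup(cat, cond, beta=1e-3, chi=0.8, seed=0)
        expected = 1 - 1e-3 * 1000**0.8 * np.exp(0.5)
        assert psup.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_in_length_without_noise(self, catalog):
        cond = ConditionSpec("s", mu=0.3, nu=1e-5, gene_noise_sd=0.0)
        psup = simulate_true_psup(catalog, cond, seed=0)
        order = np.argsort(catalog.length_nt.to_numpy())
        assert (np.diff(psup.to_numpy()[order]) <= 1e-12).all()

    def test_unclipped_overflow_raises(self, catalog):
        cond = ConditionSpec("hot", mu=5.0, gene_noise_sd=0.0)
        with pytest.raises(DomainError):
            simulate_true_psup(catalog, cond, clip=False, seed=0)

    def test_outputs_strictly_inside_unit_interval(self, catalog, stress_condition):
        psup = simulate_true_psup(catalog, stress_condition, seed=4)
        assert ((psup > 0) & (psup < 1)).all()

    def test_escape_effect_raises_lopsup_of_induced_regulon(self):
        cat = make_catalog(3000, regulon_fractions={"induced": 0.2}, seed=11)
        cond = ConditionSpec("s", mu=1.0, escape_effect={"induced": 1.5}, gene_noise_sd=0.0)
        psup = simulate_true_psup(cat, cond, seed=0)
        lop = log_odds(psup.to_numpy())
        induced = (cat.regulon == "induced").to_numpy()
        # same-length comparison is built in: the shift is purely additive
        assert np.median(lop[induced]) > np.median(lop[~induced])


class TestFractionCounts:
    def test_deterministic_given_seed(self, catalog):
        psup = simulate_true_psup(catalog, CONTROL, seed=1)
        a = simulate_fraction_counts(catalog, psup, seed=9)
        b = simulate_fraction_counts(catalog, psup, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_poisson_limit_recovers_true_psup(self):
        # dispersion -> infinity, alpha_s = alpha_p = 1: mean S/(S+P) over
        # replicates converges to the true pSup (law of large numbers)
        cat = make_catalog(50, seed=3)
        psup = simulate_true_psup(cat, CONTROL, seed=4)
        ratios = np.zeros((200, len(cat)))
        for rep in range(200):
            c = simulate_fraction_counts(cat, psup, dispersion=np.inf, depth=1e6, seed=rep)
            ratios[rep] = c["sup"] / (c["sup"] + c["pellet"])
        np.testing.assert_allclose(ratios.mean(axis=0), psup.to_numpy(), atol=0.01)

    def test_mixing_identity_regression_slope(self):
        # T against alpha_s*S + alpha_p*P with the generator's own true
        # alphas: slope within [0.95, 1.05] at 5000 transcripts, depth 1e7
        cat = make_catalog(5000, seed=21)
        psup = simulate_true_psup(cat, CONTROL, seed=22)
        c = simulate_fraction_counts(
            cat, psup, alpha_s=1.6, alpha_p=0.9, depth=1e7, dispersion=100, seed=23
        )
        x = 1.6 * c["sup"].to_numpy(float) + 0.9 * c["pellet"].to_numpy(float)
        t = c["total"].to_numpy(float)
        slope = np.sum(x * t) / np.sum(x * x)
        assert 0.95 < slope < 1.05

    def test_counts_nonnegative_integers(self, control_experiment):
        c = control_experiment.counts
        for col in ("total", "sup", "pellet"):
            assert (c[col] >= 0).all()
            assert np.issubdtype(c[col].dtype, np.integer)


class TestPolysome:
    @pytest.fixture(scope="class")
    def polysome(self):
        cat = make_catalog(1000, seed=31)
        rng = np.random.default_rng(32)
        occ = pd.Series(
            rng.beta(5, 2, len(cat)), index=pd.Index(cat.transcript_id, name="transcript_id")
        )
        occ.iloc[0] = 0.0  # a fully ribosome-free transcript
        table, truth = simulate_polysome_experiment(cat, occ, spike_set_size=20, seed=33)
        return cat, occ, table, truth

    def test_zero_occupancy_appears_only_in_free(self, polysome):
        cat, occ, table, _ = polysome
        tid = occ.index[0]
        bound = table[(table.transcript_id == tid) & (table.fraction == "bound")].tpm.iloc[0]
        free = table[(table.transcript_id == tid) & (table.fraction == "free")].tpm.iloc[0]
        assert bound == 0
        assert free > 0

    def test_spike_expectations_identical_across_fractions(self, polysome):
        _, _, _, truth = polysome
        np.testing.assert_array_equal(
            truth["expected"]["total"][-20:], truth["expected"]["free"][-20:]
        )

    def test_injected_distortion_recoverable_from_spike_ratios(self, polysome):
        _, _, table, truth = polysome
        for frac in ("total", "free", "bound"):
            sub = table[(table.fraction == frac) & table.is_spike]
            ratio = sub.tpm.to_numpy() / truth["expected"][frac][-20:]
            assert np.median(ratio) == pytest.approx(truth["distortion"][frac], rel=0.05)

    def test_empty_spike_set_rejected(self, polysome):
        cat, occ, _, _ = polysome
        with pytest.raises(ConfigurationError):
            simulate_polysome_experiment(cat, occ, spike_set_size=0, seed=1)


class TestFishField:
    def test_deterministic_given_seed(self):
        a = simulate_fish_field(4, seed=5)
        b = simulate_fish_field(4, seed=5)
        np.testing.assert_array_equal(a.marker, b.marker)
        np.testing.assert_array_equal(a.spots_image, b.spots_image)
        pd.testing.assert_frame_equal(a.spots, b.spots)

    def test_spots_lie_inside_their_cell_mask(self):
        field = simulate_fish_field(9, granule_enrichment=3.0, seed=6)
        for _, s in field.spots.iterrows():
            assert field.cell_mask[int(s.y_px), int(s.x_px)] == s.cell_id

    def test_enrichment_places_spots_in_granules(self):
        null = simulate_fish_field(20, granule_enrichment=0.0, seed=7)
        enriched = simulate_fish_field(20, granule_enrichment=10.0, seed=7)
        assert enriched.spots.in_granule.mean() > 0.8
        assert null.spots.in_granule.mean() == 0.0

    def test_normalized_intensity_is_per_cell(self):
        field = simulate_fish_field(6, seed=8)
        per_cell_mean = field.spots.groupby("cell_id").normalized_intensity.mean()
        np.testing.assert_allclose(per_cell_mean, 1.0, rtol=1e-9)

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_fish_field(0, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_fish_field(5, granule_enrichment=-1, seed=1)


class TestSimulatedExperimentInvariant:
    def test_expected_total_matches_mixed_fractions(self):
        # E[T] = alpha_s*E[S] + alpha_p*E[P]: check empirically via totals
        exp = simulate_experiment(4000, alpha_s=2.0, alpha_p=0.5, depth=5e6, seed=13)
        c = exp.counts
        lhs = c["total"].sum()
        rhs = 2.0 * c["sup"].sum() + 0.5 * c["pellet"].sum()
        assert lhs == pytest.approx(rhs, rel=0.01)
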