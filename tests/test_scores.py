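"""Condensation scores: log-odds, windowed stats, ΔSed, eSed, rSed."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedseq.exceptions import DomainError
from sedseq.scores import (
    condition_scores,
    control_sigma,
    delta_sed,
    escape_sed,
    log_odds,
    sed_score,
    windowed_stats,
)


class TestLogOdds:
    def test_symmetry_point(self):
        assert log_odds(0.5) == 0.0

    def test_scalar_value(self):
        assert log_odds(0.9) == pytest.approx(np.log(9), rel=1e-12)

    @given(st.floats(min_value=0.001, max_value=0.999))
    @settings(deadline=None)
    def test_antisymmetry(self, p):
        assert log_odds(p) == pytest.approx(-log_odds(1 - p), abs=1e-9)

    def test_boundary_values_clamped_finite(self):
        assert np.isfinite(log_odds(0.0))
        assert log_odds(1.0) == pytest.approx(np.log((1 - 1e-4) / 1e-4))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            log_odds(1.2)
        with pytest.raises(DomainError):
            log_odds(np.array([0.5, -0.1]))


def brute_force_windowed(lengths, lopsup, window_fraction):
    """Double-loop reference: mean/SD of every window, no shortcuts."""
    logL = np.log(np.asarray(lengths, float))
    y = np.asarray(lopsup, float)
    half = window_fraction * (logL.max() - logL.min()) / 2
    mu = np.empty(len(y))
    sd = np.empty(len(y))
    for i in range(len(y)):
        inside = np.abs(logL - logL[i]) <= half
        assert inside.sum() >= 3, "test data must not trigger window widening"
        vals = y[inside]
        mu[i] = vals.mean()
        sd[i] = vals.std(ddof=1)
    return mu, sd


@pytest.fixture(scope="module")
def hand_built():
    rng = np.random.default_rng(77)
    n = 250
    lengths = np.exp(rng.uniform(np.log(500), np.log(2000), n))
    lop_c = 2.0 - 0.8 * np.log(lengths / 500) + rng.normal(0, 0.3, n)
    lop_t = lop_c - 1.0 + rng.normal(0, 0.2, n)
    ids = np.array([f"g{i:03d}" for i in range(n)])
    return ids, lengths, lop_c, lop_t


def scored_frame(ids, lengths, lop, window_fraction=0.1):
    psup = 1 / (1 + np.exp(-lop))
    df = pd.DataFrame({"transcript_id": ids, "psup": psup})
    lens = pd.DataFrame({"transcript_id": ids, "length_nt": lengths})
    return condition_scores(df, lens, window_fraction=window_fraction)


class TestWindowedStats:
    def test_matches_brute_force(self, hand_built):
        ids, lengths, lop_c, _ = hand_built
        mu, sd = windowed_stats(lengths, lop_c, window_fraction=0.1)
        mu_ref, sd_ref = brute_force_windowed(lengths, lop_c, 0.1)
        np.testing.assert_allclose(mu, mu_ref, atol=1e-12)
        np.testing.assert_allclose(sd, sd_ref, atol=1e-12)

    def test_degenerate_single_length_gives_global_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        mu, sd = windowed_stats(np.full(4, 1000.0), y, window_fraction=0.02)
        np.testing.assert_allclose(mu, y.mean())
        np.testing.assert_allclose(sd, y.std(ddof=1))

    def test_centering_property(self, hand_built):
        ids, lengths, lop_c, _ = hand_built
        mu, _ = windowed_stats(lengths, lop_c, window_fraction=0.1)
        resid = lop_c - mu
        assert abs(resid.mean()) < 1e-2 * resid.std()

    def test_narrow_windows_widened_to_three_neighbors(self):
        lengths = np.array([200.0, 210.0, 5000.0, 14000.0, 14100.0])
        y = np.arange(5.0)
        mu, sd = windowed_stats(lengths, y, window_fraction=0.001)
        assert np.isfinite(mu).all() and np.isfinite(sd).all()
        assert (sd > 0).all()  # every window was expanded beyond one point


class TestDeltaAndEscape:
    def test_identity_condition_gives_zero(self, hand_built):
        ids, lengths, lop_c, _ = hand_built
        ctrl = scored_frame(ids, lengths, lop_c)
        d = delta_sed(ctrl, ctrl)
        e = escape_sed(ctrl, ctrl)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self, hand_built):
        ids, lengths, lop_c, lop_t = hand_built
        ctrl = scored_frame(ids, lengths, lop_c)
        trt = scored_frame(ids, lengths, lop_t)

        mu_c, _ = brute_force_windowed(lengths, lop_c, 0.1)
        mu_t, _ = brute_force_windowed(lengths, lop_t, 0.1)
        sigma = np.std(lop_c - mu_c, ddof=1)
        d_ref = (lop_c - lop_t) / sigma
        e_ref = ((lop_t - mu_t) - (lop_c - mu_c)) / sigma

        np.testing.assert_allclose(delta_sed(ctrl, trt).to_numpy(), d_ref, atol=1e-12)
        np.testing.assert_allclose(escape_sed(ctrl, trt).to_numpy(), e_ref, atol=1e-12)

    def test_single_transcript_perturbation_oracle(self, hand_built):
        # shifting one transcript by +1 on lopSup moves its eSed by almost
        # exactly 1/sigma_control (window means barely move)
        ids, lengths, lop_c, _ = hand_built
        lop_t = lop_c.copy()
        ctrl = scored_frame(ids, lengths, lop_c)
        base = escape_sed(ctrl, scored_frame(ids, lengths, lop_t))
        lop_t[17] += 1.0
        shifted = escape_sed(ctrl, scored_frame(ids, lengths, lop_t))
        sigma = control_sigma(ctrl)
        delta = (shifted - base).loc[ids[17]]
        # the focal transcript contributes 1/n_window to its own window mean
        assert delta == pytest.approx(1 / sigma, rel=0.1)

    def test_invariant_to_common_constant_shift(self, hand_built):
        ids, lengths, lop_c, lop_t = hand_built
        d1 = delta_sed(scored_frame(ids, lengths, lop_c), scored_frame(ids, lengths, lop_t))
        d2 = delta_sed(
            scored_frame(ids, lengths, lop_c + 3.0), scored_frame(ids, lengths, lop_t + 3.0)
        )
        # lopSup -> psup -> lopSup round trip clamps; compare where unclamped
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_unmatched_transcripts_dropped(self, hand_built):
        ids, lengths, lop_c, lop_t = hand_built
        ctrl = scored_frame(ids, lengths, lop_c)
        trt = scored_frame(ids[:-10], lengths[:-10], lop_t[:-10])
        d = delta_sed(ctrl, trt)
        assert len(d) == len(ids) - 10


def brute_force_sed_score(ids, lengths, lop, bin_size):
    """Reference rSed: sort, consecutive bins, z within bin, merge remainder."""
    order = np.lexsort((ids, lengths))
    n = len(ids)
    n_bins = max(1, n // bin_size)
    out = {}
    for b in range(n_bins):
        start = b * bin_size
        stop = n if b == n_bins - 1 else (b + 1) * bin_size
        idx = order[start:stop]
        vals = lop[idx]
        sd = vals.std(ddof=1)
        z = np.zeros(len(idx)) if sd == 0 else (vals - vals.mean()) / sd
        for i, zi in zip(idx, z):
            out[ids[i]] = zi
    return pd.Series(out)


class TestSedScore:
    def test_matches_brute_force(self, hand_built):
        ids, lengths, lop_c, _ = hand_built
        psup = pd.DataFrame({"transcript_id": ids, "psup": 1 / (1 + np.exp(-lop_c))})
        lens = pd.DataFrame({"transcript_id": ids, "length_nt": lengths})
        got = sed_score(psup, lens, bin_size=100)
        # recompute the clamped log-odds exactly as the implementation does
        lop = log_odds(psup.psup.to_numpy())
        ref = brute_force_sed_score(ids, lengths, lop, 100)
        np.testing.assert_allclose(got.sort_index(), ref.sort_index(), atol=1e-12)

    def test_constant_lopsup_gives_zero(self):
        ids = [f"g{i}" for i in range(150)]
        psup = pd.DataFrame({"transcript_id": ids, "psup": 0.8})
        lens = pd.DataFrame({"transcript_id": ids, "length_nt": np.arange(150) + 500})
        np.testing.assert_array_equal(sed_score(psup, lens).to_numpy(), 0.0)

    def test_replicates_averaged(self, hand_built):
        ids, lengths, lop_c, lop_t = hand_built
        lens = pd.DataFrame({"transcript_id": ids, "length_nt": lengths})
        rep1 = pd.DataFrame({"transcript_id": ids, "psup": 1 / (1 + np.exp(-lop_c))})
        rep2 = pd.DataFrame({"transcript_id": ids, "psup": 1 / (1 + np.exp(-lop_t))})
        avg = sed_score([rep1, rep2], lens)
        single = (sed_score(rep1, lens) + sed_score(rep2, lens)) / 2
        np.testing.assert_allclose(avg, single.reindex(avg.index), atol=1e-12)

    def test_fewer_transcripts_than_bin_size_single_bin(self):
        ids = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(5)
        psup = pd.DataFrame({"transcript_id": ids, "psup": rng.uniform(0.3, 0.9, 30)})
        lens = pd.DataFrame({"transcript_id": ids, "length_nt": np.arange(30) + 300})
        z = sed_score(psup, lens, bin_size=100)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)

    def test_rank_agreement_with_windowed_z(self):
        # the binned z and the sliding-window z are different estimators of
        # the same quantity; their ranks should agree closely
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        n = 5000
        lengths = np.exp(rng.uniform(np.log(300), np.log(8000), n))
        lop = 2.5 - 1.1 * np.log(lengths / 300) + rng.normal(0, 0.4, n)
        ids = np.array([f"g{i:04d}" for i in range(n)])
        psup = pd.DataFrame({"transcript_id": ids, "psup": 1 / (1 + np.exp(-lop))})
        lens = pd.DataFrame({"transcript_id": ids, "length_nt": lengths})
        r_sed = sed_score(psup, lens).reindex(ids)
        scored = scored_frame(ids, lengths, lop, window_fraction=0.05)
        windowed_z = (scored.lopsup - scored.mu_L) / scored.sigma_L
        rho = spearmanr(r_sed.to_numpy(), windowed_z.to_numpy()).statistic
        assert rho > 0.95
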