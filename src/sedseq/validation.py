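"""Self-validation studies: parameter recovery, test calibration, power.

Each function runs one end-to-end study on synthetic data — generating
inputs with :mod:`sedseq.synthetic`, running the estimators, and
measuring recovery or error rates — and returns a dict of summary
numbers. They back both the acceptance test suite and the
``scripts/acceptance.py`` report, and are deterministic given a seed.

Study sizes follow the package's reference conditions: 5000 transcripts
at 10^7 depth with NB dispersion 100 for pSup inference; 100 length
points with log-odds noise SD 0.2 for sedimentation-model fits; 50-cell
fields with 10 spots per cell for colocalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from sedseq.colocalization import compare_conditions, population_score, score_cells
from sedseq.fraction_quant import MixingRatioEstimator
from sedseq.physical import (
    SedimentationModel,
    effective_size_ratio,
    fit_baseline,
    mrnp_mass,
    nested_f_test,
    protein_spacing,
)
from sedseq.scores import condition_scores, delta_sed, escape_sed
from sedseq.synthetic import (
    CONTROL,
    ConditionSpec,
    make_catalog,
    simulate_experiment,
    simulate_fish_field,
    simulate_polysome_experiment,
    simulate_true_psup,
)
from sedseq.translation import (
    cushion_occupancy,
    ribosome_occupancy,
    spikein_normalize,
)

__all__ = [
    "mass_worked_examples",
    "ftest_null_calibration",
    "ftest_power",
    "baseline_recovery",
    "mixing_ratio_recovery",
    "score_direction_study",
    "colocalization_study",
    "translation_study",
]


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def mass_worked_examples() -> dict:
    """Polysome-scale mass arithmetic (deterministic desk calculations)."""
    return {
        "polysome_5rib_1800nt_mda": mrnp_mass(5, 1800),
        "mrna_1800nt_mda": mrnp_mass(0, 1800),
        "protein_spacing_17mda_1800nt_nt": protein_spacing(17.0, 1800),
        "size_ratio_psup_0p9_to_0p7_chi1": effective_size_ratio(0.9, 0.7, 1.0),
    }


def _exact_lopsup(L, beta, chi, mu=0.0, nu=0.0):
    pellet = np.clip(beta * L**chi * np.exp(mu + nu * L), 1e-12, 1 - 1e-9)
    return np.log((1 - pellet) / pellet)


def _nested_fit_pair(L, y_c, y_t, reduced_terms):
    """Fit a reduced stress model, then the full model warm-started from it.

    The warm start guarantees the full fit's RSS never exceeds the
    reduced fit's, so the F statistic reflects the models rather than
    optimizer luck.
    """
    reduced = SedimentationModel(model="stress", terms=reduced_terms, n_beta_starts=2)
    reduced.fit(L, y_c, treated_lengths=L, treated_lopsup=y_t)
    full = SedimentationModel(
        model="stress",
        terms="full",
        n_beta_starts=2,
        warm_start={
            "beta": reduced.beta_,
            "chi": reduced.chi_,
            "mu": reduced.mu_,
            "nu": reduced.nu_,
        },
    )
    full.fit(L, y_c, treated_lengths=L, treated_lopsup=y_t)
    return full.fit_, reduced.fit_


def ftest_null_calibration(
    n_reps: int = 1000,
    n_points: int = 100,
    noise_sd: float = 0.2,
    mu: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the extra-parameter F-test under the reduced model.

    Data are simulated with the per-molecule term only (μ > 0, ν = 0);
    the full (μ, ν) fit is tested against the μ-only fit. The rejection
    rate at level ``alpha`` should match ``alpha`` up to binomial error.
    The generating parameters keep the pelleted fraction below 1 at
    every simulated length: at the saturation boundary the clamped model
    is non-smooth and the F approximation degrades.
    """
    rng = np.random.default_rng(seed)
    beta, chi = 4e-4, 0.8
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        L = np.exp(rng.uniform(np.log(200), np.log(5000), n_points))
        y_c = _exact_lopsup(L, beta, chi) + rng.normal(0, noise_sd, n_points)
        y_t = _exact_lopsup(L, beta, chi, mu=mu) + rng.normal(0, noise_sd, n_points)
        full, reduced = _nested_fit_pair(L, y_c, y_t, "mu-only")
        pvals[i] = nested_f_test(full, reduced).p_value
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "nominal_rate": alpha,
        "ks_uniform_p": float(stats.kstest(pvals, "uniform").pvalue),
        "n_reps": n_reps,
    }


def ftest_power(
    n_reps: int = 200,
    n_points: int = 100,
    noise_sd: float = 0.2,
    mu: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the full-vs-ν-only F-test when the per-molecule term is real.

    Data carry a pure per-molecule shift (μ = 1, ν = 0); dropping the
    length-independent parameter should be rejected essentially always.
    """
    rng = np.random.default_rng(seed)
    beta, chi = 4e-4, 0.8
    rejections = 0
    for _ in range(n_reps):
        L = np.exp(rng.uniform(np.log(200), np.log(5000), n_points))
        y_c = _exact_lopsup(L, beta, chi) + rng.normal(0, noise_sd, n_points)
        y_t = _exact_lopsup(L, beta, chi, mu=mu) + rng.normal(0, noise_sd, n_points)
        full, reduced = _nested_fit_pair(L, y_c, y_t, "nu-only")
        rejections += nested_f_test(full, reduced).p_value < alpha
    return {"power": rejections / n_reps, "n_reps": n_reps}


def baseline_recovery(
    n_seeds: int = 20, n_points: int = 100, noise_sd: float = 0.2, seed: int = 0
) -> dict:
    """Recovery of (β, χ) by log-odds NLS under transcript-level noise."""
    beta, chi = 10**-3.5, 0.9
    beta_err, chi_err = [], []
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        L = np.exp(rng.uniform(np.log(200), np.log(7000), n_points))
        y = _exact_lopsup(L, beta, chi) + rng.normal(0, noise_sd, n_points)
        fit = fit_baseline(L, y)
        beta_err.append(abs(fit.beta / beta - 1))
        chi_err.append(abs(fit.chi / chi - 1))
    return {
        "median_beta_rel_err": float(np.median(beta_err)),
        "median_chi_rel_err": float(np.median(chi_err)),
        "n_seeds": n_seeds,
    }


def mixing_ratio_recovery(
    n_seeds: int = 20,
    n_transcripts: int = 5000,
    depth: float = 1e7,
    dispersion: float = 100.0,
    alpha_s: float = 2.0,
    alpha_p: float = 0.5,
    seed: int = 0,
) -> dict:
    """pSup inference benchmark at the reference study conditions.

    Simulates Sed-seq experiments with a 4:1 mixing-ratio imbalance,
    refits with the Bayesian MAP backend, and reports the median
    relative error of the recovered α_S/α_P ratio plus the median pSup
    MAE over well-measured transcripts (total counts > 100).
    """
    true_ratio = alpha_s / alpha_p
    ratio_err, maes = [], []
    for s in _spawn(seed, n_seeds):
        exp = simulate_experiment(
            n_transcripts,
            alpha_s=alpha_s,
            alpha_p=alpha_p,
            depth=depth,
            dispersion=dispersion,
            seed=s,
        )
        est = MixingRatioEstimator(method="map").fit(exp.counts)
        ratio_err.append(abs((est.alpha_s_ / est.alpha_p_) / true_ratio - 1))
        psup = est.transform(exp.counts).merge(exp.counts, on="transcript_id")
        well = psup[psup.total > 100]
        truth = exp.true_psup.reindex(well.transcript_id).to_numpy()
        maes.append(float(np.mean(np.abs(well.psup.to_numpy() - truth))))
    return {
        "median_ratio_rel_err": float(np.median(ratio_err)),
        "median_psup_mae": float(np.median(maes)),
        "n_seeds": n_seeds,
    }


def score_direction_study(
    n_transcripts: int = 3000,
    depth: float = 2e6,
    mu: float = 1.5,
    escape: float = 1.5,
    seed: int = 0,
) -> dict:
    """Directional behavior of ΔSed and eSed through the full pipeline.

    A stress condition with a per-molecule condensation shift (μ > 0,
    ν = 0) and an induced regulon carrying a positive escape effect is
    simulated, pSup re-estimated from counts, and the scores computed.
    Reports the transcriptome-median ΔSed (expected > 0), the Wilcoxon
    rank-sum p for the induced regulon's eSed against the rest
    (expected small), and the length trend of eSed among non-induced
    transcripts (expected to vanish: the shift is purely per-molecule).
    """
    seeds = _spawn(seed, 4)
    catalog = make_catalog(n_transcripts, regulon_fractions={"induced": 0.05}, seed=seeds[0])
    stress = ConditionSpec(
        "stress",
        mu=mu,
        induction_log2fc={"induced": 3.0},
        escape_effect={"induced": escape},
    )
    tables = {}
    for cond, s in zip((CONTROL, stress), seeds[1:3]):
        exp = simulate_experiment(
            catalog=catalog, condition=cond, depth=depth, seed=s
        )
        psup = MixingRatioEstimator().fit_transform(exp.counts)
        tables[cond.name] = condition_scores(psup, catalog, condition=cond.name)

    d = delta_sed(tables["control"], tables["stress"])
    e = escape_sed(tables["control"], tables["stress"])
    regulon = catalog.set_index("transcript_id").regulon.reindex(e.index)
    induced = (regulon == "induced").to_numpy()
    wilcoxon_p = stats.ranksums(e[induced], e[~induced], alternative="greater").pvalue

    lengths = catalog.set_index("transcript_id").length_nt.reindex(e.index).to_numpy(float)
    reg = stats.linregress(np.log(lengths[~induced]), e[~induced])
    ci_half = 1.96 * reg.stderr
    return {
        "median_delta_sed": float(d.median()),
        "median_esed_induced": float(e[induced].median()),
        "wilcoxon_p_induced_escape": float(wilcoxon_p),
        "esed_length_slope": float(reg.slope),
        "esed_length_slope_ci_low": float(reg.slope - ci_half),
        "esed_length_slope_ci_high": float(reg.slope + ci_half),
    }


def colocalization_study(
    n_cells: int = 50, enrichment: float = 8.0, seed: int = 0
) -> dict:
    """Null vs granule-enriched smFISH fields through the z-score pipeline."""
    seeds = _spawn(seed, 4)
    null_field = simulate_fish_field(n_cells, granule_enrichment=0.0, seed=seeds[0])
    enr_field = simulate_fish_field(n_cells, granule_enrichment=enrichment, seed=seeds[1])
    per_cell = {
        "null": score_cells(null_field.marker, null_field.cell_mask, null_field.spots, seed=seeds[2]),
        "enriched": score_cells(enr_field.marker, enr_field.cell_mask, enr_field.spots, seed=seeds[3]),
    }
    welch = compare_conditions(per_cell)
    return {
        "null_population_score": population_score(per_cell["null"]),
        "enriched_population_score": population_score(per_cell["enriched"]),
        "welch_holm_p": float(welch.p_holm.iloc[0]),
        "n_cells": n_cells,
    }


def translation_study(n_transcripts: int = 2000, seed: int = 0) -> dict:
    """Spike-in distortion recovery and occupancy accuracy on synthetic data."""
    seeds = _spawn(seed, 3)
    catalog = make_catalog(n_transcripts, seed=seeds[0])
    rng = np.random.default_rng(seeds[1])
    occ = pd.Series(
        rng.beta(5, 2, n_transcripts),
        index=pd.Index(catalog.transcript_id, name="transcript_id"),
    )
    table, truth = simulate_polysome_experiment(
        catalog, occ, spike_set_size=20, depth=1e6, seed=seeds[2]
    )
    normalized = spikein_normalize(table)
    distortion_errs = []
    for frac in ("total", "free", "bound"):
        spikes = table[(table.fraction == frac) & table.is_spike]
        ratio = spikes.tpm.to_numpy() / truth["expected"][frac][-20:]
        distortion_errs.append(abs(np.median(ratio) / truth["distortion"][frac] - 1))
    free = normalized[(normalized.fraction == "free") & ~normalized.is_spike]
    bound = normalized[(normalized.fraction == "bound") & ~normalized.is_spike]
    est = ribosome_occupancy(free, bound).set_index("transcript_id").occupancy
    mae = float(np.mean(np.abs(est.reindex(occ.index) - occ)))
    return {
        "max_distortion_rel_err": float(np.max(distortion_errs)),
        "occupancy_mae": mae,
        "cushion_occupancy_0p8_0p5": cushion_occupancy(0.8, 0.5),
    }
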