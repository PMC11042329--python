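"""Synthetic Sed-seq data generators.

Every generator is a pure function of its parameters and a seed, and
emulates the statistical structure the downstream analysis assumes:

- transcript catalogs with log-normally spread lengths (clipped to the
  span of the yeast transcriptome, up to the ~12.4 kb dynein transcript);
- true pSup values following the mass-based sedimentation model
  ``pSup = 1 − βL^χ`` with a condensation factor ``exp(μ + νL)`` on the
  pelleted fraction under stress, plus transcript-level scatter and
  regulon escape effects applied on the log-odds scale;
- three-fraction count tables obeying ``T ≈ α_S·S + α_P·P`` with shared
  negative-binomial dispersion;
- polysome-fraction TPM tables with fixed-amount spike-ins and
  per-fraction lognormal scale distortions;
- two-channel smFISH fields with cell masks, granule blobs and RNA spots.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sedseq.exceptions import ConfigurationError, DomainError
from sedseq.scores import log_odds

__all__ = [
    "ConditionSpec",
    "SimulatedExperiment",
    "FishField",
    "CONTROL",
    "DEFAULT_BETA",
    "DEFAULT_CHI",
    "make_catalog",
    "simulate_true_psup",
    "simulate_fraction_counts",
    "simulate_experiment",
    "simulate_polysome_experiment",
    "simulate_fish_field",
]

#: Defaults for the mass-only sedimentation law, chosen so that the pelleted
#: fraction βL^χ stays below 1 across the full 200–15000 nt length range while
#: typical ~1.3 kb transcripts keep pSup ≈ 0.88 and the longest transcripts
#: sediment strongly, as unstressed cells show.
DEFAULT_BETA = 4.0e-4
DEFAULT_CHI = 0.8

LENGTH_MIN_NT = 200
LENGTH_MAX_NT = 15_000


@dataclass(frozen=True)
class ConditionSpec:
    """A treatment condition for the condensation model.

    Parameters
    ----------
    name:
        Condition label, e.g. ``"control"`` or ``"heat_42C"``.
    mu:
        Per-molecule (length-independent) condensation parameter; the
        pelleted fraction is multiplied by ``exp(mu + nu * L)``.
    nu:
        Per-nucleotide (length-dependent) condensation parameter, 1/nt.
    induction_log2fc:
        Map regulon label -> log2 fold-change in abundance under this
        condition (transcriptional induction).
    escape_effect:
        Map regulon label -> additive shift on log-odds pSup for induced
        transcripts (escape from condensation).
    gene_noise_sd:
        SD of transcript-level scatter added on the log-odds pSup scale.
    """

    name: str
    mu: float = 0.0
    nu: float = 0.0
    induction_log2fc: dict[str, float] = field(default_factory=dict)
    escape_effect: dict[str, float] = field(default_factory=dict)
    gene_noise_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.mu < 0 or self.nu < 0:
            raise ConfigurationError("mu and nu must be nonnegative")
        if self.gene_noise_sd < 0:
            raise ConfigurationError("gene_noise_sd must be nonnegative")


#: The unstressed reference condition: no condensation, no induction.
CONTROL = ConditionSpec(name="control")


@dataclass
class SimulatedExperiment:
    """A complete simulated Sed-seq experiment with its ground truth."""

    catalog: pd.DataFrame
    condition: ConditionSpec
    true_psup: pd.Series
    counts: pd.DataFrame
    alpha_s_true: float
    alpha_p_true: float
    dispersion_true: float
    seed: int


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


def make_catalog(
    n_transcripts: int,
    length_log_mean: float = math.log(1300.0),
    length_log_sd: float = 0.6,
    regulon_fractions: dict[str, float] | None = None,
    seed: int = 0,
    abundance_log_sd: float = 1.5,
    utr5_log_mean: float = math.log(50.0),
    utr5_log_sd: float = 0.8,
) -> pd.DataFrame:
    """Generate a transcript catalog with log-normal lengths and abundances.

    Lengths are drawn log-normally (natural-log mean/sd) and clipped to
    [200, 15000] nt, spanning short yeast transcripts up to beyond the
    12.4 kb *DYN1* mRNA. Abundances are log-normal, normalized to sum to
    one million (a TPM-scale library). Regulon labels are assigned
    randomly with the given fractions; unassigned transcripts get
    ``"none"``.

    Returns a DataFrame with columns ``transcript_id``, ``length_nt``,
    ``utr5_length_nt``, ``regulon``, ``base_abundance``.
    """
    _require(n_transcripts >= 1, "n_transcripts must be >= 1")
    _require(length_log_sd > 0, "length_log_sd must be positive")
    regulon_fractions = dict(regulon_fractions or {})
    for name, frac in regulon_fractions.items():
        _require(0 <= frac <= 1, f"regulon fraction for {name!r} must be in [0,1]")
    total_frac = sum(regulon_fractions.values())
    _require(total_frac <= 1 + 1e-12, "regulon fractions must sum to <= 1")

    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.normal(length_log_mean, length_log_sd, n_transcripts))
    lengths = np.clip(np.round(lengths), LENGTH_MIN_NT, LENGTH_MAX_NT).astype(int)

    utr5 = np.exp(rng.normal(utr5_log_mean, utr5_log_sd, n_transcripts))
    utr5 = np.minimum(np.round(utr5).astype(int), lengths - 1)
    utr5 = np.maximum(utr5, 0)

    labels = ["none"] + sorted(regulon_fractions)
    probs = [1.0 - total_frac] + [regulon_fractions[k] for k in sorted(regulon_fractions)]
    regulon = rng.choice(labels, size=n_transcripts, p=np.clip(probs, 0, None) / np.sum(probs))

    abundance = np.exp(rng.normal(0.0, abundance_log_sd, n_transcripts))
    abundance = abundance / abundance.sum() * 1e6

    return pd.DataFrame(
        {
            "transcript_id": [f"t{i:05d}" for i in range(n_transcripts)],
            "length_nt": lengths,
            "utr5_length_nt": utr5,
            "regulon": regulon,
            "base_abundance": abundance,
        }
    )


def simulate_true_psup(
    catalog: pd.DataFrame,
    condition: ConditionSpec = CONTROL,
    beta: float = DEFAULT_BETA,
    chi: float = DEFAULT_CHI,
    seed: int = 0,
    clip: bool = True,
) -> pd.Series:
    """Draw true per-transcript pSup under the mass/condensation model.

    The pelleted fraction is ``β·L^χ`` in the control and
    ``β·L^χ·exp(μ + νL)`` under stress. Transcript-level noise
    (``condition.gene_noise_sd``) and regulon escape effects are added on
    the log-odds pSup scale. With ``clip=False`` a parameter combination
    that drives the pelleted fraction to >= 1 raises
    :class:`~sedseq.exceptions.DomainError`; with ``clip=True`` (default)
    it is clipped just below 1.

    Returns a Series of pSup values in (0, 1) indexed by transcript_id.
    """
    _require(beta > 0 and chi > 0, "beta and chi must be positive")
    lengths = catalog["length_nt"].to_numpy(float)
    pellet = beta * lengths**chi * np.exp(condition.mu + condition.nu * lengths)
    if np.any(pellet >= 1.0):
        if not clip:
            raise DomainError(
                "pelleted fraction >= 1 for some transcripts; "
                "reduce beta/mu/nu or enable clipping"
            )
        pellet = np.minimum(pellet, 1.0 - 1e-6)
    pellet = np.maximum(pellet, 1e-9)
    lop = log_odds(1.0 - pellet, eps=1e-9)

    rng = np.random.default_rng(seed)
    if condition.gene_noise_sd > 0:
        lop = lop + rng.normal(0.0, condition.gene_noise_sd, lengths.size)
    if condition.escape_effect:
        regulon = catalog["regulon"].to_numpy()
        for reg, shift in condition.escape_effect.items():
            lop = lop + np.where(regulon == reg, shift, 0.0)

    psup = 1.0 / (1.0 + np.exp(-lop))
    psup = np.clip(psup, 1e-9, 1 - 1e-9)
    return pd.Series(psup, index=pd.Index(catalog["transcript_id"], name="transcript_id"))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = m + m^2/dispersion.

    Falls back to Poisson for very large dispersion, where the NB shape
    parameterization loses accuracy.
    """
    mean = np.asarray(mean, float)
    if not np.isfinite(dispersion) or dispersion > 1e8:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _condition_abundance(catalog: pd.DataFrame, condition: ConditionSpec) -> np.ndarray:
    """Abundances after transcriptional induction (log2 fold-changes per regulon)."""
    abundance = catalog["base_abundance"].to_numpy(float).copy()
    if condition.induction_log2fc:
        regulon = catalog["regulon"].to_numpy()
        for reg, l2fc in condition.induction_log2fc.items():
            abundance = np.where(regulon == reg, abundance * 2.0**l2fc, abundance)
    return abundance


def simulate_fraction_counts(
    catalog: pd.DataFrame,
    true_psup: pd.Series,
    alpha_s: float = 1.0,
    alpha_p: float = 1.0,
    depth: float = 1e6,
    dispersion: float = 100.0,
    seed: int = 0,
    condition: ConditionSpec = CONTROL,
    experiment_id: str = "sim",
) -> pd.DataFrame:
    """Simulate Total/Supernatant/Pellet counts for one experiment.

    Latent per-transcript totals are proportional to (induced) abundance
    at the given depth. The supernatant and pellet expectations split the
    latent total by true pSup and are divided by the mixing ratios, so
    that ``E[T] = α_S·E[S] + α_P·E[P]`` holds exactly. All three observed
    vectors are negative-binomially distributed with a single shared
    dispersion.

    Returns a DataFrame with columns ``transcript_id``, ``total``,
    ``sup``, ``pellet``, ``experiment_id``.
    """
    _require(alpha_s > 0 and alpha_p > 0, "mixing ratios must be positive")
    _require(depth > 0, "depth must be positive")
    _require(dispersion > 0, "dispersion must be positive")
    psup = true_psup.reindex(catalog["transcript_id"]).to_numpy(float)
    if np.any(~np.isfinite(psup)):
        raise ConfigurationError("true_psup must cover every catalog transcript")

    abundance = _condition_abundance(catalog, condition)
    latent_total = abundance / abundance.sum() * depth

    rng = np.random.default_rng(seed)
    total = _nb_sample(rng, latent_total, dispersion)
    sup = _nb_sample(rng, latent_total * psup / alpha_s, dispersion)
    pellet = _nb_sample(rng, latent_total * (1.0 - psup) / alpha_p, dispersion)

    return pd.DataFrame(
        {
            "transcript_id": catalog["transcript_id"].to_numpy(),
            "total": total,
            "sup": sup,
            "pellet": pellet,
            "experiment_id": experiment_id,
        }
    )


def simulate_experiment(
    n_transcripts: int = 5000,
    condition: ConditionSpec = CONTROL,
    alpha_s: float = 1.0,
    alpha_p: float = 1.0,
    depth: float = 1e6,
    dispersion: float = 100.0,
    beta: float = DEFAULT_BETA,
    chi: float = DEFAULT_CHI,
    seed: int = 0,
    catalog: pd.DataFrame | None = None,
) -> SimulatedExperiment:
    """Convenience wrapper: catalog -> true pSup -> counts, with truth attached.

    Sub-seeds for the catalog, pSup draw and count draw are derived
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    if catalog is None:
        catalog = make_catalog(n_transcripts, seed=sub[0])
    psup = simulate_true_psup(catalog, condition, beta=beta, chi=chi, seed=sub[1])
    counts = simulate_fraction_counts(
        catalog,
        psup,
        alpha_s=alpha_s,
        alpha_p=alpha_p,
        depth=depth,
        dispersion=dispersion,
        seed=sub[2],
        condition=condition,
        experiment_id=condition.name,
    )
    return SimulatedExperiment(
        catalog=catalog,
        condition=condition,
        true_psup=psup,
        counts=counts,
        alpha_s_true=alpha_s,
        alpha_p_true=alpha_p,
        dispersion_true=dispersion,
        seed=seed,
    )


def simulate_polysome_experiment(
    catalog: pd.DataFrame,
    occupancy: pd.Series,
    spike_set_size: int = 20,
    distortion_sd: float = 0.3,
    measurement_log_sd: float = 0.05,
    depth: float = 1e6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate spike-in anchored Total/Free/Bound polysome TPM tables.

    Each transcript's abundance splits between the ribosome-free and
    ribosome-bound pools according to its occupancy. A disjoint set of
    spike-in transcripts receives identical expected abundance in every
    fraction — emulating adding a fixed amount of foreign-species total
    RNA to each pooled fraction — after which each fraction is distorted
    by a multiplicative lognormal scale factor (library-size artifact)
    and per-entry lognormal measurement noise is applied.

    Returns ``(table, truth)`` where ``table`` has columns
    ``transcript_id, fraction, tpm, est_counts, is_spike`` and ``truth``
    records the injected per-fraction distortion factors and expected
    abundances.
    """
    _require(spike_set_size >= 1, "spike_set_size must be >= 1")
    _require(distortion_sd >= 0, "distortion_sd must be nonnegative")
    occ = occupancy.reindex(catalog["transcript_id"]).to_numpy(float)
    if np.any(~np.isfinite(occ)) or np.any((occ < 0) | (occ > 1)):
        raise ConfigurationError("occupancy must cover the catalog and lie in [0,1]")

    rng = np.random.default_rng(seed)
    abundance = catalog["base_abundance"].to_numpy(float)
    # spike pool sized like a ~1% library addition so spikes comfortably clear
    # count-based QC filters at typical depths
    spike_abund = np.exp(rng.normal(math.log(400.0), 0.5, spike_set_size))
    spike_ids = [f"spike{i:03d}" for i in range(spike_set_size)]

    expected = {
        "total": np.concatenate([abundance, spike_abund]),
        "free": np.concatenate([abundance * (1.0 - occ), spike_abund]),
        "bound": np.concatenate([abundance * occ, spike_abund]),
    }
    ids = np.concatenate([catalog["transcript_id"].to_numpy(), spike_ids])
    is_spike = np.concatenate(
        [np.zeros(len(catalog), bool), np.ones(spike_set_size, bool)]
    )

    distortion = {
        frac: float(np.exp(rng.normal(0.0, distortion_sd))) for frac in expected
    }
    rows = []
    for frac, mu in expected.items():
        noisy = mu * distortion[frac]
        if measurement_log_sd > 0:
            noisy = noisy * np.exp(rng.normal(0.0, measurement_log_sd, mu.size))
        est_counts = rng.poisson(noisy / noisy.sum() * depth)
        rows.append(
            pd.DataFrame(
                {
                    "transcript_id": ids,
                    "fraction": frac,
                    "tpm": noisy,
                    "est_counts": est_counts,
                    "is_spike": is_spike,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = {"distortion": distortion, "expected": expected, "spike_ids": spike_ids}
    return table, truth


@dataclass
class FishField:
    """A simulated two-channel smFISH field with ground truth."""

    marker: np.ndarray
    spots_image: np.ndarray
    cell_mask: np.ndarray
    spots: pd.DataFrame
    granule_centers: pd.DataFrame


def _render_gaussians(
    shape: tuple[int, int],
    ys: np.ndarray,
    xs: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Render isotropic 2-D Gaussians at the given centers (additive)."""
    img = np.zeros(shape, float)
    half = max(1, int(math.ceil(4 * sigma)))
    for y, x, a in zip(ys, xs, amplitudes):
        y0, y1 = max(0, int(y) - half), min(shape[0], int(y) + half + 1)
        x0, x1 = max(0, int(x) - half), min(shape[1], int(x) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )
    return img


def simulate_fish_field(
    n_cells: int,
    spots_per_cell: int = 10,
    granule_enrichment: float = 0.0,
    psf_sigma_px: float = 1.5,
    seed: int = 0,
    cell_radius_px: int = 15,
    granules_per_cell: int = 2,
    granule_radius_px: float = 2.5,
    granule_amplitude: float = 300.0,
) -> FishField:
    """Simulate a 2-D two-channel smFISH field.

    The marker channel contains per-cell background (varying between
    cells, to exercise per-cell z-scoring) plus bright granule blobs.
    RNA spots are placed uniformly within the cell when
    ``granule_enrichment = 0``; with enrichment ``e > 0`` each spot is
    placed inside a granule with probability ``e / (1 + e)``. Cells are
    laid out on a regular grid; the field grows to fit them.

    Returns a :class:`FishField` with both channels, a labeled cell
    mask (cell ids 1..n), the ground-truth spot table and granule
    centers.
    """
    _require(n_cells >= 1, "n_cells must be >= 1")
    _require(granule_enrichment >= 0, "granule_enrichment must be nonnegative")
    _require(psf_sigma_px > 0, "psf_sigma_px must be positive")
    _require(spots_per_cell >= 1, "spots_per_cell must be >= 1")

    rng = np.random.default_rng(seed)
    box = 2 * cell_radius_px + 8
    ncol = int(math.ceil(math.sqrt(n_cells)))
    nrow = int(math.ceil(n_cells / ncol))
    shape = (nrow * box, ncol * box)

    marker = np.zeros(shape, float)
    mask = np.zeros(shape, np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    spot_rows = []
    granule_rows = []
    p_granule = granule_enrichment / (1.0 + granule_enrichment)

    for cell in range(1, n_cells + 1):
        r, c = divmod(cell - 1, ncol)
        cy = r * box + box // 2
        cx = c * box + box // 2
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px**2
        mask[inside] = cell
        background = rng.uniform(80.0, 120.0)
        marker[inside] += background

        # granule centers inside the cell, away from the rim
        g_angle = rng.uniform(0, 2 * math.pi, granules_per_cell)
        g_rad = rng.uniform(0, 0.6 * cell_radius_px, granules_per_cell)
        g_y = cy + g_rad * np.sin(g_angle)
        g_x = cx + g_rad * np.cos(g_angle)
        marker += _render_gaussians(
            shape, g_y, g_x, np.full(granules_per_cell, granule_amplitude), granule_radius_px
        )
        for gy, gx in zip(g_y, g_x):
            granule_rows.append({"cell_id": cell, "y_px": gy, "x_px": gx})

        for s in range(spots_per_cell):
            in_granule = bool(rng.random() < p_granule)
            if in_granule:
                g = rng.integers(granules_per_cell)
                sy = g_y[g] + rng.normal(0, granule_radius_px / 2)
                sx = g_x[g] + rng.normal(0, granule_radius_px / 2)
                sy = float(np.clip(sy, cy - cell_radius_px + 1, cy + cell_radius_px - 1))
                sx = float(np.clip(sx, cx - cell_radius_px + 1, cx + cell_radius_px - 1))
            else:
                while True:  # rejection-sample a uniform point in the disk
                    sy = rng.uniform(cy - cell_radius_px, cy + cell_radius_px)
                    sx = rng.uniform(cx - cell_radius_px, cx + cell_radius_px)
                    if (sy - cy) ** 2 + (sx - cx) ** 2 <= cell_radius_px**2:
                        break
            intensity = float(rng.lognormal(math.log(500.0), 0.3))
            spot_rows.append(
                {
                    "cell_id": cell,
                    "spot_id": f"c{cell}s{s}",
                    "y_px": int(round(sy)),
                    "x_px": int(round(sx)),
                    "spot_intensity": intensity,
                    "in_granule": in_granule,
                }
            )

    spots = pd.DataFrame(spot_rows)
    spots["normalized_intensity"] = spots["spot_intensity"] / spots.groupby("cell_id")[
        "spot_intensity"
    ].transform("mean")

    spots_image = _render_gaussians(
        shape,
        spots["y_px"].to_numpy(float),
        spots["x_px"].to_numpy(float),
        spots["spot_intensity"].to_numpy(float),
        psf_sigma_px,
    )
    # camera noise on both channels
    marker = marker + rng.normal(0.0, 2.0, shape)
    spots_image = spots_image + rng.normal(0.0, 2.0, shape)

    return FishField(
        marker=marker,
        spots_image=spots_image,
        cell_mask=mask,
        spots=spots,
        granule_centers=pd.DataFrame(granule_rows),
    )


def condition_to_dict(condition: ConditionSpec) -> dict:
    """JSON-serializable echo of a condition (for run manifests)."""
    return dataclasses.asdict(condition)
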