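"""smFISH colocalization between RNA spots and a granule-marker channel.

For each cell, the marker (e.g. Pab1) intensity is averaged over a 3×3
pixel box at every RNA spot centroid, and at 100 random positions drawn
uniformly from the cell mask. The per-cell colocalization score is the
z-score of the mean spot-site intensity against the random-site
distribution:

    z = (mean_spots − mean_random) / sd_random

Computing z per cell makes the score invariant to per-cell background
level and scale. The population score is the arithmetic mean over cells;
conditions are compared with pairwise Welch t-tests, Holm-adjusted.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sedseq.exceptions import DomainError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ColocalizationResult",
    "marker_intensity_at",
    "cell_zscore",
    "score_cells",
    "population_score",
    "compare_conditions",
]


@dataclass
class ColocalizationResult:
    """Per-condition colocalization summary."""

    population_score: float
    n_cells: int
    per_cell: pd.DataFrame


def marker_intensity_at(image: np.ndarray, y: int, x: int, box: int = 3) -> float:
    """Mean marker intensity in a ``box×box`` neighborhood of (y, x).

    The box is clipped at the image edge (logged); a centroid outside
    the image raises :class:`~sedseq.exceptions.InputError`. ``box`` must
    be odd; ``box=1`` returns the pixel value itself.
    """
    if box < 1 or box % 2 == 0:
        raise InputError("box must be a positive odd integer")
    h, w = image.shape
    if not (0 <= y < h and 0 <= x < w):
        raise InputError(f"centroid ({y}, {x}) outside image of shape {image.shape}")
    half = box // 2
    y0, y1 = max(0, y - half), min(h, y + half + 1)
    x0, x1 = max(0, x - half), min(w, x + half + 1)
    if (y1 - y0) != box or (x1 - x0) != box:
        logger.debug("box at (%d, %d) clipped to image bounds", y, x)
    return float(image[y0:y1, x0:x1].mean())


def cell_zscore(
    marker_image: np.ndarray,
    cell_mask: np.ndarray,
    spots: pd.DataFrame,
    n_random: int = 100,
    seed: int = 0,
    box: int = 3,
) -> float:
    """Per-cell colocalization z-score.

    ``cell_mask`` is a boolean mask of one cell; ``spots`` holds that
    cell's spot centroids (columns ``y_px``, ``x_px``). ``n_random``
    positions are sampled uniformly (with replacement) from the mask
    pixels with the given seed. Boxes may extend past the cell boundary:
    the full image neighborhood is used. A zero SD of the random-site
    intensities (e.g. a flat marker) returns 0 with a warning.
    """
    if len(spots) < 1:
        raise DomainError("cell has no spots")
    mask = np.asarray(cell_mask, bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise InputError("empty cell mask")

    spot_vals = np.array(
        [
            marker_intensity_at(marker_image, int(y), int(x), box=box)
            for y, x in zip(spots["y_px"], spots["x_px"])
        ]
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ys.size, size=n_random)
    rand_vals = np.array(
        [marker_intensity_at(marker_image, int(ys[i]), int(xs[i]), box=box) for i in idx]
    )
    sd = float(rand_vals.std(ddof=1))
    # relative floor: a flat marker yields sd ~1e-16 from mean rounding
    if sd <= 1e-12 * max(1.0, float(np.abs(rand_vals).max())):
        warnings.warn("random-site intensity SD is 0; returning z = 0", stacklevel=2)
        return 0.0
    return float((spot_vals.mean() - rand_vals.mean()) / sd)


def score_cells(
    marker_image: np.ndarray,
    cell_labels: np.ndarray,
    spots: pd.DataFrame,
    n_random: int = 100,
    seed: int = 0,
    box: int = 3,
) -> pd.DataFrame:
    """z-score every labeled cell that has at least one spot.

    ``cell_labels`` is a labeled mask (0 = background, cell ids > 0);
    ``spots`` has columns ``cell_id, y_px, x_px``. Per-cell seeds are
    derived deterministically from ``seed``. Returns a DataFrame with
    ``cell_id, z_score, n_spots, n_random``.
    """
    rows = []
    cell_ids = sorted(spots["cell_id"].unique())
    child_seeds = np.random.SeedSequence(seed).spawn(len(cell_ids))
    for cell_id, ss in zip(cell_ids, child_seeds):
        cell_spots = spots[spots["cell_id"] == cell_id]
        z = cell_zscore(
            marker_image,
            cell_labels == cell_id,
            cell_spots,
            n_random=n_random,
            seed=int(ss.generate_state(1)[0] % 2**31),
            box=box,
        )
        rows.append(
            {
                "cell_id": cell_id,
                "z_score": z,
                "n_spots": int(len(cell_spots)),
                "n_random": n_random,
            }
        )
    return pd.DataFrame(rows)


def population_score(per_cell: pd.DataFrame) -> float:
    """Mean of per-cell z-scores over all cells with at least one spot."""
    if len(per_cell) < 1:
        raise DomainError("population score requires at least one cell")
    return float(per_cell["z_score"].mean())


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def compare_conditions(per_condition: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Welch t-tests between conditions, Holm-adjusted.

    ``per_condition`` maps condition name to its per-cell score table.
    Returns one row per pair with the raw and Holm-adjusted p-values.
    """
    if len(per_condition) < 2:
        raise InputError("need at least two conditions to compare")
    pairs = list(itertools.combinations(sorted(per_condition), 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(
            per_condition[a]["z_score"],
            per_condition[b]["z_score"],
            equal_var=False,
        )
        rows.append({"condition_a": a, "condition_b": b, "t_statistic": float(t), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = _holm(out["p_value"].to_numpy())
    return out
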