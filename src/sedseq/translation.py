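"""Spike-in normalized translation metrics.

Polysome gradients are pooled into Total / Free (pre-monosome) /
Bound (ribosome-associated) fractions, each of which received a fixed
amount of foreign-species (S. pombe) total RNA before library prep.
Dividing every TPM in a fraction by the median spike-in TPM removes the
per-fraction processing scale, putting fractions on a common absolute
scale so that ribosome occupancy — the fraction of a transcript's
molecules bound by at least one ribosome — can be computed as
``bound / (bound + free)``.

For stressed samples, where condensed mRNA may pellet out of the
gradient, the lighter-weight ribosome *association* score
``TPM_bound / TPM_total`` is used instead.

Also here: the sucrose-cushion occupancy with EDTA correction (EDTA
dissolves ribosomes, so EDTA-resistant pelleting measures condensate,
not polysomes) and the length-normalized 5' UTR folding-energy score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sedseq.exceptions import DomainError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "spikein_normalize",
    "ribosome_occupancy",
    "ribosome_association",
    "cushion_occupancy",
    "structure_score",
    "DEFAULT_UTR5_LENGTH_NT",
]

#: Median yeast 5' UTR length (nt), used when a transcript has no
#: annotated 5' UTR.
DEFAULT_UTR5_LENGTH_NT = 50


def spikein_normalize(
    abundances: pd.DataFrame,
    min_spike_counts: int = 100,
    min_spikes: int = 3,
) -> pd.DataFrame:
    """Normalize each fraction's TPMs to its median spike-in TPM.

    ``abundances`` has columns ``transcript_id, fraction, tpm, is_spike``
    and optionally ``est_counts`` (used to filter spikes to those with
    more than ``min_spike_counts`` estimated counts; without the column
    all spikes qualify). Each fraction must retain at least
    ``min_spikes`` qualifying spike transcripts.

    Returns a copy with a ``norm_tpm`` column.
    """
    required = {"transcript_id", "fraction", "tpm", "is_spike"}
    if not required.issubset(abundances.columns):
        raise InputError(f"abundance table must have columns {sorted(required)}")
    out = abundances.copy()
    out["norm_tpm"] = np.nan
    for frac, grp in out.groupby("fraction"):
        spikes = grp[grp["is_spike"]]
        if "est_counts" in grp.columns:
            spikes = spikes[spikes["est_counts"] > min_spike_counts]
        if len(spikes) < min_spikes:
            raise InputError(
                f"fraction {frac!r} has {len(spikes)} qualifying spike-ins; "
                f"need at least {min_spikes}"
            )
        scale = float(spikes["tpm"].median())
        out.loc[grp.index, "norm_tpm"] = grp["tpm"] / scale
    return out


def spike_scale_factors(abundances: pd.DataFrame, min_spike_counts: int = 100) -> pd.Series:
    """Per-fraction median spike-in TPM (the recovered fraction scale)."""
    normalized = spikein_normalize(abundances, min_spike_counts=min_spike_counts)
    scales = {}
    for frac, grp in normalized.groupby("fraction"):
        scales[frac] = float((grp["tpm"] / grp["norm_tpm"]).median())
    return pd.Series(scales, name="spike_scale")


def ribosome_occupancy(
    free: pd.DataFrame,
    bound: pd.DataFrame,
    value_col: str = "norm_tpm",
) -> pd.DataFrame:
    """Absolute ribosome occupancy ``bound / (bound + free)``.

    Inputs are spike-normalized abundance tables (``transcript_id`` plus
    ``value_col``) for the ribosome-free and ribosome-bound pools.
    Transcripts with zero abundance in both pools are dropped (logged).
    """
    m = free[["transcript_id", value_col]].merge(
        bound[["transcript_id", value_col]],
        on="transcript_id",
        suffixes=("_free", "_bound"),
    )
    f = m[f"{value_col}_free"].to_numpy(float)
    b = m[f"{value_col}_bound"].to_numpy(float)
    defined = (f + b) > 0
    if int((~defined).sum()):
        logger.info("dropping %d transcripts with zero free and bound abundance", int((~defined).sum()))
    m = m.loc[defined]
    occ = b[defined] / (b[defined] + f[defined])
    return pd.DataFrame({"transcript_id": m["transcript_id"], "occupancy": occ}).reset_index(
        drop=True
    )


def ribosome_association(
    total: pd.DataFrame,
    bound: pd.DataFrame,
    value_col: str = "norm_tpm",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Ribosome association ``bound / total`` (a translation-efficiency proxy).

    Rows with ``total + pseudocount = 0`` are dropped. A log2 of the
    score with a pseudocount (default 0.5 TPM in
    :func:`association_log2_change`) is the recommended scale for
    condition-to-condition comparisons.
    """
    m = total[["transcript_id", value_col]].merge(
        bound[["transcript_id", value_col]],
        on="transcript_id",
        suffixes=("_total", "_bound"),
    )
    t = m[f"{value_col}_total"].to_numpy(float) + pseudocount
    b = m[f"{value_col}_bound"].to_numpy(float)
    keep = t > 0
    m = m.loc[keep]
    return pd.DataFrame(
        {"transcript_id": m["transcript_id"], "association": b[keep] / t[keep]}
    ).reset_index(drop=True)


def association_log2_change(
    assoc_control: pd.DataFrame,
    assoc_treated: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Plain log2 ratio of association between conditions (pseudocounted)."""
    m = assoc_control.merge(
        assoc_treated, on="transcript_id", suffixes=("_control", "_treated")
    )
    lfc = np.log2(
        (m["association_treated"] + pseudocount) / (m["association_control"] + pseudocount)
    )
    return pd.DataFrame({"transcript_id": m["transcript_id"], "log2_change": lfc})


def cushion_occupancy(
    pellet_frac_plus: float,
    pellet_frac_edta: float,
    mode: str = "conditional",
) -> float:
    """Sucrose-cushion ribosome occupancy with EDTA correction.

    ``pellet_frac_plus`` is the pelleted fraction of the transcript in
    the untreated (+Mg) cushion; ``pellet_frac_edta`` the pelleted
    fraction after EDTA dissolves ribosomes, i.e. the condensate
    contribution. The default ``"conditional"`` correction treats the
    EDTA-resistant pellet as unavailable to polysome pelleting:

        occupancy = (plus − edta) / (1 − edta), clamped to [0, 1]

    so occupancy is 0 when all pelleting survives EDTA and equals the raw
    pellet fraction when none does. ``mode="subtract"`` gives the plain
    difference ``plus − edta`` (clamped) instead.
    """
    for name, v in (("pellet_frac_plus", pellet_frac_plus), ("pellet_frac_edta", pellet_frac_edta)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1]")
    if pellet_frac_edta == 1.0:
        raise DomainError("pellet_frac_edta = 1: occupancy undefined (all pelleting is condensate)")
    if mode == "conditional":
        occ = (pellet_frac_plus - pellet_frac_edta) / (1.0 - pellet_frac_edta)
    elif mode == "subtract":
        occ = pellet_frac_plus - pellet_frac_edta
    else:
        raise InputError(f"unknown mode {mode!r}")
    return float(min(max(occ, 0.0), 1.0))


def structure_score(
    delta_g: float,
    utr5_length_nt: int | None,
    default_utr5_length_nt: int = DEFAULT_UTR5_LENGTH_NT,
) -> float:
    """Length-normalized 5' UTR folding-energy score (kcal/mol per nt).

    Folding free energy correlates with UTR length, so the score divides
    the precomputed ΔG by the UTR length; more negative means more
    structure per nucleotide. Transcripts without an annotated 5' UTR
    (length 0 or None) fall back to the median yeast UTR length (logged).
    """
    if delta_g > 0:
        logger.warning("positive folding free energy %.3g passed to structure_score", delta_g)
    if not utr5_length_nt:
        logger.info("no 5' UTR length; using default %d nt", default_utr5_length_nt)
        utr5_length_nt = default_utr5_length_nt
    if utr5_length_nt < 1:
        raise DomainError("utr5_length_nt must be >= 1")
    return float(delta_g / utr5_length_nt)
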