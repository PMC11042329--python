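"""Length-controlled condensation statistics.

All scores operate on the natural-log odds of pSup (lopSup), which avoids
compression near pSup = 0 or 1. Because sedimentation increases with
transcript length even without any condensation, each statistic controls
for length:

- ``windowed_stats``: sliding-window mean ``μ_L`` and SD ``σ_L`` of lopSup
  over log transcript length (window width = 0.02 of the full log-length
  range by default).
- ``delta_sed``: stress-induced increase in sedimentation,
  ``ΔSed = (lopSup_control − lopSup_treated) / σ_control``, where
  ``σ_control`` is the SD of all control residuals ``lopSup − μ_L``.
- ``escape_sed``: escape from sedimentation relative to same-length
  transcripts,
  ``eSed = [(lopSup_T − μ_{L,T}) − (lopSup_c − μ_{L,c})] / σ_control``.
- ``sed_score``: the within-condition relative sedimentation z-score
  (rSed / sedScore): transcripts sorted by length, binned into groups of
  100, z-scored within bins, averaged across replicates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sedseq.exceptions import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "log_odds",
    "inverse_log_odds",
    "windowed_stats",
    "condition_scores",
    "delta_sed",
    "escape_sed",
    "sed_score",
    "score_table",
]

DEFAULT_EPS = 1e-4


def log_odds(psup, eps: float = DEFAULT_EPS):
    """Natural-log odds of pSup, ``ln(p / (1 − p))``.

    Values are clamped to ``[eps, 1 − eps]`` before the transform so that
    boundary pSup values stay finite. Inputs outside [0, 1] raise
    :class:`~sedseq.exceptions.DomainError`. Accepts scalars or arrays.
    """
    p = np.asarray(psup, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("pSup values must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if np.isscalar(psup) else out


def inverse_log_odds(lop):
    """Logistic inverse of :func:`log_odds`."""
    x = np.asarray(lop, float)
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.isscalar(lop) else out


def windowed_stats(
    lengths,
    lopsup,
    window_fraction: float = 0.02,
    min_window: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and SD of lopSup over log transcript length.

    For each transcript of length L, the window contains every transcript
    whose log-length lies within ``window_fraction × (max log L − min
    log L) / 2`` of log L (the focal transcript included). Windows holding
    fewer than ``min_window`` transcripts are widened to the nearest
    ``min_window`` neighbors (logged). The SD is the sample SD (ddof=1).

    Returns ``(mu_L, sigma_L)`` arrays aligned with the input order.
    """
    L = np.asarray(lengths, float)
    y = np.asarray(lopsup, float)
    n = L.size
    if n < 2:
        raise DomainError("windowed_stats requires at least 2 transcripts")
    if np.any(L <= 0):
        raise DomainError("lengths must be positive")
    logL = np.log(L)
    half = window_fraction * (logL.max() - logL.min()) / 2.0

    order = np.argsort(logL, kind="stable")
    sl, sy = logL[order], y[order]
    cs = np.concatenate([[0.0], np.cumsum(sy)])
    cs2 = np.concatenate([[0.0], np.cumsum(sy**2)])

    lo = np.searchsorted(sl, sl - half, side="left")
    hi = np.searchsorted(sl, sl + half, side="right")

    narrow = hi - lo < min_window
    if np.any(narrow):
        logger.info(
            "widening %d windows with < %d transcripts to nearest neighbors",
            int(narrow.sum()),
            min_window,
        )
        for i in np.nonzero(narrow)[0]:
            a, b = int(lo[i]), int(hi[i])
            while b - a < min(min_window, n):
                left_gap = sl[i] - sl[a - 1] if a > 0 else np.inf
                right_gap = sl[b] - sl[i] if b < n else np.inf
                if left_gap <= right_gap:
                    a -= 1
                else:
                    b += 1
            lo[i], hi[i] = a, b

    cnt = (hi - lo).astype(float)
    mean = (cs[hi] - cs[lo]) / cnt
    var = (cs2[hi] - cs2[lo]) / cnt - mean**2
    sd = np.sqrt(np.maximum(var, 0.0) * cnt / np.maximum(cnt - 1, 1))

    mu_L = np.empty(n)
    sigma_L = np.empty(n)
    mu_L[order] = mean
    sigma_L[order] = sd
    return mu_L, sigma_L


def condition_scores(
    psup_table: pd.DataFrame,
    lengths: pd.DataFrame,
    condition: str | None = None,
    window_fraction: float = 0.02,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Per-condition score table: lopSup plus windowed length statistics.

    ``psup_table`` needs columns ``transcript_id`` and ``psup``;
    ``lengths`` needs ``transcript_id`` and ``length_nt``. Returns a
    DataFrame with ``transcript_id, condition, length_nt, lopsup, mu_L,
    sigma_L``.
    """
    df = psup_table.merge(
        lengths[["transcript_id", "length_nt"]], on="transcript_id", how="inner"
    )
    dropped = len(psup_table) - len(df)
    if dropped:
        logger.info("dropped %d transcripts without length annotation", dropped)
    df = df.copy()
    df["lopsup"] = log_odds(df["psup"].to_numpy(), eps=eps)
    mu, sigma = windowed_stats(
        df["length_nt"].to_numpy(), df["lopsup"].to_numpy(), window_fraction
    )
    df["mu_L"] = mu
    df["sigma_L"] = sigma
    if condition is not None:
        df["condition"] = condition
    return df


def _matched(control: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    m = control.merge(
        treated, on="transcript_id", how="inner", suffixes=("_control", "_treated")
    )
    n_drop = max(len(control), len(treated)) - len(m)
    if n_drop:
        logger.info("dropped %d transcripts missing in one condition", n_drop)
    if m.empty:
        raise DomainError("no transcripts shared between conditions")
    return m


def control_sigma(control: pd.DataFrame) -> float:
    """SD over all transcripts of the control residual lopSup − μ_L."""
    resid = control["lopsup"].to_numpy() - control["mu_L"].to_numpy()
    return float(np.std(resid, ddof=1))


def delta_sed(control: pd.DataFrame, treated: pd.DataFrame) -> pd.Series:
    """Differential sedimentation ΔSed, in units of σ_control.

    ``ΔSed = (lopSup_control − lopSup_treated) / σ_control``: positive
    means the transcript sediments more (condenses) under treatment.
    Both inputs are :func:`condition_scores` tables; transcripts are
    matched on id, unmatched rows dropped and logged.
    """
    m = _matched(control, treated)
    sigma = control_sigma(control)
    d = (m["lopsup_control"].to_numpy() - m["lopsup_treated"].to_numpy()) / sigma
    return pd.Series(d, index=pd.Index(m["transcript_id"], name="transcript_id"), name="delta_sed")


def escape_sed(control: pd.DataFrame, treated: pd.DataFrame) -> pd.Series:
    """Escape from sedimentation eSed, in units of σ_control.

    ``eSed = [(lopSup_T − μ_{L,T}) − (lopSup_c − μ_{L,c})] / σ_control``:
    positive means the transcript sediments less than same-length
    transcripts do under the treatment, relative to its control behavior.
    """
    m = _matched(control, treated)
    sigma = control_sigma(control)
    e = (
        (m["lopsup_treated"].to_numpy() - m["mu_L_treated"].to_numpy())
        - (m["lopsup_control"].to_numpy() - m["mu_L_control"].to_numpy())
    ) / sigma
    return pd.Series(e, index=pd.Index(m["transcript_id"], name="transcript_id"), name="e_sed")


def _binned_z(lengths: np.ndarray, lopsup: np.ndarray, ids: np.ndarray, bin_size: int) -> pd.Series:
    n = lengths.size
    order = np.lexsort((ids, lengths))  # stable: ties broken by id
    n_bins = max(1, n // bin_size)
    if n < bin_size:
        logger.info("fewer transcripts (%d) than bin_size (%d); single bin", n, bin_size)
    edges = [i * bin_size for i in range(n_bins)] + [n]  # final partial bin merged back
    z = np.empty(n)
    for b in range(n_bins):
        idx = order[edges[b] : edges[b + 1]]
        vals = lopsup[idx]
        sd = np.std(vals, ddof=1) if vals.size > 1 else 0.0
        # guard against both true ties and the ~1e-16 SD a constant array
        # acquires from rounding of its mean
        if sd <= 1e-12 * max(1.0, float(np.abs(vals).max())):
            z[idx] = 0.0
        else:
            z[idx] = (vals - vals.mean()) / sd
    return pd.Series(z, index=pd.Index(ids, name="transcript_id"), name="r_sed")


def sed_score(
    psup_replicates: list[pd.DataFrame] | pd.DataFrame,
    lengths: pd.DataFrame,
    bin_size: int = 100,
    eps: float = DEFAULT_EPS,
) -> pd.Series:
    """Relative sedimentation score rSed (a.k.a. sedScore).

    Per replicate: pSup is converted to log-odds, transcripts are sorted
    by length (including UTRs), partitioned into consecutive bins of
    ``bin_size`` (a final partial bin is merged into its predecessor),
    and z-scored within each bin. The final score is the mean of the
    per-replicate z-scores.

    ``psup_replicates`` is one or more pSup tables (columns
    ``transcript_id, psup``); ``lengths`` carries ``transcript_id,
    length_nt``.
    """
    if isinstance(psup_replicates, pd.DataFrame):
        psup_replicates = [psup_replicates]
    if not psup_replicates:
        raise DomainError("at least one replicate is required")
    per_rep = []
    for rep in psup_replicates:
        df = rep.merge(lengths[["transcript_id", "length_nt"]], on="transcript_id", how="inner")
        z = _binned_z(
            df["length_nt"].to_numpy(float),
            log_odds(df["psup"].to_numpy(), eps=eps),
            df["transcript_id"].to_numpy(),
            bin_size,
        )
        per_rep.append(z)
    combined = pd.concat(per_rep, axis=1)
    return combined.mean(axis=1).rename("r_sed")


# Methods-style alias: the binned z is reported as "sedScore" in some outputs.
sedscore = sed_score


def score_table(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    psup_replicates_treated: list[pd.DataFrame] | None = None,
    lengths: pd.DataFrame | None = None,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Assemble the full per-transcript score table for one treatment.

    Combines ΔSed, eSed and (if replicate pSup tables and lengths are
    given) the within-treatment rSed into a single DataFrame.
    """
    m = _matched(control, treated)
    out = pd.DataFrame(
        {
            "transcript_id": m["transcript_id"],
            "length_nt": m["length_nt_control"],
            "lopsup_control": m["lopsup_control"],
            "lopsup_treated": m["lopsup_treated"],
            "mu_L_control": m["mu_L_control"],
            "mu_L_treated": m["mu_L_treated"],
            "sigma_L_control": m["sigma_L_control"],
            "sigma_L_treated": m["sigma_L_treated"],
        }
    )
    out = out.set_index("transcript_id")
    out["delta_sed"] = delta_sed(control, treated)
    out["e_sed"] = escape_sed(control, treated)
    if psup_replicates_treated is not None and lengths is not None:
        out["r_sed"] = sed_score(psup_replicates_treated, lengths, bin_size=bin_size)
    return out.reset_index()
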