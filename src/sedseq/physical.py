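"""Mass-based sedimentation model, condensation extension, and mass arithmetic.

The baseline model says an mRNP pellets in proportion to a power of its
mass (proxied by transcript length L):

    pSup(L) = 1 − β·L^χ                          (baseline, 2 parameters)

Under a condensing treatment, per-molecule (μ) and per-nucleotide (ν)
interaction terms multiply the pelleted fraction:

    pSup(L) = 1 − β·L^χ·exp(μ + νL)              (stress, +2 parameters)

with μ = ν = 0 in the control. Fits are nonlinear least squares on the
log-odds(pSup) scale — approximating log-odds sedimentation as normally
distributed — with multi-start over a log-spaced β grid. Nested variants
(μ-only, ν-only) support F-tests of whether the length-independent or
length-dependent term is required.

The module also carries the polysome-scale mass arithmetic: an mRNP's
mass from its ribosome load and length, the protein-binding spacing
needed to reach a target mass, and the effective-size multiple implied
by a pSup change under the mass-only law.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from sedseq.exceptions import DomainError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "SedimentationFit",
    "NestedTestResult",
    "MassModelParams",
    "SedimentationModel",
    "fit_baseline",
    "fit_stress",
    "nested_f_test",
    "effective_size_ratio",
    "mrnp_mass",
    "protein_spacing",
]

_PELLET_CAP = 1.0 - 1e-9


@dataclass
class SedimentationFit:
    """A fitted sedimentation model."""

    beta: float
    chi: float
    mu: float
    nu: float
    rss: float
    n_points: int
    n_params: int
    converged: bool
    model: str = "baseline"
    diagnostics: dict = field(default_factory=dict)


@dataclass
class NestedTestResult:
    """Extra-sum-of-squares F-test between nested least-squares fits."""

    f_statistic: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class MassModelParams:
    """Component masses for mRNP mass arithmetic.

    Defaults: a yeast ribosome is ~3.3 MDa; an RNA nucleotide ~0.30 kDa
    (so a 1.8 kb transcript is ~0.54 MDa); a typical RNA-binding protein
    such as Pab1 is ~65 kDa.
    """

    ribosome_mass_mda: float = 3.3
    nt_mass_kda: float = 0.30
    protein_mass_kda: float = 65.0

    def __post_init__(self) -> None:
        if min(self.ribosome_mass_mda, self.nt_mass_kda, self.protein_mass_kda) <= 0:
            raise DomainError("all component masses must be positive")


def _lop_predict(
    lengths: np.ndarray, beta: float, chi: float, mu: float, nu: float, sign: float
) -> tuple[np.ndarray, bool]:
    """Predicted log-odds pSup; flags whether the pellet fraction was clamped."""
    pellet = beta * lengths**chi * np.exp(sign * (mu + nu * lengths))
    clamped = bool(np.any(pellet >= _PELLET_CAP))
    pellet = np.clip(pellet, 1e-12, _PELLET_CAP)
    psup = 1.0 - pellet
    return np.log(psup / (1.0 - psup)), clamped


class SedimentationModel(BaseEstimator):
    """Least-squares fit of the mass/condensation sedimentation model.

    Parameters
    ----------
    model:
        ``"baseline"`` fits (β, χ) only. ``"stress"`` additionally fits
        condensation terms on the treated data; which terms depends on
        ``terms``.
    terms:
        For stress fits: ``"full"`` (μ and ν), ``"mu-only"`` or
        ``"nu-only"``.
    share_baseline:
        Stress fits: if True (default) (β, χ, μ, ν) are fitted jointly on
        control + treated data with μ = ν = 0 in the control; if False,
        (β, χ) are first fitted on the control alone and then held fixed.
    exponent_sign:
        +1 (default): exp(μ + νL) multiplies the pelleted fraction, so
        positive μ, ν mean more pelleting. −1 preserves the alternative
        reading of the stress factor.
    n_beta_starts:
        Size of the log-spaced β multi-start grid.

    Attributes (after :meth:`fit`)
    ------------------------------
    beta_, chi_, mu_, nu_, rss_, converged_ and ``fit_`` (the full
    :class:`SedimentationFit`).
    """

    def __init__(
        self,
        model: str = "baseline",
        terms: str = "full",
        share_baseline: bool = True,
        exponent_sign: float = 1.0,
        n_beta_starts: int = 7,
        rss_tol: float = 1e-10,
        warm_start: dict | None = None,
    ):
        self.model = model
        self.terms = terms
        self.share_baseline = share_baseline
        self.exponent_sign = exponent_sign
        self.n_beta_starts = n_beta_starts
        self.rss_tol = rss_tol
        # optional extra start, e.g. a nested fit's solution: keys beta,
        # chi, mu, nu (missing terms default to 0). Guarantees the full
        # model can never end up with a larger RSS than a warm-start
        # nested solution.
        self.warm_start = warm_start

    # -- internal ---------------------------------------------------------

    def _free_terms(self) -> tuple[bool, bool]:
        if self.model == "baseline":
            return False, False
        return {
            "full": (True, True),
            "mu-only": (True, False),
            "nu-only": (False, True),
        }[self.terms]

    def _residuals(self, params, L, y, is_treated, fixed_baseline):
        fit_mu, fit_nu = self._free_terms()
        i = 0
        if fixed_baseline is None:
            log_beta, chi = params[0], params[1]
            i = 2
        else:
            log_beta, chi = np.log(fixed_baseline[0]), fixed_baseline[1]
        mu = params[i] if fit_mu else 0.0
        i += fit_mu
        nu = params[i] if fit_nu else 0.0
        beta = np.exp(log_beta)
        pred_c, _ = _lop_predict(L, beta, chi, 0.0, 0.0, self.exponent_sign)
        pred_t, _ = _lop_predict(L, beta, chi, mu, nu, self.exponent_sign)
        pred = np.where(is_treated, pred_t, pred_c)
        return pred - y

    def fit(
        self,
        X,
        y=None,
        treated_lengths=None,
        treated_lopsup=None,
    ) -> "SedimentationModel":
        """Fit the model.

        Baseline: ``fit(lengths, lopsup)``. Stress: additionally pass
        ``treated_lengths``/``treated_lopsup`` (the first pair is then
        the control). ``X`` may also be a DataFrame with columns
        ``length_nt`` and ``lopsup``.
        """
        L_c, y_c = _as_xy(X, y)
        if self.model == "baseline":
            L = L_c
            y_all = y_c
            is_treated = np.zeros(L.size, bool)
            fixed = None
        else:
            if treated_lopsup is None:
                raise DomainError("stress fit requires treated data")
            L_t, y_t = _as_xy(treated_lengths, treated_lopsup)
            if self.share_baseline:
                L = np.concatenate([L_c, L_t])
                y_all = np.concatenate([y_c, y_t])
                is_treated = np.concatenate(
                    [np.zeros(L_c.size, bool), np.ones(L_t.size, bool)]
                )
                fixed = None
            else:
                base = SedimentationModel(model="baseline").fit(L_c, y_c)
                L, y_all = L_t, y_t
                is_treated = np.ones(L_t.size, bool)
                fixed = (base.beta_, base.chi_)

        if L.size < 4:
            raise DomainError("need at least 4 points to fit")
        fit_mu, fit_nu = self._free_terms()
        n_params = (2 if fixed is None else 0) + fit_mu + fit_nu
        if n_params == 0:
            raise DomainError("nothing to fit: baseline fixed and no stress terms")

        nu_scale = 1.0 / max(L.max(), 1.0)
        starts: list[list[float]] = []
        if fixed is None:
            for b0 in np.logspace(-6, -2, self.n_beta_starts):
                for chi0 in (0.5, 1.0):
                    x0 = [np.log(b0), chi0]
                    if fit_mu:
                        x0.append(0.1)
                    if fit_nu:
                        x0.append(0.1 * nu_scale)
                    starts.append(x0)
        else:
            x0 = []
            if fit_mu:
                x0.append(0.1)
            if fit_nu:
                x0.append(0.1 * nu_scale)
            starts.append(x0)
        if self.warm_start is not None:
            ws = self.warm_start
            x0 = []
            if fixed is None:
                x0 += [np.log(ws["beta"]), ws["chi"]]
            if fit_mu:
                x0.append(ws.get("mu", 0.0))
            if fit_nu:
                x0.append(ws.get("nu", 0.0))
            starts.append(x0)

        best = None
        for x0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = optimize.least_squares(
                        self._residuals,
                        np.asarray(x0, float),
                        args=(L, y_all, is_treated, fixed),
                        method="lm",
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                        max_nfev=1500,
                    )
            except Exception:  # a bad start may diverge; others may still work
                continue
            rss = float(2 * res.cost)
            if res.status > 0 and (best is None or rss < best[0]):
                best = (rss, res)
        if best is None:
            raise FitError("no optimizer start converged for the sedimentation fit")
        rss, res = best

        i = 0
        if fixed is None:
            beta, chi = float(np.exp(res.x[0])), float(res.x[1])
            i = 2
        else:
            beta, chi = fixed
        mu = float(res.x[i]) if fit_mu else 0.0
        i += fit_mu
        nu = float(res.x[i]) if fit_nu else 0.0

        pellet = beta * L**chi * np.exp(
            self.exponent_sign * (mu + nu * L) * is_treated
        )
        clamped = bool(np.any(pellet >= _PELLET_CAP))
        if clamped:
            # routine for strong condensation where the truth itself saturates;
            # recorded in diagnostics rather than shouted per fit
            logger.debug("predicted pelleted fraction >= 1 was clamped during fit")

        self.beta_, self.chi_, self.mu_, self.nu_ = beta, chi, mu, nu
        self.rss_ = rss
        self.converged_ = bool(res.status > 0)
        self.n_points_ = int(L.size)
        self.fit_ = SedimentationFit(
            beta=beta,
            chi=chi,
            mu=mu,
            nu=nu,
            rss=rss,
            n_points=int(L.size),
            n_params=2 + fit_mu + fit_nu if fixed is None else fit_mu + fit_nu,
            converged=self.converged_,
            model=self.model if self.model == "baseline" else f"stress:{self.terms}",
            diagnostics={"clamped": clamped, "optimizer_status": int(res.status)},
        )
        return self

    def predict(self, lengths, treated: bool = False) -> np.ndarray:
        """Predicted log-odds pSup at the given lengths."""
        if not hasattr(self, "beta_"):
            raise FitError("model is not fitted")
        L = np.asarray(lengths, float)
        mu, nu = (self.mu_, self.nu_) if treated else (0.0, 0.0)
        pred, _ = _lop_predict(L, self.beta_, self.chi_, mu, nu, self.exponent_sign)
        return pred

    def predict_psup(self, lengths, treated: bool = False) -> np.ndarray:
        lop = self.predict(lengths, treated=treated)
        return 1.0 / (1.0 + np.exp(-lop))


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        return X["length_nt"].to_numpy(float), X["lopsup"].to_numpy(float)
    L = np.asarray(X, float).ravel()
    return L, np.asarray(y, float).ravel()


def fit_baseline(lengths, lopsup) -> SedimentationFit:
    """Fit ``pSup = 1 − βL^χ`` by log-odds NLS (multi-start)."""
    return SedimentationModel(model="baseline").fit(lengths, lopsup).fit_


def fit_stress(
    control_lengths,
    control_lopsup,
    treated_lengths,
    treated_lopsup,
    terms: str = "full",
    share_baseline: bool = True,
    exponent_sign: float = 1.0,
) -> SedimentationFit:
    """Fit the condensation extension ``pSup = 1 − βL^χ·exp(μ + νL)``.

    ``terms`` selects the free condensation parameters (``"full"``,
    ``"mu-only"``, ``"nu-only"``); ``share_baseline`` controls whether
    (β, χ) are refit jointly with the stress terms or frozen at the
    control-only fit.
    """
    model = SedimentationModel(
        model="stress",
        terms=terms,
        share_baseline=share_baseline,
        exponent_sign=exponent_sign,
    )
    model.fit(
        control_lengths,
        control_lopsup,
        treated_lengths=treated_lengths,
        treated_lopsup=treated_lopsup,
    )
    return model.fit_


def nested_f_test(fit_full: SedimentationFit, fit_reduced: SedimentationFit) -> NestedTestResult:
    """Extra-sum-of-squares F-test of a reduced model nested in a full one.

    ``F = [(RSS_r − RSS_f)/(p_f − p_r)] / [RSS_f/(n − p_f)]`` with
    p-value from the F(p_f − p_r, n − p_f) distribution. A full fit with
    *larger* RSS than the reduced fit signals an optimizer failure; this
    returns F = 0, p = 1 with a warning rather than a negative F.
    """
    if fit_full.n_points != fit_reduced.n_points:
        raise DomainError("nested fits must use identical data")
    df1 = fit_full.n_params - fit_reduced.n_params
    df2 = fit_full.n_points - fit_full.n_params
    if df1 <= 0 or df2 <= 0:
        raise DomainError("reduced model must have fewer parameters than the full model")
    if fit_full.rss > fit_reduced.rss:
        logger.warning(
            "full-model RSS exceeds reduced-model RSS (optimizer failure?); returning F = 0"
        )
        return NestedTestResult(0.0, df1, df2, 1.0)
    f = ((fit_reduced.rss - fit_full.rss) / df1) / (fit_full.rss / df2)
    return NestedTestResult(float(f), df1, df2, float(stats.f.sf(f, df1, df2)))


def effective_size_ratio(psup_control: float, psup_treated: float, chi: float) -> float:
    """Mass multiple implied by a pSup change under the mass-only law.

    With pelleting ∝ (mass)^χ, a transcript whose pSup drops from
    ``psup_control`` to ``psup_treated`` sediments as if its mass were
    multiplied by ``k = [(1 − pSup_t)/(1 − pSup_c)]^(1/χ)``. A treated
    pSup above the control gives k < 1 (apparent dissolution).
    """
    if not (0 < psup_control < 1 and 0 < psup_treated < 1):
        raise DomainError("pSup values must lie strictly in (0, 1)")
    if chi <= 0:
        raise DomainError("chi must be positive")
    return float(((1.0 - psup_treated) / (1.0 - psup_control)) ** (1.0 / chi))


def mrnp_mass(
    n_ribosomes: int, length_nt: int, params: MassModelParams = MassModelParams()
) -> float:
    """Mass of an mRNP in MDa: ribosome load plus the RNA itself.

    A five-ribosome polysome on a 1.8 kb transcript comes to ~17 MDa
    (5 × 3.3 MDa + 1800 nt × 0.30 kDa/nt ≈ 16.5 + 0.54).
    """
    if n_ribosomes < 0 or length_nt < 0:
        raise DomainError("n_ribosomes and length_nt must be nonnegative")
    return n_ribosomes * params.ribosome_mass_mda + length_nt * params.nt_mass_kda / 1000.0


def protein_spacing(
    target_mass_mda: float, length_nt: int, params: MassModelParams = MassModelParams()
) -> float:
    """Nucleotides per bound protein needed to reach a target mRNP mass.

    Computes how many proteins of ``protein_mass_kda`` must bind a
    ``length_nt`` transcript for the mRNP to weigh ``target_mass_mda``,
    and returns the implied spacing in nt per protein. Reaching polysome
    scale (~17 MDa on 1.8 kb) by protein binding alone would need one
    65 kDa protein every ~7 nt — an unphysical density.
    """
    rna_mass = mrnp_mass(0, length_nt, params)
    if target_mass_mda <= rna_mass:
        raise DomainError("target mass must exceed the bare mRNA mass")
    n_proteins = (target_mass_mda - rna_mass) * 1000.0 / params.protein_mass_kda
    return float(length_nt / n_proteins)
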