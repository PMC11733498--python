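"""Latitudinal clines in allele / arrangement frequency with an empirical
random-SNP null, and cross-range parallelism calls.

Each unit (haploblock arrangement or SNP) is fit with a per-individual
binomial logistic regression: the dosage (0/1/2) is the number of successes
in 2 trials and the predictor is absolute latitude. Significance is decided
against the empirical distribution of slopes from background SNPs sampled
outside genes and haploblocks, not against the asymptotic GLM p-value — the
null SNPs carry the same drift covariance as the tested units, so the
empirical tail calibrates the test under population structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotationSet, GenotypeMatrix, MISSING, sample_background_snps

logger = logging.getLogger(__name__)

__all__ = [
    "ClineFit",
    "NullSlopes",
    "ParallelismCall",
    "fit_cline",
    "fit_clines",
    "null_slope_distribution",
    "is_significant",
    "call_parallelism",
    "fit_cline_joint",
]

_TRIALS = 2
_MAX_ABS_SLOPE = 20.0  # |beta1| beyond this flags separation


@dataclass
class ClineFit:
    unit_id: str
    range_label: str
    beta0: float
    beta1: float
    converged: str              # "yes" | "separation"
    significant: bool | None = None
    null_lower: float = np.nan
    null_upper: float = np.nan

    @property
    def direction(self) -> str:
        return "+" if self.beta1 >= 0 else "-"


@dataclass
class NullSlopes:
    slopes: np.ndarray          # sorted, converged fits only
    lower: float
    upper: float
    tail: float
    mode: str                   # "two-sided" | "one-sided"
    n_nonconverged: int = 0


@dataclass
class ParallelismCall:
    unit_id: str
    ranges_significant: list[str] = field(default_factory=list)
    parallel: bool = False
    shared_direction: str = ""


def _irls(
    y: np.ndarray,
    x: np.ndarray,
    mask: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-row binomial(2) logistic regressions.

    y: (S, N) successes, x: (N,) predictor, mask: (S, N) True where observed.
    Returns (beta0, beta1, converged) arrays of length S.
    """
    S = y.shape[0]
    yf = np.where(mask, y, 0).astype(float)
    mvec = np.where(mask, float(_TRIALS), 0.0)
    # initialize from the empirical logit of the overall frequency
    tot = yf.sum(axis=1)
    ntr = mvec.sum(axis=1)
    p0 = np.clip((tot + 0.5) / (ntr + 1.0), 1e-6, 1 - 1e-6)
    b0 = np.log(p0 / (1 - p0))
    b1 = np.zeros(S)
    done = np.zeros(S, dtype=bool)
    saturated = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
        saturated = np.any((np.abs(eta) >= 29.0) & (mvec > 0), axis=1)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mvec * np.clip(mu * (1.0 - mu), 1e-12, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(w > 0, eta + (yf - mvec * mu) / np.where(w > 0, w, 1.0), eta)
        a = w.sum(axis=1) + ridge
        b = (w * x).sum(axis=1)
        c = (w * x * x).sum(axis=1) + ridge
        r1 = (w * z).sum(axis=1)
        r2 = (w * x * z).sum(axis=1)
        det = a * c - b * b
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (c * r1 - b * r2) / det
        nb1 = (a * r2 - b * r1) / det
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        b0, b1 = nb0, nb1
        done = done | (step < tol) | bad
        if done.all():
            break
    converged = (
        done & ~saturated & (np.abs(b1) < _MAX_ABS_SLOPE)
        & np.isfinite(b0) & np.isfinite(b1)
    )
    return b0, b1, converged


def fit_clines(
    dosages: np.ndarray,
    latitudes: np.ndarray,
    ridge_on_separation: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binomial logistic fits of many units against |latitude|.

    dosages: (S, N) in {0, 1, 2, MISSING}; latitudes: (N,).
    Returns (beta0, beta1, converged) with converged an array of strings
    "yes" / "separation".
    """
    lat = np.abs(np.asarray(latitudes, dtype=float))
    if len(np.unique(lat)) < 2:
        raise ValueError("need >= 2 distinct latitudes to fit a cline")
    d = np.atleast_2d(np.asarray(dosages))
    mask = d != MISSING
    b0, b1, ok = _irls(d, lat, mask)
    flags = np.where(ok, "yes", "separation")
    if not ok.all():
        # perfect separation or non-convergence: small ridge stabilizes
        idx = np.flatnonzero(~ok)
        rb0, rb1, _ = _irls(d[idx], lat, mask[idx], ridge=ridge_on_separation,
                            max_iter=200)
        b0[idx], b1[idx] = rb0, rb1
    return b0, b1, flags


def fit_cline(
    dosages: np.ndarray,
    latitudes: np.ndarray,
    unit_id: str = "",
    range_label: str = "",
) -> ClineFit:
    """Fit one unit's frequency cline against absolute latitude."""
    b0, b1, flags = fit_clines(np.asarray(dosages)[None, :], latitudes)
    return ClineFit(unit_id=unit_id, range_label=range_label,
                    beta0=float(b0[0]), beta1=float(b1[0]), converged=str(flags[0]))


def null_slope_distribution(
    gm: GenotypeMatrix,
    annotations: AnnotationSet,
    latitudes: np.ndarray,
    k: int = 10_000,
    tail: float = 0.05,
    mode: str = "two-sided",
    seed: int = 0,
) -> NullSlopes:
    """Empirical slope distribution from background SNPs.

    ``tail`` is the total significance level: two-sided cutoffs sit at
    tail/2 and 1 - tail/2 of the converged-slope distribution (a one-sided
    per-direction mode at ``tail`` each side is available). Non-converged
    fits are excluded and counted.
    """
    n_eligible_err = None
    try:
        idx = sample_background_snps(gm, annotations, k, seed)
    except ValueError as exc:
        n_eligible_err = str(exc)
        from .io_formats import sites_in_intervals

        excluded = sites_in_intervals(gm, annotations.genes) | sites_in_intervals(
            gm, annotations.haploblocks
        )
        idx = np.flatnonzero(~excluded)
        logger.warning("using all %d eligible background SNPs: %s", len(idx), n_eligible_err)
    lat = np.abs(np.asarray(latitudes, dtype=float))
    b0, b1, flags = fit_clines(gm.dosages[:, idx].T, lat)
    ok = flags == "yes"
    slopes = np.sort(b1[ok])
    if mode == "two-sided":
        lower = float(np.quantile(slopes, tail / 2))
        upper = float(np.quantile(slopes, 1 - tail / 2))
    elif mode == "one-sided":
        lower = float(np.quantile(slopes, tail))
        upper = float(np.quantile(slopes, 1 - tail))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NullSlopes(slopes=slopes, lower=lower, upper=upper, tail=tail,
                      mode=mode, n_nonconverged=int((~ok).sum()))


def is_significant(fit: ClineFit, null: NullSlopes) -> ClineFit:
    """Mark a fit against the null cutoffs (mutates and returns the fit)."""
    fit.null_lower, fit.null_upper = null.lower, null.upper
    fit.significant = bool(fit.beta1 < null.lower or fit.beta1 > null.upper)
    return fit


def call_parallelism(fits: list[ClineFit]) -> ParallelismCall:
    """Parallel iff >= 2 ranges are significant with the same slope sign."""
    if len(fits) < 2:
        raise ValueError("parallelism needs fits from >= 2 ranges")
    unit = fits[0].unit_id
    sig = [f for f in fits if f.significant]
    call = ParallelismCall(unit_id=unit, ranges_significant=[f.range_label for f in sig])
    directions = {f.direction for f in sig}
    if len(sig) >= 2 and len(directions) == 1:
        call.parallel = True
        call.shared_direction = directions.pop()
    return call


def fit_cline_joint(
    dosages: np.ndarray,
    latitudes: np.ndarray,
    range_labels: np.ndarray,
    alpha: float = 0.05,
):
    """Joint binomial GLM across ranges: frequency ~ |latitude| * range.

    The range x latitude interaction is dropped when its likelihood-ratio
    test is nonsignificant at ``alpha``. Returns the fitted statsmodels
    result and a dict describing the chosen model.
    """
    import pandas as pd
    import statsmodels.api as sm

    d = np.asarray(dosages, dtype=float)
    keep = d != MISSING
    lat = np.abs(np.asarray(latitudes, dtype=float))[keep]
    rng_lab = pd.Categorical(np.asarray(range_labels)[keep])
    y = np.column_stack([d[keep], _TRIALS - d[keep]])

    dummies = pd.get_dummies(rng_lab, drop_first=True).to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(lat)), lat, dummies])
    inter = np.column_stack([base, dummies * lat[:, None]])

    fit_base = sm.GLM(y, base, family=sm.families.Binomial()).fit()
    fit_inter = sm.GLM(y, inter, family=sm.families.Binomial()).fit()
    from scipy.stats import chi2

    lr = 2 * (fit_inter.llf - fit_base.llf)
    df = inter.shape[1] - base.shape[1]
    p_inter = float(chi2.sf(max(lr, 0.0), df))
    if p_inter < alpha:
        return fit_inter, {"interaction": True, "p_interaction": p_inter}
    return fit_base, {"interaction": False, "p_interaction": p_inter}
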