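"""Summary-data causal estimators for harmonized two-sample MR pairs.

Notation: for instrument j, beta_Xj is the per-allele instrument-exposure
coefficient and beta_Yj, se_Yj the instrument-outcome coefficient and its
standard error, all on the additive scale (ln odds ratios for binary
traits). The estimators implemented:

Wald (ratio)     theta_j = beta_Yj / beta_Xj, se = se_Yj / |beta_Xj|
                 (first-order delta method; the exposure-side uncertainty is
                 ignored, standard in two-sample summary MR).
IVW (fixed)      theta = sum(w_j theta_j) / sum(w_j) with w_j =
                 beta_Xj^2 / se_Yj^2, equivalently
                 sum(beta_Xj beta_Yj / se_Yj^2) / sum(beta_Xj^2 / se_Yj^2);
                 se = (sum w_j)^(-1/2). Cochran's Q reported.
Random effects   DerSimonian-Laird pooling of the per-variant ratios:
                 tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with
                 S_m = sum(w_j^m); reduces to fixed-effect pooling at
                 tau^2 = 0.
MR-Egger         weighted least squares of beta_Yj on beta_Xj *with an
                 intercept*, weights 1/se_Yj^2; the slope estimates the
                 causal effect, the intercept the average directional
                 pleiotropy. Requires exposure direction standardization
                 (otherwise the intercept is not identified), which is
                 asserted.

All estimation stays on the additive scale; :meth:`MRResult.oddsratio`
exponentiates only for presentation. A harmonization failure in exactly one
dataset negates a variant's ratio (beta_Y / -beta_X = -beta_Y / beta_X) — the
algebraic reason harmonization matters, and a property the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, ValidationError
from .harmonization import HarmonizedPair
from .summary_io import SummaryDataset

__all__ = [
    "RatioEstimate",
    "MRResult",
    "ratio_estimate",
    "ivw",
    "meta_random",
    "egger",
    "rescale_exposure",
]

Z_95 = float(stats.norm.ppf(0.975))


class RatioEstimate(NamedTuple):
    variant_id: str
    estimate: float
    se: float


@dataclass
class MRResult:
    """A causal estimate with uncertainty and per-variant evidence.

    ``estimate`` is per unit of exposure on the additive scale; for a binary
    outcome it is a ln odds ratio — use :meth:`oddsratio` for presentation.
    Heterogeneity (Cochran's Q, tau^2) and the Egger intercept are populated
    where the method defines them.
    """

    method: str
    estimate: float
    se: float
    n_variants: int
    per_variant: list[RatioEstimate] = field(default_factory=list)
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    tau2: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None

    @property
    def ci_low(self) -> float:
        return self.estimate - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z_95 * self.se

    def oddsratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper): the exponentiated estimate and 95% bounds."""
        return (
            float(np.exp(self.estimate)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_variants": self.n_variants,
            "per_variant": [r._asdict() for r in self.per_variant],
        }
        for name in ("q", "q_df", "q_pvalue", "tau2", "egger_intercept",
                     "egger_intercept_se"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return d


def _usable(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    kept = [p for p in pairs if not p.action.dropped and p.outcome is not None]
    return kept


def ratio_estimate(pair: HarmonizedPair) -> tuple[float, float]:
    """Wald ratio for one harmonized pair: (beta_Y / beta_X, se_Y / |beta_X|)."""
    if pair.action.dropped or pair.outcome is None:
        raise EstimationError(f"{pair.variant_id}: pair was dropped during harmonization")
    bx, by, sey = pair.exposure.beta, pair.outcome.beta, pair.outcome.se
    if bx == 0:
        raise EstimationError(f"{pair.variant_id}: beta_X is 0, ratio undefined")
    return by / bx, sey / abs(bx)


def _ratios(pairs: Sequence[HarmonizedPair]) -> list[RatioEstimate]:
    out = []
    for p in pairs:
        est, se = ratio_estimate(p)
        out.append(RatioEstimate(p.variant_id, est, se))
    return out


def ivw(pairs: Sequence[HarmonizedPair]) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over all usable pairs.

    With a single pair this is exactly the Wald ratio. Invariant to flipping
    a variant consistently in both datasets (beta_X beta_Y and beta_X^2 are
    orientation-invariant); flipping in only one dataset negates that
    variant's contribution.
    """
    pairs = _usable(pairs)
    if not pairs:
        raise EstimationError("IVW needs at least one usable (non-dropped) pair")
    bx = np.array([p.exposure.beta for p in pairs])
    by = np.array([p.outcome.beta for p in pairs])
    sey = np.array([p.outcome.se for p in pairs])
    if np.any(bx == 0):
        zero = [p.variant_id for p in pairs if p.exposure.beta == 0]
        raise EstimationError(f"beta_X is 0 for {', '.join(zero)}; ratio undefined")
    w = bx**2 / sey**2
    estimate = float(np.sum(bx * by / sey**2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    per_variant = _ratios(pairs)
    ratios = np.array([r.estimate for r in per_variant])
    q = float(np.sum(w * (ratios - estimate) ** 2))
    q_df = len(pairs) - 1
    result = MRResult(
        method="ivw_fixed",
        estimate=estimate,
        se=se,
        n_variants=len(pairs),
        per_variant=per_variant,
        q=q,
        q_df=q_df,
        q_pvalue=float(stats.chi2.sf(q, q_df)) if q_df > 0 else None,
    )
    return result


def meta_random(pairs: Sequence[HarmonizedPair]) -> MRResult:
    """DerSimonian-Laird random-effects pooling of the per-variant Wald ratios.

    The between-variant variance tau^2 is the usual method-of-moments
    estimate, truncated at zero; when Q does not exceed its degrees of
    freedom the result coincides with fixed-effect inverse-variance pooling
    of the ratios.
    """
    pairs = _usable(pairs)
    if len(pairs) < 2:
        raise EstimationError("random-effects pooling needs at least 2 usable pairs")
    per_variant = _ratios(pairs)
    r = np.array([x.estimate for x in per_variant])
    v = np.array([x.se for x in per_variant]) ** 2
    w = 1.0 / v
    fixed = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - fixed) ** 2))
    k = len(pairs)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    estimate = float(np.sum(w_star * r) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    return MRResult(
        method="meta_random",
        estimate=estimate,
        se=se,
        n_variants=k,
        per_variant=per_variant,
        q=q,
        q_df=k - 1,
        q_pvalue=float(stats.chi2.sf(q, k - 1)),
        tau2=float(tau2),
    )


def egger(pairs: Sequence[HarmonizedPair]) -> MRResult:
    """MR-Egger regression: WLS of beta_Y on beta_X with an intercept.

    The slope is the causal estimate under the InSIDE assumption; the
    intercept estimates average directional pleiotropy and is ~0 when the
    instruments are valid. Refuses to run unless the exposure direction has
    been standardized (all beta_X >= 0), since the intercept's meaning
    depends on a consistent instrument orientation.
    """
    pairs = _usable(pairs)
    if len(pairs) < 3:
        raise EstimationError("MR-Egger needs at least 3 usable pairs")
    bx = np.array([p.exposure.beta for p in pairs])
    if np.any(bx < 0):
        neg = [p.variant_id for p in pairs if p.exposure.beta < 0]
        raise EstimationError(
            "MR-Egger requires direction-standardized exposure coefficients "
            f"(all beta_X >= 0); negative for {', '.join(neg)}. Re-run "
            "harmonization with standardize_direction enabled."
        )
    by = np.array([p.outcome.beta for p in pairs])
    sey = np.array([p.outcome.se for p in pairs])
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sey**2).fit()
    intercept, slope = fit.params
    intercept_se, slope_se = fit.bse
    return MRResult(
        method="egger",
        estimate=float(slope),
        se=float(slope_se),
        n_variants=len(pairs),
        per_variant=_ratios(pairs),
        egger_intercept=float(intercept),
        egger_intercept_se=float(intercept_se),
    )


def rescale_exposure(dataset: SummaryDataset, factor: float) -> SummaryDataset:
    """Divide exposure coefficients and SEs by ``factor`` (unit change).

    Downstream causal estimates then read "per ``factor`` original units of
    exposure": e.g. dividing blood-pressure coefficients by 10 yields
    estimates per 10 mmHg. Applies to the exposure dataset only — rescaling
    the outcome would silently rescale the causal estimate's meaning.
    """
    if dataset.role != "exposure":
        raise ValidationError("rescale_exposure applies to the exposure dataset only")
    if not factor > 0:
        raise ValidationError(f"rescale factor must be > 0, got {factor}")
    return dataset.with_records(
        rec.with_(beta=rec.beta / factor, se=rec.se / factor) for rec in dataset
    )
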