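"""Quality-control diagnostics for the harmonization process.

Good harmonization leaves fingerprints that can be checked from summary data
alone: effect allele frequencies of the two datasets should correlate
strongly *after* (but not necessarily before) allele matching; standard
errors should sit on a line (slope != 1 when the sample sizes differ); and
the orientation-invariant quantities |beta|, SE and minor-allele frequency
must be untouched by harmonization — a variant where they differ between two
versions of a dataset points to a typographical error, the kind of single-
variant corruption that has flipped published causal effect estimates.

EAF correlations always use frequencies as proportions. With case-control
outcome data, EAFs estimated in controls are preferable when available; that
caveat cannot be enforced from summary statistics and is documentation only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import QCError
from .harmonization import HarmonizedPair, pairs_to_datasets
from .summary_io import SummaryDataset

__all__ = [
    "SERegression",
    "DiscrepancyFlag",
    "AuditResult",
    "QCReport",
    "eaf_correlation",
    "se_regression",
    "audit_datasets",
    "build_qc_report",
]

MIN_SHARED = 3


def _shared(
    ds1: SummaryDataset, ds2: SummaryDataset, fields: tuple[str, ...]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pair records by variant_id, keeping those with all ``fields`` present."""
    ids, x, y = [], [], []
    for rec in ds1:
        if rec.variant_id not in ds2:
            continue
        other = ds2.get(rec.variant_id)
        vals1 = [getattr(rec, f) for f in fields]
        vals2 = [getattr(other, f) for f in fields]
        if any(v is None for v in vals1 + vals2):
            continue
        ids.append(rec.variant_id)
        x.append(vals1[0])
        y.append(vals2[0])
    return ids, np.asarray(x, float), np.asarray(y, float)


def eaf_correlation(ds1: SummaryDataset, ds2: SummaryDataset) -> float:
    """Pearson correlation of effect allele frequencies over shared variants.

    Symmetric in its arguments, and invariant to flipping a variant
    simultaneously in both datasets. Requires >= 3 shared variants with EAF
    in both and non-degenerate variance.
    """
    ids, x, y = _shared(ds1, ds2, ("eaf",))
    if len(ids) < MIN_SHARED:
        raise QCError(
            f"EAF correlation undefined: only {len(ids)} shared variants with "
            f"EAF in both datasets (need >= {MIN_SHARED})"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QCError("EAF correlation undefined: zero variance in one dataset")
    return float(stats.pearsonr(x, y)[0])


class SERegression(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def se_regression(ds1: SummaryDataset, ds2: SummaryDataset) -> SERegression:
    """OLS of ds2 standard errors on ds1 standard errors over shared variants.

    Regression is preferred over a plain correlation here because a sample
    size difference between the two GWAS shifts the SEs systematically
    (slope away from 1) without breaking their linear relation.
    """
    ids, x, y = _shared(ds1, ds2, ("se",))
    if len(ids) < MIN_SHARED:
        raise QCError(f"SE regression undefined: only {len(ids)} shared variants")
    if np.ptp(x) == 0:
        raise QCError("SE regression undefined: zero variance in predictor SEs")
    fit = stats.linregress(x, y)
    return SERegression(float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)


@dataclass(frozen=True)
class DiscrepancyFlag:
    """One orientation-invariant quantity differing beyond tolerance."""

    variant_id: str
    quantity: str  # "beta_magnitude" | "se" | "maf"
    claimed: float
    reference: float
    rel_diff: float


@dataclass(frozen=True)
class AuditResult:
    flags: list[DiscrepancyFlag]
    orientation_mismatches: list[str]
    n_compared: int


def _rel_diff(a: float, b: float) -> float:
    denom = max(abs(a), abs(b))
    if denom == 0:
        return 0.0
    return abs(a - b) / denom


def audit_datasets(
    claimed: SummaryDataset,
    reference: SummaryDataset,
    *,
    rel_tol: float = 1e-6,
) -> AuditResult:
    """Forensically compare two versions of a dataset for typographical errors.

    For every shared variant, |beta|, SE and minor-allele frequency — all
    invariant to allele orientation — are compared at relative tolerance
    ``rel_tol`` (default 1e-6, suited to printed-precision data; widen for
    sources with heavier rounding). Variants whose effect alleles differ are
    listed separately as orientation mismatches: legitimate coding
    differences, not typos, but they must be reconciled before analysis.
    """
    shared_ids = [r.variant_id for r in claimed if r.variant_id in reference]
    if not shared_ids:
        raise QCError("audit impossible: datasets share no variant ids")
    flags: list[DiscrepancyFlag] = []
    orientation: list[str] = []
    for vid in shared_ids:
        c, r = claimed.get(vid), reference.get(vid)
        if c.effect_allele != r.effect_allele:
            orientation.append(vid)
        checks = [("beta_magnitude", abs(c.beta), abs(r.beta)), ("se", c.se, r.se)]
        if c.maf is not None and r.maf is not None:
            checks.append(("maf", c.maf, r.maf))
        for quantity, cv, rv in checks:
            d = _rel_diff(cv, rv)
            if d > rel_tol:
                flags.append(DiscrepancyFlag(vid, quantity, cv, rv, d))
    return AuditResult(flags=flags, orientation_mismatches=orientation,
                       n_compared=len(shared_ids))


@dataclass
class QCReport:
    """Aggregate harmonization-quality evidence, serializable to JSON/text."""

    eaf_corr_pre: float | None
    eaf_corr_post: float | None
    se_regression: SERegression | None
    n_variants: int
    n_surviving: int
    n_proxies_used: int
    n_dropped: dict[str, int] = field(default_factory=dict)
    flags: list[DiscrepancyFlag] = field(default_factory=list)
    orientation_mismatches: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "eaf_corr_pre": self.eaf_corr_pre,
            "eaf_corr_post": self.eaf_corr_post,
            "se_regression": None
            if self.se_regression is None
            else self.se_regression._asdict(),
            "n_variants": self.n_variants,
            "n_surviving": self.n_surviving,
            "n_proxies_used": self.n_proxies_used,
            "n_dropped": dict(self.n_dropped),
            "flags": [vars(f) for f in self.flags],
            "orientation_mismatches": list(self.orientation_mismatches),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = ["Harmonization QC report", "-----------------------"]
        fmt = lambda v: "n/a" if v is None else f"{v:.3f}"  # noqa: E731
        lines.append(f"EAF correlation pre-harmonization : {fmt(self.eaf_corr_pre)}")
        lines.append(f"EAF correlation post-harmonization: {fmt(self.eaf_corr_post)}")
        if self.se_regression is not None:
            s = self.se_regression
            lines.append(
                f"SE regression: slope {s.slope:.3f}, intercept {s.intercept:.4g}, "
                f"R^2 {s.r_squared:.3f}"
            )
        lines.append(
            f"Variants: {self.n_variants} paired, {self.n_surviving} surviving, "
            f"{self.n_proxies_used} via LD proxy"
        )
        for reason, n in sorted(self.n_dropped.items()):
            lines.append(f"  dropped ({reason}): {n}")
        lines.append(f"Typo-style discrepancy flags: {len(self.flags)}")
        for f in self.flags:
            lines.append(
                f"  {f.variant_id}: {f.quantity} {f.claimed:.6g} vs {f.reference:.6g}"
            )
        return "\n".join(lines)


def build_qc_report(
    pairs: Sequence[HarmonizedPair],
    pre_exposure: SummaryDataset,
    pre_outcome: SummaryDataset,
    *,
    audit_reference: SummaryDataset | None = None,
    rel_tol: float = 1e-6,
) -> QCReport:
    """Assemble the QC report for one harmonization run.

    ``pre_exposure`` / ``pre_outcome`` are the datasets *after* proxy
    substitution but *before* direction standardization and allele matching
    (the pre-harmonization comparison point). The post-harmonization EAF
    correlation is computed from the surviving pairs. When ``audit_reference``
    is supplied (an independent copy of the outcome associations), the
    post-harmonization outcome records are audited against it for typos.
    Statistics that are undefined on the inputs (too few EAFs, degenerate
    variance) are reported as None rather than aborting the report.
    """
    post_exp, post_out = pairs_to_datasets(list(pairs))

    def _try(fn, *args):
        try:
            return fn(*args)
        except QCError:
            return None

    report = QCReport(
        eaf_corr_pre=_try(eaf_correlation, pre_exposure, pre_outcome),
        eaf_corr_post=_try(eaf_correlation, post_exp, post_out),
        se_regression=_try(se_regression, post_exp, post_out),
        n_variants=len(pairs),
        n_surviving=len(post_exp),
        n_proxies_used=sum(1 for p in pairs if p.proxy_used is not None),
        n_dropped=dict(
            Counter(
                p.action.drop_reason.value for p in pairs if p.action.dropped
            )
        ),
    )
    if audit_reference is not None and len(post_out) > 0:
        try:
            audit = audit_datasets(post_out, audit_reference, rel_tol=rel_tol)
        except QCError:
            audit = None
        if audit is not None:
            report.flags = audit.flags
            report.orientation_mismatches = audit.orientation_mismatches
    return report
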