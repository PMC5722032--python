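"""LD-proxy substitution for instruments missing from the outcome GWAS.

When an exposure instrument was not tested in the outcome GWAS it can be
replaced by a variant in high linkage disequilibrium with it. Two modes:

``replace_in_both`` (default, preferred)
    The proxy's own summary records — which must be present in both
    datasets — take the target's place in *both* datasets. No phasing
    assumption is needed because the proxy is analysed as itself.

``replace_in_outcome_only``
    The target keeps its exposure record; the proxy's outcome record is
    adopted under the target's identity. This requires knowing the phase:
    the signed allelic correlation between the proxy's and the target's
    effect alleles. A negative sign means the proxy's effect allele travels
    with the target's *other* allele, so the adopted record is flipped
    first. Partial LD (|r| < 1) only means the alleles are *typically* in
    phase, so this mode emits a warning.

Proxies below the LD-strength threshold (default r² 0.8) are not applied;
the skip is recorded so the target is later dropped with an explicit reason.
"""

from __future__ import annotations

import warnings
from typing import Any, Sequence

from .errors import ProxyError
from .harmonization import flip
from .summary_io import ProxyEntry, SummaryDataset, VariantRecord

__all__ = ["apply_proxies", "DEFAULT_MIN_R2"]

DEFAULT_MIN_R2 = 0.8

SubstitutionLog = list[dict[str, Any]]


def _adopt_under_target(
    entry: ProxyEntry, target: VariantRecord, proxy_outcome: VariantRecord
) -> VariantRecord:
    """Re-identify a proxy outcome record as the target, honouring phase."""
    oriented = proxy_outcome if entry.signed_r > 0 else flip(proxy_outcome)
    return oriented.with_(
        variant_id=target.variant_id,
        effect_allele=target.effect_allele,
        other_allele=target.other_allele,
    )


def apply_proxies(
    exposure_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    proxies: Sequence[ProxyEntry],
    mode: str = "replace_in_both",
    *,
    min_r2: float = DEFAULT_MIN_R2,
) -> tuple[SummaryDataset, SummaryDataset, SubstitutionLog]:
    """Apply LD-proxy substitutions; returns new datasets and a substitution log.

    The number of exposure instruments never changes: substitution replaces
    rows in place (``replace_in_both``) or edits the outcome side only.
    Each log entry records target, proxy, mode, signed_r, r², whether it was
    applied, and the id the adopted record carries afterwards.
    """
    if mode not in ("replace_in_both", "replace_in_outcome_only"):
        raise ProxyError(f"unknown proxy mode {mode!r}")

    exp_records = list(exposure_ds.records)
    out_records = list(outcome_ds.records)
    log: SubstitutionLog = []

    for entry in proxies:
        if entry.target_id not in exposure_ds:
            raise ProxyError(
                f"proxy target {entry.target_id} is not in the exposure dataset"
            )
        if mode == "replace_in_outcome_only" and entry.signed_r == 0:
            raise ProxyError(
                f"proxy {entry.proxy_id} for {entry.target_id}: signed_r is 0, "
                "phase is unidentifiable in replace_in_outcome_only mode"
            )
        base = {
            "target_id": entry.target_id,
            "proxy_id": entry.proxy_id,
            "mode": mode,
            "signed_r": entry.signed_r,
            "r2": entry.ld_strength,
        }
        if entry.ld_strength < min_r2:
            warnings.warn(
                f"proxy {entry.proxy_id} for {entry.target_id} rejected: "
                f"r2={entry.ld_strength:.3f} below threshold {min_r2}",
                stacklevel=2,
            )
            log.append({**base, "applied": False, "adopted_id": None,
                        "reason": "below_min_r2"})
            continue

        if mode == "replace_in_both":
            exp_ids = [r.variant_id for r in exp_records]
            out_ids = [r.variant_id for r in out_records]
            if entry.proxy_id not in exp_ids:
                raise ProxyError(
                    f"proxy {entry.proxy_id} has no record in the exposure dataset "
                    "(replace_in_both needs the proxy's summary row in both datasets)"
                )
            if entry.proxy_id not in out_ids:
                raise ProxyError(
                    f"proxy {entry.proxy_id} has no record in the outcome dataset"
                )
            proxy_exp = exp_records[exp_ids.index(entry.proxy_id)]
            # the proxy row moves into the target's slot; its original row goes
            target_pos = exp_ids.index(entry.target_id)
            exp_records[target_pos] = proxy_exp
            exp_records = [
                r for i, r in enumerate(exp_records)
                if not (r.variant_id == entry.proxy_id and i != target_pos)
            ]
            # a stale target row in the outcome would now be unmatched; drop it
            out_records = [r for r in out_records if r.variant_id != entry.target_id]
            log.append({**base, "applied": True, "adopted_id": entry.proxy_id,
                        "reason": None})
        else:
            if entry.signed_r == 0:
                raise ProxyError(
                    f"proxy {entry.proxy_id} for {entry.target_id}: signed_r is 0, "
                    "phase is unidentifiable in replace_in_outcome_only mode"
                )
            out_ids = [r.variant_id for r in out_records]
            if entry.proxy_id not in out_ids:
                raise ProxyError(
                    f"proxy {entry.proxy_id} has no record in the outcome dataset"
                )
            target_exp = exposure_ds.get(entry.target_id)
            adopted = _adopt_under_target(
                entry, target_exp, out_records[out_ids.index(entry.proxy_id)]
            )
            warnings.warn(
                f"{entry.target_id}: outcome association taken from proxy "
                f"{entry.proxy_id} assuming phase from signed_r={entry.signed_r:+.2f}; "
                "partial LD implies the alleles are typically, not always, in phase",
                stacklevel=2,
            )
            out_records = [r for r in out_records if r.variant_id != entry.proxy_id]
            if entry.target_id in {r.variant_id for r in out_records}:
                out_records = [
                    adopted if r.variant_id == entry.target_id else r for r in out_records
                ]
            else:
                out_records.append(adopted)
            log.append({**base, "applied": True, "adopted_id": entry.target_id,
                        "reason": None})

    return (
        exposure_ds.with_records(exp_records),
        outcome_ds.with_records(out_records),
        log,
    )
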