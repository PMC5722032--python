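"""Allele harmonization between exposure and outcome summary datasets.

Two GWAS rarely code the same SNP the same way: the effect allele is an
arbitrary choice, strands may differ, and palindromic SNPs (A/T, C/G) carry
no strand information in their symbols at all. This module reconciles the
outcome dataset's coding with the exposure dataset's, variant by variant:

1. LD-proxy substitution for instruments missing from the outcome GWAS
   (delegated to :mod:`mrharmonize.proxy`);
2. direction standardization — flip exposure records so every instrument's
   effect allele is the exposure-increasing allele (``beta >= 0``), a
   precondition of MR-Egger and a convention that eases plotting;
3. per-variant allele matching — identical coding, swapped effect/other
   alleles, opposite-strand coding, or palindromes resolved by effect-allele
   frequency concordance.

The *flip* operation re-expresses an association with the opposite allele as
the effect allele: alleles swap, the additive coefficient is multiplied by
-1, the SE is untouched, and the EAF becomes 1 - EAF.

Failures are not exceptions: every irreconcilable variant yields a
``dropped`` action with a machine-readable reason, so the full audit trail
can be published alongside the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .errors import HarmonizationError, ValidationError
from .summary_io import ProxyEntry, SummaryDataset, VariantRecord

__all__ = [
    "COMPLEMENT",
    "ActionCode",
    "DropReason",
    "HarmonizationAction",
    "HarmonizedPair",
    "HarmonizationConfig",
    "complement",
    "is_palindromic",
    "flip",
    "standardize_direction",
    "match_alleles",
    "harmonize",
    "pairs_to_datasets",
    "pairs_to_frame",
    "frame_to_pairs",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Watson-Crick complement of a single allele (A<->T, C<->G)."""
    return COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the two alleles are complements (A/T or C/G pair).

    Such SNPs read identically from either strand, so strand mismatches
    cannot be detected from allele symbols alone.
    """
    return COMPLEMENT[effect_allele] == other_allele


def flip(record: VariantRecord) -> VariantRecord:
    """Re-express ``record`` with the other allele as effect allele.

    Swaps the alleles, negates beta, complements the EAF (1 - eaf; left
    missing if missing) and leaves the SE unchanged. Involution:
    ``flip(flip(r)) == r`` up to floating-point round-trip of ``1 - eaf``.
    """
    return record.with_(
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )


class ActionCode(str, Enum):
    NONE = "none"
    FLIP_OUTCOME = "flip_outcome"
    STRAND_COMPLEMENT = "strand_complement"
    STRAND_COMPLEMENT_AND_FLIP = "strand_complement_and_flip"
    PALINDROME_RESOLVED_BY_EAF = "palindrome_resolved_by_eaf"
    DROPPED = "dropped"


class DropReason(str, Enum):
    ALLELE_PAIR_MISMATCH = "allele_pair_mismatch"
    PALINDROME_AMBIGUOUS = "palindrome_ambiguous"
    MISSING_IN_OUTCOME_NO_PROXY = "missing_in_outcome_no_proxy"
    MISSING_EAF_REQUIRED = "missing_eaf_required"


@dataclass(frozen=True)
class HarmonizationAction:
    """What was done to reconcile one variant, or why it was dropped."""

    code: ActionCode
    drop_reason: DropReason | None = None

    def __post_init__(self) -> None:
        if (self.code is ActionCode.DROPPED) != (self.drop_reason is not None):
            raise ValidationError("drop_reason must be present iff code is dropped")

    @property
    def dropped(self) -> bool:
        return self.code is ActionCode.DROPPED


@dataclass(frozen=True)
class HarmonizedPair:
    """Matched exposure/outcome records for one instrument plus the audit entry.

    For surviving pairs the two records share the same (effect, other) allele
    coding. ``outcome`` is None only for variants dropped because no outcome
    record (or proxy) existed.
    """

    variant_id: str
    exposure: VariantRecord
    outcome: VariantRecord | None
    action: HarmonizationAction
    proxy_used: str | None = None


@dataclass(frozen=True)
class HarmonizationConfig:
    """Tunable thresholds and policies of the harmonization procedure.

    palindrome_maf_window
        Half-width delta of the EAF ambiguity band: a palindromic SNP with an
        EAF inside [0.5 - delta, 0.5 + delta] (in either dataset) cannot be
        oriented reliably by frequency. Default 0.08, i.e. ambiguous within
        [0.42, 0.58]; guidance in the field asks only that the minor allele
        frequency be "substantially" below 50%, so the width is configurable
        and recorded in output metadata.
    palindrome_policy
        ``keep_resolved`` (default) orients unambiguous palindromes by EAF
        concordance and drops ambiguous ones; ``drop_ambiguous`` is an alias
        of the same behaviour; ``drop_all`` discards every palindromic SNP.
    standardize_direction
        Flip exposure records so the effect allele is exposure-increasing.
    allow_strand_complement
        Attempt opposite-strand reconciliation for non-palindromic SNPs.
    require_eaf_for_palindromes
        Drop palindromes lacking an EAF on either side (default). If False,
        palindromes without EAF fall back to symbol matching under an
        assumed shared strand — use only when both sources are known to
        report the same strand.
    confirm_with_eaf
        Opt-in cross-check: after symbol-based matching of non-palindromic
        variants, warn when the major/minor classification disagrees between
        datasets. Never overrides symbol matching.
    """

    palindrome_maf_window: float = 0.08
    palindrome_policy: str = "keep_resolved"
    standardize_direction: bool = True
    allow_strand_complement: bool = True
    require_eaf_for_palindromes: bool = True
    confirm_with_eaf: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.palindrome_maf_window < 0.5:
            raise ValidationError(
                f"palindrome_maf_window must be in (0, 0.5), got {self.palindrome_maf_window}"
            )
        if self.palindrome_policy not in ("keep_resolved", "drop_ambiguous", "drop_all"):
            raise ValidationError(f"unknown palindrome_policy {self.palindrome_policy!r}")


def standardize_direction(dataset: SummaryDataset) -> SummaryDataset:
    """Flip exposure records with negative beta so all instruments increase the exposure.

    Idempotent; records with beta exactly 0 are kept as-is with a warning
    (no exposure-increasing allele is defined for them).
    """
    if dataset.role != "exposure":
        raise ValidationError("direction standardization applies to the exposure dataset")
    out: list[VariantRecord] = []
    for rec in dataset:
        if rec.beta < 0:
            out.append(flip(rec))
        else:
            if rec.beta == 0:
                warnings.warn(
                    f"{rec.variant_id}: beta is exactly 0; no exposure-increasing "
                    "allele is defined, record left unflipped",
                    stacklevel=2,
                )
            out.append(rec)
    return dataset.with_records(out)


def _dropped(reason: DropReason) -> HarmonizationAction:
    return HarmonizationAction(ActionCode.DROPPED, reason)


def _match_palindrome(
    exposure: VariantRecord, outcome: VariantRecord, config: HarmonizationConfig
) -> tuple[VariantRecord, HarmonizationAction]:
    if config.palindrome_policy == "drop_all":
        return outcome, _dropped(DropReason.PALINDROME_AMBIGUOUS)
    if set(outcome.allele_pair) != set(exposure.allele_pair):
        return outcome, _dropped(DropReason.ALLELE_PAIR_MISMATCH)
    if exposure.eaf is None or outcome.eaf is None:
        if config.require_eaf_for_palindromes:
            return outcome, _dropped(DropReason.MISSING_EAF_REQUIRED)
        # assumed shared strand: plain symbol matching, no complementation
        if outcome.allele_pair == exposure.allele_pair:
            return outcome, HarmonizationAction(ActionCode.NONE)
        return flip(outcome), HarmonizationAction(ActionCode.FLIP_OUTCOME)
    lo = 0.5 - config.palindrome_maf_window
    hi = 0.5 + config.palindrome_maf_window
    if lo <= exposure.eaf <= hi or lo <= outcome.eaf <= hi:
        return outcome, _dropped(DropReason.PALINDROME_AMBIGUOUS)
    # Express the outcome in the exposure's symbol order, then pick the
    # physical orientation whose EAF sits on the same side of 0.5 as the
    # exposure EAF. For a palindrome the opposite orientation has the same
    # symbols with beta negated and EAF complemented (flip + strand
    # complement), so symbols alone can never decide.
    base = outcome if outcome.effect_allele == exposure.effect_allele else flip(outcome)
    alt = base.with_(beta=-base.beta, eaf=1.0 - base.eaf)
    chosen = base if (base.eaf < 0.5) == (exposure.eaf < 0.5) else alt
    if chosen == outcome:
        return outcome, HarmonizationAction(ActionCode.NONE)
    return chosen, HarmonizationAction(ActionCode.PALINDROME_RESOLVED_BY_EAF)


def match_alleles(
    exposure: VariantRecord,
    outcome: VariantRecord,
    config: HarmonizationConfig | None = None,
) -> tuple[VariantRecord, HarmonizationAction]:
    """Reconcile one outcome record's allele coding with its exposure record.

    Returns the (possibly flipped/complemented) outcome record and the action
    taken. Never raises on irreconcilable input: the pair is returned with a
    ``dropped`` action so the pipeline is total.

    Resolution for non-palindromic pairs: identical coding -> ``none``;
    effect/other swapped -> flip the outcome; opposite-strand coding (the
    outcome pair equals the complemented exposure pair, same or swapped
    order) -> complement, then flip if also swapped. Palindromic exposure
    pairs bypass symbol logic entirely — complementation is unobservable for
    them — and are oriented by EAF concordance, or dropped when either EAF is
    missing or inside the ambiguity window.
    """
    config = config or HarmonizationConfig()
    if is_palindromic(*exposure.allele_pair):
        matched, action = _match_palindrome(exposure, outcome, config)
    else:
        ep, op = exposure.allele_pair, outcome.allele_pair
        if op == ep:
            matched, action = outcome, HarmonizationAction(ActionCode.NONE)
        elif op == ep[::-1]:
            matched, action = flip(outcome), HarmonizationAction(ActionCode.FLIP_OUTCOME)
        else:
            comp_pair = (complement(op[0]), complement(op[1]))
            if config.allow_strand_complement and comp_pair == ep:
                matched = outcome.with_(effect_allele=comp_pair[0], other_allele=comp_pair[1])
                action = HarmonizationAction(ActionCode.STRAND_COMPLEMENT)
            elif config.allow_strand_complement and comp_pair == ep[::-1]:
                relabeled = outcome.with_(effect_allele=comp_pair[0], other_allele=comp_pair[1])
                matched = flip(relabeled)
                action = HarmonizationAction(ActionCode.STRAND_COMPLEMENT_AND_FLIP)
            else:
                matched, action = outcome, _dropped(DropReason.ALLELE_PAIR_MISMATCH)
        if (
            config.confirm_with_eaf
            and not action.dropped
            and exposure.eaf is not None
            and matched.eaf is not None
            and (exposure.eaf < 0.5) != (matched.eaf < 0.5)
            and abs(exposure.eaf - 0.5) > config.palindrome_maf_window
            and abs(matched.eaf - 0.5) > config.palindrome_maf_window
        ):
            warnings.warn(
                f"{exposure.variant_id}: major/minor allele classification disagrees "
                f"between datasets after symbol matching (EAFs {exposure.eaf:.3f} vs "
                f"{matched.eaf:.3f}); check strand and source coding",
                stacklevel=2,
            )
    return matched, action


def harmonize(
    exposure_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    proxies: Sequence[ProxyEntry] | None = None,
    config: HarmonizationConfig | None = None,
) -> list[HarmonizedPair]:
    """Run the full harmonization pipeline and return one pair per instrument.

    Steps, in order: LD-proxy substitution (when ``proxies`` given),
    exposure direction standardization (when configured), then per-variant
    allele matching. Dropped variants are included in the result with their
    reasons. Deterministic, and idempotent: harmonizing an already
    harmonized pair of datasets yields all actions ``none``.
    """
    from .proxy import apply_proxies  # local import: proxy uses flip() above

    config = config or HarmonizationConfig()
    if len(exposure_ds) == 0 and len(outcome_ds) == 0:
        raise HarmonizationError("both datasets are empty")
    if exposure_ds.role != "exposure" or outcome_ds.role != "outcome":
        raise ValidationError("harmonize expects (exposure, outcome) datasets in that order")

    proxied_by: dict[str, str] = {}
    if proxies:
        exposure_ds, outcome_ds, sub_log = apply_proxies(exposure_ds, outcome_ds, proxies)
        proxied_by = {s["adopted_id"]: s["proxy_id"] for s in sub_log if s["applied"]}

    if config.standardize_direction:
        exposure_ds = standardize_direction(exposure_ds)

    pairs: list[HarmonizedPair] = []
    for exp_rec in exposure_ds:
        vid = exp_rec.variant_id
        if vid not in outcome_ds:
            pairs.append(
                HarmonizedPair(
                    variant_id=vid,
                    exposure=exp_rec,
                    outcome=None,
                    action=_dropped(DropReason.MISSING_IN_OUTCOME_NO_PROXY),
                    proxy_used=proxied_by.get(vid),
                )
            )
            continue
        matched, action = match_alleles(exp_rec, outcome_ds.get(vid), config)
        pairs.append(
            HarmonizedPair(
                variant_id=vid,
                exposure=exp_rec,
                outcome=matched,
                action=action,
                proxy_used=proxied_by.get(vid),
            )
        )
    if pairs and all(p.action.dropped for p in pairs):
        reasons = sorted({p.action.drop_reason.value for p in pairs})
        raise HarmonizationError(
            "no variant survived harmonization; inspect the drop log "
            f"(reasons seen: {', '.join(reasons)})"
        )
    return pairs


def pairs_to_datasets(pairs: Sequence[HarmonizedPair]) -> tuple[SummaryDataset, SummaryDataset]:
    """Post-harmonization (exposure, outcome) datasets of the surviving pairs."""
    kept = [p for p in pairs if not p.action.dropped]
    return (
        SummaryDataset([p.exposure for p in kept], role="exposure"),
        SummaryDataset([p.outcome for p in kept], role="outcome"),
    )


_PAIR_COLUMNS = [
    "variant_id",
    "exp_effect_allele", "exp_other_allele", "exp_beta", "exp_se", "exp_eaf",
    "out_effect_allele", "out_other_allele", "out_beta", "out_se", "out_eaf",
    "action", "drop_reason", "proxy_used",
]


def pairs_to_frame(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Flatten harmonized pairs into the tabular audit format (one row per variant)."""
    rows = []
    for p in pairs:
        e, o = p.exposure, p.outcome
        rows.append(
            {
                "variant_id": p.variant_id,
                "exp_effect_allele": e.effect_allele,
                "exp_other_allele": e.other_allele,
                "exp_beta": e.beta,
                "exp_se": e.se,
                "exp_eaf": e.eaf,
                "out_effect_allele": None if o is None else o.effect_allele,
                "out_other_allele": None if o is None else o.other_allele,
                "out_beta": None if o is None else o.beta,
                "out_se": None if o is None else o.se,
                "out_eaf": None if o is None else o.eaf,
                "action": p.action.code.value,
                "drop_reason": None if p.action.drop_reason is None else p.action.drop_reason.value,
                "proxy_used": p.proxy_used,
            }
        )
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[HarmonizedPair]:
    """Inverse of :func:`pairs_to_frame` (used by the CLI ``estimate`` stage)."""
    pairs: list[HarmonizedPair] = []
    for row in frame.to_dict("records"):
        exposure = VariantRecord(
            variant_id=row["variant_id"],
            effect_allele=row["exp_effect_allele"],
            other_allele=row["exp_other_allele"],
            beta=row["exp_beta"],
            se=row["exp_se"],
            eaf=None if pd.isna(row["exp_eaf"]) else row["exp_eaf"],
        )
        outcome = None
        if not pd.isna(row["out_effect_allele"]):
            outcome = VariantRecord(
                variant_id=row["variant_id"],
                effect_allele=row["out_effect_allele"],
                other_allele=row["out_other_allele"],
                beta=row["out_beta"],
                se=row["out_se"],
                eaf=None if pd.isna(row["out_eaf"]) else row["out_eaf"],
            )
        reason = row.get("drop_reason")
        action = HarmonizationAction(
            ActionCode(row["action"]),
            None if reason is None or pd.isna(reason) else DropReason(reason),
        )
        proxy = row.get("proxy_used")
        pairs.append(
            HarmonizedPair(
                variant_id=row["variant_id"],
                exposure=exposure,
                outcome=outcome,
                action=action,
                proxy_used=None if proxy is None or pd.isna(proxy) else proxy,
            )
        )
    return pairs
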