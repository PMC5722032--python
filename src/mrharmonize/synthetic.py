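"""Synthetic paired summary datasets with injected harmonization faults.

The generator emulates what a two-sample MR analyst actually downloads: an
instrument-exposure table and an instrument-outcome table produced by two
GWAS that never agreed on allele coding. Ground truth is known by
construction — the causal effect theta, every corruption applied, and the
action a correct harmonization must take for every variant — so the whole
pipeline is testable end to end without any external data.

Model: per instrument j, a true per-allele exposure effect beta_Xj (magnitude
uniform on a configurable interval, random sign, since the reported effect
allele is arbitrary) and an outcome effect beta_Yj = c + theta * beta_Xj,
observed with independent normal errors at GWAS-like standard errors that
scale as 1/sqrt(2 p (1-p)) in the allele frequency p. Instruments are
independent (no LD among them), matching the usual clumped-instrument
selection.

Fault classes injected into the *outcome* table (mutually exclusive per
variant): effect/other allele swap (the dataset reports the opposite effect
allele — beta negated, EAF complemented), opposite-strand reporting (symbols
complemented, numbers untouched), and removal (to exercise LD-proxy
substitution; a generated proxy row is placed in both tables). Palindromic
A/T and C/G variants are assigned at a configurable rate, with a
sub-fraction given near-50% frequencies that make them unresolvable.
Typographical errors multiply one variant's beta or SE by a configurable
factor (default 3x, comfortably above audit tolerance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np

from .errors import ValidationError
from .harmonization import ActionCode, DropReason, complement, flip
from .summary_io import ProxyEntry, SummaryDataset, VariantRecord

__all__ = ["FaultConfig", "TruthRecord", "TruthLog", "generate_pair", "table2_fixture"]

_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# palindrome EAF bands: unambiguous draws keep a 0.02 margin beyond the
# default +-0.08 ambiguity window so small cross-cohort frequency noise
# cannot push them across the boundary; ambiguous draws sit well inside it
_UNAMBIG_BANDS = ((0.05, 0.40), (0.60, 0.95))
_AMBIG_BAND = (0.44, 0.56)


@dataclass(frozen=True)
class FaultConfig:
    """Study conditions for one simulated exposure/outcome dataset pair.

    All proportions lie in [0, 1]; the outcome-table fault fractions
    (``frac_allele_swapped``, ``frac_strand_flipped``,
    ``frac_missing_in_outcome``) are mutually exclusive per variant and must
    sum to at most 1. ``seed`` fully determines the output.
    """

    n_variants: int = 50
    true_effect: float = 0.3
    exposure_beta_range: tuple[float, float] = (0.1, 0.5)  # interval for |beta_X|
    exposure_se: float = 0.01  # SE scale at EAF 0.5
    outcome_se: float = 0.05
    eaf_range: tuple[float, float] = (0.05, 0.95)
    frac_allele_swapped: float = 0.0
    frac_strand_flipped: float = 0.0
    frac_palindromic: float = 0.0
    frac_ambiguous_palindromes: float = 0.0
    frac_missing_in_outcome: float = 0.0
    n_typos: int = 0
    typo_factor: float = 3.0
    pleiotropy_intercept: float = 0.0
    proxy_signed_r: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")
        fracs = {
            "frac_allele_swapped": self.frac_allele_swapped,
            "frac_strand_flipped": self.frac_strand_flipped,
            "frac_palindromic": self.frac_palindromic,
            "frac_ambiguous_palindromes": self.frac_ambiguous_palindromes,
            "frac_missing_in_outcome": self.frac_missing_in_outcome,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        excl = (
            self.frac_allele_swapped
            + self.frac_strand_flipped
            + self.frac_missing_in_outcome
        )
        if excl > 1.0 + 1e-12:
            raise ValidationError(
                "mutually exclusive outcome fault fractions sum to "
                f"{excl:.3f} > 1 (allele swap + strand flip + missing)"
            )
        if not (self.exposure_se > 0 and self.outcome_se > 0):
            raise ValidationError("exposure_se and outcome_se must be > 0")
        if self.n_typos < 0:
            raise ValidationError("n_typos must be >= 0")
        if not 0 < abs(self.proxy_signed_r) <= 1:
            raise ValidationError("proxy_signed_r must be nonzero with |r| <= 1")


@dataclass
class TruthRecord:
    """Ground truth for one variant: faults applied and the action a correct
    harmonization must take (None for targets replaced by a proxy, which
    carry their expectation on the proxy's record)."""

    variant_id: str
    palindromic: bool
    ambiguous: bool
    faults: list[str] = field(default_factory=list)
    expected_action: str | None = None
    expected_drop_reason: str | None = None
    replaced_by: str | None = None


@dataclass
class TruthLog:
    true_effect: float
    pleiotropy_intercept: float
    seed: int
    records: list[TruthRecord] = field(default_factory=list)

    def expected_actions(self) -> dict[str, tuple[str, str | None]]:
        """Map variant_id -> (expected action, drop reason) for every id that
        appears as a harmonized pair (replaced targets excluded)."""
        return {
            r.variant_id: (r.expected_action, r.expected_drop_reason)
            for r in self.records
            if r.expected_action is not None
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "true_effect": self.true_effect,
                "pleiotropy_intercept": self.pleiotropy_intercept,
                "seed": self.seed,
                "records": [asdict(r) for r in self.records],
            },
            indent=2,
            **kwargs,
        )


def _se_scale(base: float, p: float) -> float:
    # GWAS-style: var(beta_hat) ~ 1 / (2 n p (1-p)); normalized to `base` at p=0.5
    return base * 0.5 / np.sqrt(p * (1.0 - p))


def _draw_unambiguous_pal_eaf(rng: np.random.Generator) -> float:
    band = _UNAMBIG_BANDS[int(rng.integers(2))]
    return float(rng.uniform(*band))


def _clip_same_band(p: float, bands) -> float:
    for lo, hi in bands if isinstance(bands, tuple) and isinstance(bands[0], tuple) else (bands,):
        if lo <= p <= hi:
            return p
    # fell outside: clip to the nearest band edge
    edges = [e for band in (bands if isinstance(bands[0], tuple) else (bands,)) for e in band]
    return float(min(edges, key=lambda e: abs(e - p)))


def _expected_action(
    palindromic: bool, ambiguous: bool, exposure_flipped: bool,
    swapped: bool, strand: bool,
) -> tuple[str, str | None]:
    if palindromic:
        if ambiguous:
            return ActionCode.DROPPED.value, DropReason.PALINDROME_AMBIGUOUS.value
        if swapped == exposure_flipped and not strand:
            return ActionCode.NONE.value, None
        return ActionCode.PALINDROME_RESOLVED_BY_EAF.value, None
    net_swap = swapped != exposure_flipped
    if strand and net_swap:
        return ActionCode.STRAND_COMPLEMENT_AND_FLIP.value, None
    if strand:
        return ActionCode.STRAND_COMPLEMENT.value, None
    if net_swap:
        return ActionCode.FLIP_OUTCOME.value, None
    return ActionCode.NONE.value, None


def generate_pair(
    config: FaultConfig,
) -> tuple[SummaryDataset, SummaryDataset, list[ProxyEntry], TruthLog]:
    """Generate (exposure dataset, outcome dataset, proxy table, truth log).

    Fully reproducible from ``config.seed``. Expected harmonization actions
    recorded in the truth log assume the default pipeline configuration
    (direction standardization on, strand complementation allowed,
    ambiguity window 0.08).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    theta, c = config.true_effect, config.pleiotropy_intercept

    # --- variant classes and fault assignment ----------------------------
    # drawn first, with a stream consumption that depends only on n and the
    # palindrome fractions, so that fault injection never perturbs the base
    # associations drawn below for the same seed
    n_pal = round(config.frac_palindromic * n)
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist()) if n_pal else set()
    n_amb = round(config.frac_ambiguous_palindromes * n_pal)
    amb_idx = (
        set(rng.choice(sorted(pal_idx), size=n_amb, replace=False).tolist())
        if n_amb
        else set()
    )
    n_swap = round(config.frac_allele_swapped * n)
    n_strand = round(config.frac_strand_flipped * n)
    n_miss = round(config.frac_missing_in_outcome * n)
    perm = rng.permutation(n)
    swap_idx = set(perm[:n_swap].tolist())
    strand_idx = set(perm[n_swap : n_swap + n_strand].tolist())
    miss_idx = set(perm[n_swap + n_strand : n_swap + n_strand + n_miss].tolist())

    # --- phase 1: clean base associations --------------------------------
    exposure_records: list[VariantRecord] = []
    clean_outcome: list[VariantRecord] = []
    bx_true_all: list[float] = []
    for j in range(n):
        vid = f"rs{j + 1}"
        palindromic = j in pal_idx
        ambiguous = j in amb_idx
        if palindromic:
            alleles = _PAL_PAIRS[int(rng.integers(len(_PAL_PAIRS)))]
            p_exp = (
                float(rng.uniform(*_AMBIG_BAND))
                if ambiguous
                else _draw_unambiguous_pal_eaf(rng)
            )
        else:
            alleles = _NONPAL_PAIRS[int(rng.integers(len(_NONPAL_PAIRS)))]
            p_exp = float(rng.uniform(*config.eaf_range))
        # outcome cohort frequency: same population, small sampling noise,
        # kept inside the same resolvability band for palindromes
        p_out = p_exp + float(rng.normal(0.0, 0.01))
        if palindromic:
            p_out = _clip_same_band(p_out, _AMBIG_BAND if ambiguous else _UNAMBIG_BANDS)
        else:
            p_out = float(np.clip(p_out, 0.01, 0.99))
        bx_true = float(rng.uniform(*config.exposure_beta_range)) * float(
            rng.choice([-1.0, 1.0])
        )
        se_x = _se_scale(config.exposure_se, p_exp)
        se_y = _se_scale(config.outcome_se, p_out)
        bx_true_all.append(bx_true)
        bx_obs = bx_true + float(rng.normal(0.0, se_x))
        by_obs = c + theta * bx_true + float(rng.normal(0.0, se_y))
        exposure_records.append(
            VariantRecord(vid, alleles[0], alleles[1], bx_obs, se_x, p_exp)
        )
        clean_outcome.append(VariantRecord(vid, alleles[0], alleles[1], by_obs, se_y, p_out))

    # --- phase 2: fault injection ----------------------------------------
    outcome_records: list[VariantRecord] = []
    proxies: list[ProxyEntry] = []
    proxy_rows: list[tuple[VariantRecord, VariantRecord]] = []  # (exposure, outcome)
    truth = TruthLog(true_effect=theta, pleiotropy_intercept=c, seed=config.seed)

    for j in range(n):
        vid = f"rs{j + 1}"
        palindromic = j in pal_idx
        ambiguous = j in amb_idx
        exp_rec = exposure_records[j]
        clean_out = clean_outcome[j]
        rec = TruthRecord(vid, palindromic=palindromic, ambiguous=ambiguous)
        exposure_flipped = exp_rec.beta < 0  # what direction standardization does

        if j in miss_idx:
            # the instrument is absent from the outcome GWAS; fabricate an
            # LD proxy (always non-palindromic) present in both tables
            rec.faults.append("missing_in_outcome")
            pid = f"{vid}p"
            rec.replaced_by = pid
            r = config.proxy_signed_r
            bxp_true = r * bx_true_all[j]
            p_p = float(np.clip(exp_rec.eaf + rng.normal(0.0, 0.02), 0.05, 0.95))
            p_alleles = _NONPAL_PAIRS[int(rng.integers(len(_NONPAL_PAIRS)))]
            se_xp = _se_scale(config.exposure_se, p_p)
            se_yp = _se_scale(config.outcome_se, p_p)
            bxp_obs = bxp_true + float(rng.normal(0.0, se_xp))
            byp_obs = c + theta * bxp_true + float(rng.normal(0.0, se_yp))
            proxy_rows.append(
                (
                    VariantRecord(pid, p_alleles[0], p_alleles[1], bxp_obs, se_xp, p_p),
                    VariantRecord(pid, p_alleles[0], p_alleles[1], byp_obs, se_yp, p_p),
                )
            )
            proxies.append(ProxyEntry(vid, pid, signed_r=r, r2=r * r))
            truth.records.append(rec)
            action, reason = _expected_action(
                palindromic=False, ambiguous=False,
                exposure_flipped=bxp_obs < 0, swapped=False, strand=False,
            )
            truth.records.append(
                TruthRecord(
                    pid, palindromic=False, ambiguous=False,
                    faults=["generated_proxy"],
                    expected_action=action, expected_drop_reason=reason,
                )
            )
            continue

        swapped = j in swap_idx
        strand = j in strand_idx
        out_rec = clean_out
        if swapped:
            rec.faults.append("allele_swap")
            out_rec = flip(out_rec)
        if strand:
            rec.faults.append("strand_flip")
            out_rec = out_rec.with_(
                effect_allele=complement(out_rec.effect_allele),
                other_allele=complement(out_rec.other_allele),
            )
        outcome_records.append(out_rec)
        rec.expected_action, rec.expected_drop_reason = _expected_action(
            palindromic, ambiguous, exposure_flipped, swapped, strand
        )
        truth.records.append(rec)

    # typos: multiplicative corruption of beta or se, on variants still present
    if config.n_typos:
        chosen = rng.choice(len(outcome_records),
                            size=min(config.n_typos, len(outcome_records)),
                            replace=False)
        by_id = {t.variant_id: t for t in truth.records}
        for i in np.sort(chosen):
            i = int(i)
            r = outcome_records[i]
            which = str(rng.choice(["beta", "se"]))
            if which == "beta":
                outcome_records[i] = r.with_(beta=r.beta * config.typo_factor)
            else:
                outcome_records[i] = r.with_(se=r.se * config.typo_factor)
            by_id[r.variant_id].faults.append(f"typo_{which}")

    for exp_rec, out_rec in proxy_rows:
        exposure_records.append(exp_rec)
        outcome_records.append(out_rec)

    return (
        SummaryDataset(exposure_records, role="exposure"),
        SummaryDataset(outcome_records, role="outcome"),
        proxies,
        truth,
    )


def table2_fixture() -> tuple[SummaryDataset, SummaryDataset, list[ProxyEntry]]:
    """The published worked example: four fictional instruments plus the
    rs3 -> rs5 LD-proxy substitution.

    The exposure dataset carries rs5's exposure-GWAS row as well (the proxy
    was available in both GWAS); the outcome dataset lacks rs3, which is why
    the proxy is needed. The signed allelic correlation of the proxy is not
    part of the published table; +0.95 is used here as a synthetic
    stand-in value consistent with "high LD". Byte-stable across calls.
    """
    exposure = SummaryDataset(
        [
            VariantRecord("rs1", "A", "C", -0.1, 0.04, 0.20),
            VariantRecord("rs2", "G", "T", -0.2, 0.03, 0.40),
            VariantRecord("rs3", "T", "C", 0.2, 0.03, 0.60),
            VariantRecord("rs4", "G", "A", 0.1, 0.04, 0.80),
            VariantRecord("rs5", "A", "G", 0.18, 0.03, 0.58),
        ],
        role="exposure",
    )
    outcome = SummaryDataset(
        [
            VariantRecord("rs1", "A", "C", -0.2, 0.04, 0.18),
            VariantRecord("rs2", "T", "G", 0.4, 0.03, 0.58),
            VariantRecord("rs4", "A", "G", -0.2, 0.04, 0.18),
            VariantRecord("rs5", "A", "G", 0.36, 0.03, 0.62),
        ],
        role="outcome",
    )
    proxies = [ProxyEntry("rs3", "rs5", signed_r=0.95, r2=0.9025)]
    return exposure, outcome, proxies
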