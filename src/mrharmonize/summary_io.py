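"""Data model and delimited-text IO for GWAS summary-association tables.

Every downstream module (harmonization, proxy substitution, QC, estimation)
operates on the containers defined here:

``VariantRecord``
    One biallelic SNP's summary association: effect/other allele, per-allele
    additive regression coefficient (a linear coefficient or ln odds ratio),
    its standard error, and optionally the effect allele frequency (EAF).
``SummaryDataset``
    An ordered, id-unique collection of records with a role (exposure or
    outcome) on the additive scale.
``ProxyEntry``
    A target-to-LD-proxy mapping with a *signed* allelic correlation, so the
    phase (which alleles co-occur) is known, not just the LD strength.

Tables are plain TSV/CSV with canonical columns ``SNP, effect_allele,
other_allele, beta, se, eaf`` (missing marker ``NA``); other headers can be
mapped via ``column_map``. Multiplicative effects (odds ratios) are
log-transformed on ingest, and the caller must declare the scale the standard
errors are reported on — GWAS sources are inconsistent about this and the
package refuses to guess.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "VALID_ALLELES",
    "VariantRecord",
    "SummaryDataset",
    "ProxyEntry",
    "as_allele",
    "read_summary_table",
    "write_summary_table",
    "read_proxy_table",
    "write_proxy_table",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical file column -> VariantRecord field
CANONICAL_COLUMNS = {
    "SNP": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
}

_CHRPOS_RE = re.compile(r"^(chr)?[0-9XYMT]+:[0-9]+$", re.IGNORECASE)


def as_allele(symbol: str) -> str:
    """Validate and upper-case a single-nucleotide allele symbol.

    Raises
    ------
    ValidationError
        If ``symbol`` is not exactly one of A/C/G/T (case-insensitive).
        Indels and multi-base strings are rejected: the harmonization
        procedure is defined for biallelic SNPs only.
    """
    s = str(symbol).strip().upper()
    if s not in VALID_ALLELES:
        raise ValidationError(f"non-SNP allele: {symbol!r}")
    return s


@dataclass(frozen=True)
class VariantRecord:
    """Summary association of one biallelic SNP.

    Invariants (enforced on construction): distinct A/C/G/T alleles,
    ``se > 0`` and ``eaf`` (when present) strictly inside (0, 1).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", as_allele(self.effect_allele))
        object.__setattr__(self, "other_allele", as_allele(self.other_allele))
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are both "
                f"{self.effect_allele}"
            )
        beta = float(self.beta)
        se = float(self.se)
        if not math.isfinite(beta):
            raise ValidationError(f"{self.variant_id}: non-finite beta")
        if not (math.isfinite(se) and se > 0):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "se", se)
        if self.eaf is not None:
            eaf = float(self.eaf)
            if math.isnan(eaf):
                object.__setattr__(self, "eaf", None)
            elif not 0.0 < eaf < 1.0:
                raise ValidationError(
                    f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}"
                )
            else:
                object.__setattr__(self, "eaf", eaf)

    @property
    def allele_pair(self) -> tuple[str, str]:
        """(effect, other) allele tuple, order-significant."""
        return (self.effect_allele, self.other_allele)

    @property
    def maf(self) -> float | None:
        """Minor allele frequency; orientation-invariant. None without EAF."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def with_(self, **changes) -> "VariantRecord":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


Role = Literal["exposure", "outcome"]


@dataclass
class SummaryDataset:
    """Ordered collection of :class:`VariantRecord` sharing a role and scale.

    Variant ids are unique within a dataset; ``scale`` is always ``additive``
    in memory (multiplicative inputs are log-transformed on ingest).
    """

    records: list[VariantRecord]
    role: Role
    scale: str = "additive"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.role not in ("exposure", "outcome"):
            raise ValidationError(f"role must be exposure or outcome, got {self.role!r}")
        if self.scale != "additive":
            raise ValidationError(
                "SummaryDataset holds additive-scale effects only; "
                "log-transform multiplicative inputs on ingest"
            )
        self.records = list(self.records)
        index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.variant_id in index:
                raise ValidationError(f"duplicate variant_id: {rec.variant_id}")
            index[rec.variant_id] = i
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> VariantRecord:
        try:
            return self.records[self._index[variant_id]]
        except KeyError:
            raise KeyError(f"{variant_id} not in {self.role} dataset") from None

    def with_records(self, records: Iterable[VariantRecord]) -> "SummaryDataset":
        return SummaryDataset(list(records), role=self.role, scale=self.scale)

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (EAF as a proportion, NaN if absent)."""
        return pd.DataFrame(
            {
                "SNP": [r.variant_id for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
            }
        )


@dataclass(frozen=True)
class ProxyEntry:
    """Target-variant to LD-proxy mapping with signed allelic correlation.

    ``signed_r`` is the Pearson correlation between the proxy's effect-allele
    dosage and the *target's* effect-allele dosage in a reference panel; its
    sign carries the phase. ``r2`` (LD strength) defaults to ``signed_r**2``.
    """

    target_id: str
    proxy_id: str
    signed_r: float
    r2: float | None = None

    def __post_init__(self) -> None:
        r = float(self.signed_r)
        if not (math.isfinite(r) and abs(r) <= 1.0):
            raise ValidationError(
                f"proxy {self.proxy_id} for {self.target_id}: |signed_r| must be "
                f"<= 1, got {self.signed_r}"
            )
        object.__setattr__(self, "signed_r", r)
        if self.r2 is not None:
            r2 = float(self.r2)
            if math.isnan(r2):
                object.__setattr__(self, "r2", None)
                return
            if not 0.0 <= r2 <= 1.0:
                raise ValidationError(f"r2 must lie in [0, 1], got {self.r2}")
            if abs(r2 - r * r) > 0.05:
                warnings.warn(
                    f"proxy {self.proxy_id}: supplied r2={r2:.3f} differs from "
                    f"signed_r^2={r * r:.3f}; check the reference panel",
                    stacklevel=2,
                )
            object.__setattr__(self, "r2", r2)

    @property
    def ld_strength(self) -> float:
        return self.r2 if self.r2 is not None else self.signed_r**2


# ---------------------------------------------------------------------------
# file IO


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if delimiter is None:
            # sniff tab vs comma from the header line
            header = path.open().readline()
            delimiter = "\t" if header.count("\t") >= header.count(",") else ","
        return pd.read_csv(path, sep=delimiter, dtype={0: str}, na_values=["NA"],
                           float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (not even a header)") from None


def read_summary_table(
    path: str | Path,
    *,
    role: Role,
    column_map: Mapping[str, str] | None = None,
    scale_hint: str = "additive",
    se_scale: str | None = None,
    delimiter: str | None = None,
) -> SummaryDataset:
    """Parse a summary-association table into a validated :class:`SummaryDataset`.

    Parameters
    ----------
    path
        TSV or CSV file (delimiter sniffed from the header unless given).
    role
        ``"exposure"`` or ``"outcome"``.
    column_map
        Maps canonical names (``SNP``, ``effect_allele``, ``other_allele``,
        ``beta``, ``se``, ``eaf``) to the file's actual headers. Unmapped
        canonical names are looked up literally. ``eaf`` is optional.
    scale_hint
        ``"additive"`` (default) or ``"multiplicative"``. Multiplicative
        effect columns (odds ratios) are natural-log-transformed; in that
        case ``se_scale`` **must** be declared.
    se_scale
        For multiplicative input only: ``"log"`` if the SE column is already
        the SE of ln(OR), ``"natural"`` if it is the SE of the OR itself
        (converted by the delta method, se_ln = se / OR).

    Notes
    -----
    Effect allele frequencies may be percentages (as often printed) or
    proportions; if any value exceeds 1 the whole column is treated as
    percentages and divided by 100. Rows that violate the record invariants
    are rejected with a line-numbered warning rather than aborting the load;
    structural problems (missing mandatory column, duplicate id) raise.
    """
    if scale_hint not in ("additive", "multiplicative"):
        raise FormatError(f"scale_hint must be additive or multiplicative: {scale_hint!r}")
    if scale_hint == "multiplicative" and se_scale not in ("log", "natural"):
        raise FormatError(
            "multiplicative input requires se_scale='log' or 'natural'; "
            "the SE scale of odds-ratio summary statistics cannot be inferred"
        )

    frame = _read_delimited(path, delimiter)
    colmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        actual = colmap.get(canon, canon)
        if actual in frame.columns:
            resolved[canon] = actual
    missing = [c for c in ("SNP", "effect_allele", "other_allele", "beta", "se") if c not in resolved]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    if frame.empty:
        warnings.warn(f"{path}: header-only file, empty dataset", stacklevel=2)
        return SummaryDataset([], role=role)

    eaf_col = resolved.get("eaf")
    eaf_values = None
    if eaf_col is not None:
        eaf_values = pd.to_numeric(frame[eaf_col], errors="coerce").to_numpy(float)
        finite = eaf_values[np.isfinite(eaf_values)]
        if finite.size and np.nanmax(finite) > 1.0:
            eaf_values = eaf_values / 100.0  # printed as percentages

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        raw = dict(zip(frame.columns, row))
        vid = str(raw[resolved["SNP"]]).strip()
        if vid in seen:
            raise FormatError(f"{path}:{line_no}: duplicate variant_id {vid!r}")
        try:
            beta = float(raw[resolved["beta"]])
            se = float(raw[resolved["se"]])
            if scale_hint == "multiplicative":
                if beta <= 0:
                    raise ValidationError(f"{vid}: odds ratio must be > 0")
                if se_scale == "natural":
                    se = se / beta  # delta method on the log scale
                beta = math.log(beta)
            rec = VariantRecord(
                variant_id=vid,
                effect_allele=raw[resolved["effect_allele"]],
                other_allele=raw[resolved["other_allele"]],
                beta=beta,
                se=se,
                eaf=None if eaf_values is None else eaf_values[i],
            )
        except (ValidationError, ValueError, TypeError) as exc:
            warnings.warn(f"{path}:{line_no}: rejected record: {exc}", stacklevel=2)
            continue
        if _CHRPOS_RE.match(vid):
            warnings.warn(
                f"{path}:{line_no}: chr:pos identifier {vid!r} is collision-prone "
                "(several variants can map to one position); prefer rs numbers",
                stacklevel=2,
            )
        seen.add(vid)
        records.append(rec)
    return SummaryDataset(records, role=role)


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical-column TSV, missing EAF rendered as ``NA``.

    Round-trip guarantee: ``read_summary_table(write(d))`` reproduces ``d``
    field-for-field (floats at full ``repr`` precision).
    """
    frame = dataset.to_frame()
    frame.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format=lambda v: repr(float(v)))


def read_proxy_table(path: str | Path, *, delimiter: str | None = None) -> list[ProxyEntry]:
    """Parse a proxy table (columns target_id, proxy_id, signed_r[, r2]).

    One proxy per target: duplicate ``target_id`` raises.
    """
    frame = _read_delimited(path, delimiter)
    for col in ("target_id", "proxy_id", "signed_r"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing proxy column {col!r}")
    entries: list[ProxyEntry] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        target = str(row["target_id"]).strip()
        if target in seen:
            raise FormatError(f"{path}: duplicate target_id {target!r} (one proxy per target)")
        seen.add(target)
        r2 = float(row["r2"]) if "r2" in frame.columns and pd.notna(row["r2"]) else None
        entries.append(
            ProxyEntry(
                target_id=target,
                proxy_id=str(row["proxy_id"]).strip(),
                signed_r=float(row["signed_r"]),
                r2=r2,
            )
        )
    return entries


def write_proxy_table(entries: Sequence[ProxyEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "target_id": [e.target_id for e in entries],
            "proxy_id": [e.proxy_id for e in entries],
            "signed_r": [e.signed_r for e in entries],
            "r2": [np.nan if e.r2 is None else e.r2 for e in entries],
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")
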