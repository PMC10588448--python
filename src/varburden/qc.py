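"""Genotype- and site-level quality filters for germline case variants.

Filters follow a GATK-style germline calling workflow: allelic balance
strictly above 0.2 on every non-reference call, genotype quality strictly
above 20, heterozygous VAF inside the inclusive 20-80% window, a minimum
alternate-read count of 10 for SNVs and 7 for indels, and per-site
missingness strictly below 25% of samples. Allelic balance and the het VAF
window are kept as distinct rules: the balance floor applies to all
non-reference calls while the window constrains heterozygotes only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .cohort_io import AnnotatedVariant, GenotypeCall, VariantKey

__all__ = [
    "QCThresholds",
    "QCOutcome",
    "variant_type_of",
    "passes_genotype_qc",
    "site_missingness",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    ab_min: float = 0.2         # allelic balance, strict >
    gq_min: int = 20            # genotype quality, strict >
    het_vaf_lo: float = 0.20    # het VAF window, inclusive
    het_vaf_hi: float = 0.80
    min_alt_snv: int = 10       # minimum alt reads, SNVs
    min_alt_indel: int = 7      # minimum alt reads, indels
    max_missing: float = 0.25   # site missingness, strict <

    def __post_init__(self) -> None:
        if not (0 <= self.ab_min <= self.het_vaf_lo <= self.het_vaf_hi <= 1):
            raise ValueError("require 0 <= ab_min <= het_vaf_lo <= het_vaf_hi <= 1")
        if self.min_alt_snv < 0 or self.min_alt_indel < 0:
            raise ValueError("min alt-read thresholds must be >= 0")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")


@dataclass(frozen=True)
class QCOutcome:
    passed: bool
    failed_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_rules) == 0)


def variant_type_of(key: VariantKey) -> str:
    """"snv" for single-base substitutions; MNVs are grouped with indels."""
    return "snv" if len(key.ref) == 1 and len(key.alt) == 1 else "indel"


def passes_genotype_qc(
    call: GenotypeCall, vtype: str, thresholds: QCThresholds = QCThresholds()
) -> QCOutcome:
    """Evaluate every genotype-level rule on a non-reference call.

    Failed rules are enumerated exhaustively (a call may fail several).
    hom_alt calls are exempt from the het VAF window.
    """
    if call.gt_class not in ("het", "hom_alt"):
        raise ValueError(f"genotype QC applies to non-reference calls, got {call.gt_class}")
    failed: list[str] = []
    vaf = call.vaf
    if vaf is None:
        failed.append("no_coverage")
    else:
        if not (vaf > thresholds.ab_min):
            failed.append("allelic_balance")
        if call.gt_class == "het" and not (
            thresholds.het_vaf_lo <= vaf <= thresholds.het_vaf_hi
        ):
            failed.append("het_vaf_window")
    if not (call.gq > thresholds.gq_min):
        failed.append("genotype_quality")
    min_alt = thresholds.min_alt_snv if vtype == "snv" else thresholds.min_alt_indel
    if call.alt_reads < min_alt:
        failed.append("min_alt_reads")
    return QCOutcome(passed=not failed, failed_rules=tuple(failed))


def site_missingness(calls: Sequence[GenotypeCall]) -> float:
    """Fraction of samples with a missing genotype at the site."""
    if not calls:
        raise ValueError("site has no genotype calls")
    return sum(1 for c in calls if c.gt_class == "missing") / len(calls)


def apply_qc(
    variants: Iterable[AnnotatedVariant], thresholds: QCThresholds = QCThresholds()
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Filter carriers by genotype QC and drop sites failing missingness.

    Returns the retained variants (with failing carriers removed) and a log
    of removal counts per rule. A call failing several rules increments each,
    so per-rule counts may sum to more than the number of removed calls.
    """
    retained: list[AnnotatedVariant] = []
    log: dict[str, int] = {
        "missingness": 0, "allelic_balance": 0, "het_vaf_window": 0,
        "genotype_quality": 0, "min_alt_reads": 0, "no_coverage": 0,
        "carriers_removed": 0, "sites_removed": 0,
    }
    for v in variants:
        if v.n_samples > 0:
            missing_frac = len(v.missing_samples) / v.n_samples
            if not (missing_frac < thresholds.max_missing):
                log["missingness"] += 1
                log["sites_removed"] += 1
                continue
        vtype = variant_type_of(v.key)
        kept = []
        for call in v.carriers:
            outcome = passes_genotype_qc(call, vtype, thresholds)
            if outcome.passed:
                kept.append(call)
            else:
                log["carriers_removed"] += 1
                for rule in outcome.failed_rules:
                    log[rule] += 1
        retained.append(replace(v, carriers=tuple(kept)))
    return retained, log
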