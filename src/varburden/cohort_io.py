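"""Reading and key-joining the three input tables of a burden analysis.

Inputs are a multi-sample germline VCF (cases, with GT/AD/GQ per genotype), a
population control allele-frequency table (gnomAD-style TSV) and a variant
annotation table. Multi-allelic VCF records are decomposed into one keyed
biallelic record per alternate allele on read; all keys use the 1-based VCF
coordinate convention. Indel keys are assumed pre-normalized upstream.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
import pysam

from .classify import ConsequenceClass, map_consequence

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "GenotypeCall",
    "ControlFrequencyRecord",
    "AnnotationRecord",
    "AnnotatedVariant",
    "CaseSite",
    "JoinStats",
    "read_case_vcf",
    "read_control_table",
    "read_annotation_table",
    "join_annotations",
    "write_variants_tsv",
    "read_variants_tsv",
]

GT_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


@dataclass(frozen=True, order=True)
class VariantKey:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str  # single decomposed alternate allele

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1 (1-based)")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        if "," in self.alt:
            raise ValueError(f"alt {self.alt!r} is multi-allelic; decompose first")

    def strip_chr(self) -> "VariantKey":
        if self.chrom.lower().startswith("chr"):
            return replace(self, chrom=self.chrom[3:])
        return self


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    gt_class: str  # hom_ref | het | hom_alt | missing
    ref_reads: int = 0
    alt_reads: int = 0
    gq: int = 0

    def __post_init__(self) -> None:
        if self.gt_class not in GT_CLASSES:
            raise ValueError(f"unknown gt_class {self.gt_class!r}")
        if self.ref_reads < 0 or self.alt_reads < 0 or self.gq < 0:
            raise ValueError("read counts and GQ must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> Optional[float]:
        """alt / (ref + alt); undefined (None) with zero informative reads."""
        return self.alt_reads / self.depth if self.depth > 0 else None


@dataclass(frozen=True)
class ControlFrequencyRecord:
    key: VariantKey
    ac: int
    an: int
    af: float
    ancestry_afs: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError(f"{self.key}: control AN must be > 0")
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"{self.key}: require 0 <= AC ({self.ac}) <= AN ({self.an})")
        if abs(self.af - self.ac / self.an) > 1e-9:
            raise ValueError(f"{self.key}: AF column {self.af} inconsistent with AC/AN {self.ac}/{self.an}")


@dataclass(frozen=True)
class AnnotationRecord:
    key: VariantKey
    gene: str
    consequence: ConsequenceClass
    hgvs_p: str = ""
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    acmg_class: Optional[str] = None
    ddg_fold: Optional[float] = None  # kcal/mol
    domain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"{self.key}: CADD Phred must be >= 0")
        if self.revel is not None and not (0 <= self.revel <= 1):
            raise ValueError(f"{self.key}: REVEL must lie in [0, 1]")


@dataclass(frozen=True)
class CaseSite:
    """One decomposed case variant: the full per-sample genotype vector."""

    key: VariantKey
    calls: tuple[GenotypeCall, ...]
    call_rate: float  # fraction of samples with a non-missing genotype


@dataclass
class AnnotatedVariant:
    """A case variant joined with control frequency and annotation.

    ``control`` is None for variants never seen in the control population
    (treated downstream as AF = 0, i.e. novel). ``carriers`` holds only
    non-hom_ref, non-missing genotype calls.
    """

    key: VariantKey
    gene: str
    annotation: AnnotationRecord
    control: Optional[ControlFrequencyRecord]
    carriers: tuple[GenotypeCall, ...]
    missing_samples: frozenset[str] = field(default_factory=frozenset)
    n_samples: int = 0

    @property
    def control_af(self) -> float:
        return self.control.af if self.control is not None else 0.0


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _classify_gt(alleles: tuple, alt_index: int) -> str:
    if alleles is None or any(a is None for a in alleles) or len(alleles) == 0:
        return "missing"
    n = sum(1 for a in alleles if a == alt_index)
    if n == 0:
        return "hom_ref"
    if n == 1:
        return "het"
    return "hom_alt"


def read_case_vcf(
    path: Union[str, Path], strip_chr: bool = False
) -> Iterator[CaseSite]:
    """Stream decomposed case sites from a multi-sample VCF.

    Each multi-allelic record yields one :class:`CaseSite` per alternate
    allele, with per-allele AD mapped to (ref_reads, alt_reads). Samples with
    missing GT or missing FORMAT fields are classed ``missing``. Records whose
    AD arity is inconsistent with the allele count are skipped with a warning.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            alts = rec.alts or ()
            n_alleles = len(alts) + 1
            bad_ad = False
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is not None and all(v is not None for v in ad) and len(ad) != n_alleles:
                    bad_ad = True
            if bad_ad:
                logger.warning(
                    "skipping %s:%s — AD arity inconsistent with %d alleles",
                    rec.chrom, rec.pos, n_alleles,
                )
                continue
            for ai, alt in enumerate(alts, start=1):
                if alt is None:
                    continue
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                if strip_chr:
                    key = key.strip_chr()
                calls = []
                n_called = 0
                for s in samples:
                    fmt = rec.samples[s]
                    gt = fmt.get("GT")
                    gt_class = _classify_gt(gt, ai)
                    ad = fmt.get("AD")
                    gq = fmt.get("GQ")
                    if gt_class != "missing" and (
                        ad is None or any(v is None for v in ad) or gq is None
                    ):
                        gt_class = "missing"
                    if gt_class == "missing":
                        calls.append(GenotypeCall(s, "missing"))
                        continue
                    n_called += 1
                    calls.append(
                        GenotypeCall(
                            s, gt_class,
                            ref_reads=int(ad[0]), alt_reads=int(ad[ai]),
                            gq=int(gq),
                        )
                    )
                yield CaseSite(key, tuple(calls), call_rate=n_called / len(samples))


def _key_from_row(row, strip_chr: bool) -> VariantKey:
    key = VariantKey(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
    return key.strip_chr() if strip_chr else key


def read_control_table(
    path: Union[str, Path], strip_chr: bool = False
) -> dict[VariantKey, ControlFrequencyRecord]:
    """Read a gnomAD-style control frequency TSV keyed by decomposed variant.

    Required columns: CHROM POS REF ALT AC AN; AF is recomputed as AC/AN when
    absent. Any additional ``AF_<ancestry>`` columns are kept as ancestry AFs.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"CHROM": str})
    required = {"CHROM", "POS", "REF", "ALT", "AC", "AN"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: control table missing columns {sorted(missing)}")
    ancestry_cols = [c for c in df.columns if c.startswith("AF_")]
    out: dict[VariantKey, ControlFrequencyRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("AC", "AN"):
            v = getattr(row, col)
            if float(v) != int(v):
                raise FormatError(f"{path} row {i}: non-integer {col}={v}")
        key = _key_from_row(row, strip_chr)
        if key in out:
            raise FormatError(f"{path} row {i}: duplicate variant key {key}")
        ac, an = int(row.AC), int(row.AN)
        af = float(row.AF) if "AF" in df.columns and pd.notna(getattr(row, "AF", None)) else (
            ac / an if an else 0.0
        )
        ancestry = {
            c[3:]: float(getattr(row, c)) for c in ancestry_cols if pd.notna(getattr(row, c))
        } or None
        try:
            out[key] = ControlFrequencyRecord(key, ac, an, af, ancestry)
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
    return out


def read_annotation_table(
    path: Union[str, Path], strip_chr: bool = False
) -> dict[VariantKey, AnnotationRecord]:
    """Read the variant annotation TSV (gene, consequence, scores, ddG, domain)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"CHROM": str})
    required = {"CHROM", "POS", "REF", "ALT", "GENE", "CONSEQUENCE"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {sorted(missing)}")

    def opt(row, col, cast=float):
        v = getattr(row, col, None)
        return cast(v) if v is not None and pd.notna(v) else None

    out: dict[VariantKey, AnnotationRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = _key_from_row(row, strip_chr)
        gene = str(row.GENE)
        if key in out and out[key].gene == gene:
            raise FormatError(f"{path} row {i}: duplicate annotation for {key} / {gene}")
        out[key] = AnnotationRecord(
            key=key,
            gene=gene,
            consequence=map_consequence(str(row.CONSEQUENCE)),
            hgvs_p=str(getattr(row, "HGVSP", "") or ""),
            cadd_phred=opt(row, "CADD_PHRED"),
            revel=opt(row, "REVEL"),
            acmg_class=opt(row, "ACMG", str),
            ddg_fold=opt(row, "DDG"),
            domain=opt(row, "DOMAIN", str),
        )
    return out


@dataclass
class JoinStats:
    n_case_sites: int = 0
    n_joined: int = 0
    n_unannotated: int = 0
    n_absent_from_controls: int = 0


def join_annotations(
    case_sites: Iterable[CaseSite],
    control_map: dict[VariantKey, ControlFrequencyRecord],
    annotation_map: dict[VariantKey, AnnotationRecord],
) -> tuple[list[AnnotatedVariant], JoinStats]:
    """Key-join QC'd case sites with control frequencies and annotations.

    A case variant absent from the control map is kept with control=None
    (novel, AF 0). A case variant with no annotation is dropped and counted.
    Zero joins across >100 case sites raises, as the signature of a
    chromosome-naming mismatch between inputs.
    """
    out: list[AnnotatedVariant] = []
    stats = JoinStats()
    for site in case_sites:
        stats.n_case_sites += 1
        ann = annotation_map.get(site.key)
        if ann is None:
            stats.n_unannotated += 1
            continue
        ctrl = control_map.get(site.key)
        if ctrl is None:
            stats.n_absent_from_controls += 1
        carriers = tuple(
            c for c in site.calls if c.gt_class in ("het", "hom_alt")
        )
        missing = frozenset(c.sample_id for c in site.calls if c.gt_class == "missing")
        out.append(
            AnnotatedVariant(
                key=site.key, gene=ann.gene, annotation=ann, control=ctrl,
                carriers=carriers, missing_samples=missing,
                n_samples=len(site.calls),
            )
        )
        stats.n_joined += 1
    if stats.n_case_sites > 100 and stats.n_joined == 0:
        raise FormatError(
            "no case variant joined to any annotation across "
            f"{stats.n_case_sites} sites — likely a chromosome-naming mismatch; "
            "try strip_chr=True to harmonize 'chr' prefixes"
        )
    if stats.n_unannotated:
        logger.info("dropped %d case sites with no annotation", stats.n_unannotated)
    return out, stats


# --- TSV interchange format for joined records (round-trippable) -----------

_TSV_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "GENE", "CONSEQUENCE", "HGVSP",
    "CADD_PHRED", "REVEL", "ACMG", "DDG", "DOMAIN",
    "CONTROL_AC", "CONTROL_AN", "CONTROL_AF",
    "CARRIERS", "MISSING_SAMPLES", "N_SAMPLES",
]


def _encode_carriers(carriers: tuple[GenotypeCall, ...]) -> str:
    return ",".join(
        f"{c.sample_id}:{c.gt_class}:{c.ref_reads}:{c.alt_reads}:{c.gq}" for c in carriers
    )


def _decode_carriers(text: str) -> tuple[GenotypeCall, ...]:
    if not text:
        return ()
    calls = []
    for item in text.split(","):
        sid, gt, rr, ar, gq = item.rsplit(":", 4)
        calls.append(GenotypeCall(sid, gt, int(rr), int(ar), int(gq)))
    return tuple(calls)


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path: Union[str, Path]) -> None:
    rows = []
    for v in variants:
        a = v.annotation
        rows.append({
            "CHROM": v.key.chrom, "POS": v.key.pos, "REF": v.key.ref, "ALT": v.key.alt,
            "GENE": v.gene, "CONSEQUENCE": a.consequence.value, "HGVSP": a.hgvs_p,
            "CADD_PHRED": a.cadd_phred, "REVEL": a.revel, "ACMG": a.acmg_class,
            "DDG": a.ddg_fold, "DOMAIN": a.domain,
            "CONTROL_AC": v.control.ac if v.control else "",
            "CONTROL_AN": v.control.an if v.control else "",
            "CONTROL_AF": repr(v.control.af) if v.control else "",
            "CARRIERS": _encode_carriers(v.carriers),
            "MISSING_SAMPLES": ",".join(sorted(v.missing_samples)),
            "N_SAMPLES": v.n_samples,
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: Union[str, Path]) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))

        def opt(v, cast=float):
            return cast(v) if v != "" else None

        ann = AnnotationRecord(
            key=key, gene=str(row.GENE),
            consequence=ConsequenceClass(row.CONSEQUENCE),
            hgvs_p=str(row.HGVSP),
            cadd_phred=opt(row.CADD_PHRED), revel=opt(row.REVEL),
            acmg_class=opt(row.ACMG, str), ddg_fold=opt(row.DDG),
            domain=opt(row.DOMAIN, str),
        )
        ctrl = None
        if row.CONTROL_AC != "":
            ctrl = ControlFrequencyRecord(
                key, int(row.CONTROL_AC), int(row.CONTROL_AN), float(row.CONTROL_AF)
            )
        out.append(
            AnnotatedVariant(
                key=key, gene=ann.gene, annotation=ann, control=ctrl,
                carriers=_decode_carriers(str(row.CARRIERS)),
                missing_samples=frozenset(
                    s for s in str(row.MISSING_SAMPLES).split(",") if s
                ),
                n_samples=int(row.N_SAMPLES),
            )
        )
    return out
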