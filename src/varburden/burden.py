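"""Gene x cohort-subset x rarity-tier-group collapsing and exact burden tests.

Qualifying alleles are collapsed per gene into a single case-vs-control 2x2
comparison per subset and tier group. Two tier groups are tested: ultra-rare
plus novel (control AF < 0.005% or absent) and all variants under 0.1%.
Control alt counts sum the population AC over *all* control variants of the
gene passing the same candidate filters, not only those seen in cases.

Two 2x2 constructions are supported. The default, ``alt_vs_total``, places
the total allele number (not total minus alt) in the second column; this is
the construction used by the published analyses this package reproduces, and
with gnomAD-scale denominators the two differ only in the fourth significant
digit. The classical ``alt_vs_ref`` construction is available as an option.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import exact
from .classify import (
    DEFAULT_CADD_MIN,
    RarityTier,
    TierBoundaries,
    classify_rarity,
    is_candidate,
)
from .cohort_io import AnnotatedVariant, AnnotationRecord, ControlFrequencyRecord, VariantKey

__all__ = [
    "CohortSubset",
    "TierGroup",
    "BurdenCell",
    "BurdenResult",
    "case_allele_counts",
    "control_allele_counts",
    "run_burden",
    "results_from_counts",
    "format_results_table",
]


@dataclass(frozen=True)
class CohortSubset:
    name: str
    sample_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.sample_ids)


class TierGroup(enum.Enum):
    ULTRA_RARE_PLUS_NOVEL = frozenset({RarityTier.NOVEL, RarityTier.ULTRA_RARE})
    RARE_UNDER_0_1 = frozenset(
        {RarityTier.NOVEL, RarityTier.ULTRA_RARE, RarityTier.VERY_RARE, RarityTier.RARE}
    )

    @property
    def members(self) -> frozenset[RarityTier]:
        return self.value


@dataclass(frozen=True)
class BurdenCell:
    gene: str
    subset: str
    tier_group: TierGroup
    case_alt: int
    case_total: int
    control_alt: int
    control_total: int

    def __post_init__(self) -> None:
        if self.case_alt > self.case_total:
            raise ValueError(f"{self.gene}/{self.subset}: case_alt > case_total")
        if self.control_alt > self.control_total:
            raise ValueError(f"{self.gene}/{self.subset}: control_alt > control_total")

    @property
    def case_af(self) -> float:
        return self.case_alt / self.case_total if self.case_total else 0.0

    @property
    def control_af(self) -> float:
        return self.control_alt / self.control_total if self.control_total else 0.0

    def contingency(self, table_policy: str = "alt_vs_total") -> exact.ContingencyTable:
        if table_policy == "alt_vs_total":
            return exact.ContingencyTable(
                self.case_alt, self.case_total, self.control_alt, self.control_total
            )
        if table_policy == "alt_vs_ref":
            return exact.ContingencyTable(
                self.case_alt, self.case_total - self.case_alt,
                self.control_alt, self.control_total - self.control_alt,
            )
        raise ValueError(f"unknown table_policy {table_policy!r}")


@dataclass(frozen=True)
class BurdenResult:
    cell: BurdenCell
    test: exact.TestResult
    family: str
    adj_greater: float
    adj_two_sided: float


def _tier_of(v: AnnotatedVariant, boundaries: TierBoundaries) -> RarityTier:
    return classify_rarity(v.control_af, boundaries)


def _an_from_sites(site_ans: Sequence[float], an_policy: str) -> int:
    if an_policy == "site_mean":
        return int(round(float(np.mean(site_ans))))
    if an_policy == "site_median":
        return int(round(float(np.median(site_ans))))
    raise ValueError(f"unknown an_policy {an_policy!r}")


def case_allele_counts(
    gene: str,
    subset: CohortSubset,
    tier_group: TierGroup,
    variants: Sequence[AnnotatedVariant],
    boundaries: TierBoundaries = TierBoundaries(),
    an_policy: str = "site_mean",
) -> tuple[int, int]:
    """Collapse qualifying case alleles for one gene/subset/tier-group cell.

    A heterozygous carrier contributes one allele, a homozygous-alt carrier
    two. The denominator follows ``an_policy``: the default averages the
    called allele number (2 x non-missing subset samples) across the gene's
    sites, mirroring per-site AN accounting; ``2n`` uses 2 x subset size.
    """
    gene_vars = [v for v in variants if v.gene == gene]
    qualifying = [v for v in gene_vars if _tier_of(v, boundaries) in tier_group.members]
    case_alt = 0
    for v in qualifying:
        for c in v.carriers:
            if c.sample_id in subset.sample_ids:
                case_alt += 1 if c.gt_class == "het" else 2
    if an_policy == "2n":
        case_total = 2 * len(subset)
    else:
        an_sites = gene_vars if gene_vars else []
        if an_sites:
            site_ans = [
                2 * (len(subset) - len(subset.sample_ids & v.missing_samples))
                for v in an_sites
            ]
            case_total = _an_from_sites(site_ans, an_policy)
        else:
            case_total = 2 * len(subset)
    if case_alt > case_total:
        raise ValueError(
            f"{gene}/{subset.name}/{tier_group.name}: case_alt {case_alt} exceeds total {case_total}"
        )
    return case_alt, case_total


def control_allele_counts(
    gene: str,
    tier_group: TierGroup,
    control_map: dict[VariantKey, ControlFrequencyRecord],
    annotation_map: dict[VariantKey, AnnotationRecord],
    boundaries: TierBoundaries = TierBoundaries(),
    cadd_min: float = DEFAULT_CADD_MIN,
    an_policy: str = "site_mean",
) -> tuple[int, int]:
    """Collapse qualifying control alleles over the gene's whole footprint.

    Every control variant annotated to the gene is passed through the same
    consequence/AF/CADD candidate filter as the cases; qualifying AC values
    are summed. The denominator is the representative AN across the gene's
    qualifying control sites (falling back to all of the gene's control
    sites when no site qualifies).
    """
    gene_records = [
        (rec, annotation_map[key])
        for key, rec in control_map.items()
        if key in annotation_map and annotation_map[key].gene == gene
    ]
    if not gene_records:
        raise ValueError(f"control table has no footprint for gene {gene}")
    qualifying = [
        rec for rec, ann in gene_records
        if is_candidate(ann.consequence, rec.af, ann.cadd_phred, boundaries, cadd_min)
        and classify_rarity(rec.af, boundaries) in tier_group.members
    ]
    control_alt = sum(rec.ac for rec in qualifying)
    an_source = qualifying if qualifying else [rec for rec, _ in gene_records]
    policy = "site_mean" if an_policy == "2n" else an_policy
    control_total = _an_from_sites([rec.an for rec in an_source], policy)
    return control_alt, control_total


def read_subsets_tsv(path) -> list[CohortSubset]:
    """Subset membership TSV: sample_id column plus one 0/1 column per subset.

    A PanCancer subset holding every listed sample is prepended.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: subset table needs a 'sample_id' column")
    all_samples = frozenset(df["sample_id"])
    subsets = [CohortSubset("PanCancer", all_samples)]
    for col in df.columns:
        if col == "sample_id":
            continue
        members = frozenset(df.loc[df[col].astype(int) == 1, "sample_id"])
        subsets.append(CohortSubset(col, members))
    return subsets


TIER_GROUP_ORDER = (TierGroup.ULTRA_RARE_PLUS_NOVEL, TierGroup.RARE_UNDER_0_1)


def run_burden(
    variants: Sequence[AnnotatedVariant],
    subsets: Sequence[CohortSubset],
    control_map: dict[VariantKey, ControlFrequencyRecord],
    annotation_map: dict[VariantKey, AnnotationRecord],
    genes: Optional[Sequence[str]] = None,
    boundaries: TierBoundaries = TierBoundaries(),
    cadd_min: float = DEFAULT_CADD_MIN,
    an_policy: str = "site_mean",
    adjust: str = "bh",
    table_policy: str = "alt_vs_total",
) -> list[BurdenResult]:
    """Run the full collapsing analysis: one result per gene x subset x tier group.

    Variants must already be QC-filtered; the candidate filter is applied
    here so case and control alleles pass identical selection. Adjusted
    p-values are computed within the per-gene family of size
    ``len(subsets) * len(tier groups)`` (8 for a four-subset run), BH by
    default with Bonferroni behind ``adjust="bonferroni"``.
    """
    candidates = [
        v for v in variants
        if is_candidate(v.annotation.consequence, v.control_af, v.annotation.cadd_phred,
                        boundaries, cadd_min)
    ]
    if genes is None:
        genes = sorted({v.gene for v in candidates})
    adjust_fn = {"bh": exact.bh_adjust, "bonferroni": exact.bonferroni_adjust}[adjust]

    results: list[BurdenResult] = []
    for gene in genes:
        cells: list[BurdenCell] = []
        for subset in subsets:
            for tier_group in TIER_GROUP_ORDER:
                case_alt, case_total = case_allele_counts(
                    gene, subset, tier_group, candidates, boundaries, an_policy
                )
                control_alt, control_total = control_allele_counts(
                    gene, tier_group, control_map, annotation_map,
                    boundaries, cadd_min, an_policy,
                )
                cells.append(
                    BurdenCell(gene, subset.name, tier_group,
                               case_alt, case_total, control_alt, control_total)
                )
        tests = [exact.test_table(c.contingency(table_policy)) for c in cells]
        m_total = len(subsets) * len(TIER_GROUP_ORDER)
        adj_g = adjust_fn([t.p_greater for t in tests], m_total)
        adj_2 = adjust_fn([t.p_two_sided for t in tests], m_total)
        for cell, test, ag, a2 in zip(cells, tests, adj_g, adj_2):
            results.append(BurdenResult(cell, test, family=gene,
                                        adj_greater=ag, adj_two_sided=a2))
    return results


def results_from_counts(
    counts: Sequence[tuple[str, str, str, int, int, int, int]],
    adjust: str = "bh",
    family_size: Optional[int] = None,
    table_policy: str = "alt_vs_total",
) -> list[BurdenResult]:
    """Build results directly from pre-collapsed allele counts.

    ``counts`` rows are (gene, subset, tier_group_name, case_alt, case_total,
    control_alt, control_total). Adjustment families are per gene;
    ``family_size`` overrides the per-gene family size (e.g. 8 when only a
    subset of a larger test family is supplied).
    """
    cells = [
        BurdenCell(g, s, TierGroup[tg], ca, ct, na, nt)
        for g, s, tg, ca, ct, na, nt in counts
    ]
    tests = [exact.test_table(c.contingency(table_policy)) for c in cells]
    adjust_fn = {"bh": exact.bh_adjust, "bonferroni": exact.bonferroni_adjust}[adjust]
    results: list[BurdenResult] = []
    for gene in dict.fromkeys(c.gene for c in cells):  # preserve input order
        idx = [i for i, c in enumerate(cells) if c.gene == gene]
        m = family_size if family_size is not None else len(idx)
        adj_g = adjust_fn([tests[i].p_greater for i in idx], m)
        adj_2 = adjust_fn([tests[i].p_two_sided for i in idx], m)
        for j, i in enumerate(idx):
            results.append(BurdenResult(cells[i], tests[i], family=gene,
                                        adj_greater=adj_g[j], adj_two_sided=adj_2[j]))
    return results


_REPORT_COLUMNS = [
    "Gene", "Subset", "Tier_Group", "Cancer_AF", "Control_AF",
    "Cancer_Alt_Count", "Cancer_Total_Count", "Control_Alt_Count", "Control_Total_Count",
    "p_greater", "OR_cmle", "FDR_greater", "p_twosided", "FDR_twosided", "OR_sample",
]


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "Inf"
    return f"{x:.9g}"


def format_results_table(results: Sequence[BurdenResult]):
    """Results as a report DataFrame (AFs at 4 dp, statistics at 9 sig figs)."""
    import pandas as pd

    if not results:
        raise ValueError("no burden results to format")
    rows = []
    for r in results:
        c = r.cell
        rows.append({
            "Gene": c.gene, "Subset": c.subset, "Tier_Group": c.tier_group.name,
            "Cancer_AF": f"{c.case_af:.4f}", "Control_AF": f"{c.control_af:.4f}",
            "Cancer_Alt_Count": c.case_alt, "Cancer_Total_Count": c.case_total,
            "Control_Alt_Count": c.control_alt, "Control_Total_Count": c.control_total,
            "p_greater": _fmt(r.test.p_greater), "OR_cmle": _fmt(r.test.or_cmle),
            "FDR_greater": _fmt(r.adj_greater), "p_twosided": _fmt(r.test.p_two_sided),
            "FDR_twosided": _fmt(r.adj_two_sided), "OR_sample": _fmt(r.test.or_sample),
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
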