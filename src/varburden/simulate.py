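"""Synthetic case cohorts with matched population-control tables.

The generator emulates the data shape of a germline collapsing analysis: a
multi-sample case VCF with read-level genotype fields (GT/AD/GQ), a
gnomAD-style control allele-frequency table spanning all rarity tiers, a
variant annotation table, and cohort-subset membership — plus a truth record
of who carries what, so every pipeline stage can be validated end to end.

Per site the control AF is drawn from a configurable spectrum; each case
sample is an independent heterozygous carrier with probability 2*AF*lambda,
where lambda is a per-gene case enrichment multiplier (lambda = 1 is the
null). Carriers are het-only by default, matching the mutually exclusive
heterozygous variants the modeled analyses observe; hom-alt injection is
available behind a flag. Clean carriers are guaranteed to pass default
genotype QC (depth and VAF clamped inside the passing region); carriers
selected by ``qc_noise`` are guaranteed to fail it (GQ at or below 20, or
VAF pushed under the allelic-balance floor).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .burden import CohortSubset, TierGroup, run_burden
from .classify import ConsequenceClass, RarityTier, TierBoundaries, classify_rarity
from .cohort_io import (
    AnnotatedVariant,
    AnnotationRecord,
    CaseSite,
    ControlFrequencyRecord,
    GenotypeCall,
    VariantKey,
)
from .qc import QCThresholds, apply_qc

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "CalibrationResult",
    "simulate_cohort",
    "evaluate_calibration",
    "derive_seed",
]

# Default control-AF spectrum: one novel, one ultra-rare, one very-rare and
# one rare point mass, equally weighted, so every rarity tier used by the
# statistics is populated.
DEFAULT_AF_SPECTRUM: tuple[tuple[float, float], ...] = (
    (0.0, 0.25),
    (2.5e-5, 0.25),
    (2.0e-4, 0.25),
    (8.0e-4, 0.25),
)

DEFAULT_GENES: tuple[tuple[str, int], ...] = tuple((f"G{i}", 8) for i in range(1, 7))

# Disjoint subset assignment probabilities (hematologic / solid / CNS),
# proportional to the stratum sizes of the modeled pan-cancer cohort.
SUBSET_PROBS: tuple[tuple[str, float], ...] = (
    ("HEM", 0.532), ("ST", 0.304), ("CNS", 0.164),
)


def derive_seed(master_seed: int, index: int) -> int:
    """Replicate seed from a master seed via a splitmix64-style scrambler.

    Declared so the stream is reproducible from (master_seed, index) in any
    language; the result is kept below 2^31.
    """
    z = (master_seed * 0x9E3779B97F4A7C15 + index + 1) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) % (2**31)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_cases: int = 500
    control_an: int = 20000
    genes: tuple[tuple[str, int], ...] = DEFAULT_GENES
    af_spectrum: tuple[tuple[float, float], ...] = DEFAULT_AF_SPECTRUM
    enrichment: dict[str, float] = field(default_factory=dict)  # gene -> lambda
    depth_mean: float = 60.0
    missing_rate: float = 0.02
    qc_noise: float = 0.0
    hom_alt_rate: float = 0.0  # fraction of carriers injected as hom-alt
    ann_cadd: float = 25.0
    ann_consequence: str = "missense_variant"

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.control_an < 1 or self.depth_mean <= 0:
            raise ValueError("n_cases, control_an and depth_mean must be positive")
        w = sum(wt for _, wt in self.af_spectrum)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"af_spectrum weights sum to {w}, expected 1")
        for name, lam in self.enrichment.items():
            if lam < 0:
                raise ValueError(f"enrichment lambda for {name} must be >= 0")
        for rate in (self.missing_rate, self.qc_noise, self.hom_alt_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")

    def lam(self, gene: str) -> float:
        return self.enrichment.get(gene, 1.0)


@dataclass(frozen=True)
class SimSite:
    key: VariantKey
    gene: str
    nominal_af: float
    control: ControlFrequencyRecord
    carriers: tuple[GenotypeCall, ...]
    missing: frozenset[str]
    truth_tier: RarityTier


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    sample_ids: tuple[str, ...]
    sites: list[SimSite]
    subsets: list[CohortSubset]
    truth: dict

    @property
    def control_map(self) -> dict[VariantKey, ControlFrequencyRecord]:
        return {s.key: s.control for s in self.sites}

    @property
    def annotation_map(self) -> dict[VariantKey, AnnotationRecord]:
        from .classify import map_consequence

        cls = map_consequence(self.config.ann_consequence)
        return {
            s.key: AnnotationRecord(
                key=s.key, gene=s.gene, consequence=cls,
                hgvs_p=f"p.sim{s.key.pos}", cadd_phred=self.config.ann_cadd,
            )
            for s in self.sites
        }

    def annotated_variants(self) -> list[AnnotatedVariant]:
        """Joined records as the pipeline would build them (pre-QC)."""
        out = []
        ann = self.annotation_map
        for s in self.sites:
            control = s.control if s.control.ac > 0 else None
            out.append(
                AnnotatedVariant(
                    key=s.key, gene=s.gene, annotation=ann[s.key],
                    control=control, carriers=s.carriers,
                    missing_samples=s.missing, n_samples=len(self.sample_ids),
                )
            )
        return out

    def case_sites(self) -> list[CaseSite]:
        """Materialize full per-sample genotype vectors (for VCF export)."""
        out = []
        for s in self.sites:
            carrier_by_id = {c.sample_id: c for c in s.carriers}
            calls = []
            n_called = 0
            for sid in self.sample_ids:
                if sid in carrier_by_id:
                    calls.append(carrier_by_id[sid])
                    n_called += 1
                elif sid in s.missing:
                    calls.append(GenotypeCall(sid, "missing"))
                else:
                    calls.append(GenotypeCall(sid, "hom_ref", ref_reads=30, gq=99))
                    n_called += 1
            out.append(CaseSite(s.key, tuple(calls), n_called / len(self.sample_ids)))
        return out

    # -- file export ---------------------------------------------------------

    def write_vcf(self, path: Union[str, Path]) -> None:
        import pysam

        header = pysam.VariantHeader()
        chroms = sorted({s.key.chrom for s in self.sites})
        for chrom in chroms:
            header.contigs.add(chrom, length=2_000_000_000)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
        for sid in self.sample_ids:
            header.add_sample(sid)
        gt_codes = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for site in self.case_sites():
                rec = out.new_record(
                    contig=site.key.chrom, start=site.key.pos - 1,
                    alleles=(site.key.ref, site.key.alt),
                )
                for call in site.calls:
                    fmt = rec.samples[call.sample_id]
                    if call.gt_class == "missing":
                        fmt["GT"] = (None, None)
                    else:
                        fmt["GT"] = gt_codes[call.gt_class]
                        fmt["AD"] = (call.ref_reads, call.alt_reads)
                        fmt["GQ"] = call.gq
                out.write(rec)

    def write_control_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\tAC\tAN\tAF\n")
            for s in self.sites:
                c = s.control
                fh.write(
                    f"{c.key.chrom}\t{c.key.pos}\t{c.key.ref}\t{c.key.alt}"
                    f"\t{c.ac}\t{c.an}\t{c.af!r}\n"
                )

    def write_annotation_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\tGENE\tCONSEQUENCE\tHGVSP\tCADD_PHRED\tREVEL\tACMG\tDDG\tDOMAIN\n")
            for s in self.sites:
                a = self.annotation_map[s.key]
                fh.write(
                    f"{s.key.chrom}\t{s.key.pos}\t{s.key.ref}\t{s.key.alt}"
                    f"\t{a.gene}\t{self.config.ann_consequence}\t{a.hgvs_p}"
                    f"\t{a.cadd_phred}\t\t\t\t\n"
                )

    def write_subsets_tsv(self, path: Union[str, Path]) -> None:
        names = [s.name for s in self.subsets if s.name != "PanCancer"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\t" + "\t".join(names) + "\n")
            members = {s.name: s.sample_ids for s in self.subsets}
            for sid in self.sample_ids:
                flags = "\t".join("1" if sid in members[n] else "0" for n in names)
                fh.write(f"{sid}\t{flags}\n")

    def write_truth_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _draw_clean_ad(rng: np.random.Generator, depth_mean: float) -> tuple[int, int]:
    """Read support guaranteed to pass default genotype QC.

    Depth is Poisson but floored at 24 and the alt count is clamped into the
    central [0.3, 0.7] VAF band (and to >= 10 reads), so a clean heterozygous
    carrier can never fail the depth, balance or window rules by bad luck.
    """
    d = max(int(rng.poisson(depth_mean)), 24)
    x = int(rng.binomial(d, 0.5))
    lo = max(10, math.ceil(0.3 * d))
    hi = math.floor(0.7 * d)
    x = min(max(x, lo), hi)
    return d - x, x


def _draw_noisy_call(rng: np.random.Generator, sid: str, gt: str, depth_mean: float) -> GenotypeCall:
    """A carrier call guaranteed to fail default genotype QC."""
    if rng.random() < 0.5:  # low genotype quality (<= 20 fails the strict > 20 rule)
        ref, alt = _draw_clean_ad(rng, depth_mean)
        return GenotypeCall(sid, gt, ref, alt, gq=int(rng.integers(0, 21)))
    d = max(int(rng.poisson(depth_mean)), 24)
    alt = max(1, d // 10)  # VAF ~0.1: fails allelic balance and the het window
    return GenotypeCall(sid, gt, d - alt, alt, gq=99)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sample_ids = tuple(f"S{i:05d}" for i in range(config.n_cases))
    afs = np.array([af for af, _ in config.af_spectrum])
    weights = np.array([w for _, w in config.af_spectrum])
    boundaries = TierBoundaries()

    sites: list[SimSite] = []
    truth_carriers: dict[str, list[str]] = {}
    truth_noisy: dict[str, list[str]] = {}
    truth_tiers: dict[str, str] = {}
    for gi, (gene, n_sites) in enumerate(config.genes):
        lam = config.lam(gene)
        for si in range(n_sites):
            af = float(afs[rng.choice(len(afs), p=weights)])
            p_carrier = 2.0 * af * lam
            if p_carrier > 1.0:
                raise ValueError(
                    f"impossible config: 2*AF*lambda = {p_carrier:.3g} > 1 "
                    f"for gene {gene} site {si}"
                )
            key = VariantKey("1", 1_000_000 * (gi + 1) + si, "A", "G")
            ac = int(math.floor(af * config.control_an + 0.5))
            control = ControlFrequencyRecord(key, ac, config.control_an, ac / config.control_an)
            carrier_mask = rng.random(config.n_cases) < p_carrier
            carriers: list[GenotypeCall] = []
            noisy_ids: list[str] = []
            for idx in np.flatnonzero(carrier_mask):
                sid = sample_ids[idx]
                gt = "hom_alt" if rng.random() < config.hom_alt_rate else "het"
                if rng.random() < config.qc_noise:
                    carriers.append(_draw_noisy_call(rng, sid, gt, config.depth_mean))
                    noisy_ids.append(sid)
                else:
                    ref, alt = _draw_clean_ad(rng, config.depth_mean)
                    carriers.append(GenotypeCall(sid, gt, ref, alt, gq=99))
            carrier_ids = {c.sample_id for c in carriers}
            missing_mask = rng.random(config.n_cases) < config.missing_rate
            missing = frozenset(
                sample_ids[i] for i in np.flatnonzero(missing_mask)
                if sample_ids[i] not in carrier_ids
            )
            tier = classify_rarity(control.af, boundaries)
            site_id = f"{key.chrom}:{key.pos}:{key.ref}:{key.alt}"
            truth_carriers[site_id] = sorted(carrier_ids)
            if noisy_ids:
                truth_noisy[site_id] = sorted(noisy_ids)
            truth_tiers[site_id] = tier.value
            sites.append(SimSite(key, gene, af, control, tuple(carriers), missing, tier))

    subset_draw = rng.random(config.n_cases)
    edges = np.cumsum([p for _, p in SUBSET_PROBS])
    subset_members: dict[str, set[str]] = {name: set() for name, _ in SUBSET_PROBS}
    for i, u in enumerate(subset_draw):
        name = SUBSET_PROBS[int(np.searchsorted(edges, u))][0] if u < edges[-1] else SUBSET_PROBS[-1][0]
        subset_members[name].add(sample_ids[i])
    subsets = [CohortSubset("PanCancer", frozenset(sample_ids))] + [
        CohortSubset(name, frozenset(m)) for name, m in subset_members.items()
    ]

    truth = {
        "seed": config.seed,
        "enrichment": {g: config.lam(g) for g, _ in config.genes},
        "carriers": truth_carriers,
        "noisy_carriers": truth_noisy,
        "tiers": truth_tiers,
    }
    return SimulatedCohort(config, sample_ids, sites, subsets, truth)


@dataclass
class CalibrationResult:
    rejection_rate: dict[str, float]   # gene -> fraction of replicates rejected
    mean_or: dict[str, float]          # gene -> mean conditional-MLE OR
    n_reps: int
    alpha: float


def evaluate_calibration(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    thresholds: QCThresholds = QCThresholds(),
) -> CalibrationResult:
    """Run the full pipeline on ``n_reps`` fresh cohorts and summarize.

    A gene is rejected in a replicate when any of its family-adjusted
    one-sided p-values (across subsets and tier groups) falls below alpha.
    The reported OR per gene is the conditional MLE of the pan-cancer
    all-rare-tiers cell, averaged over replicates (infinite estimates, which
    occur when the case count sits at the support boundary, are excluded).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    genes = [g for g, _ in config.genes]
    rejections = {g: 0 for g in genes}
    ors: dict[str, list[float]] = {g: [] for g in genes}
    from dataclasses import replace as dc_replace

    for rep in range(n_reps):
        rep_config = dc_replace(config, seed=derive_seed(config.seed, rep))
        cohort = simulate_cohort(rep_config)
        variants, _ = apply_qc(cohort.annotated_variants(), thresholds)
        results = run_burden(
            variants, cohort.subsets, cohort.control_map, cohort.annotation_map,
            genes=genes,
        )
        for gene in genes:
            gene_results = [r for r in results if r.cell.gene == gene]
            if any(r.adj_greater < alpha for r in gene_results):
                rejections[gene] += 1
            for r in gene_results:
                if (r.cell.subset == "PanCancer"
                        and r.cell.tier_group is TierGroup.RARE_UNDER_0_1
                        and math.isfinite(r.test.or_cmle)):
                    ors[gene].append(r.test.or_cmle)
    return CalibrationResult(
        rejection_rate={g: rejections[g] / n_reps for g in genes},
        mean_or={g: (float(np.mean(v)) if v else float("nan")) for g, v in ors.items()},
        n_reps=n_reps,
        alpha=alpha,
    )
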