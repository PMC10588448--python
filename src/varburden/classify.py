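"""Candidate-variant selection, population-rarity tiers, protein-stability calls.

Candidate variants are coding changes (missense / frameshift indel / stop gain
/ splice site) below a population allele-frequency ceiling of 0.5%, with
missense additionally required to carry a CADD Phred score above 15. Rarity
tiers partition the control AF axis: novel (AF exactly 0), ultra-rare
(< 0.005%), very rare, rare (< 0.1%), and a residual low-frequency band up to
the candidate ceiling. Missense stability calls use a folding free-energy
change of 1.5 kcal/mol (a ~12-fold shift in the folded:unfolded ratio) as the
threshold for a destabilizing (or, with opposite sign, stabilizing) call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "ConsequenceClass",
    "RarityTier",
    "StabilityCall",
    "TierBoundaries",
    "classify_rarity",
    "classify_stability",
    "is_candidate",
    "map_consequence",
    "load_consequence_map",
]

CANDIDATE_CONSEQUENCES = frozenset(
    {"missense", "frameshift_indel", "stopgain", "splice"}
)

DEFAULT_CADD_MIN = 15.0
DEFAULT_STABILITY_CUTOFF = 1.5  # kcal/mol


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    STOPGAIN = "stopgain"
    SPLICE = "splice"
    OTHER = "other"


class RarityTier(str, enum.Enum):
    NOVEL = "NOVEL"
    ULTRA_RARE = "ULTRA_RARE"
    VERY_RARE = "VERY_RARE"
    RARE = "RARE"
    LOW_FREQ = "LOW_FREQ"
    EXCLUDED = "EXCLUDED"


class StabilityCall(str, enum.Enum):
    DESTABILIZING = "destabilizing"
    STABILIZING = "stabilizing"
    NEUTRAL = "neutral"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class TierBoundaries:
    """Upper AF bounds of the rarity tiers (all strict).

    The very-rare bound has no published definition; 0.05% is this package's
    geometric-midpoint convention between the ultra-rare and rare bounds and
    is deliberately excluded from any statistic (tier groups used for testing
    are ultra-rare+novel and < 0.1%, which do not depend on it).
    """

    ultra_rare_max: float = 0.00005  # 0.005%
    very_rare_max: float = 0.0005    # 0.05%
    rare_max: float = 0.001          # 0.1%
    candidate_max: float = 0.005     # 0.5%

    def __post_init__(self) -> None:
        if not (0 < self.ultra_rare_max <= self.very_rare_max <= self.rare_max <= self.candidate_max):
            raise ValueError("tier boundaries must satisfy 0 < ultra_rare <= very_rare <= rare <= candidate")


def classify_rarity(af: float, b: TierBoundaries = TierBoundaries()) -> RarityTier:
    """Assign the population-rarity tier for a control allele frequency."""
    if af < 0:
        raise ValueError(f"allele frequency {af} < 0")
    if af > 1:
        raise ValueError(f"allele frequency {af} > 1")
    if af == 0:
        return RarityTier.NOVEL
    if af < b.ultra_rare_max:
        return RarityTier.ULTRA_RARE
    if af < b.very_rare_max:
        return RarityTier.VERY_RARE
    if af < b.rare_max:
        return RarityTier.RARE
    if af < b.candidate_max:
        return RarityTier.LOW_FREQ
    return RarityTier.EXCLUDED


def classify_stability(
    ddg: Optional[float], cutoff: float = DEFAULT_STABILITY_CUTOFF
) -> StabilityCall:
    """Call the folding effect of a missense change from its ddG (kcal/mol).

    Positive ddG destabilizes (less folded protein), negative stabilizes.
    The bound is inclusive: a ddG of exactly +cutoff is destabilizing.
    """
    if cutoff <= 0:
        raise ValueError("stability cutoff must be positive")
    if ddg is None:
        return StabilityCall.UNAVAILABLE
    if ddg >= cutoff:
        return StabilityCall.DESTABILIZING
    if ddg <= -cutoff:
        return StabilityCall.STABILIZING
    return StabilityCall.NEUTRAL


def is_candidate(
    consequence: ConsequenceClass,
    control_af: float,
    cadd_phred: Optional[float],
    b: TierBoundaries = TierBoundaries(),
    cadd_min: float = DEFAULT_CADD_MIN,
) -> bool:
    """Candidate filter: qualifying consequence, AF below the ceiling, and
    (missense only) CADD strictly above the cutoff.

    Missense with no CADD score is excluded (the filter retains missense
    *with* a qualifying score); callers should log such exclusions.
    """
    if consequence.value not in CANDIDATE_CONSEQUENCES:
        return False
    if not (control_af < b.candidate_max):
        return False
    if consequence is ConsequenceClass.MISSENSE:
        return cadd_phred is not None and cadd_phred > cadd_min
    return True


def load_consequence_map() -> dict[str, ConsequenceClass]:
    """Annotation-dialect dictionary (VEP / ANNOVAR terms -> consequence class).

    Ships as editable package data so new dialects can be added without code
    changes.
    """
    text = resources.files("varburden.data").joinpath("consequence_map.yaml").read_text()
    raw = yaml.safe_load(text)
    return {term.lower(): ConsequenceClass(cls) for term, cls in raw.items()}


_DEFAULT_MAP: Optional[dict[str, ConsequenceClass]] = None


def map_consequence(term: str, mapping: Optional[dict[str, ConsequenceClass]] = None) -> ConsequenceClass:
    """Map a raw annotation consequence string onto the closed class set."""
    global _DEFAULT_MAP
    if mapping is None:
        if _DEFAULT_MAP is None:
            _DEFAULT_MAP = load_consequence_map()
        mapping = _DEFAULT_MAP
    return mapping.get(term.strip().lower(), ConsequenceClass.OTHER)
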