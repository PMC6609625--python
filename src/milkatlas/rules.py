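"""Dataset categorization rules.

Each proteomics dataset is assigned a milk-fraction class from how its
proteins were isolated, and a lactation-stage class from the days-in-milk
(DIM) of sampling or, for involution samples, the day after milking
cessation.

Fraction classes are operational: skimmed milk (centrifugation below
100 000 × g, with or without casein depletion by acidification), whey
(centrifugation at or above 100 000 × g), MFGM (cream separation) and
exosomes (sucrose-gradient ultracentrifugation of skimmed milk).

Stage classes tile the DIM axis: colostrum (first 5 days post-partum),
early lactation (6–21 DIM, the negative-energy-balance window), peak
(22–80 DIM), mid/post-peak (≥81 DIM), plus drying-off for samples taken
after milking stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .atlas import IsolationDescriptor

FRACTION_CLASSES = ("skimmed", "whey", "MFGM", "exosomes")
STAGE_CLASSES = ("colostrum", "early", "peak", "mid", "drying_off")

#: g-force at/above which a centrifugation-based isolation yields whey.
WHEY_G_THRESHOLD = 100_000


@dataclass(frozen=True)
class StageRuleSet:
    """Inclusive DIM intervals for the lactation stages.

    The intervals must be disjoint, ordered and jointly cover every
    non-negative DIM; ``mid`` is open-ended (DIM >= mid_min_dim).
    """

    colostrum_max_dim: int = 5
    early_range: tuple[int, int] = (6, 21)
    peak_range: tuple[int, int] = (22, 80)
    mid_min_dim: int = 81

    def __post_init__(self) -> None:
        lo_e, hi_e = self.early_range
        lo_p, hi_p = self.peak_range
        ok = (0 <= self.colostrum_max_dim
              and lo_e == self.colostrum_max_dim + 1 and lo_e <= hi_e
              and lo_p == hi_e + 1 and lo_p <= hi_p
              and self.mid_min_dim == hi_p + 1)
        if not ok:
            raise ValueError(
                "stage intervals must be ordered, disjoint and tile the "
                f"non-negative integers; got {self}")


DEFAULT_STAGE_RULES = StageRuleSet()


def classify_stage(dim: Optional[int] = None,
                   dryoff_day: Optional[int] = None,
                   rules: StageRuleSet = DEFAULT_STAGE_RULES) -> str:
    """Map a sampling time to its lactation-stage class.

    Exactly one of *dim* / *dryoff_day* must be given; a drying-off day
    always classifies as ``drying_off`` regardless of its value.
    """
    if (dim is None) == (dryoff_day is None):
        raise ValueError("exactly one of dim / dryoff_day must be provided")
    if dryoff_day is not None:
        if dryoff_day < 0:
            raise ValueError(f"dryoff_day must be >= 0, got {dryoff_day}")
        return "drying_off"
    assert dim is not None
    if dim < 0:
        raise ValueError(f"dim must be >= 0, got {dim}")
    if dim <= rules.colostrum_max_dim:
        return "colostrum"
    if rules.early_range[0] <= dim <= rules.early_range[1]:
        return "early"
    if rules.peak_range[0] <= dim <= rules.peak_range[1]:
        return "peak"
    return "mid"


def classify_fraction(method: IsolationDescriptor) -> str:
    """Map an isolation protocol to its milk-fraction class.

    Precedence: sucrose gradient (exosomes) over cream separation (MFGM)
    over the g-force test, because exosome isolation also involves
    centrifugation of skimmed milk. Acidification and major-protein
    depletion never change the class.
    """
    technique = method.technique
    if technique == "sucrose_gradient":
        return "exosomes"
    if technique == "cream_separation":
        return "MFGM"
    if technique in ("centrifugation", "ultracentrifugation"):
        if method.max_g is None:
            raise ValueError(
                f"g-force required to classify technique {technique!r}")
        return "whey" if method.max_g >= WHEY_G_THRESHOLD else "skimmed"
    raise ValueError(f"unknown isolation technique {technique!r}")
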