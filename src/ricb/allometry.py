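"""Per-tree aboveground biomass and age estimation.

Biomass follows the national-scale Jenkins allometry: total aboveground dry
biomass (kg) is a log-linear function of diameter at breast height,

    bm = exp(B1 + B2 * ln(DIA * 2.54))

where DIA is in inches and 2.54 converts to centimetres.  B1/B2 are the
JENKINS_TOTAL_B1/B2 species-group coefficients carried on the species
reference table.

Age comes from inverting Carmean-style site-index height curves.  The
forward model gives expected height (ft) of a tree of age A (years) on a
site of index S:

    H = b1 * S^b2 * (1 - exp(b3 * A)) ^ (b4 * S^b5)

with b3 < 0 so height rises monotonically to the asymptote b1 * S^b2.
Solving for A:

    A = (1/b3) * ln(1 - (H / (b1 * S^b2)) ^ (1 / (b4 * S^b5)))

Trees whose recorded height meets or exceeds the asymptote have no finite
solution; those ages are clamped to ``max_age_yr`` and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "JenkinsCoefficients",
    "CarmeanCoefficients",
    "TreeRecord",
    "PlotRecord",
    "jenkins_biomass",
    "carmean_height",
    "carmean_age",
    "carmean_asymptote",
    "representative_species",
    "read_carmean_table",
    "read_species_reference",
]

DEFAULT_MAX_AGE_YR = 300.0


@dataclass(frozen=True)
class JenkinsCoefficients:
    """Jenkins total-aboveground-biomass coefficients for one species group."""

    b1: float
    b2: float

    def __post_init__(self):
        if not (math.isfinite(self.b1) and math.isfinite(self.b2)):
            raise ValueError("Jenkins coefficients must be finite")


@dataclass(frozen=True)
class CarmeanCoefficients:
    """Site-index height-curve coefficients for one species group.

    b1 > 0 scales the asymptote; b3 < 0 is the (negative) rate constant of
    the asymptotic decay form, which makes height strictly increasing in age.
    """

    b1: float
    b2: float
    b3: float
    b4: float
    b5: float

    def __post_init__(self):
        vals = (self.b1, self.b2, self.b3, self.b4, self.b5)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("Carmean coefficients must be finite")
        if self.b1 <= 0:
            raise ValueError(f"Carmean b1 must be positive, got {self.b1}")
        if self.b3 >= 0:
            raise ValueError(f"Carmean b3 must be negative, got {self.b3}")


@dataclass(frozen=True)
class TreeRecord:
    """One inventory tree."""

    plot_id: int
    species_symbol: str
    common_name: str
    e_spgrpcd: int
    dia_in: float
    ht_ft: float
    alive: bool

    def __post_init__(self):
        if self.dia_in < 0:
            raise ValueError(f"negative diameter {self.dia_in}")
        if self.ht_ft < 0:
            raise ValueError(f"negative height {self.ht_ft}")


@dataclass(frozen=True)
class PlotRecord:
    """One inventory plot and its site index."""

    plot_id: int
    site_index: float

    def __post_init__(self):
        if not self.site_index > 0:
            raise ValueError(f"site index must be positive, got {self.site_index}")


def jenkins_biomass(dia_in: float, coeffs: JenkinsCoefficients) -> float:
    """Total aboveground dry biomass (kg) from diameter at breast height (in)."""
    if dia_in <= 0:
        raise ValueError(f"diameter must be positive, got {dia_in}")
    return math.exp(coeffs.b1 + coeffs.b2 * math.log(dia_in * 2.54))


def carmean_asymptote(site_index: float, coeffs: CarmeanCoefficients) -> float:
    """Maximum attainable height (ft) on a site: b1 * SI^b2."""
    if site_index <= 0:
        raise ValueError(f"site index must be positive, got {site_index}")
    return coeffs.b1 * site_index**coeffs.b2


def carmean_height(
    age_yr: float, site_index: float, coeffs: CarmeanCoefficients
) -> float:
    """Expected height (ft) at a given age (yr) — the forward site-index curve."""
    if age_yr <= 0:
        raise ValueError(f"age must be positive, got {age_yr}")
    if site_index <= 0:
        raise ValueError(f"site index must be positive, got {site_index}")
    asym = carmean_asymptote(site_index, coeffs)
    expo = coeffs.b4 * site_index**coeffs.b5
    return asym * (1.0 - math.exp(coeffs.b3 * age_yr)) ** expo


def carmean_age(
    ht_ft: float,
    site_index: float,
    coeffs: CarmeanCoefficients,
    max_age_yr: float = DEFAULT_MAX_AGE_YR,
) -> float:
    """Tree age (yr) from height (ft) by inverting the site-index curve.

    Heights at or above the site asymptote have no finite age; they are
    clamped to ``max_age_yr`` with a logged warning.  Height 0 gives age 0.
    """
    if ht_ft < 0:
        raise ValueError(f"height must be nonnegative, got {ht_ft}")
    if max_age_yr <= 0:
        raise ValueError(f"max_age_yr must be positive, got {max_age_yr}")
    if ht_ft == 0.0:
        return 0.0
    asym = carmean_asymptote(site_index, coeffs)
    if ht_ft >= asym:
        logger.warning(
            "clamped_age height=%.4f >= asymptote=%.4f (SI=%.2f); age set to %.1f",
            ht_ft,
            asym,
            site_index,
            max_age_yr,
        )
        return max_age_yr
    expo = coeffs.b4 * site_index**coeffs.b5
    age = (1.0 / coeffs.b3) * math.log(1.0 - (ht_ft / asym) ** (1.0 / expo))
    return min(max(age, 0.0), max_age_yr)


def representative_species(trees: Iterable[TreeRecord]) -> dict[int, str]:
    """Most numerous species symbol per eastern species group code.

    Ties are broken by the lexicographically smallest symbol.  Raises
    ``ValueError`` on empty input.
    """
    counts: Counter[tuple[int, str]] = Counter()
    for t in trees:
        counts[(t.e_spgrpcd, t.species_symbol)] += 1
    if not counts:
        raise ValueError("no trees supplied")
    best: dict[int, tuple[int, str]] = {}
    for (grp, sym), n in sorted(counts.items()):
        cur = best.get(grp)
        # sorted() visits symbols ascending, so strict > keeps the first
        # (lexicographically smallest) symbol on ties
        if cur is None or n > cur[0]:
            best[grp] = (n, sym)
    return {grp: sym for grp, (_, sym) in best.items()}


_CARMEAN_COLS = ["e_spgrpcd", "b1", "b2", "b3", "b4", "b5"]
_SPECIES_REF_COLS = [
    "SPECIES_SYMBOL",
    "COMMON_NAME",
    "E_SPGRPCD",
    "JENKINS_SPGRPCD",
    "JENKINS_TOTAL_B1",
    "JENKINS_TOTAL_B2",
]


def read_carmean_table(path) -> dict[int, CarmeanCoefficients]:
    """Load the site-index coefficient CSV keyed by eastern species group code."""
    df = pd.read_csv(path)
    missing = [c for c in _CARMEAN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"Carmean table {path} missing columns {missing}")
    return {
        int(r.e_spgrpcd): CarmeanCoefficients(r.b1, r.b2, r.b3, r.b4, r.b5)
        for r in df.itertuples()
    }


def read_species_reference(path) -> pd.DataFrame:
    """Load the species reference CSV (symbol, name, group codes, Jenkins B1/B2)."""
    df = pd.read_csv(path)
    missing = [c for c in _SPECIES_REF_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"species reference {path} missing columns {missing}")
    return df


def jenkins_table(species_ref: pd.DataFrame) -> Mapping[str, JenkinsCoefficients]:
    """Species symbol -> Jenkins coefficients, from the reference table."""
    return {
        str(r.SPECIES_SYMBOL): JenkinsCoefficients(
            float(r.JENKINS_TOTAL_B1), float(r.JENKINS_TOTAL_B2)
        )
        for r in species_ref.itertuples()
    }
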