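"""Rate estimators for oocyte-configuration and progeny-count data.

Two kinds of counts are scored in these experiments:

* cytological counts -- oocytes classified at prometaphase I (chromosomes
  out on the spindle or congressed) or at metaphase I arrest (orientation
  of the heterologs), which need no recovery correction;
* genetic counts -- surviving progeny of single-female test crosses, where
  entire exceptional classes can be lost to sperm-genotype lethality or to
  the poor viability of haplo-4 (minute) zygotes.  The published recovery
  convention multiplies the surviving exceptional count by a power of two
  derived from the viability model, and this module derives that factor
  rather than hard-coding it per genotype.

Percentages are rounded half-away-from-zero to the printed precision.
Confidence intervals are Wilson score intervals; for corrected rates the
interval is computed on the *observed* exceptional-class proportion (which
is binomial) and mapped through the monotone correction, so that coverage
is the ordinary Wilson coverage of a binomial proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Tuple

from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

from .model import (
    CrossDesign,
    ViabilityModel,
    fertilize,
    survival,
)

__all__ = [
    "EmptySampleError",
    "NoRecoverableClassError",
    "OocyteConfigCounts",
    "ProgenyCountTable",
    "RateEstimate",
    "CytologicalRateSet",
    "ComparisonResult",
    "round_half_up",
    "wilson_interval",
    "cytological_rates",
    "orientation_hs_rate",
    "correction_factor",
    "genetic_hs_rate",
    "map_distance",
    "compare_rates",
]


class EmptySampleError(ValueError):
    """A rate was requested from a zero denominator."""


class NoRecoverableClassError(ValueError):
    """No product of the heterologous event yields a scorable survivor."""


def _nonneg(name, value):
    if not isinstance(value, int) or value < 0:
        raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")


@dataclass(frozen=True)
class OocyteConfigCounts:
    """Oocyte counts for one genotype at one cytological stage.

    single_mass and one_plus_out are mutually exclusive; compound_out is
    the subset of one_plus_out where the compound itself was out on the
    spindle; hs_config is the subset of scored oocytes in the heterologous
    biorientation; other_config counts abnormal figures outside those
    classes.
    """

    stage: str
    single_mass: int
    one_plus_out: int
    compound_out: int = 0
    hs_config: int = 0
    other_config: int = 0

    def __post_init__(self):
        if self.stage not in ("prometaphase_2d", "metaphase_4d"):
            raise ValueError(f"unknown stage {self.stage!r}")
        for f in ("single_mass", "one_plus_out", "compound_out", "hs_config", "other_config"):
            _nonneg(f, getattr(self, f))
        if self.compound_out > self.one_plus_out:
            raise ValueError("compound_out must be a subset of one_plus_out")
        if self.hs_config > self.single_mass + self.one_plus_out:
            raise ValueError("hs_config must be a subset of the scored oocytes")

    @property
    def total(self) -> int:
        return self.single_mass + self.one_plus_out


@dataclass(frozen=True)
class ProgenyCountTable:
    """Surviving progeny of a test cross, partitioned by phenotype class."""

    normal: int
    hs_exceptional: int
    other: int = 0
    recombinant: int = 0
    paternal_ndj: int = 0

    def __post_init__(self):
        for f in ("normal", "hs_exceptional", "other", "recombinant", "paternal_ndj"):
            _nonneg(f, getattr(self, f))
        if self.recombinant + self.paternal_ndj > self.other:
            raise ValueError("recombinant and paternal_ndj are subsets of other")

    @property
    def total(self) -> int:
        return self.normal + self.hs_exceptional + self.other


@dataclass(frozen=True)
class RateEstimate:
    """A percentage with its corrected counts and Wilson 95% interval."""

    point: float
    numerator: int
    denominator: int
    ci_low: float
    ci_high: float
    correction_applied: int = 1
    decimals: int = 1

    def __post_init__(self):
        if self.denominator <= 0:
            raise EmptySampleError("rate denominator must be positive")
        if not (
            0.0 <= self.ci_low <= self.point + 10.0 ** -self.decimals
            and self.point - 10.0 ** -self.decimals <= self.ci_high <= 100.0
        ):
            raise ValueError("interval must bracket the point estimate")


def round_half_up(x, decimals: int = 0) -> float:
    """Round half away from zero at *decimals* places.

    Exact for ratios of integers (the only case the estimators use), so a
    printed value like 65.4 never depends on binary-float tie behaviour.
    """
    q = Fraction(x).limit_denominator(10 ** 12) if not isinstance(x, Fraction) else x
    scaled = q * 10 ** decimals
    sign = -1 if scaled < 0 else 1
    out = sign * math.floor(abs(scaled) + Fraction(1, 2))
    return float(Fraction(out, 10 ** decimals))


def wilson_interval(k: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a proportion, in percent."""
    _nonneg("k", k)
    if n <= 0:
        raise EmptySampleError("wilson_interval requires n > 0")
    if k > n:
        raise ValueError("k must not exceed n")
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    low = 0.0 if k == 0 else max(0.0, 100.0 * low)
    high = 100.0 if k == n else min(100.0, 100.0 * high)
    return low, high


def _pct(k: int, n: int, decimals: int, correction: int = 1) -> RateEstimate:
    if n <= 0:
        raise EmptySampleError("empty sample")
    low, high = wilson_interval(k, n)
    return RateEstimate(
        point=round_half_up(Fraction(100 * k, n), decimals),
        numerator=k,
        denominator=n,
        ci_low=low,
        ci_high=high,
        correction_applied=correction,
        decimals=decimals,
    )


@dataclass(frozen=True)
class CytologicalRateSet:
    pct_single_mass: RateEstimate
    pct_one_plus_out: RateEstimate
    pct_compound_out: RateEstimate
    pct_hs: RateEstimate


def cytological_rates(c: OocyteConfigCounts) -> CytologicalRateSet:
    """Configuration rates over the scored oocytes, to the nearest percent.

    All four rates share the denominator single_mass + one_plus_out;
    hs_config is a subset of the scored oocytes and is never added to the
    denominator.
    """
    n = c.total
    if n <= 0:
        raise EmptySampleError(f"no scored oocytes at stage {c.stage}")
    return CytologicalRateSet(
        pct_single_mass=_pct(c.single_mass, n, 0),
        pct_one_plus_out=_pct(c.one_plus_out, n, 0),
        pct_compound_out=_pct(c.compound_out, n, 0),
        pct_hs=_pct(c.hs_config, n, 0),
    )


def orientation_hs_rate(
    normal: int, hs: int, other: int = 0, decimals: int = 0
) -> RateEstimate:
    """Heterologous-orientation rate from metaphase-arrest orientation counts
    (normal / HS / other), to the nearest percent."""
    for name, v in (("normal", normal), ("hs", hs), ("other", other)):
        _nonneg(name, v)
    return _pct(hs, normal + hs + other, decimals)


# ---------------------------------------------------------------------------
# viability-derived recovery correction


def _hs_products(design: CrossDesign):
    hs_labels = {
        lab for lab, cat in design.class_partition.items() if cat == "hs_exceptional"
    }
    contents = {
        ov for (ov, _sp), lab in design.marker_map.items() if lab in hs_labels
    }
    if not contents:
        raise NoRecoverableClassError(
            f"design {design.label!r} maps no ovum class to an exceptional phenotype"
        )
    all_ids = design.female.segregating_ids
    products = set()
    for c in contents:
        products.add(c)
        products.add(all_ids - c)
    if len(products) != 2:
        raise NoRecoverableClassError(
            f"design {design.label!r}: exceptional classes do not form one "
            f"reciprocal product pair (got {len(products)})"
        )
    return tuple(products)


def correction_factor(design: CrossDesign, v: Optional[ViabilityModel] = None) -> int:
    """Integer multiplier for surviving exceptional progeny counts.

    Derived from the viability model, never hard-coded per genotype: the
    heterologous event produces two reciprocal ovum classes; the count is
    doubled once if only one of the two yields any scorable exceptional
    survivor (the other being, e.g., a haplo-4 minute class with
    ``v_minute = 0``), and doubled again for every factor-of-two loss of
    the surviving classes to incompatible sperm genotypes.
    """
    if v is None:
        v = design.viability
    prod_a, prod_b = _hs_products(design)
    hs_labels = {
        lab for lab, cat in design.class_partition.items() if cat == "hs_exceptional"
    }

    def recovery(content) -> float:
        got = 0.0
        for name, sc in design.sperm_classes.items():
            z = fertilize(design, content, name)
            s = survival(z, v)
            if s <= 0.0:
                continue
            lab = design.marker_map.get((content, name))
            if lab in hs_labels:
                got += sc.prob * s
        return got

    rec = {prod_a: recovery(prod_a), prod_b: recovery(prod_b)}
    alive = [c for c, r in rec.items() if r > 0.0]
    if not alive:
        raise NoRecoverableClassError(
            f"design {design.label!r}: neither heterologous product is recoverable"
        )
    factor = 2 if len(alive) == 1 else 1
    mean_sperm = sum(rec[c] for c in alive) / len(alive)
    factor *= max(1, round(1.0 / mean_sperm))
    return factor


# ---------------------------------------------------------------------------
# corrected genetic rates


def _corrected_ci(
    hs: int, scored: int, factor: int, conf: float = 0.95
) -> Tuple[float, float]:
    # Wilson on the observed (binomial) exceptional proportion pi = hs/scored,
    # mapped through the monotone correction g(pi) = f*pi / (1 + (f-1)*pi).
    low, high = proportion_confint(hs, scored, alpha=1.0 - conf, method="wilson")

    def g(pi: float) -> float:
        return 100.0 * factor * pi / (1.0 + (factor - 1.0) * pi)

    return g(low), g(high)


def genetic_hs_rate(
    t: ProgenyCountTable, factor: int, decimals: int = 1
) -> RateEstimate:
    """Viability-corrected heterologous-segregation (or secondary-NDJ) rate.

    numerator = factor x surviving exceptional progeny; denominator =
    normal + numerator + (other - paternal NDJ): progeny from paternal
    nondisjunction are not products of the female meiosis being measured,
    while maternal recombinants stay in the denominator uncorrected.
    """
    if factor < 1:
        raise ValueError("correction factor must be >= 1")
    num = factor * t.hs_exceptional
    maternal_other = t.other - t.paternal_ndj
    den = t.normal + num + maternal_other
    if den <= 0:
        raise EmptySampleError("no scored progeny")
    scored = t.normal + t.hs_exceptional + maternal_other
    low, high = _corrected_ci(t.hs_exceptional, scored, factor)
    return RateEstimate(
        point=round_half_up(Fraction(100 * num, den), decimals),
        numerator=num,
        denominator=den,
        ci_low=low,
        ci_high=high,
        correction_applied=factor,
        decimals=decimals,
    )


def map_distance(t: ProgenyCountTable, factor: int, decimals: int = 1) -> float:
    """Map distance of the scored X interval in centimorgans.

    100 x recombinants / (normal + factor x exceptional + recombinants);
    recombinant counts themselves receive no viability correction.
    """
    if t.recombinant > t.other:
        raise ValueError("recombinant must be a subset of other")
    den = t.normal + factor * t.hs_exceptional + t.recombinant
    if den <= 0:
        raise EmptySampleError("no scored progeny")
    return round_half_up(Fraction(100 * t.recombinant, den), decimals)


@dataclass(frozen=True)
class ComparisonResult:
    """Cytology-vs-genetics concordance for one genotype."""

    p_value: float
    rate_difference: float  # cytological minus genetic, percentage points
    ci_overlap: bool
    significant: bool
    alpha: float = 0.05


def compare_rates(
    cyt: Tuple[int, int], gen: Tuple[int, int], alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided Fisher exact test of a cytological (k, n) proportion
    against the corrected genetic (numerator, denominator) pair, plus a
    Wilson 95% interval overlap flag."""
    for (k, n) in (cyt, gen):
        if n <= 0:
            raise EmptySampleError("empty sample in comparison")
        if not (0 <= k <= n):
            raise ValueError("k must lie in [0, n]")
    table = [[cyt[0], cyt[1] - cyt[0]], [gen[0], gen[1] - gen[0]]]
    _, p = fisher_exact(table, alternative="two-sided")
    c_low, c_high = wilson_interval(*cyt)
    g_low, g_high = wilson_interval(*gen)
    overlap = (c_low <= g_high) and (g_low <= c_high)
    diff = 100.0 * cyt[0] / cyt[1] - 100.0 * gen[0] / gen[1]
    return ComparisonResult(
        p_value=float(p),
        rate_difference=diff,
        ci_overlap=overlap,
        significant=bool(p < alpha),
        alpha=alpha,
    )
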