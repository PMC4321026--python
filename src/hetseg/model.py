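"""Forward model of *Drosophila melanogaster* female meiosis I for aberrant
karyotypes.

Karyotypes are built from chromosome copies (normal homologs, compound
chromosomes, inversion/balancer X's, a free Y) and the model computes the
*exact* distribution over ovum content classes under the meiosis-I
segregation rules of classical fly genetics:

* an exchange X bivalent sends its homologs to opposite poles;
* a nonexchange X pair in the presence of a Y undergoes secondary
  nondisjunction (both X's away from the Y) with a tunable probability,
  otherwise the X's disjoin and the Y goes to either pole at random;
* a heterologous pair (compound vs. compound, compound vs. the 4-4
  bivalent, or compound vs. a nonexchange XX pair) co-orients to opposite
  poles with a tunable probability, and otherwise falls back to independent
  orientation of the participants;
* a lone monovalent is included in the ovum with probability exactly 1/2.

Everything is meiosis-I reductional: no chromatid-level events are
modelled, and crossing-over in the single scored X interval (v--f) is
collapsed into a per-meiosis probability that the ovum carries a
recombinant X.  Fertilization is additive on element doses, and zygote
survival is decided by an ordered first-match rule list over those doses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "ELEMENTS",
    "MAJOR_ARMS",
    "XX_UNIT",
    "FOUR_UNIT",
    "REC_ID",
    "Rearrangement",
    "ChromosomeCopy",
    "Karyotype",
    "MeiosisParams",
    "GameteDistribution",
    "SpermClass",
    "Zygote",
    "ViabilityRule",
    "ViabilityModel",
    "CrossDesign",
    "UnsupportedKaryotypeError",
    "MarkerMapError",
    "gamete_distribution",
    "pole_partition_distribution",
    "hs_event_products",
    "heterolog_q_from_rate",
    "fertilize",
    "survival",
    "phenotype_class",
    "default_viability",
    "permissive_viability",
]

#: chromosome elements tracked as integer doses
ELEMENTS = ("X", "Y", "2L", "2R", "3L", "3R", "4")
#: the major autosome arms; any dose other than 2 is zygotic-lethal
MAJOR_ARMS = ("2L", "2R", "3L", "3R")

#: segregation-unit labels used as keys of :attr:`MeiosisParams.p_hs`
XX_UNIT = "XX"
FOUR_UNIT = "44"

#: sentinel copy id carried by ova recombinant in the scored X interval
REC_ID = "X-recombinant"

_PROB_TOL = 1e-12


class UnsupportedKaryotypeError(ValueError):
    """Raised for karyotype/parameter combinations outside the supported
    configuration families.  The model fails loudly rather than guessing."""


class MarkerMapError(KeyError):
    """A viable zygote genotype has no phenotype-class mapping."""


class Rearrangement(str, Enum):
    NORMAL = "normal"
    COMPOUND = "compound"
    INVERSION = "inversion"
    BALANCER = "balancer"
    Y_DERIVED = "Y_derived"
    EMPTY = "empty"


@dataclass(frozen=True)
class ChromosomeCopy:
    """One transmissible chromosome: a normal homolog, a compound, a
    rearranged X, a (marked) Y, or the empty placeholder written as an
    "O" slash partner in genotype notation."""

    id: str
    elements: Mapping[str, int] = field(default_factory=dict)
    rearrangement: Rearrangement = Rearrangement.NORMAL
    markers: frozenset = frozenset()
    exchange_competent: bool = True

    def __post_init__(self):
        object.__setattr__(self, "elements", dict(self.elements))
        object.__setattr__(self, "markers", frozenset(self.markers))
        for el, dose in self.elements.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element {el!r} on copy {self.id!r}")
            if not isinstance(dose, int) or dose < 0:
                raise ValueError(f"element dose must be a nonnegative integer, got {el}={dose!r}")
        if self.rearrangement is Rearrangement.EMPTY and self.total_dose() != 0:
            raise ValueError("the empty placeholder must carry zero dose of every element")
        if self.rearrangement is Rearrangement.COMPOUND and not any(
            d >= 2 for d in self.elements.values()
        ):
            raise ValueError(f"compound {self.id!r} must carry dose >= 2 of some element")

    def dose(self, element: str) -> int:
        return self.elements.get(element, 0)

    def total_dose(self) -> int:
        return sum(self.elements.values())


@dataclass(frozen=True)
class Karyotype:
    """A maternal chromosome complement.

    Only the segregationally interesting copies need to be listed; fully
    balanced homologous bivalents that always contribute one member to
    every ovum (e.g. the major autosomes in an XXY female) may be left
    implicit and are then outside the viability model's scope.
    """

    copies: tuple
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "copies", tuple(self.copies))
        ids = [c.id for c in self.copies]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate copy ids in karyotype {self.label!r}")

    def dose(self, element: str) -> int:
        """Total dose of *element* over all copies."""
        return sum(c.dose(element) for c in self.copies)

    def get(self, copy_id: str) -> ChromosomeCopy:
        for c in self.copies:
            if c.id == copy_id:
                return c
        raise KeyError(copy_id)

    @property
    def segregating_ids(self) -> frozenset:
        """Ids of all non-empty copies (the maternal centromere set)."""
        return frozenset(
            c.id for c in self.copies if c.rearrangement is not Rearrangement.EMPTY
        )


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class MeiosisParams:
    """Tunable meiosis-I rates.

    p_nonexchange_X
        Probability that an exchange-competent X pair spontaneously fails
        to cross over (5-10% for structurally normal X's; forced to 1 when
        either X is exchange-blocked, e.g. a balancer heterozygote).
    p_secondary_ndj
        Given nonexchange X's and a Y, probability of the XX<=>Y pattern.
    p_hs
        Map from a frozenset of two segregation-unit labels (``"XX"``,
        ``"44"``, or a monovalent copy id) to the probability that the two
        heterologs co-orient to opposite poles; with probability 1-q the
        participants fall back to independent orientation.
    p_recombinant_interval
        Per-meiosis probability that the ovum is recombinant in the single
        scored X interval (= map distance / 100).
    p_monovalent_recovery
        Fixed at exactly 0.5: a lone monovalent goes to either pole at
        random.
    """

    p_nonexchange_X: float = 0.0
    p_secondary_ndj: float = 0.0
    p_hs: Mapping[frozenset, float] = field(default_factory=dict)
    p_recombinant_interval: float = 0.0
    p_monovalent_recovery: float = 0.5
    seed: int = 0

    def __post_init__(self):
        _check_prob("p_nonexchange_X", self.p_nonexchange_X)
        _check_prob("p_secondary_ndj", self.p_secondary_ndj)
        _check_prob("p_recombinant_interval", self.p_recombinant_interval)
        if self.p_monovalent_recovery != 0.5:
            raise ValueError("p_monovalent_recovery is fixed at exactly 0.5")
        norm = {}
        for pair, q in dict(self.p_hs).items():
            pair = frozenset(pair)
            if len(pair) != 2:
                raise ValueError(f"p_hs keys must name two distinct units, got {set(pair)}")
            _check_prob(f"p_hs[{set(pair)}]", q)
            norm[pair] = q
        object.__setattr__(self, "p_hs", norm)


def heterolog_q_from_rate(rate: float) -> float:
    """Co-orientation probability q implied by an observed opposite-pole
    rate R for two *monovalent* heterologs.

    With probability q the pair biorients; otherwise both members orient
    independently at random and still land on opposite poles half the
    time, so R = q + (1 - q)/2 and q = 2R - 1.
    """
    _check_prob("rate", rate)
    if rate < 0.5:
        raise ValueError(
            "an opposite-pole rate below 1/2 is not representable: "
            "independent orientation already gives R = 1/2"
        )
    return 2.0 * rate - 1.0


@dataclass(frozen=True)
class GameteDistribution:
    """Exact probability distribution over ovum content classes.

    Classes are frozensets of maternal copy ids (each copy appears at most
    once); probabilities sum to 1 within 1e-12.
    """

    classes: Mapping[frozenset, float]

    def __post_init__(self):
        object.__setattr__(self, "classes", dict(self.classes))
        total = sum(self.classes.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"class probabilities sum to {total!r}, not 1")
        for content, p in self.classes.items():
            if p < -_PROB_TOL:
                raise ValueError("negative class probability")
            if not isinstance(content, frozenset):
                raise TypeError("ovum classes must be frozensets of copy ids")

    def p(self, content: Iterable[str]) -> float:
        return self.classes.get(frozenset(content), 0.0)

    def items(self):
        return self.classes.items()


# ---------------------------------------------------------------------------
# karyotype classification into segregation units


@dataclass(frozen=True)
class _Units:
    x_pair: Optional[tuple]          # (copy, copy) or None
    y_copy: Optional[ChromosomeCopy]
    four_pair: Optional[tuple]
    monovalents: tuple

    def content(self, label: str) -> tuple:
        """Copy ids making up the unit named *label*."""
        if label == XX_UNIT and self.x_pair:
            return tuple(c.id for c in self.x_pair)
        if label == FOUR_UNIT and self.four_pair:
            return tuple(c.id for c in self.four_pair)
        for m in self.monovalents:
            if m.id == label:
                return (m.id,)
        raise KeyError(label)

    @property
    def labels(self) -> set:
        out = set()
        if self.x_pair:
            out.add(XX_UNIT)
        if self.four_pair:
            out.add(FOUR_UNIT)
        out.update(m.id for m in self.monovalents)
        return out


def _classify(k: Karyotype) -> _Units:
    xs, ys, fours, monos = [], [], [], []
    for c in k.copies:
        if c.rearrangement is Rearrangement.EMPTY:
            continue
        if c.rearrangement is Rearrangement.COMPOUND:
            monos.append(c)
        elif c.rearrangement is Rearrangement.Y_DERIVED or (
            c.dose("Y") > 0 and c.dose("X") == 0
        ):
            ys.append(c)
        elif c.dose("X") == 1 and c.total_dose() == 1:
            xs.append(c)
        elif c.dose("4") == 1 and c.total_dose() == 1:
            fours.append(c)
        else:
            raise UnsupportedKaryotypeError(
                f"copy {c.id!r} of {k.label!r} does not fit any supported "
                "segregation unit (single X, single 4, Y, compound)"
            )
    if len(xs) not in (0, 2):
        raise UnsupportedKaryotypeError(
            f"{k.label!r}: need exactly 0 or 2 single-X copies, found {len(xs)}"
        )
    if len(ys) > 1:
        raise UnsupportedKaryotypeError(f"{k.label!r}: more than one Y chromosome")
    if len(fours) == 1:
        monos.append(fours[0])
        fours = []
    if len(fours) > 2:
        raise UnsupportedKaryotypeError(f"{k.label!r}: more than two free 4 chromosomes")
    if len(monos) > 2:
        raise UnsupportedKaryotypeError(f"{k.label!r}: more than two monovalents")
    return _Units(
        x_pair=tuple(xs) if xs else None,
        y_copy=ys[0] if ys else None,
        four_pair=tuple(fours) if len(fours) == 2 else None,
        monovalents=tuple(monos),
    )


@dataclass(frozen=True)
class _HSInteraction:
    q: float
    labels: frozenset
    side_a: tuple  # copy ids, pair-style unit goes together
    side_b: tuple


def _active_hs(units: _Units, params: MeiosisParams) -> Optional[_HSInteraction]:
    hits = []
    for pair, q in params.p_hs.items():
        missing = pair - units.labels
        if missing:
            raise UnsupportedKaryotypeError(
                f"p_hs names unit(s) {sorted(missing)} absent from the karyotype"
            )
        if q == 0.0:
            continue
        a, b = sorted(pair)
        if {a, b} == {XX_UNIT, FOUR_UNIT}:
            raise UnsupportedKaryotypeError(
                "heterologous co-orientation of the XX and 44 pairs is not supported"
            )
        hits.append(_HSInteraction(q, pair, units.content(a), units.content(b)))
    if len(hits) > 1:
        raise UnsupportedKaryotypeError("at most one heterologous pair may be active")
    if hits and XX_UNIT in hits[0].labels and units.y_copy is not None and params.p_secondary_ndj > 0:
        raise UnsupportedKaryotypeError(
            "an XX heterolog pair cannot compete with secondary nondisjunction"
        )
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# scenario enumeration

# a group sends side A to one pole and side B to the other; which side ends
# up in the ovum is an independent fair coin per group (pole-choice symmetry)
_Group = tuple  # ((ids...), (ids...))


def _default_groups(units: _Units, skip: set) -> list:
    groups = []
    if units.x_pair and XX_UNIT not in skip:
        x1, x2 = units.x_pair
        groups.append(((x1.id,), (x2.id,)))
    if units.y_copy and "Y" not in skip:
        groups.append(((units.y_copy.id,), ()))
    if units.four_pair and FOUR_UNIT not in skip:
        f1, f2 = units.four_pair
        groups.append(((f1.id,), (f2.id,)))
    for m in units.monovalents:
        if m.id not in skip:
            groups.append(((m.id,), ()))
    return groups


def _scenarios(k: Karyotype, params: MeiosisParams):
    """Mixture of pole-assignment scenarios: list of (probability, groups)."""
    units = _classify(k)
    hs = _active_hs(units, params)
    hs_xx = hs if (hs is not None and XX_UNIT in hs.labels) else None
    hs_other = hs if (hs is not None and XX_UNIT not in hs.labels) else None

    # sex-chromosome-level branches: (prob, leading groups, unit labels handled)
    xbranches = []
    if units.x_pair is None:
        if params.p_recombinant_interval > 0:
            raise UnsupportedKaryotypeError("recombinant ova require a single-X pair")
        xbranches.append((1.0, [], set()))
    else:
        x1, x2 = units.x_pair
        competent = x1.exchange_competent and x2.exchange_competent
        r = params.p_recombinant_interval
        if r > 0 and not competent:
            raise UnsupportedKaryotypeError(
                "recombination in the scored interval requires an "
                "exchange-competent X pair"
            )
        p_nx = params.p_nonexchange_X if competent else 1.0
        p_ex = (1.0 - r) * (1.0 - p_nx)
        p_non = (1.0 - r) * p_nx

        if r > 0:
            xbranches.append((r, [((REC_ID,), (REC_ID,))], {XX_UNIT}))
        if p_ex > 0:
            xbranches.append((p_ex, [((x1.id,), (x2.id,))], {XX_UNIT}))
        if p_non > 0:
            disjoin = (p_non, [((x1.id,), (x2.id,))], {XX_UNIT})
            if units.y_copy is not None and params.p_secondary_ndj > 0:
                p2 = params.p_secondary_ndj
                xbranches.append(
                    (
                        p_non * p2,
                        [((x1.id, x2.id), (units.y_copy.id,))],
                        {XX_UNIT, "Y"},
                    )
                )
                if p2 < 1.0:
                    xbranches.append((p_non * (1.0 - p2), disjoin[1], {XX_UNIT}))
            elif hs_xx is not None:
                partner = hs_xx.side_b if hs_xx.side_a == (x1.id, x2.id) else hs_xx.side_a
                xbranches.append(
                    (
                        p_non * hs_xx.q,
                        [((x1.id, x2.id), partner)],
                        {XX_UNIT} | set(hs_xx.labels),
                    )
                )
                if hs_xx.q < 1.0:
                    xbranches.append((p_non * (1.0 - hs_xx.q), disjoin[1], {XX_UNIT}))
            else:
                xbranches.append(disjoin)

    scen = []
    for p, lead, handled in xbranches:
        if hs_other is not None:
            scen.append(
                (
                    p * hs_other.q,
                    lead
                    + [(hs_other.side_a, hs_other.side_b)]
                    + _default_groups(units, handled | set(hs_other.labels)),
                )
            )
            if hs_other.q < 1.0:
                scen.append(
                    (p * (1.0 - hs_other.q), lead + _default_groups(units, handled))
                )
        else:
            scen.append((p, lead + _default_groups(units, handled)))
    return [(p, g) for p, g in scen if p > 0.0]


def gamete_distribution(k: Karyotype, params: MeiosisParams) -> GameteDistribution:
    """Exact ovum content-class distribution for a supported karyotype."""
    dist: dict = {}
    for p, groups in _scenarios(k, params):
        n = len(groups)
        w = p * 0.5 ** n
        for choice in itertools.product((0, 1), repeat=n):
            content = frozenset(
                itertools.chain.from_iterable(g[c] for g, c in zip(groups, choice))
            )
            dist[content] = dist.get(content, 0.0) + w
    return GameteDistribution(dist)


def pole_partition_distribution(k: Karyotype, params: MeiosisParams) -> dict:
    """Distribution over unordered pole partitions {content_A, content_B}.

    This is the cytological view of the same meiosis: an oocyte scored at
    metaphase I arrest shows both poles, whereas an ovum retains only one.
    """
    dist: dict = {}
    for p, groups in _scenarios(k, params):
        n = len(groups)
        w = p * 0.5 ** n
        for choice in itertools.product((0, 1), repeat=n):
            a = frozenset(itertools.chain.from_iterable(g[c] for g, c in zip(groups, choice)))
            b = frozenset(
                itertools.chain.from_iterable(g[1 - c] for g, c in zip(groups, choice))
            )
            key = frozenset((a, b))
            dist[key] = dist.get(key, 0.0) + w
    return dist


def hs_event_products(k: Karyotype, params: MeiosisParams):
    """The two reciprocal pole contents of the heterologous event, or None.

    For an XXY karyotype with secondary nondisjunction enabled this is
    ({X1, X2}, {Y}); for an active heterolog pair it is the contents of
    the two participating units.  Non-participating units are excluded.
    """
    units = _classify(k)
    hs = _active_hs(units, params)
    if units.x_pair and units.y_copy and params.p_secondary_ndj > 0:
        x1, x2 = units.x_pair
        return frozenset((x1.id, x2.id)), frozenset((units.y_copy.id,))
    if hs is not None:
        return frozenset(hs.side_a), frozenset(hs.side_b)
    return None


# ---------------------------------------------------------------------------
# fertilization, viability, phenotype


@dataclass(frozen=True)
class SpermClass:
    """One tester-male sperm genotype with its frequency."""

    copies: tuple
    prob: float

    def __post_init__(self):
        object.__setattr__(self, "copies", tuple(self.copies))
        _check_prob("sperm class probability", self.prob)


@dataclass(frozen=True)
class Zygote:
    """Element-dose vector plus the copy identities needed for markers."""

    dose: Mapping[str, int]
    ovum: frozenset
    sperm: str

    def __post_init__(self):
        object.__setattr__(self, "dose", dict(self.dose))

    @property
    def sex(self) -> str:
        # X-dose rule: two X's female, one X male (sufficient for these crosses)
        return "female" if self.dose.get("X", 0) >= 2 else "male"


#: (name, predicate on Zygote, survival probability); first match wins
ViabilityRule = tuple


@dataclass(frozen=True)
class ViabilityModel:
    """Ordered first-match survival rules; unmatched zygotes survive."""

    rules: tuple = ()
    v_minute: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        _check_prob("v_minute", self.v_minute)


def survival(z: Zygote, v: ViabilityModel) -> float:
    for _name, pred, prob in v.rules:
        if pred(z):
            return prob
    return 1.0


def default_viability(scope: Iterable[str], v_minute: float = 0.0) -> ViabilityModel:
    """Standard zygotic-survival rules over the elements in *scope*.

    Major-arm aneuploidy, nullo-X, triplo-X and nullo-/tetra-4 are lethal;
    haplo-4 (minute) survives with probability ``v_minute`` (default 0, the
    bookkeeping convention behind the published recovery corrections);
    triplo-4 is fully viable.
    """
    scope = set(scope)
    rules = []
    for arm in MAJOR_ARMS:
        if arm in scope:
            rules.append(
                (f"aneuploid_{arm}", (lambda z, a=arm: z.dose.get(a, 0) != 2), 0.0)
            )
    if "X" in scope:
        rules.append(("nullo_X", lambda z: z.dose.get("X", 0) == 0, 0.0))
        rules.append(("triplo_X", lambda z: z.dose.get("X", 0) >= 3, 0.0))
    if "4" in scope:
        rules.append(("nullo_4", lambda z: z.dose.get("4", 0) == 0, 0.0))
        rules.append(("tetra_4", lambda z: z.dose.get("4", 0) >= 4, 0.0))
        rules.append(("haplo_4_minute", lambda z: z.dose.get("4", 0) == 1, v_minute))
    return ViabilityModel(rules=tuple(rules), v_minute=v_minute)


def permissive_viability() -> ViabilityModel:
    """Every zygote survives; useful for toggling lethality off."""
    return ViabilityModel(rules=(), v_minute=1.0)


@dataclass(frozen=True)
class CrossDesign:
    """A single-female test cross.

    marker_map maps (ovum content, sperm class name) -> phenotype class
    label; class_partition assigns each label to one of ``normal``,
    ``hs_exceptional``, ``other`` or ``unscored``.  recombinant_labels and
    paternal_ndj_labels flag the corresponding subsets of ``other``.
    """

    female: Karyotype
    sperm_classes: Mapping[str, SpermClass]
    marker_map: Mapping[tuple, str]
    class_partition: Mapping[str, str]
    params: MeiosisParams = field(default_factory=MeiosisParams)
    viability: ViabilityModel = field(default_factory=ViabilityModel)
    recombinant_labels: frozenset = frozenset()
    paternal_ndj_labels: frozenset = frozenset()
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sperm_classes", dict(self.sperm_classes))
        object.__setattr__(
            self,
            "marker_map",
            {(frozenset(ov), sp): lab for (ov, sp), lab in dict(self.marker_map).items()},
        )
        object.__setattr__(self, "class_partition", dict(self.class_partition))
        object.__setattr__(self, "recombinant_labels", frozenset(self.recombinant_labels))
        object.__setattr__(self, "paternal_ndj_labels", frozenset(self.paternal_ndj_labels))
        total = sum(s.prob for s in self.sperm_classes.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"sperm class probabilities sum to {total!r}, not 1")
        valid = {"normal", "hs_exceptional", "other", "unscored"}
        for lab, cat in self.class_partition.items():
            if cat not in valid:
                raise ValueError(f"phenotype class {lab!r} assigned to unknown partition {cat!r}")
        for (_ov, sp), lab in self.marker_map.items():
            if sp not in self.sperm_classes:
                raise ValueError(f"marker_map references unknown sperm class {sp!r}")
            if lab not in self.class_partition:
                raise ValueError(f"marker_map label {lab!r} missing from class_partition")

    @property
    def scope(self) -> frozenset:
        els = set()
        for c in self.female.copies:
            els.update(el for el, d in c.elements.items() if d > 0)
        for s in self.sperm_classes.values():
            for c in s.copies:
                els.update(el for el, d in c.elements.items() if d > 0)
        return frozenset(els)


def fertilize(design: CrossDesign, ovum: Iterable[str], sperm: str) -> Zygote:
    """Combine an ovum content class with a named sperm class.

    Zygote dose is the element-wise sum; the recombinant sentinel counts
    as a single structurally normal X.
    """
    ovum = frozenset(ovum)
    dose = {el: 0 for el in design.scope}
    for cid in ovum:
        if cid == REC_ID:
            dose["X"] = dose.get("X", 0) + 1
            continue
        for el, d in design.female.get(cid).elements.items():
            if d:
                dose[el] = dose.get(el, 0) + d
    sc = design.sperm_classes[sperm]
    for c in sc.copies:
        for el, d in c.elements.items():
            if d:
                dose[el] = dose.get(el, 0) + d
    return Zygote(dose=dose, ovum=ovum, sperm=sperm)


def phenotype_class(z: Zygote, design: CrossDesign) -> str:
    try:
        return design.marker_map[(z.ovum, z.sperm)]
    except KeyError:
        raise MarkerMapError(
            f"no phenotype class for ovum {sorted(z.ovum)} x sperm {z.sperm!r} "
            f"in design {design.label!r}"
        ) from None
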