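"""Named presets for every genotype studied.

Each preset bundles the maternal karyotype, meiosis-I parameters set to
the rates measured in that stock, the tester-male cross design (sperm
classes, marker-to-phenotype map, class partition), the viability model,
and prometaphase movement rates.  Estimation of published count tables
only needs the design (for the viability-derived recovery correction);
simulation uses everything.

Genotype shorthand used for preset names:

========================  ====================================================
``c1_monovalent``         C(1)RM, y v / O ; sv[spa-pol]   (attached-X, free 4s)
``c2en_monovalent``       C(2)EN, bw sp / O               (attached-2)
``c4_monovalent``         y w f ; C(4)RM, ci eyR / O      (attached-4)
``c4_inversion``          y w f / In(1)dl-49, v f ; C(4)RM / O
``c4_balancer``           y w f / FM7, y w B ; C(4)RM / O
``xxy``                   y w / y w / y+Y
``fm7_xxy``               FM7, y w B / y w / y+Y
``in_dl49_xxy``           In(1)dl-49, y v f / y w / Y
``c1_c4``                 C(1)RM, y v / O ; C(4)RM, ci eyR / O
``c2l_c2r``               C(2L)RM-P1, b / O ; C(2R)RM-P4, px / O
========================  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    FOUR_UNIT,
    REC_ID,
    XX_UNIT,
    ChromosomeCopy,
    CrossDesign,
    Karyotype,
    MeiosisParams,
    Rearrangement,
    SpermClass,
    default_viability,
    heterolog_q_from_rate,
)

__all__ = ["MovementModel", "Preset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class MovementModel:
    """Prometaphase chromosome-movement rates (cytology only).

    p_out_2d: probability a 2-d mated oocyte has >= 1 chromosome out on
    the spindle; p_compound_out: probability the compound itself is out,
    given any chromosome is out; p_residual_out_4d: fraction of aged-virgin
    oocytes fixed before completing congression.
    """

    p_out_2d: float = 0.6
    p_compound_out: float = 0.5
    p_residual_out_4d: float = 0.0


@dataclass(frozen=True)
class Preset:
    name: str
    karyotype: Karyotype
    params: MeiosisParams
    design: Optional[CrossDesign] = None
    movement: MovementModel = field(default_factory=MovementModel)
    decimals: int = 1          # printed precision of the genetic rate
    correction: str = "derived"  # "derived" from the viability model, or
    #                              "raw" for counts published on a uniform-
    #                              recovery scale (no differential correction)


def _copy(cid, elements, rearr=Rearrangement.NORMAL, markers=(), exchange=True):
    return ChromosomeCopy(
        id=cid,
        elements=elements,
        rearrangement=rearr,
        markers=frozenset(markers),
        exchange_competent=exchange,
    )


# tester-male chromosomes shared across designs
_X_SPERM = _copy("X-paternal", {"X": 1}, markers=("y", "w", "f"))
_Y_SPERM = _copy("y+Y-paternal", {"Y": 1}, Rearrangement.Y_DERIVED, markers=("y+",))
_FOUR_SPERM = _copy("4-paternal", {"4": 1}, markers=("sv-spa-pol",))
_C1YS_SPERM = _copy(
    "C(1;YS)-paternal", {"X": 2, "Y": 1}, Rearrangement.COMPOUND, markers=("v", "f", "B")
)
_C4_SPERM = _copy("C(4)-paternal", {"4": 2}, Rearrangement.COMPOUND, markers=("ci", "eyR"))


def _xxy_preset(name, x2, y_copy, params, movement=MovementModel()):
    """XXY female x (X / y+Y) tester: the secondary-nondisjunction family."""
    x1 = _copy("X-yw", {"X": 1}, markers=("y", "w"))
    female = Karyotype((x1, x2, y_copy), label=name)
    sperm = {
        "X": SpermClass((_X_SPERM,), 0.5),
        "Y": SpermClass((_Y_SPERM,), 0.5),
    }
    mm = {}
    for xi in (x1.id, x2.id, REC_ID):
        kind = "recombinant" if xi == REC_ID else "normal"
        for extra in ((), (y_copy.id,)):
            mm[(frozenset((xi,) + extra), "X")] = f"{kind}_daughter"
            mm[(frozenset((xi,) + extra), "Y")] = f"{kind}_son"
    mm[(frozenset((x1.id, x2.id)), "Y")] = "ndj_daughter"
    mm[(frozenset((y_copy.id,)), "X")] = "ndj_son"
    partition = {
        "normal_daughter": "normal",
        "normal_son": "normal",
        "ndj_daughter": "hs_exceptional",
        "ndj_son": "hs_exceptional",
        "recombinant_daughter": "other",
        "recombinant_son": "other",
    }
    design = CrossDesign(
        female=female,
        sperm_classes=sperm,
        marker_map=mm,
        class_partition=partition,
        params=params,
        viability=default_viability({"X", "Y"}),
        recombinant_labels=frozenset(("recombinant_daughter", "recombinant_son")),
        label=name,
    )
    return Preset(name, female, params, design, movement, decimals=1)


def _c4_family_preset(name, x2, params, movement, decimals=1):
    """X / X' ; C(4)RM / O female x (y w / y+Y ; normal 4s) tester.

    The attached-4 makes half the ova nullo-4; with v_minute = 0 the
    XX-bearing heterologous product is a dead haplo-4 minute class, so the
    derived recovery correction is 4.
    """
    x1 = _copy("X-ywf", {"X": 1}, markers=("y", "w", "f"))
    c4 = _copy("C(4)RM", {"4": 2}, Rearrangement.COMPOUND, markers=("ci", "eyR"))
    female = Karyotype((x1, x2, c4), label=name)
    sperm = {
        "X": SpermClass((_X_SPERM, _FOUR_SPERM), 0.5),
        "Y": SpermClass((_Y_SPERM, _FOUR_SPERM), 0.5),
    }
    mm = {}
    for xi in (x1.id, x2.id, REC_ID):
        kind = "recombinant" if xi == REC_ID else "normal"
        for extra in ((), (c4.id,)):
            mm[(frozenset((xi,) + extra), "X")] = f"{kind}_daughter"
            mm[(frozenset((xi,) + extra), "Y")] = f"{kind}_son"
    # XX <=> C(4) products: the XX ovum gives a haplo-4 (minute) XXY daughter,
    # the C(4) ovum a patroclinous triplo-4 son
    mm[(frozenset((x1.id, x2.id)), "Y")] = "hs_daughter"
    mm[(frozenset((c4.id,)), "X")] = "hs_son"
    partition = {
        "normal_daughter": "normal",
        "normal_son": "normal",
        "hs_daughter": "hs_exceptional",
        "hs_son": "hs_exceptional",
        "recombinant_daughter": "other",
        "recombinant_son": "other",
    }
    design = CrossDesign(
        female=female,
        sperm_classes=sperm,
        marker_map=mm,
        class_partition=partition,
        params=params,
        viability=default_viability({"X", "Y", "4"}),
        recombinant_labels=frozenset(("recombinant_daughter", "recombinant_son")),
        label=name,
    )
    return Preset(name, female, params, design, movement, decimals=decimals)


def _c1_monovalent_preset():
    """C(1)RM / O ; free 4s: the attached-X segregates as a monovalent and
    rarely biorients against the 4-4 bivalent (C(1) <=> 44)."""
    c1 = _copy("C(1)RM", {"X": 2}, Rearrangement.COMPOUND, markers=("y", "v"))
    f1 = _copy("4-sv-1", {"4": 1}, markers=("sv-spa-pol",))
    f2 = _copy("4-sv-2", {"4": 1}, markers=("sv-spa-pol",))
    female = Karyotype((c1, f1, f2), label="c1_monovalent")
    params = MeiosisParams(p_hs={frozenset((FOUR_UNIT, c1.id)): 0.02})
    sperm = {
        "C(1;YS)": SpermClass((_C1YS_SPERM,), 0.5),
        "C(4)": SpermClass((_C4_SPERM,), 0.5),
    }
    mm = {
        # normal pattern: 4s disjoin, C(1) to either pole
        (frozenset((c1.id, f1.id)), "C(4)"): "normal_daughter",
        (frozenset((c1.id, f2.id)), "C(4)"): "normal_daughter",
        (frozenset((f1.id,)), "C(1;YS)"): "minute_daughter",
        (frozenset((f2.id,)), "C(1;YS)"): "minute_daughter",
        # heterologous products: only the C(1)-bearing ovum yields a progeny
        # class identifiable as exceptional; the 4,4 ovum gives a Bar
        # daughter indistinguishable from other paternal-X classes
        (frozenset((c1.id,)), "C(4)"): "hs_daughter",
        (frozenset((f1.id, f2.id)), "C(1;YS)"): "bar_daughter",
    }
    partition = {
        "normal_daughter": "normal",
        "minute_daughter": "normal",
        "hs_daughter": "hs_exceptional",
        "bar_daughter": "other",
    }
    design = CrossDesign(
        female=female,
        sperm_classes=sperm,
        marker_map=mm,
        class_partition=partition,
        params=params,
        viability=default_viability({"X", "Y", "4"}),
        label="c1_monovalent",
    )
    movement = MovementModel(
        p_out_2d=40 / 72, p_compound_out=23 / 40, p_residual_out_4d=9 / 121
    )
    return Preset("c1_monovalent", female, params, design, movement, decimals=0)


def _c2en_preset():
    """C(2)EN / O: cytology only; aneuploid segregants are zygotic-lethal
    with a structurally normal tester, so no genetic assay exists."""
    c2 = _copy("C(2)EN", {"2L": 2, "2R": 2}, Rearrangement.COMPOUND, markers=("bw", "sp"))
    x1 = _copy("X-1", {"X": 1})
    x2 = _copy("X-2", {"X": 1})
    f1 = _copy("4-1", {"4": 1})
    f2 = _copy("4-2", {"4": 1})
    female = Karyotype((c2, x1, x2, f1, f2), label="c2en_monovalent")
    params = MeiosisParams(
        p_nonexchange_X=0.075, p_hs={frozenset((FOUR_UNIT, c2.id)): 0.03}
    )
    movement = MovementModel(
        p_out_2d=60 / 89, p_compound_out=28 / 60, p_residual_out_4d=8 / 65
    )
    return Preset("c2en_monovalent", female, params, None, movement, decimals=0)


def _double_compound_preset(name, comp_a, comp_b, observed_rate, sperm_a, sperm_b):
    """Two compound chromosomes x complementary compound tester.

    Every recovered ovum class loses the same half of sperm genotypes, so
    the published rates are raw ratios (correction = "raw").
    """
    female = Karyotype((comp_a, comp_b), label=name)
    params = MeiosisParams(
        p_hs={frozenset((comp_a.id, comp_b.id)): heterolog_q_from_rate(observed_rate)}
    )
    sperm = {
        sperm_a.id: SpermClass((sperm_a,), 0.5),
        sperm_b.id: SpermClass((sperm_b,), 0.5),
    }
    mm = {
        (frozenset((comp_a.id,)), sperm_b.id): "hs_class_a",
        (frozenset((comp_b.id,)), sperm_a.id): "hs_class_b",
    }
    partition = {"hs_class_a": "hs_exceptional", "hs_class_b": "hs_exceptional"}
    scope = set()
    for c in (comp_a, comp_b, sperm_a, sperm_b):
        scope.update(el for el, d in c.elements.items() if d > 0)
    design = CrossDesign(
        female=female,
        sperm_classes=sperm,
        marker_map=mm,
        class_partition=partition,
        params=params,
        viability=default_viability(scope),
        label=name,
    )
    return Preset(name, female, params, design, MovementModel(), decimals=1, correction="raw")


def _build_registry():
    reg = {}

    reg["c1_monovalent"] = _c1_monovalent_preset()
    reg["c2en_monovalent"] = _c2en_preset()

    reg["c4_monovalent"] = _c4_family_preset(
        "c4_monovalent",
        _copy("X-ywf-2", {"X": 1}, markers=("y", "w", "f")),
        MeiosisParams(p_nonexchange_X=0.075),
        MovementModel(p_out_2d=2 / 74, p_compound_out=1.0, p_residual_out_4d=0.0),
        decimals=0,
    )
    reg["c4_inversion"] = _c4_family_preset(
        "c4_inversion",
        _copy(
            "In(1)dl-49", {"X": 1}, Rearrangement.INVERSION, markers=("v", "f")
        ),
        MeiosisParams(
            p_nonexchange_X=0.95,
            p_hs={frozenset((XX_UNIT, "C(4)RM")): 0.057},
            p_recombinant_interval=0.0015,
        ),
        MovementModel(p_out_2d=7 / 61, p_compound_out=1.0, p_residual_out_4d=2 / 80),
    )
    reg["c4_balancer"] = _c4_family_preset(
        "c4_balancer",
        _copy(
            "FM7", {"X": 1}, Rearrangement.BALANCER, markers=("y", "w", "B"),
            exchange=False,
        ),
        MeiosisParams(p_hs={frozenset((XX_UNIT, "C(4)RM")): 0.075}),
        MovementModel(p_out_2d=8 / 68, p_compound_out=1.0, p_residual_out_4d=2 / 72),
    )

    reg["xxy"] = _xxy_preset(
        "xxy",
        _copy("X-yw-2", {"X": 1}, markers=("y", "w")),
        _copy("y+Y", {"Y": 1}, Rearrangement.Y_DERIVED, markers=("y+",)),
        MeiosisParams(p_nonexchange_X=0.075, p_secondary_ndj=0.5),
    )
    reg["fm7_xxy"] = _xxy_preset(
        "fm7_xxy",
        _copy(
            "FM7", {"X": 1}, Rearrangement.BALANCER, markers=("y", "w", "B"),
            exchange=False,
        ),
        _copy("y+Y", {"Y": 1}, Rearrangement.Y_DERIVED, markers=("y+",)),
        MeiosisParams(p_secondary_ndj=0.614),
    )
    reg["in_dl49_xxy"] = _xxy_preset(
        "in_dl49_xxy",
        _copy(
            "In(1)dl-49", {"X": 1}, Rearrangement.INVERSION, markers=("y", "v", "f")
        ),
        _copy("Y", {"Y": 1}, Rearrangement.Y_DERIVED),
        MeiosisParams(
            p_nonexchange_X=0.95,
            p_secondary_ndj=0.692,
            p_recombinant_interval=0.006,
        ),
    )

    reg["c1_c4"] = _double_compound_preset(
        "c1_c4",
        _copy("C(1)RM", {"X": 2}, Rearrangement.COMPOUND, markers=("y", "v")),
        _copy("C(4)RM", {"4": 2}, Rearrangement.COMPOUND, markers=("ci", "eyR")),
        observed_rate=0.971,
        sperm_a=_C1YS_SPERM,
        sperm_b=_C4_SPERM,
    )
    reg["c2l_c2r"] = _double_compound_preset(
        "c2l_c2r",
        _copy("C(2L)RM", {"2L": 2}, Rearrangement.COMPOUND, markers=("b",)),
        _copy("C(2R)RM", {"2R": 2}, Rearrangement.COMPOUND, markers=("px",)),
        observed_rate=0.99,
        sperm_a=_copy("C(2L)-paternal", {"2L": 2}, Rearrangement.COMPOUND),
        sperm_b=_copy("C(2R)-paternal", {"2R": 2}, Rearrangement.COMPOUND),
    )
    return reg


PRESETS = _build_registry()


def preset_names():
    return sorted(PRESETS)


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown genotype preset {name!r}; available: {', '.join(preset_names())}"
        ) from None


def xxy_design(
    p_secondary_ndj: float,
    p_nonexchange_X: float = 1.0,
    p_recombinant_interval: float = 0.0,
    blocked: bool = True,
) -> CrossDesign:
    """Parameterized XXY / tester design for closed-loop recovery runs.

    ``blocked=True`` gives a balancer-heterozygous female (crossing-over
    impossible, every meiosis nonexchange), the cleanest configuration for
    recovering a true secondary-nondisjunction rate; ``blocked=False``
    keeps both X's exchange-competent so a recombinant interval can be
    simulated alongside.
    """
    if blocked:
        x2 = _copy(
            "FM7", {"X": 1}, Rearrangement.BALANCER, markers=("y", "w", "B"),
            exchange=False,
        )
    else:
        x2 = _copy("X-yw-2", {"X": 1}, markers=("y", "w"))
    params = MeiosisParams(
        p_nonexchange_X=p_nonexchange_X,
        p_secondary_ndj=p_secondary_ndj,
        p_recombinant_interval=p_recombinant_interval,
    )
    y = _copy("y+Y", {"Y": 1}, Rearrangement.Y_DERIVED, markers=("y+",))
    return _xxy_preset("xxy_recovery", x2, y, params).design
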