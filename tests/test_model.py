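"""Gamete-distribution, fertilization and viability model tests."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetseg.model import (
    FOUR_UNIT,
    REC_ID,
    XX_UNIT,
    ChromosomeCopy,
    Karyotype,
    MarkerMapError,
    MeiosisParams,
    Rearrangement,
    UnsupportedKaryotypeError,
    ViabilityModel,
    default_viability,
    fertilize,
    gamete_distribution,
    heterolog_q_from_rate,
    hs_event_products,
    phenotype_class,
    pole_partition_distribution,
    survival,
)
from hetseg.presets import get_preset, xxy_design

import oracles

GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


def _xxy(p_nx=0.5, p2=0.5, r=0.0, blocked=False):
    d = xxy_design(p2, p_nonexchange_X=p_nx, p_recombinant_interval=r, blocked=blocked)
    return d.female, d.params


# ---------------------------------------------------------------------------
# frozen examples


def test_independence_null_is_exact_quarters():
    """Two monovalent compounds with no co-orientation distribute at
    random: both / neither / each single class has probability 1/4."""
    k = get_preset("c1_c4").karyotype
    gd = gamete_distribution(k, MeiosisParams())
    assert len(gd.classes) == 4
    for content, p in gd.items():
        assert p == 0.25  # exact, not approximate


def test_xxy_complete_secondary_ndj_gives_xx_or_y_ova():
    female, _ = _xxy()
    params = MeiosisParams(p_nonexchange_X=1.0, p_secondary_ndj=1.0)
    gd = gamete_distribution(female, params)
    xx = frozenset(c.id for c in female.copies if c.dose("X") == 1)
    y = frozenset(c.id for c in female.copies if c.dose("Y") == 1)
    assert gd.p(xx) == 0.5
    assert gd.p(y) == 0.5
    assert len(gd.classes) == 2


def test_double_compound_single_ovum_rate_matches_parameterization():
    """At the preset co-orientation probability, the chance of exactly one
    compound in the ovum equals the observed 97.1% segregation rate."""
    p = get_preset("c1_c4")
    gd = gamete_distribution(p.karyotype, p.params)
    single = sum(v for k, v in gd.items() if len(k) == 1)
    assert single == pytest.approx(0.971, abs=1e-12)


def test_heterolog_q_from_rate_round_trip():
    assert heterolog_q_from_rate(0.5) == 0.0
    assert heterolog_q_from_rate(1.0) == 1.0
    with pytest.raises(ValueError):
        heterolog_q_from_rate(0.3)


# ---------------------------------------------------------------------------
# brute-force enumeration oracles


@pytest.mark.parametrize("p_nx", GRID)
@pytest.mark.parametrize("p2", GRID)
def test_xxy_family_matches_enumeration(p_nx, p2):
    female, _ = _xxy()
    params = MeiosisParams(p_nonexchange_X=p_nx, p_secondary_ndj=p2)
    x1, x2 = [c.id for c in female.copies if c.dose("X") == 1]
    y = next(c.id for c in female.copies if c.dose("Y") == 1)
    oracles.assert_matches(
        gamete_distribution(female, params),
        oracles.xxy_oracle(x1, x2, y, p_nx, p2),
    )


@pytest.mark.parametrize("r", [0.0, 0.25])
@pytest.mark.parametrize("p2", [0.0, 0.5])
def test_xxy_recombinant_branch_matches_enumeration(r, p2):
    female, _ = _xxy()
    params = MeiosisParams(
        p_nonexchange_X=0.5, p_secondary_ndj=p2, p_recombinant_interval=r
    )
    x1, x2 = [c.id for c in female.copies if c.dose("X") == 1]
    y = next(c.id for c in female.copies if c.dose("Y") == 1)
    oracles.assert_matches(
        gamete_distribution(female, params),
        oracles.xxy_oracle(x1, x2, y, 0.5, p2, r),
    )


@pytest.mark.parametrize("p_nx", GRID)
@pytest.mark.parametrize("q", [0.0, 0.25, 0.75])
def test_attached4_family_matches_enumeration(p_nx, q):
    k = get_preset("c4_monovalent").karyotype
    params = MeiosisParams(
        p_nonexchange_X=p_nx, p_hs={frozenset((XX_UNIT, "C(4)RM")): q}
    )
    x1, x2 = [c.id for c in k.copies if c.dose("X") == 1]
    oracles.assert_matches(
        gamete_distribution(k, params),
        oracles.x_pair_plus_compound_oracle(x1, x2, "C(4)RM", p_nx, q),
    )


@pytest.mark.parametrize("q", GRID)
def test_two_compounds_match_enumeration(q):
    k = get_preset("c1_c4").karyotype
    params = MeiosisParams(p_hs={frozenset(("C(1)RM", "C(4)RM")): q})
    oracles.assert_matches(
        gamete_distribution(k, params),
        oracles.two_compounds_oracle("C(1)RM", "C(4)RM", q),
    )


@pytest.mark.parametrize("q", GRID)
def test_attached_x_vs_four_bivalent_matches_enumeration(q):
    k = get_preset("c1_monovalent").karyotype
    params = MeiosisParams(p_hs={frozenset((FOUR_UNIT, "C(1)RM")): q})
    oracles.assert_matches(
        gamete_distribution(k, params),
        oracles.compound_vs_four_bivalent_oracle("C(1)RM", "4-sv-1", "4-sv-2", q),
    )


@pytest.mark.parametrize("q", [0.0, 0.03, 0.5])
def test_attached2_with_normal_x_matches_enumeration(q):
    k = get_preset("c2en_monovalent").karyotype
    params = MeiosisParams(
        p_nonexchange_X=0.075, p_hs={frozenset((FOUR_UNIT, "C(2)EN")): q}
    )
    oracles.assert_matches(
        gamete_distribution(k, params),
        oracles.c2en_oracle("C(2)EN", "X-1", "X-2", "4-1", "4-2", q),
    )


# ---------------------------------------------------------------------------
# invariants


@given(
    p_nx=st.floats(0, 1),
    p2=st.floats(0, 1),
    q=st.floats(0, 1),
    r=st.floats(0, 0.5),
)
def test_distribution_normalizes_over_parameter_space(p_nx, p2, q, r):
    for name, params in [
        ("xxy", MeiosisParams(p_nonexchange_X=p_nx, p_secondary_ndj=p2,
                              p_recombinant_interval=r)),
        ("c1_c4", MeiosisParams(p_hs={frozenset(("C(1)RM", "C(4)RM")): q})),
        ("c1_monovalent", MeiosisParams(p_hs={frozenset((FOUR_UNIT, "C(1)RM")): q})),
    ]:
        k = get_preset(name).karyotype
        gd = gamete_distribution(k, params)  # constructor checks sum == 1
        assert all(p >= 0 for p in gd.classes.values())


@pytest.mark.parametrize(
    "name,params",
    [
        ("xxy", MeiosisParams(p_nonexchange_X=0.3, p_secondary_ndj=0.7)),
        ("c1_c4", MeiosisParams(p_hs={frozenset(("C(1)RM", "C(4)RM")): 0.9})),
        ("c2en_monovalent", MeiosisParams(p_hs={frozenset((FOUR_UNIT, "C(2)EN")): 0.2})),
        ("c4_balancer", MeiosisParams(p_hs={frozenset((XX_UNIT, "C(4)RM")): 0.4})),
    ],
)
def test_dose_conservation_complementary_classes_equiprobable(name, params):
    """The ovum class and its complement partition the maternal centromere
    set, and pole-choice symmetry makes them equally likely."""
    k = get_preset(name).karyotype
    gd = gamete_distribution(k, params)
    all_ids = k.segregating_ids
    for content, p in gd.items():
        assert content <= all_ids
        assert gd.p(all_ids - content) == pytest.approx(p, abs=1e-12)
    # partitions marginalize consistently
    parts = pole_partition_distribution(k, params)
    assert sum(parts.values()) == pytest.approx(1.0, abs=1e-12)


def test_hs_event_products():
    d = xxy_design(0.5)
    prods = hs_event_products(d.female, d.params)
    assert set(map(frozenset, prods)) == {
        frozenset(("X-yw", "FM7")),
        frozenset(("y+Y",)),
    }
    p = get_preset("c1_c4")
    prods = hs_event_products(p.karyotype, p.params)
    assert set(map(frozenset, prods)) == {
        frozenset(("C(1)RM",)),
        frozenset(("C(4)RM",)),
    }
    assert hs_event_products(p.karyotype, MeiosisParams()) is None


# ---------------------------------------------------------------------------
# unsupported configurations fail loudly


def test_unsupported_karyotypes_raise():
    x = ChromosomeCopy("X", {"X": 1})
    with pytest.raises(UnsupportedKaryotypeError):
        gamete_distribution(Karyotype((x,), "lone-X"), MeiosisParams())
    monos = tuple(
        ChromosomeCopy(f"C{i}", {"2L": 2}, Rearrangement.COMPOUND) for i in range(3)
    )
    with pytest.raises(UnsupportedKaryotypeError):
        gamete_distribution(Karyotype(monos, "three-compounds"), MeiosisParams())


def test_p_hs_referencing_missing_unit_raises():
    k = get_preset("c1_c4").karyotype
    with pytest.raises(UnsupportedKaryotypeError):
        gamete_distribution(
            k, MeiosisParams(p_hs={frozenset((XX_UNIT, "C(1)RM")): 0.5})
        )


def test_recombination_requires_exchange_competent_pair():
    d = xxy_design(0.5, blocked=True)
    params = MeiosisParams(p_secondary_ndj=0.5, p_recombinant_interval=0.1)
    with pytest.raises(UnsupportedKaryotypeError):
        gamete_distribution(d.female, params)


def test_meiosis_params_validation():
    with pytest.raises(ValueError):
        MeiosisParams(p_secondary_ndj=1.5)
    with pytest.raises(ValueError):
        MeiosisParams(p_monovalent_recovery=0.4)
    with pytest.raises(ValueError):
        ChromosomeCopy("bad", {"X": -1})
    with pytest.raises(ValueError):
        ChromosomeCopy("notcomp", {"X": 1}, Rearrangement.COMPOUND)


# ---------------------------------------------------------------------------
# fertilization and viability


def test_fertilize_is_additive_on_doses():
    d = xxy_design(0.5)
    xx = frozenset(("X-yw", "FM7"))
    z = fertilize(d, xx, "Y")
    assert z.dose["X"] == 2 and z.dose["Y"] == 1  # XXY daughter
    assert z.sex == "female"
    z = fertilize(d, frozenset(("y+Y",)), "X")
    assert z.dose["X"] == 1 and z.dose["Y"] == 1
    assert z.sex == "male"
    # recombinant sentinel counts as one normal X
    z = fertilize(d, frozenset((REC_ID,)), "X")
    assert z.dose["X"] == 2


def test_fertilize_compound_doses():
    p = get_preset("c2l_c2r")
    z = fertilize(p.design, frozenset(("C(2L)RM",)), "C(2R)-paternal")
    assert z.dose["2L"] == 2 and z.dose["2R"] == 2
    z = fertilize(p.design, frozenset(), "C(2R)-paternal")
    assert z.dose["2L"] == 0 and z.dose["2R"] == 2


def test_survival_rules():
    d = xxy_design(0.5)
    v = d.viability
    dead = fertilize(d, frozenset(("X-yw", "FM7")), "X")  # triplo-X
    assert survival(dead, v) == 0.0
    ok = fertilize(d, frozenset(("X-yw",)), "Y")
    assert survival(ok, v) == 1.0
    p4 = get_preset("c4_balancer")
    minute = fertilize(p4.design, frozenset(("X-ywf",)), "X")  # haplo-4
    assert survival(minute, p4.design.viability) == 0.0
    assert survival(minute, default_viability({"X", "Y", "4"}, v_minute=0.3)) == 0.3
    triplo4 = fertilize(p4.design, frozenset(("X-ywf", "C(4)RM")), "X")
    assert survival(triplo4, p4.design.viability) == 1.0


def test_survival_first_match_order_independent_for_disjoint_rules():
    base = default_viability({"X", "Y", "4"}, v_minute=0.0)
    d = get_preset("c4_balancer").design
    zygotes = [
        fertilize(d, ov, sp)
        for ov in [
            frozenset(("X-ywf",)),
            frozenset(("X-ywf", "C(4)RM")),
            frozenset(("FM7", "X-ywf")),
            frozenset(("C(4)RM",)),
        ]
        for sp in ("X", "Y")
    ]
    for perm in itertools.permutations(base.rules, len(base.rules)):
        permuted = ViabilityModel(rules=perm, v_minute=base.v_minute)
        for z in zygotes:
            assert survival(z, permuted) == survival(z, base)


def test_phenotype_class_and_mapping_error():
    d = xxy_design(0.5)
    z = fertilize(d, frozenset(("X-yw", "FM7")), "Y")
    assert phenotype_class(z, d) == "ndj_daughter"
    z = fertilize(d, frozenset(("X-yw",)), "Y")
    assert phenotype_class(z, d) == "normal_son"
    bogus = fertilize(d, frozenset(("X-yw", "FM7")), "X")  # lethal, unmapped
    with pytest.raises(MarkerMapError):
        phenotype_class(bogus, d)
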