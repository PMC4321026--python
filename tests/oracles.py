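"""Independent closed-form oracles for the gamete-class distributions.

Each function enumerates the pole assignments of one configuration family
by hand, with exact Fraction arithmetic, following the segregation rules
directly rather than going through the package's scenario engine.  Tests
compare these against :func:`hetseg.gamete_distribution`.
"""

from collections import defaultdict
from fractions import Fraction as F

from hetseg.model import REC_ID


def _acc():
    return defaultdict(F)


def xxy_oracle(x1, x2, y, p_nx, p2, r=F(0)):
    """X/X'/Y female: exchange, secondary-NDJ, and recombinant branches."""
    p_nx, p2, r = F(p_nx), F(p2), F(r)
    d = _acc()
    # recombinant interval: ovum carries a recombinant X; Y random
    d[frozenset((REC_ID,))] += r / 2
    d[frozenset((REC_ID, y))] += r / 2
    # exchange: X's disjoin, Y random
    ex = (1 - r) * (1 - p_nx)
    for xi in (x1, x2):
        d[frozenset((xi,))] += ex / 4
        d[frozenset((xi, y))] += ex / 4
    # nonexchange: XX<=>Y with prob p2, else disjoin with Y random
    non = (1 - r) * p_nx
    d[frozenset((x1, x2))] += non * p2 / 2
    d[frozenset((y,))] += non * p2 / 2
    for xi in (x1, x2):
        d[frozenset((xi,))] += non * (1 - p2) / 4
        d[frozenset((xi, y))] += non * (1 - p2) / 4
    return dict(d)


def x_pair_plus_compound_oracle(x1, x2, comp, p_nx, q, r=F(0)):
    """X/X' female with a monovalent compound (e.g. attached-4):
    XX<=>compound co-orientation is only possible in nonexchange meioses."""
    p_nx, q, r = F(p_nx), F(q), F(r)
    d = _acc()
    d[frozenset((REC_ID,))] += r / 2
    d[frozenset((REC_ID, comp))] += r / 2
    ex = (1 - r) * (1 - p_nx)
    for xi in (x1, x2):
        d[frozenset((xi,))] += ex / 4
        d[frozenset((xi, comp))] += ex / 4
    non = (1 - r) * p_nx
    d[frozenset((x1, x2))] += non * q / 2
    d[frozenset((comp,))] += non * q / 2
    for xi in (x1, x2):
        d[frozenset((xi,))] += non * (1 - q) / 4
        d[frozenset((xi, comp))] += non * (1 - q) / 4
    return dict(d)


def two_compounds_oracle(a, b, q):
    """Two monovalent compounds: biorient with prob q, otherwise each goes
    to either pole independently (q = 0 is the independence null)."""
    q = F(q)
    d = _acc()
    d[frozenset((a,))] += q / 2 + (1 - q) / 4
    d[frozenset((b,))] += q / 2 + (1 - q) / 4
    d[frozenset((a, b))] += (1 - q) / 4
    d[frozenset()] += (1 - q) / 4
    return dict(d)


def compound_vs_four_bivalent_oracle(comp, f1, f2, q):
    """Monovalent compound vs the 4-4 bivalent (e.g. attached-X with free
    4s): with prob q the 4s go together opposite the compound."""
    q = F(q)
    d = _acc()
    d[frozenset((comp,))] += q / 2
    d[frozenset((f1, f2))] += q / 2
    for fi in (f1, f2):
        d[frozenset((comp, fi))] += (1 - q) / 4
        d[frozenset((fi,))] += (1 - q) / 4
    return dict(d)


def c2en_oracle(c2, x1, x2, f1, f2, q):
    """Attached-2 female with normal X's and 4s: the 44<=>C(2) interaction
    is independent of X exchange status, so the X simply disjoins."""
    q = F(q)
    d = _acc()
    for xi in (x1, x2):
        # heterologous: 4s together opposite the C(2)
        d[frozenset((xi, c2))] += q / 4
        d[frozenset((xi, f1, f2))] += q / 4
        # default: 4s disjoin, C(2) random
        for fi in (f1, f2):
            d[frozenset((xi, fi, c2))] += (1 - q) / 8
            d[frozenset((xi, fi))] += (1 - q) / 8
    return dict(d)


def assert_matches(dist, oracle, tol=1e-12):
    """Compare a float-valued GameteDistribution with a Fraction oracle."""
    keys = set(dist.classes) | set(oracle)
    for k in keys:
        got = dist.classes.get(k, 0.0)
        want = float(oracle.get(k, F(0)))
        assert abs(got - want) <= tol, (sorted(k), got, want)
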