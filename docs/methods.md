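# Methods

## The forward model

Female meiosis I is modelled at the reductional level: whole centromeres
move to poles, chromatids are never tracked. A karyotype is a list of
chromosome copies, each an integer dose vector over the elements
{X, Y, 2L, 2R, 3L, 3R, 4}. Copies are classified into segregation units —
an X pair (two single-X copies, possibly an inversion or balancer
heterozygote), one free Y, a 4-4 bivalent, and up to two monovalents
(compounds, or a lone free 4). Fully balanced bivalents that always
deliver one member per ovum (the major autosomes in most of these
genotypes) are left implicit and fall outside the viability model's
scope. Anything else raises an unsupported-configuration error rather
than guessing.

Per meiosis the model enumerates a small mixture of pole-assignment
scenarios; within a scenario each group (a disjoining pair, a co-oriented
heterolog couple, a random monovalent) independently flips which side it
sends to the ovum pole. Class probabilities are therefore exact sums of
dyadic terms, and every ovum class has a complement class of equal
probability (pole-choice symmetry), which the tests exercise as a dose
conservation invariant.

### Branch structure and parameters

| parameter | meaning | default |
|---|---|---|
| `p_nonexchange_X` | spontaneous failure of X crossing-over | genotype preset (0.075 for structurally normal X's, i.e. the 5–10% range; 0.95 for the large inversion heterozygote; forced to 1 for balancers) |
| `p_secondary_ndj` | P(XX ⇔ Y &#124; nonexchange X's, Y present) | genotype preset |
| `p_hs[{u, v}]` | co-orientation probability of heterolog pair (u, v) | genotype preset |
| `p_recombinant_interval` | P(ovum recombinant in the scored X interval) = map distance / 100 | 0 |
| `p_monovalent_recovery` | ovum inclusion of a lone monovalent | fixed ½ |
| `v_minute` | survival of haplo-4 zygotes | 0 |

Exchange dissolves heterologous associations: the XX ⇔ Y and XX ⇔
compound patterns are only reachable in the nonexchange branch. The
single scored recombination interval (v–f) is collapsed into a
per-meiosis probability that the ovum carries a recombinant X; no
interference or double-crossover classes exist, because only one map
distance is ever estimated.

**Heterolog fallback.** When a heterolog pair fails to co-orient
(probability 1 − q) the participants orient independently, so for two
monovalents the observed opposite-pole rate is R = q + (1 − q)/2 and
q = 2R − 1 (`heterolog_q_from_rate`). This choice makes q = 0 reduce
exactly to the independence null (¼, ¼, ¼, ¼), which is the natural
meaning of "no interaction"; a fallback in which the pair stayed joined
at one pole would make independence unreachable. Preset q values are
back-computed from the measured rates (e.g. 0.942 for the attached-X /
attached-4 pair, whose measured single-compound rate is 97.1%). For a
compound facing a *bivalent* (e.g. C(1) vs the 4-4 pair) the default
branch disjoins the bivalent, so there the heterologous configuration
arises only from the co-orientation branch and q equals the observed
rate directly.

### Viability and phenotype

Survival is an ordered first-match rule list over the zygote dose
vector: major-arm dose ≠ 2, nullo-X, triplo-X, nullo-4 and dose-≥4-of-4
are lethal; haplo-4 survives with probability `v_minute`; triplo-4 is
fully viable; anything unmatched survives. Triplo-4 viability is not
directly measured in these crosses; setting it to 1 is what the
published quadrupling convention implicitly assumes, and it is
configurable. Sex is an X-dose rule (2 = female), sufficient for every
cross modelled; XYY and maternal-Y-bearing XXY zygotes are viable and
phenotypically merge into the normal classes, and YY ova never meet a
viable fate, so no X:A machinery is needed.

Phenotype classes are a finite map from (ovum content, sperm class) to a
label carrying the normal / exceptional / other partition; standard
marker dominance (Bar dominant; y, w, v, f recessive) is baked into the
preset maps rather than re-derived per zygote.

## The recovery correction

The heterologous event produces two reciprocal ovum classes. The
correction factor for surviving exceptional counts is derived from the
viability model and the marker map, never hard-coded:

* ×2 if exactly one of the two products yields any survivor scorable
  *as exceptional* (e.g. the XX-bearing product of the attached-4
  crosses is a haplo-4 minute class, lost when `v_minute` = 0);
* ×round(1/s̄) where s̄ is the mean surviving-sperm fraction of the
  recoverable products (½ when half the sperm genotypes are lethal to
  them, as in all the XXY crosses).

This yields 2 for XXY crosses, 4 for the attached-4 family, and the
toggles behave as the derivation predicts: restoring minute viability
(`v_minute` = 1) turns the 4 into a 2, and a design with no lethality at
all gives 1.

The compound × compound progeny data (attached-X/attached-4 and
C(2L)/C(2R)) originate from earlier studies whose testers were themselves
compound-bearing males; there *every* recovered ovum class loses the
same fraction of sperm genotypes, a uniform loss that cancels from any
ratio of counts. Those fixtures are marked `correction = raw` (factor 1),
which is the convention that reproduces their published rates; running
the differential derivation on such a design would wrongly double-count
a loss shared by the denominator classes.

The derivation quantifies losses *relative to the identifiable
exceptional classes only*; it deliberately does not renormalize by
normal-class recovery. For the XXY family the normal classes are fully
recovered, so the corrected estimator is exactly consistent: if p is the
true heterologous rate, the expected corrected estimate equals p, which
is why the closed-loop recovery experiments use that family. For the
attached-4 family the convention additionally assumes that minute
*normal-class* progeny are scored with the normals (their phenotypes are
not distinguishable), an identifiability asymmetry the simulator's
all-or-nothing `v_minute` cannot reproduce; simulating that family with
`v_minute = 0` and quadrupling therefore overestimates the true q by
about a factor (1 + q)/2q⁻¹ — a documented limitation, not a target of
the recovery tests.

## Estimators and intervals

* Cytological configuration rates use the denominator `single_mass +
  one_plus_out`; the heterologous-configuration count is a subset of the
  scored oocytes and is never added to the denominator. This is the
  convention under which every published cytological percentage is
  reproduced from its counts.
* The corrected genetic rate is `f·H / (N + f·H + (other − paternal
  NDJ))`: progeny from paternal nondisjunction are not products of the
  female meiosis under study; maternal recombinants stay in the
  denominator uncorrected (no correction for them is derivable, and the
  published arithmetic applies none).
* Map distance: `100·R / (N + f·H + R)` cM, recombinant counts
  uncorrected. On the packaged counts this gives 0.6 cM for v–f; of the
  candidate conventions (± paternal-NDJ progeny, ± doubling), only this
  one reproduces that value.
* Rounding is half-away-from-zero at the printed precision, computed in
  exact rational arithmetic so no reported value depends on binary-float
  tie behaviour.
* Confidence intervals are Wilson score intervals. For corrected rates
  the interval is computed on the observed exceptional proportion —
  which *is* binomial given the scored total — and mapped through the
  monotone correction g(π) = f·π / (1 + (f−1)·π). Computing Wilson
  directly on the inflated corrected counts would pretend the sample is
  larger than it is and undercover (measurably so at rates near 65%);
  the transformed interval inherits exact Wilson coverage.
* The cytology-vs-genetics comparison is a two-sided Fisher exact test
  on the 2×2 table of scored oocytes vs corrected progeny counts, plus a
  Wilson-overlap flag. An exact test is appropriate because several
  exceptional counts are single digits. The attached-4 monovalent stock
  is excluded from the comparison set: its two observed exceptional
  configurations are autosomal malorientations whose products cannot
  survive, so the comparable genetic expectation is zero by
  construction, not by segregation.

## The simulator

`simulate_cross` draws meioses from the exact gamete distribution, a
sperm class, a survival Bernoulli and a phenotype label, accumulating
until the requested number of *surviving* progeny — matching how vials
are scored — using chunked rejection sampling from one seeded NumPy
generator (identical spec + seed ⇒ identical tables; the attempted-zygote
count is retained so the discarded fraction can be checked against the
analytic loss). `simulate_oocytes` draws each oocyte's orientation from
the same pole-partition distribution that drives segregation — the
model's central assumption is that orientation at metaphase I arrest and
segregation are the same draw — and classifies heterologous
configurations from the partition, so a monovalent pair that lands on
opposite poles "by chance" is counted as bioriented, exactly as a FISH
image would be scored.

Prometaphase movement (chromosomes out on the spindle at the 2-d mated
stage, and the residual not-yet-congressed fraction at the 4-d virgin
stage) has no mechanistic model here; the movement probabilities are free
parameters with per-genotype defaults calibrated once to the observed
2-d columns, and movement is assumed independent of eventual orientation
(no per-oocyte correlation is published). The simulator does not emulate:
fecundity differences between genotypes, the rare "other" cytological
classes (split autosome masses, transient join-and-reorient figures),
chromatid-level recombination, or paternal nondisjunction in the tester.
Passing recovery tests therefore demonstrate estimator correctness under
the model's segregation and viability structure, not under every
artefact of real scoring.

## Problem sizes and numerical conventions

The closed-loop recovery experiment uses exchange-blocked XXY designs at
true rates {2%, 65%, 97%}, 5000 surviving progeny per replicate. The
acceptance script runs 200 replicates per rate; the test suite runs 2000
and additionally computes the procedure's *exact* coverage by summing
the binomial law of the scored exceptional count, because an empirical
coverage estimated from R replicates carries Monte-Carlo noise of
√(0.95·0.05/R) (±1.5 pp at R = 200) that is not a property of the
estimator. Map-distance recovery simulates a 10 cM interval at 20 000
progeny. Probabilities inside the gamete engine are plain doubles; the
enumeration is exact for dyadic inputs and the test oracles use rational
arithmetic throughout. All counts-to-percentages conversions go through
`fractions.Fraction`.

## Known limitations

* The doubled secondary-NDJ rate for the balancer XXY stock computes to
  61.4% at one decimal (2154/3510); the originating study quoted 61.3%,
  a sub-rounding discrepancy in third-party data that this package does
  not chase.
* Only the configuration families occurring in the studied genotypes are
  supported (one X pair, one Y, one 4-4 bivalent, ≤ 2 monovalents, one
  active heterolog interaction); everything else fails loudly.
* `v_minute` is a single number applied to all haplo-4 zygotes; the
  identifiability asymmetry between minute normals and minute
  exceptionals discussed above is encoded in the marker maps, not in
  viability.
* Oocyte "other configuration" classes are carried through I/O and
  estimation but never generated by the simulator.
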