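# hetseg

Heterologous segregation and secondary nondisjunction in *Drosophila
melanogaster* female meiosis I: an exact forward model of gamete
formation for aberrant karyotypes, the viability-corrected rate
estimators used on progeny counts, and a seeded Monte-Carlo simulator
that closes the loop between the two.

## The problem

Most chromosomes segregate at meiosis I because crossing-over locks
homologs together. But a genome can carry chromosomes with **no**
homolog — compound chromosomes such as *C(1)RM* (two attached X's) or
*C(4)RM* — or with **too many** potential partners, as in *XXY* females.
These configurations still complete meiosis, with characteristic
non-Mendelian patterns:

* **Heterologous segregation (HS):** two non-homologous compounds
  co-orient and move to opposite poles far more often than the 50%
  expected under independence (e.g. ~97% of ova from *C(1)RM; C(4)RM*
  females carry exactly one compound).
* **Secondary nondisjunction:** in *XXY* females whose X's failed to
  cross over, both X's segregate away from the Y.

Measuring these rates genetically is complicated by zygotic lethality:
entire exceptional classes die of aneuploidy (wrong sperm genotype,
haplo-4 "minute" zygotes), so surviving exceptional progeny must be
multiplied by a recovery correction before a meiotic rate can be quoted.
This package is for geneticists who need those corrected rates — with
honest confidence intervals — from progeny-count and fixed-oocyte count
tables, and who want the whole estimation chain validated by parameter
recovery against a forward simulator.

## Model and statistics

A maternal karyotype is decomposed into segregation units: an X bivalent,
a free Y, the 4-4 bivalent, and monovalents (compounds). Per meiosis:

* an exchange X bivalent disjoins (homologs to opposite poles);
* nonexchange X's with a Y undergo the *XX ⇔ Y* pattern with probability
  `p_secondary_ndj`, otherwise the X's disjoin and the Y assorts at random;
* a heterolog pair co-orients to opposite poles with probability *q*,
  otherwise the participants orient independently; for two monovalents
  the observed opposite-pole rate is therefore *R = q + (1 − q)/2*
  (so *q* = 0 recovers the independence null: ¼ both, ¼ neither, ¼ + ¼
  single);
* a lone monovalent enters the ovum with probability exactly ½.

The class probabilities are computed analytically (exact enumeration of
pole assignments), not sampled. Fertilization adds element doses;
survival is an ordered first-match rule list (major-arm aneuploidy,
nullo/triplo-X, nullo/tetra-4 lethal; haplo-4 minute survives with
probability `v_minute`, default 0).

The corrected exceptional rate from a progeny table with `normal`,
`hs_exceptional` and `other` counts is

```
rate = f·H / (N + f·H + (other − paternal NDJ)) × 100%
```

where the integer factor *f* is **derived from the viability model**: ×2
when only one of the two reciprocal heterologous products yields a
scorable survivor, ×2 again per factor-of-two loss of the surviving
product to incompatible sperm genotypes (f = 2 for *XXY* crosses, 4 for
the attached-4 crosses, 1 for compound×compound crosses scored on a
uniform-recovery scale). Confidence intervals are Wilson score intervals
on the observed (binomial) exceptional proportion mapped through the
monotone correction. Map distance is `100·R / (N + f·H + R)` cM.
Cytology vs. genetics concordance is a two-sided Fisher exact test.

## Worked example

The packaged fixtures hold the raw counts of the two published data
tables; `hetseg estimate` recomputes every rate:

```
$ hetseg estimate
# monovalent-compound genotypes
     genotype  pct_one_plus_out_2d  pct_compound_out_2d  pct_single_mass_4d  pct_hs_cytology  correction_factor  pct_hs_genetic
c1_monovalent                 56.0                 32.0                93.0              2.0                4.0             2.0
  c4_balancer                 12.0                 12.0                97.0              7.0                4.0             7.5
...
# multiple-heterolog genotypes
   genotype  pct_hs_orientation  correction_factor  pct_hs_genetic  map_distance_cM
in_dl49_xxy                67.0                  2            65.4              0.6
      c1_c4                96.0                  1            97.1              NaN
```

Reading: in *FM7 / y w f; C(4)RM/Ø* females (`c4_balancer`) the
heterologous *XX ⇔ C(4)* configuration is seen in 7% of metaphase-arrest
oocytes, and the genetic rate from 25 surviving exceptional progeny among
1232 normals, quadrupled because the reciprocal minute class is lost and
half the survivors meet a lethal sperm, is 100/1333 = 7.5% — cytology and
genetics agree. The same arithmetic in the library:

```python
>>> from hetseg import ProgenyCountTable, genetic_hs_rate, correction_factor, get_preset
>>> design = get_preset("c4_balancer").design
>>> f = correction_factor(design)          # 4, derived from the viability model
>>> est = genetic_hs_rate(ProgenyCountTable(normal=1232, hs_exceptional=25, other=1), f)
>>> est.point, (round(est.ci_low, 1), round(est.ci_high, 1))
(7.5, (5.2, 10.7))
```

Closed-loop validation — simulate crosses at a known secondary-NDJ rate
and recover it:

```
$ hetseg recover -p 0.65 --replicates 50 -n 2000 --seed 3
 true_rate_pct  mean_estimate_pct  bias_pct  coverage
          65.0          64.962719 -0.037281      0.94
```

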