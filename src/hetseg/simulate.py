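"""Seeded Monte-Carlo generation of oocyte-configuration and progeny count
tables.

The simulator draws individual meioses from the exact gamete model, so
every count table it emits has the statistical structure the estimators
assume: oocyte orientation classes are drawn from the same pole-partition
distribution that determines segregation (orientation at metaphase I
arrest predicts the segregation rate), and progeny are accumulated one
zygote at a time -- ovum class, sperm class, survival Bernoulli, phenotype
-- until the requested number of *survivors* is reached, which is how
flies are actually scored.

A single NumPy generator seeded from the spec drives every draw, so an
identical spec + seed reproduces identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import (
    NoRecoverableClassError,
    OocyteConfigCounts,
    ProgenyCountTable,
    correction_factor,
    genetic_hs_rate,
)
from .model import (
    CrossDesign,
    Karyotype,
    MarkerMapError,
    MeiosisParams,
    ViabilityModel,
    fertilize,
    gamete_distribution,
    hs_event_products,
    phenotype_class,
    pole_partition_distribution,
    survival,
)
from .presets import MovementModel, Preset, xxy_design

__all__ = [
    "SimulationSpec",
    "SimStats",
    "simulate_oocytes",
    "simulate_cross",
    "recovery_report",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything one simulation run needs.

    ``stage_mix`` is the probability that a sampled oocyte comes from the
    2-d mated (prometaphase-enriched) prep rather than the 4-d virgin
    (metaphase-arrest) prep.  ``params`` and ``viability`` default to the
    design's own; a karyotype alone suffices for oocyte simulation.
    """

    karyotype: Karyotype
    params: MeiosisParams
    design: Optional[CrossDesign] = None
    viability: Optional[ViabilityModel] = None
    n_oocytes: int = 0
    n_progeny_target: int = 0
    stage_mix: float = 0.5
    movement: MovementModel = field(default_factory=MovementModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_oocytes < 0 or self.n_progeny_target < 0:
            raise ValueError("counts must be nonnegative")
        if not (0.0 <= self.stage_mix <= 1.0):
            raise ValueError("stage_mix must lie in [0, 1]")

    @classmethod
    def from_preset(cls, preset: Preset, **kw) -> "SimulationSpec":
        return cls(
            karyotype=preset.karyotype,
            params=preset.params,
            design=preset.design,
            movement=preset.movement,
            **kw,
        )

    @classmethod
    def from_design(cls, design: CrossDesign, **kw) -> "SimulationSpec":
        return cls(karyotype=design.female, params=design.params, design=design, **kw)


@dataclass(frozen=True)
class SimStats:
    """Bookkeeping from a progeny run: zygotes attempted vs. recovered."""

    attempts: int
    survivors: int
    expected_survival: float  # analytic per-zygote survival probability

    @property
    def discarded_fraction(self) -> float:
        return 1.0 - self.survivors / self.attempts if self.attempts else 0.0


def _is_hs_partition(partition, products) -> bool:
    if products is None:
        return False
    a, b = products
    pa, pb = tuple(partition) if len(partition) == 2 else (next(iter(partition)),) * 2
    return (a <= pa and b <= pb) or (a <= pb and b <= pa)


def simulate_oocytes(spec: SimulationSpec):
    """Draw fixed-oocyte configuration counts for both cytological preps.

    Returns a dict with keys ``prometaphase_2d`` and ``metaphase_4d``.
    Orientation (hence the heterologous configuration) is drawn per oocyte
    from the pole-partition distribution of the gamete model; prometaphase
    movement and residual (not yet congressed) figures follow the movement
    model, independent of eventual orientation.
    """
    rng = np.random.default_rng(spec.seed)
    parts = pole_partition_distribution(spec.karyotype, spec.params)
    keys = list(parts)
    probs = np.array([parts[k] for k in keys])
    probs = probs / probs.sum()
    products = hs_event_products(spec.karyotype, spec.params)
    hs_flag = np.array([_is_hs_partition(k, products) for k in keys])

    n2 = int(rng.binomial(spec.n_oocytes, spec.stage_mix)) if spec.n_oocytes else 0
    n4 = spec.n_oocytes - n2
    mv = spec.movement

    out2 = int(rng.binomial(n2, mv.p_out_2d)) if n2 else 0
    comp2 = int(rng.binomial(out2, mv.p_compound_out)) if out2 else 0
    prometa = OocyteConfigCounts(
        stage="prometaphase_2d",
        single_mass=n2 - out2,
        one_plus_out=out2,
        compound_out=comp2,
    )

    out4 = int(rng.binomial(n4, mv.p_residual_out_4d)) if n4 else 0
    if n4:
        drawn = rng.choice(len(keys), size=n4, p=probs)
        hs4 = int(hs_flag[drawn].sum())
    else:
        hs4 = 0
    meta = OocyteConfigCounts(
        stage="metaphase_4d",
        single_mass=n4 - out4,
        one_plus_out=out4,
        hs_config=hs4,
    )
    return {"prometaphase_2d": prometa, "metaphase_4d": meta}


def _zygote_tables(design: CrossDesign, params: MeiosisParams, v: ViabilityModel):
    """Vectorizable lookup tables over (ovum class, sperm class)."""
    gd = gamete_distribution(design.female, params)
    ova = list(gd.classes)
    p_ova = np.array([gd.classes[o] for o in ova])
    sperm = list(design.sperm_classes)
    p_sperm = np.array([design.sperm_classes[s].prob for s in sperm])

    labels = sorted(design.class_partition)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    surv = np.zeros((len(ova), len(sperm)))
    lab = np.full((len(ova), len(sperm)), -1, dtype=int)
    for i, o in enumerate(ova):
        for j, s in enumerate(sperm):
            z = fertilize(design, o, s)
            sv = survival(z, v)
            surv[i, j] = sv
            if sv > 0.0:
                lab[i, j] = lab_idx[phenotype_class(z, design)]
    return ova, p_ova, sperm, p_sperm, labels, surv, lab


def simulate_cross(spec: SimulationSpec, with_stats: bool = False):
    """Simulate a single-female test cross until ``n_progeny_target``
    surviving progeny have been scored.

    Raises :class:`MarkerMapError` if any viable zygote lacks a phenotype
    mapping, and :class:`NoRecoverableClassError` if no zygote of the
    design can survive.
    """
    if spec.design is None:
        raise ValueError("progeny simulation requires a cross design")
    design = spec.design
    params = spec.params or design.params
    v = spec.viability or design.viability
    ova, p_ova, sperm, p_sperm, labels, surv, lab = _zygote_tables(design, params, v)

    joint = np.outer(p_ova, p_sperm)
    expected_survival = float((joint * surv).sum())
    if expected_survival <= 0.0:
        raise NoRecoverableClassError(
            f"design {design.label!r}: every zygote class is inviable"
        )

    rng = np.random.default_rng(spec.seed)
    target = spec.n_progeny_target
    label_counts = np.zeros(len(labels), dtype=int)
    attempts = 0
    got = 0
    # chunked rejection sampling; zygotes are iid so chunking does not
    # change the distribution of the first `target` survivors
    while got < target:
        need = target - got
        chunk = max(1024, int(1.6 * need / expected_survival))
        oi = rng.choice(len(ova), size=chunk, p=p_ova)
        sj = rng.choice(len(sperm), size=chunk, p=p_sperm)
        u = rng.random(chunk)
        alive = u < surv[oi, sj]
        idx = np.flatnonzero(alive)
        if idx.size > need:
            last = idx[need - 1]
            idx = idx[:need]
            attempts += int(last) + 1
        else:
            attempts += chunk
        got += idx.size
        np.add.at(label_counts, lab[oi[idx], sj[idx]], 1)

    cats = {labels[i]: design.class_partition[labels[i]] for i in range(len(labels))}
    tally = dict(zip(labels, label_counts.tolist()))
    normal = sum(n for l, n in tally.items() if cats[l] == "normal")
    hs = sum(n for l, n in tally.items() if cats[l] == "hs_exceptional")
    other = sum(n for l, n in tally.items() if cats[l] == "other")
    rec = sum(n for l, n in tally.items() if l in design.recombinant_labels)
    pndj = sum(n for l, n in tally.items() if l in design.paternal_ndj_labels)
    table = ProgenyCountTable(
        normal=normal,
        hs_exceptional=hs,
        other=other,
        recombinant=rec,
        paternal_ndj=pndj,
    )
    if with_stats:
        return table, SimStats(
            attempts=attempts, survivors=target, expected_survival=expected_survival
        )
    return table


def expected_class_probabilities(
    design: CrossDesign,
    params: Optional[MeiosisParams] = None,
    v: Optional[ViabilityModel] = None,
) -> dict:
    """Analytic per-attempt probability of each surviving phenotype class
    (the enumeration the rejection sampler is checked against)."""
    params = params or design.params
    v = v or design.viability
    ova, p_ova, sperm, p_sperm, labels, surv, lab = _zygote_tables(design, params, v)
    out = {l: 0.0 for l in labels}
    for i in range(len(ova)):
        for j in range(len(sperm)):
            if lab[i, j] >= 0:
                out[labels[lab[i, j]]] += p_ova[i] * p_sperm[j] * surv[i, j]
    return out


def recovery_report(
    true_rates: Sequence[float],
    n_replicates: int = 200,
    n_progeny: int = 5000,
    seed: int = 0,
    conf: float = 0.95,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-loop parameter recovery for the corrected secondary-NDJ rate.

    For each true rate p, simulates ``n_replicates`` exchange-blocked XXY
    crosses of ``n_progeny`` surviving progeny each, estimates the
    viability-corrected rate with its Wilson interval, and reports bias
    and interval coverage.  Returns (per-replicate table, summary).
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for p in true_rates:
        design = xxy_design(p_secondary_ndj=p)
        factor = correction_factor(design)
        children = ss.spawn(n_replicates)
        for rep, child in enumerate(children):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            spec = SimulationSpec.from_design(
                design, n_progeny_target=n_progeny, seed=rep_seed
            )
            table = simulate_cross(spec)
            est = genetic_hs_rate(table, factor, decimals=6)
            rows.append(
                {
                    "true_rate_pct": 100.0 * p,
                    "replicate": rep,
                    "estimate_pct": 100.0 * est.numerator / est.denominator,
                    "ci_low_pct": est.ci_low,
                    "ci_high_pct": est.ci_high,
                    "covered": bool(est.ci_low <= 100.0 * p <= est.ci_high),
                }
            )
    detail = pd.DataFrame(
        rows,
        columns=[
            "true_rate_pct",
            "replicate",
            "estimate_pct",
            "ci_low_pct",
            "ci_high_pct",
            "covered",
        ],
    )
    if detail.empty:
        summary = pd.DataFrame(
            columns=["true_rate_pct", "mean_estimate_pct", "bias_pct", "coverage"]
        )
        return detail, summary
    g = detail.groupby("true_rate_pct")
    summary = pd.DataFrame(
        {
            "mean_estimate_pct": g["estimate_pct"].mean(),
            "bias_pct": g["estimate_pct"].mean() - g["true_rate_pct"].first(),
            "coverage": g["covered"].mean(),
        }
    ).reset_index()
    return detail, summary
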