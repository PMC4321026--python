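"""Assembly of the published count fixtures into estimate tables.

Every number these reports emit is recomputed at call time from raw
counts: cytological configuration rates, viability-corrected genetic
rates with their derived correction factors, the v--f map distance, and
the cytology-vs-genetics concordance tests.
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from . import io
from .estimators import (
    ComparisonResult,
    RateEstimate,
    compare_rates,
    correction_factor,
    cytological_rates,
    genetic_hs_rate,
    map_distance,
    orientation_hs_rate,
)
from .presets import get_preset

__all__ = [
    "genetic_factor",
    "table1_report",
    "table2_report",
    "concordance_report",
    "CONCORDANCE_GENOTYPES",
]

#: genotypes whose scored heterologous configurations correspond to
#: recoverable progeny classes, so cytology and genetics are comparable.
#: The attached-4 monovalent stock is excluded: its observed exceptional
#: configurations are autosomal malorientations that are zygotic-lethal,
#: and the attached-2 stock has no genetic assay at all.
CONCORDANCE_GENOTYPES = (
    "c1_monovalent",
    "c4_inversion",
    "c4_balancer",
    "xxy",
    "fm7_xxy",
    "in_dl49_xxy",
    "c1_c4",
    "c2l_c2r",
)


def genetic_factor(genotype: str, record: io.ProgenyRecord) -> int:
    """Recovery correction for a fixture row: derived from the genotype's
    viability model, or 1 for counts published on a uniform-recovery
    scale."""
    if record.correction == "raw":
        return 1
    return correction_factor(get_preset(genotype).design)


def genetic_estimate(genotype: str, record: io.ProgenyRecord) -> RateEstimate:
    return genetic_hs_rate(
        record.table, genetic_factor(genotype, record), record.decimals
    )


def table1_report() -> pd.DataFrame:
    """Monovalent-compound genotypes: movement and configuration rates at
    both stages plus the corrected genetic rate where a cross exists."""
    fx = io.table1()
    rows = []
    genotypes = sorted({g for g, _s in fx.cytology})
    for g in genotypes:
        row: Dict[str, Optional[float]] = {"genotype": g}
        pro = fx.cytology.get((g, "prometaphase_2d"))
        if pro is not None:
            rates = cytological_rates(pro)
            row["pct_one_plus_out_2d"] = rates.pct_one_plus_out.point
            row["pct_compound_out_2d"] = rates.pct_compound_out.point
        meta = fx.cytology.get((g, "metaphase_4d"))
        if meta is not None:
            rates = cytological_rates(meta)
            row["pct_single_mass_4d"] = rates.pct_single_mass.point
            row["pct_hs_cytology"] = rates.pct_hs.point
            row["n_oocytes_4d"] = meta.total
        rec = fx.progeny.get(g)
        if rec is not None:
            est = genetic_estimate(g, rec)
            row["correction_factor"] = est.correction_applied
            row["pct_hs_genetic"] = est.point
            row["genetic_numerator"] = est.numerator
            row["genetic_denominator"] = est.denominator
        rows.append(row)
    return pd.DataFrame(rows)


def table2_report() -> pd.DataFrame:
    """Multiple-heterolog genotypes: metaphase orientation rate vs the
    corrected genetic segregation rate, plus the v--f map distance where
    recombinants were scored."""
    fx = io.table2()
    rows = []
    for g, orient in fx.orientation.items():
        est_c = orientation_hs_rate(orient.normal, orient.hs, orient.other)
        row = {
            "genotype": g,
            "pct_hs_orientation": est_c.point,
            "n_oocytes": orient.total,
        }
        rec = fx.progeny.get(g)
        if rec is not None:
            est = genetic_estimate(g, rec)
            row["correction_factor"] = est.correction_applied
            row["pct_hs_genetic"] = est.point
            row["genetic_numerator"] = est.numerator
            row["genetic_denominator"] = est.denominator
            if rec.table.recombinant:
                row["map_distance_cM"] = map_distance(
                    rec.table, est.correction_applied
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _concordance_pair(genotype: str):
    """(cytological k, n) and corrected genetic (numerator, denominator)."""
    t1 = io.table1()
    t2 = io.table2()
    if genotype in t2.orientation:
        o = t2.orientation[genotype]
        cyt = (o.hs, o.total)
        rec = t2.progeny[genotype]
    else:
        c = t1.cytology[(genotype, "metaphase_4d")]
        cyt = (c.hs_config, c.total)
        rec = t1.progeny[genotype]
    est = genetic_estimate(genotype, rec)
    return cyt, (est.numerator, est.denominator)


def concordance_report(alpha: float = 0.05) -> pd.DataFrame:
    """Fisher-exact cytology-vs-genetics comparison per genotype.

    The heterologous biorientation rate at metaphase I arrest is compared
    with the corrected genetic segregation rate; agreement (no significant
    difference) is the expected outcome if orientation at arrest predicts
    segregation and the genetic exceptions are not a viability artifact.
    """
    rows = []
    for g in CONCORDANCE_GENOTYPES:
        cyt, gen = _concordance_pair(g)
        res: ComparisonResult = compare_rates(cyt, gen, alpha=alpha)
        rows.append(
            {
                "genotype": g,
                "cyt_k": cyt[0],
                "cyt_n": cyt[1],
                "gen_k": gen[0],
                "gen_n": gen[1],
                "fisher_p": res.p_value,
                "rate_difference_pct": res.rate_difference,
                "ci_overlap": res.ci_overlap,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
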