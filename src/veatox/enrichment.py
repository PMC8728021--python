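"""Variant enrichment analysis (VEA): per-patient pathway burden tests.

For each patient and each pathway the patient has touched with at least one
tier-qualifying variant, a 2x2 table is formed:

====================  =========  ===========
                      patient    reference
====================  =========  ===========
variants in pathway   a          c
variants outside      b          d
====================  =========  ===========

and tested with Fisher's exact test, one-sided by default (alternative
``greater``: the patient's in-pathway proportion exceeds the reference's,
i.e. the upper hypergeometric tail), because the question is an *increased*
pathway variant burden.  P-values are adjusted with Benjamini-Hochberg FDR,
by default across the tested pathways of each patient separately; adjusted
values below ``alpha`` (default 0.05) are flagged significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathways import PathwayDB, ReferenceCounts
from .variants import AnnotatedVariant, Tier, TierConfig, qualifying_variants

Alternative = Literal["greater", "two-sided"]
FdrScope = Literal["per_patient", "global"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (patient, pathway, tier) enrichment test."""

    patient_id: str
    pathway_id: str
    tier: Tier
    a: int  # patient variants in pathway
    b: int  # patient variants outside pathway
    c: int  # reference variants in pathway
    d: int  # reference variants outside pathway
    odds_ratio: float
    p_value: float
    q_value: float
    significant: bool


def count_patient_pathway(
    variants: Sequence[AnnotatedVariant],
    db: PathwayDB,
    count_unit: Literal["site", "allele"] = "site",
) -> tuple[dict[str, int], int]:
    """Per-pathway counts of a patient's qualifying variants, plus the total.

    The counting unit is the distinct variant site (zygosity ignored); in
    ``allele`` mode homozygous variants count twice.  A gene in several
    pathways contributes its variants to each of them, so pathway counts can
    sum to more than the total when pathways overlap.
    """
    seen: dict[tuple, AnnotatedVariant] = {}
    for v in variants:
        seen.setdefault(v.site_key, v)
    idx = db.gene_index()
    counts: dict[str, int] = {}
    total = 0
    for v in seen.values():
        w = 2 if (count_unit == "allele" and v.zygosity == "hom") else 1
        total += w
        for pid in idx.get(v.gene_symbol, ()):
            counts[pid] = counts.get(pid, 0) + w
    return counts, total


def fisher_enrichment(
    a: int, b: int, c: int, d: int, alternative: Alternative = "greater"
) -> tuple[float, float]:
    """Odds ratio and Fisher exact p for one 2x2 table.

    The one-sided p is the upper hypergeometric tail P(X >= a) with
    population ``a+b+c+d``, ``a+c`` in-pathway variants and ``a+b`` patient
    draws, computed through the hypergeometric survival function (numerically
    stable log-space summation).  ``a = 0`` therefore gives exactly 1.
    The odds ratio is ``(a*d)/(b*c)``, reported as ``inf`` on division by
    zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if c + d < 1:
        raise ValueError("reference total must be >= 1")
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    if alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return odds, min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_vea(
    patient_id: str,
    variants: Sequence[AnnotatedVariant],
    db: PathwayDB,
    ref: ReferenceCounts,
    tier: Tier,
    tier_cfg: TierConfig | None = None,
    alpha: float = 0.05,
    alternative: Alternative = "greater",
    count_unit: Literal["site", "allele"] = "site",
) -> list[EnrichmentResult]:
    """Enrichment tests for one patient, one tier.

    Only pathways where the patient has >= 1 qualifying variant are tested;
    FDR is applied across those tested pathways.  ``variants`` is the
    patient's full annotated table — tier filtering happens here.
    """
    if ref.tier != tier:
        raise ValueError(f"reference tier {ref.tier!r} does not match {tier!r}")
    if ref.total < 1:
        raise ValueError("reference total is 0; cannot test")
    tier_cfg = tier_cfg or TierConfig()
    qual = qualifying_variants(variants, tier, tier_cfg)
    counts, total = count_patient_pathway(qual, db, count_unit=count_unit)
    tested = sorted(counts)
    if not tested:
        return []
    rows = []
    for pid in tested:
        a = counts[pid]
        b = total - a
        c = ref.per_pathway.get(pid, 0)
        d = ref.total - c
        odds, p = fisher_enrichment(a, b, c, d, alternative=alternative)
        rows.append((pid, a, b, c, d, odds, p))
    q = bh_adjust([r[6] for r in rows])
    return [
        EnrichmentResult(
            patient_id=patient_id,
            pathway_id=pid,
            tier=tier,
            a=a,
            b=b,
            c=c,
            d=d,
            odds_ratio=odds,
            p_value=p,
            q_value=float(qi),
            significant=bool(qi < alpha),
        )
        for (pid, a, b, c, d, odds, p), qi in zip(rows, q)
    ]


def run_vea_cohort(
    variants_by_patient: Mapping[str, Sequence[AnnotatedVariant]],
    db: PathwayDB,
    ref: ReferenceCounts,
    tier: Tier,
    tier_cfg: TierConfig | None = None,
    alpha: float = 0.05,
    alternative: Alternative = "greater",
    fdr_scope: FdrScope = "per_patient",
) -> dict[str, list[EnrichmentResult]]:
    """Run the VEA for every patient.

    ``fdr_scope='per_patient'`` (default) adjusts each patient's p-values
    across that patient's tested pathways; ``'global'`` pools all
    (patient, pathway) tests into a single BH adjustment.
    """
    results = {
        pid: run_vea(
            pid, vs, db, ref, tier, tier_cfg, alpha=alpha, alternative=alternative
        )
        for pid, vs in variants_by_patient.items()
    }
    if fdr_scope == "global":
        flat = [(pid, r) for pid, rs in results.items() for r in rs]
        if flat:
            q = bh_adjust([r.p_value for _, r in flat])
            pooled: dict[str, list[EnrichmentResult]] = {p: [] for p in results}
            for (pid, r), qi in zip(flat, q):
                pooled[pid].append(
                    EnrichmentResult(
                        **{
                            **r.__dict__,
                            "q_value": float(qi),
                            "significant": bool(qi < alpha),
                        }
                    )
                )
            results = pooled
    return results


def results_frame(results: Iterable[EnrichmentResult], db: PathwayDB) -> pd.DataFrame:
    """Tabulate enrichment results (one row per tested pathway)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "pathway_id": r.pathway_id,
            "pathway_name": db.name_of(r.pathway_id),
            "tier": r.tier,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "pathway_id",
            "pathway_name",
            "tier",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p_value",
            "q_value",
            "significant",
        ],
    )


def write_results(
    results_by_patient: Mapping[str, Sequence[EnrichmentResult]],
    db: PathwayDB,
    out_dir: str | Path,
    tier: Tier,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, rs in results_by_patient.items():
        results_frame(rs, db).to_csv(
            out / f"vea_{tier}_{pid}.tsv", sep="\t", index=False
        )


def read_results(path: str | Path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return [
        EnrichmentResult(
            patient_id=str(r.patient_id),
            pathway_id=r.pathway_id,
            tier=r.tier,
            a=int(r.a),
            b=int(r.b),
            c=int(r.c),
            d=int(r.d),
            odds_ratio=float(r.odds_ratio),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            significant=bool(r.significant),
        )
        for r in df.itertuples()
    ]
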