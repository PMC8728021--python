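"""Seeded synthetic cohorts for the variant enrichment pipeline.

Real inputs to this pipeline — annotated exomes, a Reactome-like gene-set
database and a gnomAD-like population reference — are large downloads.  This
module generates small stand-ins with the statistical structure the analysis
assumes, so every downstream stage can be exercised end to end:

* a gene universe partitioned into pathways (GMT-style);
* a reference population of variants with allele frequencies skewed toward
  rarity (Beta-distributed), giving per-pathway reference counts;
* per-patient annotated variant tables where qualifying-variant counts per
  gene are Poisson with a configurable mean, multiplied by ``signal_fold``
  in designated *signal pathways* for patients of the *signal group* — the
  burden excess the enrichment analysis is meant to detect;
* CTCAE-style toxicity events whose grade-3 pulmonary pattern defines the
  severe-toxicity (``STox``) group, so classifying the generated events
  recovers the generated labels exactly.

Default sizes mirror a radiotherapy toxicity study cohort: 49 patients of
whom 9 are severe.  Everything is deterministic under a fixed seed; each
generation step derives an independent substream from ``(seed, step)``.

Positions and contig names are synthetic (1-based, GRCh38-style ``chr``
labels) and carry no biological meaning.  Reads, linkage between variants
and realistic human allele-frequency spectra are out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayDB, ReferenceCounts, build_reference_counts, write_gmt, write_reference_counts
from .toxicity import (
    NONPULMONARY_TERMS,
    NOSTOX,
    PULMONARY_TERMS,
    STOX,
    ToxicityEvent,
    write_groups_table,
    write_toxicity_table,
)
from .variants import (
    AnnotatedVariant,
    TierConfig,
    write_variant_table,
    write_vcf,
)

_FUNCTIONAL_CLASSES = (
    "frameshift insertion",
    "frameshift deletion",
    "stopgain",
    "stoploss",
    "splicing",
)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort.

    ``background_rate`` is the expected number of qualifying variants per
    gene, per patient, per tier; in signal pathways it is multiplied by
    ``signal_fold`` for patients of ``signal_group``.  ``reference_n`` is the
    nominal reference sample count (sets the allele-frequency floor);
    ``ref_variants_per_gene`` the expected reference variants per gene per
    tier.  ``rare_af_max`` is the allele-frequency ceiling defining "rare".
    """

    seed: int = 0
    n_patients: int = 49
    n_stox: int = 9
    n_genes: int = 400
    n_pathways: int = 20
    genes_per_pathway: int | tuple[int, int] = 20
    background_rate: float = 0.05
    signal_pathways: tuple[str, ...] | None = None  # None -> first two pathways
    signal_group: str = STOX
    signal_fold: float = 5.0
    reference_n: int = 1000
    ref_variants_per_gene: float = 4.0
    rare_af_max: float = 0.01
    noise_rate: float = 0.05
    pool_size: int = 6
    hom_rate: float = 0.05
    nonpulmonary_g3_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_stox > self.n_patients:
            raise ValueError("n_stox must be <= n_patients")
        if self.signal_fold < 1:
            raise ValueError("signal_fold must be >= 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if not 1 <= self.n_pathways <= self.n_genes:
            raise ValueError("need n_genes >= n_pathways >= 1")
        gpp = self.genes_per_pathway
        lo, hi = (gpp, gpp) if isinstance(gpp, int) else gpp
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError(
                f"genes_per_pathway {gpp} infeasible for {self.n_genes} genes"
            )

    def resolved_signal_pathways(self) -> tuple[str, ...]:
        if self.signal_pathways is not None:
            return tuple(self.signal_pathways)
        return tuple(pathway_id(i) for i in range(min(2, self.n_pathways)))

    def tier_config(self) -> TierConfig:
        return TierConfig(rare_af_max=self.rare_af_max)


def _rng(cfg: SimConfig, step: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, step])


def gene_symbol(i: int) -> str:
    return f"G{i:04d}"


def gene_entrez(i: int) -> int:
    return 1000 + i


def pathway_id(i: int) -> str:
    return f"R-HSA-{100001 + i}"


def patient_ids(cfg: SimConfig) -> list[str]:
    return [str(i + 1) for i in range(cfg.n_patients)]


# ---------------------------------------------------------------------------
# Pathway DB


def generate_pathway_db(cfg: SimConfig) -> PathwayDB:
    """Partition (or sample) the gene universe into pathway gene sets.

    When the requested sizes fit disjointly, genes are shuffled and dealt out
    in consecutive blocks (a partition); otherwise each pathway samples its
    genes independently, giving a many-to-many mapping.
    """
    rng = _rng(cfg, 1)
    gpp = cfg.genes_per_pathway
    lo, hi = (gpp, gpp) if isinstance(gpp, int) else gpp
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    genes = np.array([gene_symbol(i) for i in range(cfg.n_genes)])
    names: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    if int(sizes.sum()) <= cfg.n_genes:
        perm = rng.permutation(cfg.n_genes)
        start = 0
        for i, size in enumerate(sizes):
            pid = pathway_id(i)
            names[pid] = f"Simulated pathway {i + 1}"
            sets[pid] = frozenset(genes[perm[start : start + size]])
            start += int(size)
    else:
        for i, size in enumerate(sizes):
            pid = pathway_id(i)
            names[pid] = f"Simulated pathway {i + 1}"
            sets[pid] = frozenset(rng.choice(genes, size=int(size), replace=False))
    return PathwayDB(names=names, genes=sets)


# ---------------------------------------------------------------------------
# Reference population


@dataclass
class SimReference:
    """Simulated reference population: per-variant AF table + counts."""

    variants: list[AnnotatedVariant]
    counts: dict[str, ReferenceCounts]

    def af_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v.chrom, v.pos, v.ref, v.alt, v.gene_symbol, v.consequence, v.ref_af)
                for v in self.variants
            ],
            columns=["chrom", "pos", "ref", "alt", "gene_symbol", "consequence", "ref_af"],
        )


def _site(gene_idx: int, offset: int, rng: np.random.Generator) -> tuple[str, int, str, str]:
    chrom = f"chr{(gene_idx % 22) + 1}"
    pos = 1 + gene_idx * 10_000 + offset
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return chrom, pos, _BASES[ref], _BASES[alt]


def generate_reference(cfg: SimConfig, db: PathwayDB) -> SimReference:
    """Simulate the reference population's variants and per-pathway counts.

    Per gene and tier the variant count is Poisson(``ref_variants_per_gene``);
    allele frequencies are Beta(0.3, 8) — skewed toward rarity — floored at
    one allele in ``2 * reference_n`` haplotypes so every AF is in (0, 1].
    Counts are then plain sums over each pathway's member genes.
    """
    if len(db) == 0:
        raise ValueError("pathway database is empty")
    rng = _rng(cfg, 2)
    af_floor = 1.0 / (2 * cfg.reference_n)
    variants: list[AnnotatedVariant] = []
    n_func = rng.poisson(cfg.ref_variants_per_gene, size=cfg.n_genes)
    n_imp = rng.poisson(cfg.ref_variants_per_gene, size=cfg.n_genes)
    n_syn = rng.poisson(1.0, size=cfg.n_genes)
    for gi in range(cfg.n_genes):
        offset = 0
        for tier_n, classes in (
            (n_func[gi], _FUNCTIONAL_CLASSES),
            (n_imp[gi], ("nonsynonymous SNV",)),
            (n_syn[gi], ("synonymous SNV",)),
        ):
            for _ in range(int(tier_n)):
                chrom, pos, ref, alt = _site(gi, offset, rng)
                offset += 1
                af = float(np.clip(rng.beta(0.3, 8.0), af_floor, 1.0))
                variants.append(
                    AnnotatedVariant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gene_symbol=gene_symbol(gi),
                        entrez_id=gene_entrez(gi),
                        consequence=classes[int(rng.integers(len(classes)))],
                        ref_af=af,
                    )
                )
    tier_cfg = cfg.tier_config()
    counts = {
        tier: build_reference_counts(
            variants, db, tier_cfg, tier, source_label="simulated reference"
        )
        for tier in ("functional", "impact")
    }
    return SimReference(variants=variants, counts=counts)


# ---------------------------------------------------------------------------
# Patient cohort


def _qualifying_pools(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, dict[int, list[AnnotatedVariant]]]:
    """Fixed per-gene pools of candidate qualifying sites, shared by patients.

    Sampling patients' variants from finite pools makes variants recur
    across patients, which the shared-variant and PCA stages need.  Pool
    sites occupy a position range disjoint from reference sites, and their
    AFs are absent (novel) or below the rarity ceiling by construction.
    """
    pools: dict[str, dict[int, list[AnnotatedVariant]]] = {
        "functional": {},
        "impact": {},
        "noise": {},
    }
    for gi in range(cfg.n_genes):
        func, imp, noise = [], [], []
        for slot in range(cfg.pool_size):
            chrom, pos, ref, alt = _site(gi, 5000 + slot, rng)
            af = (
                None
                if rng.random() < 0.5
                else float(rng.uniform(0, cfg.rare_af_max * 0.9))
            )
            csq = _FUNCTIONAL_CLASSES[int(rng.integers(len(_FUNCTIONAL_CLASSES)))]
            func.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene_symbol=gene_symbol(gi),
                    entrez_id=gene_entrez(gi),
                    consequence=csq,
                    hgvs_c=f"c.{pos % 997 + 1}del" if "deletion" in csq else f"c.{pos % 997 + 1}{ref}>{alt}",
                    ref_af=af,
                    cadd_phred=None,
                )
            )
        for slot in range(cfg.pool_size):
            chrom, pos, ref, alt = _site(gi, 6000 + slot, rng)
            af = (
                None
                if rng.random() < 0.5
                else float(rng.uniform(0, cfg.rare_af_max * 0.9))
            )
            imp.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene_symbol=gene_symbol(gi),
                    entrez_id=gene_entrez(gi),
                    consequence="nonsynonymous SNV",
                    hgvs_c=f"c.{pos % 997 + 1}{ref}>{alt}",
                    ref_af=af,
                    cadd_phred=float(rng.uniform(15.0, 40.0)),
                    impact_score=int(rng.integers(2, 10)),
                )
            )
        for slot in range(3):
            chrom, pos, ref, alt = _site(gi, 7000 + slot, rng)
            noise.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene_symbol=gene_symbol(gi),
                    entrez_id=gene_entrez(gi),
                    consequence="synonymous SNV",
                    hgvs_c=f"c.{pos % 997 + 1}{ref}>{alt}",
                    ref_af=float(rng.uniform(0.05, 0.5)),
                )
            )
        pools["functional"][gi] = func
        pools["impact"][gi] = imp
        pools["noise"][gi] = noise
    return pools


def generate_labels(cfg: SimConfig) -> dict[str, str]:
    """Assign ``n_stox`` randomly chosen patients to the severe group."""
    rng = _rng(cfg, 5)
    ids = patient_ids(cfg)
    stox = set(rng.choice(len(ids), size=cfg.n_stox, replace=False).tolist())
    return {pid: (STOX if i in stox else NOSTOX) for i, pid in enumerate(ids)}


def generate_cohort(
    cfg: SimConfig, db: PathwayDB, labels: Mapping[str, str] | None = None
) -> tuple[dict[str, list[AnnotatedVariant]], dict[str, str]]:
    """Per-patient annotated variant tables plus group labels.

    Per patient, gene and tier, the qualifying-variant count is Poisson with
    mean ``background_rate``, times ``signal_fold`` when the gene lies in a
    signal pathway and the patient is in the signal group; the variants
    themselves are drawn without replacement from the gene's site pool.
    Synonymous/common noise variants are added at ``noise_rate`` per gene.
    """
    if cfg.n_genes == 0:
        raise ValueError("empty gene universe")
    missing = [p for p in cfg.resolved_signal_pathways() if p not in db]
    if missing:
        raise ValueError(f"signal pathways not in database: {missing}")
    labels = dict(labels) if labels is not None else generate_labels(cfg)
    rng = _rng(cfg, 3)
    pools = _qualifying_pools(cfg, rng)

    signal_genes: set[str] = set()
    for pid in cfg.resolved_signal_pathways():
        signal_genes |= db.genes_of(pid)
    sig_cols = np.array(
        [gene_symbol(i) in signal_genes for i in range(cfg.n_genes)], dtype=bool
    )
    ids = patient_ids(cfg)
    sig_rows = np.array([labels[p] == cfg.signal_group for p in ids], dtype=bool)

    lam = np.full((cfg.n_patients, cfg.n_genes), cfg.background_rate)
    lam[np.ix_(sig_rows, sig_cols)] *= cfg.signal_fold

    cohort: dict[str, list[AnnotatedVariant]] = {p: [] for p in ids}
    for tier in ("functional", "impact"):
        counts = rng.poisson(lam)
        for i, j in zip(*np.nonzero(counts)):
            pool = pools[tier][int(j)]
            k = min(int(counts[i, j]), len(pool))
            picks = rng.choice(len(pool), size=k, replace=False)
            for s in picks:
                v = pool[int(s)]
                if rng.random() < cfg.hom_rate:
                    v = dataclasses.replace(v, zygosity="hom")
                v = dataclasses.replace(
                    v,
                    qual=float(np.round(rng.uniform(40, 1500), 1)),
                    depth=int(rng.integers(60, 260)),
                )
                cohort[ids[int(i)]].append(v)
    noise_counts = rng.poisson(cfg.noise_rate, size=(cfg.n_patients, cfg.n_genes))
    for i, j in zip(*np.nonzero(noise_counts)):
        pool = pools["noise"][int(j)]
        k = min(int(noise_counts[i, j]), len(pool))
        for s in rng.choice(len(pool), size=k, replace=False):
            cohort[ids[int(i)]].append(pool[int(s)])
    for p in cohort:
        cohort[p].sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return cohort, labels


# ---------------------------------------------------------------------------
# Toxicity events


def generate_toxicity(
    cfg: SimConfig, labels: Mapping[str, str]
) -> list[ToxicityEvent]:
    """CTCAE-style events consistent with the group labels.

    Every severe-group patient gets at least one grade-3 pulmonary event
    (term drawn among the five qualifying terms, acute or late phase); all
    other patients' pulmonary events stay at grade <= 2.  Non-pulmonary
    grade-3 noise is added at ``nonpulmonary_g3_rate`` per patient in both
    groups, so labels are recoverable only through the pulmonary rule.
    """
    rng = _rng(cfg, 4)
    pulmonary = sorted(PULMONARY_TERMS)
    nonpulmonary = sorted(NONPULMONARY_TERMS)
    events: list[ToxicityEvent] = []
    for pid, group in labels.items():
        n_before = len(events)
        if group == STOX:
            n_severe = 1 + int(rng.integers(0, 2))
            for _ in range(n_severe):
                events.append(
                    ToxicityEvent(
                        patient_id=pid,
                        term=pulmonary[int(rng.integers(len(pulmonary)))],
                        grade=3,
                        phase=("acute", "late")[int(rng.integers(2))],
                    )
                )
        for _ in range(int(rng.integers(0, 3))):
            events.append(
                ToxicityEvent(
                    patient_id=pid,
                    term=pulmonary[int(rng.integers(len(pulmonary)))],
                    grade=1 + int(rng.integers(2)),
                    phase=("early", "acute", "late")[int(rng.integers(3))],
                )
            )
        if rng.random() < cfg.nonpulmonary_g3_rate:
            events.append(
                ToxicityEvent(
                    patient_id=pid,
                    term=nonpulmonary[int(rng.integers(len(nonpulmonary)))],
                    grade=3,
                    phase=("early", "acute", "late")[int(rng.integers(3))],
                )
            )
        if rng.random() < 0.6:
            events.append(
                ToxicityEvent(
                    patient_id=pid,
                    term=nonpulmonary[int(rng.integers(len(nonpulmonary)))],
                    grade=1 + int(rng.integers(2)),
                    phase=("early", "acute", "late")[int(rng.integers(3))],
                )
            )
        if len(events) == n_before:
            # every patient appears in the table, so groups are recoverable
            events.append(
                ToxicityEvent(patient_id=pid, term="fatigue", grade=1, phase="early")
            )
    return events


# ---------------------------------------------------------------------------
# One-call simulation and run-directory output


@dataclass
class SimResult:
    cfg: SimConfig
    db: PathwayDB
    reference: SimReference
    cohort: dict[str, list[AnnotatedVariant]]
    labels: dict[str, str]
    toxicity: list[ToxicityEvent]


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic study: pathways, reference, cohort, toxicity."""
    db = generate_pathway_db(cfg)
    reference = generate_reference(cfg, db)
    labels = generate_labels(cfg)
    cohort, labels = generate_cohort(cfg, db, labels)
    toxicity = generate_toxicity(cfg, labels)
    return SimResult(
        cfg=cfg,
        db=db,
        reference=reference,
        cohort=cohort,
        labels=labels,
        toxicity=toxicity,
    )


def write_run(
    result: SimResult,
    out_dir: str | Path,
    variant_format: Literal["tsv", "vcf"] = "tsv",
) -> Path:
    """Write a complete run directory with a manifest echoing the config."""
    out = Path(out_dir)
    (out / "variants").mkdir(parents=True, exist_ok=True)
    write_gmt(result.db, out / "pathways.gmt")
    write_variant_table(result.reference.variants, out / "reference_variants.tsv")
    for tier, counts in result.reference.counts.items():
        write_reference_counts(counts, out / f"refcounts_{tier}.tsv")
    for pid, vs in result.cohort.items():
        if variant_format == "vcf":
            write_vcf(vs, out / "variants" / f"patient_{pid}.vcf", sample=f"x{pid}")
        else:
            write_variant_table(vs, out / "variants" / f"patient_{pid}.tsv")
    write_toxicity_table(result.toxicity, out / "toxicity.tsv")
    write_groups_table(result.labels, out / "labels.tsv")
    manifest = {
        "config": dataclasses.asdict(result.cfg),
        "signal_pathways": list(result.cfg.resolved_signal_pathways()),
        "variant_format": variant_format,
        "n_reference_variants": len(result.reference.variants),
        "af_source": "simulated reference",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
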