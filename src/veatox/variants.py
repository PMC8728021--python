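"""Annotated-variant records, tier classification and descriptive reports.

Variants arrive annotated (gene symbol, exonic consequence, reference
population allele frequency, CADD, a 0-10 deleteriousness-predictor consensus
score) either as a VCF with the annotations in INFO keys or as a
tab-separated table with one named column per field.

Two variant tiers drive the downstream enrichment analysis:

* **functional** — protein-truncating-style consequences (frameshift
  insertion/deletion, stopgain, stoploss, splicing) that are absent from, or
  rare in, the reference population;
* **impact** — nonsynonymous SNVs that are absent/rare in the reference and
  carry high deleteriousness scores (CADD and predictor consensus above
  configurable thresholds).

A variant is never in both tiers because the consequence sets are disjoint.
All cutoffs live in :class:`TierConfig` and are declared assumptions: the
tiers mirror the "functional variants" / "impact variants" blocks of clinical
radiogenomics reports, which do not print exact score thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Tier = Literal["functional", "impact"]
TIERS: tuple[Tier, ...] = ("functional", "impact")

#: Controlled consequence vocabulary (ANNOVAR exonic-function style).
CONSEQUENCES = (
    "frameshift insertion",
    "frameshift deletion",
    "stopgain",
    "stoploss",
    "splicing",
    "nonsynonymous SNV",
    "synonymous SNV",
    "other",
)

# common alternative spellings -> canonical
_CONSEQUENCE_ALIASES = {
    "frameshift_insertion": "frameshift insertion",
    "frameshift_deletion": "frameshift deletion",
    "nonframeshift insertion": "other",
    "nonframeshift deletion": "other",
    "nonsynonymous_snv": "nonsynonymous SNV",
    "nonsynonymous snv": "nonsynonymous SNV",
    "synonymous_snv": "synonymous SNV",
    "synonymous snv": "synonymous SNV",
    "stop gain": "stopgain",
    "stop loss": "stoploss",
}


def canonical_consequence(value: str) -> str:
    v = value.strip()
    if v in CONSEQUENCES:
        return v
    low = v.lower().replace("-", " ")
    if low in CONSEQUENCES:
        return low
    if low in _CONSEQUENCE_ALIASES:
        return _CONSEQUENCE_ALIASES[low]
    logger.warning("unknown consequence %r mapped to 'other'", value)
    return "other"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant call (one site/alt-allele per record)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    consequence: str
    entrez_id: int | None = None
    hgvs_c: str = ""
    rsid: str | None = None
    ref_af: float | None = None
    qual: float | None = None
    depth: int | None = None
    cadd_phred: float | None = None
    impact_score: int | None = None
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref_af is not None and not 0.0 <= self.ref_af <= 1.0:
            raise ValueError(f"ref_af out of [0,1]: {self.ref_af}")
        if self.impact_score is not None and not 0 <= self.impact_score <= 10:
            raise ValueError(f"impact_score out of [0,10]: {self.impact_score}")
        object.__setattr__(self, "consequence", canonical_consequence(self.consequence))

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Variant identity used throughout: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TierConfig:
    """Thresholds defining the functional and impact variant tiers."""

    functional_consequences: frozenset[str] = frozenset(
        {
            "frameshift insertion",
            "frameshift deletion",
            "stopgain",
            "stoploss",
            "splicing",
        }
    )
    impact_consequences: frozenset[str] = frozenset({"nonsynonymous SNV"})
    min_cadd: float = 10.0
    min_impact_score: int = 1
    rare_af_max: float = 0.01
    treat_missing_af_as_rare: bool = True

    def __post_init__(self) -> None:
        if self.functional_consequences & self.impact_consequences:
            raise ValueError("functional and impact consequence sets must be disjoint")
        if min(self.min_cadd, self.min_impact_score, self.rare_af_max) < 0:
            raise ValueError("tier thresholds must be non-negative")

    def with_(self, **kwargs) -> "TierConfig":
        return replace(self, **kwargs)


def is_rare(v: AnnotatedVariant, cfg: TierConfig | None = None) -> bool:
    """Absent from the reference population, or below the rarity ceiling.

    A missing reference allele frequency means the variant was never seen in
    the reference and counts as rare (configurable); otherwise rarity is the
    strict inequality ``ref_af < rare_af_max``.
    """
    cfg = cfg or TierConfig()
    if v.ref_af is None:
        return cfg.treat_missing_af_as_rare
    return v.ref_af < cfg.rare_af_max


def classify_tier(v: AnnotatedVariant, cfg: TierConfig | None = None) -> str:
    """Assign ``functional``, ``impact`` or ``none``; never both tiers."""
    cfg = cfg or TierConfig()
    if not is_rare(v, cfg):
        return "none"
    if v.consequence in cfg.functional_consequences:
        return "functional"
    if (
        v.consequence in cfg.impact_consequences
        and v.cadd_phred is not None
        and v.cadd_phred >= cfg.min_cadd
        and v.impact_score is not None
        and v.impact_score >= cfg.min_impact_score
    ):
        return "impact"
    return "none"


def qualifying_variants(
    variants: Iterable[AnnotatedVariant], tier: Tier, cfg: TierConfig | None = None
) -> list[AnnotatedVariant]:
    """The subset of ``variants`` belonging to the given tier."""
    cfg = cfg or TierConfig()
    return [v for v in variants if classify_tier(v, cfg) == tier]


# ---------------------------------------------------------------------------
# Readers / writers

#: Column order of the annotated-variant TSV dialect (ANNOVAR-multianno-like).
TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "entrez_id",
    "consequence",
    "hgvs_c",
    "rsid",
    "ref_af",
    "qual",
    "depth",
    "cadd_phred",
    "impact_score",
    "zygosity",
]

_MISSING = "."


def _opt(value, cast):
    if value is None:
        return None
    s = str(value)
    if s in ("", _MISSING, "nan", "NA", "None"):
        return None
    return cast(value)


def read_variant_table(
    path: str | Path, dialect: Literal["annovar_tsv", "vcf"] = "annovar_tsv"
) -> list[AnnotatedVariant]:
    """Read one patient's annotated variants.

    ``annovar_tsv`` expects the documented named columns (:data:`TSV_COLUMNS`,
    missing values as ``.``); ``vcf`` expects a VCF 4.2 with annotations in
    INFO keys ``GENE, ENTREZ, CSQCLASS, HGVSC, RSID, AF_NFE, CADD, IMPACT``.
    Multi-allelic VCF rows are split into one record per alt allele.
    """
    if dialect == "annovar_tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_tsv(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"chrom", "pos", "ref", "alt", "gene_symbol", "consequence"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    out = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, r))
        try:
            out.append(
                AnnotatedVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene_symbol=row["gene_symbol"],
                    consequence=row["consequence"],
                    entrez_id=_opt(row.get("entrez_id"), int),
                    hgvs_c=row.get("hgvs_c", "") or "",
                    rsid=_opt(row.get("rsid"), str),
                    ref_af=_opt(row.get("ref_af"), float),
                    qual=_opt(row.get("qual"), float),
                    depth=_opt(row.get("depth"), lambda x: int(float(x))),
                    cadd_phred=_opt(row.get("cadd_phred"), float),
                    impact_score=_opt(row.get("impact_score"), lambda x: int(float(x))),
                    zygosity=row.get("zygosity", "het") or "het",
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return out


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, float) and value == int(value):
        return str(value)
    return str(value)


def write_variant_table(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write the ANNOVAR-style TSV dialect (lossless round-trip)."""
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene_symbol": v.gene_symbol,
                "entrez_id": _fmt(v.entrez_id),
                "consequence": v.consequence,
                "hgvs_c": v.hgvs_c or "",
                "rsid": _fmt(v.rsid),
                "ref_af": _fmt(v.ref_af),
                "qual": _fmt(v.qual),
                "depth": _fmt(v.depth),
                "cadd_phred": _fmt(v.cadd_phred),
                "impact_score": _fmt(v.impact_score),
                "zygosity": v.zygosity,
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


_VCF_INFO_KEYS = {
    "GENE": "gene_symbol",
    "ENTREZ": "entrez_id",
    "CSQCLASS": "consequence",
    "HGVSC": "hgvs_c",
    "RSID": "rsid",
    "AF_NFE": "ref_af",
    "CADD": "cadd_phred",
    "IMPACT": "impact_score",
}


def _read_vcf(path: str | Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        alts = rec.ALT or []
        gts = rec.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        zyg = "hom" if len(gts) and gts[0] == 3 else "het"
        for j, alt in enumerate(alts):

            def info(key, cast=str):
                val = rec.INFO.get(key)
                if isinstance(val, tuple):  # Number=A fields
                    val = val[j] if j < len(val) else None
                return _opt(val, cast)

            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene_symbol=info("GENE") or "",
                    consequence=info("CSQCLASS") or "other",
                    entrez_id=info("ENTREZ", int),
                    hgvs_c=info("HGVSC") or "",
                    rsid=info("RSID"),
                    ref_af=info("AF_NFE", float),
                    qual=rec.QUAL,
                    depth=_opt(rec.INFO.get("DP"), int),
                    cadd_phred=info("CADD", float),
                    impact_score=info("IMPACT", lambda x: int(float(x))),
                    zygosity=zyg,
                )
            )
    return out


def write_vcf(
    variants: Sequence[AnnotatedVariant], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write a minimal single-sample VCF 4.2 with annotation INFO keys."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=ENTREZ,Number=1,Type=Integer,Description="Entrez gene id">',
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="Transcript change">',
        '##INFO=<ID=RSID,Number=1,Type=String,Description="dbSNP id">',
        '##INFO=<ID=AF_NFE,Number=1,Type=Float,Description="Reference population AF">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">',
        '##INFO=<ID=IMPACT,Number=1,Type=Integer,Description="Predictor consensus 0-10">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    lines = list(header)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = [f"GENE={v.gene_symbol}", f"CSQCLASS={v.consequence.replace(' ', '_')}"]
        if v.entrez_id is not None:
            info.append(f"ENTREZ={v.entrez_id}")
        if v.hgvs_c:
            info.append(f"HGVSC={v.hgvs_c}")
        if v.rsid:
            info.append(f"RSID={v.rsid}")
        if v.ref_af is not None:
            info.append(f"AF_NFE={v.ref_af:.6g}")
        if v.cadd_phred is not None:
            info.append(f"CADD={v.cadd_phred:.6g}")
        if v.impact_score is not None:
            info.append(f"IMPACT={v.impact_score}")
        if v.depth is not None:
            info.append(f"DP={v.depth}")
        gt = "1/1" if v.zygosity == "hom" else "0/1"
        qual = _MISSING if v.qual is None else f"{v.qual:.6g}"
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    v.rsid or _MISSING,
                    v.ref,
                    v.alt,
                    qual,
                    "PASS",
                    ";".join(info),
                    "GT",
                    gt,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Descriptive exome report


def exome_report(variants: Sequence[AnnotatedVariant]) -> dict[str, pd.DataFrame]:
    """Descriptive summary of a variant set.

    Returns tables of counts (and percentages of the input size) by
    consequence class, by genomic location class (splicing vs exonic, the two
    location classes this exonic-level annotation distinguishes) and per gene.
    Counts in each table sum to the number of input variants.
    """
    n = len(variants)

    def tally(keys: Iterable[str]) -> pd.DataFrame:
        counts: dict[str, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        df = pd.DataFrame(sorted(counts.items()), columns=["category", "n"])
        df["pct"] = (100.0 * df["n"] / n).round(2) if n else 0.0
        return df

    by_consequence = tally(v.consequence for v in variants)
    by_location = tally(
        "splicing" if v.consequence == "splicing" else "exonic" for v in variants
    )
    by_gene = tally(v.gene_symbol for v in variants)
    by_gene = by_gene.rename(columns={"category": "gene_symbol"})
    return {
        "by_consequence": by_consequence,
        "by_location": by_location,
        "by_gene": by_gene,
        "n_variants": pd.DataFrame({"n": [n]}),
    }
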