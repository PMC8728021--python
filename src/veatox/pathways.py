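"""Pathway gene-set database (GMT) and reference-population variant counts.

The enrichment analysis compares, pathway by pathway, a patient's qualifying
variant counts against counts from a large reference population (a
gnomAD-non-Finnish-European-like dataset).  This module holds the gene-set
database and builds the per-pathway reference counts.

The reference side counts all variants of a tier's consequence classes with
no rarity filter: rarity is defined *relative to* this same reference, so
filtering the reference by its own frequencies would be circular.  A switch
is exposed for the alternative construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .variants import AnnotatedVariant, Tier, TierConfig, is_rare


@dataclass
class PathwayDB:
    """Pathway id -> (name, gene set) mapping, GMT-style.

    Gene identifiers are opaque strings (symbols or numeric ids, stored
    verbatim); a gene may belong to any number of pathways.
    """

    names: dict[str, str] = field(default_factory=dict)
    genes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, gset in self.genes.items():
            if not gset:
                raise ValueError(f"pathway {pid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.genes

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.genes)

    def name_of(self, pathway_id: str) -> str:
        return self.names.get(pathway_id, pathway_id)

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.genes[pathway_id]

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for gset in self.genes.values():
            out |= gset
        return frozenset(out)

    def pathways_of_gene(self, gene: str) -> list[str]:
        return [pid for pid, gset in self.genes.items() if gene in gset]

    def gene_index(self) -> dict[str, list[str]]:
        """Reverse index gene -> pathway ids (insertion order preserved)."""
        idx: dict[str, list[str]] = {}
        for pid, gset in self.genes.items():
            for g in gset:
                idx.setdefault(g, []).append(pid)
        return idx


def read_gmt(path: str | Path) -> PathwayDB:
    """Parse a GMT file: one pathway per line, ``id <TAB> name <TAB> genes...``.

    Duplicate pathway ids are an error; duplicate genes within one line are
    deduplicated silently.
    """
    names: dict[str, str] = {}
    genes: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            pid, name, *members = parts
            if pid in genes:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway id {pid}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway {pid} has no genes")
            names[pid] = name
            genes[pid] = frozenset(members)
    return PathwayDB(names=names, genes=genes)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    """Write GMT with genes sorted for byte-stable output."""
    lines = [
        "\t".join([pid, db.name_of(pid), *sorted(db.genes[pid])])
        for pid in db.pathway_ids
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ReferenceCounts:
    """Per-pathway qualifying-variant counts in the reference population."""

    tier: Tier
    per_pathway: dict[str, int]
    total: int
    source_label: str = "reference"
    universe_label: str = "all reference genes"

    def __post_init__(self) -> None:
        if self.total < 0 or any(c < 0 for c in self.per_pathway.values()):
            raise ValueError("reference counts must be non-negative")
        bad = {p: c for p, c in self.per_pathway.items() if c > self.total}
        if bad:
            raise ValueError(f"per-pathway counts exceed total: {bad}")


def build_reference_counts(
    ref_variants: Iterable[AnnotatedVariant],
    db: PathwayDB,
    tier_cfg: TierConfig,
    tier: Tier,
    source_label: str = "reference",
    apply_rarity_filter: bool = False,
) -> ReferenceCounts:
    """Count reference variants of the tier's consequence classes per pathway.

    A gene in *k* pathways contributes its variants to all *k*; ``total`` is
    the count over the whole reference, whether or not the gene is in any
    pathway.  Only the consequence class is filtered (plus, optionally, the
    rarity filter — off by default, see module docstring); CADD/impact-score
    thresholds are patient-side concepts and are not applied to reference
    counts.
    """
    classes = (
        tier_cfg.functional_consequences
        if tier == "functional"
        else tier_cfg.impact_consequences
    )
    idx = db.gene_index()
    per_pathway = {pid: 0 for pid in db.pathway_ids}
    total = 0
    for v in ref_variants:
        if v.consequence not in classes:
            continue
        if apply_rarity_filter and not is_rare(v, tier_cfg):
            continue
        total += 1
        for pid in idx.get(v.gene_symbol, ()):
            per_pathway[pid] += 1
    return ReferenceCounts(
        tier=tier, per_pathway=per_pathway, total=total, source_label=source_label
    )


# ---------------------------------------------------------------------------
# Precomputed-count TSV (pathway_id, count, plus a TOTAL row)

_TOTAL_KEY = "TOTAL"


def write_reference_counts(ref: ReferenceCounts, path: str | Path) -> None:
    lines = [
        f"# tier={ref.tier}",
        f"# source={ref.source_label}",
        f"# universe={ref.universe_label}",
        "pathway_id\tcount",
    ]
    lines += [f"{pid}\t{n}" for pid, n in ref.per_pathway.items()]
    lines.append(f"{_TOTAL_KEY}\t{ref.total}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference_counts(path: str | Path) -> ReferenceCounts:
    meta = {"tier": "functional", "source": "reference", "universe": ""}
    per_pathway: dict[str, int] = {}
    total: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("pathway_id"):
                continue
            pid, _, count = line.partition("\t")
            if not count:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            if pid == _TOTAL_KEY:
                total = int(count)
            else:
                per_pathway[pid] = int(count)
    if total is None:
        raise ValueError(f"{path}: missing {_TOTAL_KEY} row")
    return ReferenceCounts(
        tier=meta["tier"],  # type: ignore[arg-type]
        per_pathway=per_pathway,
        total=total,
        source_label=meta["source"],
        universe_label=meta["universe"],
    )
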