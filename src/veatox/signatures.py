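"""Group-level synthesis: exclusive pathway signatures and trace-back.

After the per-patient enrichment analysis, the two toxicity groups are
compared at the pathway level.  A pathway is *exclusive* to a group when it
is significantly enriched in at least one patient of that group and in no
patient of the other group (the Venn-diagram set difference of the per-group
significant-pathway unions).  Exclusive pathways are then traced back to the
qualifying variants and genes that produced them, group-exclusive shared
variants are extracted, and a noncentered PCA of the patients-by-variants
matrix summarizes the overall variant distribution.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult
from .pathways import PathwayDB
from .variants import AnnotatedVariant, Tier, TierConfig, qualifying_variants


@dataclass
class SignatureRow:
    pathway_id: str
    pathway_name: str
    patients: tuple[str, ...]

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class GroupSignature:
    """Pathways exclusive to one group for one variant tier."""

    group: str
    tier: Tier
    rows: list[SignatureRow] = field(default_factory=list)
    # pathway_id -> traced-back qualifying variants (union over supporters)
    traceback: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return [r.pathway_id for r in self.rows]

    def traceback_totals(self) -> tuple[int, int]:
        """(distinct variants, distinct genes) over the whole signature."""
        sites = set()
        genes = set()
        for vs in self.traceback.values():
            for v in vs:
                sites.add(v.site_key)
                genes.add(v.gene_symbol)
        return len(sites), len(genes)


def significant_pathways(
    results_by_patient: Mapping[str, Sequence[EnrichmentResult]],
) -> dict[str, set[str]]:
    """patient -> set of significantly enriched pathway ids."""
    return {
        pid: {r.pathway_id for r in rs if r.significant}
        for pid, rs in results_by_patient.items()
    }


def exclusive_pathways(
    results_by_patient: Mapping[str, Sequence[EnrichmentResult]],
    groups: Mapping[str, str],
    tier: Tier,
    db: PathwayDB | None = None,
    min_patients: int = 1,
) -> dict[str, GroupSignature]:
    """Per-group exclusive pathway signatures.

    A pathway enters group G's signature iff it is significant in
    ``>= min_patients`` patients of G and in zero patients of the other
    group(s); the supporting patients are exactly G's significant patients
    for that pathway.  Rows keep a stable order: by first supporting patient
    (cohort order), then pathway id.
    """
    missing = [p for p in results_by_patient if p not in groups]
    if missing:
        raise ValueError(f"patients missing a group label: {missing}")
    sig = significant_pathways(results_by_patient)
    group_names = sorted({groups[p] for p in results_by_patient})
    patient_order = list(results_by_patient)

    out: dict[str, GroupSignature] = {}
    for g in group_names:
        own = [p for p in patient_order if groups[p] == g]
        others = [p for p in patient_order if groups[p] != g]
        other_union: set[str] = set()
        for p in others:
            other_union |= sig[p]
        supporters: dict[str, list[str]] = {}
        for p in own:
            for pw in sig[p]:
                if pw not in other_union:
                    supporters.setdefault(pw, []).append(p)
        rows = [
            SignatureRow(
                pathway_id=pw,
                pathway_name=db.name_of(pw) if db else pw,
                patients=tuple(pats),
            )
            for pw, pats in supporters.items()
            if len(pats) >= min_patients
        ]
        rows.sort(key=lambda r: (patient_order.index(r.patients[0]), r.pathway_id))
        out[g] = GroupSignature(group=g, tier=tier, rows=rows)
    return out


def traceback_variants(
    signature: GroupSignature,
    variants_by_patient: Mapping[str, Sequence[AnnotatedVariant]],
    db: PathwayDB,
    tier_cfg: TierConfig | None = None,
) -> GroupSignature:
    """Attach, per pathway, the qualifying variants that drive the signature.

    For each signature row the union is taken, over the supporting patients,
    of their tier-qualifying variants lying in the pathway's genes (distinct
    by site).  Returns the same signature object with ``traceback`` filled.
    """
    tier_cfg = tier_cfg or TierConfig()
    for row in signature.rows:
        if row.pathway_id not in db:
            raise KeyError(f"unknown pathway in signature: {row.pathway_id}")
        genes = db.genes_of(row.pathway_id)
        seen: dict[tuple, AnnotatedVariant] = {}
        for pid in row.patients:
            for v in qualifying_variants(
                variants_by_patient.get(pid, ()), signature.tier, tier_cfg
            ):
                if v.gene_symbol in genes:
                    seen.setdefault(v.site_key, v)
        signature.traceback[row.pathway_id] = sorted(
            seen.values(), key=lambda v: _chrom_key(v.chrom) + (v.pos, v.ref, v.alt)
        )
    return signature


def group_exclusive_shared_variants(
    variants_by_patient: Mapping[str, Sequence[AnnotatedVariant]],
    groups: Mapping[str, str],
    tier: Tier,
    tier_cfg: TierConfig | None = None,
    min_patients: int = 2,
) -> dict[str, list[AnnotatedVariant]]:
    """Tier-qualifying variants shared within one group and absent from the other.

    A variant (identified by chrom/pos/ref/alt) is reported for group G when
    it occurs in ``>= min_patients`` patients of G and in no patient of any
    other group.  Output sorted by chromosome then position.
    """
    tier_cfg = tier_cfg or TierConfig()
    carriers: dict[tuple, dict[str, set[str]]] = {}
    rep: dict[tuple, AnnotatedVariant] = {}
    for pid, vs in variants_by_patient.items():
        g = groups[pid]
        for v in qualifying_variants(vs, tier, tier_cfg):
            carriers.setdefault(v.site_key, {}).setdefault(g, set()).add(pid)
            rep.setdefault(v.site_key, v)
    out: dict[str, list[AnnotatedVariant]] = {
        g: [] for g in sorted(set(groups.values()))
    }
    for key, by_group in carriers.items():
        if len(by_group) == 1:
            (g,) = by_group
            if len(by_group[g]) >= min_patients:
                out[g].append(rep[key])
    for g in out:
        out[g].sort(key=lambda v: _chrom_key(v.chrom) + (v.pos, v.ref, v.alt))
    return out


# ---------------------------------------------------------------------------
# Variant matrix and noncentered PCA


def _chrom_key(chrom: str) -> tuple:
    m = re.fullmatch(r"(?:chr)?(\d+|[XYM]T?)", chrom, flags=re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
        return (0, order.get(tok, int(tok) if tok.isdigit() else 99), chrom)
    return (1, 0, chrom)


def variant_matrix(
    variants_by_patient: Mapping[str, Sequence[AnnotatedVariant]],
    mode: str = "site",
) -> pd.DataFrame:
    """Patients x variants presence matrix.

    Columns are variant identities ``chrom:pos:ref:alt`` in deterministic
    (chrom, pos, ref, alt) order; entries are 0/1 in ``site`` mode and allele
    dosage 0/1/2 in ``dosage`` mode (2 = homozygous).
    """
    if len(variants_by_patient) < 2:
        raise ValueError("variant_matrix needs >= 2 patients")
    universe: dict[tuple, None] = {}
    for vs in variants_by_patient.values():
        for v in vs:
            universe[v.site_key] = None
    cols = sorted(universe, key=lambda k: _chrom_key(k[0]) + k[1:])
    col_index = {k: j for j, k in enumerate(cols)}
    patients = list(variants_by_patient)
    mat = np.zeros((len(patients), len(cols)), dtype=float)
    for i, pid in enumerate(patients):
        for v in variants_by_patient[pid]:
            val = 2.0 if (mode == "dosage" and v.zygosity == "hom") else 1.0
            j = col_index[v.site_key]
            mat[i, j] = max(mat[i, j], val)
    names = [f"{c}:{p}:{r}:{a}" for c, p, r, a in cols]
    return pd.DataFrame(mat, index=patients, columns=names)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # patients x components
    loadings: pd.DataFrame  # variants x components
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]
    scaled: pd.DataFrame  # the scaled matrix that was decomposed


def pca_noncentered(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Noncentered PCA of a patients-by-variants matrix.

    Columns are scaled to unit variance about zero — divided by their root
    mean square ``sqrt(sum(x^2)/(n-1))`` — *without* mean-centering, and the
    scaled matrix is decomposed by SVD (equivalently, an eigen-decomposition
    of the uncentered cross-product).  All-zero columns cannot be scaled and
    are dropped with a warning.  Scores are ``X_scaled @ loadings``, so
    ``scores @ loadings.T`` reconstructs the scaled matrix when all
    components are kept (the default).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows for PCA")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    rms = np.sqrt((X**2).sum(axis=0) / (n - 1))
    keep = rms > 0
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-zero column(s) before PCA")
    if not keep.any():
        raise ValueError("matrix has no nonzero columns after dropping")
    Xs = X[:, keep] / rms[keep]
    k = min(Xs.shape) if n_components is None else min(n_components, *Xs.shape)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    # sign convention: largest-magnitude loading positive, for determinism
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=matrix.index, columns=comp)
    kept_cols = [c for c, m in zip(matrix.columns, keep) if m]
    loadings = pd.DataFrame(Vt[:k].T, index=kept_cols, columns=comp)
    evr = (s**2 / (s**2).sum())[:k]
    scaled = pd.DataFrame(Xs, index=matrix.index, columns=kept_cols)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        dropped_columns=dropped,
        scaled=scaled,
    )


def outlier_flag(scores: pd.DataFrame, n_scales: float = 3.0) -> pd.Series:
    """Flag patients far from the score centroid.

    A patient is flagged when its Euclidean distance from the centroid of
    the PCA scores exceeds ``median + n_scales * 1.4826 * MAD`` of the
    distances (a robust z-like rule; with a zero MAD only strictly larger
    distances can be flagged).
    """
    pts = scores.to_numpy(dtype=float)
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    thresh = med + n_scales * 1.4826 * mad
    return pd.Series(d > thresh, index=scores.index, name="outlier")


# ---------------------------------------------------------------------------
# Report rendering (signature and trace-back tables, optional Venn figure)

SIGNATURE_HEADER = ["DB_ID", "Pathway name", "Patient ID#", "Number of patients"]
TRACEBACK_HEADER = [
    "DB_ID",
    "Pathway name",
    "Patient ID#",
    "Gene",
    "ENTREZ ID",
    "Exon/Change",
    "rs ID",
    "QUAL/AD",
    "Chr",
    "Position",
    "Type",
    "Impact score/CADD",
]


def _xid(patient_id: str) -> str:
    return patient_id if patient_id.startswith("x") else f"x{patient_id}"


def render_signature_table(signature: GroupSignature) -> str:
    """Signature rows as a TSV string (DB_ID / name / x-ids / n patients)."""
    lines = ["\t".join(SIGNATURE_HEADER)]
    for r in signature.rows:
        lines.append(
            "\t".join(
                [
                    r.pathway_id,
                    r.pathway_name,
                    ",".join(_xid(p) for p in r.patients),
                    str(r.n_patients),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_signature_table(
    text: str, group: str, tier: Tier
) -> GroupSignature:
    """Inverse of :func:`render_signature_table` (round-trip safe)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != SIGNATURE_HEADER:
        raise ValueError("not a signature table: bad header")
    rows = []
    for ln in lines[1:]:
        pid, name, pats, n = ln.split("\t")
        patients = tuple(p.strip() for p in pats.split(",") if p.strip())
        if len(patients) != int(n):
            raise ValueError(f"patient list and count disagree on line: {ln!r}")
        rows.append(SignatureRow(pathway_id=pid, pathway_name=name, patients=patients))
    return GroupSignature(group=group, tier=tier, rows=rows)


def _na(v) -> str:
    return "NA" if v in (None, "") else str(v)


def render_traceback_table(signature: GroupSignature) -> str:
    """Traced-back variants as a TSV with report-style columns."""
    lines = ["\t".join(TRACEBACK_HEADER)]
    for row in signature.rows:
        for v in signature.traceback.get(row.pathway_id, []):
            impact = (
                f"{_na(v.impact_score)}/{_na(v.cadd_phred)}"
                if (v.impact_score is not None or v.cadd_phred is not None)
                else "NA"
            )
            qual_ad = (
                f"{_na(None if v.qual is None else int(v.qual))}/{_na(v.depth)}"
                if (v.qual is not None or v.depth is not None)
                else "NA"
            )
            lines.append(
                "\t".join(
                    [
                        row.pathway_id,
                        row.pathway_name,
                        ",".join(_xid(p) for p in row.patients),
                        v.gene_symbol,
                        _na(v.entrez_id),
                        v.hgvs_c or "NA",
                        _na(v.rsid),
                        qual_ad,
                        v.chrom.removeprefix("chr"),
                        str(v.pos),
                        v.consequence,
                        impact,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def render_reports(
    signatures: Mapping[str, GroupSignature],
    out_dir: str | Path,
    venn: bool = False,
    significant_by_group: Mapping[str, set[str]] | None = None,
) -> list[Path]:
    """Write signature and trace-back TSVs (and optionally a Venn figure).

    One ``signature_<tier>_<group>.tsv`` and, when trace-back data is
    attached, one ``traceback_<tier>_<group>.tsv`` per group.  With
    ``venn=True`` and per-group significant pathway sets supplied, a two-set
    Venn diagram of the groups' significant pathways is saved as SVG.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tier = None
    for g, sig in signatures.items():
        tier = sig.tier
        p = out / f"signature_{sig.tier}_{g}.tsv"
        p.write_text(render_signature_table(sig))
        written.append(p)
        if sig.traceback:
            p = out / f"traceback_{sig.tier}_{g}.tsv"
            p.write_text(render_traceback_table(sig))
            written.append(p)
    if venn and significant_by_group and len(significant_by_group) == 2:
        p = out / f"venn_{tier}.svg"
        venn_figure(significant_by_group, p)
        written.append(p)
    return written


def venn_figure(sets_by_group: Mapping[str, set[str]], path: str | Path) -> None:
    """Two-circle Venn diagram of per-group significant pathway sets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    (ga, sa), (gb, sb) = sets_by_group.items()
    only_a, both, only_b = len(sa - sb), len(sa & sb), len(sb - sa)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((0.38, 0.5), 0.32, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.62, 0.5), 0.32, alpha=0.4, color="tab:orange"))
    ax.text(0.25, 0.5, str(only_a), ha="center", va="center", fontsize=14)
    ax.text(0.50, 0.5, str(both), ha="center", va="center", fontsize=14)
    ax.text(0.75, 0.5, str(only_b), ha="center", va="center", fontsize=14)
    ax.text(0.25, 0.88, ga, ha="center", fontsize=12)
    ax.text(0.75, 0.88, gb, ha="center", fontsize=12)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
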