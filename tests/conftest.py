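from pathlib import Path

import pandas as pd
import pytest

from veatox import (
    AnnotatedVariant,
    GroupSignature,
    SimConfig,
    parse_signature_table,
    read_toxicity_table,
)

DATA = Path(__file__).parent / "data"


def load_signature(tier: str, group: str) -> GroupSignature:
    text = (DATA / f"signature_{tier}_{group}.tsv").read_text()
    return parse_signature_table(text, group=group, tier=tier)


def load_selected_variants() -> pd.DataFrame:
    return pd.read_csv(
        DATA / "selected_variants.tsv", sep="\t", comment="#", dtype=str
    )


def _opt(val, cast):
    return None if val in (None, "NA", "") or pd.isna(val) else cast(val)


def selected_variant(row) -> AnnotatedVariant:
    """Build an AnnotatedVariant from one selected-variants fixture row."""
    return AnnotatedVariant(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        gene_symbol=row["gene_symbol"],
        entrez_id=int(row["entrez_id"]),
        consequence=row["consequence"],
        hgvs_c=row["exon_change"],
        rsid=_opt(row["rsid"], str),
        qual=float(row["qual"]),
        depth=int(row["depth"]),
        cadd_phred=_opt(row["cadd_phred"], float),
        impact_score=_opt(row["impact_score"], int),
    )


@pytest.fixture(scope="session")
def severe_events():
    return read_toxicity_table(DATA / "severe_patient_events.tsv")


@pytest.fixture(scope="session")
def summary_counts():
    return pd.read_csv(DATA / "toxicity_summary_counts.tsv", sep="\t")


@pytest.fixture(scope="session")
def selected_variants():
    return load_selected_variants()


@pytest.fixture(scope="session")
def small_config():
    """A reduced simulation for fast unit tests (full pipeline still runs)."""
    return SimConfig(
        seed=7,
        n_patients=12,
        n_stox=3,
        n_genes=60,
        n_pathways=6,
        genes_per_pathway=10,
        background_rate=0.1,
    )
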