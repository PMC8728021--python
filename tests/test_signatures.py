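"""Exclusive pathway signatures, trace-back, shared variants, PCA, reports."""

import numpy as np
import pytest

from veatox import (
    EnrichmentResult,
    PathwayDB,
    TierConfig,
    exclusive_pathways,
    group_exclusive_shared_variants,
    outlier_flag,
    parse_signature_table,
    pca_noncentered,
    render_reports,
    render_signature_table,
    traceback_variants,
    variant_matrix,
)
from .conftest import DATA, load_selected_variants, load_signature, selected_variant
from .test_variants import make_variant


def result(pid, pathway, significant, q=None):
    return EnrichmentResult(
        patient_id=pid, pathway_id=pathway, tier="functional",
        a=2, b=8, c=5, d=95, odds_ratio=4.75,
        p_value=0.02, q_value=(0.01 if significant else 0.5) if q is None else q,
        significant=significant,
    )


class TestExclusivePathways:
    def test_symmetric_significance_gives_empty_signatures(self):
        results = {
            "1": [result("1", "PW1", True)],
            "2": [result("2", "PW1", True)],
        }
        groups = {"1": "NoSTox", "2": "STox"}
        sigs = exclusive_pathways(results, groups, "functional")
        assert sigs["NoSTox"].rows == [] and sigs["STox"].rows == []

    def test_single_patient_exclusive_pathway(self):
        """A pathway significant only in one severe patient enters that group's
        signature with a single supporter (the fibrin-clot situation)."""
        results = {
            "2": [result("2", "R-HSA-75205", True)],
            "7": [result("7", "R-HSA-75205", False), result("7", "PWX", True)],
        }
        groups = {"2": "STox", "7": "NoSTox"}
        sigs = exclusive_pathways(results, groups, "functional")
        (row,) = sigs["STox"].rows
        assert row.pathway_id == "R-HSA-75205"
        assert row.patients == ("2",) and row.n_patients == 1
        assert sigs["NoSTox"].pathway_ids == ["PWX"]

    def test_missing_group_label_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            exclusive_pathways({"1": []}, {}, "functional")

    def test_min_patients_threshold(self):
        results = {
            "1": [result("1", "PW1", True)],
            "2": [result("2", "PW1", True)],
            "3": [],
        }
        groups = {"1": "A", "2": "A", "3": "B"}
        assert exclusive_pathways(results, groups, "functional",
                                  min_patients=2)["A"].pathway_ids == ["PW1"]
        assert exclusive_pathways(results, groups, "functional",
                                  min_patients=3)["A"].rows == []

    def test_randomized_vs_set_logic_oracle(self):
        rng = np.random.default_rng(5)
        patients = [str(i) for i in range(10)]
        groups = {p: ("STox" if i < 4 else "NoSTox") for i, p in enumerate(patients)}
        pathways = [f"PW{j}" for j in range(8)]
        results = {
            p: [result(p, pw, bool(rng.random() < 0.3)) for pw in pathways]
            for p in patients
        }
        sigs = exclusive_pathways(results, groups, "functional")
        sig_sets = {p: {r.pathway_id for r in rs if r.significant}
                    for p, rs in results.items()}
        for g in ("STox", "NoSTox"):
            own = set().union(*(sig_sets[p] for p in patients if groups[p] == g))
            other = set().union(*(sig_sets[p] for p in patients if groups[p] != g))
            assert set(sigs[g].pathway_ids) == own - other
            for row in sigs[g].rows:
                assert set(row.patients) == {
                    p for p in patients
                    if groups[p] == g and row.pathway_id in sig_sets[p]
                }

    def test_antisymmetric(self):
        """No pathway can sit in both groups' signatures for one tier."""
        rng = np.random.default_rng(9)
        patients = [str(i) for i in range(8)]
        groups = {p: ("A" if int(p) % 2 else "B") for p in patients}
        results = {
            p: [result(p, f"PW{j}", bool(rng.random() < 0.5)) for j in range(6)]
            for p in patients
        }
        sigs = exclusive_pathways(results, groups, "functional")
        assert not set(sigs["A"].pathway_ids) & set(sigs["B"].pathway_ids)


class TestTraceback:
    def test_empty_signature(self):
        sig = exclusive_pathways({"1": []}, {"1": "A"}, "functional")["A"]
        db = PathwayDB(names={"P": "p"}, genes={"P": frozenset({"G"})})
        traceback_variants(sig, {"1": []}, db)
        assert sig.traceback_totals() == (0, 0)

    def test_serpinf2_traceback(self, selected_variants):
        """The fibrin-clot pathway traces back to the SERPINF2 stopgain."""
        row = selected_variants[selected_variants.gene_symbol == "SERPINF2"].iloc[0]
        v = selected_variant(row)
        db = PathwayDB(names={"R-HSA-75205": "Dissolution of fibrin clot"},
                       genes={"R-HSA-75205": frozenset({"SERPINF2"})})
        results = {"2": [result("2", "R-HSA-75205", True)], "7": []}
        sigs = exclusive_pathways(results, {"2": "STox", "7": "NoSTox"}, "functional")
        sig = traceback_variants(sigs["STox"], {"2": [v], "7": []}, db)
        traced = sig.traceback["R-HSA-75205"]
        assert [t.gene_symbol for t in traced] == ["SERPINF2"]
        assert traced[0].consequence == "stopgain"
        assert sig.traceback_totals() == (1, 1)

    def test_totals_vs_nested_loop(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(10)]
        db = PathwayDB(
            names={f"P{j}": f"p{j}" for j in range(5)},
            genes={f"P{j}": frozenset(genes[2 * j: 2 * j + 2]) for j in range(5)},
        )
        patients = [str(i) for i in range(6)]
        cohort = {
            p: [make_variant(pos=int(pos), gene_symbol=genes[int(g)],
                             consequence="stopgain")
                for pos, g in zip(rng.integers(1, 500, 12), rng.integers(0, 10, 12))]
            for p in patients
        }
        groups = {p: ("A" if int(p) < 3 else "B") for p in patients}
        results = {
            p: [result(p, f"P{j}", bool(rng.random() < 0.4)) for j in range(5)]
            for p in patients
        }
        sigs = exclusive_pathways(results, groups, "functional")
        cfg = TierConfig()
        for sig in sigs.values():
            traceback_variants(sig, cohort, db, cfg)
            sites, gene_count = set(), set()
            for row in sig.rows:
                expected = {
                    v.site_key
                    for pid in row.patients
                    for v in cohort[pid]
                    if v.gene_symbol in db.genes[row.pathway_id]
                }
                assert {v.site_key for v in sig.traceback[row.pathway_id]} == expected
                sites |= expected
                gene_count |= {v.gene_symbol for v in sig.traceback[row.pathway_id]}
            assert sig.traceback_totals() == (len(sites), len(gene_count))

    def test_traced_variants_belong_to_pathway_genes(self):
        """Conservation: every traced variant maps to a supporter and its pathway."""
        db = PathwayDB(names={"P": "p"}, genes={"P": frozenset({"A"})})
        va = make_variant(pos=1, gene_symbol="A", consequence="stopgain")
        vb = make_variant(pos=2, gene_symbol="B", consequence="stopgain")
        results = {"1": [result("1", "P", True)], "2": []}
        sigs = exclusive_pathways(results, {"1": "X", "2": "Y"}, "functional")
        sig = traceback_variants(sigs["X"], {"1": [va, vb], "2": []}, db)
        assert [v.gene_symbol for v in sig.traceback["P"]] == ["A"]


class TestGroupExclusiveSharedVariants:
    def test_identical_sets_give_empty(self):
        v = make_variant(pos=1, gene_symbol="A", consequence="stopgain")
        cohort = {"1": [v], "2": [v]}
        out = group_exclusive_shared_variants(
            cohort, {"1": "A", "2": "B"}, "functional", min_patients=1
        )
        assert out["A"] == [] and out["B"] == []

    def test_two_of_three_reported(self):
        v = make_variant(pos=7, gene_symbol="A", consequence="stopgain")
        cohort = {"1": [v], "2": [v], "3": [], "4": []}
        groups = {"1": "A", "2": "A", "3": "A", "4": "B"}
        out = group_exclusive_shared_variants(cohort, groups, "functional",
                                              min_patients=2)
        assert [x.site_key for x in out["A"]] == [v.site_key]
        assert out["B"] == []

    def test_random_vs_brute_force(self):
        rng = np.random.default_rng(13)
        sites = [(f"chr{int(c)}", int(p)) for c, p in
                 zip(rng.integers(1, 4, 15), rng.integers(1, 2000, 15))]
        patients = [str(i) for i in range(8)]
        groups = {p: ("A" if int(p) < 5 else "B") for p in patients}
        cohort = {
            p: [make_variant(chrom=c, pos=pos, gene_symbol="G",
                             consequence="stopgain")
                for c, pos in sites if rng.random() < 0.35]
            for p in patients
        }
        k = 2
        out = group_exclusive_shared_variants(cohort, groups, "functional",
                                              min_patients=k)
        qual = {p: {v.site_key for v in vs} for p, vs in cohort.items()}
        for g in ("A", "B"):
            own = [p for p in patients if groups[p] == g]
            other = [p for p in patients if groups[p] != g]
            expected = {
                s for s in {sk for p in own for sk in qual[p]}
                if sum(s in qual[p] for p in own) >= k
                and not any(s in qual[p] for p in other)
            }
            assert {v.site_key for v in out[g]} == expected
            positions = [(v.chrom, v.pos) for v in out[g]]
            assert positions == sorted(positions)


class TestVariantMatrix:
    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            variant_matrix({"1": []})

    def test_empty_universe(self):
        m = variant_matrix({"1": [], "2": []})
        assert m.shape == (2, 0)

    def test_shared_and_private(self):
        shared = make_variant(pos=1, gene_symbol="A")
        private = make_variant(pos=2, gene_symbol="A")
        m = variant_matrix({"1": [shared, private], "2": [shared]})
        assert m.shape == (2, 2)
        assert m.loc["1"].tolist() == [1.0, 1.0]
        assert m.loc["2"].tolist() == [1.0, 0.0]

    def test_dosage_mode(self):
        hom = make_variant(pos=1, gene_symbol="A", zygosity="hom")
        m = variant_matrix({"1": [hom], "2": []}, mode="dosage")
        assert m.loc["1"].tolist() == [2.0]

    def test_column_order_deterministic_and_chromosome_aware(self):
        v10 = make_variant(chrom="chr10", pos=5, gene_symbol="A")
        v2 = make_variant(chrom="chr2", pos=9, gene_symbol="A")
        m = variant_matrix({"1": [v10, v2], "2": []})
        assert list(m.columns) == ["chr2:9:A:T", "chr10:5:A:T"]

    def test_random_fixture_vs_recount(self):
        rng = np.random.default_rng(2)
        vs = [make_variant(pos=int(p), gene_symbol="G")
              for p in rng.choice(np.arange(1, 100), size=10, replace=False)]
        cohort = {str(i): [v for v in vs if rng.random() < 0.5] for i in range(4)}
        m = variant_matrix(cohort)
        for pid, pvs in cohort.items():
            keys = {f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}" for v in pvs}
            assert set(m.columns[m.loc[pid] == 1.0]) == keys


class TestPcaNoncentered:
    def test_single_nonzero_column_axis(self):
        import pandas as pd

        m = pd.DataFrame({"v1": [1.0, 2.0, 3.0]}, index=list("abc"))
        res = pca_noncentered(m)
        assert abs(res.loadings.iloc[0, 0]) == pytest.approx(1.0)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 10)).astype(float))
        m.iloc[0, 0] = 1.0  # guarantee at least one nonzero column
        res = pca_noncentered(m)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, res.scaled.to_numpy(), atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_uncentered_cross_product_eigendecomposition(self):
        """Oracle: eigen-decompose X'X of the scaled (not centered) matrix."""
        import pandas as pd

        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.integers(0, 2, size=(7, 5)).astype(float)) + 0.0
        m.iloc[:, :] += rng.normal(0, 0.01, size=m.shape)  # break ties
        res = pca_noncentered(m)
        Xs = res.scaled.to_numpy()
        evals = np.sort(np.linalg.eigvalsh(Xs.T @ Xs))[::-1]
        svals = (res.scores.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(np.sort(svals)[::-1], evals[: len(svals)], atol=1e-8)

    def test_scaling_is_rms_not_centered(self):
        import pandas as pd

        m = pd.DataFrame({"v": [1.0, 1.0, 1.0]})
        res = pca_noncentered(m)
        # centered scaling would divide by sd=0 and fail; RMS scaling keeps the
        # constant column, normalized so that sum(x^2)/(n-1) == 1
        v = res.scaled["v"].to_numpy()
        assert (v**2).sum() / (len(v) - 1) == pytest.approx(1.0)
        assert np.allclose(v, v[0])

    def test_duplicated_rows_identical_scores(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, size=8).astype(float)
        row[0] = 1.0
        m = pd.DataFrame([row, row, rng.integers(0, 2, 8).astype(float)])
        res = pca_noncentered(m)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1], atol=1e-10)

    def test_zero_columns_dropped_with_warning(self):
        import pandas as pd

        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="dropping"):
            res = pca_noncentered(m)
        assert res.dropped_columns == ["b"]

    def test_all_zero_matrix_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError), pytest.warns(UserWarning):
            pca_noncentered(pd.DataFrame(np.zeros((3, 2))))


class TestOutlierFlag:
    def test_identical_points_unflagged(self):
        import pandas as pd

        scores = pd.DataFrame(np.ones((5, 2)), index=list("abcde"))
        assert not outlier_flag(scores).any()

    def test_displaced_point_flagged(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, size=(20, 2))
        pts[7] = (40.0, 40.0)
        flags = outlier_flag(pd.DataFrame(pts))
        assert flags.iloc[7]
        assert flags.sum() == 1

    def test_two_clusters_smoke(self):
        import pandas as pd

        pts = np.array([[1.0, 0], [1, 0], [1, 0], [-1, 0], [-1, 0], [-1, 0]])
        flags = outlier_flag(pd.DataFrame(pts))
        assert flags.dtype == bool  # documented smoke contract: no crash


class TestRenderReports:
    def test_empty_signature_header_only(self, tmp_path):
        sigs = exclusive_pathways({"1": []}, {"1": "A"}, "functional")
        paths = render_reports(sigs, tmp_path)
        text = paths[0].read_text()
        assert text.splitlines() == ["DB_ID\tPathway name\tPatient ID#\tNumber of patients"]

    def test_fixture_byte_identical_round_trip(self):
        """Parse-then-render of the severe-group functional table is lossless."""
        raw = (DATA / "signature_functional_STox.tsv").read_text()
        sig = parse_signature_table(raw, group="STox", tier="functional")
        assert render_signature_table(sig) == raw

    def test_fixture_patient_counts_consistent(self):
        for tier, group in [("functional", "NoSTox"), ("functional", "STox"),
                            ("impact", "NoSTox"), ("impact", "STox")]:
            sig = load_signature(tier, group)
            for row in sig.rows:
                assert row.n_patients == len(row.patients)

    def test_row_counts_conserved(self, tmp_path):
        results = {
            "1": [result("1", "PW1", True), result("1", "PW2", True)],
            "2": [result("2", "PW3", True)],
        }
        sigs = exclusive_pathways(results, {"1": "A", "2": "B"}, "functional")
        paths = render_reports(sigs, tmp_path)
        for p in paths:
            group = p.stem.rsplit("_", 1)[1]
            assert len(p.read_text().splitlines()) - 1 == len(sigs[group].rows)

    def test_venn_figure_written(self, tmp_path):
        from veatox import venn_figure

        out = tmp_path / "venn.svg"
        venn_figure({"A": {"p1", "p2"}, "B": {"p2", "p3"}}, out)
        assert out.exists() and out.stat().st_size > 0
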