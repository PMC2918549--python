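from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from regioprot.errors import ValidationError
from regioprot.inference import InferenceResult, assign_peptides
from regioprot.region_compare import (
    DEFAULT_REGIONS,
    RegionMatrix,
    build_matrix,
    call_regions,
    compare_scores,
    recount_summary,
    summarize,
)

from conftest import make_psm


def result_with(region, replicate, proteins):
    """proteins: mapping accession -> (score, n_peptides)"""
    res = InferenceResult(region=region, replicate_id=replicate)
    for acc, (score, n_pep) in proteins.items():
        res.assignments[acc] = [
            make_psm(
                region=region,
                replicate=replicate,
                spectrum_id=f"{acc}{i}",
                candidates=(acc,),
            )
            for i in range(n_pep)
        ]
        res.protein_score[acc] = score
        res.single_peptide_flag[acc] = n_pep == 1
    return res


def make_random_matrix(rng, n_proteins=8, n_regions=4, n_replicates=3):
    score = rng.uniform(0, 100, size=(n_proteins, n_regions, n_replicates))
    score[rng.random(score.shape) < 0.4] = 0.0
    keep = score.reshape(n_proteins, -1).max(axis=1) > 0
    score = score[keep]
    n_proteins = score.shape[0]
    return RegionMatrix(
        proteins=[f"P{i}" for i in range(n_proteins)],
        regions=[f"R{j}" for j in range(n_regions)],
        replicates=[f"rep{k}" for k in range(n_replicates)],
        score=score,
        peptide_count=(score > 0).astype(int),
    )


class TestBuildMatrix:
    def test_single_region_detection(self):
        res = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        matrix = build_matrix([res], regions=DEFAULT_REGIONS)
        assert matrix.proteins == ["P1"]
        i = matrix.regions.index("thalamus")
        assert matrix.score[0, i, 0] == 15.0
        assert np.count_nonzero(matrix.score) == 1

    def test_two_replicates_fill_independent_cells(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("thalamus", "rat2", {"P1": (30.0, 3)})
        matrix = build_matrix([r1, r2], regions=["thalamus"])
        assert sorted(matrix.score[0, 0, :]) == [15.0, 30.0]

    def test_empty_results_error(self):
        with pytest.raises(ValidationError):
            build_matrix([])

    def test_duplicate_region_replicate_error(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("thalamus", "rat1", {"P2": (10.0, 1)})
        with pytest.raises(ValidationError, match="duplicate"):
            build_matrix([r1, r2])

    def test_lexicographic_protein_order(self):
        res = result_with(
            "thalamus", "rat1", {"PB": (1.0, 1), "PA": (2.0, 1)}
        )
        matrix = build_matrix([res], regions=["thalamus"])
        assert matrix.proteins == ["PA", "PB"]


class TestCallRegions:
    def test_unique_in_exactly_one_region(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("amygdala", "rat1", {"P2": (10.0, 1)})
        matrix = build_matrix([r1, r2], regions=["thalamus", "amygdala"])
        calls = call_regions(matrix)
        assert calls.unique_per_region["thalamus"] == {"P1"}
        assert calls.unique_per_region["amygdala"] == {"P2"}

    def test_shared_protein_not_unique(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("amygdala", "rat1", {"P1": (10.0, 1)})
        matrix = build_matrix([r1, r2], regions=["thalamus", "amygdala"])
        calls = call_regions(matrix)
        assert calls.detected_per_region["thalamus"] == {"P1"}
        assert calls.detected_per_region["amygdala"] == {"P1"}
        assert calls.unique_per_region["thalamus"] == set()
        assert calls.unique_per_region["amygdala"] == set()

    def test_total_peptides_with_redundancy(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("amygdala", "rat1", {"P1": (10.0, 3)})
        matrix = build_matrix([r1, r2], regions=["thalamus", "amygdala"])
        calls = call_regions(matrix)
        assert calls.total_proteins == 1
        assert calls.total_peptides == 5

    def test_min_replicates_knob(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("thalamus", "rat2", {})
        matrix = build_matrix([r1, r2], regions=["thalamus"])
        assert call_regions(matrix, min_replicates=1).detected_per_region[
            "thalamus"
        ] == {"P1"}
        assert (
            call_regions(matrix, min_replicates=2).detected_per_region[
                "thalamus"
            ]
            == set()
        )

    def test_invariants_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            matrix = make_random_matrix(rng)
            if not matrix.proteins:
                continue
            calls = call_regions(matrix)
            regions = matrix.regions
            for r in regions:
                assert (
                    calls.unique_per_region[r]
                    <= calls.detected_per_region[r]
                )
            for i, r1 in enumerate(regions):
                for r2 in regions[i + 1 :]:
                    assert not (
                        calls.unique_per_region[r1]
                        & calls.unique_per_region[r2]
                    )
            assert (
                sum(len(calls.unique_per_region[r]) for r in regions)
                <= calls.total_proteins
            )

    def test_invariant_under_rescaling_and_replicate_permutation(self):
        rng = np.random.default_rng(8)
        matrix = make_random_matrix(rng)
        base = call_regions(matrix)
        scaled = RegionMatrix(
            proteins=matrix.proteins,
            regions=matrix.regions,
            replicates=matrix.replicates,
            score=matrix.score * 7.3,
            peptide_count=matrix.peptide_count,
        )
        permuted = RegionMatrix(
            proteins=matrix.proteins,
            regions=matrix.regions,
            replicates=list(reversed(matrix.replicates)),
            score=matrix.score[:, :, ::-1],
            peptide_count=matrix.peptide_count[:, :, ::-1],
        )
        for other in (scaled, permuted):
            calls = call_regions(other)
            assert calls.detected_per_region == base.detected_per_region
            assert calls.unique_per_region == base.unique_per_region


def anova_oracle(groups):
    """Textbook sum-of-squares one-way ANOVA."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


def matrix_from_groups(groups):
    score = np.array(groups)[np.newaxis, :, :]
    return RegionMatrix(
        proteins=["P1"],
        regions=[f"R{j}" for j in range(len(groups))],
        replicates=[f"rep{k}" for k in range(len(groups[0]))],
        score=score,
        peptide_count=(score > 0).astype(int),
    )


class TestCompareScores:
    def test_identical_scores_give_f_zero_p_one(self):
        matrix = matrix_from_groups([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        comp = compare_scores(matrix, "P1")
        assert comp.computable
        assert comp.anova_f == 0.0
        assert comp.anova_p == 1.0

    def test_separated_groups_significant(self):
        # oracle: F = 15000, p = 2.67e-8
        matrix = matrix_from_groups([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        comp = compare_scores(matrix, "P1")
        assert comp.anova_f == pytest.approx(15000.0)
        assert comp.anova_p == pytest.approx(2.6654818961636e-08, rel=1e-9)
        assert comp.anova_p < 0.05

    def test_bonferroni_never_below_raw_and_capped(self):
        rng = np.random.default_rng(4)
        groups = [rng.uniform(0, 50, size=3) for _ in range(4)]
        matrix = matrix_from_groups([list(g) for g in groups])
        comp = compare_scores(matrix, "P1")
        n_pairs = 6
        for (r1, r2), adj in comp.pairwise.items():
            i, j = int(r1[1:]), int(r2[1:])
            raw = sps.ttest_ind(groups[i], groups[j]).pvalue
            assert adj >= raw - 1e-12
            assert adj <= 1.0
            assert adj == pytest.approx(min(1.0, raw * n_pairs))

    def test_insufficient_replication_flagged(self):
        score = np.array([[[5.0], [7.0]]])
        matrix = RegionMatrix(
            proteins=["P1"],
            regions=["R0", "R1"],
            replicates=["rep0"],
            score=score,
            peptide_count=(score > 0).astype(int),
        )
        comp = compare_scores(matrix, "P1")
        assert not comp.computable
        assert comp.reason

    def test_anova_matches_oracle_on_50_random_datasets(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(2, 6))
            groups = [rng.uniform(1, 100, size=n) for _ in range(k)]
            matrix = matrix_from_groups([list(g) for g in groups])
            comp = compare_scores(matrix, "P1")
            f_exp, p_exp = anova_oracle(groups)
            assert comp.anova_f == pytest.approx(f_exp, rel=1e-10)
            assert comp.anova_p == pytest.approx(p_exp, rel=1e-10)


class TestSummarize:
    def test_region_abundant_total(self):
        # planted unique counts 63/38/14/66/24/36 -> total 241
        unique_counts = [63, 38, 14, 66, 24, 36]
        detected = {
            r: {f"{r}_{i}" for i in range(c + 10)}
            for r, c in zip(DEFAULT_REGIONS, unique_counts)
        }
        unique = {
            r: {f"{r}_{i}" for i in range(c)}
            for r, c in zip(DEFAULT_REGIONS, unique_counts)
        }
        from regioprot.region_compare import RegionCallSet

        callset = RegionCallSet(
            detected_per_region=detected,
            unique_per_region=unique,
            total_proteins=515,
            total_peptides=2909,
        )
        n = sum(len(v) for v in detected.values())
        score = np.zeros((1, 6, 3))
        score[0, 0, :] = 5.0
        matrix = RegionMatrix(
            proteins=["P1"],
            regions=list(DEFAULT_REGIONS),
            replicates=["rat1", "rat2", "rat3"],
            score=score,
            peptide_count=(score > 0).astype(int),
        )
        region_df, protein_df = summarize(matrix, callset)
        assert region_df.attrs["region_abundant_total"] == 241
        assert region_df.attrs["region_abundant_total"] > 200
        assert region_df["n_unique"].tolist() == unique_counts

    def test_empty_unique_sets(self):
        r1 = result_with("thalamus", "rat1", {"P1": (15.0, 2)})
        r2 = result_with("amygdala", "rat1", {"P1": (10.0, 1)})
        matrix = build_matrix([r1, r2], regions=["thalamus", "amygdala"])
        calls = call_regions(matrix)
        region_df, _ = summarize(matrix, calls)
        assert region_df.attrs["region_abundant_total"] == 0

    def test_mean_and_se(self):
        matrix = matrix_from_groups([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        calls = call_regions(matrix)
        _, protein_df = summarize(matrix, calls)
        row = protein_df.iloc[0]
        assert row["R0_mean"] == pytest.approx(2.0)
        assert row["R0_se"] == pytest.approx(1.0 / np.sqrt(3))


class TestRecountSummary:
    def test_recount_matches_hand_construction(self, tmp_path):
        from regioprot.io_formats import read_protein_summary

        path = tmp_path / "summary.tsv"
        path.write_text(
            "accession\tgene_symbol\tlocalization\t"
            "thalamus_peptides\thippocampus_peptides\n"
            "P1\tG1\tM\t2\t0\n"
            "P2\tG2\tCy\t1\t3\n"
            "P3\tG3\tND\t0\t4\n"
        )
        calls = recount_summary(read_protein_summary(path))
        assert calls.detected_per_region["thalamus"] == {"P1", "P2"}
        assert calls.unique_per_region["thalamus"] == {"P1"}
        assert calls.unique_per_region["hippocampus"] == {"P3"}
        assert calls.total_proteins == 3
        assert calls.total_peptides == 10
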