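import numpy as np
import pandas as pd
import pytest

from pigmentrial.panel import (
    GradeValidationError,
    ICCError,
    icc_by_visit,
    icc_two_way_random,
    intergrader_icc,
    method_correlation,
    panel_scores,
    per_grader_means,
)


def grade_table(rows):
    return pd.DataFrame(
        rows, columns=["participant", "eye", "visit_month", "grader_id", "image_index", "grade"]
    )


def matrix_to_grades(matrix, eye="OD", visit=0):
    """Participants x graders matrix -> one grade record per cell."""
    rows = []
    for i, row in enumerate(matrix):
        for g, val in enumerate(row):
            rows.append((f"P{i:03d}", eye, visit, f"G{g:02d}", 1, float(val)))
    return grade_table(rows)


# --- independent longhand oracle -------------------------------------------

def icc_absolute_agreement_oracle(matrix):
    """Two-way ANOVA variance components by explicit summation."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    grand = matrix.sum() / (n * k)
    ssr = sum(k * (matrix[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (matrix[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((matrix[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


WORKED_MATRIX = np.array(
    [
        [4.2, 4.8, 4.5],
        [2.1, 2.6, 2.0],
        [6.6, 7.0, 6.9],
        [3.3, 3.9, 3.5],
        [5.0, 5.8, 5.4],
    ]
)


class TestPanelScores:
    def test_constant_panel(self):
        rows = [
            ("P001", "OD", 0, f"G{g:02d}", j, 5.0)
            for g in range(18) for j in (1, 2)
        ]
        table = panel_scores(grade_table(rows))
        assert table["panel_score"].iloc[0] == pytest.approx(5.0)
        assert table["n_graders_used"].iloc[0] == 18

    def test_two_stage_mean_hand_example(self):
        # grader A: 4.0 & 5.0 -> 4.5; grader B: 6.0 & 7.0 -> 6.5; panel 5.5
        rows = [
            ("P001", "OD", 0, "A", 1, 4.0),
            ("P001", "OD", 0, "A", 2, 5.0),
            ("P001", "OD", 0, "B", 1, 6.0),
            ("P001", "OD", 0, "B", 2, 7.0),
        ]
        table = panel_scores(grade_table(rows))
        assert table["panel_score"].iloc[0] == pytest.approx(5.5)

    def test_two_stage_differs_from_pooled_mean_when_unbalanced(self):
        # grader A graded one image, grader B two: per-grader means first
        rows = [
            ("P001", "OD", 0, "A", 1, 2.0),
            ("P001", "OD", 0, "B", 1, 6.0),
            ("P001", "OD", 0, "B", 2, 8.0),
        ]
        table = panel_scores(grade_table(rows))
        assert table["panel_score"].iloc[0] == pytest.approx((2.0 + 7.0) / 2)

    def test_permutation_invariance(self, rng):
        rows = [
            ("P001", "OD", 0, f"G{g:02d}", j, float(np.round(rng.uniform(0, 8), 1)))
            for g in range(6) for j in (1, 2)
        ]
        df = grade_table(rows)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        pd.testing.assert_frame_equal(panel_scores(df), panel_scores(shuffled))

    @pytest.mark.parametrize("bad", [-0.1, 8.1, 3.25, np.nan])
    def test_invalid_grades_rejected(self, bad):
        rows = [("P001", "OD", 0, "A", 1, bad), ("P001", "OD", 0, "B", 1, 4.0)]
        with pytest.raises(GradeValidationError):
            per_grader_means(grade_table(rows))


class TestICC:
    def test_perfect_agreement(self):
        matrix = np.tile(np.array([[1.0], [3.0], [5.0], [7.0]]), (1, 6))
        res = intergrader_icc(matrix_to_grades(matrix), "OD", 0)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_worked_matrix_matches_longhand_oracle(self):
        icc1, lo, hi, icck, lok, hik = icc_two_way_random(WORKED_MATRIX)
        assert icc1 == pytest.approx(icc_absolute_agreement_oracle(WORKED_MATRIX), abs=1e-10)
        assert lo <= icc1 <= hi
        assert icc1 <= icck

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        n, k = WORKED_MATRIX.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": WORKED_MATRIX.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        icc1, lo, hi, icck, lok, hik = icc_two_way_random(WORKED_MATRIX)
        assert icc1 == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        # pingouin reports CI bounds rounded to 2 decimals
        assert (lo, hi) == pytest.approx(tuple(ref.loc["ICC(A,1)", "CI95"]), abs=6e-3)
        assert icck == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-9)
        assert (lok, hik) == pytest.approx(tuple(ref.loc["ICC(A,k)", "CI95"]), abs=6e-3)

    def test_null_panel_icc_near_zero(self, rng):
        matrix = np.round(np.clip(rng.normal(4.0, 1.0, size=(200, 6)), 0, 8), 1)
        res = intergrader_icc(matrix_to_grades(matrix), "OD", 0)
        assert abs(res.icc) < 0.05

    def test_single_leq_average_measure(self, rng):
        matrix = rng.normal(4.0, 1.0, size=(10, 5)) + np.arange(10)[:, None] * 0.5
        icc1, _, _, icck, _, _ = icc_two_way_random(matrix)
        assert icc1 <= icck

    def test_constant_grades_undefined(self):
        matrix = np.full((5, 4), 3.0)
        with pytest.raises(ICCError, match="constant"):
            icc_two_way_random(matrix)

    def test_missing_cells_strict_by_default(self):
        grades = matrix_to_grades(WORKED_MATRIX)
        grades = grades[~((grades["participant"] == "P000") & (grades["grader_id"] == "G00"))]
        with pytest.raises(ICCError, match="incomplete"):
            intergrader_icc(grades, "OD", 0)
        res = intergrader_icc(grades, "OD", 0, allow_missing=True)
        assert res.n_participants == WORKED_MATRIX.shape[0] - 1

    def test_icc_decreases_with_grader_noise(self, rng):
        signal = rng.normal(4.0, 1.0, size=(80, 1))
        iccs = []
        for noise_sd in (0.1, 0.5, 1.5):
            matrix = np.clip(signal + rng.normal(0, noise_sd, size=(80, 8)), 0, 8)
            iccs.append(icc_two_way_random(matrix)[0])
        assert iccs[0] > iccs[1] > iccs[2]

    def test_icc_by_visit_covers_all_strata(self, noisy_bundle):
        table = icc_by_visit(noisy_bundle.grades)
        visits = noisy_bundle.grades["visit_month"].nunique()
        assert len(table) == 2 * visits
        assert (table["n_graders"] == 18).all()


class TestMethodCorrelation:
    @staticmethod
    def paired_tables(panel_vals, semi_vals):
        base = pd.DataFrame(
            {
                "participant": [f"P{i}" for i in range(len(panel_vals))],
                "eye": "OD",
                "visit_month": 0,
            }
        )
        panel = base.assign(panel_score=panel_vals)
        semi = base.assign(semiquant_score=semi_vals)
        return panel, semi

    def test_monotone_transform_gives_one(self):
        panel, semi = self.paired_tables([1, 2, 3, 5, 7], [0.1, 0.4, 0.9, 2.5, 6.3])
        assert method_correlation(panel, semi) == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        panel, semi = self.paired_tables([1, 2, 3, 5, 7], [6.3, 2.5, 0.9, 0.4, 0.1])
        assert method_correlation(panel, semi) == pytest.approx(-1.0)

    def test_worked_six_pairs_matches_midrank_oracle(self):
        x = [3.0, 1.0, 4.0, 4.0, 5.0, 2.0]
        y = [2.5, 1.0, 3.0, 5.0, 5.0, 1.5]

        def midranks(v):
            v = np.asarray(v, dtype=float)
            ranks = np.empty(len(v))
            for i, vi in enumerate(v):
                less = np.sum(v < vi)
                ties = np.sum(v == vi)
                ranks[i] = less + (ties + 1) / 2.0
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        panel, semi = self.paired_tables(x, y)
        assert method_correlation(panel, semi) == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        panel, semi = self.paired_tables([1, 2], [1, 2])
        with pytest.raises(ValueError, match=">=3"):
            method_correlation(panel, semi)
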