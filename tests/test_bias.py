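"""Relative abundance, seven-category classification and shift tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadscope.bias import (
    CATEGORIES,
    CENTROIDS,
    classify_bias,
    compute_bias,
    log_transform,
    relative_abundance,
    select_complete_triads,
    shift_table,
    ternary_coordinates,
)
from triadscope.errors import ConfigurationError, ValidationError
from triadscope.roster import SUBGENOMES

from conftest import make_matrix, make_triad

simplex_points = st.tuples(
    st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(0.001, 1.0)
).map(lambda t: tuple(x / sum(t) for x in t))


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)),
            ((2, 1, 1), (0.5, 0.25, 0.25)),
        ],
    )
    def test_normalisation(self, triplet, expected):
        assert relative_abundance(triplet) == pytest.approx(expected)

    def test_below_threshold_is_not_expressed(self):
        assert relative_abundance((0, 0, 0), min_total_tpm=0.5) is None
        assert relative_abundance((0.1, 0.1, 0.1), min_total_tpm=0.5) is None

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError):
            relative_abundance((-1, 2, 3))

    @settings(max_examples=100, deadline=None)
    @given(simplex_points)
    def test_expressed_output_sums_to_one(self, rel):
        scaled = tuple(100 * r for r in rel)
        out = relative_abundance(scaled)
        assert out is not None
        assert abs(out.sum() - 1.0) < 1e-9


class TestClassifyBias:
    def test_each_centroid_classifies_to_itself(self):
        assert len(CATEGORIES) == 7
        for cat, centroid in CENTROIDS.items():
            assert classify_bias(centroid) == cat

    def test_near_boundary_suppressed_point(self):
        # nearest centroid of (0.05, 0.475, 0.475) is (0, 0.5, 0.5)
        assert classify_bias((0.05, 0.475, 0.475)) == "A_suppressed"

    def test_balanced_radius_overrides_nearest_centroid(self):
        point = (0.15, 0.425, 0.425)  # nearest centroid is A_suppressed
        assert classify_bias(point) == "A_suppressed"
        assert classify_bias(point, balanced_radius=0.3) == "Balanced"

    def test_off_simplex_rejected(self):
        with pytest.raises(ValidationError):
            classify_bias((0.5, 0.5, 0.5))

    def test_scale_free_via_relative_abundance(self):
        for scale in (1.0, 17.3, 4000.0):
            rel = relative_abundance((scale * 8, scale * 1, scale * 1))
            assert classify_bias(rel) == "A_dominant"

    @settings(max_examples=200, deadline=None)
    @given(simplex_points, st.permutations([0, 1, 2]))
    def test_subgenome_permutation_equivariance(self, rel, perm):
        """Permuting (r_A, r_B, r_D) permutes the category label identically."""
        base = classify_bias(rel)
        permuted = classify_bias(tuple(rel[i] for i in perm))
        if base == "Balanced":
            assert permuted == "Balanced"
        else:
            sub, kind = base.split("_")
            idx = "ABD".index(sub)
            new_idx = perm.index(idx)
            assert permuted == f"{'ABD'[new_idx]}_{kind}"


class TestTernaryCoordinates:
    @pytest.mark.parametrize(
        "rel,xy",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, np.sqrt(3) / 2)),
            ((1 / 3, 1 / 3, 1 / 3), (0.5, np.sqrt(3) / 6)),
        ],
    )
    def test_corners_and_centroid(self, rel, xy):
        assert ternary_coordinates(rel) == pytest.approx(xy)

    @settings(max_examples=100, deadline=None)
    @given(simplex_points)
    def test_round_trip_inverts(self, rel):
        x, y = ternary_coordinates(rel)
        r_d = 2.0 * y / np.sqrt(3.0)
        r_b = x - r_d / 2.0
        r_a = 1.0 - r_b - r_d
        assert (r_a, r_b, r_d) == pytest.approx(rel, abs=1e-12)


class TestLogTransform:
    def test_log2_plus_one_and_missing_preserved(self):
        m = make_matrix(
            {"h1": {"s1": 0.0, "s2": 7.0}, "h2": {"s1": 1.0, "s2": np.nan}},
            {"s1": "control", "s2": "control"},
        )
        out = log_transform(m)
        assert out.values.loc["h1", "s1"] == 0.0
        assert out.values.loc["h1", "s2"] == 3.0
        assert out.values.loc["h2", "s1"] == 1.0
        assert np.isnan(out.values.loc["h2", "s2"])


def _triads_and_matrix(n=5, missing_d_in=None, conditions=("control",)):
    triads = [make_triad(gene=f"g{i}") for i in range(n)]
    tpm = {}
    for i, t in enumerate(triads):
        for s in SUBGENOMES:
            hid = t.members[s].homoeolog_id
            if i == missing_d_in and s == "D":
                continue
            tpm[hid] = {f"{c}_rep1": 10.0 * (i + 1) for c in conditions}
    meta = {f"{c}_rep1": c for c in conditions}
    return triads, make_matrix(tpm, meta)


class TestSelectCompleteTriads:
    def test_missing_row_drops_triad(self):
        triads, matrix = _triads_and_matrix(n=5, missing_d_in=2)
        kept = select_complete_triads(matrix, triads)
        assert len(kept) == 4
        assert all(t.gene_name != "g2" for t in kept)

    def test_all_complete_is_identity(self):
        triads, matrix = _triads_and_matrix(n=5)
        assert select_complete_triads(matrix, triads) == triads

    def test_nan_cell_in_scope_drops_triad(self):
        triads, matrix = _triads_and_matrix(n=3, conditions=("control", "stress"))
        hid = triads[1].members["B"].homoeolog_id
        matrix.values.loc[hid, "stress_rep1"] = np.nan
        assert len(select_complete_triads(matrix, triads, conditions=["stress"])) == 2
        assert len(select_complete_triads(matrix, triads, conditions=["control"])) == 3

    def test_unknown_condition_rejected(self):
        triads, matrix = _triads_and_matrix()
        with pytest.raises(ConfigurationError):
            select_complete_triads(matrix, triads, conditions=["nonesuch"])


class TestComputeBias:
    def test_replicates_averaged_before_normalisation(self):
        triad = make_triad(gene="g0")
        tpm = {
            "g0_A": {"s1": 10.0, "s2": 30.0},  # mean 20
            "g0_B": {"s1": 10.0, "s2": 10.0},
            "g0_D": {"s1": 10.0, "s2": 10.0},
        }
        m = make_matrix(tpm, {"s1": "control", "s2": "control"})
        (b,) = compute_bias(m, [triad], "control")
        assert b.rel == pytest.approx((0.5, 0.25, 0.25))

    def test_below_threshold_triad_is_unexpressed(self):
        triad = make_triad(gene="g0")
        m = make_matrix(
            {f"g0_{s}": {"s1": 0.05} for s in SUBGENOMES}, {"s1": "control"}
        )
        (b,) = compute_bias(m, [triad], "control")
        assert not b.expressed
        assert b.category is None


class TestShiftTable:
    def _biases(self, cats, condition):
        triads = [make_triad(gene=f"g{i}") for i in range(len(cats))]
        tpm = {}
        for t, cat in zip(triads, cats):
            rel = CENTROIDS[cat]
            for s, r in zip(SUBGENOMES, rel):
                tpm[t.members[s].homoeolog_id] = {f"{condition}_rep1": 100.0 * r}
        m = make_matrix(tpm, {f"{condition}_rep1": condition})
        return compute_bias(m, triads, condition)

    def test_identical_classifications_are_diagonal(self):
        cats = ["Balanced", "A_dominant", "D_suppressed"]
        t = shift_table(self._biases(cats, "control"), self._biases(cats, "stress"))
        assert t.n_shared == 3
        assert np.trace(t.transitions.to_numpy()) == 3

    def test_single_shift_is_off_diagonal(self):
        t = shift_table(
            self._biases(["Balanced"], "control"),
            self._biases(["B_dominant"], "stress"),
        )
        assert t.transitions.loc["Balanced", "B_dominant"] == 1
        assert t.transitions.to_numpy().sum() == 1

    def test_per_subgenome_tally(self):
        cats = ["Balanced", "D_dominant", "D_dominant", "A_suppressed"]
        t = shift_table(self._biases(cats, "control"), self._biases(cats, "stress"))
        tally = t.per_subgenome["control"]
        assert tally["D"]["dominant"] == 2
        assert tally["A"]["suppressed"] == 1
        assert tally["balanced"] == 1

    def test_duplicate_gene_rejected(self):
        b = self._biases(["Balanced"], "control")
        with pytest.raises(ValidationError, match="duplicate"):
            shift_table(b + b, b)
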