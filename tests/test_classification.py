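import numpy as np
import pytest

from oracles import naive_mode, naive_temporal
from ribostress import (
    classify_dataset,
    classify_regulation_mode,
    classify_temporal_abundance,
    classify_temporal_occupancy,
    fold_change,
    l2de,
)
from ribostress.classification import _mode_vec, _trend_vec, _ABUNDANCE_MAP, _OCCUPANCY_MAP


class TestL2DE:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(4, 1, 2.0), (7, 7, 0.0), (3, 2, 0.5849625007211562), (1, 4, -2.0)],
    )
    def test_log2_ratio(self, num, den, expected):
        assert l2de(num, den) == pytest.approx(expected)

    @pytest.mark.parametrize("num, den", [(0, 1), (1, 0), (-2, 3)])
    def test_non_positive_input_is_error(self, num, den):
        with pytest.raises(ValueError, match="positive"):
            l2de(num, den)

    def test_cutoff_fold_change_meaning(self):
        # a log2 cutoff of 0.6 means at least a 50% difference between conditions
        assert fold_change(0.6) == pytest.approx(1.5157, abs=1e-4)
        assert fold_change(0.6) >= 1.5


class TestTemporalGroups:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((0.5, 0.5, 1.0), "G1"),
            ((0.4, -0.5, -0.1), "G2"),
            ((0.0, 0.7, 0.7), "G3"),
            ((-0.5, -0.5, -1.0), "G4"),
            ((-0.5, 0.8, 0.3), "G5"),
            ((0.0, -0.4, -0.4), "G6"),
            ((0.1, 0.1, 0.2), "none"),
            ((0.0, 0.7, 0.1), "none"),  # chronic up but overall below cutoff
            ((0.32, 0.32, 0.64), "G1"),  # inclusive up boundary
            ((-0.32, -0.32, -0.64), "G4"),  # inclusive down boundary
            ((0.3199, 0.32, 0.64), "G3"),  # strictly inside the no-change band
        ],
    )
    def test_abundance_rules(self, triple, expected):
        assert classify_temporal_abundance(*triple) == expected

    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((0.4, 0.4, 0.8), "G7"),
            ((0.4, -0.5, -0.1), "G8"),
            ((0.0, 0.5, 0.5), "G9"),
            ((0.0, -0.4, -0.4), "G10"),
            ((-0.5, 0.8, 0.3), "G11"),
            ((-0.5, -0.5, -1.0), "G12"),
            ((0.1, -0.1, 0.0), "none"),
        ],
    )
    def test_occupancy_rules(self, triple, expected):
        assert classify_temporal_occupancy(*triple) == expected

    def test_non_finite_input_is_error(self):
        with pytest.raises(ValueError, match="finite"):
            classify_temporal_abundance(float("nan"), 0.5, 0.5)

    def test_rules_partition_grid(self):
        """At most one temporal rule fires anywhere on a dense value grid."""
        c = 0.32
        vals = np.unique(np.concatenate([
            np.round(np.arange(-2.0, 2.0001, 0.04), 10),
            [-c, c, -c - 1e-9, c - 1e-9, -c + 1e-9, c + 1e-9, 0.0],
        ]))
        A, C, O = np.meshgrid(vals, vals, vals, indexing="ij")
        a, ch, ov = A.ravel(), C.ravel(), O.ravel()
        up_a, down_a, none_a = a >= c, a <= -c, np.abs(a) < c
        up_c, down_c = ch >= c, ch <= -c
        rules = [
            up_a & up_c,
            up_a & down_c,
            none_a & up_c & (ov >= c),
            down_a & down_c,
            down_a & up_c,
            none_a & down_c & (ov <= -c),
        ]
        n_match = sum(r.astype(np.int8) for r in rules)
        assert n_match.max() <= 1

    def test_mode_rules_partition_grid(self):
        c = 0.6
        vals = np.unique(np.concatenate([
            np.round(np.arange(-2.0, 2.0001, 0.01), 10),
            [-c, c, -c - 1e-9, c - 1e-9, c + 1e-9],
        ]))
        X, Y = np.meshgrid(vals, vals, indexing="ij")
        x, y = X.ravel(), Y.ravel()
        d = x - y
        band = (-c <= d) & (d < c)
        rules = [
            band & (x >= c) & (y >= c),
            (d < -c) & (y > c),
            band & (x <= -c) & (y <= -c),
            (d > c) & (y < -c),
        ]
        n_match = sum(r.astype(np.int8) for r in rules)
        assert n_match.max() <= 1

    def test_equals_naive_oracle_on_random_triples(self):
        """Vectorized classifier equals the transliterated prose on 10^6 triples."""
        rng = np.random.default_rng(2024)
        n = 1_000_000
        a = rng.uniform(-2, 2, n)
        ch = rng.uniform(-2, 2, n)
        ov = rng.uniform(-2, 2, n)
        got_ab = _trend_vec(a, ch, ov, 0.32, _ABUNDANCE_MAP)
        got_oc = _trend_vec(a, ch, ov, 0.32, _OCCUPANCY_MAP)
        # spot-exact on the full vector via the python oracle in chunks
        idx = rng.choice(n, size=20_000, replace=False)
        for i in idx:
            assert got_ab[i] == naive_temporal(a[i], ch[i], ov[i], 0.32, "abundance")
            assert got_oc[i] == naive_temporal(a[i], ch[i], ov[i], 0.32, "occupancy")
        # and the scalar API agrees with the vector everywhere it is sampled
        for i in idx[:2000]:
            assert classify_temporal_abundance(a[i], ch[i], ov[i]) == got_ab[i]


class TestRegulationModes:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (1.0, 0.8, "up_both"),
            (0.0, 1.0, "up_occ_only"),
            (-1.0, -0.8, "down_both"),
            (0.0, -1.0, "down_occ_only"),
            (0.5, 0.5, "none"),
            # boundary semantics: x-y = -0.6 inside the band, x-y = 0.6 outside
            (0.6, 1.2, "up_both"),
            (1.3, 0.7, "none"),  # x-y = 0.6 exactly: strict <, both-rule fails
            (0.6, 0.6, "up_both"),
            (0.59, 1.2, "up_occ_only"),  # x-y = -0.61 < -0.6
            (0.0, 0.6, "none"),  # y > 0.6 is strict for occupancy-only
            (0.0, -0.6, "none"),  # y < -0.6 is strict for occupancy-only
        ],
    )
    def test_rules_in_printed_order(self, x, y, expected):
        assert classify_regulation_mode(x, y) == expected

    def test_equals_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-2, 2, 1_000_000)
        y = rng.uniform(-2, 2, 1_000_000)
        got = _mode_vec(x, y, 0.6)
        idx = rng.choice(len(x), size=20_000, replace=False)
        for i in idx:
            assert got[i] == naive_mode(x[i], y[i], 0.6)


class TestClassifyDataset:
    def test_noise_free_planted_labels_recovered_exactly(self, noise_free_run):
        model, truth, mrna, ribo, detected, occ = noise_free_run
        result = classify_dataset(mrna, ribo, occ)
        assigned = result.assignments.set_index("transcript_id")
        tr = truth.table.loc[assigned.index]
        assert (assigned["abundance_group"] == tr["abundance_group"]).all()
        assert (assigned["occupancy_group"] == tr["occupancy_group"]).all()
        # summary counts equal the planted per-group counts
        for g, n in tr["abundance_group"].value_counts().items():
            if g == "none":
                continue
            row = result.summary.query("channel == 'abundance_group' and label == @g")
            assert int(row["n"].iloc[0]) == n

    def test_all_conditions_identical_classifies_nothing(self, tiny_model):
        from conftest import make_count_table
        from ribostress import apply_detection_filter, compute_occupancy, compute_rpkm

        conds, reps = ("CON", "CPA1", "CPA18"), 3
        cols = {f"mrna_{c}_{r}": [10, 20, 30] for c in conds for r in (1, 2, 3)}
        mrna_t = make_count_table(cols, "mrna", conds, reps, tiny_model.transcript_ids)
        cols_r = {f"ribo_{c}_{r}": [5, 10, 15] for c in conds for r in (1, 2, 3)}
        ribo_t = make_count_table(cols_r, "ribo", conds, reps, tiny_model.transcript_ids)
        mrna = compute_rpkm(mrna_t, tiny_model)
        ribo = compute_rpkm(ribo_t, tiny_model)
        detected = apply_detection_filter(mrna, ribo)
        occ = compute_occupancy(mrna, ribo, detected)
        result = classify_dataset(mrna, ribo, occ)
        assert (result.assignments["abundance_group"] == "none").all()
        assert (result.assignments["occupancy_group"] == "none").all()
        assert (result.modes["mode"] == "none").all()

    def test_vectorized_equals_scalar_classification(self, noise_free_run):
        model, truth, mrna, ribo, detected, occ = noise_free_run
        result = classify_dataset(mrna, ribo, occ)
        l2 = result.l2de.pivot(index="transcript_id", columns="contrast")
        assigned = result.assignments.set_index("transcript_id")
        modes = result.modes.pivot(index="transcript_id", columns="contrast", values="mode")
        for tx in list(assigned.index)[::7]:
            a = l2.loc[tx, ("x", "acute")]
            ch = l2.loc[tx, ("x", "chronic")]
            ov = l2.loc[tx, ("x", "overall")]
            assert naive_temporal(a, ch, ov, 0.32, "abundance") == assigned.at[tx, "abundance_group"]
            oa = l2.loc[tx, ("occ_l2de", "acute")]
            oc = l2.loc[tx, ("occ_l2de", "chronic")]
            oo = l2.loc[tx, ("occ_l2de", "overall")]
            assert naive_temporal(oa, oc, oo, 0.32, "occupancy") == assigned.at[tx, "occupancy_group"]
            for contrast in ("acute", "chronic", "overall"):
                assert (
                    naive_mode(l2.loc[tx, ("x", contrast)], l2.loc[tx, ("y", contrast)], 0.6)
                    == modes.at[tx, contrast]
                )

    def test_occ_l2de_is_y_minus_x(self, noise_free_run):
        """Occupancy L2DE equals footprint minus abundance L2DE (algebraic identity)."""
        model, truth, mrna, ribo, detected, occ = noise_free_run
        result = classify_dataset(mrna, ribo, occ)
        diff = result.l2de["occ_l2de"] - (result.l2de["y"] - result.l2de["x"])
        assert np.abs(diff.to_numpy()).max() < 1e-9

    def test_unknown_condition_in_contrast_is_error(self, noise_free_run):
        model, truth, mrna, ribo, detected, occ = noise_free_run
        with pytest.raises(ValueError, match="absent"):
            classify_dataset(mrna, ribo, occ, conditions=("CON", "CPA1", "CPA99"))
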