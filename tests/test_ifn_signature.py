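import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ifnsig.deg_analysis import per_patient_log2fc
from ifnsig.ifn_signature import (
    batch_center,
    compare_fc_by_outcome,
    score_dynamics,
    signature_score,
    signature_scores,
    zscore,
)
from ifnsig.io_formats import GeneSetCollection
from ifnsig.synthetic_data import default_study_design, generate_cohort

from conftest import make_expression, paired_metadata, swap_timepoints


class TestBatchCenter:
    def test_single_batch_identity(self):
        expr = make_expression(
            np.arange(8.0).reshape(2, 4), sample_ids=[f"P{i}_pre" for i in range(4)]
        )
        meta = paired_metadata([])
        rows = []
        for i in range(4):
            rows.append([f"P{i}_pre", f"P{i}", "pre", "BRT", "survivor", "b0"])
        from conftest import make_metadata

        meta = make_metadata(rows)
        centered = batch_center(expr, meta)
        np.testing.assert_array_equal(centered.values, expr.values)

    def _two_batch(self):
        rng = np.random.default_rng(0)
        expr = make_expression(
            rng.normal(size=(5, 6)), sample_ids=[f"P{i}_pre" for i in range(6)]
        )
        from conftest import make_metadata

        rows = [
            [f"P{i}_pre", f"P{i}", "pre", "BRT", "survivor", "b0" if i < 3 else "b1"]
            for i in range(6)
        ]
        return expr, make_metadata(rows)

    def test_batch_means_zero_after_centering(self):
        expr, meta = self._two_batch()
        centered = batch_center(expr, meta)
        np.testing.assert_allclose(centered.values[:, :3].mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(centered.values[:, 3:].mean(axis=1), 0, atol=1e-12)

    def test_idempotence(self):
        expr, meta = self._two_batch()
        once = batch_center(expr, meta)
        twice = batch_center(once, meta)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_planted_offsets_removed(self):
        cohort = generate_cohort(default_study_design(seed=3))
        centered = batch_center(cohort.expression, cohort.metadata)
        batch_of = cohort.metadata.attr_of_sample("batch")
        cols = {b: [] for b in set(batch_of.values())}
        for j, s in enumerate(centered.sample_ids):
            cols[batch_of[s]].append(j)
        means = [centered.values[:, c].mean(axis=1) for c in cols.values()]
        np.testing.assert_allclose(means[0], means[1], atol=1e-12)


class TestZScore:
    def test_simple_row(self):
        z = zscore(make_expression([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.z[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        z = zscore(make_expression(rng.normal(5, 3, size=(40, 7))))
        np.testing.assert_allclose(z.z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_zero_variance_gene_listed(self):
        with pytest.raises(ValueError, match="g1"):
            zscore(make_expression([[2.0, 2.0], [1.0, 3.0]], gene_ids=("g1", "g2")))

    def test_population_denominator_option(self):
        z = zscore(make_expression([[1.0, 2.0, 3.0]]), ddof=0)
        np.testing.assert_allclose(z.z.std(axis=1, ddof=0), 1, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        values=arrays(
            float,
            (6, 5),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-20, 20),
    )
    def test_affine_invariance(self, values, a, b):
        sds = values.std(axis=1, ddof=1)
        if np.any(sds < 1e-6):
            return
        z1 = zscore(make_expression(values))
        z2 = zscore(make_expression(a * values + b))
        np.testing.assert_allclose(z1.z, z2.z, atol=1e-6)


class TestSignatureScore:
    def test_balanced_zero(self):
        z = zscore(make_expression([[0.5, -0.5], [-0.5, 0.5]]))
        # construct a z matrix directly with known values instead
        from ifnsig.ifn_signature import ZScoreMatrix

        zm = ZScoreMatrix(("g1", "g2"), ("s1",), np.array([[0.5], [-0.5]]))
        s = signature_score(zm, ["g1", "g2"])
        assert s["s1"] == pytest.approx(0.0)

    def test_hand_arithmetic_with_signs(self):
        from ifnsig.ifn_signature import ZScoreMatrix

        zm = ZScoreMatrix(("g1", "g2"), ("s1",), np.array([[1.2], [0.2]]))
        coll = GeneSetCollection(sets={"s": ("g1", "g2")}, signs={"g2": -1})
        s = signature_score(zm, ["g1", "g2"], coll)
        assert s["s1"] == pytest.approx(1.0)
        # brute-force cross-check
        brute = sum(
            coll.sign_of(g) * zm.z[i, 0] for i, g in enumerate(("g1", "g2"))
        )
        assert s["s1"] == pytest.approx(brute)

    def test_sign_flip_negates_scores(self, default_cohort):
        expr, meta = default_cohort.expression, default_cohort.metadata
        z = zscore(batch_center(expr, meta))
        genes = default_cohort.gene_sets["ifn_type_III"]
        plus = signature_score(z, genes)
        flipped = GeneSetCollection(
            sets={"s": genes}, signs={g: -1 for g in genes}
        )
        minus = signature_score(z, genes, flipped)
        np.testing.assert_allclose(minus.to_numpy(), -plus.to_numpy(), atol=1e-12)

    def test_linearity_over_disjoint_union(self, default_cohort):
        expr, meta = default_cohort.expression, default_cohort.metadata
        z = zscore(batch_center(expr, meta))
        a = list(default_cohort.gene_sets["ifn_type_III"])
        b = list(default_cohort.gene_sets["coagulation"])[:7]
        su = signature_score(z, a + b)
        np.testing.assert_allclose(
            su.to_numpy(),
            signature_score(z, a).to_numpy() + signature_score(z, b).to_numpy(),
            atol=1e-10,
        )

    def test_missing_genes_skipped_with_warning(self, default_cohort, caplog):
        expr, meta = default_cohort.expression, default_cohort.metadata
        z = zscore(batch_center(expr, meta))
        genes = list(default_cohort.gene_sets["ifn_type_III"]) + ["NOT_A_GENE"]
        with caplog.at_level("WARNING"):
            s = signature_score(z, genes)
        assert any("NOT_A_GENE" in r.message for r in caplog.records)
        assert len(s) == expr.n_samples

    def test_empty_intersection_rejected(self, default_cohort):
        z = zscore(batch_center(default_cohort.expression, default_cohort.metadata))
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(z, ["NOPE1", "NOPE2"])

    def test_score_bound(self, default_cohort):
        expr, meta = default_cohort.expression, default_cohort.metadata
        z = zscore(batch_center(expr, meta))
        genes = default_cohort.gene_sets["ifn_type_I"]
        s = signature_score(z, genes)
        bound = len(genes) * np.abs(z.z).max()
        assert np.all(np.abs(s.to_numpy()) <= bound + 1e-9)


class TestDynamics:
    def _scores(self, cohort):
        z = zscore(batch_center(cohort.expression, cohort.metadata))
        return signature_scores(z, cohort.gene_sets)

    def test_planted_directions(self, default_cohort):
        scores = self._scores(default_cohort)
        dyn = score_dynamics(scores, default_cohort.metadata)
        tr = dyn["trajectories"]
        for set_name in ("ifn_type_II", "ifn_type_III"):
            sub = tr[tr["set_name"] == set_name]
            dec = sub[sub["outcome"] == "deceased"]
            sur = sub[sub["outcome"] == "survivor"]
            assert (dec["delta"] > 0).all()
            assert (sur["delta"] <= 0).all()
            assert set(dec["direction"]) == {"up"}

    def test_delta_antisymmetric_under_timepoint_swap(self, default_cohort):
        scores = self._scores(default_cohort)
        meta = default_cohort.metadata
        d1 = score_dynamics(scores, meta)["trajectories"]
        d2 = score_dynamics(scores, swap_timepoints(meta))["trajectories"]
        merged = d1.merge(d2, on=["patient_id", "set_name"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["delta_a"], -merged["delta_b"], atol=1e-12
        )

    def test_zero_effect_mean_delta_near_zero(self):
        deltas = []
        for seed in range(8):
            design = default_study_design(seed=seed)
            design = type(design)(
                patients=design.patients,
                n_genes=design.n_genes,
                module_specs=design.module_specs,
                effect_sizes={},
                batch_offsets=design.batch_offsets,
                noise_sd=design.noise_sd,
                baseline_mean_sd=design.baseline_mean_sd,
                seed=seed,
            )
            cohort = generate_cohort(design)
            scores = self._scores(cohort)
            dyn = score_dynamics(scores, cohort.metadata)
            deltas.extend(dyn["trajectories"]["delta"].tolist())
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 3 * se


class TestCompareFcByOutcome:
    def test_planted_separation(self, default_cohort):
        fc = per_patient_log2fc(default_cohort.expression, default_cohort.metadata)
        for name in ("ifn_type_I", "ifn_type_II", "ifn_type_III"):
            rep = compare_fc_by_outcome(
                fc, default_cohort.metadata, default_cohort.gene_sets[name]
            )
            assert rep["groups"] == ("deceased", "survivor")
            assert rep["mean"]["survivor"] < rep["mean"]["deceased"]
            assert rep["p_value"] < 0.05

    def test_identical_groups_give_p_one(self):
        values = np.tile([[1.0, 2.0, 1.0, 2.0]], (5, 1))
        from ifnsig.deg_analysis import FoldChangeMatrix

        fc = FoldChangeMatrix(
            tuple(f"g{i}" for i in range(5)), ("A", "B", "C", "D"), values
        )
        meta = paired_metadata(
            [
                ("A", "BRT", "survivor", "b0"),
                ("B", "BRT", "survivor", "b0"),
                ("C", "TC", "deceased", "b0"),
                ("D", "TC", "deceased", "b0"),
            ]
        )
        rep = compare_fc_by_outcome(fc, meta, [f"g{i}" for i in range(5)])
        assert rep["t"] == pytest.approx(0.0)
        assert rep["p_value"] == pytest.approx(1.0)

    def test_label_exchange_negates_t(self, default_cohort):
        fc = per_patient_log2fc(default_cohort.expression, default_cohort.metadata)
        genes = default_cohort.gene_sets["ifn_type_II"]
        rep = compare_fc_by_outcome(fc, default_cohort.metadata, genes)
        from ifnsig.io_formats import SampleMetadata

        table = default_cohort.metadata.table.copy()
        table["outcome"] = table["outcome"].map(
            {"survivor": "deceased", "deceased": "survivor"}
        )
        swapped = compare_fc_by_outcome(fc, SampleMetadata(table), genes)
        assert swapped["t"] == pytest.approx(-rep["t"], abs=1e-9)
        assert swapped["p_value"] == pytest.approx(rep["p_value"], abs=1e-12)

    def test_tiny_set_rejected(self, default_cohort):
        fc = per_patient_log2fc(default_cohort.expression, default_cohort.metadata)
        with pytest.raises(ValueError, match=">= 2"):
            compare_fc_by_outcome(
                fc, default_cohort.metadata, [default_cohort.expression.gene_ids[0]]
            )


def test_pipeline_order_property(default_cohort):
    """batch_center then zscore leaves each batch's genewise means equal."""
    expr, meta = default_cohort.expression, default_cohort.metadata
    z = zscore(batch_center(expr, meta))
    batch_of = meta.attr_of_sample("batch")
    cols = {}
    for j, s in enumerate(z.sample_ids):
        cols.setdefault(batch_of[s], []).append(j)
    batch_means = [z.z[:, c].mean(axis=1) for c in cols.values()]
    np.testing.assert_allclose(batch_means[0], batch_means[1], atol=1e-9)


def test_direction_recovery_over_seeds():
    """Planted delta directions recovered in >= 95% of 20 seeds."""
    ok = 0
    for seed in range(20):
        cohort = generate_cohort(default_study_design(seed=seed))
        z = zscore(batch_center(cohort.expression, cohort.metadata))
        scores = signature_scores(z, cohort.gene_sets)
        tr = score_dynamics(scores, cohort.metadata)["trajectories"]
        good = True
        for set_name in ("ifn_type_II", "ifn_type_III"):
            sub = tr[tr["set_name"] == set_name]
            good &= (sub[sub["outcome"] == "deceased"]["delta"] > 0).all()
            good &= (sub[sub["outcome"] == "survivor"]["delta"] <= 0).all()
        ok += bool(good)
    assert ok >= 19
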