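"""DVHs, dose metrics, EUD/EQD2 maps, normalization and constraint reports."""

import numpy as np
import pytest

from mrteud import (
    ConstraintSpec,
    Metric,
    VoxelGrid,
    build_histogram,
    constraint_report,
    dose_metric,
    dvh,
    eqd2_map,
    eud_from_histogram,
    eud_map,
    evaluate_constraints,
    normalize_to_reference_d98,
)
from mrteud.errors import ConfigError, GeometryError, InputError
from mrteud.evaluation import resolve_params_arrays
from mrteud.geometry import LabelGrid
from mrteud.microdose import SubvoxelBlock


def grid_of(values):
    values = np.asarray(values, dtype=float)
    return VoxelGrid(values, (2.0, 2.0, 2.0))


# ---------------------------------------------------------------------------
# DVH


class TestDVH:
    def test_uniform_structure_is_a_step(self):
        g = grid_of(np.full((4, 4, 1), 10.0))
        curve = dvh(g, np.ones(g.shape, bool))
        assert curve.volume_pct_at(0.0) == 100.0
        assert curve.volume_pct_at(10.0) == 100.0
        assert curve.volume_pct_at(10.0 + 1e-6) == 0.0

    def test_two_level_structure(self):
        values = np.concatenate([np.full(8, 10.0), np.full(8, 20.0)]).reshape(4, 4, 1)
        curve = dvh(grid_of(values), np.ones((4, 4, 1), bool))
        assert curve.volume_pct_at(5.0) == 100.0
        assert curve.volume_pct_at(15.0) == 50.0
        assert curve.volume_pct_at(25.0) == 0.0

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 60, (10, 10, 4))
        mask = rng.random((10, 10, 4)) < 0.5
        curve = dvh(grid_of(values), mask)
        doses = values[mask]
        for q in rng.uniform(0, 65, 50):
            expected = 100.0 * np.count_nonzero(doses >= q) / doses.size
            assert curve.volume_pct_at(q) == pytest.approx(expected, abs=1e-9)

    def test_monotone_invariants(self):
        rng = np.random.default_rng(1)
        curve = dvh(grid_of(rng.uniform(0, 30, (6, 6, 2))), np.ones((6, 6, 2), bool))
        assert curve.dose[0] == 0.0 and curve.volume_pct[0] == 100.0
        assert np.all(np.diff(curve.volume_pct) <= 0)
        assert curve.volume_pct[-1] == 0.0

    def test_empty_structure_rejected(self):
        with pytest.raises(GeometryError):
            dvh(grid_of(np.ones((2, 2, 1))), np.zeros((2, 2, 1), bool))


# ---------------------------------------------------------------------------
# Dose metrics


class TestDoseMetric:
    def test_uniform_structure_all_metrics_agree(self):
        g = grid_of(np.full((5, 5, 1), 10.0))
        mask = np.ones(g.shape, bool)
        for m in ("Dmax", "Dmean", "D2%", "D98%"):
            assert dose_metric(g, mask, m) == pytest.approx(10.0)

    def test_canonical_1_to_100_case(self):
        g = grid_of(np.arange(1.0, 101.0).reshape(10, 10, 1))
        mask = np.ones(g.shape, bool)
        assert dose_metric(g, mask, "D98%") == pytest.approx(3.0)
        assert dose_metric(g, mask, "D2%") == pytest.approx(99.0)
        assert dose_metric(g, mask, "Dmax") == 100.0
        assert dose_metric(g, mask, "Dmean") == pytest.approx(50.5)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        g = grid_of(rng.gamma(3.0, 5.0, (10, 10, 2)))
        mask = np.ones(g.shape, bool)
        d98 = dose_metric(g, mask, "D98%")
        dmean = dose_metric(g, mask, "Dmean")
        d2 = dose_metric(g, mask, "D2%")
        dmax = dose_metric(g, mask, "Dmax")
        assert d98 <= dmean <= d2 <= dmax

    def test_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 80, (20, 20, 10))  # 4000-voxel structure
        g = grid_of(values)
        mask = rng.random(g.shape) < 0.7
        doses = np.sort(values[mask])[::-1]
        n = doses.size
        for k in (1, 2, n // 4, n // 2, n - 1, n):
            pct = 100.0 * k / n
            assert dose_metric(g, mask, f"D{pct}%") == pytest.approx(doses[k - 1], rel=1e-6)
        # V_dose against counting
        for q in (10.0, 40.0, 79.0):
            expected = 100.0 * np.count_nonzero(doses >= q) / n
            assert dose_metric(g, mask, f"V{q}Gy") == pytest.approx(expected)
        # absolute-volume metric at whole-voxel volumes
        vv = g.voxel_volume_cm3
        for k in (1, 5, n):
            assert dose_metric(g, mask, Metric("dose_at_cc", k * vv)) == pytest.approx(
                doses[k - 1], rel=1e-6
            )

    def test_volume_beyond_structure_rejected(self):
        g = grid_of(np.ones((2, 2, 1)))
        with pytest.raises(InputError):
            dose_metric(g, np.ones(g.shape, bool), Metric("dose_at_cc", 1000.0))

    def test_metric_parsing(self):
        assert Metric.parse("D_max").kind == "dmax"
        assert Metric.parse("Dmean").kind == "dmean"
        assert Metric.parse("D0.1cc") == Metric("dose_at_cc", 0.1)
        assert Metric.parse("D150cm3") == Metric("dose_at_cc", 150.0)
        assert Metric.parse("V20Gy") == Metric("vol_pct_at_dose", 20.0)
        assert Metric.parse("V50%") == Metric("dose_at_pct", 50.0)
        with pytest.raises(ConfigError):
            Metric.parse("Q17")


# ---------------------------------------------------------------------------
# Maps


def constant_block_provider(value, n=70):
    def provider(idx):
        return SubvoxelBlock(idx, np.full(n, value), (n, 1, 1), (0.025, 0.025, 0.025))

    return provider


class TestMaps:
    def test_all_zero_blocks_give_zero_map(self, small_phantom, registry):
        density, labels = small_phantom
        out = eud_map(density, labels, [], registry, block_provider=constant_block_provider(0.0))
        assert np.all(out.values == 0.0)

    def test_uniform_dose_is_reproduced_for_any_tissue(self, small_phantom, registry):
        density, labels = small_phantom
        out = eud_map(
            density, labels, [], registry,
            priority=["PTV", "brain_stem"],
            block_provider=constant_block_provider(5.0),
        )
        np.testing.assert_allclose(out.values, 5.0, atol=1e-9)

    def test_bimodal_voxel_against_unbinned_oracle(self, small_phantom, registry, default_params):
        density, labels = small_phantom
        samples = np.concatenate([np.full(300, 2.0), np.full(50, 120.0)])

        def provider(idx):
            return SubvoxelBlock(idx, samples, (350, 1, 1), (0.025, 0.025, 0.025))

        region = np.zeros(density.shape, bool)
        region[0, 0, 0] = True
        out = eud_map(density, labels, [], registry, region=region, block_provider=provider)
        full = eud_from_histogram(build_histogram(samples, n_bins=350), default_params)
        assert out.values[0, 0, 0] == pytest.approx(full, rel=1e-6)

    def test_clinical_reference_fractionation_unchanged(self, small_phantom, registry):
        density, labels = small_phantom
        dose = density.like(np.full(density.shape, 60.0))
        out = eqd2_map(dose, labels, registry, n_fractions=30)
        np.testing.assert_allclose(out.values, 60.0, rtol=1e-12)

    def test_mrt_single_fraction_voxel_value(self, small_phantom):
        density, labels = small_phantom
        from mrteud import TissueParams

        registry = {"default": TissueParams("default", alpha=0.3, alpha_beta=3.0)}
        dose = density.like(np.full(density.shape, 20.0))
        out = eqd2_map(dose, labels, registry, single_fraction=True)
        np.testing.assert_allclose(out.values, 92.0, rtol=1e-12)

    def test_zero_map_stays_zero(self, small_phantom, registry):
        density, labels = small_phantom
        dose = density.like(np.zeros(density.shape))
        out = eqd2_map(dose, labels, registry, single_fraction=True)
        assert np.all(out.values == 0.0)

    def test_missing_fraction_scheme_rejected(self, small_phantom, registry):
        density, labels = small_phantom
        with pytest.raises(InputError):
            eqd2_map(density.like(np.ones(density.shape)), labels, registry)

    def test_overlap_priority_on_param_arrays(self, small_phantom, registry):
        density, labels = small_phantom
        overlap = labels.structure("PTV") & labels.structure("brain_stem")
        assert overlap.any()  # the phantom is built with an overlap scenario
        alpha, _ = resolve_params_arrays(labels, registry, priority=["PTV", "brain_stem"])
        assert np.all(alpha[overlap] == registry["PTV"].alpha)
        alpha2, _ = resolve_params_arrays(labels, registry, priority=["brain_stem", "PTV"])
        assert np.all(alpha2[overlap] == registry["brain_stem"].alpha)


# ---------------------------------------------------------------------------
# Normalization


class TestNormalization:
    def test_matching_plan_returns_factor_one(self, small_phantom, registry):
        density, labels = small_phantom
        provider = constant_block_provider(10.0)
        ab = registry["PTV"].alpha_beta
        from mrteud import eqd2_of_single_fraction_eud

        reference = eqd2_of_single_fraction_eud(10.0, ab)
        res = normalize_to_reference_d98(
            [], density, labels, registry, reference, priority=["PTV"],
            block_provider=provider,
        )
        assert res.factor == pytest.approx(1.0, abs=1e-6)

    def test_uniform_plan_closed_form_inversion(self, small_phantom, registry):
        # EQD2(E) = 50 has the closed-form solution E* of E(E+ab) = 50(2+ab)
        density, labels = small_phantom
        ab = registry["PTV"].alpha_beta
        e_star = (-ab + np.sqrt(ab * ab + 4 * 50.0 * (2 + ab))) / 2.0
        res = normalize_to_reference_d98(
            [], density, labels, registry, 50.0, priority=["PTV"],
            block_provider=constant_block_provider(10.0),
        )
        assert res.factor == pytest.approx(e_star / 10.0, rel=1e-6)

    def test_end_to_end_recovery_and_idempotence(self, small_plan, registry):
        density, labels, beams = small_plan
        subs = (80, 80, 1)
        res = normalize_to_reference_d98(
            beams, density, labels, registry, 53.05,
            priority=["PTV", "brain_stem"], subdivisions=subs,
        )
        assert res.achieved_d98 == pytest.approx(53.05, rel=1e-3)
        # re-normalizing the scaled plan must return factor 1
        res2 = normalize_to_reference_d98(
            list(res.beams), density, labels, registry, 53.05,
            priority=["PTV", "brain_stem"], subdivisions=subs,
        )
        assert res2.factor == pytest.approx(1.0, abs=1e-3)

    def test_dose_free_target_rejected(self, small_phantom, registry):
        from mrteud.errors import ConvergenceError

        density, labels = small_phantom
        with pytest.raises(ConvergenceError):
            normalize_to_reference_d98(
                [], density, labels, registry, 50.0,
                block_provider=constant_block_provider(0.0),
            )


# ---------------------------------------------------------------------------
# Constraints


class TestConstraints:
    def test_brain_stem_pass_and_fail(self):
        c = ConstraintSpec("brain_stem", Metric.parse("Dmax"), 54.0, "<")
        report = evaluate_constraints([c], {("brain_stem", "Dmax"): 51.49})
        assert report.all_passed
        report = evaluate_constraints([c], {("brain_stem", "Dmax"): 65.79})
        assert report.n_failed == 1

    def test_empty_constraint_list(self):
        report = evaluate_constraints([], {})
        assert report.rows == () and report.all_passed

    def test_report_frame_schema(self):
        c = ConstraintSpec("lung", Metric.parse("V20Gy"), 20.0, "<", plan="sbrt")
        df = evaluate_constraints([c], {("lung", "V20Gy"): 5.12}).to_frame()
        assert list(df.columns) == [
            "plan", "structure", "metric", "comparator", "threshold", "achieved", "passed",
        ]
        assert bool(df["passed"].iloc[0])

    def test_computed_report_from_dose_map(self, small_phantom):
        density, labels = small_phantom
        dose = density.like(np.full(density.shape, 30.0))
        cons = [
            ConstraintSpec("brain_stem", Metric.parse("Dmax"), 54.0),
            ConstraintSpec("brain_stem", Metric.parse("Dmean"), 20.0),
        ]
        report = constraint_report(dose, labels, cons)
        assert [passed for _, _, passed in report.rows] == [True, False]

    def test_missing_achieved_value_rejected(self):
        c = ConstraintSpec("x", Metric.parse("Dmax"), 5.0)
        with pytest.raises(InputError):
            evaluate_constraints([c], {})
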