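"""Densitometry/qPCR normalization and morphometric surface correction."""

import numpy as np
import pandas as pd
import pytest

from epibarrier import (apply_surface_correction, ddct_fold_change,
                        densitometric_normalize, generate_expression_data)
from epibarrier.expression import ExpressionError


def dens_table(pp_ratios, ve_ratios, control=1000.0):
    rows = []
    for grp, ratios in (("PP", pp_ratios), ("VE", ve_ratios)):
        for i, r in enumerate(ratios):
            rows.append({"sample_id": f"{grp}{i + 1}", "group": grp,
                         "target_id": "CLDN4", "target_signal": r * control,
                         "control_signal": control, "assay": "densitometry"})
    return pd.DataFrame(rows)


def ct_table(pp_dct, ve_dct, ref_ct=20.0):
    rows = []
    for grp, dcts in (("PP", pp_dct), ("VE", ve_dct)):
        for i, d in enumerate(dcts):
            rows.append({"sample_id": f"{grp}{i + 1}", "group": grp,
                         "target_id": "CLDN4", "target_signal": ref_ct + d,
                         "control_signal": ref_ct, "assay": "qpcr"})
    return pd.DataFrame(rows)


class TestDensitometricNormalize:
    def test_equal_ratios_give_flat_100(self):
        norm = densitometric_normalize(dens_table([1.0, 1.0], [1.0, 1.0]))
        assert np.allclose(norm.per_sample["value"], 100.0)
        stats = norm.group_stats.set_index("group")
        assert stats.loc["VE", "mean"] == 100.0 and stats.loc["VE", "sem"] == 0.0
        assert stats.loc["PP", "mean"] == 100.0

    def test_hand_computed_percentage(self):
        norm = densitometric_normalize(dens_table([0.954, 0.954], [1.0, 1.0]))
        stats = norm.group_stats.set_index("group")
        assert stats.loc["PP", "mean"] == pytest.approx(95.4)

    def test_intensity_scale_invariance(self):
        t1 = dens_table([0.8, 1.2], [0.9, 1.1])
        t2 = t1.copy()
        t2[["target_signal", "control_signal"]] *= 10.0
        n1 = densitometric_normalize(t1)
        n2 = densitometric_normalize(t2)
        np.testing.assert_allclose(n1.per_sample["value"], n2.per_sample["value"])

    def test_ve_sem_conventions(self):
        table = dens_table([1.0, 1.0], [0.8, 1.2])
        zero = densitometric_normalize(table, ve_sem_mode="zero")
        prop = densitometric_normalize(table, ve_sem_mode="propagate")
        assert zero.group_stats.set_index("group").loc["VE", "sem"] == 0.0
        ve_prop = prop.group_stats.set_index("group").loc["VE"]
        assert ve_prop["mean"] == pytest.approx(100.0)  # anchored mean
        assert ve_prop["sem"] > 0.0

    def test_zero_control_names_sample(self):
        table = dens_table([1.0, 1.0], [1.0, 1.0])
        table.loc[table["sample_id"] == "PP2", "control_signal"] = 0.0
        with pytest.raises(ExpressionError, match="PP2"):
            densitometric_normalize(table)

    def test_missing_reference_group_rejected(self):
        table = dens_table([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ExpressionError, match="reference group"):
            densitometric_normalize(table[table["group"] == "PP"])

    def test_multiple_targets_rejected(self):
        a = dens_table([1.0], [1.0])
        b = dens_table([1.0], [1.0]).assign(target_id="CLDN1")
        with pytest.raises(ExpressionError, match="one target"):
            densitometric_normalize(pd.concat([a, b]))


class TestSurfaceCorrection:
    def test_factor_one_is_identity(self):
        norm = densitometric_normalize(dens_table([0.9, 1.1], [1.0, 1.0]))
        out = apply_surface_correction(norm, 1.0)
        np.testing.assert_allclose(out.per_sample["value"], norm.per_sample["value"])

    def test_per_sample_scaling(self):
        norm = densitometric_normalize(dens_table([1.0, 1.0], [1.0, 1.0]))
        out = apply_surface_correction(norm, 2.3)
        stats = out.group_stats.set_index("group")
        assert stats.loc["PP", "mean"] == pytest.approx(230.0)
        assert stats.loc["VE", "mean"] == 100.0  # reference untouched

    def test_mean_level_variant(self):
        norm = densitometric_normalize(dens_table([0.954, 0.954], [1.0, 1.0]))
        out = apply_surface_correction(norm, 2.3, level="mean")
        stats = out.group_stats.set_index("group")
        assert stats.loc["PP", "mean"] == pytest.approx(95.4 * 2.3)

    def test_correction_commutes_with_averaging(self):
        norm = densitometric_normalize(dens_table([0.7, 1.3, 0.9], [0.95, 1.05]))
        per_sample = apply_surface_correction(norm, 2.3)
        pp_mean = norm.group_stats.set_index("group").loc["PP", "mean"]
        assert (per_sample.group_stats.set_index("group").loc["PP", "mean"]
                == pytest.approx(2.3 * pp_mean))

    def test_nonpositive_factor_rejected(self):
        norm = densitometric_normalize(dens_table([1.0, 1.0], [1.0, 1.0]))
        with pytest.raises(ExpressionError, match="factor"):
            apply_surface_correction(norm, 0.0)


class TestDdctFoldChange:
    def test_equal_dct_gives_unit_fold(self):
        norm = ddct_fold_change(ct_table([5.0, 5.0], [5.0, 5.0]))
        assert np.allclose(norm.per_sample["value"], 1.0)

    def test_exact_power_of_two(self):
        # PP dCt 3 against VE mean dCt 5: ddCt = -2, fold = 4
        norm = ddct_fold_change(ct_table([3.0, 3.0], [5.0, 5.0]))
        pp = norm.value_arrays()["PP"]
        assert np.allclose(pp, 4.0)

    def test_correction_multiplies_folds(self):
        norm = ddct_fold_change(ct_table([np.log2(1 / 1.5) + 5.0] * 2, [5.0, 5.0]),
                                correction=2.3)
        pp = norm.value_arrays()["PP"]
        assert np.allclose(pp, 1.5 * 2.3)

    def test_reference_group_anchored_at_unity(self):
        norm = ddct_fold_change(ct_table([3.0, 4.0], [5.0, 5.0, 5.0]))
        ve = norm.group_stats.set_index("group").loc["VE"]
        assert ve["mean"] == pytest.approx(1.0)

    def test_missing_ct_names_sample(self):
        table = ct_table([3.0, 3.0], [5.0, 5.0])
        table.loc[table["sample_id"] == "VE1", "control_signal"] = np.nan
        with pytest.raises(ExpressionError, match="VE1"):
            ddct_fold_change(table)

    def test_ct_out_of_range_rejected(self):
        table = ct_table([3.0], [5.0], ref_ct=44.0)
        with pytest.raises(ExpressionError, match="outside"):
            ddct_fold_change(table)


class TestEndToEndRecovery:
    def test_noiseless_generator_recovery_is_exact(self):
        """Per-cell fold 2.3 hidden by density ratio 2.3: raw PP reads 100%,
        surface correction recovers 230%; qPCR fold recovers 2.3 exactly."""
        dens, qpcr = generate_expression_data(2.3, 2.3, n=5, noise_cv=0.0, seed=0)
        norm = densitometric_normalize(dens)
        stats = norm.group_stats.set_index("group")
        assert stats.loc["PP", "mean"] == pytest.approx(100.0)
        corrected = apply_surface_correction(norm, 2.3)
        assert corrected.group_stats.set_index("group").loc["PP", "mean"] \
            == pytest.approx(230.0)
        fold = ddct_fold_change(qpcr, correction=2.3)
        assert np.allclose(fold.value_arrays()["PP"], 2.3)

    def test_noisy_generator_recovery_within_tolerance(self):
        dens, _ = generate_expression_data(2.3, 2.3, n=24, noise_cv=0.15, seed=5)
        norm = densitometric_normalize(dens)
        corrected = apply_surface_correction(norm, 2.3)
        pp = corrected.group_stats.set_index("group").loc["PP"]
        # mean of 24 samples at cv~0.2 (two lognormal factors): ~4% SEM
        assert pp["mean"] == pytest.approx(230.0, rel=0.15)
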