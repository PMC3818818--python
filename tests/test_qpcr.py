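"""ΔΔCt quantitation, Z-scores, standard curves and ChIP arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkbcoupling import (
    CtTable,
    ExpressionMatrix,
    chip_fold_enrichment,
    ddct_fold_change,
    fit_standard_curve,
    load_panel,
    zscore_transform,
)


def _table(rows):
    return CtTable(pd.DataFrame(
        rows, columns=["gene", "pathway", "condition", "time_min",
                       "replicate", "ct"]
    ))


def _cols(m):
    return list(m.data.columns)


class TestDdct:
    def test_equal_shift_gives_fold_change_one(self):
        """Gene and reference shifting together leaves ΔΔCt at zero."""
        rows = []
        for cond, time, shift in [("control", 0, 0.0), ("EMT", 0, 3.0)]:
            rows.append(("G1", "x", cond, time, 1, 25.0 + shift))
            rows.append(("POLB", "ref", cond, time, 1, 20.0 + shift))
        fc = ddct_fold_change(_table(rows))
        assert fc.data.loc["G1", ("EMT", 0)] == pytest.approx(1.0)

    def test_one_cycle_doubling_identity(self):
        rows = [
            ("G1", "x", "control", 0, 1, 25.0),
            ("G1", "x", "EMT", 0, 1, 24.0),
            ("POLB", "ref", "control", 0, 1, 20.0),
            ("POLB", "ref", "EMT", 0, 1, 20.0),
        ]
        fc = ddct_fold_change(_table(rows))
        assert fc.data.loc["G1", ("EMT", 0)] == pytest.approx(2.0)
        assert fc.data.loc["G1", ("control", 0)] == pytest.approx(1.0)

    def test_column_shift_equivariance(self):
        """Adding a constant to every Ct in one column leaves every fold
        change unchanged (it cancels against the reference)."""
        base = [
            ("G1", "x", "control", 0, 1, 24.0),
            ("G2", "x", "control", 0, 1, 28.0),
            ("POLB", "ref", "control", 0, 1, 20.0),
            ("G1", "x", "EMT", 60, 1, 23.0),
            ("G2", "x", "EMT", 60, 1, 27.5),
            ("POLB", "ref", "EMT", 60, 1, 19.5),
        ]
        shifted = [
            (g, p, c, t, r, ct + (2.7 if (c, t) == ("EMT", 60) else 0.0))
            for g, p, c, t, r, ct in base
        ]
        a = ddct_fold_change(_table(base)).data
        b = ddct_fold_change(_table(shifted)).data
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_column_warns_and_propagates(self, caplog):
        rows = [
            ("G1", "x", "control", 0, 1, 24.0),
            ("POLB", "ref", "control", 0, 1, 20.0),
            ("G1", "x", "EMT", 0, 1, 23.0),
            ("POLB", "ref", "EMT", 0, 1, np.nan),
        ]
        with caplog.at_level("WARNING"):
            fc = ddct_fold_change(_table(rows))
        assert math.isnan(fc.data.loc["G1", ("EMT", 0)])
        assert any("reference Ct missing" in r.message for r in caplog.records)

    def test_replicates_averaged_on_ct_scale(self):
        rows = [
            ("G1", "x", "control", 0, 1, 24.0),
            ("G1", "x", "control", 0, 2, 26.0),  # mean Ct 25
            ("POLB", "ref", "control", 0, 1, 20.0),
            ("G1", "x", "EMT", 0, 1, 24.0),
            ("POLB", "ref", "EMT", 0, 1, 20.0),
        ]
        fc = ddct_fold_change(_table(rows))
        assert fc.data.loc["G1", ("EMT", 0)] == pytest.approx(2.0)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            _table([("G1", "x", "control", 0, 1, 0.0)])
        with pytest.raises(ValueError):
            _table([("G1", "x", "control", 0, 1, 44.0)])

    def test_missing_reference_gene_rejected(self):
        with pytest.raises(ValueError, match="reference gene"):
            ddct_fold_change(_table([("G1", "x", "control", 0, 1, 24.0)]))


class TestZscore:
    def _matrix(self, rows, genes):
        cols = pd.MultiIndex.from_tuples(
            [("c", float(i)) for i in range(len(rows[0]))],
            names=["condition", "time_min"],
        )
        return ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=cols, dtype=float),
            "fold_change",
        )

    def test_simple_row(self):
        z = zscore_transform(self._matrix([[1.0, 2.0, 3.0]], ["g"]))
        assert np.allclose(z.data.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self):
        z = zscore_transform(self._matrix([[5.0, 5.0, 5.0, 5.0]], ["g"]))
        assert np.allclose(z.data.loc["g"], 0.0)

    def test_missing_preserved_with_sample_sd(self):
        """Row (1, NA, 3): mean 2, sample SD sqrt(2) -> (-0.7071, NA, 0.7071)."""
        z = zscore_transform(self._matrix([[1.0, np.nan, 3.0]], ["g"]))
        row = z.data.loc["g"]
        assert row.iloc[0] == pytest.approx(-1 / math.sqrt(2), abs=1e-4)
        assert math.isnan(row.iloc[1])
        assert row.iloc[2] == pytest.approx(1 / math.sqrt(2), abs=1e-4)

    def test_under_two_observations_becomes_missing(self):
        z = zscore_transform(
            self._matrix([[1.0, np.nan, np.nan]], ["g"])
        )
        assert z.data.loc["g"].isna().all()

    def test_row_mean_zero_sd_one_invariant(self):
        rng = np.random.default_rng(7)
        rows = rng.lognormal(0, 1, size=(12, 8))
        z = zscore_transform(self._matrix(rows, [f"g{i}" for i in range(12)]))
        means = z.data.mean(axis=1)
        sds = z.data.std(axis=1, ddof=1)
        assert np.all(np.abs(means) < 1e-9)
        assert np.allclose(sds, 1.0)

    def test_idempotence_within_tolerance(self):
        rng = np.random.default_rng(3)
        rows = rng.lognormal(0, 1, size=(6, 10))
        z1 = zscore_transform(self._matrix(rows, [f"g{i}" for i in range(6)]))
        z1.value_kind = "fold_change"  # re-enter the transform
        z2 = zscore_transform(z1)
        assert np.nanmax(np.abs(z2.data.to_numpy() - z1.data.to_numpy())) < 1e-9

    def test_empty_matrix_rejected(self):
        cols = pd.MultiIndex.from_tuples([("c", 0.0)],
                                         names=["condition", "time_min"])
        empty = ExpressionMatrix(pd.DataFrame(columns=cols), "fold_change")
        with pytest.raises(ValueError):
            zscore_transform(empty)

    def test_matrix_tsv_round_trip(self, tmp_path):
        m = self._matrix([[1.0, np.nan, 3.0]], ["g"])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        assert "NA" in path.read_text()
        back = ExpressionMatrix.from_tsv(path, "fold_change")
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)


class TestPanel:
    def test_shipped_panel_valid(self):
        panel = load_panel()
        assert len(panel) == 50
        assert panel.gene.is_unique
        assert panel.amplicon_bp.between(51, 132).all()


class TestStandardCurve:
    def test_perfect_doubling_slope(self):
        """Textbook 100%-efficiency series: slope -1/log10(2) = -3.3219."""
        curve = fit_standard_curve([(1, 30.0), (10, 26.678), (100, 23.356)])
        assert curve.slope == pytest.approx(-3.322, abs=1e-3)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)

    def test_jittered_series_still_tight(self):
        curve = fit_standard_curve(
            [(1, 30.01), (10, 26.668), (100, 23.356)]
        )
        assert curve.r_squared > 0.999

    def test_round_trip_exact(self):
        slope, intercept = -3.1, 31.2
        pts = [(m, slope * math.log10(m) + intercept) for m in (1, 5, 20, 100)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(10, 25.0), (10, 25.1), (10, 24.9)])
        with pytest.raises(ValueError):
            fit_standard_curve([(1, 30.0), (2, 29.0)])


class TestChip:
    def test_self_normalisation(self):
        assert chip_fold_enrichment(0.5, 10.0, 0.05) == pytest.approx(1.0)

    def test_linearity(self):
        assert chip_fold_enrichment(1.0, 10.0, 0.05) == pytest.approx(2.0)

    def test_curve_composed_enrichment(self):
        """Quantities recovered through the standard curve: a 10-fold IP
        increase at fixed input gives 10x enrichment."""
        slope, intercept = -3.3219280948873623, 30.0
        curve = fit_standard_curve(
            [(m, slope * math.log10(m) + intercept) for m in (1, 10, 100)]
        )
        input_ct = curve.ct_from_mass(10.0)
        base_ip_ct = curve.ct_from_mass(0.2)
        stim_ip_ct = curve.ct_from_mass(2.0)
        inp = curve.mass_from_ct(input_ct)
        baseline = curve.mass_from_ct(base_ip_ct) / inp
        fold = chip_fold_enrichment(curve.mass_from_ct(stim_ip_ct), inp, baseline)
        assert fold == pytest.approx(10.0, abs=0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chip_fold_enrichment(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            chip_fold_enrichment(1.0, 1.0, 0.0)


@settings(max_examples=30, deadline=None)
@given(
    cts=st.lists(st.floats(10.0, 35.0), min_size=2, max_size=6),
    shift=st.floats(-3.0, 3.0),
)
def test_ddct_shift_invariance_property(cts, shift):
    """Shifting all Cts of one column by a constant never changes fold
    changes (scale equivariance of the comparative-Ct method)."""
    rows, rows_shifted = [], []
    for j, ct in enumerate(cts):
        for tab, s in ((rows, 0.0), (rows_shifted, shift)):
            tab.append((f"G{j}", "x", "control", 0, 1, ct))
            tab.append((f"G{j}", "x", "EMT", 0, 1, ct + 1.0 + s * 0))
    for tab, s in ((rows, 0.0), (rows_shifted, shift)):
        tab.append(("POLB", "ref", "control", 0, 1, 20.0))
        tab.append(("POLB", "ref", "EMT", 0, 1, 20.0 + s))
    # apply the same shift to the gene rows of the EMT column
    rows_shifted = [
        (g, p, c, t, r, ct + (shift if (c == "EMT" and g != "POLB") else 0.0))
        for g, p, c, t, r, ct in rows_shifted
    ]
    a = ddct_fold_change(_table(rows)).data
    b = ddct_fold_change(_table(rows_shifted)).data
    assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)
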