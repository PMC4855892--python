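import numpy as np
import pandas as pd
import pytest

from conftest import toy_ct
from mepscope.panel import Assay, GenePanel
from mepscope.qc import (
    ConfigurationError,
    FormatError,
    ParseError,
    PipelineError,
    filter_assays,
    filter_cells,
    fit_titration,
    merge_duplicate_assays,
    normalize_to_housekeeping,
    read_ct_table,
)
from mepscope.synthetic import simulate_titration


class TestReadCtTable:
    def test_fail_token_becomes_lod_dropout(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell_id,B2M,GAPDH\nc1,12.5,Fail\nc2,11.0,14.2\n")
        ct = read_ct_table(p)
        assert ct.ct.at["c1", "GAPDH"] == 40.0
        assert bool(ct.dropout.at["c1", "GAPDH"])
        assert not ct.dropout.at["c2", "GAPDH"]

    def test_values_beyond_lod_censored(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell_id,B2M,GAPDH\nc1,12.5,999\n")
        ct = read_ct_table(p)
        assert ct.ct.at["c1", "GAPDH"] == 40.0 and bool(ct.dropout.at["c1", "GAPDH"])

    def test_garbage_names_cell_and_assay(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell_id,B2M,GAPDH\nc1,12.5,oops\n")
        with pytest.raises(ParseError, match="c1.*GAPDH"):
            read_ct_table(p)

    def test_missing_housekeeping_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell_id,B2M,GATA1\nc1,12.5,22\n")
        with pytest.raises(FormatError, match="GAPDH"):
            read_ct_table(p)

    def test_meta_columns_split_off(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell_id,B2M,GAPDH,sort_gate\nc1,12,13,unselected_MEP\n")
        ct = read_ct_table(p)
        assert "sort_gate" not in ct.assay_ids
        assert ct.cell_meta.at["c1", "sort_gate"] == "unselected_MEP"


def _dup_panel():
    return GenePanel(
        [
            Assay("B2M", "B2M", "housekeeping"),
            Assay("GAPDH", "GAPDH", "housekeeping"),
            Assay("X_A", "X", "other", duplicate_group="X"),
            Assay("X_B", "X", "other", duplicate_group="X"),
        ]
    )


class TestMergeDuplicates:
    def _matrix(self, rng, rho_high=True, n=60):
        base = rng.normal(22, 3, n)
        other = base + rng.normal(0, 0.3, n) if rho_high else rng.normal(22, 3, n)
        cols = np.column_stack(
            [np.full(n, 11.0), np.full(n, 13.0), base, other]
        ).clip(1, 39)
        return toy_ct(cols, assays=["B2M", "GAPDH", "X_A", "X_B"])

    def test_correlated_pair_merged_by_mean(self):
        ct = toy_ct(
            [[11, 13, 20, 22], [11, 13, 18, 19]],
            assays=["B2M", "GAPDH", "X_A", "X_B"],
        )
        # force merge path with a correlated backdrop
        rng = np.random.default_rng(0)
        big = self._matrix(rng, rho_high=True)
        merged, rep = merge_duplicate_assays(big, _dup_panel())
        assert "X_A" in merged.assay_ids and "X_B" not in merged.assay_ids
        expected = (big.ct["X_A"] + big.ct["X_B"]) / 2
        assert np.allclose(merged.ct["X_A"], expected)
        assert (rep.excluded_assays["reason"] == "merged_duplicate").all()

    def test_one_member_dropout_keeps_detected_value(self):
        rng = np.random.default_rng(1)
        big = self._matrix(rng, rho_high=True)
        big.ct.iloc[0, 3] = 40.0
        big.dropout.iloc[0, 3] = True
        val = big.ct.iloc[0, 2]
        merged, _ = merge_duplicate_assays(big, _dup_panel())
        assert merged.ct.iloc[0]["X_A"] == val
        assert not merged.dropout.iloc[0]["X_A"]

    def test_uncorrelated_pair_reduced_to_one_member(self):
        rng = np.random.default_rng(2)
        big = self._matrix(rng, rho_high=False)
        merged, rep = merge_duplicate_assays(big, _dup_panel())
        kept = [a for a in ("X_A", "X_B") if a in merged.assay_ids]
        assert len(kept) == 1
        assert (rep.excluded_assays["reason"] == "bad_duplicate").all()

    def test_absent_member_is_configuration_error(self):
        ct = toy_ct([[11, 13, 20]], assays=["B2M", "GAPDH", "X_A"])
        with pytest.raises(ConfigurationError, match="X_B"):
            merge_duplicate_assays(ct, _dup_panel())


class TestFilterAssays:
    def test_constant_assays_removed_and_counted(self):
        vals = np.tile([11.0, 13.0, 22.0, 40.0, 7.0, 7.0], (5, 1))
        vals[:, 2] = [20, 21, 22, 23, 24]
        ct = toy_ct(vals, assays=["B2M", "GAPDH", "G", "DEAD", "K1", "K2"])
        # B2M/GAPDH constant here too: build variation into them
        ct.ct["B2M"] += np.arange(5) * 0.01
        ct.ct["GAPDH"] += np.arange(5) * 0.01
        out, rep = filter_assays(ct)
        removed = set(rep.excluded_assays["assay_id"])
        assert removed == {"DEAD", "K1", "K2"}
        assert len(removed) == 3
        assert out.n_assays == 3
        rep.validate_counts()

    def test_no_constant_assay_identity(self, qc_passed):
        out, rep = filter_assays(qc_passed)
        assert out.ct.equals(qc_passed.ct)
        assert rep.excluded_assays.empty

    def test_all_removed_is_pipeline_error(self):
        ct = toy_ct(np.tile([11.0, 13.0], (4, 1)), assays=["B2M", "GAPDH"])
        with pytest.raises(PipelineError):
            filter_assays(ct)


class TestFilterCells:
    def _cell(self, n_drop, b2m=11.0, gapdh=13.0, fill=18.0, n_assays=87):
        row = np.full(n_assays, fill)
        row[0], row[1] = b2m, gapdh
        row[n_assays - n_drop:] = 40.0
        return row

    def _names(self, n=87):
        return ["B2M", "GAPDH"] + [f"g{i}" for i in range(n - 2)]

    def test_many_dropouts_excluded_first(self):
        ct = toy_ct(
            [self._cell(71), self._cell(70)], assays=self._names()
        )
        out, rep = filter_cells(ct)
        assert list(out.cell_ids) == ["c1"]
        assert rep.excluded_cells.iloc[0]["reason"] == "too_many_failed"

    def test_boundary_housekeeping_retained(self):
        ct = toy_ct(
            [self._cell(0, b2m=13.0, gapdh=15.0), self._cell(0, b2m=13.01)],
            assays=self._names(),
        )
        out, rep = filter_cells(ct)
        assert "c0" in out.cell_ids  # strict inequality keeps Ct == cutoff
        assert rep.excluded_cells.iloc[0]["reason"] == "low_B2M"

    def test_mean_over_detected_only(self):
        # detected mean 19 < 20 even though drop-outs at 40 would push it over
        row = self._cell(30, fill=19.5)
        ct = toy_ct([row], assays=self._names())
        out, _ = filter_cells(ct)
        assert out.n_cells == 1

    def test_matches_bruteforce_oracle(self, dataset):
        ct = dataset.ct
        out, rep = filter_cells(ct)
        keep = []
        for cell in ct.cell_ids:
            drops = int(ct.dropout.loc[cell].sum())
            det = ct.ct.loc[cell][~ct.dropout.loc[cell]]
            ok = (
                drops <= 70
                and ct.ct.at[cell, "B2M"] <= 13
                and ct.ct.at[cell, "GAPDH"] <= 15
                and (det.mean() <= 20 if len(det) else False)
            )
            if ok:
                keep.append(cell)
        assert list(out.cell_ids) == keep
        rep.validate_counts()

    def test_idempotent(self, dataset):
        once, _ = filter_cells(dataset.ct)
        twice, rep = filter_cells(once)
        assert twice.ct.equals(once.ct)
        assert rep.excluded_cells.empty

    def test_missing_housekeeping_raises(self):
        ct = toy_ct([[20.0, 21.0]], assays=["GATA1", "KLF1"])
        with pytest.raises(ConfigurationError):
            filter_cells(ct)


class TestNormalize:
    def test_delta_ct_arithmetic(self):
        ct = toy_ct([[12.0, 14.0, 25.0]], assays=["B2M", "GAPDH", "GATA1"])
        expr = normalize_to_housekeeping(ct)
        assert expr.norm_ct.at["c0", "GATA1"] == pytest.approx(12.0)
        # housekeeping genes land symmetric around zero
        assert expr.norm_ct.at["c0", "B2M"] == pytest.approx(-1.0)
        assert expr.norm_ct.at["c0", "GAPDH"] == pytest.approx(1.0)
        assert expr.housekeeping_mean.at["c0"] == pytest.approx(13.0)

    def test_constant_shift_invariance(self):
        base = toy_ct([[12.0, 14.0, 25.0, 30.0]], assays=["B2M", "GAPDH", "A", "B"])
        shifted = toy_ct(
            [[15.0, 17.0, 28.0, 33.0]], assays=["B2M", "GAPDH", "A", "B"]
        )
        e1 = normalize_to_housekeeping(base)
        e2 = normalize_to_housekeeping(shifted)
        pd.testing.assert_frame_equal(e1.norm_ct, e2.norm_ct)


class TestTitrationFit:
    def test_noiseless_exact_line(self, panel):
        fit = fit_titration(simulate_titration(panel, noise_sd=0.0))
        assert np.allclose(fit.per_assay["slope"], -1.0)
        assert np.allclose(fit.per_assay["r_squared"], 1.0)

    def test_noise_lowers_r2(self, panel):
        fit = fit_titration(simulate_titration(panel, noise_sd=0.5, seed=4))
        assert (fit.per_assay["r_squared"] < 1.0).all()

    def test_pool_offsets_recovered(self, panel):
        t = simulate_titration(
            panel, n_pools=2, pool_offsets=[0.0, 3.0], noise_sd=0.05, seed=6
        )
        fit = fit_titration(t)
        assert fit.pool_offsets["pool2"] == pytest.approx(3.0, abs=0.1)
        assert fit.per_assay["slope"].mean() == pytest.approx(-1.0, abs=0.02)

    def test_single_dilution_assay_flagged_unfit(self, panel):
        t = simulate_titration(panel, noise_sd=0.0)
        t = t[(t.assay != "B2M") | (t.dilution_step == 0)]
        fit = fit_titration(t)
        assert bool(fit.per_assay.at["B2M", "unfit"])
        assert np.isnan(fit.per_assay.at["B2M", "slope"])
        assert not fit.per_assay.drop("B2M")["unfit"].any()
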