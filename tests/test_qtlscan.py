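"""Genome scans, multiple-testing threshold, peak selection, QTL x Site model."""

import numpy as np
import pandas as pd
import pytest

from beanqtl import genotypes as gt, qtlscan, simdata


@pytest.fixture(scope="module")
def scan_inputs(paper_map, paper_geno, paper_truth, paper_records):
    records, _ = paper_records
    means = records.rename(columns={"tf": "tf_adj"})[["site", "line", "tf_adj"]]
    grid = gt.pseudomarker_dosages(paper_geno, paper_map, 1.0)
    dos = gt.impute_hmm(paper_geno, paper_map, 0.0)
    return means, grid, dos


class TestLiJiThreshold:
    def test_independent_markers_approach_bonferroni(self):
        # n >> p so every correlation eigenvalue stays in (0, 2); the
        # fractional-part rule then sums to the trace, i.e. the marker count
        rng = np.random.default_rng(1)
        vals = rng.choice([-1.0, 1.0], size=(6000, 513))
        dos = gt.DosageMatrix(
            lines=[f"l{i}" for i in range(6000)],
            positions=pd.DataFrame(
                {"name": [f"m{j}" for j in range(513)], "chrom": 1, "pos_cm": np.arange(513.0)}
            ),
            values=vals,
        )
        m_eff, thr = qtlscan.liji_threshold(dos)
        assert abs(m_eff - 513) < 15
        assert abs(thr - 4.011) < 0.02

    def test_duplicated_marker_counts_once(self):
        rng = np.random.default_rng(2)
        col = rng.choice([-1.0, 1.0], size=(200, 1))
        dos = gt.DosageMatrix(
            lines=[f"l{i}" for i in range(200)],
            positions=pd.DataFrame(
                {"name": ["a", "b"], "chrom": 1, "pos_cm": [0.0, 0.0]}
            ),
            values=np.hstack([col, col]),
        )
        m_eff, _ = qtlscan.liji_threshold(dos)
        assert m_eff == pytest.approx(1.0, abs=1e-6)

    def test_printed_threshold_at_meff_140(self):
        assert -np.log10(0.05 / 140) == pytest.approx(3.447, abs=5e-4)

    def test_linked_panel_meff_below_marker_count(self, paper_map, paper_geno):
        dos = gt.impute_hmm(paper_geno, paper_map, 0.0)
        m_eff, thr = qtlscan.liji_threshold(dos)
        assert m_eff < len(paper_map.markers)
        assert thr < -np.log10(0.05 / len(paper_map.markers))


class TestScans:
    def test_cim_without_cofactors_equals_sim(self, scan_inputs):
        means, grid, _ = scan_inputs
        sim = qtlscan.sim_scan(means, grid)
        cim = qtlscan.cim_scan(means, grid, cofactors=None)
        pd.testing.assert_frame_equal(sim.table, cim.table)

    def test_scan_is_deterministic(self, scan_inputs):
        means, grid, _ = scan_inputs
        a = qtlscan.sim_scan(means, grid)
        b = qtlscan.sim_scan(means, grid)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_line_order_invariance(self, scan_inputs):
        means, grid, _ = scan_inputs
        a = qtlscan.sim_scan(means, grid)
        b = qtlscan.sim_scan(means.sample(frac=1.0, random_state=3), grid)
        np.testing.assert_allclose(
            a.table["neglog10p"], b.table["neglog10p"], atol=1e-8
        )

    def test_major_qtl_detected_near_truth(self, scan_inputs, paper_truth):
        means, grid, dos = scan_inputs
        truth, qtab = paper_truth
        _, thr = qtlscan.liji_threshold(dos)
        prof = qtlscan.sim_scan(means, grid)
        peaks = qtlscan.select_peaks(prof, thr, min_sep=10.0)
        big = qtab[qtab["effect"].abs() >= 1.0]
        found = 0
        for _, q in big.iterrows():
            near = peaks.table[
                (peaks.table["chrom"] == q["chrom"])
                & ((peaks.table["pos_cm"] - q["pos_cm"]).abs() <= 10.0)
            ]
            found += len(near) > 0
        assert found >= len(big) - 1

    def test_cofactor_near_test_position_excluded(self, scan_inputs, paper_map):
        means, grid, dos = scan_inputs
        prof = qtlscan.sim_scan(means, grid)
        peaks = qtlscan.select_peaks(prof, 3.0, min_sep=10.0)
        assert len(peaks) > 0
        # scanning at the cofactor's own position must not regress on it:
        # the profile there reflects the QTL term, not a self-covariate
        cim = qtlscan.cim_scan(means, grid, peaks, window=5.0, min_cofactor_distance=50.0)
        mk = peaks.table.iloc[0]["marker"]
        row = cim.table[cim.table["name"] == mk].iloc[0]
        assert np.isfinite(row["neglog10p"]) and row["neglog10p"] > 0

    def test_monomorphic_position_reports_p_one(self, scan_inputs):
        means, grid, _ = scan_inputs
        vals = grid.values.copy()
        vals[:, 0] = 1.0
        grid2 = gt.DosageMatrix(grid.lines, grid.positions, vals)
        prof = qtlscan.sim_scan(means, grid2)
        assert prof.table.iloc[0]["neglog10p"] == 0.0


class TestPeakSelection:
    def _profile(self, values, chrom=1):
        t = pd.DataFrame(
            {
                "chrom": chrom,
                "pos_cm": np.arange(len(values), dtype=float),
                "name": [f"m{i}" for i in range(len(values))],
                "neglog10p": values,
            }
        )
        return qtlscan.ScanProfile(table=t, sites=["A", "B"])

    def test_flat_profile_below_threshold_gives_empty_set(self):
        prof = self._profile([1.0] * 20)
        assert len(qtlscan.select_peaks(prof, 3.0)) == 0

    def test_close_maxima_keep_only_higher(self):
        v = np.zeros(20)
        v[5], v[9] = 6.0, 5.0  # 4 cM apart
        peaks = qtlscan.select_peaks(self._profile(v), 3.0, min_sep=10.0)
        assert len(peaks) == 1
        assert peaks.table.iloc[0]["pos_cm"] == 5.0

    def test_separate_maxima_both_kept(self):
        v = np.zeros(40)
        v[5], v[30] = 6.0, 5.0
        peaks = qtlscan.select_peaks(self._profile(v), 3.0, min_sep=10.0)
        assert len(peaks) == 2

    def test_non_maxima_above_threshold_not_selected(self):
        v = np.array([0, 4.0, 5.0, 6.0, 5.0, 4.0, 0])  # one ridge
        peaks = qtlscan.select_peaks(self._profile(v), 3.5, min_sep=1.0)
        assert len(peaks) == 1


class TestQtlSiteModel:
    def _inputs(self, effects_by_site, seed=0, nl=300):
        """Two-marker panel; marker m1 has per-site effects from the dict."""
        rng = np.random.default_rng(seed)
        sites = list(effects_by_site)
        x1 = rng.choice([-1.0, 1.0], nl)
        x2 = rng.choice([-1.0, 1.0], nl)
        pos = pd.DataFrame(
            {"name": ["m1", "m2"], "chrom": [1, 2], "pos_cm": [0.0, 0.0]}
        )
        dos = gt.DosageMatrix([f"l{i}" for i in range(nl)], pos, np.column_stack([x1, x2]))
        g = rng.normal(0, 1.0, nl)
        rows = []
        for s in sites:
            rows.append(
                pd.DataFrame(
                    {
                        "site": s,
                        "line": dos.lines,
                        "tf_adj": 40 + effects_by_site[s] * x1 + 0.8 * x2 + g
                        + rng.normal(0, 1.0, nl),
                    }
                )
            )
        means = pd.concat(rows, ignore_index=True)
        qtls = qtlscan.QtlSet(
            pd.DataFrame(
                {
                    "qtl": ["Q1", "Q2"], "marker": ["m1", "m2"], "chrom": [1, 2],
                    "pos_cm": [0.0, 0.0], "neglog10p": [10.0, 10.0], "interacts": False,
                }
            )
        )
        return qtls, means, dos

    def test_stable_qtl_loses_interaction_and_keeps_main(self):
        eff = {s: -1.4 for s in ("A", "B", "C", "D", "E")}
        qtls, means, dos = self._inputs(eff)
        model = qtlscan.fit_qtl_site_model(qtls, means, dos)
        assert "m1" not in model.interacting
        se = model.fit.se["m1"]
        assert abs(model.qtl_main["m1"] + 1.4) < 3 * se

    def test_site_varying_qtl_keeps_interaction(self):
        eff = dict(zip("ABCDE", [-3.1, -2.6, -1.3, -3.1, -1.8]))
        qtls, means, dos = self._inputs(eff, seed=1)
        model = qtlscan.fit_qtl_site_model(qtls, means, dos)
        assert "m1" in model.interacting
        for s, v in eff.items():
            assert model.per_site_effects.loc["m1", s] == pytest.approx(v, abs=0.45)

    def test_null_qtl_terms_removable(self):
        # with zero effects the interaction terms are dropped
        eff = {s: 0.0 for s in ("A", "B", "C")}
        qtls, means, dos = self._inputs(eff, seed=2)
        model = qtlscan.fit_qtl_site_model(qtls, means, dos)
        assert model.interacting == []

    def test_aliased_qtl_dropped(self):
        eff = {s: -1.0 for s in ("A", "B")}
        qtls, means, dos = self._inputs(eff, seed=3)
        vals = dos.values.copy()
        vals[:, 1] = vals[:, 0]
        dos2 = gt.DosageMatrix(dos.lines, dos.positions, vals)
        with pytest.warns(UserWarning, match="aliased"):
            model = qtlscan.fit_qtl_site_model(qtls, means, dos2)
        assert list(model.qtl_main) == ["m1"]
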