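"""Two-stage multi-allele association scan against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from namhap import assoc as asc
from namhap.markers import MISSING
from tests.conftest import toy_marker_set


def random_marker_set(rng, n_lines=80, allele_counts=(2, 3, 2, 4, 2, 3)):
    cols = [rng.integers(1, k + 1, size=n_lines).astype(np.int16) for k in allele_counts]
    h = np.stack(cols, axis=1)
    return toy_marker_set(h, h.copy())


def random_eigenvectors(rng, line_ids, k=2):
    return pd.DataFrame(
        rng.normal(size=(len(line_ids), k)),
        index=line_ids,
        columns=[f"EV{i + 1}" for i in range(k)],
    )


def no_eigenvectors(line_ids):
    return pd.DataFrame(index=line_ids)


class TestMarkerDesigns:
    def test_dosage_coding_heterozygote_half(self):
        h1 = np.array([[1], [1], [2], [1]], dtype=np.int16)
        h2 = np.array([[1], [2], [2], [1]], dtype=np.int16)
        hms = toy_marker_set(h1, h2)
        d = asc.build_marker_designs(hms, hms.line_ids)[0]
        assert d.allele_codes[0] == 1  # most frequent = reference
        assert list(d.columns[:, 0]) == [0.0, 0.5, 1.0, 0.0]
        assert d.freqs[0] == pytest.approx(0.625)

    def test_monomorphic_markers_skipped(self):
        h = np.column_stack(
            [np.ones(5, dtype=np.int16), np.array([1, 1, 2, 2, 1], dtype=np.int16)]
        )
        hms = toy_marker_set(h, h.copy())
        designs = asc.build_marker_designs(hms, hms.line_ids)
        assert [d.marker_id for d in designs] == ["LDB_chr1_2000"]

    def test_missing_calls_mean_imputed(self):
        h1 = np.array([[1], [2], [2], [MISSING]], dtype=np.int16)
        hms = toy_marker_set(h1, h1.copy(), n_alleles=[2])
        d = asc.build_marker_designs(hms, hms.line_ids)[0]
        observed = d.columns[:3, 0]
        assert d.columns[3, 0] == pytest.approx(observed.mean())


class TestStage1:
    def test_matches_statsmodels_nested_f_test(self):
        rng = np.random.default_rng(0)
        hms = random_marker_set(rng)
        y = pd.Series(rng.normal(size=80), index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        scan = asc.stage1_scan(hms, y, ev, return_all=True)
        designs = {d.marker_id: d for d in asc.build_marker_designs(hms, hms.line_ids)}
        x0 = np.column_stack([np.ones(80), ev.to_numpy()])
        for row in scan.itertuples(index=False):
            d = designs[row.marker_id]
            fit0 = sm.OLS(y.to_numpy(), x0).fit()
            fit1 = sm.OLS(y.to_numpy(), np.hstack([x0, d.columns])).fit()
            f, p, df = fit1.compare_f_test(fit0)
            assert row.F == pytest.approx(f, abs=1e-10, rel=1e-10)
            assert row.p == pytest.approx(p, abs=1e-12, rel=1e-10)
            assert row.df1 == int(df)

    def test_true_signal_ranks_first(self):
        rng = np.random.default_rng(1)
        hms = random_marker_set(rng, n_lines=120)
        d = asc.build_marker_designs(hms, hms.line_ids)
        causal = d[3]  # the 4-allele marker
        y_vals = causal.columns @ np.array([4.0, 8.0, 12.0]) + rng.normal(0, 0.5, 120)
        y = pd.Series(y_vals, index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        scan = asc.stage1_scan(hms, y, ev, return_all=True)
        assert scan.iloc[0]["marker_id"] == causal.marker_id
        assert scan.iloc[0]["p"] < 1e-20

    def test_alpha_threshold_filters(self):
        rng = np.random.default_rng(2)
        hms = random_marker_set(rng)
        y = pd.Series(rng.normal(size=80), index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        full = asc.stage1_scan(hms, y, ev, return_all=True)
        sel = asc.stage1_scan(hms, y, ev, alpha=0.5)
        assert set(sel["marker_id"]) == set(full[full["p"] <= 0.5]["marker_id"])

    def test_allele_relabeling_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        hms = random_marker_set(rng)
        y = pd.Series(rng.normal(size=80), index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        base = asc.stage1_scan(hms, y, ev, return_all=True).set_index("marker_id")["p"]
        # swap allele labels 1 <-> 2 at every marker
        h1 = hms.h1.copy()
        h2 = hms.h2.copy()
        for arr in (h1, h2):
            one, two = arr == 1, arr == 2
            arr[one], arr[two] = 2, 1
        relabeled = toy_marker_set(h1, h2)
        new = asc.stage1_scan(relabeled, y, ev, return_all=True).set_index("marker_id")["p"]
        assert np.allclose(base.sort_index(), new.sort_index(), atol=1e-10)

    def test_only_ril_lines_enter(self):
        rng = np.random.default_rng(4)
        h = rng.integers(1, 3, size=(40, 3)).astype(np.int16)
        roles = ["parent", "parent"] + ["ril"] * 38
        hms = toy_marker_set(h, h.copy(), roles=roles)
        y = pd.Series(rng.normal(size=40), index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        _, _, _, lines = asc._prepare(hms, y, ev, 2)
        assert "L1" not in lines and "L2" not in lines and len(lines) == 38


class TestStage2:
    def _world(self, seed=10, n_lines=150, noise=0.5):
        rng = np.random.default_rng(seed)
        hms = random_marker_set(
            rng, n_lines=n_lines, allele_counts=(2, 3, 2, 4, 2, 3, 2, 2, 3, 2)
        )
        designs = asc.build_marker_designs(hms, hms.line_ids)
        causal = [designs[1], designs[6]]
        y_vals = (
            causal[0].columns @ np.full(causal[0].columns.shape[1], 6.0)
            + causal[1].columns @ np.full(causal[1].columns.shape[1], 3.0)
            + rng.normal(0, noise, n_lines)
        )
        y = pd.Series(y_vals, index=hms.line_ids)
        ev = random_eigenvectors(rng, hms.line_ids)
        return hms, y, ev, [c.marker_id for c in causal]

    def test_recovers_causal_markers(self):
        hms, y, ev, causal_ids = self._world()
        pre = asc.stage1_scan(hms, y, ev, alpha=0.01)
        res = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.01)
        assert set(causal_ids) <= {r.marker_id for r in res}

    def test_r2_ordering_and_budget(self):
        hms, y, ev, causal_ids = self._world()
        pre = asc.stage1_scan(hms, y, ev, alpha=0.01)
        res = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.01)
        r2 = {r.marker_id: r.r2_percent for r in res}
        assert r2[causal_ids[0]] > r2[causal_ids[1]]  # larger effect, larger R2
        assert sum(r2.values()) <= 100.0 + 1e-9

    def test_perfect_ld_pair_keeps_one(self):
        rng = np.random.default_rng(11)
        h = rng.integers(1, 3, size=(100, 4)).astype(np.int16)
        h[:, 1] = h[:, 0]  # markers 1 and 2 identical
        hms = toy_marker_set(h, h.copy())
        d0 = asc.build_marker_designs(hms, hms.line_ids)[0]
        y = pd.Series(
            d0.columns[:, 0] * 5.0 + rng.normal(0, 0.3, 100), index=hms.line_ids
        )
        ev = no_eigenvectors(hms.line_ids)
        pre = asc.stage1_scan(hms, y, ev, alpha=0.05, n_eigenvectors=0)
        res = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.05, n_eigenvectors=0)
        kept = {r.marker_id for r in res}
        assert len(kept & {"LDB_chr1_1000", "LDB_chr1_2000"}) == 1

    def test_noiseless_single_qtl_r2_near_total(self):
        rng = np.random.default_rng(12)
        h = rng.integers(1, 4, size=(80, 3)).astype(np.int16)
        hms = toy_marker_set(h, h.copy())
        d = asc.build_marker_designs(hms, hms.line_ids)[0]
        y = pd.Series(d.columns @ np.array([5.0, 10.0]), index=hms.line_ids)
        ev = no_eigenvectors(hms.line_ids)
        pre = asc.stage1_scan(hms, y, ev, alpha=0.05, n_eigenvectors=0)
        res = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.05, n_eigenvectors=0)
        hit = [r for r in res if r.marker_id == "LDB_chr1_1000"][0]
        assert hit.r2_percent > 99.0

    def test_empty_preselection_returns_empty(self):
        hms, y, ev, _ = self._world()
        empty = pd.DataFrame(columns=["marker_id"])
        assert asc.stage2_stepwise(hms, empty, y, ev) == []

    def test_bonferroni_is_stricter(self):
        hms, y, ev, _ = self._world(noise=4.0)
        pre = asc.stage1_scan(hms, y, ev, alpha=0.2)
        loose = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.05)
        strict = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.05, bonferroni=True)
        assert {r.marker_id for r in strict} <= {r.marker_id for r in loose}

    def test_deterministic(self):
        hms, y, ev, _ = self._world()
        pre = asc.stage1_scan(hms, y, ev, alpha=0.01)
        a = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.01)
        b = asc.stage2_stepwise(hms, pre, y, ev, alpha=0.01)
        assert [(r.marker_id, r.p_value, r.r2_percent) for r in a] == [
            (r.marker_id, r.p_value, r.r2_percent) for r in b
        ]


class TestAlleleEffects:
    def test_noiseless_three_allele_contrasts_exact(self):
        rng = np.random.default_rng(20)
        h = rng.integers(1, 4, size=(90, 1)).astype(np.int16)
        hms = toy_marker_set(h, h.copy())
        d = asc.build_marker_designs(hms, hms.line_ids)[0]
        # effects 0 (ref), 5, 10 on the design's allele order
        y = pd.Series(d.columns @ np.array([5.0, 10.0]), index=hms.line_ids)
        ev = no_eigenvectors(hms.line_ids)
        eff = asc.allele_effects(hms, y, ev, [d.marker_id], d.marker_id, n_eigenvectors=0)
        a0, a1, a2 = d.allele_codes
        assert eff[a1] - eff[a0] == pytest.approx(5.0, abs=1e-8)
        assert eff[a2] - eff[a0] == pytest.approx(10.0, abs=1e-8)

    def test_frequency_weighted_effects_sum_to_zero(self):
        rng = np.random.default_rng(21)
        h = rng.integers(1, 4, size=(90, 1)).astype(np.int16)
        hms = toy_marker_set(h, h.copy())
        d = asc.build_marker_designs(hms, hms.line_ids)[0]
        y = pd.Series(d.columns @ np.array([3.0, 7.0]) + rng.normal(0, 1, 90), index=hms.line_ids)
        eff = asc.allele_effects(
            hms, y, no_eigenvectors(hms.line_ids), [d.marker_id], d.marker_id, n_eigenvectors=0
        )
        weighted = sum(d.freqs[i] * eff[a] for i, a in enumerate(d.allele_codes))
        assert weighted == pytest.approx(0.0, abs=1e-10)


class TestAnnotation:
    def _results(self):
        return [
            asc.QTLResult("LDB_chr1_1000", "chr1", 1000, 3, 1e-8, 10.0),
            asc.QTLResult("LDB_chr2_5000", "chr2", 5000, 2, 1e-6, 5.0),
        ]

    def test_exact_id_match(self):
        anchors = pd.DataFrame({"marker_id": ["LDB_chr1_1000"], "gene": ["Ppd-like"]})
        out = asc.annotate_known_genes(self._results(), anchors)
        assert out[0].gene == "Ppd-like"
        assert out[1].gene == "-"

    def test_positional_match_within_window(self):
        anchors = pd.DataFrame(
            {"marker_id": ["X"], "gene": ["Rht-like"], "chrom": ["chr2"], "pos_bp": [5400]}
        )
        out = asc.annotate_known_genes(self._results(), anchors, window_bp=500)
        assert out[1].gene == "Rht-like"

    def test_zero_window_requires_exact_position(self):
        anchors = pd.DataFrame(
            {"marker_id": ["X"], "gene": ["Rht-like"], "chrom": ["chr2"], "pos_bp": [5400]}
        )
        out = asc.annotate_known_genes(self._results(), anchors, window_bp=0)
        assert out[1].gene == "-"

    def test_results_table_shape(self):
        tbl = asc.results_table(self._results(), trait="maturity", environment="E1")
        assert list(tbl["marker"]) == ["LDB_chr1_1000", "LDB_chr2_5000"]
        assert (tbl["trait"] == "maturity").all()
        assert set(tbl.columns) == {
            "trait", "environment", "marker", "chromosome",
            "n_alleles", "corresponding_gene", "p_value", "R2_percent",
        }
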