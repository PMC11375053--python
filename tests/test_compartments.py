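"""Region calling, TCA components, EBV/plasma stratification, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tlsniche.compartments as comp
from tlsniche.compartments import (SpotGrid, bin_stereo_spots, call_regions,
                                   classify_plasma_cooccurrence,
                                   compare_apoptosis, find_tca_components,
                                   infiltration_bin, normalized_connection,
                                   stratify_ebv)


def _square_grid(n, pitch=100.0):
    ids = [f"s{i}" for i in range(n * n)]
    xx, yy = np.meshgrid(np.arange(n), np.arange(n))
    coords = pd.DataFrame({"x": xx.ravel() * pitch, "y": yy.ravel() * pitch},
                          index=ids)
    return SpotGrid(coords=coords, platform="stereo-bin", pitch=pitch)


# ---------------------------------------------------------------------------
# Stereo-seq binning
# ---------------------------------------------------------------------------

class TestBinStereo:
    def _raw(self, n_side, rng=None):
        """Raw 0.5 µm-pitch spot field, n_side x n_side spots."""
        ix, iy = np.meshgrid(np.arange(n_side), np.arange(n_side))
        coords = pd.DataFrame({"x": ix.ravel() * 0.5, "y": iy.ravel() * 0.5})
        vals = (np.ones((n_side * n_side, 2)) if rng is None
                else rng.poisson(2.0, size=(n_side * n_side, 2)))
        counts = pd.DataFrame(vals, columns=["g1", "g2"])
        return counts, coords

    def test_uniform_field_full_bins_sum_exactly(self):
        counts, coords = self._raw(200)  # exactly 2x2 full bins of 100x100
        binned, grid = bin_stereo_spots(counts, coords, bin_width=100)
        assert len(binned) == 4
        assert (binned["g1"] == 10_000).all()
        assert not grid.coords["partial"].any()

    def test_partial_edge_bins_kept_and_flagged(self):
        counts, coords = self._raw(150)
        binned, grid = bin_stereo_spots(counts, coords, bin_width=100)
        assert len(binned) == 4
        assert grid.coords["partial"].sum() == 3

    def test_totals_match_brute_force_window_sums(self):
        rng = np.random.default_rng(2)
        counts, coords = self._raw(120, rng)
        binned, _ = bin_stereo_spots(counts, coords, bin_width=50)
        ix = (coords["x"] / 0.5).round().astype(int) // 50
        iy = (coords["y"] / 0.5).round().astype(int) // 50
        for (bx, by), idx in counts.groupby([ix, iy]).groups.items():
            assert binned.loc[f"bin_{bx}_{by}", "g1"] == \
                counts.loc[idx, "g1"].sum()

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        counts, coords = self._raw(130, rng)
        binned, _ = bin_stereo_spots(counts, coords)
        assert binned.to_numpy().sum() == counts.to_numpy().sum()

    def test_bin100_pitch_matches_platform(self):
        counts, coords = self._raw(100)
        _, grid = bin_stereo_spots(counts, coords, bin_width=100)
        assert grid.pitch == pytest.approx(49.72)

    def test_rebinning_rejected(self):
        counts, coords = self._raw(100)
        with pytest.raises(ValueError, match="already binned"):
            bin_stereo_spots(counts, coords, already_binned=True)

    def test_nonpositive_width_rejected(self):
        counts, coords = self._raw(100)
        with pytest.raises(ValueError, match="width"):
            bin_stereo_spots(counts, coords, bin_width=0)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

class TestCallRegions:
    def _scores(self, mal, b, t):
        return pd.DataFrame({"malignant": mal, "B": b, "T": t},
                            index=[f"s{i}" for i in range(len(mal))])

    def test_low_scores_go_to_stroma(self, rng):
        s = self._scores(rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                         rng.normal(0, 1, 50))
        s.iloc[0] = [-5.0, -5.0, -5.0]  # all-low spot
        assert call_regions(s).iloc[0] == "stroma"

    def test_tie_between_malignant_and_lymphoid_goes_to_tca(self, rng):
        base = rng.normal(0, 1, 50)
        # all three z-scores coincide: the precedence rule must pick TCA
        s = self._scores(base.copy(), base.copy(), base.copy())
        out = call_regions(s)
        z = (base - base.mean()) / base.std()
        assert (out[z > 0.5] == "TCA").all()
        assert not (out == "TLS").any()

    def test_constant_score_rejected(self):
        s = self._scores(np.ones(10), np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            call_regions(s)

    def test_planted_regions_recovered(self, default_sim):
        from tlsniche.simulate import score_region_call
        acc = score_region_call(default_sim["truth"], default_sim["regions"])
        assert acc >= 0.95

    def test_accuracy_degrades_towards_chance_as_fold_change_drops(self):
        import warnings

        from tlsniche.scoring import log_normalize, module_score
        from tlsniche.simulate import (default_spatial_config,
                                       generate_spatial_sample,
                                       score_region_call)
        accs = {}
        for fc in (1.0, 2.0, 8.0):
            adata, truth = generate_spatial_sample(
                default_spatial_config(seed=21, fold_change=fc))
            ln = log_normalize(adata)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = pd.DataFrame({
                    r: module_score(ln, truth.signatures[r], seed=0)
                    for r in ("malignant", "B", "T")})
            accs[fc] = score_region_call(truth, call_regions(scores))
        stroma_frac = 971 / 1600  # chance: everything called stroma
        assert accs[1.0] < stroma_frac + 0.10
        assert accs[1.0] <= accs[2.0] + 0.05 <= accs[8.0] + 0.10
        assert accs[8.0] >= 0.95


# ---------------------------------------------------------------------------
# TCA components
# ---------------------------------------------------------------------------

class TestComponents:
    def test_isolated_spot_is_singleton(self):
        grid = _square_grid(5)
        regions = pd.Series("stroma", index=grid.coords.index, dtype=object)
        regions.iloc[12] = "TCA"
        c = find_tca_components(regions, grid)
        assert (c >= 0).sum() == 1

    def test_distant_spots_split_into_components(self):
        grid = _square_grid(7)
        regions = pd.Series("stroma", index=grid.coords.index, dtype=object)
        regions.loc["s0"] = "TCA"   # (0,0)
        regions.loc["s3"] = "TCA"   # (3,0): 3 pitches away
        c = find_tca_components(regions, grid)
        assert c[c >= 0].nunique() == 2

    def test_matches_flood_fill_oracle(self, rng):
        grid = _square_grid(12)
        for _ in range(5):
            mask = rng.random(144) < 0.4
            regions = pd.Series(np.where(mask, "TCA", "stroma"),
                                index=grid.coords.index)
            got = find_tca_components(regions, grid)
            # oracle: BFS flood fill on 4-connectivity
            coords = {s: (int(grid.coords.loc[s, "x"] // 100),
                          int(grid.coords.loc[s, "y"] // 100))
                      for s in grid.coords.index[mask]}
            seen, groups = set(), []
            for s in coords:
                if s in seen:
                    continue
                stack, grp = [s], set()
                while stack:
                    u = stack.pop()
                    if u in grp:
                        continue
                    grp.add(u)
                    ux, uy = coords[u]
                    for v, (vx, vy) in coords.items():
                        if v not in grp and abs(ux - vx) + abs(uy - vy) == 1:
                            stack.append(v)
                seen |= grp
                groups.append(grp)
            oracle = {}
            for g in groups:
                for s in g:
                    oracle[s] = min(g)
            lab = {s: oracle[s] for s in coords}
            # same partition: equal label <-> equal component
            spots = list(coords)
            for i in range(0, len(spots) - 1, 3):
                a, b = spots[i], spots[i + 1]
                assert (lab[a] == lab[b]) == (got[a] == got[b])

    def test_partition_invariant_to_spot_order(self, default_sim):
        regions, grid = default_sim["regions"], default_sim["grid"]
        perm = np.random.default_rng(5).permutation(len(regions))
        regions_p = regions.iloc[perm]
        grid_p = SpotGrid(coords=grid.coords.iloc[perm],
                          platform=grid.platform, pitch=grid.pitch)
        a = find_tca_components(regions, grid)
        b = find_tca_components(regions_p, grid_p)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


# ---------------------------------------------------------------------------
# EBV stratification
# ---------------------------------------------------------------------------

class TestStratifyEbv:
    def _comps(self, n, c=0):
        idx = [f"s{i}" for i in range(n)]
        return pd.Series(c, index=idx)

    def test_distinct_scores_quartile_counts(self):
        comps = self._comps(100)
        score = pd.Series(np.arange(1.0, 101.0), index=comps.index)
        spot_cls, _ = stratify_ebv(comps, score)
        assert (spot_cls == "high").sum() == 25
        assert (spot_cls == "low").sum() == 25
        assert (spot_cls == "mid").sum() == 50

    def test_all_equal_scores_all_mid(self):
        comps = self._comps(40)
        spot_cls, comp_cls = stratify_ebv(
            comps, pd.Series(2.0, index=comps.index))
        assert (spot_cls == "mid").all()
        assert comp_cls == {0: "mid"}

    def test_matches_quantile_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 200))
            comps = self._comps(n)
            vals = rng.normal(size=n)
            score = pd.Series(vals, index=comps.index)
            spot_cls, _ = stratify_ebv(comps, score)
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            oracle = np.where(vals > q3, "high",
                              np.where(vals < q1, "low", "mid"))
            assert (spot_cls.to_numpy() == oracle).all()

    def test_quartile_conservation_property(self, rng):
        for n in (40, 101, 997):
            comps = self._comps(n)
            score = pd.Series(rng.permutation(np.arange(n, dtype=float)),
                              index=comps.index)
            spot_cls, _ = stratify_ebv(comps, score)
            assert abs((spot_cls == "high").sum() - n // 4) <= 1
            assert abs((spot_cls == "low").sum() - n // 4) <= 1

    def test_too_few_tca_spots_all_mid_with_warning(self):
        comps = self._comps(3)
        with pytest.warns(UserWarning, match="fewer than 4"):
            _, comp_cls = stratify_ebv(
                comps, pd.Series([1.0, 2.0, 3.0], index=comps.index))
        assert comp_cls == {0: "mid"}

    def test_majority_vote_with_tie_to_mid(self):
        idx = [f"s{i}" for i in range(8)]
        comps = pd.Series([0, 0, 1, 1, 2, 2, 2, 2], index=idx)
        score = pd.Series([10, 9, 1, 2, 5, 6, 4, 7.0], index=idx)
        _, comp_cls = stratify_ebv(comps, score)
        assert comp_cls[0] == "high" and comp_cls[1] == "low"
        assert comp_cls[2] == "mid"


# ---------------------------------------------------------------------------
# plasma co-occurrence
# ---------------------------------------------------------------------------

class TestPlasmaCooccurrence:
    def test_cold_component_is_wop(self):
        grid = _square_grid(10)
        comps = pd.Series(-1, index=grid.coords.index)
        comps.iloc[:4] = 0
        plasma = pd.Series(0.0, index=grid.coords.index)
        plasma.iloc[50:] = np.linspace(1, 2, 50)  # hot spots far away
        cls = classify_plasma_cooccurrence(comps, plasma, grid)
        assert cls[0] == "woP"

    def test_zero_quantile_makes_every_component_wp(self, rng):
        grid = _square_grid(6)
        comps = pd.Series(-1, index=grid.coords.index)
        comps.iloc[:3] = 0
        plasma = pd.Series(rng.random(36), index=grid.coords.index)
        cls = classify_plasma_cooccurrence(comps, plasma, grid,
                                           occupancy_quantile=0.0)
        assert cls[0] == "wP"

    def test_halo_spot_counts(self):
        grid = _square_grid(10)
        comps = pd.Series(-1, index=grid.coords.index)
        comps.loc["s44"] = 0           # (4,4)
        plasma = pd.Series(0.0, index=grid.coords.index)
        plasma.loc["s45"] = 10.0       # one pitch away -> in the halo
        cls = classify_plasma_cooccurrence(comps, plasma, grid)
        assert cls[0] == "wP"

    def test_planted_plasma_components_recovered(self, default_sim):
        truth = default_sim["truth"]
        plasma_cls = default_sim["plasma_class"]
        comps = default_sim["components"]
        hits, total = 0, 0
        for disc in truth.components.index:
            spots = truth.spots.index[truth.spots["component"] == disc]
            pred = comps.reindex(spots)
            pred = pred[pred >= 0]
            if pred.empty:
                continue
            pcomp = int(pred.mode().iloc[0])
            want = "wP" if truth.components.loc[disc, "plasma"] else "woP"
            hits += plasma_cls.get(pcomp) == want
            total += 1
        assert total >= 8 and hits / total >= 0.9


# ---------------------------------------------------------------------------
# apoptosis comparison, normalised connection, infiltration bins
# ---------------------------------------------------------------------------

class TestCompareApoptosis:
    def test_planted_uplift_ranks_high_wp_first(self, default_sim):
        ebv_cls, plasma_cls = (default_sim["ebv_class"],
                               default_sim["plasma_class"])
        comps = default_sim["components"]
        combo = comps.map(lambda c: f"{ebv_cls[c]}-{plasma_cls[c]}"
                          if c >= 0 else "none")
        summary, tests, highest = compare_apoptosis(
            combo, default_sim["scores"]["apoptosis"])
        assert highest == "high-wP"
        n_classes = summary.shape[0]
        assert tests.shape[0] == n_classes * (n_classes - 1) // 2

    def test_null_distributions_give_uniform_p(self, rng):
        pvals = []
        for _ in range(200):
            cls = pd.Series(rng.permutation(["a"] * 30 + ["b"] * 30))
            score = pd.Series(rng.normal(size=60), index=cls.index)
            _, tests, _ = compare_apoptosis(cls, score)
            pvals.append(tests["p"].iloc[0])
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_class_rejected(self):
        cls = pd.Series(["a"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            compare_apoptosis(cls, pd.Series(np.arange(10.0)))

    def test_tiny_class_excluded_with_warning(self, rng):
        cls = pd.Series(["a"] * 10 + ["b"] * 1 + ["c"] * 10)
        score = pd.Series(rng.normal(size=21), index=cls.index)
        with pytest.warns(UserWarning, match="excluded"):
            summary, _, _ = compare_apoptosis(cls, score)
        assert set(summary["cls"]) == {"a", "c"}


class TestNormalizedConnection:
    def test_worked_example(self):
        assert normalized_connection(6.0, 2, 3) == pytest.approx(1.0)

    def test_zero_value(self):
        assert normalized_connection(0.0, 5, 7) == 0.0

    def test_symmetry(self):
        assert normalized_connection(4.0, 2, 5) == \
            normalized_connection(4.0, 5, 2)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            normalized_connection(1.0, 0, 3)


class TestInfiltrationBin:
    @pytest.mark.parametrize("frac,expected", [
        (0.0, 1), (0.10, 1), (0.25, 1), (0.26, 2), (0.50, 2),
        (0.60, 3), (0.75, 3), (0.76, 4), (1.0, 4),
    ])
    def test_bin_assignment(self, frac, expected):
        assert infiltration_bin(frac) == expected

    @given(st.floats(min_value=0.0, max_value=1.0,
                     allow_nan=False))
    def test_always_in_range(self, frac):
        assert infiltration_bin(frac) in (1, 2, 3, 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infiltration_bin(1.2)
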