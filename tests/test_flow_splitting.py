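import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aneuflow import (
    NetworkProperties,
    VesselTree,
    area_split,
    bifurcation_split,
    circular_section,
    compute_all_splits,
    make_tree,
    murray_split,
    zero_pressure_network_split,
)
from aneuflow.vessel_model import CrossSection


def y_tree(r1=1.0, r2=1.0, trunk=1.5, lengths=(5.0, 5.0, 5.0)):
    t = VesselTree()
    t.add_node("in", kind="inlet")
    t.add_node("j", kind="junction")
    t.add_node("a", kind="outlet")
    t.add_node("b", kind="outlet")
    t.add_segment("in", "j", length=lengths[0], radius=trunk)
    t.add_segment("j", "a", length=lengths[1], radius=r1)
    t.add_segment("j", "b", length=lengths[2], radius=r2)
    return t


def two_level_tree():
    # root splits into A (D=2) and B (D=1); A splits into A1, A2 (D=1 each)
    t = VesselTree()
    for n, k in [("in", "inlet"), ("j1", "junction"), ("j2", "junction"),
                 ("a1", "outlet"), ("a2", "outlet"), ("b", "outlet")]:
        t.add_node(n, kind=k)
    t.add_segment("in", "j1", length=5, radius=1.5)
    t.add_segment("j1", "j2", length=5, radius=1.0)   # branch A, D=2
    t.add_segment("j1", "b", length=5, radius=0.5)    # branch B, D=1
    t.add_segment("j2", "a1", length=5, radius=0.5)
    t.add_segment("j2", "a2", length=5, radius=0.5)
    return t


class TestMurray:
    def test_symmetric_split(self):
        assert murray_split({"a": 1, "b": 1}, n=2).fractions == {"a": 0.5, "b": 0.5}

    def test_square_law(self):
        f = murray_split({"a": 1, "b": 2}, n=2).fractions
        assert f["a"] == pytest.approx(0.2)
        assert f["b"] == pytest.approx(0.8)

    def test_published_cube_law_consistency(self):
        # diameters inferred from a published n=2 row (0.236, 0.182, 0.581)
        # via D_i ~ sqrt(f_i); the n=3 split must reproduce the printed
        # n=3 row of the same vessel at 3 decimals
        f2 = {"o1": 0.236, "o2": 0.182, "o3": 0.581}
        d = {k: np.sqrt(v) for k, v in f2.items()}
        f3 = murray_split(d, n=3, method="bc3").fractions
        assert round(f3["o3"], 3) == 0.697
        assert round(f3["o1"], 3) == 0.181

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            murray_split({}, n=2)
        with pytest.raises(ValueError):
            murray_split({"a": -1.0, "b": 1.0}, n=2)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=8),
           st.floats(0.5, 4.0))
    def test_conservation_and_permutation(self, diam, n):
        keys = [f"o{i}" for i in range(len(diam))]
        f = murray_split(dict(zip(keys, diam)), n=n).fractions
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
        rev = murray_split(dict(zip(keys[::-1], diam[::-1])), n=n).fractions
        for k in keys:
            assert rev[k] == pytest.approx(f[k], rel=1e-12)

    def test_monotone_in_own_diameter(self):
        base = {"a": 1.0, "b": 2.0, "c": 1.5}
        for n in (2, 3):
            f0 = murray_split(base, n=n).fractions["a"]
            bigger = dict(base, a=1.2)
            assert murray_split(bigger, n=n).fractions["a"] > f0


class TestBifurcationSplit:
    def test_single_junction_matches_global_murray(self):
        t = y_tree(r1=0.5, r2=1.0)
        local = bifurcation_split(t).fractions
        assert local["a"] == pytest.approx(0.2)
        assert local["b"] == pytest.approx(0.8)

    def test_two_level_hand_product(self):
        f = bifurcation_split(two_level_tree()).fractions
        assert f["a1"] == pytest.approx(0.8 * 0.5)
        assert f["a2"] == pytest.approx(0.8 * 0.5)
        assert f["b"] == pytest.approx(0.2)

    def test_hierarchical_differs_from_global_murray(self):
        # same leaves (D=1 each) but hierarchy matters: global Murray
        # gives thirds, the local product gives (0.4, 0.4, 0.2)
        t = two_level_tree()
        local = bifurcation_split(t).fractions
        flat = murray_split({"a1": 1.0, "a2": 1.0, "b": 1.0}, n=2).fractions
        assert flat["b"] == pytest.approx(1 / 3)
        assert local["b"] == pytest.approx(0.2)

    def test_one_junction_equals_murray_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            radii = rng.uniform(0.3, 3.0, size=rng.integers(2, 6))
            t = y_like = VesselTree()
            t.add_node("in", kind="inlet")
            t.add_node("j", kind="junction")
            t.add_segment("in", "j", length=5, radius=float(np.max(radii) * 1.3))
            for i, r in enumerate(radii):
                t.add_node(f"o{i}", kind="outlet")
                t.add_segment("j", f"o{i}", length=5, radius=float(r))
            local = bifurcation_split(t).fractions
            flat = murray_split({f"o{i}": 2 * r for i, r in enumerate(radii)}, n=2).fractions
            for k in local:
                assert local[k] == pytest.approx(flat[k], rel=1e-12)


class TestAreaSplit:
    def test_circular_sections_match_diameter_split(self):
        t = make_tree([1.0, 2.0, 1.5], section_points=720)
        f_area = area_split(t, n_rays=720).fractions
        f_diam = bifurcation_split(t).fractions
        for k in f_area:
            assert f_area[k] == pytest.approx(f_diam[k], abs=1e-4)

    def test_elliptical_vs_circular_section(self):
        # semi-axes (1, 2) vs circle r=1: fractions ~ (2/3, 1/3)
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ellipse = np.column_stack([np.cos(theta), 2 * np.sin(theta), np.zeros_like(theta)])
        t = VesselTree()
        t.add_node("in", kind="inlet")
        t.add_node("j", kind="junction")
        t.add_node("e", kind="outlet")
        t.add_node("c", kind="outlet")
        t.add_segment("in", "j", length=5, radius=2.0)
        t.add_segment("j", "e", length=5,
                      section=CrossSection([0, 0, 0], [0, 0, 1], ellipse))
        t.add_segment("j", "c", length=5,
                      section=circular_section([5, 0, 0], [0, 0, 1], 1.0, n_points=720))
        f = area_split(t, n_rays=720).fractions
        assert f["e"] == pytest.approx(2 / 3, abs=1e-3)
        assert f["c"] == pytest.approx(1 / 3, abs=1e-3)

    def test_uniform_dilation_leaves_fractions_unchanged(self):
        t1 = make_tree([1.0, 2.0, 1.5])
        t2 = make_tree([1.1, 2.2, 1.65])  # all boundaries dilated x1.1
        f1 = area_split(t1).fractions
        f2 = area_split(t2).fractions
        for k in f1:
            assert f2[k] == pytest.approx(f1[k], abs=1e-9)


class TestZeroPressureNetwork:
    def test_symmetric_y(self):
        f = zero_pressure_network_split(y_tree()).fractions
        assert f["a"] == pytest.approx(0.5, abs=1e-12)

    def test_fourth_power_of_radius(self):
        # equal lengths, radii 1 and 2: conductances 1:16 -> (1/17, 16/17)
        f = zero_pressure_network_split(y_tree(r1=1.0, r2=2.0)).fractions
        assert f["a"] == pytest.approx(1 / 17, rel=1e-10)
        assert f["b"] == pytest.approx(16 / 17, rel=1e-10)

    def test_three_outlet_series_parallel_oracle(self):
        # inlet -> j1 -> {o1, j2}; j2 -> {o2, o3}; oracle: series-parallel
        # reduction of the Poiseuille conductances
        t = VesselTree()
        for n, k in [("in", "inlet"), ("j1", "junction"), ("j2", "junction"),
                     ("o1", "outlet"), ("o2", "outlet"), ("o3", "outlet")]:
            t.add_node(n, kind=k)
        segs = {("in", "j1"): (4.0, 1.4), ("j1", "o1"): (6.0, 0.9),
                ("j1", "j2"): (3.0, 1.1), ("j2", "o2"): (5.0, 0.7),
                ("j2", "o3"): (7.0, 0.8)}
        for (u, v), (length, radius) in segs.items():
            t.add_segment(u, v, length=length, radius=radius)

        mu = 0.004
        g = {k: np.pi * (r * 1e-3) ** 4 / (8 * mu * l * 1e-3) for k, (l, r) in segs.items()}
        g23 = g[("j2", "o2")] + g[("j2", "o3")]
        g_sub = 1.0 / (1.0 / g[("j1", "j2")] + 1.0 / g23)  # j1 -> ground via j2
        f1 = g[("j1", "o1")] / (g[("j1", "o1")] + g_sub)
        f2 = (1 - f1) * g[("j2", "o2")] / g23
        f3 = (1 - f1) * g[("j2", "o3")] / g23

        f = zero_pressure_network_split(t, NetworkProperties(viscosity=mu)).fractions
        assert f["o1"] == pytest.approx(f1, rel=1e-10)
        assert f["o2"] == pytest.approx(f2, rel=1e-10)
        assert f["o3"] == pytest.approx(f3, rel=1e-10)

    def test_zero_radius_is_error(self):
        t = y_tree(r1=0.0)
        with pytest.raises(ValueError):
            zero_pressure_network_split(t)


class TestComputeAllSplits:
    def test_symmetric_tree_all_methods_agree(self):
        t = make_tree([1.0, 1.0])
        for method, res in compute_all_splits(t).items():
            for frac in res.fractions.values():
                assert frac == pytest.approx(0.5, abs=1e-9), method

    def test_conservation_everywhere(self, three_outlet_tree):
        for res in compute_all_splits(three_outlet_tree).values():
            assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_bc4_bc5_agree_for_circular_sections(self):
        t = make_tree([1.0, 2.0, 1.5], section_points=720)
        s = compute_all_splits(t, n_rays=720)
        for k in s["bc4"].fractions:
            assert s["bc5"].fractions[k] == pytest.approx(s["bc4"].fractions[k], abs=1e-4)

    def test_outlet_order_is_stable(self, three_outlet_tree):
        s = compute_all_splits(three_outlet_tree)
        for res in s.values():
            assert list(res.fractions) == ["o1", "o2", "o3"]
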