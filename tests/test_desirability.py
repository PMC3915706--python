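import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from releaseopt import (
    Component,
    CompositeSpec,
    DesirabilitySpec,
    composite_desirability,
    d_ltb,
    d_ntb,
    d_stb,
)
from releaseopt.rsm import ModelTermSet, ResponseSurface, Term


def constant_surface(value, k=1, label="c", role="mean"):
    return ResponseSurface(
        terms=ModelTermSet((Term((0,) * k),)),
        coefficients=(value,),
        role=role,
        label=label,
    )


class TestIndividualDesirabilities:
    def test_ntb_identities(self):
        assert d_ntb(30, 20, 30, 40) == 1.0
        assert d_ntb(20, 20, 30, 40) == 0.0
        assert d_ntb(40, 20, 30, 40) == 0.0
        assert d_ntb(12, 20, 30, 40) == 0.0
        assert d_ntb(55, 20, 30, 40) == 0.0

    def test_ntb_linear_midpoints(self):
        # profile spec (20, 30, 40): halfway up the rising side
        assert d_ntb(25, 20, 30, 40) == pytest.approx(0.5)
        assert d_ntb(35, 20, 30, 40) == pytest.approx(0.5)

    def test_ltb_and_stb(self):
        assert d_ltb(120, 50, 100) == 1.0
        assert d_ltb(40, 50, 100) == 0.0
        assert d_ltb(75, 50, 100) == pytest.approx(0.5)
        assert d_stb(0.0, 0, 10) == 1.0
        assert d_stb(12, 0, 10) == 0.0
        assert d_stb(5, 0, 10) == pytest.approx(0.5)

    def test_ntb_exponents_shape_the_ramp(self):
        assert d_ntb(25, 20, 30, 40, r=2) == pytest.approx(0.25)
        assert d_ntb(35, 20, 30, 40, s=0.5) == pytest.approx(np.sqrt(0.5))

    @given(
        lsl=st.floats(-50, 40),
        width1=st.floats(0.5, 30),
        width2=st.floats(0.5, 30),
        r=st.floats(0.2, 4),
        s=st.floats(0.2, 4),
    )
    def test_ntb_in_unit_interval_and_unimodal(self, lsl, width1, width2, r, s):
        target, usl = lsl + width1, lsl + width1 + width2
        ys = np.linspace(lsl - 5, usl + 5, 101)
        d = d_ntb(ys, lsl, target, usl, r, s)
        assert np.all((0 <= d) & (d <= 1))
        below = d[ys <= target]
        above = d[ys >= target]
        assert np.all(np.diff(below) >= -1e-12)
        assert np.all(np.diff(above) <= 1e-12)

    @given(lower=st.floats(-20, 20), width=st.floats(0.5, 40), r=st.floats(0.2, 4))
    def test_ltb_stb_monotone(self, lower, width, r):
        upper = lower + width
        ys = np.linspace(lower - 3, upper + 3, 64)
        assert np.all(np.diff(d_ltb(ys, lower, upper, r)) >= -1e-12)
        assert np.all(np.diff(d_stb(ys, lower, upper, r)) <= 1e-12)

    def test_linear_ntb_matches_independent_piecewise_formula(self):
        def piecewise(y, lsl, t, usl):
            if y <= lsl or y >= usl:
                return 0.0
            return (y - lsl) / (t - lsl) if y <= t else (usl - y) / (usl - t)

        ys = np.linspace(10, 50, 81)
        for y in ys:
            assert d_ntb(y, 20, 30, 40) == pytest.approx(
                piecewise(y, 20, 30, 40), abs=1e-12
            )


class TestComposite:
    def composite_of(self, values, weights=None):
        weights = weights or [1.0] * len(values)
        comps = [
            Component(
                constant_surface(v, label=f"c{i}"),
                DesirabilitySpec("STB", target=0.0, usl=1.0),
                weight=w,
                name=f"c{i}",
            )
            for i, (v, w) in enumerate(zip(values, weights))
        ]
        return CompositeSpec(comps)

    def test_all_components_one(self):
        # STB with upper bound 1: value 0 -> d = 1
        comp = self.composite_of([0.0, 0.0, 0.0])
        assert composite_desirability(np.zeros(1), comp) == pytest.approx(1.0)

    def test_annihilation(self):
        comp = self.composite_of([0.0, 1.0])  # second component d = 0
        assert composite_desirability(np.zeros(1), comp) == 0.0

    def test_geometric_mean_of_quarter_and_one(self):
        comp = self.composite_of([0.75, 0.0])  # d = 0.25 and d = 1
        assert composite_desirability(np.zeros(1), comp) == pytest.approx(0.5)

    def test_weight_scaling_invariance(self):
        values = [0.3, 0.6, 0.15]
        base = composite_desirability(np.zeros(1), self.composite_of(values))
        scaled = composite_desirability(
            np.zeros(1), self.composite_of(values, weights=[7.0] * 3)
        )
        assert base == pytest.approx(scaled)

    @given(
        vals=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5),
        c=st.floats(0.1, 20),
    )
    def test_weight_scaling_invariance_property(self, vals, c):
        base = composite_desirability(np.zeros(1), self.composite_of(vals))
        scaled = composite_desirability(
            np.zeros(1), self.composite_of(vals, weights=[c] * len(vals))
        )
        assert base == pytest.approx(scaled, rel=1e-9)

    def test_zero_weights_rejected(self):
        comps = [
            Component(
                constant_surface(0.5),
                DesirabilitySpec("STB", target=0.0, usl=1.0),
                weight=0.0,
            )
        ]
        with pytest.raises(ValueError, match="weight"):
            CompositeSpec(comps)

    def test_zero_weight_components_ignored(self):
        comp = CompositeSpec(
            [
                Component(
                    constant_surface(0.75, label="live"),
                    DesirabilitySpec("STB", target=0.0, usl=1.0),
                    weight=2.0,
                    name="live",
                ),
                Component(
                    constant_surface(1.0, label="dead"),  # would be d = 0
                    DesirabilitySpec("STB", target=0.0, usl=1.0),
                    weight=0.0,
                    name="dead",
                ),
            ]
        )
        assert composite_desirability(np.zeros(1), comp) == pytest.approx(0.25)

    def test_breakdown_reports_components(self):
        comp = self.composite_of([0.2, 0.9])
        res = composite_desirability(np.zeros(1), comp, return_breakdown=True)
        assert len(res.breakdown) == 2
        names = [b["component"] for b in res.breakdown]
        assert names == ["c0", "c1"]
        d0 = res.breakdown[0]["desirability"]
        assert d0 == pytest.approx(0.8)

    def test_negative_dispersion_clamped_to_ideal(self):
        comp = CompositeSpec(
            [
                Component(
                    constant_surface(-3.0, label="var"),
                    DesirabilitySpec("STB", target=0.0, usl=1.0),
                    name="var",
                    clamp_nonnegative=True,
                )
            ]
        )
        assert composite_desirability(np.zeros(1), comp) == pytest.approx(1.0)

    def test_batch_evaluation_matches_scalar(self):
        spec = DesirabilitySpec("NTB", lsl=20, target=30, usl=40)
        surface = ResponseSurface(
            terms=ModelTermSet((Term((0,)), Term((1,)))),
            coefficients=(30.0, 5.0),
            label="mu",
        )
        comp = CompositeSpec([Component(surface, spec, name="mu")])
        pts = np.linspace(-3, 3, 25)[:, None]
        batch = composite_desirability(pts, comp)
        singles = [composite_desirability(p, comp) for p in pts]
        assert np.allclose(batch, singles)
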