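"""Anchor location, hinge angles, distances and their changes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fabcompare import (
    AnchorPlan,
    AngleMetrics,
    SyntheticSpec,
    anchor_distances,
    angle_change,
    assign_regions,
    find_anchors,
    generate_couple,
    hinge_angle,
    measure_angles,
)
from fabcompare.errors import (
    AnchorIdentityError,
    AnchorMismatchError,
    AnchorNotFoundError,
    DegenerateError,
)
from fabcompare.geometry import AnchorPoint, AnchorSet

from oracles import angle_by_law_of_cosines


def _anchor_set(pv, pl, pc, chain_type="heavy"):
    return AnchorSet(
        chain_type=chain_type,
        v_cys=AnchorPoint(85, "C", "SG", np.asarray(pv, float)),
        linker_anchor=AnchorPoint(108, "S", "OG", np.asarray(pl, float)),
        c_cys=AnchorPoint(147, "C", "SG", np.asarray(pc, float)),
    )


@pytest.fixture(scope="module")
def planted_couple():
    """Noise-free couple with anchors planted at 92/108/140."""
    spec = SyntheticSpec(noise_sigma=0.0,
                         anchor_plan=AnchorPlan(v_cys=92, linker=108,
                                                c_cys=140))
    return generate_couple(spec)


class TestFindAnchors:
    def test_finds_planted_anchors(self, planted_couple):
        chain = planted_couple.free_heavy
        anchors = find_anchors(chain, assign_regions(chain))
        assert anchors.indices == (92, 108, 140)
        assert anchors.v_cys.atom == "SG"
        assert anchors.linker_anchor.atom == "OG"

    def test_light_chain_anchor_identity(self, planted_couple):
        chain = planted_couple.free_light
        anchors = find_anchors(chain, assign_regions(chain))
        assert anchors.linker_anchor.aa == "R"      # kappa -> arginine
        assert anchors.linker_anchor.atom == "CZ"

    def test_missing_linker_anchor_raises(self, planted_couple):
        chain = planted_couple.free_light.copy()
        chain.residue(108).aa = "A"                 # no Arg left in linker
        with pytest.raises(AnchorNotFoundError):
            find_anchors(chain, assign_regions(chain))

    def test_override_used_verbatim_after_validation(self, planted_couple):
        chain = planted_couple.free_heavy.copy()
        chain.residue(90).aa = "C"                  # extra Cys earlier
        ann = assign_regions(chain)
        default = find_anchors(chain, ann)
        assert default.v_cys.seq_index == 92        # last Cys in variable
        overridden = find_anchors(chain, ann, overrides={"v_cys": 90})
        assert overridden.v_cys.seq_index == 90

    def test_override_wrong_identity_raises(self, planted_couple):
        chain = planted_couple.free_heavy
        with pytest.raises(AnchorIdentityError):
            find_anchors(chain, assign_regions(chain),
                         overrides={"v_cys": 50})

    def test_override_outside_region_raises(self, planted_couple):
        chain = planted_couple.free_heavy
        with pytest.raises(AnchorNotFoundError):
            find_anchors(chain, assign_regions(chain),
                         overrides={"v_cys": 140})

    def test_ca_fallback_when_sidechain_missing(self, planted_couple, caplog):
        chain = planted_couple.free_heavy.copy()
        chain.residue(92).sidechain_anchor = None
        anchors = find_anchors(chain, assign_regions(chain))
        assert anchors.v_cys.atom == "CA"
        np.testing.assert_allclose(anchors.v_cys.coord,
                                   chain.residue(92).backbone_coords["CA"])


class TestHingeAngle:
    def test_collinear_is_180(self):
        a = _anchor_set((0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert hinge_angle(a) == pytest.approx(180.0)

    def test_right_angle(self):
        a = _anchor_set((1, 0, 0), (0, 0, 0), (0, 1, 0))
        assert hinge_angle(a) == pytest.approx(90.0)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            pv, pl, pc = rng.normal(0, 5, (3, 3))
            a = _anchor_set(pv, pl, pc)
            assert hinge_angle(a) == pytest.approx(
                angle_by_law_of_cosines(pv, pl, pc), abs=1e-9)

    def test_coincident_anchors_degenerate(self):
        a = _anchor_set((1, 0, 0), (1, 0, 0), (0, 1, 0))
        with pytest.raises(DegenerateError):
            hinge_angle(a)

    def test_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(11)
        pv, pl, pc = rng.normal(0, 5, (3, 3))
        base = hinge_angle(_anchor_set(pv, pl, pc))
        rot = Rotation.from_euler("xyz", [15, -40, 70], degrees=True).as_matrix()
        trans = np.array([3.0, -1.0, 2.0])
        moved = hinge_angle(_anchor_set(rot @ pv + trans, rot @ pl + trans,
                                        rot @ pc + trans))
        assert moved == pytest.approx(base, abs=1e-9)


class TestDistances:
    def test_three_angstrom_per_axis(self):
        h = _anchor_set((0, 0, 0), (1, 1, 1), (3, 3, 3))
        l = _anchor_set((0, 0, 10), (4, 1, 1), (3, 3, 13), "light_kappa")
        d = anchor_distances(h, l)
        assert d["cys_cys_distance_heavy"] == pytest.approx(np.sqrt(27))
        assert d["linker_linker_distance"] == pytest.approx(3.0)

    def test_random_pairs_match_norm(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = rng.normal(0, 5, (6, 3))
            h = _anchor_set(p[0], p[1], p[2])
            l = _anchor_set(p[3], p[4], p[5], "light_kappa")
            d = anchor_distances(h, l)
            assert d["cys_cys_distance_light"] == pytest.approx(
                float(np.linalg.norm(p[3] - p[5])), abs=1e-12)


class TestAngleChange:
    def _metrics(self, heavy, light, link=10.0):
        return AngleMetrics(
            heavy_angle=heavy, light_angle=light,
            cys_cys_distance_heavy=40.0, cys_cys_distance_light=40.0,
            linker_linker_distance=link,
            heavy_anchor_indices=(85, 108, 147),
            light_anchor_indices=(85, 108, 147),
        )

    def test_signed_deltas_and_average(self):
        change = angle_change(self._metrics(120, 110), self._metrics(110, 120))
        assert change.delta_heavy == pytest.approx(-10.0)
        assert change.delta_light == pytest.approx(10.0)
        assert change.average_abs_change == pytest.approx(10.0)

    def test_identical_metrics_zero(self):
        m = self._metrics(115, 112)
        change = angle_change(m, m)
        assert change.delta_heavy == 0 and change.delta_light == 0
        assert change.average_abs_change == 0

    def test_antisymmetric_under_swap(self):
        f, b = self._metrics(120, 110, 10.0), self._metrics(113, 117, 12.0)
        fwd, rev = angle_change(f, b), angle_change(b, f)
        assert fwd.delta_heavy == pytest.approx(-rev.delta_heavy)
        assert fwd.delta_light == pytest.approx(-rev.delta_light)
        assert fwd.average_abs_change == pytest.approx(rev.average_abs_change)
        assert fwd.delta_linker_linker == pytest.approx(
            -rev.delta_linker_linker)

    def test_anchor_mismatch_raises(self):
        f = self._metrics(120, 110)
        b = self._metrics(110, 120)
        b.heavy_anchor_indices = (90, 108, 147)
        with pytest.raises(AnchorMismatchError):
            angle_change(f, b)


class TestParameterRecovery:
    def test_heavy_hinge_recovered_within_a_degree(self):
        """A +15-degree heavy hinge opens the measured angle by 15 degrees."""
        spec = SyntheticSpec(hinge_angle_heavy=15.0, noise_sigma=0.1, seed=21)
        couple = generate_couple(spec)
        anchors = {}
        for label, chain in (("fh", couple.free_heavy),
                             ("fl", couple.free_light),
                             ("bh", couple.bound_heavy),
                             ("bl", couple.bound_light)):
            anchors[label] = find_anchors(chain, assign_regions(chain))
        change = angle_change(
            measure_angles(anchors["fh"], anchors["fl"]),
            measure_angles(anchors["bh"], anchors["bl"]),
        )
        assert change.delta_heavy == pytest.approx(15.0, abs=1.0)
        assert change.delta_light == pytest.approx(0.0, abs=1.0)
        assert change.average_abs_change == pytest.approx(7.5, abs=1.0)
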