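"""ECV / plasma-volume-fraction arithmetic, phase pairing, regional split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungecv.compartments import (
    MissingPhaseError,
    UninterpretableContrastError,
    compute_ecv,
    compute_ecv_extravascular,
    compute_pvf,
    ecv_result_from_t1,
    pair_phases,
    regional_sections,
)
from lungecv.relaxometry import delta_r1
from lungecv.types import ValidationError


class TestComputeEcv:
    def test_equal_delta_r1_zero_hematocrit_limit(self):
        # Hct -> 0 limit of the identity case: ECV -> 100%
        assert compute_ecv(1e-3, 1e-3, 1e-12) == pytest.approx(1.0)

    def test_blood_roi_self_application_returns_one_minus_hct(self):
        d = float(delta_r1(609.0, 1199.0))
        assert compute_ecv(d, d, 0.23) == 1.0 - 0.23

    def test_study_t1_mean_arithmetic(self):
        """Group-mean T1s (931->559 lung, 1199->609 blood, Hct 0.23)
        give 68.1% -- the T1-mean route, distinct from the per-animal
        average the study reports."""
        dl = float(delta_r1(559.0, 931.0))
        db = float(delta_r1(609.0, 1199.0))
        assert compute_ecv(dl, db, 0.23) == pytest.approx(0.681, abs=0.001)

    def test_zero_blood_delta_r1_uninterpretable(self):
        with pytest.raises(UninterpretableContrastError):
            compute_pvf(1e-3, 0.0, 0.23)

    def test_negative_delta_r1_flagged_not_clipped(self):
        flags = []
        v = compute_ecv(-1e-4, 1e-3, 0.3, flags=flags)
        assert v < 0 and "negative_delta_r1" in flags

    def test_invalid_hematocrit_rejected(self):
        with pytest.raises(ValidationError):
            compute_ecv(1e-3, 1e-3, 1.2)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dl=st.floats(1e-5, 5e-3), db=st.floats(1e-5, 5e-3),
           h=st.floats(0.05, 0.6), scale=st.floats(0.1, 10.0))
    def test_common_scaling_invariance(self, dl, db, h, scale):
        """Scaling both dR1 values leaves ECV unchanged (the agent
        concentration cancels)."""
        assert compute_ecv(dl * scale, db * scale, h) == pytest.approx(
            compute_ecv(dl, db, h), rel=1e-9)


class TestExtravascular:
    @pytest.mark.parametrize("ecv, pvf, expected_pct", [
        (0.70, 0.43, 27), (0.78, 0.46, 32), (0.5, 0.5, 0),
    ])
    def test_subtraction(self, ecv, pvf, expected_pct):
        assert round(100 * compute_ecv_extravascular(ecv, pvf)) == expected_pct

    def test_negative_flagged(self):
        flags = []
        v = compute_ecv_extravascular(0.40, 0.45, flags=flags)
        assert v == pytest.approx(-0.05)
        assert "negative_ecv_extravascular" in flags

    def test_result_identity_enforced(self):
        res = ecv_result_from_t1(
            "naive", 0.23,
            t1_lung_native_ms=931.0, t1_blood_native_ms=1199.0,
            t1_lung_gadolinium_ms=559.0, t1_blood_gadolinium_ms=609.0,
            t1_lung_ferumoxytol_ms=287.0, t1_blood_ferumoxytol_ms=199.0,
        )
        assert res.ecv_extravascular == res.ecv - res.pvf


class TestPairPhases:
    def _mr_manifest(self):
        recs = []
        for cond in ("baseline", "regurgitation"):
            for i, ph in enumerate(("native", "gadolinium", "ferumoxytol")):
                recs.append({"condition": cond, "phase": ph, "order": i})
        return recs

    def test_mr_layout_pairs_each_condition_separately(self):
        pairs = pair_phases(self._mr_manifest())
        assert len(pairs) == 4  # two agents x two conditions
        for p in pairs:
            assert p.native["condition"] == p.condition

    def test_ferumoxytol_first_naive_layout_is_order_variant(self):
        recs = [
            {"condition": "naive", "phase": "native", "order": 0},
            {"condition": "naive", "phase": "ferumoxytol", "order": 1},
            {"condition": "naive", "phase": "gadolinium", "order": 2},
        ]
        pairs = pair_phases(recs)
        gad = [p for p in pairs if p.agent == "gadolinium"][0]
        fex = [p for p in pairs if p.agent == "ferumoxytol"][0]
        assert gad.order_variant and not fex.order_variant

    def test_missing_native_names_the_absent_map(self):
        recs = [{"condition": "volume_loaded", "phase": "gadolinium"}]
        with pytest.raises(MissingPhaseError, match="volume_loaded"):
            pair_phases(recs)

    def test_volume_loaded_uses_post_infusion_native(self):
        recs = [
            {"condition": "volume_loaded", "phase": "native", "id": "post"},
            {"condition": "volume_loaded", "phase": "gadolinium"},
        ]
        pairs = pair_phases(recs)
        assert pairs[0].native["id"] == "post"


class TestRegionalSections:
    def test_extent_ten_splits_3_3_4(self):
        mask = np.zeros((4, 12, 2), dtype=bool)
        mask[:, 1:11, :] = True
        ant, mid, post, (a0, a1, a2, a3) = regional_sections(mask, ap_axis=1)
        assert (a1 - a0, a2 - a1, a3 - a2) == (3, 3, 4)
        assert ant.sum() + mid.sum() + post.sum() == mask.sum()

    def test_extent_eleven_remainder_goes_posterior_first(self):
        mask = np.zeros((2, 11, 2), dtype=bool)
        mask[:, :, :] = True
        _, _, _, (a0, a1, a2, a3) = regional_sections(mask, ap_axis=1)
        assert (a1 - a0, a2 - a1, a3 - a2) == (3, 4, 4)

    def test_sections_partition_the_lung_mask(self):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 9, 4)) > 0.4
        mask[:, 0, :] = False
        ant, mid, post, _ = regional_sections(mask, ap_axis=1)
        combined = ant | mid | post
        assert np.array_equal(combined, mask)
        assert not (np.any(ant & mid) or np.any(mid & post))

    def test_tiny_extent_rejected(self):
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[:, 1:3, :] = True
        with pytest.raises(ValidationError):
            regional_sections(mask, ap_axis=1)

    def test_uniform_phantom_has_identical_section_fractions(
            self, uniform_phantom):
        cmap, _ = uniform_phantom
        ant, mid, post, _ = regional_sections(cmap.lung_mask, cmap.ap_axis)
        vals = [cmap.f_pl[m].mean() for m in (ant, mid, post)]
        assert np.ptp(vals) < 1e-12

    def test_gradient_phantom_posterior_plasma_exceeds_anterior(
            self, naive_phantom):
        cmap, _ = naive_phantom
        ant, _, post, _ = regional_sections(cmap.lung_mask, cmap.ap_axis)
        water = cmap.water
        pvf_ant = (cmap.f_pl[ant] / water[ant]).mean()
        pvf_post = (cmap.f_pl[post] / water[post]).mean()
        assert pvf_post > pvf_ant
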