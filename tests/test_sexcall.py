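import numpy as np
import pytest

from flywalk import bodyseg, sexcall
from flywalk.config import SexConfig
from flywalk.sexcall import (
    CombResult,
    LuminanceProfile,
    abdominal_profile,
    combine_evidence,
    correlate_templates,
    default_templates,
    detect_sex_combs,
)


def _profile(values):
    values = np.asarray(values, dtype=float)
    return LuminanceProfile(
        positions=np.linspace(0, 1, len(values)), values=values / values.mean()
    )


class TestAbdominalProfile:
    def test_uniform_abdomen_gives_flat_unit_profile(self):
        frame = np.full((60, 40), 120.0)
        mask = np.zeros((60, 40), dtype=bool)
        mask[10:50, 10:30] = True
        prof = abdominal_profile(frame, mask, n_samples=50)
        assert np.allclose(prof.values, 1.0)

    def test_luminance_scaling_cancels_out(self, male_fly):
        mask = male_fly.model.segment_mask("abdomen")
        frame = male_fly.red_al[male_fly.brightest]
        a = abdominal_profile(frame, mask)
        b = abdominal_profile(frame * 2.0, mask)
        assert np.allclose(a.values, b.values)

    def test_male_profile_darkens_posteriorly(self, male_fly):
        mask = male_fly.model.segment_mask("abdomen")
        prof = abdominal_profile(male_fly.red_al[male_fly.brightest], mask)
        anterior = prof.values[: len(prof.values) // 3].mean()
        posterior = prof.values[-len(prof.values) // 3 :].mean()
        assert posterior < anterior - 0.3

    def test_tiny_abdomen_rejected(self):
        with pytest.raises(ValueError):
            abdominal_profile(np.zeros((10, 10)), np.zeros((10, 10), bool))


class TestCorrelate:
    def test_self_correlation_is_one(self):
        tpl = np.sin(np.linspace(0, 3, 100)) + 2
        prof = _profile(tpl)
        r_m, r_f = correlate_templates(prof, prof.values, -prof.values)
        assert r_m == pytest.approx(1.0)
        assert r_f == pytest.approx(-1.0)

    def test_constant_profile_scores_zero(self):
        prof = _profile(np.full(100, 5.0))
        r_m, r_f = correlate_templates(prof, np.sin(np.arange(100)), np.cos(np.arange(100)))
        assert r_m == 0.0 and r_f == 0.0

    def test_matches_textbook_pearson_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(size=80) + 2
            tpl = rng.normal(size=80)
            prof = _profile(v)
            r, _ = correlate_templates(prof, tpl, tpl)
            x, y = prof.values, tpl
            oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_generator_profiles_prefer_their_own_template(self, male_fly, female_fly):
        tpl_m, tpl_f = default_templates(100)
        for fly, own in ((male_fly, "male"), (female_fly, "female")):
            prof = abdominal_profile(
                fly.red_al[fly.brightest], fly.model.segment_mask("abdomen")
            )
            r_m, r_f = correlate_templates(prof, tpl_m, tpl_f)
            assert (r_m > r_f) == (own == "male")

    def test_strictly_increasing_positions_enforced(self):
        with pytest.raises(ValueError):
            LuminanceProfile(positions=np.zeros(5), values=np.ones(5))


class TestCombDetection:
    def _frames_with_blob(self, semi_axes, value=40.0):
        """One frame: a leg with a dark blob attached, anterior region."""
        frame = np.full((200, 300), 18.0)
        frame[20:160, 148:151] = 110.0  # leg
        rr, cc = np.mgrid[0:200, 0:300]
        blob = ((rr - 60) / semi_axes[0]) ** 2 + ((cc - 152) / semi_axes[1]) ** 2 <= 1
        frame[blob] = value
        return frame[None, ...]

    def test_compact_dark_spot_detected(self):
        frames = self._frames_with_blob((2.5, 1.8))
        res = detect_sex_combs(
            frames, np.array([[190.0, 150.0]]), np.array([True])
        )
        assert res.detected and res.confidence > 0.3

    def test_elongated_artifact_rejected_by_eccentricity(self):
        """A leg-over-antenna streak has eccentricity near 1 and is ignored."""
        frames = self._frames_with_blob((12.0, 1.2))
        res = detect_sex_combs(
            frames, np.array([[190.0, 150.0]]), np.array([True])
        )
        assert not res.detected

    def test_male_render_yields_comb_and_female_does_not(self, male_fly, female_fly):
        for fly, expect in ((male_fly, True), (female_fly, False)):
            call = sexcall.call_sex(
                fly.red_al,
                fly.seq.red[fly.valid].astype(float),
                fly.stack.transforms,
                fly.model,
            )
            assert call.comb_detected is expect
            if expect:
                assert call.comb_confidence > 0.3


class TestCombineEvidence:
    def test_confident_comb_beats_weak_female_luminance(self):
        call = combine_evidence(0.2, 0.3, CombResult(True, 0.9))
        assert call.sex == "male"

    def test_clear_luminance_margin_decides_without_comb(self):
        call = combine_evidence(0.1, 0.5, CombResult(False, 0.0))
        assert call.sex == "female"
        call = combine_evidence(0.6, 0.2, CombResult(False, 0.0))
        assert call.sex == "male"

    def test_ambiguous_evidence_is_unknown(self):
        call = combine_evidence(0.40, 0.41, CombResult(False, 0.0))
        assert call.sex == "unknown"

    def test_absent_comb_lowers_the_bar_for_female(self):
        cfg = SexConfig()
        margin = cfg.tau_lum * 0.75  # below tau_lum, above tau_lum/2
        call = combine_evidence(0.3, 0.3 + margin, CombResult(False, 0.0))
        assert call.sex == "female"
        # the same margin toward male stays unknown
        call = combine_evidence(0.3 + margin, 0.3, CombResult(False, 0.0))
        assert call.sex == "unknown"


def test_luminance_alone_sexes_flies_when_combs_never_render():
    """With comb rendering disabled the call falls back to luminance."""
    from flywalk import frameqc, headmetrics
    from flywalk.synthio import RenderConfig, render_sequence, sample_fly

    correct = 0
    n = 8
    for i in range(n):
        sex = "male" if i % 2 else "female"
        truth = sample_fly(7000 + i, sex=sex)
        seq = render_sequence(
            truth, RenderConfig(n_frames=4, seed=i, comb_frame_frac=0.0)
        )
        valid = [j for j, r in enumerate(frameqc.validate_sequence(seq)) if r.valid]
        model, stack = bodyseg.build_body_model(seq, valid)
        red_al = bodyseg.align_channel(seq, "red", stack, valid)
        call = sexcall.call_sex(
            red_al, seq.red[valid].astype(float), stack.transforms, model
        )
        correct += call.sex == sex
    assert correct / n > 0.9
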