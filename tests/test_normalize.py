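import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import siscreen as ss
from siscreen.errors import ValidationError
from siscreen.normalize import COMMON, NONE


def plate_frame(raws, perts, plate="P1", batch=1, arm="VEHICLE"):
    n = len(raws)
    return pd.DataFrame(
        {
            "plate": plate,
            "batch": batch,
            "row": ["A"] * n,
            "col": range(1, n + 1),
            "perturbation": perts,
            "co_treatment": arm,
            "viability": [2 * r if r is not None else np.nan for r in raws],
            "count": [r if r is not None else np.nan for r in raws],
        }
    )


class TestNormalizePlate:
    def test_well_at_nc_center_maps_to_zero(self):
        df = plate_frame([100, 100, 100], ["NC", "NC", "GENEA"])
        norm = ss.normalize_plate(df, "COUNT")
        assert norm.iloc[2] == 0.0

    def test_hand_arithmetic_quarter_of_controls(self):
        df = plate_frame([100, 100, 25], ["NC", "NC", "GENEA"])
        norm = ss.normalize_plate(df, "COUNT")
        assert norm.iloc[2] == pytest.approx(-2.0)

    def test_all_missing_readout_propagates(self):
        df = plate_frame([None, None, None], ["NC", "NC", "GENEA"])
        norm = ss.normalize_plate(df, "COUNT")
        assert norm.isna().all()

    def test_zero_raw_value_is_error(self):
        df = plate_frame([100, 100, 0], ["NC", "NC", "GENEA"])
        with pytest.raises(ValidationError, match="non-positive"):
            ss.normalize_plate(df, "COUNT")

    def test_fewer_than_two_nc_is_error(self):
        df = plate_frame([100, 25], ["NC", "GENEA"])
        with pytest.raises(ValidationError, match="siNC"):
            ss.normalize_plate(df, "COUNT")

    def test_median_center_resists_one_bad_control(self):
        df = plate_frame([100, 100, 100, 10_000, 50], ["NC", "NC", "NC", "NC", "GENEA"])
        assert ss.normalize_plate(df, "COUNT").iloc[4] == pytest.approx(-1.0)
        assert ss.normalize_plate(df, "COUNT", nc_center="mean").iloc[4] < -1.0

    @given(scale=st.floats(0.01, 1000))
    def test_scale_invariance(self, scale):
        raws = [100, 120, 80, 33]
        df1 = plate_frame(raws, ["NC", "NC", "GENEA", "GENEB"])
        df2 = plate_frame([r * scale for r in raws], ["NC", "NC", "GENEA", "GENEB"])
        n1 = ss.normalize_plate(df1, "COUNT")
        n2 = ss.normalize_plate(df2, "COUNT")
        assert np.allclose(n1, n2)


class TestAggregateGene:
    def test_strong_effect_against_tight_controls(self, noiseless_screen):
        """Per-batch values {-2,-2,-2} vs zero-variance siNC: the effect is
        exact and the t-test p collapses to ~0; cross-checked against the
        scipy two-sample implementation."""
        norm = ss.normalize_screen(noiseless_screen)
        eff = ss.aggregate_gene(norm, "G001", "SINGLE")
        assert eff.log2fc_count == pytest.approx(-2.0)
        assert eff.n_reps == 3
        assert eff.p_count < 1e-6

    def test_t_test_matches_scipy_oracle(self, default_screen):
        norm = ss.normalize_screen(default_screen)
        eff = ss.aggregate_gene(norm, "G002", "SINGLE")
        nc = norm[
            (norm["perturbation"] == "NC") & (norm["co_treatment"] == "VEHICLE")
        ]["norm_count"].to_numpy()
        t, p = sps.ttest_ind(np.asarray(eff.batch_values_count), nc, equal_var=True)
        assert eff.p_count == pytest.approx(p, rel=1e-9)

    def test_single_replicate_reports_effect_without_p(self):
        dfs = [plate_frame([100, 100, 50], ["NC", "NC", "GENEA"])]
        # add a second gene present in 3 batches so the pivot has batch columns
        norm = ss.normalize_screen(pd.concat(dfs, ignore_index=True))
        eff = ss.aggregate_gene(norm, "GENEA", "SINGLE")
        assert eff.log2fc_count == pytest.approx(-1.0)
        assert eff.n_reps == 1
        assert np.isnan(eff.p_count)

    def test_null_gene_p_is_not_extreme(self, default_screen):
        norm = ss.normalize_screen(default_screen)
        effects = [e for e in ss.aggregate_effects(norm) if e.arm == "SINGLE"]
        p = np.array([e.p_count for e in effects if e.gene != "G001"])
        # 11 null genes: all p-values defined and not systematically tiny
        assert np.isfinite(p).all()
        assert p.min() > 1e-6

    def test_against_zero_variant(self, default_screen):
        norm = ss.normalize_screen(default_screen)
        eff = ss.aggregate_gene(norm, "G002", "SINGLE", test_against="zero")
        vals = np.asarray(eff.batch_values_count)
        _, p = sps.ttest_1samp(vals, 0.0)
        assert eff.p_count == pytest.approx(p, rel=1e-9)


class TestCallHits:
    def _effect(self, gene, arm, fc, p, batch_values=None):
        if batch_values is None:
            batch_values = (fc, fc, fc)
        return ss.GeneEffect(
            gene=gene, arm=arm, log2fc_count=fc, log2fc_viability=fc / 2,
            p_count=p, p_viability=0.5, n_reps=3,
            batch_values_count=batch_values,
        )

    def test_both_arms_significant_is_common(self):
        effects = [
            self._effect("G", "SINGLE", -1.5, 0.001),
            self._effect("G", "COMBINED", -1.6, 0.001),
        ]
        [call] = ss.call_hits(effects)
        assert call.category == COMMON

    def test_weak_effects_are_none(self):
        effects = [
            self._effect("G", "SINGLE", -0.2, 0.5),
            self._effect("G", "COMBINED", -0.2, 0.5),
        ]
        [call] = ss.call_hits(effects)
        assert call.category == NONE

    def test_fold_threshold_vetoes_significant_p(self):
        effects = [
            self._effect("G", "SINGLE", -0.5, 0.0001),
            self._effect("G", "COMBINED", -0.5, 0.0001),
        ]
        [call] = ss.call_hits(effects)
        assert call.category == NONE

    def test_sensitized_category(self):
        effects = [
            self._effect("G", "SINGLE", -0.1, 0.8, batch_values=(-0.1, -0.11, -0.09)),
            self._effect("G", "COMBINED", -1.6, 0.001, batch_values=(-1.6, -1.62, -1.58)),
        ]
        [call] = ss.call_hits(effects)
        assert call.category == "CISPLATIN_SENSITIZED"
        assert call.sensitized
        assert call.sensitization_p < 0.01

    def test_growth_promoting_gene_is_never_a_hit(self):
        effects = [
            self._effect("G", "SINGLE", 1.5, 0.0001),
            self._effect("G", "COMBINED", 1.6, 0.0001),
        ]
        [call] = ss.call_hits(effects)
        assert call.category == NONE

    def test_missing_arm_is_error(self):
        with pytest.raises(ValidationError, match="arm"):
            ss.call_hits([self._effect("G", "SINGLE", -1.5, 0.001)])

    def test_hit_calling_monotone_in_effect_size(self):
        """Strengthening a planted effect with the same seed (identical noise
        draws for every well) never removes a COMMON call."""
        seeds_called = []
        for effect in (-1.3, -2.0, -3.0):
            cfg = ss.ScreenSimConfig(
                n_genes=12, planted_effects={"G005": (effect, effect)}, seed=21
            )
            norm = ss.normalize_screen(ss.generate_screen(cfg))
            calls = {c.gene: c.category for c in ss.call_hits(ss.aggregate_effects(norm))}
            seeds_called.append(calls["G005"] == COMMON)
        assert seeds_called[0] is True  # -1.3 at 10% CV is already called
        # once called, stronger effects keep the call
        for earlier, later in zip(seeds_called, seeds_called[1:]):
            assert later >= earlier
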