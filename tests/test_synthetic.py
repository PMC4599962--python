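"""Synthetic community generator: spectra, evolution, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surnamebias import (
    KinshipModel,
    SynthParams,
    evolve_community,
    generate_founding,
    generate_study,
    immigration_rate_for_fraction,
    sdb_census,
    select_locally_spread,
)
from surnamebias.exceptions import ConfigurationError
from surnamebias.metrics import isonymy
from surnamebias.pipeline import load_dataset
from surnamebias.resampling import regress_bias


class TestGenerateFounding:
    def test_exact_totals(self):
        params = SynthParams(s0=37, n0=412)
        rep = generate_founding(params)
        assert (rep.s, rep.n) == (37, 412)

    def test_all_singletons_when_s0_equals_n0(self):
        rep = generate_founding(SynthParams(s0=50, n0=50))
        assert set(rep.counts.values()) == {1}

    def test_monomorphic_when_s0_is_one(self):
        rep = generate_founding(SynthParams(s0=1, n0=30))
        assert rep.s == 1 and rep.n == 30
        assert isonymy(rep).isonymy == 1.0

    def test_large_shape_gives_one_dominant_plus_singletons(self):
        rep = generate_founding(SynthParams(s0=20, n0=100, spectrum_shape=50.0))
        counts = sorted(rep.counts.values(), reverse=True)
        assert counts[0] == 100 - 19 and set(counts[1:]) == {1}

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthParams(s0=10, n0=5)

    @given(
        s0=st.integers(min_value=1, max_value=40),
        extra=st.integers(min_value=0, max_value=200),
        shape=st.floats(min_value=0.0, max_value=5.0, allow_nan=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_spectrum_invariants(self, s0, extra, shape):
        params = SynthParams(s0=s0, n0=s0 + extra, spectrum_shape=shape)
        rep = generate_founding(params)
        assert rep.s == s0 and rep.n == s0 + extra
        assert min(rep.counts.values()) >= 1


class TestEvolveCommunity:
    def test_closed_population_truth_is_all_founding(self):
        params = SynthParams(immigration_rate=0.0, innovation_rate=0.0, seed=0)
        founding = generate_founding(params)
        ev = evolve_community(founding, params)
        assert ev.truth.table.founding.all()
        assert ev.truth.immigrant_bearer_fraction == 0.0
        for model in ("LK", "HK"):
            assert sdb_census(ev.present, founding, model).sdb == 0.0

    def test_hk_census_sdb_equals_realized_immigrant_fraction(self):
        # With novel-surname immigrants and no innovation, non-founding
        # bearers are exactly the immigrant-descent ones.
        params = SynthParams(immigration_rate=0.05, innovation_rate=0.0, seed=1)
        founding = generate_founding(params)
        ev = evolve_community(founding, params)
        hk = sdb_census(ev.present, founding, "HK").sdb
        assert hk == pytest.approx(ev.truth.immigrant_bearer_fraction, abs=1e-12)
        assert ev.truth.immigrant_bearer_fraction > 0

    def test_truth_flags_partition_present_support(self):
        params = SynthParams(
            immigration_rate=0.06, innovation_rate=0.01, seed=2
        )
        founding = generate_founding(params)
        ev = evolve_community(founding, params)
        table = ev.truth.table
        assert set(table.surname) == set(ev.present.counts)
        classes = (
            table.founding.astype(int)
            + table.immigrant_origin.astype(int)
            + table.innovation.astype(int)
        )
        assert (classes == 1).all()

    def test_determinism_and_seed_sensitivity(self):
        params = SynthParams(immigration_rate=0.05, seed=3)
        f = generate_founding(params, np.random.default_rng(3))
        a = evolve_community(f, params, np.random.default_rng(7))
        b = evolve_community(f, params, np.random.default_rng(7))
        c = evolve_community(f, params, np.random.default_rng(8))
        assert a.present.counts == b.present.counts
        assert a.present.counts != c.present.counts

    def test_midera_snapshot_supports_grandparents_strategy(self):
        params = SynthParams(generations=10, seed=4)
        founding = generate_founding(params)
        ev = evolve_community(founding, params)
        assert founding.era_year < ev.midera.era_year < ev.present.era_year

    def test_cumulative_immigration_rate_inversion(self):
        m = immigration_rate_for_fraction(0.3, 10)
        assert 1 - (1 - m) ** 10 == pytest.approx(0.3)


class TestGenerateStudy:
    def test_round_trip_through_readers(self, tmp_path):
        study = generate_study(3, seed=5)
        study.to_directory(tmp_path / "data")
        loaded = load_dataset(tmp_path / "data")
        assert len(loaded) == 3
        for orig, back in zip(study.communities, loaded):
            assert back.founding.counts == orig.founding.counts
            assert back.present.counts == orig.present.counts
            assert back.midera is not None and back.annotation is not None

    def test_local_annotation_supports_ls_strategy(self):
        study = generate_study(2, seed=6)
        c = study.communities[0]
        sel = select_locally_spread(
            c.present, c.annotation, c.meta.province, KinshipModel.LK
        )
        assert sel.types <= c.founding.types

    def test_decoupled_altitude_is_null_for_regression(self):
        # With no altitude->immigration coupling the expected R^2 is 1/(n-1).
        study = generate_study(26, seed=7, altitude_coupling=0.0)
        ys = [
            sdb_census(c.present, c.founding, "LK").sdb for c in study.communities
        ]
        xs = [c.meta.altitude_m for c in study.communities]
        out = regress_bias(ys, xs)
        assert out["p_value"] > 0.01  # no induced association

    def test_strong_coupling_recovers_negative_altitude_sign(self):
        study = generate_study(26, seed=8, base_immigration=0.12, altitude_coupling=1.0)
        ys = [
            sdb_census(c.present, c.founding, "LK").sdb for c in study.communities
        ]
        xs = [c.meta.altitude_m for c in study.communities]
        out = regress_bias(ys, xs)
        assert out["sign"] == "-"
        assert out["p_value"] < 0.05

    def test_metadata_frame_matches_repertoires(self):
        study = generate_study(4, seed=9)
        frame = study.metadata_frame()
        assert frame.n0.tolist() == [c.founding.n for c in study.communities]
        assert frame.st.tolist() == [c.present.s for c in study.communities]
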