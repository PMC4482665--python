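"""Data model, CSV round-trips, validation, and the z-score diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatracer import (
    FractionationSpec,
    LibraryFormatError,
    LibraryValidationError,
    Profile,
    SourceLibrary,
    TracerKind,
    TracerSet,
    builtin_si_table1,
    read_consumers,
    read_fractionation,
    read_source_library,
    summarize_profiles,
    validate_library,
    write_consumers,
    write_source_library,
    zscore_diagnostic,
)


class TestBuiltinSiLibrary:
    def test_printed_values(self, si_library):
        lib, frac = si_library
        assert lib.mean_of("d13C", "Diatoms") == -29.8
        assert lib.sd_of("d13C", "Diatoms") == 2.3
        assert lib.mean_of("d15N", "Cyanobacteria") == 2.8
        assert lib.sd_of("d15N", "Cyanobacteria") == 2.5
        assert lib.mean_of("d13C", "Chlorophytes") == -23.7
        assert lib.mean_of("d15N", "Chlorophytes") == 8.7

    def test_fractionation_zero_mean_printed_sds(self, si_library):
        _, frac = si_library
        np.testing.assert_array_equal(frac.mean, [0.0, 0.0])
        np.testing.assert_array_equal(frac.sd, [1.3, 1.0])

    def test_validates_clean(self, si_library):
        lib, _ = si_library
        assert validate_library(lib) == []


class TestCsvRoundTrip:
    @pytest.mark.parametrize("wide", [False, True])
    def test_roundtrip_preserves_fields(self, si_library, tmp_path, wide):
        lib, _ = si_library
        path = tmp_path / "lib.csv"
        write_source_library(lib, path, wide=wide)
        back = read_source_library(path, wide=wide)
        assert back.groups == lib.groups
        assert back.tracer_set.names == lib.tracer_set.names
        assert back.tracer_set.kind is TracerKind.SI_DELTA
        np.testing.assert_array_equal(back.mean, lib.mean)
        np.testing.assert_array_equal(back.sd, lib.sd)

    def test_zero_sd_identity_read(self, tmp_path):
        rows = [(g, t, float(i), 0.0)
                for i, g in enumerate(["a", "b", "c"]) for t in ["x", "y"]]
        path = tmp_path / "z.csv"
        pd.DataFrame(rows, columns=["group", "tracer", "mean", "sd"]).to_csv(path, index=False)
        lib = read_source_library(path)
        assert np.all(lib.sd == 0)
        assert lib.groups == ("a", "b", "c")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"group": ["a"], "tracer": ["x"], "mean": [1.0]}).to_csv(path, index=False)
        with pytest.raises(LibraryFormatError, match="sd"):
            read_source_library(path)

    def test_negative_sd_names_cell(self, tmp_path):
        path = tmp_path / "neg.csv"
        pd.DataFrame(
            {"group": ["a", "a"], "tracer": ["x", "y"], "mean": [1, 2], "sd": [0.1, -1]}
        ).to_csv(path, index=False)
        with pytest.raises(LibraryValidationError, match="'y'"):
            read_source_library(path)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        pd.DataFrame(
            {"group": ["a", "a"], "tracer": ["x", "x"], "mean": [1, 2], "sd": [0.1, 0.2]}
        ).to_csv(path, index=False)
        with pytest.raises(LibraryValidationError, match="duplicate"):
            read_source_library(path)


class TestConsumerIO:
    def test_roundtrip_and_synonym_matching(self, tmp_path):
        ts = TracerSet(("18:3w3", "16:1w7"), TracerKind.FA_PROPORTION)
        # file written with the omega spelling must still match
        path = tmp_path / "cons.csv"
        pd.DataFrame({"id": ["c1"], "18:3ω3": [40.0], "16:1ω7": [60.0]}).to_csv(path, index=False)
        (c,) = read_consumers(path, ts)
        np.testing.assert_array_equal(c.values, [40.0, 60.0])
        write_consumers([c], tmp_path / "out.csv")
        (back,) = read_consumers(tmp_path / "out.csv", ts)
        np.testing.assert_array_equal(back.values, c.values)

    def test_missing_tracer_named(self, tmp_path):
        ts = TracerSet(("d13C", "d15N"), TracerKind.SI_DELTA)
        path = tmp_path / "cons.csv"
        pd.DataFrame({"d13C": [-28.0]}).to_csv(path, index=False)
        with pytest.raises(LibraryFormatError, match="d15N"):
            read_consumers(path, ts)

    def test_fractionation_read(self, tmp_path):
        ts = TracerSet(("d13C", "d15N"), TracerKind.SI_DELTA)
        path = tmp_path / "frac.csv"
        pd.DataFrame(
            {"tracer": ["d15N", "d13C"], "mean": [3.4, 0.4], "sd": [1.0, 1.3]}
        ).to_csv(path, index=False)
        frac = read_fractionation(path, ts)  # reordered to tracer-set order
        np.testing.assert_array_equal(frac.mean, [0.4, 3.4])
        np.testing.assert_array_equal(frac.sd, [1.3, 1.0])


class TestSummarizeProfiles:
    def _profiles(self, ts, groups_values):
        return [
            Profile(ts, np.atleast_1d(v), g) for g, vals in groups_values for v in vals
        ]

    def test_sample_sd(self):
        ts = TracerSet(("x",), TracerKind.SI_DELTA)
        lib = summarize_profiles(self._profiles(ts, [("g", [1.0, 2.0, 3.0])]))
        assert lib.mean_of("x", "g") == 2.0
        assert lib.sd_of("x", "g") == 1.0  # n-1 denominator

    def test_identical_profiles_sd_zero(self):
        ts = TracerSet(("x", "y"), TracerKind.SI_DELTA)
        lib = summarize_profiles(
            [Profile(ts, [1.0, 2.0], "g"), Profile(ts, [1.0, 2.0], "g")]
        )
        assert np.all(lib.sd == 0)

    def test_single_profile_group_warns(self):
        ts = TracerSet(("x",), TracerKind.SI_DELTA)
        with pytest.warns(UserWarning, match="single profile"):
            lib = summarize_profiles([Profile(ts, [1.0], "g")])
        assert lib.sd_of("x", "g") == 0.0

    def test_mismatched_tracer_sets_rejected(self):
        a = Profile(TracerSet(("x",), TracerKind.SI_DELTA), [1.0], "g")
        b = Profile(TracerSet(("y",), TracerKind.SI_DELTA), [1.0], "g")
        with pytest.raises(LibraryValidationError, match="tracer set"):
            summarize_profiles([a, b])

    @settings(deadline=None, max_examples=25)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["g1", "g2"]),
                st.lists(st.floats(-50, 50), min_size=2, max_size=2),
            ),
            min_size=4,
            max_size=12,
        ).filter(lambda d: all(sum(1 for g, _ in d if g == gg) >= 2 for gg in {g for g, _ in d})),
        seed=st.integers(0, 10_000),
    )
    def test_permutation_invariance_and_two_pass_agreement(self, data, seed):
        ts = TracerSet(("x", "y"), TracerKind.SI_DELTA)
        profs = [Profile(ts, np.array(v), g) for g, v in data]
        lib = summarize_profiles(profs)
        perm = np.random.default_rng(seed).permutation(len(profs))
        lib2 = summarize_profiles([profs[i] for i in perm])
        for g in lib.groups:
            i, i2 = lib.group_index(g), lib2.group_index(g)
            np.testing.assert_allclose(lib.mean[:, i], lib2.mean[:, i2], atol=1e-12)
            np.testing.assert_allclose(lib.sd[:, i], lib2.sd[:, i2], atol=1e-12)
            vals = np.array([v for gg, v in data if gg == g])
            np.testing.assert_allclose(lib.mean[:, i], vals.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(lib.sd[:, i], vals.std(axis=0, ddof=1), atol=1e-12)


class TestZScoreDiagnostic:
    def _fa_profiles(self, rng, n_per_group=6):
        ts = TracerSet(("big1", "big2", "small"), TracerKind.FA_PROPORTION)
        out = []
        for g, (m1, m2) in [("a", (60, 37)), ("b", (55, 42))]:
            for _ in range(n_per_group):
                v1 = m1 + rng.normal(0, 1.5)
                v2 = m2 + rng.normal(0, 1.5)
                out.append(Profile(ts, [v1, v2, 100 - v1 - v2], g))
        return out

    def test_groupwise_standardization(self, rng):
        profs = self._fa_profiles(rng)
        summary = zscore_diagnostic(profs, abundance_threshold=5.0)
        assert "small" not in summary.tracers_included
        # each selected tracer standardized within group: pooled mean ~0; the
        # pooled sample SD is sqrt(sum(n_g - 1) / (N - 1)) by construction
        # (2 groups x 2 tracers x 6 profiles: sqrt(20/23))
        assert abs(summary.pooled_scores.mean()) < 1e-10
        np.testing.assert_allclose(summary.pooled_sd, np.sqrt(20 / 23), atol=1e-9)
        assert abs(summary.pooled_median) < 0.6

    def test_no_tracer_passes_threshold(self, rng):
        profs = self._fa_profiles(rng)
        with pytest.raises(LibraryValidationError, match="grand mean"):
            zscore_diagnostic(profs, abundance_threshold=99.0)

    def test_requires_fa_kind(self, si_library):
        lib, _ = si_library
        ts = lib.tracer_set
        with pytest.raises(LibraryValidationError, match="FA"):
            zscore_diagnostic([Profile(ts, [-28.0, 7.0], "g")])


class TestValidateLibrary:
    def test_mutated_negative_sd_reported_once(self, si_library):
        lib, _ = si_library
        bad = SourceLibrary(lib.tracer_set, lib.groups, lib.mean.copy(), lib.sd.copy())
        bad.sd[0, 1] = -1.0
        report = validate_library(bad)
        assert len(report) == 1
        assert "d13C" in report[0] and "Chlorophytes" in report[0]

    def test_fa_closure_violation(self):
        ts = TracerSet(("a", "b"), TracerKind.FA_PROPORTION)
        lib = SourceLibrary(ts, ("g",), np.array([[40.0], [20.0]]), np.zeros((2, 1)))
        report = validate_library(lib)
        assert any("closure" in v for v in report)

    def test_profile_closure_check(self):
        ts = TracerSet(("a", "b"), TracerKind.FA_PROPORTION)
        Profile(ts, [60.0, 42.0], "ok").check_closure()  # 102 within 100±5
        with pytest.raises(LibraryValidationError, match="sum"):
            Profile(ts, [30.0, 30.0], "low").check_closure()
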