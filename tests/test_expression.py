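"""tpm normalization, response calling and diversification scoring."""

import numpy as np
import pandas as pd
import pytest

from optfam.expression import (
    call_presence,
    call_response,
    diversification_matrix,
    normalize_tpm,
    response_profiles,
)
from optfam.simulate import simulate_expression


def small_matrix():
    counts = pd.DataFrame(
        {"lib1": [50, 950_000], "lib2": [100, 199_900]},
        index=["g1", "other"],
    )
    return counts


class TestNormalize:
    def test_per_cell_definition(self):
        counts = small_matrix()
        tpm = normalize_tpm(counts)
        assert tpm.at["g1", "lib1"] == pytest.approx(50 / 950_050 * 1e6)
        assert list(tpm.sum(axis=0)) == pytest.approx([1e6, 1e6])

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, (20, 4)),
            index=[f"g{i}" for i in range(20)], columns=list("abcd"),
        )
        scaled = counts.copy()
        scaled["b"] *= 7
        t1, t2 = normalize_tpm(counts), normalize_tpm(scaled)
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_independent_recomputation(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 3)),
            index=[f"g{i}" for i in range(30)], columns=list("xyz"),
        )
        counts.iloc[0] += 1  # keep totals positive
        tpm = normalize_tpm(counts)
        for lib in counts.columns:
            total = counts[lib].sum()
            for g in counts.index:
                assert tpm.at[g, lib] == pytest.approx(
                    counts.at[g, lib] / total * 1e6
                )

    def test_zero_library_named(self):
        counts = small_matrix()
        counts["lib2"] = 0
        with pytest.raises(ValueError, match="lib2"):
            normalize_tpm(counts)

    def test_negative_counts_rejected(self):
        counts = small_matrix()
        counts.iloc[0, 0] = -1
        with pytest.raises(ValueError):
            normalize_tpm(counts)


class TestCalls:
    def test_presence_thresholds(self):
        row = pd.Series([0.0, 1.0, 4.9], index=list("abc"))
        assert list(call_presence(row)) == [False, True, True]
        assert list(call_presence(row, min_tpm=5)) == [False, False, False]

    @pytest.mark.parametrize(
        "control,treatment,expected",
        [(10, 20, "up"), (10, 19, "none"), (40, 10, "down"), (0.2, 0.5,
          "not_assessable")],
    )
    def test_two_fold_rule_boundary_inclusive(self, control, treatment, expected):
        rc = call_response(control, treatment, pseudo=0.0)
        assert rc.call == expected

    def test_up_down_duality_without_pseudo(self, rng):
        for _ in range(50):
            a, b = rng.uniform(1, 200, 2)
            fwd = call_response(a, b, pseudo=0.0)
            rev = call_response(b, a, pseudo=0.0)
            assert (fwd.call == "up") == (rev.call == "down")

    def test_pseudo_count_damps_zero_control(self):
        assert call_response(0.0, 3.0, pseudo=1.0).call == "up"
        assert call_response(0.0, 0.9, pseudo=1.0, min_tpm=0.5).call == "none"

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_response(1, 2, fold_threshold=1.0)


def _profiled_setup():
    meta = pd.DataFrame(
        {
            "tissue": ["root", "leaf", "seedling", "seedling"],
            "class": ["Tissues", "Tissues", "Salt", "Salt"],
            "control_library": ["", "", "", "salt_control"],
        },
        index=["root", "leaf", "salt_control", "salt_treatment"],
    )
    tpm = pd.DataFrame(
        {
            "root": [50.0, 50.0, 40.0],
            "leaf": [50.0, 0.0, 40.0],
            "salt_control": [20.0, 20.0, 40.0],
            "salt_treatment": [80.0, 20.0, 40.0],
        },
        index=["g1", "g2", "g3"],
    )
    return tpm, meta


class TestProfilesAndDiversification:
    def test_response_profile_wiring(self):
        tpm, meta = _profiled_setup()
        profiles = response_profiles(tpm, meta, pseudo=0.0)
        assert set(profiles["contrast"]) == {"salt_treatment"}
        calls = profiles.set_index("gene")["call"]
        assert calls["g1"] == "up" and calls["g2"] == "none"

    def test_missing_control_library_rejected(self):
        tpm, meta = _profiled_setup()
        meta.loc["salt_treatment", "control_library"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            response_profiles(tpm, meta)

    def test_identical_profiles_all_minus(self):
        tpm, meta = _profiled_setup()
        tpm.loc["g2"] = tpm.loc["g1"]
        profiles = response_profiles(tpm, meta, pseudo=0.0)
        presence = call_presence(tpm)
        table = diversification_matrix(
            profiles, presence, meta, [("g1", "g2")],
            classes=("Tissues", "Salt"),
        )
        assert list(table.iloc[0][["Tissues", "Salt"]]) == ["−", "−"]

    def test_planted_differences_flagged_per_class(self):
        tpm, meta = _profiled_setup()
        profiles = response_profiles(tpm, meta, pseudo=0.0)
        presence = call_presence(tpm)
        table = diversification_matrix(
            profiles, presence, meta, [("g1", "g2"), ("g2", "g1")],
            classes=("Tissues", "Salt"),
        )
        # g1 present everywhere, g2 absent in leaf → Tissues '+'
        # g1 responds to salt, g2 does not → Salt '+'
        assert list(table.iloc[0][["Tissues", "Salt"]]) == ["+", "+"]
        # symmetric under pair order
        assert list(table.iloc[1][["Tissues", "Salt"]]) == ["+", "+"]

    def test_agreeing_contrast_never_flips_plus(self):
        tpm, meta = _profiled_setup()
        profiles = response_profiles(tpm, meta, pseudo=0.0)
        presence = call_presence(tpm)
        base = diversification_matrix(
            profiles, presence, meta, [("g1", "g3")], classes=("Salt",),
        )
        # add a second salt contrast where both members agree
        meta2 = meta.copy()
        meta2.loc["salt_treatment2"] = ["seedling", "Salt", "salt_control"]
        tpm2 = tpm.copy()
        tpm2["salt_treatment2"] = tpm2["salt_control"]
        profiles2 = response_profiles(tpm2, meta2, pseudo=0.0)
        extended = diversification_matrix(
            profiles2, call_presence(tpm2), meta2, [("g1", "g3")],
            classes=("Salt",),
        )
        assert base.iloc[0]["Salt"] == "+" == extended.iloc[0]["Salt"]

    def test_unprofiled_member_rejected(self):
        tpm, meta = _profiled_setup()
        profiles = response_profiles(tpm, meta)
        with pytest.raises(KeyError, match="ghost"):
            diversification_matrix(
                profiles, call_presence(tpm), meta, [("g1", "ghost")]
            )


class TestSimulatedRecovery:
    def test_planted_up_called(self):
        from optfam.simulate import PlantedResponse

        sim = simulate_expression(
            n_genes=30, seed=11,
            planted=[PlantedResponse("gene005", "Drought", fold=4.0,
                                     baseline_tpm=50.0)],
        )
        tpm = normalize_tpm(sim.counts)
        profiles = response_profiles(tpm, sim.meta)
        call = profiles[
            (profiles["gene"] == "gene005")
            & (profiles["class"] == "Drought")
        ].iloc[0]["call"]
        assert call == "up"
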