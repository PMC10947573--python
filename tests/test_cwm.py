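"""Trait derivation, CWM scales, slope decomposition and species trends."""

import numpy as np
import pandas as pd
import pytest

from firetraits.community import CoverTable
from firetraits.cwm import (
    OrphanSpeciesError,
    SCALES,
    cwm,
    cwm_profiles,
    decompose,
    derive_traits,
    species_trends,
    trend_summary,
)
from firetraits.synth import SimulationConfig, make_dataset

from conftest import make_traits


class TestDeriveTraits:
    def test_unit_arithmetic(self):
        raw = pd.DataFrame(
            {"plot": ["p"], "species": ["s"], "percent_n": [2.0],
             "percent_c": [45.0], "sla": [200.0]}
        )
        out = derive_traits(raw)
        assert out.loc[0, "n_mass"] == pytest.approx(20.0)
        assert out.loc[0, "n_area"] == pytest.approx(0.1)

    def test_cn_ratio(self):
        raw = pd.DataFrame(
            {"plot": ["p"], "species": ["s"], "percent_n": [1.5],
             "percent_c": [45.0], "sla": [100.0]}
        )
        assert derive_traits(raw).loc[0, "cn_ratio"] == pytest.approx(30.0)

    def test_nonpositive_records_rejected_with_log(self, caplog):
        raw = pd.DataFrame(
            {"plot": ["p", "p"], "species": ["s", "t"],
             "percent_n": [0.0, 2.0], "percent_c": [45.0, 45.0],
             "sla": [100.0, -5.0]}
        )
        with caplog.at_level("WARNING"):
            out, rejected = derive_traits(raw, return_rejected=True)
        assert len(out) == 0 and len(rejected) == 2
        assert "non-positive" in caplog.text

    def test_derived_identities_hold(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            {"plot": "p", "species": [f"s{i}" for i in range(20)],
             "percent_n": rng.uniform(0.5, 4, 20),
             "percent_c": rng.uniform(40, 50, 20),
             "sla": rng.uniform(50, 400, 20)}
        )
        out = derive_traits(raw)
        assert np.allclose(out["n_area"], out["n_mass"] / out["sla"])
        assert np.allclose(out["cn_ratio"],
                           out["percent_c"] * 10 / out["n_mass"])


def _single_genus_cover(matrix, plots, species, genus=None, group=None):
    tax = pd.DataFrame(
        {
            "genus": genus or [s.split("_")[0] for s in species],
            "family": "f",
            "functional_group": group or "forb",
        },
        index=pd.Index(species, name="species"),
    )
    return CoverTable(
        matrix=pd.DataFrame(matrix, index=plots, columns=species), taxonomy=tax
    )


class TestCWM:
    def test_single_species_plot_equals_its_trait(self):
        cov = _single_genus_cover([[5.0, 0.0]], ["p1"], ["ga_s1", "ga_s2"])
        traits = make_traits([("p1", "ga_s1", 20.0, 200.0)])
        for scale in ("full_variability", "species_means"):
            prof = cwm(cov, traits, scale)
            assert prof.loc["p1", "n_mass"] == pytest.approx(20.0)

    def test_equal_cover_two_species_mean(self):
        cov = _single_genus_cover([[5.0, 5.0]], ["p1"], ["ga_s1", "gb_s1"])
        traits = make_traits(
            [("p1", "ga_s1", 10.0, 100.0), ("p1", "gb_s1", 20.0, 100.0)]
        )
        for scale in SCALES:
            prof = cwm(cov, traits, scale)
            assert prof.loc["p1", "n_mass"] == pytest.approx(15.0)

    def test_cwm_within_contributing_range(self, small_cover):
        records = [
            (p, s, 10 + 5 * i, 100 + 10 * i)
            for i, s in enumerate(small_cover.species)
            for p in small_cover.plots
        ]
        traits = make_traits(records)
        for scale in SCALES:
            prof = cwm(small_cover, traits, scale)
            assert (prof["n_mass"] >= 10 - 1e-9).all()
            assert (prof["n_mass"] <= 25 + 1e-9).all()

    def test_invariant_to_uniform_cover_rescaling(self, small_cover):
        records = [
            (p, s, 10 + 5 * i, 100 + 10 * i)
            for i, s in enumerate(small_cover.species)
            for p in small_cover.plots
        ]
        traits = make_traits(records)
        scaled = CoverTable(matrix=small_cover.matrix * 13.7,
                            taxonomy=small_cover.taxonomy)
        for scale in SCALES:
            a = cwm(small_cover, traits, scale)
            b = cwm(scaled, traits, scale)
            pd.testing.assert_frame_equal(a, b)

    def test_orphan_species_error_lists_names(self, small_cover):
        traits = make_traits([("p1", "ga_s1", 10.0, 100.0)])
        with pytest.raises(OrphanSpeciesError, match="gb_s1"):
            cwm(small_cover, traits, "species_means")

    def test_uniform_genus_trait_makes_species_and_genus_scales_agree(
        self, small_cover
    ):
        # all species in a genus share one value -> aggregation is a no-op
        genus_val = {"ga": 10.0, "gb": 30.0}
        records = [
            (p, s, genus_val[s.split("_")[0]], 200.0)
            for s in small_cover.species
            for p in small_cover.plots
        ]
        traits = make_traits(records)
        a = cwm(small_cover, traits, "species_means")
        b = cwm(small_cover, traits, "genera_means")
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_uniform_group_trait_makes_genus_and_functional_scales_agree(
        self, small_cover
    ):
        group_val = {"forb": 12.0, "grass": 24.0}
        gmap = small_cover.taxonomy["functional_group"]
        records = [
            (p, s, group_val[gmap[s]], 200.0)
            for s in small_cover.species
            for p in small_cover.plots
        ]
        traits = make_traits(records)
        a = cwm(small_cover, traits, "genera_means")
        b = cwm(small_cover, traits, "functional_means")
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_fallback_to_species_mean_when_plot_record_missing(self, caplog):
        cov = _single_genus_cover([[5.0, 5.0], [5.0, 5.0]], ["p1", "p2"],
                                  ["ga_s1", "gb_s1"])
        # gb_s1 measured only in p1
        traits = make_traits(
            [("p1", "ga_s1", 10.0, 100.0), ("p2", "ga_s1", 14.0, 100.0),
             ("p1", "gb_s1", 20.0, 100.0)]
        )
        prof = cwm(cov, traits, "full_variability")
        # p2 uses gb_s1's cross-plot mean (20)
        assert prof.loc["p2", "n_mass"] == pytest.approx((14 + 20) / 2)


class TestDecompose:
    @staticmethod
    def _profiles_from(slopes_by_scale, fire):
        rows = []
        for scale, slope in slopes_by_scale.items():
            for plot, f in fire.items():
                rows.append(
                    {"scale": scale, "plot": plot, "n_mass": 20 + slope * f,
                     "n_area": 0.1, "cn_ratio": 20.0, "sla": 200.0}
                )
        return pd.DataFrame(rows)

    def setup_method(self):
        self.fire = {f"p{i}": f for i, f in enumerate(
            [0.0, 0.1, 0.3, 0.5, 0.77])}
        self.env = pd.DataFrame(
            {"plot": list(self.fire), "fire_freq": list(self.fire.values())}
        )

    def test_identical_profiles_zero_changes_co_gradient(self):
        prof = self._profiles_from({s: -5.0 for s in SCALES}, self.fire)
        dec = decompose(prof, self.env)
        sub = dec.pct_change[dec.pct_change.trait == "n_mass"]
        assert np.allclose(sub["pct_change"], 0.0)
        assert dec.co_gradient["n_mass"]

    def test_percent_change_definition(self):
        prof = self._profiles_from(
            {"functional_means": -2.0, "genera_means": -3.0,
             "species_means": -4.0, "full_variability": -6.0},
            self.fire,
        )
        dec = decompose(prof, self.env)
        sub = dec.pct_change[dec.pct_change.trait == "n_mass"]
        got = dict(zip(zip(sub.coarser, sub.finer), sub["pct_change"]))
        # signed definition: 100 * (slope_finer - slope_coarser) / |slope_coarser|
        assert got[("functional_means", "genera_means")] == pytest.approx(-50.0)
        assert got[("species_means", "full_variability")] == pytest.approx(-50.0)

    def test_opposing_intraspecific_slope_breaks_co_gradient(self):
        prof = self._profiles_from(
            {"functional_means": 2.0, "genera_means": 2.5,
             "species_means": 3.0, "full_variability": -1.0},
            self.fire,
        )
        dec = decompose(prof, self.env)
        assert not dec.co_gradient["n_mass"]

    def test_constant_fire_is_degenerate(self):
        env = pd.DataFrame({"plot": list(self.fire), "fire_freq": 0.3})
        prof = self._profiles_from({s: -5.0 for s in SCALES}, self.fire)
        with pytest.raises(ValueError, match="gradient"):
            decompose(prof, env)


class TestSpeciesTrends:
    def test_two_plot_species_marked_unfit(self):
        traits = make_traits(
            [("p1", "s1", 10.0, 100.0), ("p2", "s1", 12.0, 100.0)]
        )
        env = pd.DataFrame({"plot": ["p1", "p2"], "fire_freq": [0.0, 0.5]})
        out = species_trends(traits, env)
        row = out[(out.species == "s1") & (out.trait == "n_mass")].iloc[0]
        assert not row["fit"] and not row["significant"]

    def test_noise_free_slope_recovered_exactly(self):
        fire = {"p1": 0.0, "p2": 0.2, "p3": 0.5, "p4": 0.77}
        delta = -3.6
        traits = make_traits(
            [(p, "s1", 20.0 + delta * f, 200.0) for p, f in fire.items()]
        )
        env = pd.DataFrame({"plot": list(fire), "fire_freq": list(fire.values())})
        out = species_trends(traits, env)
        row = out[(out.species == "s1") & (out.trait == "n_mass")].iloc[0]
        assert row["slope"] == pytest.approx(delta, abs=1e-10)

    def test_summary_counts_significant_negatives(self):
        fire = dict(zip([f"p{i}" for i in range(8)],
                        np.linspace(0, 0.77, 8)))
        env = pd.DataFrame({"plot": list(fire), "fire_freq": list(fire.values())})
        records = [(p, "down", 30 - 10 * f, 200.0) for p, f in fire.items()]
        records += [(p, "flat", 30.0, 200.0) for p, f in fire.items()]
        out = species_trends(make_traits(records), env, alpha=0.10)
        summ = trend_summary(out)
        assert summ.loc["n_mass", "n_significant"] == 1
        assert summ.loc["n_mass", "n_significant_negative"] == 1


class TestGeneratorGroundTruth:
    """Spec'd interplay between the generator and the decomposition."""

    def test_zero_intraspecific_slope_equates_full_and_species_scales(self):
        cfg = SimulationConfig(
            intraspecific_slope_n=0.0, intraspecific_slope_sla=0.0,
            individual_noise_sd={"n_mass": 0.0, "sla": 0.0, "percent_c": 0.0},
            rng_seed=5,
        )
        ds = make_dataset(cfg)
        full = cwm(ds.cover, ds.traits, "full_variability")
        spm = cwm(ds.cover, ds.traits, "species_means")
        pd.testing.assert_frame_equal(
            full[["n_mass", "sla"]], spm.loc[full.index, ["n_mass", "sla"]],
            check_exact=False, atol=1e-9,
        )

    def test_decomposition_recovers_slope_difference_at_zero_noise(self):
        cfg = SimulationConfig(
            individual_noise_sd={"n_mass": 0.0, "sla": 0.0, "percent_c": 0.0},
            cover_lognormal_sd=0.0,
            bm_sd={"n_mass": 0.0, "sla": 0.0},
            rng_seed=17,
        )
        ds = make_dataset(cfg)
        dec = decompose(cwm_profiles(ds.cover, ds.traits), ds.environment)
        delta = cfg.intraspecific_slope_n
        diff = (dec.slopes.loc[("n_mass", "full_variability"), "slope"]
                - dec.slopes.loc[("n_mass", "species_means"), "slope"])
        assert diff == pytest.approx(delta, rel=0.10)
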