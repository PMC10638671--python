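"""Decision tables, effect size, mode switching, effect-size ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cistrans_atac as ct
from cistrans_atac.datatypes import INHERITANCE_CALLS, REGULATORY_CALLS
from cistrans_atac.modes import (
    classify_inheritance,
    classify_regulatory,
    count_mode_switches,
    effect_size,
    mode_tallies,
    rank_by_effect,
)


def _inh(p, m, f, mat=10.0, pat=20.0, hyb=15.0):
    return classify_inheritance(
        np.array([p]), np.array([m]), np.array([f]),
        np.array([mat]), np.array([pat]), np.array([hyb]),
    )[0]


def _reg(p, h, t, lp=1.0, lh=0.5, require=True):
    return classify_regulatory(
        np.array([p]), np.array([h]), np.array([t]),
        np.array([lp]), np.array([lh]), require_parental_sig=require,
    )[0]


class TestInheritanceTable:
    def test_no_significance_is_conserved(self):
        assert _inh(False, False, False) == "conserved"

    def test_maternal_dominant_pattern(self):
        # hybrid indistinguishable from the mother, differs from the father
        assert _inh(True, False, True) == "maternal_dominant"

    def test_paternal_dominant_pattern(self):
        assert _inh(True, True, False) == "paternal_dominant"

    def test_additive_between_parents(self):
        assert _inh(True, True, True, mat=10, pat=20, hyb=15) == "additive"

    def test_overdominant_above_both(self):
        assert _inh(False, True, True, mat=10, pat=20, hyb=30) == "overdominant"

    def test_underdominant_below_both(self):
        assert _inh(False, True, True, mat=10, pat=20, hyb=5) == "underdominant"

    def test_exact_tie_is_ambiguous(self):
        assert _inh(True, True, True, mat=10, pat=20, hyb=20) == "ambiguous"

    def test_table_is_total_and_single_valued(self):
        # every significance pattern x hybrid position maps to exactly one call
        for p, m, f in itertools.product([False, True], repeat=3):
            for hyb in (5.0, 15.0, 25.0, 10.0):
                call = _inh(p, m, f, mat=10, pat=20, hyb=hyb)
                assert call in INHERITANCE_CALLS


class TestRegulatoryTable:
    def test_cis_pattern(self):
        # parents differ, alleles differ, ratios agree
        assert _reg(True, True, False) == "cis"

    def test_trans_pattern(self):
        # parents differ, alleles equalize
        assert _reg(True, False, True) == "trans"

    def test_compensatory_pattern(self):
        assert _reg(False, True, True) == "compensatory"

    def test_cis_plus_trans_same_signs(self):
        assert _reg(True, True, True, lp=2.0, lh=1.0) == "cis_plus_trans"

    def test_cis_x_trans_opposite_signs(self):
        assert _reg(True, True, True, lp=0.5, lh=1.5) == "cis_x_trans"

    def test_conserved_pattern(self):
        assert _reg(False, False, False) == "conserved"

    def test_zero_component_tie_is_ambiguous(self):
        assert _reg(True, True, True, lp=1.0, lh=1.0) == "ambiguous"

    @pytest.mark.parametrize("require", [True, False])
    def test_table_is_total(self, require):
        for p, h, t in itertools.product([False, True], repeat=3):
            for lp, lh in ((2.0, 1.0), (0.5, 1.5), (1.0, 1.0), (-1.0, 0.5)):
                call = _reg(p, h, t, lp=lp, lh=lh, require=require)
                assert call in REGULATORY_CALLS

    def test_relaxed_parental_requirement(self):
        assert _reg(False, True, False, require=False) == "cis"
        assert _reg(False, False, True, require=False) == "trans"


class TestEffectSize:
    def test_equal_means_zero(self):
        assert effect_size(np.array([10.0]), np.array([10.0]))[0] == 0.0

    def test_four_to_one(self):
        es = effect_size(np.array([4000.0]), np.array([1000.0]), pseudocount=0.5)[0]
        assert es == pytest.approx(2.0, abs=1e-3)

    def test_zero_zero_symmetry(self):
        assert effect_size(np.array([0.0]), np.array([0.0]), pseudocount=0.5)[0] == 0.0

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            effect_size(np.array([-1.0]), np.array([1.0]))


class TestClassifyAll:
    def test_conserved_simulation_mostly_conserved(self):
        truth = ct.make_truth(800, {"conserved": 1.0}, seed=31)
        cm, desc = ct.simulate_counts(truth, ct.SimulationDesign(seed=32))
        cm = ct.size_factors(ct.cpm_filter(cm, desc), desc)
        calls = ct.classify_all(cm, desc)
        for col in ("inheritance_mode", "regulatory_mode"):
            assert (calls[col] == "conserved").mean() >= 0.93

    def test_six_mode_recovery_majority(self, mixed_run):
        truth, calls = mixed_run["truth"], mixed_run["calls"]
        tf = pd.DataFrame(
            {"peak_id": [t.peak_id for t in truth],
             "true": [t.true_regulatory_mode for t in truth]}
        )
        merged = calls.merge(tf, on="peak_id")
        for mode, sub in merged.groupby("true"):
            assert (sub["regulatory_mode"] == mode).mean() > 0.5, mode

    def test_single_stage_input(self):
        truth = ct.make_truth(50, {"conserved": 1.0}, seed=33)
        cm, desc = ct.simulate_counts(
            truth, ct.SimulationDesign(stages=("gastrula",), seed=34)
        )
        cm = ct.size_factors(ct.cpm_filter(cm, desc), desc)
        calls = ct.classify_all(cm, desc)
        assert set(calls["stage"]) == {"gastrula"}

    def test_conserved_regulatory_call_not_in_da_set(self, mixed_run):
        calls = mixed_run["calls"]
        conserved = calls[calls["regulatory_mode"] == "conserved"]
        assert (conserved["padj_P"] > 0.05).all()

    def test_label_swap_symmetry(self, mixed_run):
        # exchanging maternal and paternal labels everywhere swaps the
        # dominant calls, keeps cis/trans, and negates the effect size
        cm, desc = mixed_run["cm"], mixed_run["descriptors"]
        swap_cross = {
            "maternal_species": "paternal_species",
            "paternal_species": "maternal_species",
            "hybrid": "hybrid",
        }
        swap_allele = {"total": "total", "maternal": "paternal", "paternal": "maternal"}
        swapped_desc = [
            ct.SampleDescriptor(
                d.sample_id, swap_cross[d.cross], d.stage, d.replicate,
                swap_allele[d.allele],
            )
            for d in desc
        ]
        calls = ct.classify_all(cm, desc)
        flipped = ct.classify_all(cm, swapped_desc)
        swap_inh = {
            "maternal_dominant": "paternal_dominant",
            "paternal_dominant": "maternal_dominant",
        }
        expected_inh = calls["inheritance_mode"].map(lambda m: swap_inh.get(m, m))
        assert (flipped["inheritance_mode"] == expected_inh).all()
        assert (flipped["regulatory_mode"] == calls["regulatory_mode"]).all()
        assert np.allclose(flipped["effect_size"], -calls["effect_size"], atol=1e-9)

    def test_tallies_conserve_totals(self, mixed_run):
        calls = mixed_run["calls"]
        tallies = mode_tallies(calls)
        for (stage, kind), sub in tallies.groupby(["stage", "classification"]):
            n_stage = (calls["stage"] == stage).sum()
            assert sub["count"].sum() == n_stage
            assert sub["proportion"].sum() == pytest.approx(1.0)


class TestModeSwitches:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["peak_id", "stage", "regulatory_mode"]).assign(
            inheritance_mode="conserved", effect_size=0.0
        )

    def test_identical_calls_no_switch(self):
        calls = self._calls(
            [("p1", s, "cis") for s in ("blastula", "gastrula", "larva")]
        )
        switches, matrix = count_mode_switches(calls)
        assert switches["p1"] == 0
        assert matrix.loc["cis", "cis"] == 2

    def test_single_switch(self):
        calls = self._calls(
            [("p1", "blastula", "cis"), ("p1", "gastrula", "cis"), ("p1", "larva", "trans")]
        )
        switches, matrix = count_mode_switches(calls)
        assert switches["p1"] == 1
        assert matrix.loc["cis", "trans"] == 1

    def test_fewer_than_two_stages_rejected(self):
        calls = self._calls([("p1", "blastula", "cis")])
        with pytest.raises(ValueError, match="2 stages"):
            count_mode_switches(calls)

    def test_random_calls_brute_force_recount(self, rng):
        stages = ["s1", "s2", "s3"]
        peaks = [f"p{i}" for i in range(50)]
        modes = list(REGULATORY_CALLS)
        rows = [
            (p, s, modes[rng.integers(len(modes))]) for p in peaks for s in stages
        ]
        calls = self._calls(rows)
        switches, matrix = count_mode_switches(calls)
        wide = calls.pivot(index="peak_id", columns="stage", values="regulatory_mode")
        for p in peaks:
            expect = sum(
                wide.loc[p, a] != wide.loc[p, b] for a, b in zip(stages[:-1], stages[1:])
            )
            assert switches[p] == expect
        assert switches.isin([0, 1, 2]).all()
        assert matrix.to_numpy().sum() == len(peaks) * (len(stages) - 1)


class TestRankByEffect:
    def test_full_k_matches_overall_proportions(self, mixed_run):
        calls = mixed_run["calls"]
        sub = calls[calls["stage"] == "blastula"]
        top, fractions = rank_by_effect(sub, len(sub))
        overall = sub["regulatory_mode"].value_counts(normalize=True)
        for mode in overall.index:
            assert fractions[mode] == pytest.approx(overall[mode])

    def test_top_one_selects_larger(self):
        calls = pd.DataFrame(
            {
                "peak_id": ["a", "b"],
                "stage": ["s", "s"],
                "regulatory_mode": ["cis", "trans"],
                "inheritance_mode": ["conserved", "conserved"],
                "effect_size": [-3.0, 1.0],
            }
        )
        top, _ = rank_by_effect(calls, 1)
        assert list(top["peak_id"]) == ["a"]

    def test_nonpositive_k_rejected(self, mixed_run):
        with pytest.raises(ValueError, match="positive"):
            rank_by_effect(mixed_run["calls"], 0)

    def test_cis_enriched_in_top_ten_when_cis_law_larger(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = ct.make_truth(
                400,
                {"conserved": 0.4, "cis": 0.3, "trans": 0.3},
                effect_size_law={
                    "cis": ("uniform", 1.5, 2.5),
                    "trans": ("uniform", 0.5, 1.5),
                },
                seed=seed,
            )
            cm, desc = ct.simulate_counts(truth, ct.SimulationDesign(seed=seed + 31))
            cm = ct.size_factors(ct.cpm_filter(cm, desc), desc)
            calls = ct.classify_all(cm, desc)
            sub = calls[calls["stage"] == "blastula"]
            _, fractions = rank_by_effect(sub, 10)
            overall_cis = (sub["regulatory_mode"] == "cis").mean()
            wins += fractions["cis"] > overall_cis
        assert wins > n_seeds / 2

    def test_mean_abs_effect_cis_exceeds_trans(self):
        from cistrans_atac.association import group_compare

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = ct.make_truth(
                400,
                {"conserved": 0.4, "cis": 0.3, "trans": 0.3},
                effect_size_law={
                    "cis": ("uniform", 1.5, 2.5),
                    "trans": ("uniform", 0.5, 1.5),
                },
                seed=seed,
            )
            cm, desc = ct.simulate_counts(truth, ct.SimulationDesign(seed=seed + 31))
            cm = ct.size_factors(ct.cpm_filter(cm, desc), desc)
            calls = ct.classify_all(cm, desc)
            sub = calls[calls["stage"] == "blastula"]
            res = group_compare(
                {
                    "cis": sub.loc[sub["regulatory_mode"] == "cis", "effect_size"].abs(),
                    "trans": sub.loc[sub["regulatory_mode"] == "trans", "effect_size"].abs(),
                },
                "welch_t",
            )
            one_sided = res["p"] / 2 if res["statistic"] > 0 else 1 - res["p"] / 2
            wins += one_sided < 0.05
        assert wins >= 0.9 * n_seeds
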