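"""Generator contracts: determinism, exact degenerate cases, CLT-level
recovery of planted temporal archetypes, and planted-structure wiring."""

import numpy as np
import pandas as pd
import pytest

import androdyn as ad
from androdyn.errors import ParameterError
from androdyn.simulate import (ARCHETYPES, DEFAULT_PAIR_EXCESS,
                               generate_paired_dataset)


class TestGenerateProfiles:
    def test_deterministic_given_seed(self):
        a, ta = ad.generate_profiles(n_proteins=200, seed=11)
        b, tb = ad.generate_profiles(n_proteins=200, seed=11)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_series_equal(ta.archetypes, tb.archetypes)
        c, _ = ad.generate_profiles(n_proteins=200, seed=12)
        assert not a.values.equals(c.values)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            ad.generate_profiles(n_proteins=100,
                                 archetype_mix={"A": 0.5, "B": 0.4})
        with pytest.raises(ParameterError):
            ad.generate_profiles(n_proteins=100,
                                 archetype_mix={"Z": 1.0})
        with pytest.raises(ParameterError):
            ad.generate_profiles(n_proteins=10)

    def test_zero_noise_all_a_recovers_archetype_exactly(self):
        """With zero noise and an all-A population the standardized profiles
        equal the A template exactly.

        Per-sample median centering is disabled here: centering by the data
        median removes any signal shared by >50% of proteins, so a pure
        single-archetype population is only recoverable without it (with the
        default mixed population the null fraction anchors the medians and
        centering is safe).
        """
        table, truth = ad.generate_profiles(
            n_proteins=60, archetype_mix={"A": 1.0}, noise_sd=0.0, seed=5,
            sample_scale_sd=0.0, rep_noise_sd=0.0,
            frac_low_peptide=0.0, frac_missing=0.0)
        prof = ad.standardize_profiles(ad.compute_ratios(table),
                                       median_center=False)
        arr = prof.profiles.to_numpy()
        assert np.allclose(arr, ARCHETYPES["A"], atol=1e-9)

    def test_archetype_mean_profiles_match_templates(self):
        """CLT check: the per-archetype mean standardized profile matches the
        template at every time point.

        The empirical mean is re-standardized before comparison: the
        per-protein z-score shrinks each profile by the factor
        1/sqrt(1 + noise-variance share), a scalar that would otherwise eat
        most of the 3*sd/sqrt(n) CLT band.  Sample-scale factors and median
        centering are disabled so the test isolates the profile
        construction; centering's factor removal has its own test below.
        """
        table, truth = ad.generate_profiles(n_proteins=1000, noise_sd=0.3,
                                            seed=7, sample_scale_sd=0.0,
                                            frac_low_peptide=0.0,
                                            frac_missing=0.0)
        prof = ad.standardize_profiles(ad.compute_ratios(table),
                                       median_center=False)
        for letter in "ABCDE":
            members = truth.members(letter)
            mean = prof.profiles.loc[members].mean(axis=0).to_numpy()
            mean = (mean - mean.mean()) / mean.std(ddof=1)
            tol = 3 * 0.3 / np.sqrt(len(members))
            assert np.allclose(mean, ARCHETYPES[letter], atol=tol + 0.02), \
                letter

    def test_median_centering_removes_sample_factors(self):
        """On a mostly-null population, per-sample median centering recovers
        the profiles generated without any sample-scale distortion.

        Median centering estimates each sample's scale factor by the column
        median, which is unbiased only when most proteins are unchanged at
        each time point; hence the 80% null mix here.  The same seed
        consumes the identical random stream for both calls, so the only
        difference is the planted factors.
        """
        mix = {"A": 0.1, "E": 0.1, "noise": 0.8}
        kw = dict(n_proteins=1000, archetype_mix=mix, noise_sd=0.3, seed=13,
                  frac_low_peptide=0.0, frac_missing=0.0)
        with_f, _ = ad.generate_profiles(sample_scale_sd=0.15, **kw)
        without_f, _ = ad.generate_profiles(sample_scale_sd=0.0, **kw)
        clean = ad.standardize_profiles(ad.compute_ratios(without_f),
                                        median_center=False)
        centered = ad.standardize_profiles(ad.compute_ratios(with_f),
                                           median_center=True)
        uncentered = ad.standardize_profiles(ad.compute_ratios(with_f),
                                             median_center=False)
        err_centered = (centered.profiles - clean.profiles).abs().mean().mean()
        err_raw = (uncentered.profiles - clean.profiles).abs().mean().mean()
        assert err_centered < 0.5 * err_raw
        assert err_centered < 0.1

    def test_flawed_proteins_marked_dropped(self):
        table, truth = ad.generate_profiles(n_proteins=500, seed=1)
        n_dropped = (truth.archetypes == "dropped").sum()
        assert n_dropped == round(0.03 * 500) + round(0.02 * 500)
        survivors = ad.filter_quantified(table)
        assert set(truth.archetypes[truth.archetypes == "dropped"].index) \
            .isdisjoint(survivors.proteins)


class TestGenerateAnnotations:
    def test_deterministic_and_biased(self):
        _, truth = ad.generate_profiles(n_proteins=2000, seed=0)
        a = ad.generate_annotations(truth, bias_odds=8.0, seed=3)
        b = ad.generate_annotations(truth, bias_odds=8.0, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        # planted direction: archetype A members hit the plasma membrane
        # more often than the population baseline
        in_a = a.table.loc[truth.members("A"), "compartment"]
        rest = a.table.loc[truth.members("E"), "compartment"]
        assert (in_a == "plasma membrane").mean() > \
            3 * (rest == "plasma membrane").mean()

    def test_bias_odds_below_one_rejected(self):
        _, truth = ad.generate_profiles(n_proteins=100, seed=0)
        with pytest.raises(ParameterError):
            ad.generate_annotations(truth, bias_odds=0.5)


class TestGeneratePpi:
    def test_hub_degree_by_construction(self):
        _, truth = ad.generate_profiles(n_proteins=500, seed=0)
        g = ad.generate_ppi(truth, base_rate=0.0, hub_spec={"EGFR": 97},
                            seed=0)
        assert g.degree["EGFR"] == 97

    def test_deterministic_simple_graph(self):
        _, truth = ad.generate_profiles(n_proteins=400, seed=0)
        g1 = ad.generate_ppi(truth, pair_excess=DEFAULT_PAIR_EXCESS, seed=9)
        g2 = ad.generate_ppi(truth, pair_excess=DEFAULT_PAIR_EXCESS, seed=9)
        assert set(g1.edges) == set(g2.edges)
        assert not any(a == b for a, b in g1.edges)

    def test_excess_raises_cross_pair_density(self):
        _, truth = ad.generate_profiles(n_proteins=1500, seed=0)
        g = ad.generate_ppi(truth, base_rate=0.002,
                            pair_excess={("C", "E"): 5.0}, seed=4)
        ce, cd = 0, 0
        lab = truth.archetypes
        for a, b in g.edges:
            pair = tuple(sorted((lab[a], lab[b])))
            ce += pair == ("C", "E")
            cd += pair == ("C", "D")
        assert ce > 2.5 * max(cd, 1)


class TestGenerateMarkers:
    def test_planted_genes_shift_in_enough_datasets(self):
        dss = ad.generate_marker_datasets(n_datasets=4, n_genes=300,
                                          effect=2.0, seed=0)
        planted = dss[0].values.attrs["planted"]
        assert (planted["n_datasets"] >= 2).all()
        assert set(planted["direction"]) <= {"up", "down"}

    def test_determinism(self):
        a = ad.generate_marker_datasets(n_genes=100, seed=2)
        b = ad.generate_marker_datasets(n_genes=100, seed=2)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.values, y.values)

    def test_paired_dataset_structure(self):
        ds = generate_paired_dataset(n_genes=200, n_pairs=10, seed=0)
        assert ds.pairs is not None
        assert (ds.groups == "case").sum() == 10
        assert ds.pairs.nunique() == 10


class TestGenerateConcepts:
    def test_deterministic_and_designated(self):
        _, truth = ad.generate_profiles(n_proteins=1000, seed=0)
        c1 = ad.generate_concepts(truth, overlap_odds=10, seed=5)
        c2 = ad.generate_concepts(truth, overlap_odds=10, seed=5)
        assert c1.sets == c2.sets
        assert set(truth.concept_clusters.values()) <= set("ABCDE")
        with pytest.raises(ParameterError):
            ad.generate_concepts(truth, overlap_odds=0.2)


def test_truth_json_export(tmp_path):
    _, truth = ad.generate_profiles(n_proteins=100, seed=0)
    truth.to_json(tmp_path / "truth.json")
    import json
    payload = json.loads((tmp_path / "truth.json").read_text())
    assert set(payload["archetypes"]) == set(truth.archetypes.index)
    assert payload["params"]["noise_sd"] == 0.3
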