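"""Apoptotic/lytic classification and the fluorescence verification statistics."""

import numpy as np
import pandas as pd
import pytest

from qpi_deathwatch.death_classification import (
    DeathTypeClassifier,
    apoptotic_fraction,
    casp_pi_onset_delay,
    classify_deaths,
    feature_subset_sweep,
    nucleus_brightness,
    summarize_predeath,
    summarize_population,
    train_type_classifier,
)
from qpi_deathwatch.io_formats import FEATURE_COLUMNS
from qpi_deathwatch.synthetic_scenes import (
    SceneConfig,
    generate_feature_signals,
    generate_scene,
)


def _cell_table(T=400, density=2.0, cds=0.05, cell_id=1):
    df = pd.DataFrame({c: 1.0 for c in FEATURE_COLUMNS}, index=range(T))
    df["density"] = density
    df["cds"] = cds
    df["frame"] = range(T)
    df["cell_id"] = cell_id
    return df


def _toy_summaries(n=50, seed=0):
    rng = np.random.default_rng(seed)
    apo = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "density": rng.normal(3.0, 0.2, n),
            "cds": rng.normal(0.3, 0.03, n),
        }
    )
    lyt = pd.DataFrame(
        {
            "cell_id": np.arange(n, 2 * n),
            "density": rng.normal(1.2, 0.2, n),
            "cds": rng.normal(0.05, 0.02, n),
        }
    )
    summaries = pd.concat([apo, lyt], ignore_index=True)
    labels = np.array(["apoptotic"] * n + ["lytic"] * n)
    return summaries, labels


class TestSummarizePredeath:
    def test_full_window_is_200_frames(self):
        s = summarize_predeath(_cell_table(), 300)
        assert s.window_frames == 200

    def test_short_history_uses_shorter_window(self):
        s = summarize_predeath(_cell_table(), 50)
        assert s.window_frames == 50

    def test_constant_density_mean(self):
        s = summarize_predeath(_cell_table(density=2.0), 300)
        assert s.means["density"] == 2.0

    def test_window_excludes_death_frame_and_after(self):
        table = _cell_table(T=400)
        table.loc[table["frame"] >= 300, "density"] = 99.0
        s = summarize_predeath(table, 300)
        assert s.means["density"] == 2.0

    def test_death_at_zero_rejected(self):
        with pytest.raises(ValueError):
            summarize_predeath(_cell_table(), 0)


class TestClassifier:
    def test_separable_clusters_fit_perfectly(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        assert (clf.predict(summaries) == labels).mean() == 1.0

    def test_label_swap_negates_weights(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        swapped = np.where(labels == "apoptotic", "lytic", "apoptotic")
        clf2 = train_type_classifier(summaries, swapped)
        # up to the SVC solver's convergence tolerance
        np.testing.assert_allclose(clf.coef_, -clf2.coef_, rtol=1e-3)

    def test_single_class_rejected(self):
        summaries, _ = _toy_summaries()
        with pytest.raises(ValueError):
            train_type_classifier(summaries, ["apoptotic"] * len(summaries))

    def test_margin_geometry(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        far_apo = pd.DataFrame({"cell_id": [0], "density": [5.0], "cds": [0.6]})
        far_lyt = pd.DataFrame({"cell_id": [1], "density": [0.5], "cds": [0.01]})
        assert clf.decision_margin(far_apo)[0] > 1.0
        assert clf.decision_margin(far_lyt)[0] < -1.0
        # point midway between class means sits near the boundary
        mid = pd.DataFrame({"cell_id": [2], "density": [2.1], "cds": [0.175]})
        assert abs(clf.decision_margin(mid)[0]) < 1.0

    def test_config_round_trip_predicts_identically(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        back = DeathTypeClassifier.from_config(clf.to_config())
        np.testing.assert_array_equal(back.predict(summaries), clf.predict(summaries))
        np.testing.assert_allclose(
            back.decision_margin(summaries), clf.decision_margin(summaries)
        )

    def test_synthetic_population_held_out_accuracy(self):
        plan = {
            cid: (250, "apoptotic" if cid <= 40 else "lytic")
            for cid in range(1, 81)
        }
        table, anns = generate_feature_signals(80, 300, plan, noise_sd=0.05, seed=4)
        frames = {a.cell_id: a.death_frame for a in anns if a.death_frame}
        summaries = summarize_population(table, frames)
        labels = np.array(
            ["apoptotic" if c <= 40 else "lytic" for c in summaries["cell_id"]]
        )
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(summaries))
        train, test = idx[:56], idx[56:]
        clf = train_type_classifier(summaries.iloc[train], labels[train])
        acc = (clf.predict(summaries.iloc[test]) == labels[test]).mean()
        assert acc >= 0.9


class TestClassifyDeaths:
    def test_training_set_of_separable_demo_matches_labels(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        out = classify_deaths(clf, summaries)
        assert (out["type"].to_numpy() == labels).all()

    def test_missing_features_yield_unclassified(self):
        summaries, labels = _toy_summaries()
        clf = train_type_classifier(summaries, labels)
        summaries.loc[0, "density"] = np.nan
        out = classify_deaths(clf, summaries)
        assert out.loc[0, "type"] == "unclassified"
        assert np.isnan(out.loc[0, "margin"])

    def test_apoptotic_fraction(self):
        assert apoptotic_fraction(["apoptotic", "lytic", "apoptotic", "unclassified"]) == pytest.approx(2 / 3)
        assert np.isnan(apoptotic_fraction([]))


class TestSubsetSweep:
    def test_three_features_give_seven_subsets(self):
        summaries, labels = _toy_summaries()
        summaries["mass"] = np.random.default_rng(0).normal(size=len(summaries))
        out = feature_subset_sweep(
            summaries, labels, k_range=(1, 2, 3),
            candidate_features=("density", "cds", "mass"), cv=3,
        )
        assert len(out) == 7

    def test_duplicated_feature_scores_like_singleton(self):
        summaries, labels = _toy_summaries()
        summaries["density2"] = summaries["density"]
        out = feature_subset_sweep(
            summaries, labels, k_range=(1, 2),
            candidate_features=("density", "density2"), cv=3,
        )
        accs = {tuple(r["subset"]): r["accuracy"] for _, r in out.iterrows()}
        assert accs[("density", "density2")] == pytest.approx(accs[("density",)])


class TestOnsetDelay:
    def test_step_before_death_gives_positive_delay(self):
        casp = np.zeros(1300)
        casp[900:] = 1.0
        assert casp_pi_onset_delay(casp, 1000) == 100.0

    def test_step_at_death_gives_zero(self):
        casp = np.zeros(1300)
        casp[1000:] = 1.0
        assert casp_pi_onset_delay(casp, 1000) == 0.0

    def test_flat_zero_is_missing(self):
        assert np.isnan(casp_pi_onset_delay(np.zeros(1300), 1000))


class TestNucleusBrightness:
    def test_constant_brightness(self):
        frames = np.full((300, 8, 8), 10.0)
        masks = np.ones((300, 8, 8), bool)
        assert nucleus_brightness(frames, masks, 250) == 10.0

    def test_linear_ramp_averages_to_midpoint(self):
        T = 250
        frames = np.zeros((T, 4, 4))
        ramp = np.linspace(0, 10, 200, endpoint=False)
        frames[50:250] = ramp[:, None, None]
        masks = np.ones((T, 4, 4), bool)
        assert nucleus_brightness(frames, masks, 250) == pytest.approx(5.0, abs=0.1)

    def test_empty_masks_missing(self):
        frames = np.ones((50, 4, 4))
        masks = np.zeros((50, 4, 4), bool)
        assert np.isnan(nucleus_brightness(frames, masks, 40))

    def test_apoptotic_nuclei_brighter_than_lytic_in_scene(self):
        cfg = SceneConfig(
            n_cells=2, T=60, H=240, W=240, noise_sd=0.0, seed=8,
            death_plan={1: (50, "apoptotic"), 2: (50, "lytic")},
            predeath_window=40,
        )
        seq, gt, centers, _ = generate_scene(cfg)
        nuc = seq.channels["nuclei"]
        vals = {}
        for cid in (1, 2):
            masks = [(gt.labels[t] == cid) & (nuc[t] > 0.2) for t in range(60)]
            vals[cid] = nucleus_brightness(nuc, masks, 50, window=40)
        assert vals[1] > vals[2]
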