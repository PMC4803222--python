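"""Presence-background habitat model: bootstrap balancing, screening,
replicate fitting, AUC, and variable-importance measures."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from glspipe.habitat import (
    MaxentModel,
    PresenceSet,
    auc_band,
    balance_presences,
    phase_months,
    predictor_table,
    screen_predictors,
)
from glspipe.synth import SimConfig, TrueTrack, make_environment, simulate_tracks


def _uniform_tracks(n_birds, seed, n_fix=300):
    """Tracks with fixes uniform over the study area (no habitat signal)."""
    rng = np.random.default_rng(seed)
    t0 = np.datetime64("2012-06-01", "s")
    times = t0 + np.arange(n_fix) * np.timedelta64(3600, "s")
    out = []
    for b in range(n_birds):
        lon = rng.uniform(-39.5, -8.5, n_fix)
        lat = rng.uniform(22.5, 45.5, n_fix)
        out.append(
            TrueTrack(f"CI{b:02d}", "CI", times, lon, lat, times[:1],
                      np.array(["WATER"]))
        )
    return out


@pytest.fixture(scope="module")
def sst_pset(env):
    """Presences from tracks driven purely by cold-water preference."""
    pref = {(c, p): {"SST": -2.0} for c in ("CI", "SG") for p in ("BREEDING", "NONBREEDING")}
    cfg = SimConfig(seed=2, n_birds={"CI": 6, "SG": 0}, preference_weights=pref)
    tracks = simulate_tracks(env, cfg, start="2012-06-01", n_days=60)
    for tr in tracks:  # discard the transient dispersal from the colony
        cut = 10 * 24
        tr.times, tr.lon, tr.lat = tr.times[cut:], tr.lon[cut:], tr.lat[cut:]
    return balance_presences(tracks, env, "CI", "NONBREEDING",
                             n_per_bird=100, n_background=4000, seed=2)


# --- balancing -------------------------------------------------------------


def test_balance_counts_and_determinism(env, small_tracks):
    _, tracks = small_tracks
    a = balance_presences(tracks, env, "CI", "NONBREEDING", n_per_bird=50,
                          n_background=500, seed=4)
    b = balance_presences(tracks, env, "CI", "NONBREEDING", n_per_bird=50,
                          n_background=500, seed=4)
    assert len(a.presence) == 50 * 3  # three CI birds, equal shares
    assert a.presence.groupby("bird").size().nunique() == 1
    pd.testing.assert_frame_equal(a.presence, b.presence)


def test_one_fix_bird_gives_repeated_cell(env):
    t0 = np.datetime64("2012-06-01", "s")
    tr = TrueTrack("CI00", "CI", np.array([t0, t0 + np.timedelta64(3600, "s")]),
                   np.array([-20.0, -20.0]), np.array([35.0, 35.0]),
                   np.array([t0]), np.array(["WATER"]))
    pset = balance_presences([tr], env, "CI", "NONBREEDING", n_per_bird=40,
                             n_background=100, seed=0)
    assert pset.presence["cell"].nunique() == 1
    assert len(pset.presence) == 40


def test_phase_months_partition_year():
    assert sorted(phase_months("BREEDING") + phase_months("NONBREEDING")) == list(range(1, 13))


# --- screening -------------------------------------------------------------


def _toy_pset(rng, extra=None):
    n = 600
    base = pd.DataFrame({
        "X1": rng.normal(size=n),
        "X2": rng.normal(size=n),
    })
    if extra is not None:
        base[extra[0]] = extra[1]
    pres = base.iloc[: n // 3].copy()
    pres.insert(0, "cell", np.arange(len(pres)))
    pres.insert(0, "bird", "b0")
    bg = base.copy()
    bg.insert(0, "cell", np.arange(n))
    return PresenceSet(pres, bg, tuple(c for c in base.columns))


def test_screening_drops_duplicated_variable(rng):
    pset = _toy_pset(rng)
    pset.background["X3"] = pset.background["X1"] + rng.normal(0, 1e-4, len(pset.background))
    pset.presence["X3"] = pset.presence["X1"]
    pset = PresenceSet(pset.presence, pset.background, ("X1", "X2", "X3"))
    kept = screen_predictors(pset)
    assert "X2" in kept
    assert ("X1" in kept) != ("X3" in kept)  # exactly one of the pair


def test_screening_keeps_independent_variables(rng):
    pset = _toy_pset(rng)
    assert set(screen_predictors(pset)) == {"X1", "X2"}


# --- fitting ---------------------------------------------------------------


def test_separable_predictor_gives_high_auc(rng):
    n = 400
    signal = np.concatenate([np.ones(150), np.zeros(n)])
    df = pd.DataFrame({"S": signal, "N": rng.normal(size=n + 150)})
    pres = df.iloc[:150].copy()
    pres.insert(0, "cell", np.arange(150))
    pres.insert(0, "bird", "b0")
    bg = df.iloc[150:].copy()
    bg.insert(0, "cell", np.arange(n))
    pset = PresenceSet(pres, bg, ("S", "N"))
    res = MaxentModel(pset, variables=("S", "N")).fit(n_replicates=10, seed=2,
                                                      contribution_replicates=0)
    assert res.mean_test_auc > 0.95


def test_suitability_bounded_and_deterministic(env, sst_pset):
    model = MaxentModel(sst_pset)
    res = model.fit(n_replicates=5, seed=1, contribution_replicates=0)
    mean, cv = res.suitability_surfaces(env, "CI", "NONBREEDING")
    assert float(mean.min()) >= 0.0 and float(mean.max()) <= 1.0
    res2 = MaxentModel(sst_pset).fit(n_replicates=5, seed=1, contribution_replicates=0)
    np.testing.assert_array_equal(res.auc_, res2.auc_)


def test_sst_preference_recovered(env, sst_pset):
    res = MaxentModel(sst_pset).fit(n_replicates=20, seed=3, contribution_replicates=8)
    pc = res.percent_contribution
    assert pc.idxmax() == "SST"
    assert pc.sum() == pytest.approx(100.0, abs=0.5)
    jk = res.jackknife()
    assert jk["gain_alone"].idxmax() == "SST"
    assert res.mean_test_auc > 0.8


def test_null_tracks_give_chance_auc(env):
    tracks = _uniform_tracks(6, seed=9)
    pset = balance_presences(tracks, env, "CI", "NONBREEDING", n_per_bird=100,
                             n_background=3000, seed=9)
    res = MaxentModel(pset).fit(n_replicates=20, seed=9, contribution_replicates=0)
    assert abs(res.mean_test_auc - 0.5) < 0.05
    perm = res.permutation_contribution
    assert perm.sum() == pytest.approx(100.0, abs=0.5) or perm.sum() == 0.0


def test_single_variable_model_contribution_is_total(env, sst_pset):
    res = MaxentModel(sst_pset, variables=("SST",)).fit(
        n_replicates=5, seed=0, contribution_replicates=5
    )
    assert res.percent_contribution["SST"] == pytest.approx(100.0)
    assert res.permutation_contribution["SST"] == pytest.approx(100.0)


# --- AUC -------------------------------------------------------------------


def test_auc_equals_brute_force_pair_counting(rng):
    scores = rng.normal(size=20)
    labels = (rng.random(20) < 0.5).astype(int)
    if labels.sum() in (0, 20):
        labels[0] = 1 - labels[0]
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    brute = wins / (len(pos) * len(neg))
    assert roc_auc_score(labels, scores) == pytest.approx(brute)


def test_auc_invariant_under_monotone_transform(env, sst_pset):
    model = MaxentModel(sst_pset, variables=("SST",))
    res = model.fit(n_replicates=3, seed=5, contribution_replicates=0)
    clf = res.replicates[0]["clf"]
    bg = sst_pset.background
    pres = sst_pset.presence
    s = np.concatenate([model.predict(clf, pres), model.predict(clf, bg)])
    y = np.concatenate([np.ones(len(pres)), np.zeros(len(bg))])
    a1 = roc_auc_score(y, s)
    a2 = roc_auc_score(y, np.log(s / (1 - s)))  # logit is monotone
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_auc_bands():
    assert auc_band(0.95) == "excellent"
    assert auc_band(0.85) == "good"
    assert auc_band(0.75) == "acceptable"
    assert auc_band(0.65) == "bad"
    assert auc_band(0.55) == "invalid"


# --- jackknife -------------------------------------------------------------


def test_jackknife_noise_variable_near_zero(env, rng):
    n_pres, n_bg = 300, 2000
    table = predictor_table(env, "CI", "NONBREEDING", ("SST", "WSPD"))
    cold = table.nsmallest(3000, "SST").sample(n_pres, random_state=1)
    pres = cold.copy()
    pres.insert(0, "cell", cold.index.to_numpy())
    pres.insert(0, "bird", "b0")
    bg = table.sample(n_bg, random_state=2).copy()
    bg.insert(0, "cell", bg.index.to_numpy())
    bg = bg.reset_index(drop=True)
    pres = pres.reset_index(drop=True)
    pres["NOISE"] = rng.normal(size=n_pres)
    bg["NOISE"] = rng.normal(size=n_bg)
    pset = PresenceSet(pres, bg, ("SST", "NOISE"))
    jk = MaxentModel(pset, variables=("SST", "NOISE")).jackknife_gains()
    assert jk.loc["NOISE", "gain_alone"] < 0.02
    assert jk.loc["SST", "gain_alone"] > 5 * max(jk.loc["NOISE", "gain_alone"], 1e-6)
    # omitting the redundant noise variable costs nothing
    assert jk.loc["NOISE", "gain_without"] == pytest.approx(
        jk.loc["SST", "gain_alone"], rel=0.2
    )
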