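"""Presence-background habitat-suitability modelling.

A maximum-entropy (MaxEnt-style) habitat model contrasts cells a
population used against random background cells of the study area.  It is
implemented through the equivalence between MaxEnt and penalized logistic
regression: linear + quadratic features of the standardized predictors
with an L2 penalty, logistic output in [0, 1] per grid cell.  The protocol
mirrors standard tracking-data practice:

* equal numbers of locations per bird, drawn with replacement (bootstrap),
  so no individual dominates the model;
* collinearity screening (drop one of any predictor pair with |r| > 0.7 on
  background cells) plus information-criterion ranking of candidate sets;
* many replicate fits on random 70/30 presence splits, averaged into a
  mean suitability surface and a coefficient-of-variation surface;
* test AUC per replicate with the conventional interpretation bands;
* variable importance as percent contribution (training-gain decomposition
  over a greedy fit path), permutation contribution (test-AUC drop when a
  variable is shuffled), and jackknife gains (each variable alone /
  omitted).

``MaxentModel`` holds the data and configuration; ``fit()`` returns a
``MaxentResults`` with estimates, uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "PresenceSet",
    "MaxentModel",
    "MaxentResults",
    "balance_presences",
    "phase_months",
    "predictor_table",
    "screen_predictors",
    "auc_band",
]

ALL_VARS = ("BAT", "SST", "CHL", "BATG", "SSTG", "CHLG", "WSPD", "DCOL")
DEFAULT_BACKGROUND = 10_000
COLLINEARITY_R = 0.7


def phase_months(phase: str):
    """Months of the annual cycle phase (BREEDING Dec-May, else Jun-Nov)."""
    return [12, 1, 2, 3, 4, 5] if phase == "BREEDING" else [6, 7, 8, 9, 10, 11]


def predictor_table(env: xr.Dataset, colony: str, phase: str, variables=ALL_VARS) -> pd.DataFrame:
    """Per-cell predictor matrix for one colony and phase.

    Dynamic layers are averaged over the phase months (monthly composites
    -> phase composite); DCOL uses the colony's layer.  Returns a frame
    indexed by flat cell id with ``lon``/``lat`` columns plus one column
    per predictor.
    """
    months = [m for m in phase_months(phase) if m in env["month"].values]
    lon = np.asarray(env["lon"], dtype=float)
    lat = np.asarray(env["lat"], dtype=float)
    LON, LAT = np.meshgrid(lon, lat)
    cols = {"lon": LON.ravel(), "lat": LAT.ravel()}
    for var in variables:
        layer = env[var]
        if "colony" in layer.dims:
            layer = layer.sel(colony=colony)
        if "month" in layer.dims:
            layer = layer.sel(month=months).mean("month")
        cols[var] = np.asarray(layer, dtype=float).ravel()
    return pd.DataFrame(cols)


@dataclass
class PresenceSet:
    """Bird-balanced presence cells plus background cells with predictors."""

    presence: pd.DataFrame    # columns: bird, cell, lon, lat, predictors...
    background: pd.DataFrame  # columns: cell, lon, lat, predictors...
    variables: tuple
    grid_shape: tuple = ()
    grid_coords: dict = field(default_factory=dict)

    @property
    def n_per_bird(self) -> int:
        return int(self.presence.groupby("bird").size().iloc[0])


def _snap(values, axis):
    cell = axis[1] - axis[0]
    return np.clip(((values - axis[0]) / cell).round().astype(int), 0, axis.size - 1)


def balance_presences(
    tracks,
    env: xr.Dataset,
    colony: str,
    phase: str,
    n_per_bird: int = 100,
    n_background: int = DEFAULT_BACKGROUND,
    variables=ALL_VARS,
    seed: int = 0,
) -> PresenceSet:
    """Equal-location bootstrap of presences per bird, plus random background.

    For every track of ``colony``, ``n_per_bird`` fixes of the phase are
    drawn with replacement and snapped to grid cells; the background is a
    uniform random sample (with replacement) of study-area cells.  Birds
    with no fix in the phase are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    table = predictor_table(env, colony, phase, variables)
    lon_ax = np.asarray(env["lon"], dtype=float)
    lat_ax = np.asarray(env["lat"], dtype=float)
    nlon = lon_ax.size
    rows = []
    for track in tracks:
        if getattr(track, "colony", colony) != colony:
            continue
        phases = np.asarray(track.phases)
        sel = phases == phase
        lon = np.asarray(track.lon)[sel]
        lat = np.asarray(track.lat)[sel]
        if lon.size == 0:
            warnings.warn(f"track {track.bird_id} has no fixes in phase {phase}; excluded")
            continue
        pick = rng.integers(0, lon.size, size=n_per_bird)
        cells = _snap(lat[pick], lat_ax) * nlon + _snap(lon[pick], lon_ax)
        sub = table.iloc[cells].reset_index(drop=True)
        sub.insert(0, "cell", cells)
        sub.insert(0, "bird", track.bird_id)
        rows.append(sub)
    if not rows:
        raise ValueError(f"no tracks with fixes for colony {colony}, phase {phase}")
    presence = pd.concat(rows, ignore_index=True)
    bg_cells = rng.integers(0, len(table), size=n_background)
    background = table.iloc[bg_cells].reset_index(drop=True)
    background.insert(0, "cell", bg_cells)
    return PresenceSet(
        presence,
        background,
        tuple(variables),
        grid_shape=(lat_ax.size, lon_ax.size),
        grid_coords={"lat": lat_ax, "lon": lon_ax},
    )


# ---------------------------------------------------------------------------
# fitting machinery


class _Design:
    """Standardized linear+quadratic feature expansion over named variables."""

    def __init__(self, background: pd.DataFrame, variables):
        self.variables = tuple(variables)
        self.mean = background[list(variables)].mean()
        self.std = background[list(variables)].std().replace(0.0, 1.0)

    def matrix(self, df: pd.DataFrame, variables=None) -> np.ndarray:
        variables = self.variables if variables is None else tuple(variables)
        z = (df[list(variables)] - self.mean[list(variables)]) / self.std[list(variables)]
        z = z.to_numpy()
        return np.hstack([z, z * z])

    def columns(self, variables=None):
        variables = self.variables if variables is None else tuple(variables)
        return [f"{v}:lin" for v in variables] + [f"{v}:quad" for v in variables]


def _fit_logistic(X, y, C):
    clf = LogisticRegression(C=C, max_iter=2000, tol=1e-5)  # L2 penalty (default)
    clf.fit(X, y)
    return clf


def _gain(clf, X, y) -> float:
    """Mean log-likelihood improvement over the intercept-only model."""
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    ll = np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll0 = pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)
    return float(ll - ll0)


def _single_gain(design, presence, background, var, C) -> float:
    Xp = design.matrix(presence, [var])
    Xb = design.matrix(background, [var])
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    return _gain(_fit_logistic(X, y, C), X, y)


def screen_predictors(pset: PresenceSet, candidate_sets=None, C: float = 1.0):
    """Collinearity screen + information-criterion ranking of variable sets.

    Of any pair with |Pearson r| > 0.7 on background cells, the variable
    with the lower single-variable training gain is dropped.  Remaining
    candidate sets (intersected with the surviving variables) are ranked
    by AIC of a single penalized fit; the best set is returned.
    """
    variables = list(pset.variables)
    design = _Design(pset.background, variables)
    gains = {
        v: _single_gain(design, pset.presence, pset.background, v, C) for v in variables
    }
    corr = pset.background[variables].corr().abs()
    dropped = set()
    order = sorted(variables, key=lambda v: -gains[v])
    for i, a in enumerate(order):
        if a in dropped:
            continue
        for b in order[i + 1 :]:
            if b in dropped:
                continue
            if corr.loc[a, b] > COLLINEARITY_R:
                dropped.add(b)  # keep the higher-gain variable
    kept = [v for v in variables if v not in dropped]
    if not kept:  # all collinear: keep the single best variable
        kept = [max(variables, key=lambda v: gains[v])]
    if candidate_sets is None:
        return tuple(kept)
    best, best_aic = None, np.inf
    for cand in candidate_sets:
        use = [v for v in cand if v in kept]
        if not use:
            continue
        Xp = design.matrix(pset.presence, use)
        Xb = design.matrix(pset.background, use)
        X = np.vstack([Xp, Xb])
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
        clf = _fit_logistic(X, y, C)
        p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        k = X.shape[1] + 1
        aic = 2 * k - 2 * ll
        if aic < best_aic:
            best, best_aic = tuple(use), aic
    return best


def auc_band(auc: float) -> str:
    """Conventional AUC interpretation bands."""
    if auc > 0.90:
        return "excellent"
    if auc > 0.80:
        return "good"
    if auc > 0.70:
        return "acceptable"
    if auc > 0.60:
        return "bad"
    return "invalid"


class MaxentModel:
    """Presence-background suitability model for one colony and phase.

    Parameters
    ----------
    pset : PresenceSet with presences, background and predictors.
    variables : predictors to use (default: collinearity-screened set).
    C : inverse L2 penalty strength; ``None`` selects it by inner
        validation on a held-out quarter of the presences.
    """

    def __init__(self, pset: PresenceSet, variables=None, C: float | None = None):
        self.pset = pset
        self.variables = tuple(variables) if variables is not None else screen_predictors(pset)
        self.design = _Design(pset.background, self.variables)
        self.C = C

    @classmethod
    def from_tracks(cls, tracks, env, colony, phase, n_per_bird=100,
                    n_background=DEFAULT_BACKGROUND, seed=0, **kw):
        pset = balance_presences(tracks, env, colony, phase, n_per_bird, n_background, seed=seed)
        return cls(pset, **kw)

    # -- internals ---------------------------------------------------------

    def _dedup(self, df: pd.DataFrame) -> pd.DataFrame:
        """Duplicate cells removed before fitting (one record per cell)."""
        return df.drop_duplicates(subset="cell")

    def _select_C(self, rng) -> float:
        pres = self._dedup(self.pset.presence)
        bg = self.pset.background
        n = len(pres)
        idx = rng.permutation(n)
        cut = max(1, int(0.75 * n))
        tr, va = pres.iloc[idx[:cut]], pres.iloc[idx[cut:]]
        Xb = self.design.matrix(bg)
        best, best_auc = 1.0, -np.inf
        for C in (0.01, 0.1, 1.0, 10.0):
            clf = _fit_logistic(
                np.vstack([self.design.matrix(tr), Xb]),
                np.concatenate([np.ones(len(tr)), np.zeros(len(bg))]),
                C,
            )
            scores = np.concatenate(
                [clf.predict_proba(self.design.matrix(va))[:, 1], clf.predict_proba(Xb)[:, 1]]
            )
            lab = np.concatenate([np.ones(len(va)), np.zeros(len(bg))])
            a = roc_auc_score(lab, scores)
            if a > best_auc:
                best, best_auc = C, a
        return best

    def _replicate(self, rng, C, contribution_path=True):
        pres = self._dedup(self.pset.presence)
        bg = self.pset.background
        n = len(pres)
        idx = rng.permutation(n)
        n_test = max(1, int(round(0.0 + self._test_frac * n)))
        test, train = pres.iloc[idx[:n_test]], pres.iloc[idx[n_test:]]
        Xb = self.design.matrix(bg)
        yb = np.zeros(len(bg))
        Xt = self.design.matrix(train)
        X = np.vstack([Xt, Xb])
        y = np.concatenate([np.ones(len(train)), yb])
        clf = _fit_logistic(X, y, C)
        # test AUC: test presences ranked against the background sample
        scores = np.concatenate(
            [clf.predict_proba(self.design.matrix(test))[:, 1], clf.predict_proba(Xb)[:, 1]]
        )
        labels = np.concatenate([np.ones(len(test)), yb])
        if np.ptp(scores) == 0:
            auc = 0.5
        else:
            auc = float(roc_auc_score(labels, scores))
        out = {"clf": clf, "auc": auc, "gain": _gain(clf, X, y)}
        # permutation contribution: drop in test AUC when one variable is
        # shuffled across evaluation cells
        drops = {}
        both = pd.concat([test, bg], ignore_index=True)
        for var in self.variables:
            shuffled = both.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            s2 = clf.predict_proba(self.design.matrix(shuffled))[:, 1]
            if np.ptp(s2) == 0:
                a2 = 0.5
            else:
                a2 = float(roc_auc_score(labels, s2))
            drops[var] = max(0.0, auc - a2)
        out["perm_drop"] = drops
        # percent contribution: greedy forward path, gain increments
        if contribution_path:
            out["path_gain"] = self._path_gains(train, bg, C)
        return out

    def _path_gains(self, train, bg, C):
        """Greedy forward-selection gain increments per variable."""
        y = np.concatenate([np.ones(len(train)), np.zeros(len(bg))])
        chosen: list = []
        remaining = list(self.variables)
        gain_prev = 0.0
        incr = {}
        while remaining:
            best_var, best_gain = None, -np.inf
            for var in remaining:
                use = chosen + [var]
                X = np.vstack([self.design.matrix(train, use), self.design.matrix(bg, use)])
                g = _gain(_fit_logistic(X, y, C), X, y)
                if g > best_gain:
                    best_var, best_gain = var, g
            incr[best_var] = max(0.0, best_gain - gain_prev)
            gain_prev = best_gain
            chosen.append(best_var)
            remaining.remove(best_var)
        return incr

    # -- public API --------------------------------------------------------

    def fit(
        self,
        n_replicates: int = 50,
        test_fraction: float = 0.30,
        seed: int = 0,
        contribution_replicates: int | None = 10,
    ) -> "MaxentResults":
        """Fit replicate models on random 70/30 presence splits.

        ``contribution_replicates`` limits the (expensive) forward-path
        percent-contribution decomposition to the first k replicates; AUC,
        surfaces and permutation contributions always use all replicates.
        Replicates that fail to converge are dropped (the model is invalid
        if more than 20% drop).
        """
        self._test_frac = float(test_fraction)
        rng = np.random.default_rng([seed, 1237])
        C = self.C if self.C is not None else self._select_C(rng)
        if contribution_replicates is None:
            contribution_replicates = n_replicates
        reps = []
        dropped = 0
        for r in range(n_replicates):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", category=ConvergenceWarning)
                    reps.append(self._replicate(rng, C, contribution_path=r < contribution_replicates))
            except (ConvergenceWarning, np.linalg.LinAlgError):
                dropped += 1
        if dropped > 0.2 * n_replicates:
            raise RuntimeError(f"{dropped}/{n_replicates} replicates failed to converge")
        return MaxentResults(self, reps, C, dropped)

    def predict(self, clf, df: pd.DataFrame) -> np.ndarray:
        return clf.predict_proba(self.design.matrix(df))[:, 1]

    def jackknife_gains(self, C: float = 1.0) -> pd.DataFrame:
        """Training gain of each variable alone and of the model omitting it."""
        pres = self._dedup(self.pset.presence)
        bg = self.pset.background
        y = np.concatenate([np.ones(len(pres)), np.zeros(len(bg))])

        def g(variables):
            X = np.vstack(
                [self.design.matrix(pres, variables), self.design.matrix(bg, variables)]
            )
            return _gain(_fit_logistic(X, y, C), X, y)

        rows = []
        for var in self.variables:
            alone = g([var])
            without = g([v for v in self.variables if v != var]) if len(self.variables) > 1 else 0.0
            rows.append((var, alone, without))
        return pd.DataFrame(rows, columns=["variable", "gain_alone", "gain_without"]).set_index(
            "variable"
        )


class MaxentResults:
    """Replicate-averaged suitability model results."""

    def __init__(self, model: MaxentModel, reps, C, n_dropped):
        self.model = model
        self.replicates = reps
        self.C = C
        self.n_dropped = n_dropped
        self.auc_ = np.array([r["auc"] for r in reps])

    @property
    def mean_test_auc(self) -> float:
        return float(self.auc_.mean())

    @property
    def auc_bands(self):
        return [auc_band(a) for a in self.auc_]

    def _contrib_table(self, key) -> pd.Series:
        rows = []
        for r in self.replicates:
            if key not in r:
                continue
            vals = pd.Series(r[key], dtype=float)
            total = vals.sum()
            rows.append(vals / total * 100.0 if total > 0 else vals * 0.0)
        if not rows:
            return pd.Series(0.0, index=list(self.model.variables))
        return pd.concat(rows, axis=1).mean(axis=1).reindex(list(self.model.variables))

    @property
    def percent_contribution(self) -> pd.Series:
        """Training-gain share per variable along the fit path, mean %, sums to 100."""
        return self._contrib_table("path_gain")

    @property
    def permutation_contribution(self) -> pd.Series:
        """Normalized test-AUC drop per permuted variable, mean %, sums to 100."""
        return self._contrib_table("perm_drop")

    def suitability_surfaces(self, env: xr.Dataset, colony: str, phase: str):
        """Mean and CV logistic-suitability surfaces over the grid."""
        table = predictor_table(env, colony, phase, self.model.variables)
        preds = np.stack([self.model.predict(r["clf"], table) for r in self.replicates])
        mean = preds.mean(axis=0)
        sd = preds.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / mean, 0.0)
        shape = (env["lat"].size, env["lon"].size)
        coords = {"lat": env["lat"].values, "lon": env["lon"].values}
        return (
            xr.DataArray(mean.reshape(shape), coords=coords, dims=("lat", "lon"), name="suitability"),
            xr.DataArray(cv.reshape(shape), coords=coords, dims=("lat", "lon"), name="cv"),
        )

    def jackknife(self, C: float | None = None) -> pd.DataFrame:
        return self.model.jackknife_gains(C if C is not None else self.C)

    def summary(self) -> str:
        pc = self.percent_contribution
        perm = self.permutation_contribution
        lines = [
            "Presence-background habitat model (penalized logistic MaxEnt surrogate)",
            f"  variables: {', '.join(self.model.variables)}",
            f"  replicates: {len(self.replicates)} (dropped {self.n_dropped}); C = {self.C}",
            f"  mean test AUC: {self.mean_test_auc:.3f} ({auc_band(self.mean_test_auc)})",
            "",
            f"  {'variable':8s} {'% contribution':>15s} {'% permutation':>15s}",
        ]
        for var in self.model.variables:
            lines.append(f"  {var:8s} {pc[var]:15.1f} {perm[var]:15.1f}")
        return "\n".join(lines)

    def plot_suitability(self, env, colony, phase, ax=None):
        """Map of the replicate-mean suitability surface."""
        import matplotlib.pyplot as plt

        mean, _ = self.suitability_surfaces(env, colony, phase)
        if ax is None:
            _, ax = plt.subplots()
        mean.plot(ax=ax, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{colony} {phase}: mean suitability")
        return ax
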