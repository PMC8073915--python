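"""Route-choice and daylight-distance models, statsmodels style.

:class:`CrossingModel` is the Bayesian mixed logistic regression of the
cross/detour decision:

    logit P(cross_i) = b0 + b1 * tailwind_s + b2 * ratio_s
                       + b3 * night + u_bird(i),   u_b ~ Normal(0, sigma^2)

with tailwind and the water:land ratio scaled and centred (mean 0,
sample SD 1) before entering the linear predictor.  ``fit()`` runs the
adaptive MCMC of :mod:`nightcross.sampler` and returns a
:class:`CrossingResults` carrying posterior draws, estimates, 95%
credible intervals, split-Rhat/ESS diagnostics and Bayes R^2.

:class:`DaylightTrendModel` is the ordinary least-squares regression of
log-transformed segment distance on the minutes of daylight available
within each nominal 12-h segment, fitted separately for day and night
segments; it asks whether "night" flights that brush dawn or dusk cover
more ground.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .crossing import Departure, scale_center
from .sampler import sample_logistic_mixed

COEF_NAMES = ("Intercept", "Tailwind", "Water:Land", "DayOrNight")


class CrossingModel:
    """Mixed-effects logistic model of the decision to cross a waterbody."""

    def __init__(self, y, tailwind, ratio, night, bird_ids):
        y = np.asarray(y, float)
        if y.size < 2 or len(set(bird_ids)) < 2:
            raise ValueError("model needs >= 2 observations from >= 2 birds")
        if y.min() == y.max():
            raise ValueError("all outcomes identical; nothing to model")
        self.y = y
        self.tailwind_raw = np.asarray(tailwind, float)
        self.ratio_raw = np.asarray(ratio, float)
        self.night = np.asarray(night, float)
        self.birds = sorted(set(bird_ids))
        self.bird_idx = np.array([self.birds.index(b) for b in bird_ids])
        tw_s = scale_center(self.tailwind_raw)
        ratio_s = scale_center(self.ratio_raw)
        self.exog = np.column_stack([np.ones_like(y), tw_s, ratio_s, self.night])
        if not np.all(np.isfinite(self.exog)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite covariate or outcome")

    @classmethod
    def from_departures(cls, departures: list[Departure]) -> "CrossingModel":
        deps = [d for d in departures if d.excluded_reason is None]
        return cls(
            y=[1.0 if d.decision == "cross" else 0.0 for d in deps],
            tailwind=[d.tailwind_ms for d in deps],
            ratio=[d.ratio for d in deps],
            night=[float(d.night) for d in deps],
            bird_ids=[d.bird_id for d in deps],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CrossingModel":
        """Build from a departure table (decision/cross column, tailwind_ms,
        ratio, night, bird_id)."""
        if "cross" in df.columns:
            y = df["cross"].astype(float)
        else:
            y = (df["decision"] == "cross").astype(float)
        return cls(y, df["tailwind_ms"], df["ratio"], df["night"].astype(float), list(df["bird_id"]))

    def fit(
        self,
        chains: int = 4,
        iterations: int = 2000,
        seed: int | None = None,
        flat_priors: bool = False,
    ) -> "CrossingResults":
        if chains < 2:
            raise ValueError("need >= 2 chains for split-Rhat diagnostics")
        draws = sample_logistic_mixed(
            self.y, self.exog, self.bird_idx, len(self.birds),
            chains=chains, iterations=iterations, seed=seed, flat_priors=flat_priors,
        )
        return CrossingResults(self, draws)


class CrossingResults:
    """Posterior summaries of a fitted :class:`CrossingModel`."""

    def __init__(self, model: CrossingModel, draws: dict):
        self.model = model
        self.draws = draws
        post = {name: draws["beta"][:, :, i] for i, name in enumerate(COEF_NAMES)}
        post["sigma_bird"] = draws["sigma"]
        for i, b in enumerate(model.birds):
            post[f"u[{b}]"] = draws["u"][:, :, i]
        self._idata = az.from_dict(posterior=post)
        self._param_names = list(post)

    # -- point estimates and intervals ---------------------------------
    @property
    def params(self) -> pd.Series:
        means = {n: float(self._idata.posterior[n].mean()) for n in self._param_names}
        return pd.Series(means)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        rows = {}
        for n in self._param_names:
            x = self._idata.posterior[n].values.ravel()
            rows[n] = (np.percentile(x, lo), np.percentile(x, hi))
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    @property
    def rhat(self) -> pd.Series:
        r = az.rhat(self._idata)
        return pd.Series({n: float(r[n]) for n in self._param_names})

    def ess(self, method: str = "bulk") -> pd.Series:
        e = az.ess(self._idata, method=method)
        return pd.Series({n: float(e[n]) for n in self._param_names})

    @property
    def converged(self) -> bool:
        return bool((self.rhat < 1.05).all())

    # -- fitted values --------------------------------------------------
    def _eta_draws(self) -> np.ndarray:
        """Linear predictor per posterior draw, (draws, n) incl. bird effects."""
        beta = self.draws["beta"].reshape(-1, self.draws["beta"].shape[-1])
        u = self.draws["u"].reshape(-1, self.draws["u"].shape[-1])
        return beta @ self.model.exog.T + u[:, self.model.bird_idx]

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean crossing probability (population level when new
        covariates are supplied, i.e. random effect at zero)."""
        if exog is None:
            return 1.0 / (1.0 + np.exp(-self._eta_draws())).mean(axis=0)
        beta = self.draws["beta"].reshape(-1, self.draws["beta"].shape[-1])
        eta = beta @ np.asarray(exog, float).T
        return 1.0 / (1.0 + np.exp(-eta)).mean(axis=0)

    def bayes_r2(self) -> tuple[float, tuple[float, float]]:
        """Variance explained, per posterior draw, with 95% interval.

        Per draw s: R2_s = Var_i(pi) / (Var_i(pi) + mean_i(pi (1 - pi)))
        with pi the fitted crossing probabilities of draw s.
        """
        pi = 1.0 / (1.0 + np.exp(-self._eta_draws()))
        var_fit = pi.var(axis=1, ddof=1)
        var_res = (pi * (1.0 - pi)).mean(axis=1)
        r2 = var_fit / (var_fit + var_res)
        return float(r2.mean()), (float(np.percentile(r2, 2.5)), float(np.percentile(r2, 97.5)))

    def summary(self) -> pd.DataFrame:
        """Coefficient table: Estimate, Est.Error, l-95% CI, u-95% CI,
        Rhat, Bulk_ESS, Tail_ESS."""
        ci = self.conf_int()
        rhat, bulk, tail = self.rhat, self.ess("bulk"), self.ess("tail")
        rows = []
        for n in (*COEF_NAMES, "sigma_bird"):
            x = self._idata.posterior[n].values.ravel()
            rows.append(
                {
                    "Covariate": n,
                    "Estimate": float(x.mean()),
                    "Est.Error": float(x.std(ddof=1)),
                    "l-95% CI": ci.loc[n, "lower"],
                    "u-95% CI": ci.loc[n, "upper"],
                    "Rhat": rhat[n],
                    "Bulk_ESS": bulk[n],
                    "Tail_ESS": tail[n],
                }
            )
        return pd.DataFrame(rows).set_index("Covariate")

    def to_frame(self) -> pd.DataFrame:
        """All posterior draws in long (chain, draw) tabular form."""
        frames = []
        for n in self._param_names:
            arr = self._idata.posterior[n].values
            c, d = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij")
            frames.append(
                pd.DataFrame({"parameter": n, "chain": c.ravel(), "draw": d.ravel(), "value": arr.ravel()})
            )
        return pd.concat(frames, ignore_index=True)


def bayes_r2(results: CrossingResults) -> tuple[float, tuple[float, float]]:
    """Module-level convenience wrapper around
    :meth:`CrossingResults.bayes_r2`."""
    return results.bayes_r2()


# ---------------------------------------------------------------------------


@dataclass
class DaylightTrendResults:
    """OLS fit of log distance on daylight minutes for one phase."""

    phase: str
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    n_segments: int
    pvalue: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phase": self.phase,
                    "n_segments": self.n_segments,
                    "slope_per_min": self.slope,
                    "slope_l95": self.slope_ci[0],
                    "slope_u95": self.slope_ci[1],
                    "intercept": self.intercept,
                    "pvalue": self.pvalue,
                }
            ]
        )


class DaylightTrendModel:
    """log(distance_km + 1) ~ daylight_min, per flight phase.

    The +1 km offset keeps zero-distance segments (birds that sat still
    through a scheduled interval) in the regression.
    """

    def __init__(self, daylight_min, distance_km, phase: str):
        self.daylight = np.asarray(list(daylight_min), float)
        self.distance = np.asarray(list(distance_km), float)
        self.phase = phase
        if self.daylight.size < 3:
            raise ValueError("need at least 3 segments")
        if np.ptp(self.daylight) == 0:
            raise ValueError("constant daylight; slope not identifiable")

    @classmethod
    def from_segments(cls, segments, phase: str) -> "DaylightTrendModel":
        segs = [
            s for s in segments
            if s.phase == phase and s.daylight_min is not None and np.isfinite(s.daylight_min)
        ]
        return cls([s.daylight_min for s in segs], [s.distance_km for s in segs], phase)

    def fit(self) -> DaylightTrendResults:
        import statsmodels.api as sm

        X = sm.add_constant(self.daylight)
        res = sm.OLS(np.log(self.distance + 1.0), X).fit()
        lo, hi = res.conf_int(alpha=0.05)[1]
        return DaylightTrendResults(
            phase=self.phase,
            slope=float(res.params[1]),
            slope_ci=(float(lo), float(hi)),
            intercept=float(res.params[0]),
            n_segments=int(res.nobs),
            pvalue=float(res.pvalues[1]),
        )


def fit_crossing_model(departures, chains: int = 4, iterations: int = 2000, seed=None) -> CrossingResults:
    """Functional facade: build and fit the crossing model from departures."""
    return CrossingModel.from_departures(departures).fit(
        chains=chains, iterations=iterations, seed=seed
    )


def fit_daylight_regression(segments, phase: str) -> DaylightTrendResults:
    return DaylightTrendModel.from_segments(segments, phase).fit()
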