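"""The inference battery: five trial-level models as sklearn-style estimators.

All update models regress the PE-aligned update (``dir_update``) on functions
of the absolute prediction error with a per-participant random intercept,
estimated by exact maximum likelihood (:mod:`frogpan._lmm`):

* :class:`ConditionLearningRateModel` — PE x change-mode interaction model;
  its composite learning rates (shared slope + condition interaction) are the
  condition-wise learning rates.
* :class:`QuadraticUpdateModel` — adds a squared-PE term as a nonlinearity
  probe.
* :class:`SegmentedUpdateModel` — broken-line model with an unknown
  breakpoint psi, profiled over a psi grid and polished with a Muggeo-style
  linearization step; profile-likelihood or participant-bootstrap CI for psi.
* :class:`ThresholdLogisticModel` — logistic regression of 1[|PE| > threshold]
  on change mode (quasi-separation detected and flagged).
* :class:`ReactionTimeModel` — mixed model of included RTs on change mode.

Estimators accept the analysis table (see :mod:`frogpan.metrics`) or a raw
cohort table, expose fitted ``*_`` attributes, and compose with sklearn's
``get_params``/``set_params``/``clone``.  Non-updating trials (update exactly
zero) are excluded from update-model fits by default; they form a separate
behavioral mode whose inclusion would attenuate every coefficient.

Wald tests use a normal reference; p-values are reported as descriptive
diagnostics only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from ._lmm import RandomInterceptLM
from .metrics import DUMMY_COLUMNS, build_analysis_table
from .task_design import BASELINE_LABEL, LABELS

__all__ = [
    "FitError",
    "SeparationError",
    "ConditionLearningRateModel",
    "QuadraticUpdateModel",
    "SegmentedUpdateModel",
    "ThresholdLogisticModel",
    "ReactionTimeModel",
    "fit_condition_lr_model",
    "fit_quadratic_model",
    "fit_segmented_model",
    "fit_threshold_logistic",
    "fit_rt_model",
]

_NONBASE = [lbl for lbl in LABELS if lbl != BASELINE_LABEL]


class FitError(RuntimeError):
    """Model could not be fit on the supplied table."""


class SeparationError(FitError):
    """Logistic outcome is constant (complete separation)."""


def _as_analysis(
    table: pd.DataFrame,
    cols: tuple[str, ...] = ("dir_update", "abs_pe", "is_nonupdating"),
) -> pd.DataFrame:
    """Pass tables that already carry the needed derived columns through
    untouched; otherwise derive the full analysis table."""
    if all(c in table.columns for c in cols):
        return table
    return build_analysis_table(table)


def _check_levels(table: pd.DataFrame) -> None:
    present = set(table["condition"].astype(str).unique())
    for lbl in LABELS:
        if lbl not in present:
            raise FitError(f"missing condition level {lbl!r} in table")


def _check_participants(table: pd.DataFrame, minimum: int = 2) -> None:
    if table["participant_id"].nunique() < minimum:
        raise FitError(f"need at least {minimum} participants")


class _MixedModelMixin:
    """Shared LMM plumbing for the update and RT models."""

    def _run_lmm(self, X, y, groups, names):
        lmm = RandomInterceptLM(tol=self.tol, max_iter=self.max_iter)
        res = lmm.fit(X, y, groups, exog_names=names)
        self.result_ = res
        self.coef_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.bse_robust_ = pd.Series(res.bse_robust, index=names)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_robust_ = self.coef_ / self.bse_robust_
        self.zvalues_ = pd.Series(res.zvalues, index=names)
        self.pvalues_ = pd.Series(res.pvalues, index=names)
        self.cov_ = pd.DataFrame(res.cov_params, index=names, columns=names)
        self.loglik_ = res.loglik
        self.resid_var_ = res.sigma2_resid
        self.random_intercept_var_ = res.sigma2_group
        self.converged_ = res.converged
        self.degenerate_ = res.degenerate
        self.n_obs_ = res.nobs
        self.n_participants_ = res.ngroups
        return res

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.bse_,
                "z": self.zvalues_,
                "p": self.pvalues_,
            }
        )

    def to_dict(self) -> dict:
        out = {
            "coefficients": self.coef_.to_dict(),
            "se": self.bse_.to_dict(),
            "z": self.zvalues_.to_dict(),
            "p": self.pvalues_.to_dict(),
            "loglik": float(self.loglik_),
            "resid_var": float(self.resid_var_),
            "random_intercept_var": float(self.random_intercept_var_),
            "n_obs": int(self.n_obs_),
            "n_participants": int(self.n_participants_),
            "converged": bool(self.converged_),
        }
        return out


class _UpdateModelBase(_MixedModelMixin, BaseEstimator):
    """Common row selection for models of the update."""

    def _rows(self, table: pd.DataFrame) -> pd.DataFrame:
        table = _as_analysis(table)
        sub = table[table["update"].notna()]
        if self.drop_nonupdating:
            sub = sub[~sub["is_nonupdating"]]
        if len(sub) == 0:
            raise FitError("no usable update rows in table")
        return sub


class ConditionLearningRateModel(_UpdateModelBase):
    """Mixed model: update ~ |PE| x change mode, random participant intercept.

    The composite learning rate of a condition is the shared |PE| slope plus
    that condition's interaction; the baseline composite is the slope itself.

    Fitted attributes include ``coef_``/``bse_`` (indexed by term name),
    ``composite_lr_`` (condition -> (estimate, se)) and
    ``random_intercept_var_``.
    """

    def __init__(self, drop_nonupdating: bool = True, response: str = "dir_update",
                 tol: float = 1e-10, max_iter: int = 200):
        self.drop_nonupdating = drop_nonupdating
        self.response = response
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, sub: pd.DataFrame):
        x = sub["abs_pe"].to_numpy(dtype=float)
        cols = [np.ones(len(sub)), x]
        names = ["intercept", "abs_pe"]
        for lbl in _NONBASE:
            d = sub[f"d_{lbl}"].to_numpy(dtype=float)
            cols.append(d)
            names.append(lbl)
        for lbl in _NONBASE:
            d = sub[f"d_{lbl}"].to_numpy(dtype=float)
            cols.append(x * d)
            names.append(f"abs_pe:{lbl}")
        return np.column_stack(cols), names

    def fit(self, table: pd.DataFrame, y=None):
        sub = self._rows(table)
        _check_participants(sub)
        _check_levels(sub)
        X, names = self._design(sub)
        self._run_lmm(X, sub[self.response].to_numpy(dtype=float),
                      sub["participant_id"].to_numpy(), names)
        comp: dict[str, tuple[float, float]] = {}
        v = self.cov_
        base_lr = self.coef_["abs_pe"]
        comp[BASELINE_LABEL] = (float(base_lr), float(self.bse_["abs_pe"]))
        for lbl in _NONBASE:
            term = f"abs_pe:{lbl}"
            est = float(base_lr + self.coef_[term])
            var = (
                v.loc["abs_pe", "abs_pe"]
                + v.loc[term, term]
                + 2.0 * v.loc["abs_pe", term]
            )
            comp[lbl] = (est, float(np.sqrt(max(var, 0.0))))
        self.composite_lr_ = comp
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        sub = _as_analysis(table, ("abs_pe", *DUMMY_COLUMNS))
        X, _ = self._design(sub)
        return X @ self.coef_.to_numpy()

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["composite_lr"] = {k: {"estimate": e, "se": s} for k, (e, s) in self.composite_lr_.items()}
        return out


class QuadraticUpdateModel(_UpdateModelBase):
    """Mixed model: update ~ |PE| + |PE|^2, random participant intercept.

    The squared term's sign and Wald test act as the nonlinearity detector:
    zero-centred under a purely linear rule, positive under a segmented one.
    """

    def __init__(self, drop_nonupdating: bool = True, response: str = "dir_update",
                 tol: float = 1e-10, max_iter: int = 200):
        self.drop_nonupdating = drop_nonupdating
        self.response = response
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, table: pd.DataFrame, y=None):
        sub = self._rows(table)
        _check_participants(sub)
        x = sub["abs_pe"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), x, x**2])
        names = ["intercept", "abs_pe", "abs_pe_sq"]
        self._run_lmm(X, sub[self.response].to_numpy(dtype=float),
                      sub["participant_id"].to_numpy(), names)
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = _as_analysis(table, ("abs_pe",))["abs_pe"].to_numpy(dtype=float)
        b = self.coef_.to_numpy()
        return b[0] + b[1] * x + b[2] * x**2


class SegmentedUpdateModel(_UpdateModelBase):
    """Broken-line mixed model with unknown breakpoint psi.

    For every candidate psi on a grid the model
    ``update ~ |PE| + max(0, |PE| - psi)`` (random participant intercept) is
    fit by ML; ``psi_`` maximizes the resulting profile likelihood and is then
    polished by iterating Muggeo's linearization (adding the gap covariate
    ``-1[|PE| > psi]`` whose coefficient, scaled by the slope increment,
    is the breakpoint correction).  Ties on a flat profile resolve to the
    smallest psi, with ``flat_profile_`` set.

    ``psi_ci_`` comes from profile-likelihood inversion by default or from a
    participant-level nonparametric bootstrap (``ci_method='bootstrap'``).
    Fitted attributes: ``beta0_``, ``beta1_``, ``delta_``, ``psi_``,
    ``slope_above_``, ``psi_ci_``, ``profile_`` (DataFrame), plus the usual
    coefficient tables for the final fit.
    """

    def __init__(
        self,
        psi_min: float = 1.0,
        psi_max: float = 12.0,
        psi_step: float = 0.05,
        refine: bool = True,
        ci_method: str = "profile",
        ci_level: float = 0.95,
        n_boot: int = 100,
        min_points_above: int = 10,
        drop_nonupdating: bool = True,
        response: str = "dir_update",
        tol: float = 1e-10,
        max_iter: int = 200,
        random_state: int | None = None,
    ):
        self.psi_min = psi_min
        self.psi_max = psi_max
        self.psi_step = psi_step
        self.refine = refine
        self.ci_method = ci_method
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.min_points_above = min_points_above
        self.drop_nonupdating = drop_nonupdating
        self.response = response
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _fit_at(self, x, y, groups, psi, with_gap=False):
        lmm = RandomInterceptLM(tol=self.tol, max_iter=self.max_iter)
        cols = [np.ones(len(x)), x, np.maximum(0.0, x - psi)]
        names = ["intercept", "abs_pe", "abs_pe_above"]
        if with_gap:
            cols.append(-(x > psi).astype(float))
            names.append("gap")
        return lmm.fit(np.column_stack(cols), y, groups, exog_names=names)

    def _profile(self, x, y, groups):
        grid = np.round(
            np.arange(self.psi_min, self.psi_max + self.psi_step / 2, self.psi_step), 10
        )
        lls = np.full(len(grid), -np.inf)
        valid = np.zeros(len(grid), dtype=bool)
        for i, psi in enumerate(grid):
            if np.sum(x > psi) < self.min_points_above:
                continue
            res = self._fit_at(x, y, groups, psi)
            lls[i] = res.loglik
            valid[i] = True
        if not valid.any():
            raise FitError(
                "no candidate breakpoint has enough points above it; "
                "widen the grid or lower min_points_above"
            )
        return grid, lls, valid

    def _refine(self, x, y, groups, psi0):
        """Muggeo linearization with step halving (damped to stop the
        oscillation the undamped update can fall into near the optimum)."""
        psi = psi0
        ll_cur = self._fit_at(x, y, groups, psi).loglik
        for _ in range(50):
            res = self._fit_at(x, y, groups, psi, with_gap=True)
            names = res.exog_names
            delta = res.params[names.index("abs_pe_above")]
            gamma = res.params[names.index("gap")]
            if abs(delta) < 1e-12:
                return psi, False
            step = gamma / delta
            moved = False
            for _half in range(12):
                cand = float(np.clip(psi + step, self.psi_min, self.psi_max))
                ll_new = self._fit_at(x, y, groups, cand).loglik
                if ll_new >= ll_cur - 1e-12:
                    accepted = abs(cand - psi)
                    psi, ll_cur, moved = cand, ll_new, True
                    break
                step /= 2.0
            if not moved or accepted < 1e-9:
                return psi, True
        return psi, True

    def _profile_ci(self, grid, lls, valid, ll_max, psi_hat):
        if np.isinf(ll_max):  # saturated zero-noise fit: CI collapses
            pts = grid[valid & np.isinf(lls)]
            if len(pts) == 0:
                return float(psi_hat), float(psi_hat)
            return float(pts.min()), float(pts.max())
        thresh = ll_max - chi2.ppf(self.ci_level, df=1) / 2.0
        g = grid[valid]
        l = lls[valid]
        inside = l >= thresh
        if not inside.any():
            return float("nan"), float("nan")
        lo_i = int(np.argmax(inside))
        hi_i = len(inside) - 1 - int(np.argmax(inside[::-1]))
        lo = g[lo_i]
        hi = g[hi_i]
        # linear interpolation across the threshold crossing
        if lo_i > 0:
            l0, l1 = l[lo_i - 1], l[lo_i]
            lo = g[lo_i - 1] + (thresh - l0) / (l1 - l0) * (g[lo_i] - g[lo_i - 1])
        if hi_i < len(g) - 1:
            l0, l1 = l[hi_i], l[hi_i + 1]
            hi = g[hi_i] + (l0 - thresh) / (l0 - l1) * (g[hi_i + 1] - g[hi_i])
        return float(lo), float(hi)

    def _bootstrap_ci(self, sub):
        rng = np.random.default_rng(self.random_state)
        ids = sub["participant_id"].unique()
        groups = {pid: g for pid, g in sub.groupby("participant_id")}
        psis = []
        coarse = SegmentedUpdateModel(
            psi_min=self.psi_min, psi_max=self.psi_max,
            psi_step=max(self.psi_step, 0.25), refine=True,
            ci_method="none", min_points_above=self.min_points_above,
            drop_nonupdating=False, response=self.response,
        )
        for _ in range(self.n_boot):
            chosen = rng.choice(ids, size=len(ids), replace=True)
            frames = []
            for k, pid in enumerate(chosen):
                g = groups[pid].copy()
                g["participant_id"] = k  # resampled clones are distinct groups
                frames.append(g)
            boot = pd.concat(frames, ignore_index=True)
            try:
                coarse.fit(boot)
                psis.append(coarse.psi_)
            except FitError:
                continue
        if len(psis) < max(10, self.n_boot // 2):
            return float("nan"), float("nan")
        a = (1.0 - self.ci_level) / 2.0
        return tuple(float(q) for q in np.quantile(psis, [a, 1.0 - a]))

    # -- api ----------------------------------------------------------------

    def fit(self, table: pd.DataFrame, y=None):
        sub = self._rows(table)
        _check_participants(sub)
        x = sub["abs_pe"].to_numpy(dtype=float)
        yv = sub[self.response].to_numpy(dtype=float)
        groups = sub["participant_id"].to_numpy()
        if x.min() >= self.psi_max or x.max() <= self.psi_min:
            raise FitError("abs_pe does not span the searched psi range")

        grid, lls, valid = self._profile(x, yv, groups)
        self.profile_ = pd.DataFrame({"psi": grid, "loglik": lls, "valid": valid})
        best = int(np.argmax(np.where(valid, lls, -np.inf)))
        ll_max = lls[best]
        psi_hat = float(grid[best])
        vidx = np.flatnonzero(valid)
        self.boundary_flag_ = best in (vidx[0], vidx[-1])

        finite = lls[valid][np.isfinite(lls[valid])]
        self.flat_profile_ = bool(
            len(finite) > 1 and (finite.max() - finite.min()) < 0.5
        )
        if self.flat_profile_:
            warnings.warn("breakpoint profile is nearly flat; psi is weakly "
                          "identified", RuntimeWarning, stacklevel=2)

        self.refine_converged_ = None
        if self.refine and not self.boundary_flag_ and not self.flat_profile_:
            psi_ref, ok = self._refine(x, yv, groups, psi_hat)
            res_ref = self._fit_at(x, yv, groups, psi_ref)
            if res_ref.loglik >= ll_max - 1e-9:
                psi_hat = psi_ref
                self.refine_converged_ = ok
            else:  # refinement wandered off; keep the grid maximizer
                self.refine_converged_ = False

        self.psi_ = psi_hat
        res = self._fit_at(x, yv, groups, psi_hat)
        self._run_lmm(
            np.column_stack([np.ones(len(x)), x, np.maximum(0.0, x - psi_hat)]),
            yv, groups, ["intercept", "abs_pe", "abs_pe_above"],
        )
        self.beta0_ = float(self.coef_["intercept"])
        self.beta1_ = float(self.coef_["abs_pe"])
        self.delta_ = float(self.coef_["abs_pe_above"])
        self.slope_above_ = self.beta1_ + self.delta_

        if self.ci_method == "profile":
            self.psi_ci_ = self._profile_ci(
                grid, lls, valid, max(ll_max, res.loglik), psi_hat
            )
        elif self.ci_method == "bootstrap":
            self.psi_ci_ = self._bootstrap_ci(sub)
        else:
            self.psi_ci_ = (float("nan"), float("nan"))
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = _as_analysis(table, ("abs_pe",))["abs_pe"].to_numpy(dtype=float)
        return self.beta0_ + self.beta1_ * x + self.delta_ * np.maximum(0.0, x - self.psi_)

    def to_dict(self) -> dict:
        out = super().to_dict()
        out.update(
            psi=float(self.psi_),
            psi_ci=[float(v) for v in self.psi_ci_],
            delta=self.delta_,
            slope_above=self.slope_above_,
            boundary_flag=bool(self.boundary_flag_),
            flat_profile=bool(self.flat_profile_),
        )
        return out


class ThresholdLogisticModel(BaseEstimator):
    """Logistic regression of 1[|PE| > threshold] on change mode.

    Plain (fixed-effects) maximum-likelihood logistic fit; condition cells
    that are empty, all-below or all-above the threshold raise the
    ``separation_flag_`` because the corresponding odds ratio diverges —
    expected for abrupt trials, whose PEs exceed any mid-range threshold
    almost surely.
    """

    def __init__(self, threshold: float = 5.337, max_iter: int = 50):
        self.threshold = threshold
        self.max_iter = max_iter

    def fit(self, table: pd.DataFrame, y=None):
        if self.threshold <= 0:
            raise FitError("threshold must be > 0")
        sub = _as_analysis(table, ("abs_pe", "condition", *DUMMY_COLUMNS))
        sub = sub[sub["abs_pe"].notna()]
        _check_levels(sub)
        outcome = (sub["abs_pe"] > self.threshold).astype(float).to_numpy()
        if outcome.min() == outcome.max():
            raise SeparationError(
                "outcome is constant: every |PE| is on one side of the threshold"
            )
        cells = sub.assign(_y=outcome).groupby("condition", observed=False)["_y"].agg(
            ["size", "mean"]
        )
        self.cell_rates_ = cells["mean"].to_dict()
        self.separation_flag_ = bool(
            ((cells["size"] == 0) | (cells["mean"] == 0.0) | (cells["mean"] == 1.0)).any()
        )

        import statsmodels.api as sm

        X = np.column_stack(
            [np.ones(len(sub))] + [sub[f"d_{l}"].to_numpy(dtype=float) for l in _NONBASE]
        )
        names = ["intercept"] + list(_NONBASE)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(outcome, X, family=sm.families.Binomial()).fit(
                maxiter=self.max_iter
            )
        self.coef_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.zvalues_ = pd.Series(res.tvalues, index=names)
        self.pvalues_ = pd.Series(res.pvalues, index=names)
        self.odds_ratio_ = np.exp(self.coef_)
        self.n_obs_ = int(len(sub))
        self.converged_ = bool(res.converged)
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        sub = _as_analysis(table, ("abs_pe", *DUMMY_COLUMNS))
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[f"d_{l}"].to_numpy(dtype=float) for l in _NONBASE]
        )
        eta = X @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.bse_,
                "z": self.zvalues_,
                "p": self.pvalues_,
                "exp(coef)": self.odds_ratio_,
            }
        )

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "coefficients": self.coef_.to_dict(),
            "se": self.bse_.to_dict(),
            "odds_ratio": self.odds_ratio_.to_dict(),
            "p": self.pvalues_.to_dict(),
            "separation_flag": bool(self.separation_flag_),
            "cell_exceedance": {str(k): float(v) for k, v in self.cell_rates_.items()},
            "n_obs": self.n_obs_,
        }


class ReactionTimeModel(_MixedModelMixin, BaseEstimator):
    """Mixed model: RT ~ change mode, random participant intercept.

    Only rows passing the 3 s exclusion enter the fit; the intercept is the
    baseline (gradual-block fluctuation) mean RT and the abrupt offset is the
    surprise signature.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, table: pd.DataFrame, y=None):
        sub = _as_analysis(table, ("rt", "rt_included", *DUMMY_COLUMNS))
        sub = sub[sub["rt_included"]]
        _check_participants(sub)
        _check_levels(sub)
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[f"d_{l}"].to_numpy(dtype=float) for l in _NONBASE]
        )
        names = ["intercept"] + list(_NONBASE)
        self._run_lmm(X, sub["rt"].to_numpy(dtype=float),
                      sub["participant_id"].to_numpy(), names)
        self.intercept_ = float(self.coef_["intercept"])
        self.offsets_ = {l: float(self.coef_[l]) for l in _NONBASE}
        if self.intercept_ <= 0:
            warnings.warn("non-positive baseline RT", RuntimeWarning, stacklevel=2)
        return self

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["intercept_rt"] = self.intercept_
        out["offsets"] = self.offsets_
        return out


# -- thin functional wrappers ------------------------------------------------


def fit_condition_lr_model(table: pd.DataFrame, **kwargs) -> ConditionLearningRateModel:
    return ConditionLearningRateModel(**kwargs).fit(table)


def fit_quadratic_model(table: pd.DataFrame, **kwargs) -> QuadraticUpdateModel:
    return QuadraticUpdateModel(**kwargs).fit(table)


def fit_segmented_model(table: pd.DataFrame, **kwargs) -> SegmentedUpdateModel:
    return SegmentedUpdateModel(**kwargs).fit(table)


def fit_threshold_logistic(table: pd.DataFrame, threshold: float = 5.337, **kwargs) -> ThresholdLogisticModel:
    return ThresholdLogisticModel(threshold=threshold, **kwargs).fit(table)


def fit_rt_model(table: pd.DataFrame, **kwargs) -> ReactionTimeModel:
    return ReactionTimeModel(**kwargs).fit(table)
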