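"""Mixed-model inference: control analyses, hypothesis tests, moderation,
standardized effects, and the simulation-based sensitivity analysis.

All tests are likelihood-ratio comparisons of nested linear mixed-effects
models.  LRTs use maximum likelihood by default (REML likelihoods are not
comparable across fixed-effect structures); a ``reml_lrt`` compatibility
switch refits with REML for procedures that prescribe it literally.
Confidence intervals use the Wald normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as sp_stats
from statsmodels.regression.mixed_linear_model import MixedLM

from . import config, synth


class StatsError(ValueError):
    pass


class UsageError(StatsError):
    pass


#: Random-effect structures understood by :func:`fit_lmm`, keyed by the
#: conventional formula shorthand.
RANDOM_STRUCTURES = {
    "dyad": "(1|Dyad)",
    "roi": "(1|ROI)",
    "individual": "(1|Individual)",
    "dyad/roi": "(1|Dyad/ROI)",
    "dyad+roi": "(1|Dyad) + (1|ROI)",
}

_RANDOM_COLUMNS = {
    "dyad": ("dyad_id",),
    "roi": ("roi",),
    "individual": ("individual",),
    "dyad/roi": ("dyad_id", "roi"),
    "dyad+roi": ("dyad_id", "roi"),
}

_OPTIMIZERS = ("lbfgs", "bfgs", "powell", "cg")

#: Treatment-coded Time x Group fixed structures (pre / control as reference).
TIME = "C(period, Treatment('pre'))"
GROUP = "C(group, Treatment('control'))"
TIME_GROUP_FULL = f"{TIME} * {GROUP}"
TIME_GROUP_REDUCED = f"{TIME} + {GROUP}"



@dataclass
class ModelSpec:
    """Outcome, fixed-effects formula (patsy RHS) and random structure."""

    outcome: str
    fixed: str  # e.g. TIME_GROUP_FULL or "1"
    random: str  # key of RANDOM_STRUCTURES
    method: str = "ML"  # "ML" | "REML"
    name: str = ""

    def __post_init__(self):
        if self.random not in RANDOM_STRUCTURES:
            raise UsageError(
                f"unknown random structure {self.random!r}; one of "
                f"{sorted(RANDOM_STRUCTURES)}")
        if self.method not in ("ML", "REML"):
            raise UsageError("method must be 'ML' or 'REML'")
        if not self.name:
            self.name = (f"{self.outcome} ~ {self.fixed} + "
                         f"{RANDOM_STRUCTURES[self.random]} [{self.method}]")

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ {self.fixed}"


@dataclass
class LMMFit:
    spec: ModelSpec
    estimates: dict  # name -> {estimate, se, ci_lo, ci_hi}
    varcomps: dict  # name -> variance
    loglik: float
    npar: int
    aic: float
    bic: float
    nobs: int
    converged: bool
    notes: list = field(default_factory=list)
    _result: object = field(default=None, repr=False, compare=False)
    _data: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name, "estimates": self.estimates,
            "varcomps": self.varcomps, "loglik": self.loglik,
            "npar": self.npar, "aic": self.aic, "bic": self.bic,
            "nobs": self.nobs, "converged": self.converged,
            "notes": list(self.notes),
        }


@dataclass
class LRTResult:
    chi_sq: float
    df: int
    p_value: float
    full: str
    reduced: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EffectSummary:
    term: str
    beta_std: float
    ci_lo: float
    ci_hi: float
    marginal_r2: float
    partial_r2: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SensitivityResult:
    effect_grid: list
    power: list
    mde_at_80: float  # minimal detectable effect at power 0.8 (nan if not reached)
    n_replicates: int
    alpha: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise a rank-deficiency error naming the collinear columns."""
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    # A column is implicated if dropping it does not reduce the rank.
    collinear = [name for j, name in enumerate(names)
                 if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank]
    raise StatsError(
        f"fixed-effects design is rank deficient (rank {rank} < "
        f"{design.shape[1]} columns); collinear terms: {collinear}")


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> LMMFit:
    """Fit a linear mixed model; non-convergence is flagged, never hidden."""
    missing = [c for c in (spec.outcome, *_RANDOM_COLUMNS[spec.random])
               if c not in data.columns]
    if missing:
        raise StatsError(f"missing required columns: {missing}")
    data = data.reset_index(drop=True)
    if data[spec.outcome].isna().any():
        data = data.dropna(subset=[spec.outcome]).reset_index(drop=True)
    for col in _RANDOM_COLUMNS[spec.random]:
        if data[col].nunique() < 2:
            raise StatsError(
                f"random factor {col!r} needs >= 2 levels, has "
                f"{data[col].nunique()}")
    kwargs: dict = {}
    if spec.random == "dyad":
        kwargs = dict(groups=data["dyad_id"], re_formula="1")
    elif spec.random == "roi":
        kwargs = dict(groups=data["roi"], re_formula="1")
    elif spec.random == "individual":
        kwargs = dict(groups=data["individual"], re_formula="1")
    elif spec.random == "dyad/roi":
        kwargs = dict(groups=data["dyad_id"], re_formula="1",
                      vc_formula={"roi": "0 + C(roi)"})
    elif spec.random == "dyad+roi":
        kwargs = dict(groups=np.ones(len(data)), re_formula="0",
                      vc_formula={"dyad": "0 + C(dyad_id)",
                                  "roi": "0 + C(roi)"})
    model = MixedLM.from_formula(spec.formula, data, **kwargs)
    _check_rank(model.exog, list(model.exog_names))

    reml = spec.method == "REML"
    result = None
    notes: list[str] = []
    converged = False
    for opt in _OPTIMIZERS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                attempt = model.fit(reml=reml, method=opt, maxiter=200)
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"optimizer {opt} failed: {exc}")
            continue
        if not np.isfinite(attempt.llf):
            notes.append(f"optimizer {opt} returned a non-finite "
                         f"log-likelihood; discarded")
            continue
        result = attempt
        if attempt.converged:
            converged = True
            if opt != _OPTIMIZERS[0]:
                notes.append(f"converged with fallback optimizer {opt}")
            break
        notes.append(f"optimizer {opt} did not converge")
    if result is None:
        raise StatsError(f"all optimizers failed for {spec.name}: {notes}")

    k_fe = model.exog.shape[1]
    n_vc = int(np.size(result.vcomp))
    k_re = int(result.cov_re.shape[0]) if result.cov_re.size else 0
    n_re_par = k_re * (k_re + 1) // 2
    npar = k_fe + n_re_par + n_vc + 1  # + residual variance
    llf = float(result.llf)
    nobs = int(model.nobs)
    z = sp_stats.norm.ppf(0.975)
    estimates = {}
    with warnings.catch_warnings():
        # boundary variance estimates can make Wald SEs undefined (NaN)
        warnings.simplefilter("ignore", RuntimeWarning)
        bse_fe = result.bse_fe
    for name in model.exog_names:
        est = float(result.fe_params[name])
        se = float(bse_fe[name])
        estimates[name] = {"estimate": est, "se": se,
                           "ci_lo": est - z * se, "ci_hi": est + z * se}
    varcomps = {}
    if k_re:
        varcomps["group_intercept"] = float(result.cov_re.values[0, 0])
    for name, val in zip(model.exog_vc.names if n_vc else [], result.vcomp):
        varcomps[name] = float(val)
    varcomps["residual"] = float(result.scale)
    return LMMFit(spec=spec, estimates=estimates, varcomps=varcomps,
                  loglik=llf, npar=npar, aic=2 * npar - 2 * llf,
                  bic=npar * np.log(nobs) - 2 * llf, nobs=nobs,
                  converged=converged, notes=notes,
                  _result=result, _data=data)


def lrt_compare(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same data and method."""
    if full.spec.outcome != reduced.spec.outcome:
        raise UsageError("models compare different outcomes")
    if full.spec.method != reduced.spec.method:
        raise UsageError("models use different estimation methods")
    if full.nobs != reduced.nobs:
        raise UsageError("models were fitted on different data")
    full_cols = set(full.estimates)
    red_cols = set(reduced.estimates)
    if not red_cols <= full_cols:
        raise UsageError(
            f"reduced model is not nested in full: extra terms "
            f"{sorted(red_cols - full_cols)}")
    df = full.npar - reduced.npar
    if df == 0:
        if (full.spec.formula != reduced.spec.formula
                or full.spec.random != reduced.spec.random):
            raise UsageError(
                "models have the same parameter count but different "
                "specifications; not a nested pair")
        # identical models: the trivial comparison
        return LRTResult(chi_sq=0.0, df=0, p_value=1.0,
                         full=full.spec.name, reduced=reduced.spec.name)
    if df < 0:
        raise UsageError("full model must have more parameters than reduced")
    chi_sq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(chi_sq=chi_sq, df=df,
                     p_value=float(sp_stats.chi2.sf(chi_sq, df)),
                     full=full.spec.name, reduced=reduced.spec.name)


def _fit_lrt(outcome: str, full_fixed: str, reduced_fixed: str, random: str,
             data: pd.DataFrame, method: str = "ML",
             fallback_random: str | None = None):
    """Fit full/reduced pair with the documented convergence fallback."""
    notes = []
    for rnd in ([random] + ([fallback_random] if fallback_random else [])):
        full = fit_lmm(ModelSpec(outcome, full_fixed, rnd, method), data)
        red = fit_lmm(ModelSpec(outcome, reduced_fixed, rnd, method), data)
        if full.converged and red.converged:
            if rnd != random:
                notes.append(
                    f"random structure {RANDOM_STRUCTURES[random]} did not "
                    f"converge; fell back to {RANDOM_STRUCTURES[rnd]}")
            return full, red, notes
        notes.append(f"non-convergence with {RANDOM_STRUCTURES[rnd]}")
    return full, red, notes  # last attempt, flagged not converged


# ---------------------------------------------------------------------------
# Scripted analyses
# ---------------------------------------------------------------------------

def run_control_analyses(features: pd.DataFrame,
                         behavior: pd.DataFrame | None = None,
                         permuted_features: pd.DataFrame | None = None,
                         difficulty: pd.DataFrame | None = None,
                         reml_lrt: bool = False) -> dict:
    """The three control analyses: induced IBS, manipulation checks,
    behavioral disruption effects.

    The real-vs-permuted comparison uses pre-disruption IBS levels only
    (real rows are filtered; a permuted table containing post-period rows is
    rejected as a usage error).  Behavioral outcomes are tested with
    Time x Group LRTs and the prescribed random intercepts.
    """
    method = "REML" if reml_lrt else "ML"
    report: dict = {"lrts": {}, "models": {}, "notes": []}

    if permuted_features is not None:
        if (permuted_features["period"] != "pre").any():
            raise UsageError(
                "permuted feature table contains post-period rows; the "
                "real-vs-permuted control is defined on the pre-disruption "
                "period only")
        real_pre = features[features["period"] == "pre"]
        both = pd.concat([
            real_pre.assign(dyad_type="real"),
            permuted_features.assign(dyad_type="permuted"),
        ], ignore_index=True)
        if "value" not in both.columns:
            if "level" not in both.columns:
                raise StatsError("feature tables need a 'level' column")
            both = both.rename(columns={"level": "value"})
        full, red, notes = _fit_lrt("value", "C(dyad_type)", "1", "roi",
                                    both, method)
        report["lrts"]["dyad_type"] = lrt_compare(full, red).to_dict()
        report["models"]["dyad_type_full"] = full.to_dict()
        report["models"]["dyad_type_reduced"] = red.to_dict()
        report["notes"] += notes
        report["mean_level_real"] = float(
            both.loc[both.dyad_type == "real", "value"].mean())
        report["mean_level_permuted"] = float(
            both.loc[both.dyad_type == "permuted", "value"].mean())

    def _tg(outcome, random, data):
        miss = [c for c in (outcome, "period", "group") if c not in data.columns]
        if miss:
            raise StatsError(f"missing outcome columns: {miss}")
        full, red, notes = _fit_lrt(outcome, TIME_GROUP_FULL,
                                    TIME_GROUP_REDUCED, random, data,
                                    method)
        report["lrts"][outcome] = lrt_compare(full, red).to_dict()
        report["models"][f"{outcome}_full"] = full.to_dict()
        report["notes"] += notes

    if behavior is not None:
        _tg("mean_error", "dyad", behavior)
        _tg("total_speaking_time", "dyad", behavior)
        valid = behavior
        if "speech_ratio_valid" in behavior.columns:
            valid = behavior[behavior["speech_ratio_valid"]]
        _tg("speech_ratio", "dyad", valid)
    if difficulty is not None:
        _tg("difficulty", "individual", difficulty)
    return report


def run_ibs_hypothesis_tests(features: pd.DataFrame,
                             reml_lrt: bool = False) -> dict:
    """Time x Group LRT for each IBS feature (level, slope, pct_det).

    Full model ``feature ~ Time x Group + (1|Dyad/ROI)`` against the
    no-interaction reduced model; on non-convergence falls back to crossed
    intercepts ``(1|Dyad) + (1|ROI)`` with a logged notice.  Reports the
    standardized interaction coefficient and its partial R-squared.
    """
    if set(features["period"].unique()) < {"pre", "post"}:
        raise UsageError("hypothesis tests need both pre and post periods")
    method = "REML" if reml_lrt else "ML"
    report: dict = {"lrts": {}, "effects": {}, "models": {}, "notes": []}
    for feat in ("level", "slope", "pct_det"):
        if feat not in features.columns:
            raise StatsError(f"missing feature column {feat!r}")
        data = features.dropna(subset=[feat])
        if data[feat].nunique() <= 1:
            report["notes"].append(
                f"{feat}: degenerate (constant) outcome, test skipped")
            report["lrts"][feat] = None
            continue
        full, red, notes = _fit_lrt(feat, TIME_GROUP_FULL,
                                    TIME_GROUP_REDUCED, "dyad/roi", data,
                                    method, fallback_random="dyad+roi")
        report["lrts"][feat] = lrt_compare(full, red).to_dict()
        report["models"][f"{feat}_full"] = full.to_dict()
        report["models"][f"{feat}_reduced"] = red.to_dict()
        report["notes"] += notes
        inter = [n for n in full.estimates if ":" in n]
        if inter:
            report["effects"][feat] = standardized_effects(
                full, term=inter[0], reduced=red).to_dict()
    return report


def run_moderation(features: pd.DataFrame, deltas: pd.DataFrame,
                   reml_lrt: bool = False) -> dict:
    """Moderation by behavioral change: Time x Group x Delta models.

    ``deltas`` has one row per dyad with columns ``dyad_id`` plus one or more
    delta columns (e.g. post-minus-pre total speaking time).  Each delta is
    tested on each IBS feature with crossed random intercepts (the structure
    that converges for three-way models), full factorial expansion against
    the Time x Group reduced model (4-df test).
    """
    if "dyad_id" not in deltas.columns:
        raise StatsError("deltas must contain dyad_id")
    delta_cols = [c for c in deltas.columns if c != "dyad_id"]
    if not delta_cols:
        raise StatsError("no delta columns provided")
    missing = set(features["dyad_id"]) - set(deltas["dyad_id"])
    if missing:
        raise StatsError(f"missing deltas for dyads: {sorted(missing)[:5]}")
    method = "REML" if reml_lrt else "ML"
    merged = features.merge(deltas, on="dyad_id", how="left")
    report: dict = {"lrts": {}, "models": {}, "notes": []}
    for feat in ("level", "slope", "pct_det"):
        if feat not in merged.columns:
            continue
        data = merged.dropna(subset=[feat])
        for delta in delta_cols:
            full, red, notes = _fit_lrt(
                feat, f"{TIME_GROUP_FULL} * {delta}",
                TIME_GROUP_FULL, "dyad+roi", data, method)
            key = f"{feat}~{delta}"
            report["lrts"][key] = lrt_compare(full, red).to_dict()
            report["models"][key] = full.to_dict()
            report["notes"] += notes
    return report


def standardized_effects(fit: LMMFit, term: str,
                         reduced: LMMFit | None = None) -> EffectSummary:
    """Standardized beta with Wald CI, marginal and partial R-squared.

    Betas are standardized by the outcome SD and the design-column SD of the
    term.  Marginal R2 = var(fixed-effects prediction) / (that + all variance
    components + residual); partial R2 for ``term`` = marginal R2(full) -
    marginal R2(reduced), floored at 0.
    """
    if fit._result is None or fit._data is None:
        raise StatsError("fit does not carry its data (refit required)")
    if term not in fit.estimates:
        raise StatsError(f"term {term!r} not in model: {sorted(fit.estimates)}")
    model = fit._result.model
    y = np.asarray(model.endog, dtype=float)
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise StatsError("outcome variance is zero")
    j = list(model.exog_names).index(term)
    sd_x = model.exog[:, j].std(ddof=1)
    scale = sd_x / sd_y
    est = fit.estimates[term]
    beta_std = est["estimate"] * scale
    m_r2 = marginal_r2(fit)
    partial = None
    if reduced is not None:
        partial = max(0.0, m_r2 - marginal_r2(reduced))
    return EffectSummary(term=term, beta_std=beta_std,
                         ci_lo=est["ci_lo"] * scale, ci_hi=est["ci_hi"] * scale,
                         marginal_r2=m_r2, partial_r2=partial)


def marginal_r2(fit: LMMFit) -> float:
    """Fixed-effects variance over total (fixed + random + residual)."""
    if fit._result is None:
        raise StatsError("fit does not carry its fitted model")
    model = fit._result.model
    pred = model.exog @ np.asarray(
        [fit.estimates[n]["estimate"] for n in model.exog_names])
    var_f = float(np.var(pred))
    var_r = sum(v for k, v in fit.varcomps.items() if k != "residual")
    var_e = fit.varcomps["residual"]
    total = var_f + var_r + var_e
    return var_f / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# Sensitivity / power simulation
# ---------------------------------------------------------------------------

def sensitivity_simulation(effect_grid, n_reps: int = 100, alpha: float = 0.05,
                           seed: int = 0, n_dyads: int = 40, n_rois: int = 6,
                           sd_dyad: float = 0.5, sd_roi: float = 0.3,
                           sd_resid: float = 1.0,
                           random: str = "dyad/roi") -> SensitivityResult:
    """Monte-Carlo power of the Time x Group interaction LRT over a grid.

    Each replicate simulates a balanced feature table from the nested
    generative model with the given interaction effect (in residual-SD
    units when sd_resid=1) and runs the scripted full-vs-reduced LRT.
    The minimal detectable effect is interpolated at power 0.8.
    """
    effect_grid = [float(e) for e in effect_grid]
    if not effect_grid:
        raise StatsError("effect grid must be nonempty")
    if n_reps < 50:
        raise StatsError("n_reps must be >= 50 for stable power estimates")
    rng = np.random.default_rng(seed)
    power = []
    for eff in effect_grid:
        hits = 0
        for _ in range(n_reps):
            tab = synth.simulate_feature_table(
                n_dyads=n_dyads, n_rois=n_rois, effect=eff,
                sd_dyad=sd_dyad, sd_roi=sd_roi, sd_resid=sd_resid, rng=rng)
            full, red, _ = _fit_lrt("value", TIME_GROUP_FULL,
                                    TIME_GROUP_REDUCED, random, tab,
                                    "ML", fallback_random="dyad+roi")
            if lrt_compare(full, red).p_value < alpha:
                hits += 1
        power.append(hits / n_reps)
    mde = float("nan")
    order = np.argsort(effect_grid)
    eg = np.asarray(effect_grid)[order]
    pw = np.asarray(power)[order]
    above = np.nonzero(pw >= 0.8)[0]
    if above.size:
        i = above[0]
        if i == 0:
            mde = float(eg[0])
        else:
            e0, e1, p0, p1 = eg[i - 1], eg[i], pw[i - 1], pw[i]
            mde = float(e0 + (0.8 - p0) * (e1 - e0) / max(p1 - p0, 1e-12))
    return SensitivityResult(effect_grid=effect_grid, power=power,
                             mde_at_80=mde, n_replicates=n_reps, alpha=alpha,
                             seed=seed)
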