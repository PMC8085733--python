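"""Analysis tables and mixed-model fitting.

All confirmatory models are linear mixed models with a by-participant random
intercept, fitted by REML.  Fixed effects follow the per-DV covariate lists:
variability and volatility as simple factors, AQ continuous, all
interactions, plus model-specific covariates.  F statistics are Wald tests
per term; denominator degrees of freedom use the residual approximation
(Satterthwaite machinery is not exposed by the fitting backend, which is a
documented substitution).  Post-hocs are Bonferroni-corrected pairwise cell
contrasts; AQ interactions are probed at low (< mean - 1 SD), mid and high
(> mean + 1 SD) trait groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sstats

__all__ = [
    "ModelSpec",
    "confirmatory_model_specs",
    "build_tables",
    "fit_mixed_model",
    "MixedFit",
    "posthoc_contrasts",
    "aq_groups",
    "bonferroni",
]


@dataclass(frozen=True)
class ModelSpec:
    dependent: str
    fixed: tuple[str, ...]
    random_intercept: str = "participant"
    data_grain: str = "trial"  # "trial" | "condition" | "cell"
    random_slope: str | None = None  # sensitivity-variant random slope term

    @property
    def formula(self) -> str:
        return f"{self.dependent} ~ {' + '.join(self.fixed)}"


_BASE = ("variability * volatility * aq",)


def confirmatory_model_specs() -> dict[str, ModelSpec]:
    """One model specification per dependent variable (covariates per the
    per-dependent-variable covariate list)."""
    return {
        "accuracy": ModelSpec("accuracy", _BASE),
        "time_moving": ModelSpec("time_moving", _BASE + ("time_to_onset",)),
        "speed": ModelSpec("speed", _BASE),
        "accel": ModelSpec("accel", _BASE),
        "jerk": ModelSpec("jerk", _BASE),
        "dominant_turns": ModelSpec("dominant_turns", _BASE + ("n_turns",)),
        "n_switches": ModelSpec("n_switches", _BASE),
        "mean_pe": ModelSpec(
            "mean_pe", ("variability * volatility * aq * accuracy",)
        ),
        "condition_slope": ModelSpec(
            "slope", _BASE, data_grain="condition", random_slope="accuracy"
        ),
        "agency_slope": ModelSpec(
            "slope", ("judged_agency * accuracy * aq",), data_grain="cell"
        ),
        "erpe": ModelSpec(
            "bin_pe",
            ("variability * volatility * aq * C(time_bin)", "mean_pe", "n_switches"),
            data_grain="condition",
        ),
    }


def build_tables(
    trial_table: pd.DataFrame,
    pe_long: pd.DataFrame | None = None,
    fps: float = 60.0,
) -> dict[str, pd.DataFrame]:
    """Trial-wise and condition-wise tidy analysis tables.

    ``trial_table`` must hold one row per retained trial with the condition
    labels, AQ, accuracy, judged-agency flag and the behavioural DVs.
    ``pe_long`` (optional) is the per-frame prediction-error table
    {participant, trial, frame, pe_px, variability, volatility, accuracy,
    judged_agency} used to build condition-wise and agency-wise slope tables.
    """
    from .gaze import pe_slope

    required = {
        "participant", "trial", "variability", "volatility", "aq",
        "accuracy", "judged_agency",
    }
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out: dict[str, pd.DataFrame] = {"trial": trial_table.copy()}
    if pe_long is not None:
        cond = pe_slope(pe_long, ["variability", "volatility"], fps=fps)
        agency = pe_slope(pe_long, ["accuracy", "judged_agency"], fps=fps)
        aq_map = trial_table.groupby("participant")["aq"].first()
        for tbl in (cond, agency):
            tbl["aq"] = tbl["participant"].map(aq_map)
        out["condition_slopes"] = cond
        out["agency_slopes"] = agency
    return out


@dataclass
class MixedFit:
    spec: ModelSpec
    result: object  # statsmodels results instance
    effects: pd.DataFrame  # term, F, df_num, df_den, p
    fell_back_to_ols: bool = False
    centering: dict = field(default_factory=dict)  # column -> subtracted mean

    @property
    def params(self) -> pd.Series:
        return self.result.params


def _wald_effects(result, df_den: float) -> pd.DataFrame:
    """Per-term Wald F tests from a fitted model."""
    rows = []
    design_info = result.model.data.design_info
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.slice(name)
        idx = list(range(sl.start or 0, sl.stop))
        k = len(result.params)
        L = np.zeros((len(idx), k))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        wt = result.wald_test(L, use_f=False, scalar=False)
        chi2 = float(np.squeeze(wt.statistic))
        df_num = len(idx)
        F = chi2 / df_num
        p = float(sstats.f.sf(F, df_num, df_den))
        rows.append({"term": name, "F": F, "df_num": df_num, "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


def fit_mixed_model(spec: ModelSpec, table: pd.DataFrame) -> MixedFit:
    """REML linear mixed model with a by-participant random intercept.

    A singular or non-converging fit falls back to OLS without the random
    intercept and is flagged.  The returned effect table reports a Wald F,
    numerator df, residual-approximation denominator df and p per fixed term.
    """
    data = table.dropna(subset=[spec.dependent]).copy()
    if data[spec.random_intercept].nunique() < 2:
        raise ValueError("need at least 2 participants")
    # centre continuous covariates; improves conditioning and
    # makes lower-order terms read as effects at the covariate mean
    joined = " ".join(spec.fixed)
    centering = {}
    for col in data.columns:
        if (
            col != spec.dependent
            and col != spec.random_intercept
            and col in joined
            and pd.api.types.is_float_dtype(data[col])
        ):
            centering[col] = float(data[col].mean())
            data[col] = data[col] - centering[col]
    re_formula = f"~{spec.random_slope}" if spec.random_slope else None
    fell_back = False
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(
                spec.formula, data, groups=data[spec.random_intercept],
                re_formula=re_formula,
            )
            result = md.fit(reml=True)
            if not result.converged or np.any(~np.isfinite(result.bse_fe)):
                result = None
        except (np.linalg.LinAlgError, ValueError):
            result = None
        if result is None:
            result = smf.ols(spec.formula, data).fit()
            fell_back = True
    n = len(data)
    k = len(result.params) if fell_back else len(result.fe_params)
    df_den = max(n - k - (0 if fell_back else data[spec.random_intercept].nunique()), 1)
    effects = _wald_effects(result, df_den)
    return MixedFit(spec=spec, result=result, effects=effects,
                    fell_back_to_ols=fell_back, centering=centering)


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, m * p)."""
    return np.minimum(1.0, np.asarray(p, float) * m)


def aq_groups(aq: np.ndarray) -> tuple[float, float, pd.Categorical]:
    """Split AQ scores at mean +/- 1 SD into low / mid / high groups.

    Returns (low cutpoint, high cutpoint, per-observation group labels).
    """
    aq = np.asarray(aq, float)
    mu, sd = aq.mean(), aq.std()
    lo, hi = mu - sd, mu + sd
    labels = np.where(aq < lo, "low", np.where(aq > hi, "high", "mid"))
    return lo, hi, pd.Categorical(labels, categories=["low", "mid", "high"])


def _cell_estimate(result, data: pd.DataFrame, assign: dict, centering: dict) -> tuple[float, float]:
    """Estimated marginal mean for one cell: average the fixed-effect design
    over the observed rows with the cell's columns overwritten.  ``centering``
    re-applies the covariate shifts used at fit time."""
    from patsy import build_design_matrices

    grid = data.copy()
    for col, off in centering.items():
        grid[col] = grid[col] - off
    for col, val in assign.items():
        grid[col] = val - centering.get(col, 0.0) if isinstance(val, float) else val
    design_info = result.model.data.design_info
    X = np.asarray(build_design_matrices([design_info], grid)[0])
    a = X.mean(axis=0)
    params = np.asarray(result.params)[: X.shape[1]]
    cov = np.asarray(result.cov_params())[: X.shape[1], : X.shape[1]]
    est = float(a @ params)
    se = float(np.sqrt(a @ cov @ a))
    return est, se


def posthoc_contrasts(
    fit: MixedFit,
    data: pd.DataFrame,
    factors: list[str],
    aq_col: str | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise contrasts between factor cells.

    ``factors`` are categorical fixed-effect columns; the contrast grid is
    their observed level combinations.  When ``aq_col`` is given, contrasts
    are additionally probed at the low/mid/high AQ group means (simple
    effects for AQ interactions).  Empty AQ groups are skipped with a
    warning.
    """
    result = fit.result
    levels = [sorted(data[f].unique()) for f in factors]
    grids: list[dict] = [{}]
    for f, lv in zip(factors, levels):
        grids = [{**g, f: v} for g in grids for v in lv]

    aq_points: list[tuple[str, float | None]] = [("all", None)]
    if aq_col is not None:
        lo, hi, labels = aq_groups(data[aq_col].to_numpy())
        aq_points = []
        for g in ("low", "mid", "high"):
            mask = np.asarray(labels == g)
            if not mask.any():
                warnings.warn(f"empty AQ group {g!r}: contrast skipped")
                continue
            aq_points.append((g, float(data[aq_col].to_numpy()[mask].mean())))

    rows = []
    for gname, aq_val in aq_points:
        cells = []
        for g in grids:
            assign = dict(g)
            if aq_val is not None:
                assign[aq_col] = aq_val
            est, se = _cell_estimate(result, data, assign, fit.centering)
            cells.append((g, est, se))
        pairs = list(combinations(range(len(cells)), 2))
        for i, j in pairs:
            gi, ei, si = cells[i]
            gj, ej, sj = cells[j]
            diff = ei - ej
            se = float(np.hypot(si, sj))
            z = diff / se if se > 0 else np.nan
            p = 2 * sstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {
                    "aq_group": gname,
                    "cell_a": "/".join(str(gi[f]) for f in factors),
                    "cell_b": "/".join(str(gj[f]) for f in factors),
                    "estimate": diff,
                    "se": se,
                    "z": z,
                    "p_raw": p,
                    "n_comparisons": len(pairs) * len(aq_points),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(), int(out["n_comparisons"].iloc[0]))
    return out
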