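"""Statistical stage: metric correlations, collinearity screening, and
Gamma log-link mixed models for group-size and female-choice questions.

Two families of questions are answered on a per-display metrics table
joined to court-level female visitation/copulation rates:

* does group size shift display frequency or any recurrence metric?
  (one Gamma GLMM per response, male count as predictor, court as the
  random intercept), and
* do females visit/copulate more at courts whose displays are more
  consistent? (rate responses, standardized display metrics as
  predictors, court random intercept).

Collinear predictors are screened beforehand by iteratively dropping the
largest variance inflation factor above a threshold (default 3.5);
determinism and laminarity are strongly collinear in this kind of data,
so determinism is typically the first to go.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GammaGLMMFit, fit_gamma_glmm_arrays

__all__ = [
    "ModelSpec",
    "ModelResult",
    "VIFReport",
    "spearman_matrix",
    "vif_screen",
    "fit_gamma_glmm",
    "run_group_size_analysis",
    "run_female_choice_analysis",
    "GROUP_SIZE_RESPONSES",
    "FEMALE_CHOICE_PREDICTORS",
]

GROUP_SIZE_RESPONSES = ("frequency", "rr", "det", "lam", "mcentr", "radius")
#: determinism is pre-excluded: it fails the VIF screen against laminarity
FEMALE_CHOICE_PREDICTORS = ("n_males", "frequency", "rr", "lam", "mcentr", "radius")


@dataclass
class ModelSpec:
    """What to fit: response, predictors, grouping factor, scaling."""

    response: str
    predictors: tuple[str, ...] | list[str]
    group: str = "court_id"
    family: str = "gamma"
    link: str = "log"
    standardize_predictors: bool = True


@dataclass
class ModelResult:
    """A fitted model plus the bookkeeping of how the data were prepared."""

    spec: ModelSpec
    fit: GammaGLMMFit
    zero_shift: float | None = None  # value added in place of zero responses
    notes: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return self.fit.table()

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictors": list(self.spec.predictors),
            "standardized": self.spec.standardize_predictors,
            "coefficients": self.table().reset_index(names="term").to_dict(orient="records"),
            "ranef_var": self.fit.ranef_var,
            "ranef_sd": self.fit.ranef_sd,
            "shape": self.fit.shape,
            "loglik": self.fit.loglik,
            "n_obs": self.fit.n_obs,
            "n_groups": self.fit.n_groups,
            "converged": self.fit.converged,
            "singular": self.fit.singular,
            "method": self.fit.method,
            "zero_shift": self.zero_shift,
            "notes": self.notes + self.fit.messages,
        }


def spearman_matrix(
    metrics: pd.DataFrame,
    columns: tuple[str, ...] | list[str] | None = None,
    heatmap_path=None,
) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of the recurrence metrics.

    Constant columns have undefined rank correlation; those pairs are
    returned as NaN and reported in a warning. ``heatmap_path`` writes a
    correlation heatmap PNG.
    """
    df = metrics[list(columns)] if columns is not None else metrics.select_dtypes("number")
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlations undefined (NaN)", stacklevel=2)
    corr = df.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    if heatmap_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(corr), 1.0 + 0.8 * len(corr)))
        im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(corr)), corr.index)
        for i in range(len(corr)):
            for j in range(len(corr)):
                v = corr.values[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=120)
        plt.close(fig)
    return corr


@dataclass
class VIFReport:
    """Outcome of the iterative collinearity screen."""

    retained: list[str]
    dropped: list[str]
    trace: list[dict]  # one entry per round: {'vif': {name: value}, 'dropped': name|None}

    def final_vifs(self) -> dict:
        return self.trace[-1]["vif"]


def _vif_one(X: np.ndarray, k: int) -> float:
    """VIF of column k: 1 / (1 - R^2) regressing it on the others + intercept."""
    n = X.shape[0]
    others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
    target = X[:, k]
    coef, *_ = np.linalg.lstsq(others, target, rcond=None)
    resid = target - others @ coef
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(
    predictors: pd.DataFrame,
    threshold: float = 3.5,
) -> VIFReport:
    """Iteratively drop the predictor with the largest VIF above threshold.

    Perfectly collinear predictors produce infinite VIFs and are dropped
    first. Returns the retained set and the full per-round trace.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("VIF screening needs at least 2 predictors")
    if len(predictors) <= len(cols):
        raise ValueError("need more rows than predictors")
    dropped: list[str] = []
    trace: list[dict] = []
    while True:
        X = predictors[cols].to_numpy(dtype=float)
        vifs = {c: _vif_one(X, i) for i, c in enumerate(cols)}
        worst = max(vifs, key=lambda c: vifs[c])
        if len(cols) > 2 and vifs[worst] > threshold:
            trace.append({"vif": vifs, "dropped": worst})
            dropped.append(worst)
            cols.remove(worst)
            continue
        if vifs[worst] > threshold and len(cols) == 2:
            # a collinear pair: drop one, the survivor has no VIF to check
            trace.append({"vif": vifs, "dropped": worst})
            dropped.append(worst)
            cols.remove(worst)
        else:
            trace.append({"vif": vifs, "dropped": None})
        break
    return VIFReport(retained=cols, dropped=dropped, trace=trace)


def _prepare_response(y: pd.Series) -> tuple[np.ndarray, float | None]:
    """Gamma responses must be positive: zeros become half the smallest
    positive observed value; all-zero (or negative) responses are an error."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"response {y.name!r} contains negative values")
    if np.all(arr == 0):
        raise ValueError(
            f"response {y.name!r} is zero everywhere; a Gamma model needs "
            "positive values and no zero-shift is definable"
        )
    shift = None
    if np.any(arr == 0):
        shift = 0.5 * float(arr[arr > 0].min())
        arr = np.where(arr == 0, shift, arr)
    return arr, shift


def fit_gamma_glmm(data: pd.DataFrame, spec: ModelSpec, chi2: str = "wald") -> ModelResult:
    """Fit one Gamma log-link GLMM described by ``spec`` on ``data``.

    Predictors are optionally standardized (centred, unit SD); zero
    responses are shifted as documented in :func:`_prepare_response`.
    ``chi2="lr"`` replaces the default Wald statistics by
    likelihood-ratio tests (one single-term-deletion refit per
    predictor); the intercept keeps its Wald statistic.
    """
    if chi2 not in ("wald", "lr"):
        raise ValueError("chi2 must be 'wald' or 'lr'")
    missing = [c for c in [spec.response, *spec.predictors, spec.group] if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    y, shift = _prepare_response(data[spec.response])
    notes = []
    if shift is not None:
        notes.append(f"{int((np.asarray(data[spec.response]) == 0).sum())} zero "
                     f"response values shifted to {shift:.4g}")
    X = data[list(spec.predictors)].to_numpy(dtype=float)
    if spec.standardize_predictors:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [p for p, s in zip(spec.predictors, sd) if s == 0]
            raise ValueError(f"cannot standardize constant predictor(s): {bad}")
        X = (X - X.mean(axis=0)) / sd
    design = np.column_stack([np.ones(len(X)), X])
    names = ["intercept", *spec.predictors]
    groups = data[spec.group].to_numpy()
    fit = fit_gamma_glmm_arrays(y, design, groups, names=names)
    if chi2 == "lr" and fit.method == "laplace":
        from scipy import stats as _stats

        for k in range(1, design.shape[1]):
            reduced = fit_gamma_glmm_arrays(
                y, np.delete(design, k, axis=1), groups,
                names=[n for i, n in enumerate(names) if i != k],
            )
            stat = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
            fit.wald_chi2[k] = stat
            fit.pvalues[k] = _stats.chi2.sf(stat, 1)
        notes.append("chi2/p are likelihood-ratio statistics")
    return ModelResult(spec=spec, fit=fit, zero_shift=shift, notes=notes)


def run_group_size_analysis(
    dataset: pd.DataFrame,
    responses: tuple[str, ...] = GROUP_SIZE_RESPONSES,
) -> dict[str, ModelResult]:
    """One Gamma GLMM per display metric with male count as the predictor.

    Male count stays on its natural scale (per-male effect sizes); court
    identity is the random intercept.
    """
    results: dict[str, ModelResult] = {}
    for resp in responses:
        spec = ModelSpec(
            response=resp,
            predictors=("n_males",),
            standardize_predictors=False,
        )
        results[resp] = fit_gamma_glmm(dataset, spec)
    return results


def run_female_choice_analysis(
    dataset: pd.DataFrame,
    predictors: tuple[str, ...] = FEMALE_CHOICE_PREDICTORS,
    aggregate: str = "duplicate",
) -> tuple[ModelResult, ModelResult]:
    """Visitation-rate and copulation-rate models on standardized predictors.

    Rates are court-level while metrics are display-level; the default
    ``duplicate`` mode keeps one row per display with its court's rate
    repeated (the random intercept absorbs the court dependence), while
    ``court_mean`` collapses each court to the mean of its display
    metrics first.
    """
    if aggregate == "duplicate":
        df = dataset
    elif aggregate == "court_mean":
        df = (
            dataset.groupby("court_id", as_index=False)
            .agg({**{p: "mean" for p in predictors}, "visit_rate": "first", "copulation_rate": "first"})
        )
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    visit = fit_gamma_glmm(
        df, ModelSpec(response="visit_rate", predictors=tuple(predictors))
    )
    cop = fit_gamma_glmm(
        df, ModelSpec(response="copulation_rate", predictors=tuple(predictors))
    )
    return visit, cop
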