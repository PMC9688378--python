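"""Inferential layer: BH-FDR, Spearman, mixed models, stepwise selection,
family selection by AIC, and BH-corrected pairwise contrasts.

The modeling conventions mirror common practice in motor-control EEG work:

* tracking error (positive, right-skewed) is modeled with a generalized
  linear mixed model — inverse-Gaussian response and identity link by
  default, with the family/link pair chosen by AIC among candidates;
* MRBD (dB, roughly symmetric) is modeled with Gaussian linear mixed
  models; all models carry exactly one random intercept per participant;
* models start from the full factorial (interactions up to the highest
  order requested) and are reduced by backward stepwise elimination,
  removing at each step the least-supported hierarchy-respecting term via
  likelihood-ratio tests (AIC-based removal available);
* significant effects are interpreted through pairwise contrasts between
  estimated cell means, BH-FDR corrected within each contrast family.

Per-term tests are Wald chi-square (the covariance comes from the ML fit);
the method used is recorded on the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .glmm import GLMMResult, fit_glmm

__all__ = [
    "ModelSpec",
    "FitResult",
    "ContrastSet",
    "SpearmanResult",
    "bh_fdr",
    "spearman",
    "fit_model",
    "select_family",
    "stepwise_backward",
    "pairwise_contrasts",
    "association_model",
    "qq_diagnostic",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification.

    ``terms`` are tuples of variable names; a length-1 tuple is a main
    effect, longer tuples are interactions.  Model hierarchy is enforced:
    every interaction requires all its marginal (lower-order) terms.
    """

    response: str
    terms: tuple[tuple[str, ...], ...]
    groups: str = "participant"
    family: str = "gaussian"
    link: str = "identity"

    def __post_init__(self) -> None:
        seen = set(self.terms)
        if len(seen) != len(self.terms):
            raise ValueError("duplicate terms")
        for term in self.terms:
            if len(term) > 1:
                for r in range(1, len(term)):
                    for sub in itertools.combinations(term, r):
                        if tuple(sub) not in seen:
                            raise ValueError(
                                f"interaction {term} requires marginal term {sub}"
                            )

    @property
    def variables(self) -> tuple[str, ...]:
        out: list[str] = []
        for t in self.terms:
            for v in t:
                if v not in out:
                    out.append(v)
        return tuple(out)

    def removable_terms(self) -> list[tuple[str, ...]]:
        """Terms not marginal to any retained higher-order term."""
        out = []
        for t in self.terms:
            if not any(set(t) < set(u) for u in self.terms):
                out.append(t)
        return out

    def drop(self, term: tuple[str, ...]) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    @staticmethod
    def full_factorial(
        response: str,
        factors: list[str],
        covariates: list[str] | None = None,
        max_order: int | None = None,
        **kwargs,
    ) -> "ModelSpec":
        """All interactions among ``factors`` up to ``max_order`` plus
        additive covariates."""
        max_order = max_order or len(factors)
        terms: list[tuple[str, ...]] = []
        for r in range(1, max_order + 1):
            terms.extend(tuple(c) for c in itertools.combinations(factors, r))
        for cov in covariates or []:
            terms.append((cov,))
        return ModelSpec(response=response, terms=tuple(terms), **kwargs)


def _is_categorical(s: pd.Series) -> bool:
    return (
        s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == bool
    )


def _term_str(term: tuple[str, ...], data: pd.DataFrame) -> str:
    parts = [f"C({v})" if _is_categorical(data[v]) else v for v in term]
    return ":".join(parts)


def build_formula(spec: ModelSpec, data: pd.DataFrame) -> str:
    rhs = " + ".join(_term_str(t, data) for t in spec.terms) or "1"
    return f"{spec.response} ~ {rhs}"


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    term_tests: pd.DataFrame  # term, df, statistic, p
    design_info: object
    data: pd.DataFrame
    backend: str
    test_method: str = "wald-chi2"
    tau: float | None = None
    dispersion: float | None = None

    def fitted_values(self) -> np.ndarray:
        X = patsy.build_design_matrices([self.design_info], self.data)[0]
        eta = np.asarray(X) @ self.params.values
        if self.spec.link == "identity":
            return eta
        if self.spec.link == "log":
            return np.exp(eta)
        return 1.0 / eta

    def residuals(self) -> np.ndarray:
        return self.data[self.spec.response].to_numpy() - self.fitted_values()


def _wald_term_tests(
    params: pd.Series, cov: pd.DataFrame, design_info
) -> pd.DataFrame:
    rows = []
    for term_name, sl in design_info.term_name_slices.items():
        if term_name == "Intercept":
            continue
        idx = list(range(sl.start, sl.stop))
        b = params.values[idx]
        V = cov.values[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
            p = float(sp_stats.chi2.sf(stat, df=len(idx)))
        except np.linalg.LinAlgError:
            stat, p = np.nan, np.nan
        rows.append(
            {"term": term_name, "df": len(idx), "statistic": stat, "p": p}
        )
    return pd.DataFrame(rows, columns=["term", "df", "statistic", "p"])


def fit_model(spec: ModelSpec, data: pd.DataFrame, **_ignored) -> FitResult:
    """Fit a random-intercept mixed model by maximum likelihood.

    Gaussian/identity models use the exact closed-form marginal likelihood
    (equivalent to an ML linear mixed model; cross-checked against
    statsmodels MixedLM and lme4 in the test suite); other family/link
    pairs use adaptive Gauss-Hermite quadrature.  Both come from the same
    likelihood machinery, so AIC values are comparable across families.
    """
    missing = [
        v
        for v in (*spec.variables, spec.response, spec.groups)
        if v not in data.columns
    ]
    if missing:
        raise ValueError(f"data is missing variables: {missing}")
    if spec.family in ("inverse_gaussian", "gamma") and np.any(
        data[spec.response].to_numpy() <= 0
    ):
        raise ValueError(
            f"{spec.family} family requires strictly positive responses"
        )
    formula = build_formula(spec, data)
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    y = y_dm.to_numpy().ravel()
    X = X_dm.to_numpy()
    design_info = X_dm.design_info
    col_names = list(X_dm.columns)
    groups = data[spec.groups].to_numpy()

    return _fit_ghq(spec, data, y, X, groups, design_info, col_names)


def _fit_ghq(
    spec: ModelSpec,
    data: pd.DataFrame,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    design_info,
    col_names: list[str],
) -> FitResult:
    res: GLMMResult = fit_glmm(y, X, groups, family=spec.family, link=spec.link)
    params = pd.Series(res.params, index=col_names)
    cov = pd.DataFrame(res.cov, index=col_names, columns=col_names)
    backend = (
        "closed-form-ml"
        if spec.family == "gaussian" and spec.link == "identity"
        else "agq-glmm"
    )
    return FitResult(
        spec=spec,
        params=params,
        cov=cov,
        loglik=res.loglik,
        aic=res.aic,
        converged=res.converged,
        n_obs=res.n_obs,
        term_tests=_wald_term_tests(params, cov, design_info),
        design_info=design_info,
        data=data,
        backend=backend,
        tau=res.tau,
        dispersion=res.dispersion,
    )


# ---------------------------------------------------------------------------
# family selection and stepwise reduction
# ---------------------------------------------------------------------------

DEFAULT_FAMILY_CANDIDATES: tuple[tuple[str, str], ...] = (
    ("inverse_gaussian", "identity"),
    ("gaussian", "identity"),
    ("gamma", "identity"),
    ("inverse_gaussian", "log"),
    ("gamma", "log"),
)


def select_family(
    spec: ModelSpec,
    data: pd.DataFrame,
    candidates: tuple[tuple[str, str], ...] = DEFAULT_FAMILY_CANDIDATES,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Pick the family/link pair with minimal AIC (ties: first declared).

    Every candidate is fitted with the Gauss-Hermite backend so the AICs
    are directly comparable.  Returns the winning spec and the AIC table.
    """
    rows = []
    best: tuple[float, int] | None = None
    for i, (family, link) in enumerate(candidates):
        try:
            fit = fit_model(
                replace(spec, family=family, link=link), data, force_ghq=True
            )
            aic, converged = fit.aic, fit.converged
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            rows.append(
                {"family": family, "link": link, "aic": np.nan,
                 "converged": False, "error": str(exc)}
            )
            continue
        rows.append(
            {"family": family, "link": link, "aic": aic,
             "converged": converged, "error": ""}
        )
        if converged and (best is None or aic < best[0] - 1e-9):
            best = (aic, i)
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no candidate family converged")
    family, link = candidates[best[1]]
    return replace(spec, family=family, link=link), table


def stepwise_backward(
    spec: ModelSpec,
    data: pd.DataFrame,
    criterion: str = "lrt",
    alpha: float = 0.05,
) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Backward stepwise model reduction.

    At each step, every removable term (one not contained in a retained
    higher-order interaction) is dropped in turn; with the default
    likelihood-ratio criterion the term with the largest LRT p-value is
    removed as long as p > alpha, with ``criterion='aic'`` the drop that
    lowers AIC the most is taken.  The full removal trace is returned.
    """
    if criterion not in ("lrt", "aic"):
        raise ValueError("criterion must be 'lrt' or 'aic'")
    current = spec
    fit = fit_model(current, data)
    if not fit.converged:
        raise RuntimeError("initial model did not converge")
    trace: list[dict] = []
    step = 0
    while True:
        removable = current.removable_terms()
        if not removable:
            break
        best_candidate = None  # (sort key, term, reduced fit, record)
        for term in removable:
            reduced = current.drop(term)
            try:
                red_fit = fit_model(reduced, data)
            except Exception:
                continue
            if not red_fit.converged:
                continue
            df = len(fit.params) - len(red_fit.params)
            stat = max(0.0, 2.0 * (fit.loglik - red_fit.loglik))
            p = float(sp_stats.chi2.sf(stat, df=max(df, 1)))
            record = {
                "step": step,
                "term": ":".join(term),
                "df": df,
                "lrt_statistic": stat,
                "p": p,
                "aic_full": fit.aic,
                "aic_reduced": red_fit.aic,
            }
            key = p if criterion == "lrt" else -(fit.aic - red_fit.aic)
            if best_candidate is None or (
                (key > best_candidate[0]) if criterion == "lrt" else (key < best_candidate[0])
            ):
                best_candidate = (key, term, red_fit, record)
        if best_candidate is None:
            break
        key, term, red_fit, record = best_candidate
        remove = (
            record["p"] > alpha
            if criterion == "lrt"
            else record["aic_reduced"] < record["aic_full"]
        )
        record["removed"] = bool(remove)
        trace.append(record)
        if not remove:
            break
        current = current.drop(term)
        fit = red_fit
        step += 1
    trace_df = pd.DataFrame(
        trace,
        columns=[
            "step", "term", "df", "lrt_statistic", "p",
            "aic_full", "aic_reduced", "removed",
        ],
    )
    return current, fit, trace_df


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastSet:
    table: pd.DataFrame  # cell_a, cell_b, estimate, se, z, p, p_adj, reject
    factors: tuple[str, ...]
    adjust: str = "bh"

    def __len__(self) -> int:
        return len(self.table)


def pairwise_contrasts(
    fit: FitResult,
    factors: list[str] | str,
    q: float = 0.05,
) -> ContrastSet:
    """All pairwise contrasts among the cells of ``factors``.

    Cell means are estimated marginal means: design rows are averaged over
    the levels of the model's other categorical variables (equally
    weighted) with numeric covariates held at their mean.  p-values are
    from Wald z tests, BH-FDR adjusted within this contrast family.
    """
    if isinstance(factors, str):
        factors = [factors]
    data = fit.data
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"unknown factor {f!r}")
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    model_vars = fit.spec.variables
    others_cat = [
        v
        for v in model_vars
        if v not in factors and _is_categorical(data[v])
    ]
    numeric = [
        v
        for v in model_vars
        if v not in factors and not _is_categorical(data[v])
    ]
    cell_levels = [sorted(data[f].unique()) for f in factors]
    other_levels = [sorted(data[v].unique()) for v in others_cat]

    cells = list(itertools.product(*cell_levels))
    grid_rows = []
    cell_of_row = []
    for cell in cells:
        for other in itertools.product(*other_levels) if others_cat else [()]:
            row = dict(zip(factors, cell))
            row.update(dict(zip(others_cat, other)))
            for v in numeric:
                row[v] = float(data[v].mean())
            grid_rows.append(row)
            cell_of_row.append(cell)
    grid = pd.DataFrame(grid_rows)
    X = np.asarray(patsy.build_design_matrices([fit.design_info], grid)[0])
    L_cells = {}
    for cell in cells:
        sel = [i for i, c in enumerate(cell_of_row) if c == cell]
        L_cells[cell] = X[sel].mean(axis=0)

    beta = fit.params.values
    V = fit.cov.values
    rows = []
    for a, b in itertools.combinations(cells, 2):
        L = L_cells[a] - L_cells[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        z = est / se if se > 0 else np.nan
        p = float(2 * sp_stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append(
            {
                "cell_a": ", ".join(map(str, a)),
                "cell_b": ", ".join(map(str, b)),
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p"].to_numpy(), q=q)
    table["p_adj"] = p_adj
    table["reject"] = reject
    return ContrastSet(table=table, factors=tuple(factors))


# ---------------------------------------------------------------------------
# elementary procedures
# ---------------------------------------------------------------------------


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject, adjusted p).  Rejects H_(i) for all i <= k where
    k = max{i : p_(i) <= i*q/m}; adjusted p-values are the step-up monotone
    minima, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str


def spearman(x, y, exact_max_n: int = 10) -> SpearmanResult:
    """Spearman rank correlation with midranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 10 and a
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact two-sided permutation p on the rank inner product
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        s_obs = abs(float(rxc @ ryc))
        count = 0
        total = 0
        chunk: list[np.ndarray] = []
        for perm in itertools.permutations(ryc):
            chunk.append(perm)
            if len(chunk) == 100_000:
                s = np.abs(np.asarray(chunk) @ rxc)
                count += int(np.sum(s >= s_obs - 1e-9))
                total += len(chunk)
                chunk = []
        if chunk:
            s = np.abs(np.asarray(chunk) @ rxc)
            count += int(np.sum(s >= s_obs - 1e-9))
            total += len(chunk)
        return SpearmanResult(rho, count / total, n, "exact-permutation")
    res = sp_stats.spearmanr(x, y)
    return SpearmanResult(rho, float(res.pvalue), n, "t-approximation")


# ---------------------------------------------------------------------------
# association model
# ---------------------------------------------------------------------------

MRBD_PREDICTORS = [
    f"mrbd_{region}_{hemi}_{stage}"
    for region in ("frontal", "central", "parietal")
    for hemi in ("left", "right")
    for stage in ("planning", "execution")
]


def mrbd_wide(mrbd_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the MRBD table to one row per participant x condition with the
    12 region x hemisphere x stage dB predictors as columns."""
    t = mrbd_table.copy()
    t["predictor"] = (
        "mrbd_" + t["region"] + "_" + t["hemisphere"] + "_" + t["stage"]
    )
    # electrodes map 1:1 onto region x hemisphere, so the pivot is lossless
    wide = t.pivot_table(
        index=["participant", "group", "condition"],
        columns="predictor",
        values="mrbd_db",
    ).reset_index()
    wide.columns.name = None
    return wide


def association_model(
    mrbd_table: pd.DataFrame,
    behavior: pd.DataFrame,
    include_interactions: bool = True,
    stepwise: bool = True,
    alpha: float = 0.05,
) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Model tracking error from the 12 regional MRBD predictors.

    Tracking error (averaged per participant x condition) is regressed on
    MRBD in the left/right frontal, central and parietal regions during
    planning and execution, plus group and condition, with a participant
    random intercept.  A positive coefficient on an MRBD dB predictor means
    that less desynchronization goes with worse (higher) tracking error.

    Returns (reduced spec, fit, stepwise trace).
    """
    wide = mrbd_wide(mrbd_table)
    missing = [p for p in MRBD_PREDICTORS if p not in wide.columns]
    if missing:
        raise ValueError(f"MRBD table is missing predictors: {missing}")
    beh = (
        behavior.groupby(["participant", "condition"], as_index=False)[
            "tracking_error"
        ].mean()
    )
    joined = wide.merge(beh, on=["participant", "condition"], how="left")
    if joined["tracking_error"].isna().any():
        bad = joined.loc[
            joined["tracking_error"].isna(), ["participant", "condition"]
        ]
        raise ValueError(
            "behavior table lacks rows for these participant x condition "
            f"keys:\n{bad.to_string(index=False)}"
        )
    terms: list[tuple[str, ...]] = [("group",), ("condition",)]
    terms += [(p,) for p in MRBD_PREDICTORS]
    if include_interactions:
        terms += [(p, "group") for p in MRBD_PREDICTORS]
        terms += [(p, "condition") for p in MRBD_PREDICTORS]
    spec = ModelSpec(
        response="tracking_error",
        terms=tuple(terms),
        groups="participant",
        family="gaussian",
        link="identity",
    )
    if stepwise:
        return stepwise_backward(spec, joined, alpha=alpha)
    fit = fit_model(spec, joined)
    return spec, fit, pd.DataFrame()


def qq_diagnostic(fit: FitResult, path: str | None = None):
    """Residual normality check: Shapiro statistic plus an optional Q-Q plot.

    Never gates the pipeline — the numbers are recorded for inspection.
    """
    resid = fit.residuals()
    stat, p = sp_stats.shapiro(resid[:5000])
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        sp_stats.probplot(resid, dist="norm", plot=ax)
        ax.set_title("Residual Q-Q")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return float(stat), float(p)
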