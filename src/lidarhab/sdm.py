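"""Presence-background maximum-entropy habitat modelling.

The model is the Gibbs/exponential density q(x) ∝ exp(λ·f(x)) over the
background sample, fitted by maximizing the regularized log-likelihood of
the presences

    L(λ) = (1/n_pres) Σ_pres λ·f(x)  −  log[(1/n_bg) Σ_bg e^{λ·f(x)}]
           − β Σ_j s_j |λ_j|

where f expands each (standardized) variable into linear and quadratic
features and s_j is the feature's SD over the background (so the L1 penalty
is scale-free).  The fit uses monotone proximal-gradient descent with
Barzilai-Borwein steps and soft-thresholding, which keeps the penalized
objective non-increasing iteration by iteration.

Outputs follow the two standard scalings: the *raw* output e^{λ·f}/Z̄
averages 1 over the training background; the *logistic* output is
p·e^H/(1 + p·e^H) with p the sum-to-one raw distribution over the training
background and H its entropy, so an uninformative model scores 0.5
everywhere.

Model quality is assessed on held-out splits with AUC (rank probability),
COR (point-biserial correlation), TSS (max sensitivity + specificity − 1
over thresholds) and deviance (−2 × mean Bernoulli log-likelihood of the
labels under the logistic output).  Variable importance is the per-run
permutation drop in test AUC, normalized to sum to one; response curves
sweep one variable over its observed range with the others held at their
mean over the combined presence + background table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ConvergenceError

PRESENCE, BACKGROUND = "presence", "background"


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Positions × variables with presence/background labels.

    Standardization constants (mean, SD) are computed over the background
    rows, so presences are expressed relative to landscape availability.
    Rows with any undefined variable and columns without variation are
    dropped at construction.
    """

    data: pd.DataFrame  # variable columns only, complete rows
    labels: np.ndarray  # "presence" / "background"
    mean: pd.Series
    sd: pd.Series
    n_rows_dropped: int = 0
    columns_dropped: list = field(default_factory=list)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "FeatureTable":
        if label_column not in df.columns:
            raise ValueError(f"table lacks a {label_column!r} column")
        labels = df[label_column].to_numpy()
        bad = ~np.isin(labels, [PRESENCE, BACKGROUND])
        if bad.any():
            raise ValueError(f"unknown labels: {sorted(set(labels[bad]))}")
        vars_df = df.drop(columns=[label_column]).astype(float)
        complete = vars_df.notna().all(axis=1).to_numpy()
        vars_df = vars_df.loc[complete]
        labels = labels[complete]
        bg = vars_df.loc[labels == BACKGROUND]
        if (labels == PRESENCE).sum() < 2 or len(bg) < 2:
            raise ValueError("need at least 2 presences and 2 background rows")
        sd = bg.std(ddof=0)
        dead = sd[sd == 0].index.tolist()
        if dead:
            warnings.warn(f"dropping zero-variance columns {dead}", stacklevel=2)
            vars_df = vars_df.drop(columns=dead)
            bg = bg.drop(columns=dead)
            sd = sd.drop(index=dead)
        return cls(
            data=vars_df.reset_index(drop=True),
            labels=labels,
            mean=bg.mean(),
            sd=sd,
            n_rows_dropped=int((~complete).sum()),
            columns_dropped=dead,
        )

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def is_presence(self) -> np.ndarray:
        return self.labels == PRESENCE

    def standardized(self, df: pd.DataFrame | None = None) -> np.ndarray:
        if df is None:
            df = self.data
        return ((df[self.variables] - self.mean[self.variables]) / self.sd[self.variables]).to_numpy()

    def select(self, variables: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[variables].copy(),
            labels=self.labels,
            mean=self.mean[variables],
            sd=self.sd[variables],
            n_rows_dropped=self.n_rows_dropped,
            columns_dropped=self.columns_dropped,
        )

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            mean=self.mean,
            sd=self.sd,
        )


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def spearman_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average ranks for ties)."""
    df = table.data if isinstance(table, FeatureTable) else table
    cols = list(df.columns)
    if len(cols) < 2:
        return pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    rho = stats.spearmanr(df.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def _single_variable_auc(table: FeatureTable, variable: str, beta: float = 1.0) -> float:
    """Training AUC of a one-variable model, used to rank collinear pairs."""
    sub = table.select([variable])
    model = fit_maxent(sub, beta=beta)
    preds = predict(model, sub.data)
    return _auc(preds[sub.is_presence], preds[~sub.is_presence])


def collinearity_filter(
    table: FeatureTable, threshold: float = 0.7, beta: float = 1.0
) -> tuple[list[str], list[dict]]:
    """Stepwise removal of collinear variables (|rho| > threshold).

    At each step the most strongly correlated pair is found and the member
    with the lower single-variable training AUC is removed; the Spearman
    matrix is recomputed and the loop continues until no pair exceeds the
    threshold.  Returns the retained columns and a removal log.
    """
    retained = list(table.variables)
    log: list[dict] = []
    auc_cache: dict[str, float] = {}

    def sv_auc(v: str) -> float:
        if v not in auc_cache:
            auc_cache[v] = _single_variable_auc(table, v, beta=beta)
        return auc_cache[v]

    while len(retained) >= 2:
        rho = spearman_matrix(table.select(retained)).to_numpy()
        np.fill_diagonal(rho, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(rho)), rho.shape)
        if abs(rho[i, j]) <= threshold:
            break
        a, b = retained[i], retained[j]
        drop = a if sv_auc(a) <= sv_auc(b) else b
        log.append(
            {
                "removed": drop,
                "kept": b if drop == a else a,
                "rho": float(rho[i, j]),
                "auc_removed": sv_auc(drop),
                "auc_kept": sv_auc(b if drop == a else a),
            }
        )
        retained.remove(drop)
    return retained, log


# ---------------------------------------------------------------------------
# feature expansion and the Maxent fit
# ---------------------------------------------------------------------------

@dataclass
class FeatureSpec:
    """Expansion of standardized variables into model features."""

    linear: bool = True
    quadratic: bool = True
    hinge: bool = False
    hinge_knots: int = 4

    def expand(self, Z: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
        parts = []
        if self.linear:
            parts.append(Z)
        if self.quadratic:
            parts.append(Z**2)
        if self.hinge and knots is not None:
            for k in range(knots.shape[1]):
                parts.append(np.maximum(Z - knots[:, k][None, :], 0.0))
        return np.hstack(parts)

    def names(self, variables: list[str]) -> list[str]:
        out = []
        if self.linear:
            out += [f"{v}:lin" for v in variables]
        if self.quadratic:
            out += [f"{v}:quad" for v in variables]
        if self.hinge:
            out += [f"{v}:hinge{k}" for k in range(self.hinge_knots) for v in variables]
        return out


@dataclass
class MaxentModel:
    """A fitted maximum-entropy presence-background model."""

    variables: list[str]
    mean: pd.Series
    sd: pd.Series
    spec: FeatureSpec
    hinge_knots: np.ndarray | None
    lam: np.ndarray  # coefficients, one per expanded feature
    log_z_mean: float  # log mean_bg e^{λ·f}; raw output normalizer
    log_z_sum: float  # log sum_bg e^{λ·f}; probability-scale normalizer
    entropy: float  # H of the fitted distribution over training background
    beta: float
    reg_weights: np.ndarray
    n_iter: int
    objective_path: np.ndarray  # penalized objective per iteration (non-increasing)

    def features(self, df: pd.DataFrame) -> np.ndarray:
        Z = ((df[self.variables] - self.mean[self.variables]) / self.sd[self.variables]).to_numpy()
        return self.spec.expand(Z, self.hinge_knots)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.features(df) @ self.lam


def _objective_and_grad(lam, F_pres_mean, F_bg):
    eta_bg = F_bg @ lam
    lse = logsumexp(eta_bg)
    g = lse - np.log(len(F_bg)) - F_pres_mean @ lam
    q = np.exp(eta_bg - lse)
    grad = q @ F_bg - F_pres_mean
    return g, grad


def fit_maxent(
    table: FeatureTable,
    spec: FeatureSpec | None = None,
    beta: float = 1.0,
    seed: int = 0,
    max_iter: int = 5000,
    grad_tol: float = 1e-6,
    obj_tol: float = 1e-9,
    lam_max: float = 30.0,
) -> MaxentModel:
    """Fit λ by monotone proximal-gradient descent on the penalized loss.

    ``beta`` scales the L1 penalty (0 disables it); features are built from
    background-standardized variables and the per-feature penalty weight is
    the feature's background SD.  Deterministic given the data (the seed is
    only used for random initialization, default zero start).  Raises
    :class:`ConvergenceError` carrying the final gradient norm if neither
    the gradient-norm nor the objective-change criterion is met.
    """
    if spec is None:
        spec = FeatureSpec()
    Z = table.standardized()
    knots = None
    if spec.hinge:
        qs = np.linspace(0.05, 0.95, spec.hinge_knots)
        knots = np.quantile(Z, qs, axis=0).T  # (n_vars, n_knots)
    F = spec.expand(Z, knots)
    pres = table.is_presence
    F_pres_mean = F[pres].mean(axis=0)
    F_bg = F[~pres]
    s = F_bg.std(axis=0, ddof=0)
    s = np.where(s > 0, s, 1.0)
    # L1 weight per feature: SD-scaled, decaying with presence sample size as
    # in Maxent's default regularization
    reg = beta * s / np.sqrt(pres.sum())

    lam = np.zeros(F.shape[1])
    g, grad = _objective_and_grad(lam, F_pres_mean, F_bg)
    obj = g + reg @ np.abs(lam)
    path = [obj]
    t = 1.0
    lam_prev, grad_prev = None, None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if lam_prev is not None:
            dl = lam - lam_prev
            dg = grad - grad_prev
            denom = dg @ dg
            if denom > 0:
                t = max(min((dl @ dg) / denom, 1e6), 1e-12)  # BB2 step
        # monotone backtracking on the penalized objective
        for _ in range(60):
            cand = np.sign(lam - t * grad) * np.maximum(np.abs(lam - t * grad) - t * reg, 0.0)
            g_new, grad_new = _objective_and_grad(cand, F_pres_mean, F_bg)
            obj_new = g_new + reg @ np.abs(cand)
            if obj_new <= obj + 1e-15:
                break
            t *= 0.5
        if obj_new > obj + 1e-15:
            break  # no numerically attainable descent: at the optimum
        lam_prev, grad_prev = lam, grad
        lam, grad, g = cand, grad_new, g_new
        if np.abs(lam).max() > lam_max:
            # separable training data: the likelihood is unbounded and the
            # penalty too weak to bound the fit — a genuine failure mode
            raise ConvergenceError(
                "coefficients diverged (training presences separable from "
                "background; increase beta)",
                grad_norm=float(np.linalg.norm(grad)),
            )
        path.append(min(obj_new, obj))
        converged_obj = abs(obj - obj_new) < obj_tol
        obj = min(obj_new, obj)
        # optimality: gradient of smooth part within the subgradient box of the penalty
        kkt = np.where(lam != 0, grad + np.sign(lam) * reg, np.maximum(np.abs(grad) - reg, 0.0))
        if np.linalg.norm(kkt) < grad_tol or converged_obj:
            break
    else:
        raise ConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(grad norm {np.linalg.norm(grad):.3g})",
            grad_norm=float(np.linalg.norm(grad)),
        )

    eta_bg = F_bg @ lam
    log_z_sum = logsumexp(eta_bg)
    log_z_mean = log_z_sum - np.log(len(F_bg))
    p = np.exp(eta_bg - log_z_sum)
    entropy = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    return MaxentModel(
        variables=table.variables,
        mean=table.mean,
        sd=table.sd,
        spec=spec,
        hinge_knots=knots,
        lam=lam,
        log_z_mean=float(log_z_mean),
        log_z_sum=float(log_z_sum),
        entropy=entropy,
        beta=beta,
        reg_weights=reg,
        n_iter=n_iter,
        objective_path=np.asarray(path),
    )


def predict(model: MaxentModel, rows: pd.DataFrame, transform: str = "logistic") -> np.ndarray:
    """Model output for new rows.

    ``raw``: e^{λ·f}/Z̄, mean 1 over the training background.
    ``logistic``: p·e^H/(1+p·e^H) on the sum-to-one scale; 0.5 for a null
    model, monotone in the linear predictor, values in (0, 1).
    """
    eta = model.linear_predictor(rows)
    if transform == "raw":
        return np.exp(eta - model.log_z_mean)
    if transform == "logistic":
        logit = eta - model.log_z_sum + model.entropy
        return 1.0 / (1.0 + np.exp(-logit))
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _auc(scores_pres: np.ndarray, scores_bg: np.ndarray) -> float:
    """P(presence scored above background) + ½ P(tie), via rank statistics."""
    n1, n0 = len(scores_pres), len(scores_bg)
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([scores_pres, scores_bg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _tss(scores_pres: np.ndarray, scores_bg: np.ndarray) -> float:
    """Max over thresholds of sensitivity + specificity − 1.

    Thresholds sweep all unique scores plus midpoints between consecutive
    unique scores (prediction ≥ threshold ⇒ presence), plus one threshold
    above the maximum (nothing classified presence).
    """
    if len(scores_pres) == 0 or len(scores_bg) == 0:
        return float("nan")
    allv = np.unique(np.concatenate([scores_pres, scores_bg]))
    mids = (allv[:-1] + allv[1:]) / 2.0 if len(allv) > 1 else np.empty(0)
    thresholds = np.concatenate([allv, mids, [allv[-1] + 1.0]])
    best = -1.0
    for thr in thresholds:
        sens = np.mean(scores_pres >= thr)
        spec = np.mean(scores_bg < thr)
        best = max(best, sens + spec - 1.0)
    return float(best)


def evaluate(model: MaxentModel, test: FeatureTable) -> dict:
    """AUC, COR, TSS and deviance on a held-out table.

    A test set lacking either class yields NaN for every metric.
    """
    pres = test.is_presence
    if pres.all() or not pres.any():
        return {"auc": np.nan, "cor": np.nan, "tss": np.nan, "deviance": np.nan}
    preds = predict(model, test.data, transform="logistic")
    y = pres.astype(float)
    sp, sb = preds[pres], preds[~pres]
    auc = _auc(sp, sb)
    cor = float(stats.pearsonr(preds, y).statistic) if np.std(preds) > 0 else float("nan")
    tss = _tss(sp, sb)
    p = np.clip(preds, 1e-9, 1 - 1e-9)
    deviance = float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return {"auc": auc, "cor": cor, "tss": tss, "deviance": deviance}


# ---------------------------------------------------------------------------
# bootstrap ensemble, importance, response curves, backward selection
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRun:
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: MaxentModel
    metrics: dict
    auc_drop: dict  # variable -> max(0, AUC_full − AUC_permuted)
    beta_used: float = 1.0


@dataclass
class EnsembleResult:
    table: FeatureTable
    runs: list[EnsembleRun]
    n_failed: int

    def metric_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.metrics for r in self.runs])

    def summary(self) -> pd.DataFrame:
        mf = self.metric_frame()
        return pd.DataFrame({"mean": mf.mean(), "sd": mf.std(ddof=1)})


def _split_stratified(
    rng: np.random.Generator, labels_presence: np.ndarray, train_frac: float, replace: bool
) -> tuple[np.ndarray, np.ndarray]:
    """70/30-style split, stratified per class, without replacement by default."""
    train_parts, test_parts = [], []
    for cls_mask in (labels_presence, ~labels_presence):
        idx = np.nonzero(cls_mask)[0]
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        if replace:
            train = rng.choice(idx, size=n_train, replace=True)
            test = np.setdiff1d(idx, train)
        else:
            perm = rng.permutation(idx)
            train, test = perm[:n_train], perm[n_train:]
        train_parts.append(train)
        test_parts.append(test)
    return np.concatenate(train_parts), np.concatenate(test_parts)


def bootstrap_ensemble(
    table: FeatureTable,
    runs: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    beta: float = 1.0,
    spec: FeatureSpec | None = None,
    replace: bool = False,
    compute_importance: bool = True,
) -> EnsembleResult:
    """Repeated stratified 70/30 fits with held-out evaluation.

    Each run draws ``train_frac`` of the presences and of the background
    without replacement (``replace=True`` switches to classical bootstrap
    resampling), fits the model on the training rows and evaluates on the
    remainder; the run's RNG also supplies the single permutation per
    variable used for the AUC-drop importance.  Fully reproducible from the
    master seed.  Runs whose fit fails are logged and excluded; the
    ensemble is valid while at least 90% succeed.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(runs)
    pres = table.is_presence
    results: list[EnsembleRun] = []
    n_failed = 0
    for r in range(runs):
        rng = np.random.default_rng(child_seeds[r])
        train_idx, test_idx = _split_stratified(rng, pres, train_frac, replace)
        train = table.subset_rows(train_idx)
        test = table.subset_rows(test_idx)
        # a separable training split makes the fit diverge; escalate the
        # penalty for that run until the fit is bounded
        model = None
        beta_used = beta
        for escalation in range(6):
            beta_used = beta * 4**escalation if beta > 0 else float(4**escalation - 1)
            try:
                model = fit_maxent(train, spec=spec, beta=beta_used, seed=int(child_seeds[r]))
                break
            except ConvergenceError:
                continue
        if model is None:
            n_failed += 1
            continue
        m = evaluate(model, test)
        drops: dict = {}
        if compute_importance and np.isfinite(m["auc"]):
            preds_full = predict(model, test.data)
            auc_full = _auc(preds_full[test.is_presence], preds_full[~test.is_presence])
            for v in table.variables:
                shuffled = test.data.copy()
                shuffled[v] = rng.permutation(shuffled[v].to_numpy())
                preds_p = predict(model, shuffled)
                auc_p = _auc(preds_p[test.is_presence], preds_p[~test.is_presence])
                drops[v] = max(0.0, auc_full - auc_p)
        results.append(
            EnsembleRun(
                seed=int(child_seeds[r]),
                train_idx=train_idx,
                test_idx=test_idx,
                model=model,
                metrics=m,
                auc_drop=drops,
                beta_used=beta_used,
            )
        )
    if len(results) < 0.9 * runs:
        raise ConvergenceError(
            f"only {len(results)}/{runs} ensemble runs converged", grad_norm=float("nan")
        )
    return EnsembleResult(table=table, runs=results, n_failed=n_failed)


def variable_importance(ensemble: EnsembleResult) -> pd.DataFrame:
    """Permutation (AUC-drop) importance, normalized per run to sum to 1.

    Returns a frame indexed by variable with columns ``mean`` and ``sd``,
    sorted by decreasing mean importance.
    """
    rows = []
    for run in ensemble.runs:
        if not run.auc_drop:
            continue
        vals = pd.Series(run.auc_drop, dtype=float)
        total = vals.sum()
        rows.append(vals / total if total > 0 else pd.Series(1.0 / len(vals), index=vals.index))
    per_run = pd.DataFrame(rows)
    out = pd.DataFrame({"mean": per_run.mean(), "sd": per_run.std(ddof=1)})
    return out.sort_values("mean", ascending=False)


def response_curve(
    ensemble: EnsembleResult, variable: str, grid_points: int = 100
) -> pd.DataFrame:
    """Predicted occurrence along one variable, others fixed at their mean.

    The grid spans the variable's observed range over the combined
    presence + background table; the band is the 2.5/97.5 percentile of the
    per-run logistic predictions.  Columns: value, mean, lo95, hi95.
    """
    table = ensemble.table
    col = table.data[variable]
    grid = np.linspace(col.min(), col.max(), grid_points)
    base = table.data.mean()
    rows = pd.DataFrame({v: np.full(grid_points, base[v]) for v in table.variables})
    rows[variable] = grid
    preds = np.vstack([predict(run.model, rows) for run in ensemble.runs])
    return pd.DataFrame(
        {
            "value": grid,
            "mean": preds.mean(axis=0),
            "lo95": np.percentile(preds, 2.5, axis=0),
            "hi95": np.percentile(preds, 97.5, axis=0),
        }
    )


def backward_selection(
    table: FeatureTable,
    runs: int = 20,
    train_frac: float = 0.7,
    seed: int = 0,
    beta: float = 1.0,
    tolerance: float = 0.01,
) -> tuple[list[str], list[dict]]:
    """Stepwise removal of the least important variable.

    Starting from the (collinearity-filtered) table, each step runs a small
    ensemble, finds the lowest-importance variable and drops it; the drop is
    kept while the mean test AUC does not fall by more than ``tolerance``.
    Returns the final variable set and the audit trail
    (variable, auc_before, auc_after, kept).
    """
    current = list(table.variables)
    ens = bootstrap_ensemble(table.select(current), runs=runs, train_frac=train_frac, seed=seed, beta=beta)
    auc_current = float(ens.metric_frame()["auc"].mean())
    trail: list[dict] = []
    step = 0
    while len(current) > 1:
        step += 1
        imp = variable_importance(ens)
        weakest = imp.index[-1]
        candidate = [v for v in current if v != weakest]
        ens_new = bootstrap_ensemble(
            table.select(candidate), runs=runs, train_frac=train_frac, seed=seed + step, beta=beta
        )
        auc_new = float(ens_new.metric_frame()["auc"].mean())
        keep_drop = auc_new >= auc_current - tolerance
        trail.append(
            {
                "variable": weakest,
                "auc_before": auc_current,
                "auc_after": auc_new,
                "dropped": bool(keep_drop),
            }
        )
        if not keep_drop:
            break
        current, ens, auc_current = candidate, ens_new, auc_new
    return current, trail
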