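"""Survival association screens: univariate Cox per miRNA with BH
correction, and an L1-penalised (LASSO) Cox over all miRNAs at once.

The univariate fit maximises the Cox partial likelihood by Newton's
method (Breslow tie handling by default, Efron available) to a score
tolerance of 1e-8 and reports the log hazard ratio per unit of the
covariate (log2 expression in the pipeline), its Wald p-value and the
BH-adjusted p-value across miRNAs.

The LASSO fit delegates the coordinate-descent path to scikit-survival's
Coxnet and selects the penalty by K-fold cross-validated partial
likelihood (Verweij & van Houwelingen: the fold's contribution is the
full-data partial log-likelihood minus the training-set one, both
evaluated at the training fit).  The default penalty choice is the
one-standard-error rule — the strongest penalty whose CV curve lies
within one standard error of the optimum — because the CV curve is
typically flat near its top and the plain maximiser then picks up noise
covariates; ``rule="max"`` selects the raw CV maximiser instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _check_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) != len(event):
        raise ValueError("time and event differ in length")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicators must be 0/1")
    return time, event


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Breslow log partial likelihood at coefficient vector `beta`."""
    X = np.atleast_2d(X)
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ np.asarray(beta, dtype=float)
    order = np.argsort(-time, kind="stable")
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # risk set of an event at t includes everyone with time >= t: within
    # tied times take the last cumulative entry of the tie block
    _, inv, counts = np.unique(-t_o, return_inverse=True,
                               return_counts=True)
    block_last = np.cumsum(counts) - 1
    denom = log_cum[block_last[inv]]
    return float(np.sum(e_o * (eta_o - denom)))


def _cox_score_info(x, time, event, beta, ties="breslow"):
    """Score and information of the single-covariate partial likelihood."""
    order = np.argsort(-time, kind="stable")
    x_o, t_o, e_o = x[order], time[order], event[order]
    w = np.exp(beta * x_o)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_o)
    s2 = np.cumsum(w * x_o ** 2)
    _, inv, counts = np.unique(-t_o, return_inverse=True,
                               return_counts=True)
    last = np.cumsum(counts) - 1
    i0, i1, i2 = s0[last[inv]], s1[last[inv]], s2[last[inv]]
    if ties == "breslow":
        mu = i1 / i0
        U = float(np.sum(e_o * (x_o - mu)))
        I = float(np.sum(e_o * (i2 / i0 - mu ** 2)))
        return U, I
    if ties != "efron":
        raise ValueError(f"unknown tie handling {ties!r}")
    # Efron: within a tie block of d events, the j-th event's denominator
    # subtracts j/d of the tied events' own risk terms
    U = I = 0.0
    n_blocks = int(inv.max()) + 1
    starts = np.concatenate(([0], np.cumsum(counts)))
    for b in range(n_blocks):
        blk = slice(starts[b], starts[b + 1])
        ev = e_o[blk].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        S0, S1, S2 = s0[starts[b + 1] - 1], s1[starts[b + 1] - 1], \
            s2[starts[b + 1] - 1]
        wd = w[blk][ev]
        xd = x_o[blk][ev]
        D0, D1, D2 = wd.sum(), (wd * xd).sum(), (wd * xd ** 2).sum()
        for j in range(d):
            f = j / d
            a0, a1, a2 = S0 - f * D0, S1 - f * D1, S2 - f * D2
            mu = a1 / a0
            U += float(xd.sum() / d - mu)
            I += float(a2 / a0 - mu ** 2)
    return U, I


def cox_univariate(x, time, event, ties: str = "breslow",
                   tol: float = 1e-8, max_iter: int = 100
                   ) -> dict[str, float]:
    """Single-covariate Cox proportional hazards fit by Newton iteration.

    Returns coefficient (log hazard ratio per unit x), hazard ratio,
    standard error and two-sided Wald p-value.
    """
    x = np.asarray(x, dtype=float)
    time, event = _check_survival(time, event)
    if event.sum() == 0:
        raise ValueError("no events: Cox model is not identifiable")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: Cox model is not "
                         "identifiable")
    x = x - x.mean()  # centring stabilises the exponentials
    beta = 0.0
    for _ in range(max_iter):
        U, I = _cox_score_info(x, time, event, beta, ties)
        if I <= 0:
            raise RuntimeError("non-positive information in Newton step")
        step = U / I
        beta += np.clip(step, -2.0, 2.0)
        if abs(U) < tol:
            break
    else:
        raise RuntimeError(f"Cox Newton iteration did not converge "
                           f"(|score|={abs(U):.2e})")
    _, I = _cox_score_info(x, time, event, beta, ties)
    se = 1.0 / np.sqrt(I)
    z = beta / se
    return {"coef": float(beta), "hazard_ratio": float(np.exp(beta)),
            "se": float(se), "p_value": float(2 * norm.sf(abs(z)))}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-miRNA screen


@dataclass
class CoxScreenResults:
    """Per-feature univariate Cox estimates with BH adjustment."""

    table: pd.DataFrame
    endpoint: str
    n_events: int

    def summary(self) -> str:
        sig = self.table[self.table["p_adjusted"] < 0.05]
        lines = [
            f"Univariate Cox screen ({self.endpoint}), "
            f"{len(self.table)} features, {self.n_events} events",
            f"  significant after BH (p_adj < 0.05): {len(sig)}",
            "",
            self.table.head(10).to_string(),
        ]
        return "\n".join(lines)


class CoxScreen:
    """Univariate Cox association of each feature with one endpoint.

    data : DataFrame (features x samples) of log2 expression.
    time, event : per-sample survival time and 0/1 event indicator,
        aligned with the columns of `data`.
    """

    def __init__(self, data: pd.DataFrame, time, event,
                 endpoint: str = "os"):
        self.data = data
        self.time, self.event = _check_survival(time, event)
        if len(self.time) != data.shape[1]:
            raise ValueError("survival rows do not match samples")
        self.endpoint = endpoint

    def fit(self, ties: str = "breslow") -> CoxScreenResults:
        rows = {}
        for name, values in self.data.iterrows():
            x = values.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                rows[name] = {"coef": np.nan, "hazard_ratio": np.nan,
                              "se": np.nan, "p_value": np.nan}
                continue
            rows[name] = cox_univariate(x, self.time, self.event, ties)
        table = pd.DataFrame.from_dict(rows, orient="index")
        ok = table["p_value"].notna()
        adj = pd.Series(np.nan, index=table.index)
        adj[ok] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
        table["p_adjusted"] = adj
        table = table.sort_values("p_adjusted")
        table.index.name = self.data.index.name
        return CoxScreenResults(table, self.endpoint,
                                int(self.event.sum()))


# ---------------------------------------------------------------------------
# LASSO Cox


@dataclass
class LassoCoxResults:
    """Cross-validated L1-penalised Cox fit."""

    alphas: np.ndarray
    cv_mean: np.ndarray            # mean CV partial log-likelihood
    cv_se: np.ndarray
    alpha_selected: float
    coef: pd.Series                # coefficients at the selected penalty
    coef_path: pd.DataFrame        # features x alphas

    @property
    def selected(self) -> pd.Series:
        """Nonzero coefficients at the selected penalty (possibly empty)."""
        return self.coef[self.coef != 0.0]

    def summary(self) -> str:
        lines = [
            "LASSO Cox (cross-validated partial likelihood)",
            f"  penalty grid:    {len(self.alphas)} values "
            f"[{self.alphas.min():.4g}, {self.alphas.max():.4g}]",
            f"  selected alpha:  {self.alpha_selected:.4g}",
            f"  selected set:    {len(self.selected)} feature(s)",
        ]
        if len(self.selected):
            lines.append(self.selected.to_string())
        return "\n".join(lines)


class LassoCox:
    """L1-penalised Cox over all features simultaneously (p may exceed n).

    data : DataFrame (features x samples); time/event as in CoxScreen.
    """

    def __init__(self, data: pd.DataFrame, time, event):
        self.data = data
        self.time, self.event = _check_survival(time, event)
        if len(self.time) != data.shape[1]:
            raise ValueError("survival rows do not match samples")
        if self.event.sum() < 2:
            raise ValueError("need at least 2 events for LASSO Cox")

    def fit(self, cv: int = 10, seed: int = 0, rule: str = "1se",
            n_alphas: int = 50, alphas=None,
            max_refolds: int = 20) -> LassoCoxResults:
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        if cv < 2:
            raise ValueError("cv folds must be >= 2")
        X = self.data.to_numpy(dtype=float).T  # samples x features
        y = Surv.from_arrays(self.event.astype(bool), self.time)
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alphas=alphas,
            alpha_min_ratio=0.01, fit_baseline_model=False)
        path.fit(X, y)
        grid = np.asarray(path.alphas_)
        coef_path = path.coef_  # features x alphas

        folds = self._event_safe_folds(cv, seed, max_refolds)
        cvpl = np.zeros((cv, len(grid)))
        for k, test_idx in enumerate(folds):
            train = np.ones(len(self.time), dtype=bool)
            train[test_idx] = False
            est = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=list(grid), alpha_min_ratio=0.01,
                fit_baseline_model=False)
            est.fit(X[train], Surv.from_arrays(
                self.event[train].astype(bool), self.time[train]))
            fitted = np.asarray(est.alphas_)
            for j, a in enumerate(grid):
                jj = int(np.argmin(np.abs(fitted - a)))
                beta = est.coef_[:, jj]
                # Verweij-van Houwelingen fold contribution
                cvpl[k, j] = (
                    breslow_loglik(X, self.time, self.event, beta)
                    - breslow_loglik(X[train], self.time[train],
                                     self.event[train], beta))
        cv_mean = cvpl.mean(axis=0)
        cv_se = cvpl.std(axis=0, ddof=1) / np.sqrt(cv)

        best = int(np.argmax(cv_mean))
        if rule == "1se":
            bound = cv_mean[best] - cv_se[best]
            # largest penalty whose CVPL is within one SE of the best
            candidates = np.nonzero(cv_mean >= bound)[0]
            best = int(candidates[np.argmax(grid[candidates])])
        elif rule != "max":
            raise ValueError(f"unknown selection rule {rule!r}")

        coef = pd.Series(coef_path[:, best], index=self.data.index,
                         name="coef")
        path_df = pd.DataFrame(coef_path, index=self.data.index,
                               columns=[f"{a:.6g}" for a in grid])
        return LassoCoxResults(grid, cv_mean, cv_se, float(grid[best]),
                               coef, path_df)

    def coefficients_at(self, alpha: float) -> pd.Series:
        """Fit at a single fixed penalty (no cross-validation)."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv
        X = self.data.to_numpy(dtype=float).T
        y = Surv.from_arrays(self.event.astype(bool), self.time)
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha],
                                     fit_baseline_model=False)
        est.fit(X, y)
        return pd.Series(est.coef_[:, 0], index=self.data.index,
                         name="coef")

    def _event_safe_folds(self, cv: int, seed: int,
                          max_refolds: int) -> list[np.ndarray]:
        """K-fold splits whose training parts all contain events."""
        n = len(self.time)
        rng = np.random.default_rng(seed)
        for _ in range(max_refolds):
            perm = rng.permutation(n)
            folds = np.array_split(perm, cv)
            ok = all(self.event[np.setdiff1d(perm, f)].sum() >= 2
                     for f in folds)
            if ok:
                return folds
        raise RuntimeError("could not build folds with events in every "
                           "training set; too few events")
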