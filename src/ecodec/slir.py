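"""Sparse linear regression by variational Bayes with automatic relevance
determination (ARD).

Model, per muscle k (fits factorise over muscles):

    y = X w + b + eps,    eps ~ N(0, beta^-1)
    w_i ~ N(0, alpha_i^-1),  alpha_i ~ Gamma(a0, b0),  beta ~ Gamma(c0, d0)

The variational posterior factorises as q(w) q(alpha) q(beta); coordinate
updates of the three factors monotonically increase the variational free
energy (ELBO).  Relevance precisions of columns that do not help the fit
diverge; once alpha_i exceeds ``prune_threshold`` the column is removed from
the active set and its weight is exactly zero.  A pruned column contributes a
constant to the free energy in the diverged limit, so the recorded free-energy
trace is shifted by that constant at prune events to stay comparable (and
monotone) across the whole fit.

All updates use only the sufficient statistics X'X, X'y, y'y and n, so fits on
long recordings never materialise the design matrix.  Fits are deterministic:
there is no randomness anywhere in the algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln

from .errors import ContractError, DataError, ParameterError
from .features import DesignMatrix
from .session_io import ArdHyper

_CHUNK = 8192  # rows per accumulation block; fixed so identical row sets
               # produce bit-identical sufficient statistics on every path

_LN2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class SuffStats:
    """First and second moments of (X, Y) needed by the VB updates."""

    G: np.ndarray      # X'X  [p x p]
    XtY: np.ndarray    # X'Y  [p x K]
    sx: np.ndarray     # column sums of X [p]
    sy: np.ndarray     # column sums of Y [K]
    yty: np.ndarray    # diag(Y'Y) [K]
    n: int

    def centered(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        xbar = self.sx / self.n
        ybar = self.sy / self.n
        Gc = self.G - self.n * np.outer(xbar, xbar)
        XtYc = self.XtY - self.n * np.outer(xbar, ybar)
        ytyc = self.yty - self.n * ybar * ybar
        return Gc, XtYc, ytyc, xbar, ybar


def accumulate_stats(X, Y: np.ndarray, rows: np.ndarray | None = None) -> SuffStats:
    """Accumulate sufficient statistics over the given rows in fixed chunks.

    ``X`` may be a :class:`DesignMatrix` (rows materialised lazily) or a dense
    array.  ``Y`` is [n_rows_total x K] aligned with X's rows when ``rows`` is
    None, or [len(rows) x K] when explicit rows are given for a dense ``X``.
    """
    lazy = isinstance(X, DesignMatrix)
    if rows is None:
        rows = np.arange(X.n_rows if lazy else X.shape[0])
    else:
        rows = np.asarray(rows)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    p = X.n_cols if lazy else X.shape[1]
    K = Y.shape[1]
    G = np.zeros((p, p))
    XtY = np.zeros((p, K))
    sx = np.zeros(p)
    sy = np.zeros(K)
    yty = np.zeros(K)
    for start in range(0, rows.size, _CHUNK):
        sel = rows[start:start + _CHUNK]
        B = X.rows(sel) if lazy else np.asarray(X[sel], dtype=float)
        Yb = Y[sel]
        G += B.T @ B
        XtY += B.T @ Yb
        sx += B.sum(axis=0)
        sy += Yb.sum(axis=0)
        yty += (Yb * Yb).sum(axis=0)
    return SuffStats(G=G, XtY=XtY, sx=sx, sy=sy, yty=yty, n=int(rows.size))


# ---------------------------------------------------------------------------
# VB-ARD core (single target)
# ---------------------------------------------------------------------------

def _vb_ard(Gc: np.ndarray, xty: np.ndarray, yty: float, n: int, hyper: ArdHyper
            ) -> dict:
    """Run the VB coordinate updates for one target; returns the fitted state."""
    a0, b0 = hyper.alpha_prior
    c0, d0 = hyper.beta_prior
    p = Gc.shape[0]
    fixed = hyper.fixed_alpha is not None

    active = np.arange(p)
    alpha = np.full(p, hyper.fixed_alpha if fixed else 1.0, dtype=float)
    g = np.ascontiguousarray(Gc)
    t = xty.copy()
    var_y = max(yty / max(n, 1), np.finfo(float).tiny)
    c_q, d_q = c0 + 0.5 * n, d0 + 0.5 * yty  # beta posterior, initialised crudely
    beta = (c0 + 0.5 * n) / (d0 + 0.5 * n * var_y)
    mu = np.zeros(0)
    Sigma = np.zeros((0, 0))
    logdet_Sigma = 0.0
    offset = 0.0
    fe_trace: list[float] = []
    converged = False

    a_q = a0 + 0.5
    b_q = np.full(p, b0 + 0.5, dtype=float)

    def elbo(mu, Sigma, logdet_Sigma, b_q, alpha, g, t, e_resid, c_q, d_q):
        pa = mu.size
        e_lnbeta = digamma(c_q) - np.log(d_q)
        e_beta = c_q / d_q
        f = 0.5 * n * (e_lnbeta - _LN2PI) - 0.5 * e_beta * e_resid
        m2 = mu * mu + np.diag(Sigma) if pa else np.zeros(0)
        if fixed:
            e_lnalpha = np.log(alpha)
            e_alpha = alpha
            f += 0.5 * np.sum(e_lnalpha) - 0.5 * np.sum(e_alpha * m2) - 0.5 * pa * _LN2PI
        else:
            e_lnalpha = digamma(a_q) - np.log(b_q)
            e_alpha = a_q / b_q
            f += 0.5 * np.sum(e_lnalpha) - 0.5 * np.sum(e_alpha * m2) - 0.5 * pa * _LN2PI
            f += np.sum(a0 * np.log(b0) - gammaln(a0)
                        + (a0 - 1.0) * e_lnalpha - b0 * e_alpha)
            f += np.sum(gammaln(a_q) - (a_q - 1.0) * digamma(a_q) - np.log(b_q) + a_q)
        f += c0 * np.log(d0) - gammaln(c0) + (c0 - 1.0) * e_lnbeta - d0 * e_beta
        f += gammaln(c_q) - (c_q - 1.0) * digamma(c_q) - np.log(d_q) + c_q
        f += 0.5 * logdet_Sigma + 0.5 * pa * (1.0 + _LN2PI)
        return float(f)

    def residual_moment(mu, Sigma, g, t):
        if mu.size == 0:
            return float(yty)
        gmu = g @ mu
        return float(yty - 2.0 * mu @ t + mu @ gmu + np.sum(g * Sigma))

    prev_f = -np.inf
    it = 0
    for it in range(1, hyper.max_iter + 1):
        pa = active.size
        if pa:
            A = beta * g + np.diag(alpha[active])
            L = cho_factor(A, lower=True, check_finite=False)
            Sigma = cho_solve(L, np.eye(pa), check_finite=False)
            logdet_Sigma = -2.0 * np.sum(np.log(np.diag(L[0])))
            mu = beta * (Sigma @ t)
            m2 = mu * mu + np.diag(Sigma)
        else:
            Sigma = np.zeros((0, 0))
            mu = np.zeros(0)
            logdet_Sigma = 0.0
            m2 = np.zeros(0)

        if not fixed and pa:
            b_q_act = b0 + 0.5 * m2
            alpha_act = a_q / b_q_act
            b_q[active] = b_q_act
            alpha[active] = alpha_act
            dead = alpha_act > hyper.prune_threshold
            if dead.any():
                e_resid = residual_moment(mu, Sigma, g, t)
                f_before = elbo(mu, Sigma, logdet_Sigma, b_q[active], alpha[active],
                                g, t, e_resid, c_q, d_q)
                keep = ~dead
                active = active[keep]
                mu = mu[keep]
                Sigma = np.ascontiguousarray(Sigma[np.ix_(keep, keep)])
                g = np.ascontiguousarray(Gc[np.ix_(active, active)])
                t = xty[active].copy()
                if mu.size:
                    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
                else:
                    logdet_Sigma = 0.0
                e_resid = residual_moment(mu, Sigma, g, t)
                f_after = elbo(mu, Sigma, logdet_Sigma, b_q[active], alpha[active],
                               g, t, e_resid, c_q, d_q)
                offset += f_before - f_after

        e_resid = residual_moment(mu, Sigma, g, t)
        c_q = c0 + 0.5 * n
        d_q = d0 + 0.5 * max(e_resid, np.finfo(float).tiny)
        beta = c_q / d_q

        f = elbo(mu, Sigma, logdet_Sigma,
                 b_q[active] if active.size else np.zeros(0),
                 alpha[active] if active.size else np.zeros(0),
                 g, t, e_resid, c_q, d_q) + offset
        fe_trace.append(f)
        if np.isfinite(prev_f) and abs(f - prev_f) < hyper.tol * max(1.0, abs(f)):
            converged = True
            break
        prev_f = f

    # final refresh of q(w) with the converged noise precision, so reported
    # weights satisfy mu = beta (beta G + diag(alpha))^-1 X'y exactly
    if active.size:
        A = beta * g + np.diag(alpha[active])
        L = cho_factor(A, lower=True, check_finite=False)
        Sigma = cho_solve(L, np.eye(active.size), check_finite=False)
        mu = beta * (Sigma @ t)

    w = np.zeros(p)
    w[active] = mu
    mask = np.zeros(p, dtype=bool)
    mask[active] = True
    return {
        "w": w,
        "alpha": alpha,
        "beta": float(beta),
        "active": mask,
        "free_energy": np.array(fe_trace),
        "iterations": it,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# model container and public API
# ---------------------------------------------------------------------------

@dataclass
class SlirModel:
    """Fitted sparse decoder: weights [muscles x sources x lags] plus biases."""

    weights: np.ndarray          # [K x M x N]
    bias: np.ndarray             # [K]
    ard_alpha: np.ndarray        # [K x M*N]
    noise_precision: np.ndarray  # [K]
    active_mask: np.ndarray      # [K x M*N], False -> weight exactly 0
    fit_info: list[dict]
    manifest: dict
    muscle_names: list[str]
    train_span: tuple[str, float, float] | None = None  # (session id, t0, t1)
    hyper: ArdHyper = field(default_factory=ArdHyper)

    @property
    def n_muscles(self) -> int:
        return self.weights.shape[0]

    @property
    def coef(self) -> np.ndarray:
        """Weights flattened to the design-column layout [K x M*N]."""
        k, m, nl = self.weights.shape
        return self.weights.reshape(k, m * nl)

    def save(self, path: str | Path) -> None:
        d = {
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "ard_alpha": self.ard_alpha.tolist(),
            "noise_precision": self.noise_precision.tolist(),
            "active_mask": self.active_mask.astype(int).tolist(),
            "fit_info": [
                {**fi, "free_energy": np.asarray(fi["free_energy"]).tolist()}
                for fi in self.fit_info
            ],
            "manifest": self.manifest,
            "muscle_names": self.muscle_names,
            "train_span": list(self.train_span) if self.train_span else None,
            "hyper": {
                "max_iter": self.hyper.max_iter,
                "tol": self.hyper.tol,
                "prune_threshold": self.hyper.prune_threshold,
                "alpha_prior": list(self.hyper.alpha_prior),
                "beta_prior": list(self.hyper.beta_prior),
                "fixed_alpha": self.hyper.fixed_alpha,
            },
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "SlirModel":
        d = json.loads(Path(path).read_text())
        hy = d["hyper"]
        manifest = d["manifest"]
        if "source_index" in manifest:
            manifest["source_index"] = [tuple(x) for x in manifest["source_index"]]
        return cls(
            weights=np.array(d["weights"], dtype=float),
            bias=np.array(d["bias"], dtype=float),
            ard_alpha=np.array(d["ard_alpha"], dtype=float),
            noise_precision=np.array(d["noise_precision"], dtype=float),
            active_mask=np.array(d["active_mask"], dtype=bool),
            fit_info=[{**fi, "free_energy": np.array(fi["free_energy"])}
                      for fi in d["fit_info"]],
            manifest=manifest,
            muscle_names=list(d["muscle_names"]),
            train_span=tuple(d["train_span"]) if d["train_span"] else None,
            hyper=ArdHyper(max_iter=hy["max_iter"], tol=hy["tol"],
                           prune_threshold=hy["prune_threshold"],
                           alpha_prior=tuple(hy["alpha_prior"]),
                           beta_prior=tuple(hy["beta_prior"]),
                           fixed_alpha=hy["fixed_alpha"]),
        )


def _generic_manifest(p: int) -> dict:
    return {"source_index": [(f"col{i}", "none") for i in range(p)],
            "n_lags": 1, "lag_step_samples": 1, "lag_offset": 0, "rate": None}


def fit_slir(X, Y, hyper: ArdHyper | None = None, *, rows: np.ndarray | None = None,
             muscle_names: Sequence[str] | None = None,
             train_span: tuple[str, float, float] | None = None,
             stats: SuffStats | None = None) -> SlirModel:
    """Fit the sparse decoder.

    ``X`` is a :class:`DesignMatrix` or dense [n x p] array; ``Y`` is the
    matching [n x K] target block (or the full-session target matrix when
    ``X`` is a design matrix and ``rows`` indexes into it).  Targets and
    features are centred internally; the bias absorbs the means.  The fit is
    deterministic.
    """
    hyper = hyper or ArdHyper()
    hyper.validate()
    lazy = isinstance(X, DesignMatrix)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.isfinite(Y).all():
        raise DataError("targets contain non-finite values")
    if not lazy:
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise DataError("design matrix contains non-finite values")
    if stats is None:
        stats = accumulate_stats(X, Y, rows)
    Gc, XtYc, ytyc, xbar, ybar = stats.centered()
    p = Gc.shape[0]
    K = XtYc.shape[1]
    if lazy:
        manifest = X.manifest()
        m_sources, n_lags = X.sources.n_sources, X.n_lags
    else:
        manifest = _generic_manifest(p)
        m_sources, n_lags = p, 1

    weights = np.zeros((K, p))
    bias = np.zeros(K)
    alpha = np.zeros((K, p))
    betas = np.zeros(K)
    mask = np.zeros((K, p), dtype=bool)
    infos: list[dict] = []
    for k in range(K):
        if ytyc[k] <= max(stats.n, 1) * 1e-15 * max(1.0, ybar[k] ** 2):
            warnings.warn(f"target {k} has (near-)zero variance; bias-only fit",
                          RuntimeWarning, stacklevel=2)
            bias[k] = ybar[k]
            alpha[k] = np.inf
            betas[k] = np.inf
            infos.append({"iterations": 0, "converged": True,
                          "free_energy": np.zeros(0), "bias_only": True})
            continue
        res = _vb_ard(Gc, XtYc[:, k], float(ytyc[k]), stats.n, hyper)
        weights[k] = res["w"]
        alpha[k] = res["alpha"]
        betas[k] = res["beta"]
        mask[k] = res["active"]
        bias[k] = ybar[k] - xbar @ res["w"]
        infos.append({"iterations": res["iterations"], "converged": res["converged"],
                      "free_energy": res["free_energy"]})
    names = list(muscle_names) if muscle_names is not None else [f"muscle{k}" for k in range(K)]
    return SlirModel(
        weights=weights.reshape(K, m_sources, n_lags),
        bias=bias,
        ard_alpha=alpha,
        noise_precision=betas,
        active_mask=mask,
        fit_info=infos,
        manifest=manifest,
        muscle_names=names,
        train_span=train_span,
        hyper=hyper,
    )


def _check_manifest(model: SlirModel, X) -> None:
    if isinstance(X, DesignMatrix):
        m = X.manifest()
        ours = dict(model.manifest)
        ours["source_index"] = [tuple(s) for s in ours["source_index"]]
        m["source_index"] = [tuple(s) for s in m["source_index"]]
        if m != ours:
            raise ContractError("design-matrix column manifest does not match the model")
    else:
        if np.asarray(X).shape[-1] != model.coef.shape[1]:
            raise ContractError(
                f"feature count {np.asarray(X).shape[-1]} != model columns "
                f"{model.coef.shape[1]}"
            )


def predict(model: SlirModel, X, rows: np.ndarray | None = None) -> np.ndarray:
    """Linear prediction X W' + b, rows x muscles."""
    _check_manifest(model, X)
    W = model.coef.T  # [p x K]
    if isinstance(X, DesignMatrix):
        if rows is None:
            rows = np.arange(X.n_rows)
        rows = np.asarray(rows)
        out = np.empty((rows.size, model.n_muscles))
        for start in range(0, rows.size, _CHUNK):
            sel = rows[start:start + _CHUNK]
            out[start:start + sel.size] = X.rows(sel) @ W
    else:
        out = np.asarray(X, dtype=float) @ W
    return out + model.bias


def active_summary(model: SlirModel) -> dict:
    """Counts of surviving (unpruned) columns grouped by band, channel and lag.

    Counts are summed over muscles; ``total`` equals the number of active
    (muscle, column) pairs, and each grouping partitions that total.
    """
    source_index = [tuple(s) for s in model.manifest["source_index"]]
    n_lags = int(model.manifest["n_lags"])
    records = []
    for k in range(model.n_muscles):
        act = np.flatnonzero(model.active_mask[k])
        for c in act:
            ch, band = source_index[c // n_lags]
            records.append((model.muscle_names[k], ch, band, int(c % n_lags)))
    df = pd.DataFrame(records, columns=["muscle", "channel", "band", "lag"])
    return {
        "by_band": df.groupby("band").size() if len(df) else pd.Series(dtype=int),
        "by_channel": df.groupby("channel").size() if len(df) else pd.Series(dtype=int),
        "by_lag": df.groupby("lag").size() if len(df) else pd.Series(dtype=int),
        "by_muscle": df.groupby("muscle").size() if len(df) else pd.Series(dtype=int),
        "total": int(model.active_mask.sum()),
        "table": df,
    }
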