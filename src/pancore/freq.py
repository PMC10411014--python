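"""Joint maximum-likelihood estimation of gene frequencies and genome
recovery rates from binary pangenome matrices.

Model
-----
Presence of gene i in genome j is Bernoulli with success probability
``p_i * q_j``, where ``p_i`` is the gene's true frequency in the species and
``q_j`` is the genome's gene recovery rate (fraction of its genes surviving
sequencing/assembly/annotation).  The log-likelihood of a matrix X is

    LL(X, p, q) = sum_ij  x_ij log(p_i q_j) + (1 - x_ij) log(1 - p_i q_j)

and both parameter vectors are estimated simultaneously by bounded L-BFGS-B
with exact analytic gradients

    dLL/dp_k = sum_j  x_kj / p_k  -  (1 - x_kj) q_j / (1 - p_k q_j)
    dLL/dq_k = sum_i  x_ik / q_k  -  (1 - x_ik) p_i / (1 - p_i q_k)

Estimation is restricted to genes with observed frequency above a floor
(default 10%); rarer genes keep their observed frequency, flagged as not
estimated — they can never be called core so this is inert downstream.  Only
the products p_i q_j are identifiable in general; initializing every q at
0.99 and p at the observed frequencies pins the scale in practice.

The species core genome is the set of genes with estimated frequency
strictly above 99.99%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "FrequencyEstimate",
    "GeneFrequencyEstimator",
    "log_likelihood",
    "gradient",
    "estimate",
    "call_core",
    "discretize",
    "DistributionFit",
    "fit_distribution",
    "CORE_THRESHOLD",
    "BOUND_EPS",
]

BOUND_EPS = 1e-8
CORE_THRESHOLD = 0.9999


def _as_entries(X) -> np.ndarray:
    if isinstance(X, PresenceAbsenceMatrix):
        return np.asarray(X.entries, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("X must be binary")
    return X


def log_likelihood(X, p, q) -> float:
    """Bernoulli log-likelihood of the presence/absence matrix.

    Raises ValueError when an observation has probability 0 under (p, q)
    (non-finite likelihood).
    """
    x = _as_entries(X)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (x.shape[0],) or q.shape != (x.shape[1],):
        raise ValueError("dimension mismatch between X, p, q")
    pq = np.outer(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = x * np.log(pq) + (1.0 - x) * np.log1p(-pq)
    ll = float(terms.sum())
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood: some p_i*q_j is 0 or 1 "
                         "with an opposing observation")
    return ll


def gradient(X, p, q) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradient of the log-likelihood w.r.t. p and q."""
    x = _as_entries(X)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (x.shape[0],) or q.shape != (x.shape[1],):
        raise ValueError("dimension mismatch between X, p, q")
    pq = np.outer(p, q)
    denom = 1.0 - pq
    if np.any(denom <= 0) or np.any(pq <= 0):
        raise ValueError("p_i*q_j outside (0,1): gradient undefined")
    one_minus = (1.0 - x) / denom
    dp = x.sum(axis=1) / p - one_minus @ q
    dq = x.sum(axis=0) / q - p @ one_minus
    return dp, dq


@dataclass
class FrequencyEstimate:
    """Fitted frequencies and recovery rates with optimizer diagnostics."""

    genes: list[str]
    genomes: list[str]
    p_hat: np.ndarray = field(repr=False)
    q_hat: np.ndarray = field(repr=False)
    estimated_mask: np.ndarray = field(repr=False)
    observed_freqs: np.ndarray = field(repr=False)
    final_ll: float
    initial_ll: float
    converged: bool
    n_iterations: int

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "observed_freq": self.observed_freqs,
                "p_hat": self.p_hat,
                "estimated": self.estimated_mask,
            }
        )

    def genome_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genome": self.genomes, "q_hat": self.q_hat})


class GeneFrequencyEstimator:
    """Scikit-learn style estimator for the Bernoulli product model.

    Parameters
    ----------
    estimation_floor : float
        Genes with observed frequency <= this value are excluded from the
        likelihood; their ``p_hat`` is the observed frequency (clipped to the
        optimizer bounds) and their mask entry is False.
    q_init : float
        Initial guess for every genome recovery rate.
    tol : float
        Convergence tolerance on the relative change of the log-likelihood
        (L-BFGS-B ``ftol``).
    max_iter : int
        Iteration cap for the optimizer.

    Attributes (after ``fit``)
    --------------------------
    p_hat_, q_hat_, estimated_mask_, observed_freqs_, final_ll_,
    initial_ll_, converged_, n_iter_
    """

    def __init__(
        self,
        estimation_floor: float = 0.10,
        q_init: float = 0.99,
        tol: float = 1e-9,
        max_iter: int = 15000,
    ) -> None:
        self.estimation_floor = estimation_floor
        self.q_init = q_init
        self.tol = tol
        self.max_iter = max_iter

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "estimation_floor": self.estimation_floor,
            "q_init": self.q_init,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "GeneFrequencyEstimator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "GeneFrequencyEstimator":
        x = _as_entries(X)
        m, n = x.shape
        if isinstance(X, PresenceAbsenceMatrix):
            self.genes_, self.genomes_ = list(X.genes), list(X.genomes)
        else:
            self.genes_ = [f"G{i:05d}" for i in range(m)]
            self.genomes_ = [f"S{j:05d}" for j in range(n)]
        obs = x.mean(axis=1) if n else np.zeros(m)
        mask = obs > self.estimation_floor
        if not mask.any():
            raise ValueError("no gene above the estimation floor; nothing to estimate")

        xe = x[mask]
        me = int(mask.sum())
        lo, hi = BOUND_EPS, 1.0 - BOUND_EPS
        p0 = np.clip(obs[mask], lo, hi)
        q0 = np.full(n, np.clip(self.q_init, lo, hi))
        z0 = np.concatenate([p0, q0])

        def neg_ll(z):
            p, q = z[:me], z[me:]
            pq = np.outer(p, q)
            terms = xe * np.log(pq) + (1.0 - xe) * np.log1p(-pq)
            return -terms.sum()

        def neg_grad(z):
            p, q = z[:me], z[me:]
            pq = np.outer(p, q)
            one_minus = (1.0 - xe) / (1.0 - pq)
            dp = xe.sum(axis=1) / p - one_minus @ q
            dq = xe.sum(axis=0) / q - p @ one_minus
            return -np.concatenate([dp, dq])

        initial_ll = -neg_ll(z0)
        res = optimize.minimize(
            neg_ll,
            z0,
            jac=neg_grad,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * (me + n),
            options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter,
                     "ftol": self.tol, "gtol": 1e-12},
        )
        z = res.x
        final_ll = -float(res.fun)
        if final_ll < initial_ll:  # defensive: never report a worse point
            z, final_ll = z0, initial_ll

        p_hat = np.clip(obs, lo, hi)
        p_hat[mask] = z[:me]
        self.p_hat_ = p_hat
        self.q_hat_ = z[me:]
        self.estimated_mask_ = mask
        self.observed_freqs_ = obs
        self.final_ll_ = final_ll
        self.initial_ll_ = float(initial_ll)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        return self

    def result_(self) -> FrequencyEstimate:
        return FrequencyEstimate(
            genes=self.genes_,
            genomes=self.genomes_,
            p_hat=self.p_hat_,
            q_hat=self.q_hat_,
            estimated_mask=self.estimated_mask_,
            observed_freqs=self.observed_freqs_,
            final_ll=self.final_ll_,
            initial_ll=self.initial_ll_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
        )

    def core_genes(self, threshold: float = CORE_THRESHOLD) -> set:
        return call_core(self.result_(), threshold)


def estimate(
    X,
    estimation_floor: float = 0.10,
    q_init: float = 0.99,
    tol: float = 1e-9,
    max_iter: int = 15000,
) -> FrequencyEstimate:
    """Functional wrapper around :class:`GeneFrequencyEstimator`."""
    est = GeneFrequencyEstimator(estimation_floor, q_init, tol, max_iter).fit(X)
    return est.result_()


def call_core(est: FrequencyEstimate, threshold: float = CORE_THRESHOLD) -> set:
    """Genes with estimated frequency strictly greater than the threshold."""
    return {g for g, p in zip(est.genes, est.p_hat) if p > threshold}


# ---------------------------------------------------------------------------
# frequency-distribution discretization and fitting


def discretize(freqs, n_genomes: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram frequencies into right-closed bins of width 1/n_genomes.

    Returns (counts, bin_edges); a frequency of exactly 0 is placed in the
    first bin, a frequency of 1.0 in the last.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    edges = np.arange(n_genomes + 1) / n_genomes
    counts = np.zeros(n_genomes, dtype=int)
    if freqs.size:
        idx = np.ceil(freqs * n_genomes).astype(int) - 1
        idx = np.clip(idx, 0, n_genomes - 1)
        np.add.at(counts, idx, 1)
    return counts, edges


@dataclass
class DistributionFit:
    """Result of fitting a closed-form model to a frequency histogram."""

    model: str
    k: float
    c: float
    a: float
    r_squared: float
    mae: float
    ok: bool = True
    message: str = ""


def _model_p(model: str, x: np.ndarray, k: float, c: float, a: float) -> np.ndarray:
    if model == "power":
        return k * np.power(x, -a) + c
    if model == "exponential":
        return k * np.exp(-a * x) + c
    raise ValueError(f"unknown model {model!r}")


def fit_distribution(
    counts,
    bin_edges,
    model: str = "power",
) -> DistributionFit:
    """Fit a frequency-count model through its cumulative form.

    The model for per-bin gene counts P(x) is ``k*x^(-a) + c`` (power; a > 1)
    or ``k*exp(-a*x) + c`` (exponential), evaluated at bin centers x.  The
    cumulative form F(x) — genes with frequency <= x — is obtained by discrete
    summation over bins; the observed F is scaled to maximum 1 and the model
    is fit to it by nonlinear least squares with initial guesses (1, 1, 2)
    for the power model and (1, 1, 1) for the exponential.  Fitted parameters
    are then applied directly to P(x) and the fit quality (R^2 and mean
    absolute error) is evaluated against the identically scaled counts.

    Fit failures and underdetermined inputs are returned flagged, not raised.
    """
    counts = np.asarray(counts, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.size != counts.size + 1:
        raise ValueError("bin_edges must have len(counts)+1 entries")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    nonempty = int((counts > 0).sum())
    if nonempty < 4:
        return DistributionFit(model, np.nan, np.nan, np.nan, np.nan, np.nan,
                               ok=False, message=f"underdetermined: {nonempty} non-empty bins")
    total = counts.sum()
    f_obs = np.cumsum(counts) / total  # scaled to max 1
    p_obs = counts / total

    def f_model(x, k, c, a):
        # discrete cumulative summation over the fixed bin grid
        return np.cumsum(_model_p(model, centers, k, c, a))

    eps = 1e-12
    if model == "power":
        p0, lower = (1.0, 1.0, 2.0), (eps, eps, 1.0 + eps)
    elif model == "exponential":
        p0, lower = (1.0, 1.0, 1.0), (eps, eps, eps)
    else:
        raise ValueError(f"unknown model {model!r}")
    try:
        popt, _ = optimize.curve_fit(
            f_model, centers, f_obs, p0=p0,
            bounds=(lower, (np.inf, np.inf, np.inf)), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return DistributionFit(model, np.nan, np.nan, np.nan, np.nan, np.nan,
                               ok=False, message=f"fit failed: {exc}")
    k, c, a = (float(v) for v in popt)
    p_fit = _model_p(model, centers, k, c, a)
    resid = p_obs - p_fit
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((p_obs - p_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mae = float(np.mean(np.abs(resid)))
    return DistributionFit(model, k, c, a, r2, mae)
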