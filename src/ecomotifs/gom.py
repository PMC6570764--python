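"""Grade-of-membership (mixed-membership) models fit by MAP EM.

Two observation models share one latent structure. Each sample (row) n
carries a membership vector omega_n on the K-simplex; each motif k
carries a feature profile theta_k. The implied per-entry probability is

    p_ng = sum_k omega_nk * theta_kg.

* Multinomial model: row n of a count matrix is Mult(c_n+, p_n.), with
  theta rows on the G-simplex — the topic-model / ADMIXTURE likelihood.
* Bernoulli model: each entry m_ng is Bernoulli(p_ng), with theta
  entrywise in [0, 1] — a mixed-membership model for presence-absence.

Both are fit by EM on the MAP objective (log likelihood plus log prior;
the multinomial coefficient, constant on fixed data, is dropped
throughout). Priors are symmetric Dirichlet on omega rows and, for the
multinomial, on theta rows; Beta on each Bernoulli theta entry. The
defaults (all concentration 1) are flat, so MAP EM reduces to maximum
likelihood EM. The E-step introduces a per-observation latent motif
indicator whose marginal is exactly p_ng above, so the objective is
monotone non-decreasing by the usual EM argument.

Model comparison uses an approximate log Bayes factor against the K=1
fit of the same data: the MAP-objective gap penalised BIC-style by half
the extra parameter count times log(number of observations). It is an
approximation meant only to rank fits of identical data — restarts,
choices of K, observed vs permuted matrices — never to compare across
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrices import CountMatrix, LabelledMatrix, PresenceMatrix

__all__ = [
    "MotifFit",
    "PartitionLabels",
    "fit_multinomial_gom",
    "fit_bernoulli_gom",
    "fit_gom",
    "loglik",
    "log_bayes_factor",
    "multistart_fit",
    "constrained_partition_fit",
    "align_motifs",
    "apply_motif_permutation",
    "save_fit",
    "load_fit",
]

_EPS = 1e-12  # probability clip inside E-steps and logs


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MotifFit:
    """A fitted grade-of-membership model.

    omega is N x K (rows on the simplex), theta is K x G (rows on the
    simplex for the multinomial model, entrywise in [0, 1] for the
    Bernoulli model). ``log_bf`` is the approximate log Bayes factor
    against the K=1 fit of the same data.
    """

    model_kind: str
    K: int
    omega: np.ndarray
    theta: np.ndarray
    loglik_trace: np.ndarray
    log_bf: float
    seed: int | None
    converged: bool
    prior_omega: float = 1.0
    prior_theta: float | tuple[float, float] = 1.0
    free_omega: bool = True
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.model_kind not in {"multinomial", "bernoulli"}:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        _check_simplex(self.omega, "omega rows")
        if self.model_kind == "multinomial":
            _check_simplex(self.theta, "theta rows")
        else:
            if (self.theta < -1e-12).any() or (self.theta > 1 + 1e-12).any():
                raise ValueError("bernoulli theta must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.omega.shape[0]

    @property
    def n_features(self) -> int:
        return self.theta.shape[1]

    def implied_probabilities(self) -> np.ndarray:
        """p_ng = sum_k omega_nk theta_kg for every entry."""
        return self.omega @ self.theta


@dataclass
class PartitionLabels:
    """Hard per-row motif assignment for partition-constrained fits."""

    assignment: np.ndarray  # integer motif index per row, in 1..K

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1-D integer array")
        if a.min() < 1:
            raise ValueError("motif indices are 1-based")
        self.assignment = a

    @property
    def K(self) -> int:
        return int(self.assignment.max())

    def validate_cover(self) -> None:
        present = set(np.unique(self.assignment).tolist())
        missing = sorted(set(range(1, self.K + 1)) - present)
        if missing:
            raise ValueError(f"motifs with no assigned rows: {missing}")

    def one_hot(self) -> np.ndarray:
        self.validate_cover()
        omega = np.zeros((self.assignment.size, self.K))
        omega[np.arange(self.assignment.size), self.assignment - 1] = 1.0
        return omega


def _check_simplex(mat: np.ndarray, what: str, tol: float = 1e-8) -> None:
    if (mat < -tol).any() or (mat > 1 + tol).any():
        raise ValueError(f"{what} must lie in [0, 1]")
    sums = mat.sum(axis=1)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError(f"{what} must each sum to 1 (max deviation {np.abs(sums-1).max():.2e})")


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def _mult_objective(C: np.ndarray, omega: np.ndarray, theta: np.ndarray,
                    a_omega: float, a_theta: float) -> float:
    P = np.clip(omega @ theta, _EPS, None)
    obj = float(np.sum(C * np.log(P)))
    if a_omega != 1.0:
        obj += (a_omega - 1.0) * float(np.sum(np.log(np.clip(omega, _EPS, None))))
    if a_theta != 1.0:
        obj += (a_theta - 1.0) * float(np.sum(np.log(np.clip(theta, _EPS, None))))
    return obj


def _bern_objective(M: np.ndarray, omega: np.ndarray, theta: np.ndarray,
                    a_omega: float, beta: tuple[float, float]) -> float:
    P = np.clip(omega @ theta, _EPS, 1 - _EPS)
    obj = float(np.sum(M * np.log(P) + (1 - M) * np.log1p(-P)))
    if a_omega != 1.0:
        obj += (a_omega - 1.0) * float(np.sum(np.log(np.clip(omega, _EPS, None))))
    a, b = beta
    if a != 1.0 or b != 1.0:
        th = np.clip(theta, _EPS, 1 - _EPS)
        obj += float((a - 1.0) * np.sum(np.log(th)) + (b - 1.0) * np.sum(np.log1p(-th)))
    return obj


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _init_params(N: int, G: int, K: int, model_kind: str, rng: np.random.Generator):
    omega = rng.dirichlet(np.ones(K), size=N)
    if model_kind == "multinomial":
        theta = rng.gamma(1.0, size=(K, G))
        theta /= theta.sum(axis=1, keepdims=True)
    else:
        theta = rng.uniform(0.1, 0.9, size=(K, G))
    return omega, theta


# ---------------------------------------------------------------------------
# EM fits
# ---------------------------------------------------------------------------


def fit_multinomial_gom(
    counts: CountMatrix,
    K: int,
    prior_omega: float = 1.0,
    prior_theta: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = 0,
) -> MotifFit:
    """Fit the multinomial grade-of-membership model by MAP EM.

    Parameters
    ----------
    counts
        Site-by-feature abundance matrix.
    K
        Number of motifs, ``1 <= K <= min(N, G)``.
    prior_omega, prior_theta
        Symmetric Dirichlet concentrations for the omega rows and theta
        rows; 1 is flat (MAP = MLE). Values >= 1 keep EM monotone.
    max_iter, tol
        EM stops when the relative change of the MAP objective drops
        below ``tol``, or after ``max_iter`` sweeps.
    seed
        Seeds the random initialisation; ``None`` draws fresh entropy.
    """
    _check_k(counts, K)
    if tol <= 0:
        raise ValueError("tol must be positive")
    C = counts.values.astype(float)
    N, G = C.shape
    rng = np.random.default_rng(seed)
    omega, theta = _init_params(N, G, K, "multinomial", rng)

    trace = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        P = np.clip(omega @ theta, _EPS, None)
        R = C / P  # N x G
        # E + M in multiplicative form: expected motif loads
        load_omega = omega * (R @ theta.T)           # N x K, = sum_g c_ng r_ngk
        load_theta = theta * (omega.T @ R)           # K x G, = sum_n c_ng r_ngk
        omega = _normalise_rows(load_omega + (prior_omega - 1.0))
        theta = _normalise_rows(load_theta + (prior_theta - 1.0))
        obj = _mult_objective(C, omega, theta, prior_omega, prior_theta)
        trace.append(obj)
        if np.isfinite(prev) and abs(obj - prev) <= tol * (abs(prev) + _EPS):
            converged = True
            break
        prev = obj

    fit = MotifFit(
        model_kind="multinomial", K=K, omega=omega, theta=theta,
        loglik_trace=np.asarray(trace), log_bf=0.0, seed=seed, converged=converged,
        prior_omega=prior_omega, prior_theta=prior_theta,
        row_ids=list(counts.row_ids), col_ids=list(counts.col_ids),
    )
    fit.log_bf = log_bayes_factor(fit, counts)
    return fit


def fit_bernoulli_gom(
    presence: PresenceMatrix,
    K: int,
    prior_omega: float = 1.0,
    prior_theta: tuple[float, float] = (1.0, 1.0),
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = 0,
) -> MotifFit:
    """Fit the Bernoulli grade-of-membership model by MAP EM.

    Each entry carries a latent motif indicator z_ng ~ Cat(omega_n.);
    m_ng | z_ng = k is Bernoulli(theta_kg), so the marginal presence
    probability is exactly sum_k omega_nk theta_kg. ``prior_theta`` is a
    Beta(a, b) pair applied to every theta entry; (1, 1) is flat.
    """
    if not isinstance(presence, PresenceMatrix):
        raise TypeError("fit_bernoulli_gom requires a PresenceMatrix")
    _check_k(presence, K)
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = presence.values.astype(float)
    N, G = M.shape
    a, b = prior_theta
    rng = np.random.default_rng(seed)
    omega, theta = _init_params(N, G, K, "bernoulli", rng)

    trace = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        P = np.clip(omega @ theta, _EPS, 1 - _EPS)
        Rp = M / P                 # weight where present
        Ra = (1 - M) / (1 - P)     # weight where absent
        # responsibilities split by observed state; all reductions are matmuls
        load_present = omega * (Rp @ theta.T)          # sum_g r_ngk m_ng
        load_absent = omega * (Ra @ (1 - theta).T)     # sum_g r_ngk (1-m_ng)
        omega = _normalise_rows(load_present + load_absent + (prior_omega - 1.0))
        num = theta * (omega.T @ Rp)                   # sum_n r_ngk m_ng
        den = num + (1 - theta) * (omega.T @ Ra)       # sum_n r_ngk
        theta = np.clip((num + (a - 1.0)) / (den + (a - 1.0) + (b - 1.0)), _EPS, 1 - _EPS)
        obj = _bern_objective(M, omega, theta, prior_omega, (a, b))
        trace.append(obj)
        if np.isfinite(prev) and abs(obj - prev) <= tol * (abs(prev) + _EPS):
            converged = True
            break
        prev = obj

    fit = MotifFit(
        model_kind="bernoulli", K=K, omega=omega, theta=theta,
        loglik_trace=np.asarray(trace), log_bf=0.0, seed=seed, converged=converged,
        prior_omega=prior_omega, prior_theta=(a, b),
        row_ids=list(presence.row_ids), col_ids=list(presence.col_ids),
    )
    fit.log_bf = log_bayes_factor(fit, presence)
    return fit


def fit_gom(data: LabelledMatrix, K: int, **kwargs) -> MotifFit:
    """Dispatch on matrix type: PresenceMatrix -> Bernoulli, else multinomial."""
    if isinstance(data, PresenceMatrix):
        return fit_bernoulli_gom(data, K, **kwargs)
    return fit_multinomial_gom(data, K, **kwargs)


def _normalise_rows(mat: np.ndarray) -> np.ndarray:
    mat = np.clip(mat, _EPS, None)
    return mat / mat.sum(axis=1, keepdims=True)


def _check_k(data: LabelledMatrix, K: int) -> None:
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(data.shape):
        raise ValueError(f"K={K} exceeds min(N, G) = {min(data.shape)}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def loglik(fit: MotifFit, data: LabelledMatrix) -> float:
    """Log likelihood of ``data`` under ``fit`` (no prior terms).

    The multinomial value omits the multinomial coefficient, which is
    constant on fixed data; the Bernoulli value is the full sum of entry
    log probabilities. An implied probability of exactly 0 against a
    positive observation yields ``-inf`` rather than an exception.
    """
    _check_match(fit, data)
    P = fit.implied_probabilities()
    if fit.model_kind == "multinomial":
        C = data.values
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(C > 0, C * np.log(P), 0.0)
        return float(terms.sum())
    M = data.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(M == 1, np.log(P), np.log1p(-P))
    return float(terms.sum())


def _map_objective(fit: MotifFit, data: LabelledMatrix) -> float:
    if fit.model_kind == "multinomial":
        return _mult_objective(data.values.astype(float), fit.omega, fit.theta,
                               fit.prior_omega, float(fit.prior_theta))
    return _bern_objective(data.values.astype(float), fit.omega, fit.theta,
                           fit.prior_omega, tuple(fit.prior_theta))


def _k1_objective(fit: MotifFit, data: LabelledMatrix) -> float:
    """Closed-form MAP objective of the K=1 model on the same data/priors."""
    vals = data.values.astype(float)
    N, G = vals.shape
    if fit.model_kind == "multinomial":
        a = float(fit.prior_theta)
        theta = _normalise_rows((vals.sum(axis=0) + (a - 1.0))[None, :])
        return _mult_objective(vals, np.ones((N, 1)), theta, fit.prior_omega, a)
    a, b = fit.prior_theta
    theta = (vals.sum(axis=0) + (a - 1.0)) / (N + (a - 1.0) + (b - 1.0))
    theta = np.clip(theta, _EPS, 1 - _EPS)[None, :]
    return _bern_objective(vals, np.ones((N, 1)), theta, fit.prior_omega, (a, b))


def _n_free_params(fit: MotifFit, K: int | None = None) -> int:
    K = fit.K if K is None else K
    N, G = fit.n_rows, fit.n_features
    omega_params = N * (K - 1) if fit.free_omega else 0
    if fit.model_kind == "multinomial":
        return omega_params + K * (G - 1)
    return omega_params + K * G


def log_bayes_factor(fit: MotifFit, data: LabelledMatrix) -> float:
    """Approximate log Bayes factor of ``fit`` against the K=1 fit.

    BIC-style: the MAP-objective gap minus half the extra free-parameter
    count times log(number of observations) — total individuals for the
    multinomial model, N*G Bernoulli trials for the presence model.
    Exactly 0 at K=1. Valid only for ranking fits of identical data.
    """
    _check_match(fit, data)
    if fit.K == 1 and fit.free_omega:
        return 0.0
    obj_k = _map_objective(fit, data)
    obj_1 = _k1_objective(fit, data)
    if fit.model_kind == "multinomial":
        n_obs = float(data.values.sum())
    else:
        n_obs = float(data.values.size)
    # K=1 baseline: G-1 (multinomial theta) or G (bernoulli theta) params
    base = (fit.n_features - 1) if fit.model_kind == "multinomial" else fit.n_features
    delta_params = _n_free_params(fit) - base
    return float(obj_k - obj_1 - 0.5 * delta_params * np.log(n_obs))


def _check_match(fit: MotifFit, data: LabelledMatrix) -> None:
    if fit.omega.shape[0] != data.n_rows or fit.theta.shape[1] != data.n_cols:
        raise ValueError(
            f"fit dimensions ({fit.omega.shape[0]} x {fit.theta.shape[1]}) do not "
            f"match data ({data.n_rows} x {data.n_cols})"
        )
    if fit.model_kind == "bernoulli" and not isinstance(data, PresenceMatrix):
        raise TypeError("bernoulli fit must be evaluated on a PresenceMatrix")


# ---------------------------------------------------------------------------
# restarts / constrained competitor
# ---------------------------------------------------------------------------


def multistart_fit(
    data: LabelledMatrix,
    K: int,
    n_starts: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> MotifFit:
    """Run EM from ``n_starts`` seeded initialisations, keep the best log BF.

    Child seeds are ``seed + restart_index``; the whole procedure is
    deterministic given the master seed. Per-restart failures propagate
    only if every restart fails.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    best: MotifFit | None = None
    errors: list[Exception] = []
    for i in range(n_starts):
        try:
            fit = fit_gom(data, K, seed=seed + i, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - recorded, only fatal if all fail
            errors.append(exc)
            continue
        if best is None or fit.log_bf > best.log_bf:
            best = fit
    if best is None:
        raise RuntimeError(f"all {n_starts} restarts failed; first error: {errors[0]}")
    return best


def constrained_partition_fit(
    counts: LabelledMatrix,
    labels: PartitionLabels,
    prior_theta: float | tuple[float, float] = 1.0,
    prior_omega: float = 1.0,
) -> MotifFit:
    """Competitor fit with memberships preset to a hard partition.

    Omega rows are one-hot per ``labels``; only theta is estimated, in
    closed form (pooled prior-smoothed column proportions per motif for
    counts; pooled Bernoulli means for presence). The log Bayes factor
    uses the same approximation as the free fits, counting only theta as
    estimated, so constrained and unconstrained fits are comparable.
    """
    if labels.assignment.size != counts.n_rows:
        raise ValueError("labels must cover every row")
    omega = labels.one_hot()
    K = labels.K
    vals = counts.values.astype(float)
    G = counts.n_cols
    if isinstance(counts, PresenceMatrix):
        a, b = prior_theta if isinstance(prior_theta, tuple) else (prior_theta, prior_theta)
        theta = np.empty((K, G))
        for k in range(K):
            rows = vals[labels.assignment == k + 1]
            theta[k] = (rows.sum(axis=0) + (a - 1.0)) / (len(rows) + (a - 1.0) + (b - 1.0))
        theta = np.clip(theta, _EPS, 1 - _EPS)
        kind = "bernoulli"
        ptheta: float | tuple[float, float] = (a, b)
    else:
        a = float(prior_theta)
        theta = np.empty((K, G))
        for k in range(K):
            rows = vals[labels.assignment == k + 1]
            theta[k] = rows.sum(axis=0) + (a - 1.0)
        theta = _normalise_rows(theta)
        kind = "multinomial"
        ptheta = a
    fit = MotifFit(
        model_kind=kind, K=K, omega=omega, theta=theta,
        loglik_trace=np.empty(0), log_bf=0.0, seed=None, converged=True,
        prior_omega=prior_omega, prior_theta=ptheta, free_omega=False,
        row_ids=list(counts.row_ids), col_ids=list(counts.col_ids),
    )
    fit.loglik_trace = np.array([_map_objective(fit, counts)])
    fit.log_bf = log_bayes_factor(fit, counts)
    return fit


# ---------------------------------------------------------------------------
# label switching
# ---------------------------------------------------------------------------


def align_motif_rows(theta_a: np.ndarray, theta_b: np.ndarray) -> np.ndarray:
    """Permutation matching the rows of ``theta_b`` to those of
    ``theta_a`` by maximising summed Pearson correlation (optimal
    assignment, deterministic)."""
    theta_a = np.asarray(theta_a, float)
    theta_b = np.asarray(theta_b, float)
    if theta_a.shape != theta_b.shape:
        raise ValueError("theta matrices must share shape")
    score = _theta_correlations(theta_a, theta_b)
    _, cols = linear_sum_assignment(-score)
    return cols


def align_motifs(fit_a: MotifFit, fit_b: MotifFit) -> np.ndarray:
    """Permutation matching fit_b's motifs to fit_a's.

    Returns ``perm`` such that motif ``perm[k]`` of ``fit_b`` corresponds
    to motif ``k`` of ``fit_a``, maximising the summed Pearson
    correlation of matched theta rows (optimal assignment; deterministic).
    """
    if fit_a.K != fit_b.K:
        raise ValueError("fits must share K")
    if fit_a.n_features != fit_b.n_features:
        raise ValueError("fits must share the feature set")
    return align_motif_rows(fit_a.theta, fit_b.theta)


def _theta_correlations(ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    a = ta - ta.mean(axis=1, keepdims=True)
    b = tb - tb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (a @ b.T) / np.outer(na, nb)
    return np.nan_to_num(corr)  # zero-variance rows contribute 0


def apply_motif_permutation(fit: MotifFit, perm: Sequence[int]) -> MotifFit:
    """Relabel motifs: omega columns and theta rows reordered by ``perm``."""
    perm = np.asarray(perm, dtype=int)
    if sorted(perm.tolist()) != list(range(fit.K)):
        raise ValueError("perm must be a permutation of 0..K-1")
    return MotifFit(
        model_kind=fit.model_kind, K=fit.K,
        omega=fit.omega[:, perm], theta=fit.theta[perm],
        loglik_trace=fit.loglik_trace.copy(), log_bf=fit.log_bf, seed=fit.seed,
        converged=fit.converged, prior_omega=fit.prior_omega,
        prior_theta=fit.prior_theta, free_omega=fit.free_omega,
        row_ids=list(fit.row_ids), col_ids=list(fit.col_ids),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_fit(fit: MotifFit, directory: str | Path) -> None:
    """Write omega.csv, theta.csv and a JSON metadata sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    motifs = [f"motif_{k + 1}" for k in range(fit.K)]
    rows = fit.row_ids or [f"row{i}" for i in range(fit.n_rows)]
    cols = fit.col_ids or [f"col{j}" for j in range(fit.n_features)]
    pd.DataFrame(fit.omega, index=rows, columns=motifs).rename_axis("id").to_csv(d / "omega.csv")
    pd.DataFrame(fit.theta, index=motifs, columns=cols).rename_axis("motif").to_csv(d / "theta.csv")
    meta = {
        "model_kind": fit.model_kind,
        "K": fit.K,
        "seed": fit.seed,
        "log_bf": fit.log_bf,
        "converged": fit.converged,
        "n_iterations": int(fit.loglik_trace.size),
        "final_objective": float(fit.loglik_trace[-1]) if fit.loglik_trace.size else None,
        "prior_omega": fit.prior_omega,
        "prior_theta": list(fit.prior_theta) if isinstance(fit.prior_theta, tuple) else fit.prior_theta,
        "free_omega": fit.free_omega,
    }
    (d / "fit.json").write_text(json.dumps(meta, indent=2))


def load_fit(directory: str | Path) -> MotifFit:
    d = Path(directory)
    meta = json.loads((d / "fit.json").read_text())
    omega_df = pd.read_csv(d / "omega.csv", index_col=0)
    theta_df = pd.read_csv(d / "theta.csv", index_col=0)
    prior_theta = meta["prior_theta"]
    if isinstance(prior_theta, list):
        prior_theta = tuple(prior_theta)
    return MotifFit(
        model_kind=meta["model_kind"], K=meta["K"],
        omega=omega_df.to_numpy(), theta=theta_df.to_numpy(),
        loglik_trace=np.empty(0), log_bf=meta["log_bf"], seed=meta["seed"],
        converged=meta["converged"], prior_omega=meta["prior_omega"],
        prior_theta=prior_theta, free_omega=meta.get("free_omega", True),
        row_ids=[str(i) for i in omega_df.index],
        col_ids=[str(c) for c in theta_df.columns],
    )
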