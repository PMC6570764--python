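"""Community null models and observed-vs-null Bayes-factor comparison.

Four classic randomizations of a site-by-species matrix, matching the
community-ecology conventions the names denote:

frequency
    shuffle entries within each column — species occurrence frequencies
    (column multisets) are preserved, site richness is not;
richness
    shuffle entries within each row — site totals/richness (row
    multisets) are preserved, species frequencies are not;
independentswap / trialswap
    repeated 2x2 checkerboard submatrix swaps: for cells (i, j), (k, l)
    occupied and (i, l), (k, j) empty, move the values across the
    diagonal. On binary matrices this preserves BOTH row and column
    sums. ``independentswap`` counts successful swaps, ``trialswap``
    counts attempted ones.

The significance procedure refits the grade-of-membership model at a
fixed K on many permuted matrices and compares the observed fit's
approximate log Bayes factor with the resulting null distribution, via
an empirical tail probability and a Mann-Whitney U test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gom
from .matrices import CountMatrix, LabelledMatrix, PresenceMatrix

__all__ = [
    "NULL_METHODS",
    "NullEnsemble",
    "NullComparison",
    "permute_matrix",
    "null_bf_distribution",
    "compare_to_null",
]

NULL_METHODS = ("frequency", "richness", "independentswap", "trialswap")

# Separation between replicate seed streams; child restart seeds within a
# replicate are replicate_seed + restart_index, so streams never collide for
# any realistic number of restarts.
_SEED_STRIDE = 100_003


@dataclass
class NullEnsemble:
    """Null log-Bayes-factor distribution for one method and K."""

    method: str
    n_replicates: int
    log_bf: np.ndarray
    K: int
    seed: int
    binarized: bool = False
    failed_replicates: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in NULL_METHODS:
            raise ValueError(f"unknown null method {self.method!r}")
        self.log_bf = np.asarray(self.log_bf, dtype=float)
        if self.log_bf.size != self.n_replicates:
            raise ValueError("log_bf length must equal n_replicates")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "replicate": np.arange(self.n_replicates),
            "seed": self.seed + _SEED_STRIDE * np.arange(self.n_replicates),
            "log_bf": self.log_bf,
        }).to_csv(d / "null_bf.csv", index=False)
        meta = {
            "method": self.method, "K": self.K, "seed": self.seed,
            "n_replicates": self.n_replicates, "binarized": self.binarized,
            "failed_replicates": self.failed_replicates,
        }
        (d / "ensemble.json").write_text(json.dumps(meta, indent=2))


def permute_matrix(
    m: LabelledMatrix,
    method: str,
    n_swaps: int | None = None,
    seed: int | None = 0,
) -> LabelledMatrix:
    """Randomize a community matrix under one of the four null models.

    ``n_swaps`` applies to the swap methods only: attempted moves for
    ``trialswap``, successful moves for ``independentswap``; the default
    is 10x the number of occupied cells. If the matrix admits no
    checkerboard unit the input is returned unchanged with a warning.
    """
    if method not in NULL_METHODS:
        raise ValueError(f"unknown null method {method!r}; choose from {NULL_METHODS}")
    rng = np.random.default_rng(seed)
    vals = m.values.copy()

    if method == "frequency":
        for j in range(vals.shape[1]):
            vals[:, j] = rng.permutation(vals[:, j])
    elif method == "richness":
        for i in range(vals.shape[0]):
            vals[i, :] = rng.permutation(vals[i, :])
    else:
        vals = _checkerboard_swaps(vals, method, n_swaps, rng)

    # Row/column shuffles can strand an all-zero row, which the containers
    # reject; re-draw those rows from the same conserved multiset cannot help
    # (the multiset IS all zeros only if the input row was), so only the
    # frequency method can produce one — re-permute until every row is alive.
    if method == "frequency":
        tries = 0
        while (vals.sum(axis=1) == 0).any():
            tries += 1
            if tries > 1000:
                raise RuntimeError("frequency null could not avoid an all-zero row")
            for j in range(vals.shape[1]):
                vals[:, j] = rng.permutation(vals[:, j])
    return type(m)(vals, list(m.row_ids), list(m.col_ids))


def _checkerboard_swaps(
    vals: np.ndarray, method: str, n_swaps: int | None, rng: np.random.Generator
) -> np.ndarray:
    occupied = int((vals > 0).sum())
    if n_swaps is None:
        n_swaps = 10 * occupied
    n_rows, n_cols = vals.shape
    if n_rows < 2 or n_cols < 2:
        warnings.warn("matrix too small for checkerboard swaps; returned unchanged")
        return vals
    successes = 0
    attempts = 0
    # trialswap: fixed number of attempts; independentswap: fixed number of
    # successes, with an attempt cap so swap-free matrices terminate.
    max_attempts = n_swaps if method == "trialswap" else max(1000, 200 * n_swaps)
    while attempts < max_attempts:
        attempts += 1
        i, k = rng.choice(n_rows, size=2, replace=False)
        j, l = rng.choice(n_cols, size=2, replace=False)
        if vals[i, j] > 0 and vals[k, l] > 0 and vals[i, l] == 0 and vals[k, j] == 0:
            vals[i, l], vals[i, j] = vals[i, j], 0
            vals[k, j], vals[k, l] = vals[k, l], 0
            successes += 1
            if method == "independentswap" and successes >= n_swaps:
                break
    if successes == 0:
        warnings.warn(
            f"{method}: no checkerboard unit found in {attempts} attempts; "
            "matrix returned unchanged"
        )
    return vals


def null_bf_distribution(
    m: LabelledMatrix,
    K: int,
    method: str,
    n_null: int = 100,
    n_starts_per_null: int = 1,
    seed: int = 0,
    n_swaps: int | None = None,
    binarize: bool = False,
    **fit_kwargs,
) -> NullEnsemble:
    """Null distribution of log Bayes factors at fixed K.

    Each replicate permutes the matrix with its own derived seed, refits
    the model (multistart), and records the best log BF. ``binarize``
    converts counts to presence-absence before permuting, for running
    the Bernoulli model on abundance surveys. Failed replicates are
    recorded (as NaN) rather than fatal, unless every replicate fails.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    source: LabelledMatrix = m
    if binarize and not isinstance(m, PresenceMatrix):
        source = PresenceMatrix((m.values > 0).astype(int), list(m.row_ids), list(m.col_ids))
    bfs = np.full(n_null, np.nan)
    failed: list[int] = []
    for r in range(n_null):
        rep_seed = seed + _SEED_STRIDE * r
        try:
            null_m = permute_matrix(source, method, n_swaps=n_swaps, seed=rep_seed)
            fit = gom.multistart_fit(null_m, K, n_starts=n_starts_per_null,
                                     seed=rep_seed, **fit_kwargs)
            bfs[r] = fit.log_bf
        except Exception:  # noqa: BLE001 - per-replicate failure is recorded
            failed.append(r)
    if len(failed) == n_null:
        raise RuntimeError("every null replicate failed to fit")
    return NullEnsemble(
        method=method, n_replicates=n_null, log_bf=bfs, K=K, seed=seed,
        binarized=binarize, failed_replicates=failed,
    )


@dataclass
class NullComparison:
    """Observed-vs-null report: empirical tail p and Mann-Whitney U."""

    empirical_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    n_observed: int
    n_null: int
    note: str

    def to_dict(self) -> dict:
        return {
            "empirical_p": self.empirical_p,
            "mannwhitney_u": self.mannwhitney_u,
            "mannwhitney_p": self.mannwhitney_p,
            "n_observed": self.n_observed,
            "n_null": self.n_null,
            "note": self.note,
        }


def compare_to_null(observed_bfs: Sequence[float], ensemble: NullEnsemble) -> NullComparison:
    """Compare observed log Bayes factors with a null ensemble.

    The empirical p is the add-one tail probability of the WORST observed
    value, ``(1 + #{null >= min(observed)}) / (n_null + 1)``; the
    Mann-Whitney U (rank-sum with tie correction, alternative: observed
    greater) treats the observed values — typically the multistart
    spread — as a sample. Both are reported; with a single observed
    value the U test degenerates and the empirical p is the one to read.
    """
    obs = np.asarray(list(observed_bfs), dtype=float)
    null = ensemble.log_bf[~np.isnan(ensemble.log_bf)]
    if obs.size == 0 or null.size == 0:
        raise ValueError("both observed and null lists must be non-empty")
    emp_p = (1.0 + float((null >= obs.min()).sum())) / (null.size + 1.0)
    res = stats.mannwhitneyu(obs, null, alternative="greater")
    note = (
        "empirical_p: add-one tail of min(observed) in the null distribution; "
        "mannwhitney: observed list vs null list, alternative='greater'"
    )
    return NullComparison(
        empirical_p=emp_p,
        mannwhitney_u=float(res.statistic),
        mannwhitney_p=float(res.pvalue),
        n_observed=int(obs.size),
        n_null=int(null.size),
        note=note,
    )
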