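"""Consensus independent component analysis of expression matrices.

A feature-by-sample expression matrix ``E`` (n x m) is modelled as a linear
mixture of ``k`` statistically independent, non-Gaussian transcriptional
signals::

    E = S @ M

where the columns of ``S`` (n x k) are *metagenes* — each feature's
contribution to one component — and the rows of ``M`` (k x m) are the
component *weights* across samples.  Single FastICA runs suffer from sign
and order ambiguity and, for weakly expressed signals, from run-to-run
irreproducibility.  The consensus procedure therefore repeats the
decomposition ``nt`` times, each time on the matrix with one randomly
excluded sample, aligns every run to a standard run by metagene
correlation (resolving permutation and sign), and averages the aligned
metagenes.  The mean squared Pearson correlation between a component's
metagene across pairs of runs is reported as its stability R²: stable
components reappear essentially unchanged in every resampled run, while
components chasing noise scatter and score low.

The public surface follows the model/results convention: build a
:class:`ConsensusICA` from the data, call :meth:`~ConsensusICA.fit`, and
work with the returned :class:`ConsensusICAResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .matrix import ExpressionMatrix

__all__ = ["ConsensusICA", "ConsensusICAResults", "RunResult",
           "run_single_ica", "project_weights", "match_components",
           "consensus_decompose"]


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def project_weights(S: np.ndarray | pd.DataFrame,
                    E_centred: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Least-squares weights ``W`` minimising ``||E_centred - S @ W||_F``.

    Used to complete each run's weight matrix for all samples (every run
    sees the matrix minus one sample) and to derive the consensus ``M``
    from the consensus metagenes, which keeps ``S @ M`` an actual
    least-squares reconstruction of the centred data.

    Raises on a rank-deficient metagene matrix.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(E_centred, dtype=float)
    W, _, rank, _ = np.linalg.lstsq(S, X, rcond=None)
    if rank < S.shape[1]:
        raise ValueError(f"metagene matrix is rank deficient (rank {rank} < {S.shape[1]})")
    return W


def match_components(S_std: np.ndarray, S_run: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve ICA's permutation and sign ambiguity against a standard run.

    Greedily assigns run components to standard components in descending
    order of absolute metagene Pearson correlation (ties broken by lower
    component index), and returns signs making every matched correlation
    positive.

    Returns
    -------
    perm : int array, ``perm[i]`` = run column matched to standard column i
    signs : +/-1 array aligned with ``perm``
    """
    S_std = np.asarray(S_std, dtype=float)
    S_run = np.asarray(S_run, dtype=float)
    if S_std.shape[0] != S_run.shape[0] or S_std.shape[1] > S_run.shape[1]:
        raise ValueError("run matrix must have same rows and at least as "
                         "many columns as the standard")
    k = S_std.shape[1]
    # corr[i, j] = Pearson r between standard metagene i and run metagene j
    A = S_std - S_std.mean(axis=0)
    B = S_run - S_run.mean(axis=0)
    A /= np.linalg.norm(A, axis=0)
    B /= np.linalg.norm(B, axis=0)
    corr = A.T @ B

    perm = np.full(k, -1, dtype=int)
    signs = np.ones(k)
    absC = np.abs(corr).copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(absC), absC.shape)
        perm[i] = j
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
        absC[i, :] = -np.inf
        absC[:, j] = -np.inf
    return perm, signs


@dataclass
class RunResult:
    """One resampled FastICA run: metagenes, completed weights, bookkeeping."""

    S_run: np.ndarray            # n x k, columns unit sd
    M_run: np.ndarray            # k x m, weights completed for all samples
    excluded_sample: str | None  # sample left out of this run
    converged: bool


def _fastica_sources(X: np.ndarray, k: int, seed: int, *, fun: str,
                     tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """FastICA source matrix (features as observations), unit-sd columns.

    Sources are read out as uncentred projections ``X @ components_.T``
    rather than FastICA's internally re-centred scores: the two differ only
    by a scalar shift per component, but the uncentred form keeps every
    metagene inside the column space of the data, so ``S @ M`` plus the
    per-feature offsets reconstructs rank-k data exactly.
    """
    est = FastICA(n_components=k, algorithm="parallel", fun=fun,
                  whiten="unit-variance", whiten_solver="svd",
                  tol=tol, max_iter=max_iter, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X)
    converged = est.n_iter_ < max_iter
    S = X @ est.components_.T
    S = S / S.std(axis=0, ddof=0)
    return S, converged


def run_single_ica(E: ExpressionMatrix | pd.DataFrame, k: int, seed: int,
                   *, fun: str = "logcosh", tol: float = 1e-6,
                   max_iter: int = 1000) -> RunResult:
    """One FastICA decomposition of a feature-centred expression matrix.

    Deterministic given ``seed``.  ``S_run @ M_run`` reconstructs the
    centred matrix up to the unexplained subspace; weights are obtained by
    least-squares projection onto the extracted metagenes.
    """
    data = E.data if isinstance(E, ExpressionMatrix) else E
    if isinstance(E, ExpressionMatrix) and E.scale == "raw_count":
        raise ValueError("decompose log-like values, not raw counts")
    X = data.to_numpy(dtype=float)
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m) = {min(n, m)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    S, converged = _fastica_sources(Xc, k, seed, fun=fun, tol=tol,
                                    max_iter=max_iter)
    M = project_weights(S, Xc)
    return RunResult(S_run=S, M_run=M, excluded_sample=None, converged=converged)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ConsensusICA:
    """Consensus ICA model for a feature-by-sample expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix or DataFrame
        Log-like expression values, features in rows.
    n_components : int
        Number of components ``k`` to extract (``k < min(n, m - 1)``).
    n_runs : int
        Number of resampled runs ``nt`` (>= 2).  Each run excludes one
        uniformly drawn sample (with replacement across runs).
    fun, tol, max_iter : FastICA contrast and convergence settings.
    standard_run : "first" or "best"
        Which converged run anchors the alignment; "best" picks the run
        with the highest mean absolute matched correlation to all others.
    component_prefix : str
        Component naming, e.g. "RIC" for mRNA or "MIC" for miRNA layers.
    """

    def __init__(self, data: ExpressionMatrix | pd.DataFrame, n_components: int,
                 n_runs: int = 100, *, fun: str = "logcosh", tol: float = 1e-6,
                 max_iter: int = 1000, standard_run: str = "first",
                 component_prefix: str = "IC",
                 discard_nonconverged: bool = False):
        if isinstance(data, ExpressionMatrix):
            if data.scale == "raw_count":
                raise ValueError("decompose log-like values, not raw counts; "
                                 "apply log_transform first")
            self.data = data.data
        else:
            self.data = pd.DataFrame(data)
        n, m = self.data.shape
        if n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if n_components >= min(n, m - 1):
            raise ValueError(f"n_components={n_components} must be < min(n, m-1)")
        if standard_run not in ("first", "best"):
            raise ValueError("standard_run must be 'first' or 'best'")
        self.n_components = n_components
        self.n_runs = n_runs
        self.fun = fun
        self.tol = tol
        self.max_iter = max_iter
        self.standard_run = standard_run
        self.component_prefix = component_prefix
        self.discard_nonconverged = discard_nonconverged

    def fit(self, seed: int = 0, n_jobs: int = 1) -> "ConsensusICAResults":
        """Run the consensus decomposition.

        The result is a pure function of ``(data, settings, seed)``:
        per-run seeds and excluded samples are all derived from ``seed``
        up front, so parallel execution (``n_jobs``) returns bitwise the
        same result as sequential execution.
        """
        X = self.data.to_numpy(dtype=float)
        n, m = X.shape
        k, nt = self.n_components, self.n_runs
        row_means = X.mean(axis=1)
        Xc = X - row_means[:, None]

        root = np.random.SeedSequence(seed)
        excl_ss, run_ss = root.spawn(2)
        excluded = np.random.default_rng(excl_ss).integers(0, m, size=nt)
        run_seeds = [int(s.generate_state(1)[0] >> 1) for s in run_ss.spawn(nt)]

        def one_run(j: int, rs: int) -> tuple[np.ndarray, bool]:
            Xr = np.delete(Xc, j, axis=1)
            Xr = Xr - Xr.mean(axis=1, keepdims=True)
            return _fastica_sources(Xr, k, rs, fun=self.fun, tol=self.tol,
                                    max_iter=self.max_iter)

        runs = Parallel(n_jobs=n_jobs)(
            delayed(one_run)(int(j), rs) for j, rs in zip(excluded, run_seeds))

        converged_flags = [c for _, c in runs]
        if self.discard_nonconverged:
            kept = [S for S, c in runs if c]
            if len(kept) < nt / 2:
                raise RuntimeError(
                    f"only {len(kept)}/{nt} runs converged; decomposition aborted")
        else:
            # runs stopped at max_iter are still valid decompositions;
            # their scatter is what the stability index measures
            kept = [S for S, _ in runs]

        std_idx = 0 if self.standard_run == "first" else _best_standard(kept)
        S_std = kept[std_idx]
        aligned = []
        for S_run in kept:
            perm, signs = match_components(S_std, S_run)
            aligned.append(S_run[:, perm] * signs)

        S_mean = np.mean(aligned, axis=0)
        sd = S_mean.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise RuntimeError("degenerate consensus metagene (zero variance)")
        S_cons = S_mean / sd
        M_cons = project_weights(S_cons, Xc)
        stab = _pairwise_stability(aligned)

        comp_ids = [f"{self.component_prefix}{i + 1}" for i in range(k)]
        return ConsensusICAResults(
            metagenes=pd.DataFrame(S_cons, index=self.data.index, columns=comp_ids),
            weights=pd.DataFrame(M_cons, index=comp_ids, columns=self.data.columns),
            stability=pd.Series(stab, index=comp_ids, name="stability_r2"),
            row_offsets=pd.Series(row_means, index=self.data.index, name="offset"),
            k=k, nt=nt, seed=seed,
            n_converged=int(sum(converged_flags)),
            excluded_samples=[str(self.data.columns[j]) for j in excluded],
            model=self,
        )


def _pairwise_stability(aligned: list[np.ndarray]) -> np.ndarray:
    """Per-component stability R²: mean squared Pearson correlation between
    the component's metagene in every pair of aligned runs.

    Computed from the Gram matrix of centred unit-norm run metagenes, so the
    cost is O(nt² · n) per component without forming all pairs explicitly.
    """
    R = len(aligned)
    if R < 2:
        return np.ones(aligned[0].shape[1])
    k = aligned[0].shape[1]
    stab = np.empty(k)
    for c in range(k):
        V = np.column_stack([A[:, c] for A in aligned])   # n x R
        V = V - V.mean(axis=0)
        V /= np.linalg.norm(V, axis=0)
        G = V.T @ V
        stab[c] = (np.sum(G * G) - R) / (R * (R - 1))
    return np.clip(stab, 0.0, 1.0)


def _best_standard(kept: list[np.ndarray]) -> int:
    """Index of the run with highest mean |matched r| to all other runs."""
    scores = []
    for i, S_i in enumerate(kept):
        total = 0.0
        for j, S_j in enumerate(kept):
            if i == j:
                continue
            perm, signs = match_components(S_i, S_j)
            A = (S_i - S_i.mean(axis=0))
            A /= np.linalg.norm(A, axis=0)
            B = S_j[:, perm] * signs
            B = B - B.mean(axis=0)
            B /= np.linalg.norm(B, axis=0)
            total += np.abs(np.sum(A * B, axis=0)).mean()
        scores.append(total)
    return int(np.argmax(scores))


class ConsensusICAResults:
    """Fitted consensus decomposition: ``E ~ S @ M + per-feature offsets``.

    Attributes
    ----------
    metagenes : DataFrame, features x k — consensus ``S``, unit-sd columns.
    weights : DataFrame, k x samples — consensus ``M``.
    stability : Series — per-component R² in [0, 1].
    row_offsets : Series — per-feature centring offsets removed before ICA.
    k, nt, seed : decomposition provenance.
    """

    def __init__(self, metagenes: pd.DataFrame, weights: pd.DataFrame,
                 stability: pd.Series, row_offsets: pd.Series, k: int,
                 nt: int, seed: int, n_converged: int,
                 excluded_samples: list[str] | None = None, model=None):
        self.metagenes = metagenes
        self.weights = weights
        self.stability = stability
        self.row_offsets = row_offsets
        self.k = k
        self.nt = nt
        self.seed = seed
        self.n_converged = n_converged
        self.excluded_samples = excluded_samples or []
        self.model = model

    # -- basic accessors --------------------------------------------------
    @property
    def component_ids(self) -> list[str]:
        return list(self.metagenes.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.metagenes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.weights.columns)

    # -- operations --------------------------------------------------------
    def reconstruct(self) -> ExpressionMatrix:
        """``S @ M`` plus the stored per-feature offsets."""
        values = self.metagenes.to_numpy() @ self.weights.to_numpy()
        values = values + self.row_offsets.to_numpy()[:, None]
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.feature_ids, columns=self.sample_ids),
            scale="log2")

    def project(self, E_new: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        """Weights of new samples on the fitted metagenes.

        New columns are centred with the *training* per-feature offsets and
        projected onto ``S`` by least squares over the shared features.
        """
        data = E_new.data if isinstance(E_new, ExpressionMatrix) else E_new
        shared = [f for f in self.feature_ids if f in set(data.index)]
        if len(shared) < self.k:
            raise ValueError("fewer shared features than components")
        Xc = (data.loc[shared].to_numpy(dtype=float)
              - self.row_offsets.loc[shared].to_numpy()[:, None])
        W = project_weights(self.metagenes.loc[shared].to_numpy(), Xc)
        return pd.DataFrame(W, index=self.component_ids, columns=data.columns)

    def flip(self, component_ids: list[str]) -> "ConsensusICAResults":
        """Return a copy with the given components' metagene columns and
        weight rows negated; ``S @ M`` is unchanged."""
        S = self.metagenes.copy()
        M = self.weights.copy()
        S.loc[:, component_ids] *= -1.0
        M.loc[component_ids, :] *= -1.0
        return ConsensusICAResults(S, M, self.stability.copy(),
                                   self.row_offsets, self.k, self.nt,
                                   self.seed, self.n_converged,
                                   list(self.excluded_samples), self.model)

    def summary(self) -> str:
        """Text summary in the spirit of a fitted-model report."""
        lines = [
            "Consensus ICA decomposition",
            "=" * 60,
            f"features: {len(self.feature_ids)}   samples: {len(self.sample_ids)}",
            f"components (k): {self.k}   runs (nt): {self.nt}   seed: {self.seed}",
            f"converged runs: {self.n_converged}/{self.nt}",
            "-" * 60,
            f"{'component':<12}{'stability R2':>14}",
        ]
        for cid in self.component_ids:
            lines.append(f"{cid:<12}{self.stability[cid]:>14.4f}")
        lines.append("-" * 60)
        lines.append(f"mean stability: {self.stability.mean():.4f}   "
                     f"components with R2 > 0.5: {(self.stability > 0.5).sum()}")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------
    def save(self, directory) -> None:
        """Write S.tsv / M.tsv / stability.tsv / offsets.tsv + meta.json."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.metagenes.to_csv(d / "S.tsv", sep="\t", index_label="feature_id")
        self.weights.to_csv(d / "M.tsv", sep="\t", index_label="component_id")
        self.stability.to_frame().to_csv(d / "stability.tsv", sep="\t",
                                         index_label="component_id")
        self.row_offsets.to_frame().to_csv(d / "offsets.tsv", sep="\t",
                                           index_label="feature_id")
        meta = {"k": self.k, "nt": self.nt, "seed": self.seed,
                "n_converged": self.n_converged,
                "excluded_samples": self.excluded_samples}
        (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory) -> "ConsensusICAResults":
        d = Path(directory)
        S = pd.read_csv(d / "S.tsv", sep="\t", index_col=0)
        M = pd.read_csv(d / "M.tsv", sep="\t", index_col=0)
        stab = pd.read_csv(d / "stability.tsv", sep="\t", index_col=0).iloc[:, 0]
        stab.name = "stability_r2"
        offsets = pd.read_csv(d / "offsets.tsv", sep="\t", index_col=0).iloc[:, 0]
        offsets.name = "offset"
        meta = json.loads((d / "meta.json").read_text())
        return cls(S, M, stab, offsets, meta["k"], meta["nt"], meta["seed"],
                   meta["n_converged"], meta.get("excluded_samples"))


def consensus_decompose(E: ExpressionMatrix | pd.DataFrame, k: int, nt: int,
                        seed: int = 0, n_jobs: int = 1,
                        **kwargs) -> ConsensusICAResults:
    """Functional one-call wrapper around ``ConsensusICA(...).fit(...)``."""
    return ConsensusICA(E, n_components=k, n_runs=nt, **kwargs).fit(
        seed=seed, n_jobs=n_jobs)
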