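"""Ground-truth generators for testing the deconvolution pipeline.

The decomposition model assumes a bulk expression matrix is a linear mixture
of a small number of statistically independent, super-Gaussian source
signals: ``E = S_true @ M_true + noise (+ batch offsets)``.  The generators
here produce exactly that structure with known ``S_true`` and ``M_true``, so
recovery, stability, batch-isolation, survival and classification behaviour
can all be measured against the truth.

Everything is deterministic given the scenario seed; ground-truth matrices
are returned (and written) alongside the mixture so tests never re-derive
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["SyntheticScenario", "simulate_mixture", "simulate_survival",
           "simulate_labels"]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic mixing experiment.

    Defaults describe the reference benchmark used throughout the test
    suite: 5 Laplace sources over 2000 features mixed into 100 samples with
    additive Gaussian noise of sd 0.1 and no batch structure.

    Attributes
    ----------
    n_features, n_samples, k_true : int
        Matrix dimensions and true source count (``k_true < min(n, m)``).
    source_family : str
        ``laplace`` (scale 1; simplest super-Gaussian, ICA-identifiable) or
        ``sparse_spike`` (mostly zero with a few large positive loadings,
        mimicking cell-type marker metagenes).
    sparsity : float
        Fraction of non-zero loadings for ``sparse_spike`` sources.
    mixing_sd : float
        Mixing weights are drawn i.i.d. N(0, mixing_sd^2).
    noise_sd : float
        Additive Gaussian observation noise.
    batch_samples : int
        Size of the trailing "investigation" block receiving a per-feature
        additive offset (0 = no batch structure).
    batch_offset_sd : float
        Scale of the per-feature offsets.  Offsets are drawn from a Laplace
        distribution: a Gaussian offset profile would be the one source
        family ICA cannot isolate, and the batch scenario exists precisely
        to test that the offset is recoverable as a component.
    seed : int
        Root seed; all randomness is derived from it.
    """

    n_features: int = 2000
    n_samples: int = 100
    k_true: int = 5
    source_family: str = "laplace"
    sparsity: float = 0.05
    mixing_sd: float = 1.0
    noise_sd: float = 0.1
    batch_samples: int = 0
    batch_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true >= min(self.n_features, self.n_samples):
            raise ValueError("k_true must be < min(n_features, n_samples)")
        if self.source_family not in ("laplace", "sparse_spike"):
            raise ValueError(f"unknown source family {self.source_family!r}")
        if self.batch_samples >= self.n_samples:
            raise ValueError("batch block must be smaller than the sample count")


def _draw_sources(scn: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    n, k = scn.n_features, scn.k_true
    if scn.source_family == "laplace":
        return rng.laplace(loc=0.0, scale=1.0, size=(n, k))
    # sparse spikes: a few large positive loadings on a near-zero background
    S = rng.normal(0.0, 0.05, size=(n, k))
    for j in range(k):
        idx = rng.choice(n, size=max(1, int(scn.sparsity * n)), replace=False)
        S[idx, j] += rng.exponential(scale=3.0, size=idx.size)
    return S


def simulate_mixture(scn: SyntheticScenario
                     ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``E = S_true @ M_true + noise + batch offsets``.

    Returns
    -------
    E : ExpressionMatrix (scale ``log2`` — values are treated as already
        log-like, matching what the decomposition consumes)
    S_true : DataFrame, features x k_true source loadings
    M_true : DataFrame, k_true x samples mixing weights
    batches : DataFrame (sample_id, batch) — ``discovery`` for the leading
        block, ``investigation`` for the offset block (all discovery when
        ``batch_samples == 0``)
    """
    root = np.random.SeedSequence(scn.seed)
    rng_s, rng_m, rng_e, rng_b = (np.random.default_rng(s) for s in root.spawn(4))

    S = _draw_sources(scn, rng_s)
    M = rng_m.normal(0.0, scn.mixing_sd, size=(scn.k_true, scn.n_samples))
    E = S @ M
    if scn.noise_sd > 0:
        E = E + rng_e.normal(0.0, scn.noise_sd, size=E.shape)

    batch = np.array(["discovery"] * scn.n_samples, dtype=object)
    if scn.batch_samples > 0:
        batch[-scn.batch_samples:] = "investigation"
        if scn.batch_offset_sd > 0:
            # Laplace offsets, sd = batch_offset_sd (Laplace sd = scale*sqrt(2))
            offsets = rng_b.laplace(0.0, scn.batch_offset_sd / np.sqrt(2.0),
                                    size=scn.n_features)
            E[:, -scn.batch_samples:] += offsets[:, None]

    features = [f"g{i + 1}" for i in range(scn.n_features)]
    samples = [f"s{j + 1}" for j in range(scn.n_samples)]
    comps = [f"src{c + 1}" for c in range(scn.k_true)]
    Em = ExpressionMatrix(pd.DataFrame(E, index=features, columns=samples),
                          scale="log2")
    S_df = pd.DataFrame(S, index=features, columns=comps)
    M_df = pd.DataFrame(M, index=comps, columns=samples)
    batches = pd.DataFrame({"sample_id": samples, "batch": batch})
    return Em, S_df, M_df, batches


def _calibrate_cens_horizon(times: np.ndarray, censor_frac: float) -> float:
    """Bisection for the uniform-censoring horizon T_max.

    With C ~ U(0, T_max) the expected censored fraction is
    mean_i min(t_i / T_max, 1); solve for the requested fraction.
    """
    lo, hi = 1e-9, float(times.max()) * 1e6

    def frac(tmax: float) -> float:
        return float(np.mean(np.minimum(times / tmax, 1.0)))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(M_true: pd.DataFrame, driver: str | int, beta: float,
                      baseline: float = 0.01, censor_frac: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival driven by one component's weights.

    Event times are exponential with hazard ``baseline * exp(beta * w*)``
    where ``w*`` is the driver weight row standardised to zero mean / unit
    sd.  Censoring is independent uniform on (0, T_max) with T_max
    calibrated by bisection so the expected censored fraction matches
    ``censor_frac``.

    Returns a DataFrame with columns sample_id, time, event.
    """
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    row = M_true.iloc[driver] if isinstance(driver, int) else M_true.loc[driver]
    w = row.to_numpy(dtype=float)
    sd = w.std(ddof=0)
    if sd == 0:
        raise ValueError("driver weight row is constant")
    w_std = (w - w.mean()) / sd

    root = np.random.SeedSequence(seed)
    rng_t, rng_c = (np.random.default_rng(s) for s in root.spawn(2))
    hazard = baseline * np.exp(beta * w_std)
    times = rng_t.exponential(1.0 / hazard)

    if censor_frac == 0:
        observed, event = times, np.ones(times.size, dtype=int)
    else:
        tmax = _calibrate_cens_horizon(times, censor_frac)
        cens = rng_c.uniform(0.0, tmax, size=times.size)
        event = (times <= cens).astype(int)
        observed = np.minimum(times, cens)

    return pd.DataFrame({"sample_id": list(M_true.columns),
                         "time": observed, "event": event})


def simulate_labels(M_true: pd.DataFrame, driver: str | int,
                    rule: str = "sign", noise: float = 0.0,
                    seed: int = 0) -> pd.Series:
    """Class labels deterministically driven by one component's weights.

    ``sign`` splits at zero into ``lo``/``hi``; ``tertile`` cuts the weight
    distribution into three equal-frequency classes ``low``/``mid``/``high``.
    ``noise`` is the fraction of labels replaced by a uniform random class.
    """
    if rule not in ("sign", "tertile"):
        raise ValueError(f"unknown rule {rule!r}")
    row = M_true.iloc[driver] if isinstance(driver, int) else M_true.loc[driver]
    w = row.to_numpy(dtype=float)
    if rule == "sign":
        labels = np.where(w > 0, "hi", "lo").astype(object)
        classes = np.array(["lo", "hi"], dtype=object)
    else:
        ranks = np.argsort(np.argsort(w))
        thirds = (ranks * 3) // w.size
        labels = np.array(["low", "mid", "high"], dtype=object)[thirds]
        classes = np.array(["low", "mid", "high"], dtype=object)
    if noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(w.size) < noise
        labels[flip] = rng.choice(classes, size=int(flip.sum()))
    return pd.Series(labels, index=M_true.columns, name="label")
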