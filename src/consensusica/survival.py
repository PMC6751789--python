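"""Linking component weights to clinical outcomes.

Two uses of the fitted decomposition are covered here.

*Survival.*  Each component's weight row is screened with a univariable Cox
proportional-hazards fit on standardised weights; significance is taken
from the score (log-rank) test and BH-adjusted across components.  The
significant components are combined into a per-sample risk score

    RS_j = sum_i  H_i * R2_i * M*_ij

where H_i is the component's log-hazard ratio (set to 0 when the adjusted
p-value fails the threshold), R2_i its stability, and M*_ij its weight in
sample j standardised with the *discovery* mean and sd.  Freezing the
standardisation at training time lets the same score be applied to a
validation cohort without leakage.

*Classification.*  Component weights serve as features for a random-forest
classifier (leave-one-out cross-validated), and a nested cross-validation
over candidate component counts chooses k by classification accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .ica import ConsensusICA, ConsensusICAResults
from .matrix import ExpressionMatrix
from .signatures import benjamini_hochberg

__all__ = ["ComponentCoxScreen", "ComponentCoxResults", "RiskScoreModel",
           "cox_score_test", "cox_per_component", "build_risk_score",
           "score_samples", "classify_and_validate", "select_num_components",
           "read_clinical_tsv"]


def read_clinical_tsv(path) -> pd.DataFrame:
    """Clinical table: sample_id, time, event, plus arbitrary label columns."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def cox_score_test(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Score (log-rank) test p-value for a single covariate Cox model.

    Evaluates the partial-likelihood score at beta = 0 with Breslow
    handling of ties: over distinct event times, U accumulates the
    difference between the covariate sum of the deaths and the risk-set
    mean, and V the risk-set covariate variance.  U^2 / V is chi-squared
    with 1 df under the null — for a single covariate this is the log-rank
    trend test reported by standard survival software.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    n = len(x)
    U = 0.0
    V = 0.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        deaths = [idx for idx in range(i, j) if event[idx] == 1]
        if deaths:
            risk = x[i:]                      # risk set: time >= t
            m1 = risk.mean()
            m2 = (risk ** 2).mean()
            d = len(deaths)
            U += x[deaths].sum() - d * m1
            V += d * (m2 - m1 ** 2)
        i = j
    if V <= 0:
        return 1.0
    return float(stats.chi2.sf(U * U / V, df=1))


@dataclass
class ComponentCoxResults:
    """Per-component survival screen plus what is needed to build Eq.-style
    risk scores: the discovery standardisation and component stability."""

    table: pd.DataFrame          # index component; columns LHR, p, adj_p
    standardisation: pd.DataFrame  # index component; columns mean, sd
    stability: pd.Series
    alpha_default: float = 0.05

    def summary(self) -> str:
        lines = ["Per-component Cox survival screen",
                 "=" * 60,
                 f"{'component':<12}{'LHR':>10}{'p':>12}{'adj_p':>12}"]
        for cid, row in self.table.iterrows():
            lines.append(f"{cid:<12}{row.LHR:>10.4f}{row.p:>12.3e}{row.adj_p:>12.3e}")
        sig = (self.table["adj_p"] < self.alpha_default).sum()
        lines.append("-" * 60)
        lines.append(f"significant at adj_p < {self.alpha_default}: {sig}/{len(self.table)}")
        return "\n".join(lines)

    def risk_score(self, alpha: float = 0.05) -> "RiskScoreModel":
        """Risk-score model: H_i = LHR_i where adj_p < alpha, else 0."""
        H = np.where(self.table["adj_p"].to_numpy() < alpha,
                     self.table["LHR"].to_numpy(), 0.0)
        return RiskScoreModel(
            component_ids=list(self.table.index),
            H=H.tolist(),
            stability=self.stability.reindex(self.table.index).to_numpy().tolist(),
            mean=self.standardisation["mean"].to_numpy().tolist(),
            sd=self.standardisation["sd"].to_numpy().tolist(),
            alpha=alpha,
        )


class ComponentCoxScreen:
    """Univariable Cox screen of every component weight row.

    Parameters
    ----------
    results : ConsensusICAResults (or a k x m weight DataFrame together
        with a stability Series via ``weights=``/``stability=``)
    survival : DataFrame with columns sample_id, time, event.
    """

    def __init__(self, results: ConsensusICAResults | None = None,
                 survival: pd.DataFrame | None = None, *,
                 weights: pd.DataFrame | None = None,
                 stability: pd.Series | None = None):
        if results is not None:
            weights = results.weights
            stability = results.stability
        if weights is None or survival is None:
            raise ValueError("need a decomposition (or weights) and survival data")
        surv = survival.set_index(survival["sample_id"].astype(str))
        shared = [s for s in weights.columns if s in set(surv.index)]
        if len(shared) < 3:
            raise ValueError("fewer than 3 samples with survival data")
        self.weights = weights[shared]
        self.time = surv.loc[shared, "time"].to_numpy(dtype=float)
        self.event = surv.loc[shared, "event"].to_numpy(dtype=int)
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if self.event.sum() < 2:
            raise ValueError("fewer than 2 observed events; Cox screen undefined")
        self.stability = (stability if stability is not None
                          else pd.Series(1.0, index=weights.index))

    def fit(self) -> ComponentCoxResults:
        rows = []
        std_rows = []
        for cid in self.weights.index:
            w = self.weights.loc[cid].to_numpy(dtype=float)
            mu, sd = w.mean(), w.std(ddof=0)
            if sd == 0:
                raise ValueError(f"constant weight row {cid}")
            w_std = (w - mu) / sd
            df = pd.DataFrame({"w": w_std, "time": self.time, "event": self.event})
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            lhr = float(cph.params_["w"])
            p = cox_score_test(w_std, self.time, self.event)
            rows.append((cid, lhr, p))
            std_rows.append((cid, mu, sd))
        table = pd.DataFrame(rows, columns=["component", "LHR", "p"]
                             ).set_index("component")
        table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
        std = pd.DataFrame(std_rows, columns=["component", "mean", "sd"]
                           ).set_index("component")
        return ComponentCoxResults(table=table, standardisation=std,
                                   stability=self.stability)


def cox_per_component(results: ConsensusICAResults,
                      survival: pd.DataFrame) -> ComponentCoxResults:
    """Functional wrapper: ``ComponentCoxScreen(results, survival).fit()``."""
    return ComponentCoxScreen(results, survival).fit()


@dataclass
class RiskScoreModel:
    """Frozen risk-score model: RS = sum_i H_i * R2_i * standardised weight.

    ``H`` is zero for components whose BH-adjusted log-rank p failed the
    threshold, so an all-null screen scores every sample 0.  Mean/sd are
    the discovery-cohort weight statistics and are *not* recomputed when
    scoring new cohorts.
    """

    component_ids: list[str]
    H: list[float]
    stability: list[float]
    mean: list[float]
    sd: list[float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for h, s in zip(self.H, self.sd):
            if h != 0 and s <= 0:
                raise ValueError("retained component has non-positive sd")

    @property
    def significant_components(self) -> list[str]:
        return [c for c, h in zip(self.component_ids, self.H) if h != 0]

    def score(self, M_new: pd.DataFrame) -> pd.Series:
        """Risk score of each column (sample) of a weight matrix."""
        missing = [c for c in self.component_ids if c not in M_new.index]
        if missing:
            raise ValueError(f"weight matrix lacks components: {missing[:5]}")
        W = M_new.loc[self.component_ids].to_numpy(dtype=float)
        mu = np.asarray(self.mean)[:, None]
        sd = np.asarray(self.sd)[:, None]
        sd = np.where(sd == 0, 1.0, sd)     # H is 0 there anyway
        W_std = (W - mu) / sd
        coef = np.asarray(self.H) * np.asarray(self.stability)
        rs = coef @ W_std
        return pd.Series(rs, index=M_new.columns, name="RS")

    # -- serialisation ----------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RiskScoreModel":
        return cls(**json.loads(Path(path).read_text()))


def build_risk_score(results: ConsensusICAResults, survival: pd.DataFrame,
                     alpha: float = 0.05) -> RiskScoreModel:
    """Screen components on the discovery cohort and freeze the risk score."""
    return cox_per_component(results, survival).risk_score(alpha=alpha)


def score_samples(model: RiskScoreModel, M_new: pd.DataFrame) -> pd.Series:
    """Apply a frozen risk-score model to new sample weights."""
    return model.score(M_new)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_and_validate(results: ConsensusICAResults | pd.DataFrame,
                          labels: pd.Series, seed: int = 0,
                          n_estimators: int = 100) -> tuple[RandomForestClassifier, dict]:
    """Random-forest classification of samples from component weights.

    Leave-one-out cross-validation on the given cohort; reports overall
    accuracy, per-class sensitivity/specificity, and per-sample vote
    fractions (class probabilities).  Returns the forest refitted on all
    samples (for predicting new cohorts) plus the report dict.
    """
    weights = results.weights if isinstance(results, ConsensusICAResults) else results
    labels = pd.Series(labels)
    shared = [s for s in weights.columns if s in set(labels.index)]
    X = weights[shared].to_numpy(dtype=float).T
    y = labels.loc[shared].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for LOOCV")

    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    proba = cross_val_predict(clf, X, y, cv=LeaveOneOut(), method="predict_proba")
    pred = classes[np.argmax(proba, axis=1)]
    accuracy = float((pred == y).mean())

    per_class = []
    for c in classes:
        tp = ((pred == c) & (y == c)).sum()
        fn = ((pred != c) & (y == c)).sum()
        tn = ((pred != c) & (y != c)).sum()
        fp = ((pred == c) & (y != c)).sum()
        per_class.append((c, tp / (tp + fn) if tp + fn else np.nan,
                          tn / (tn + fp) if tn + fp else np.nan))
    per_class = pd.DataFrame(per_class,
                             columns=["class", "sensitivity", "specificity"]
                             ).set_index("class")
    votes = pd.DataFrame(proba, index=shared, columns=classes)
    clf.fit(X, y)
    report = {"accuracy": accuracy, "per_class": per_class, "votes": votes,
              "predicted": pd.Series(pred, index=shared, name="predicted")}
    return clf, report


def select_num_components(E: ExpressionMatrix | pd.DataFrame, labels: pd.Series,
                          candidate_ks: list[int], *, nt: int = 5,
                          n_repeats: int = 3, test_frac: float = 0.2,
                          seed: int = 0, n_jobs: int = 1) -> dict:
    """Choose the component count k by nested cross-validated classification.

    For each outer repeat, 20% of samples are held out; the remaining 80%
    are decomposed at every candidate k, a forest is trained on the
    training weights, the held-out samples are projected onto the training
    metagenes and classified.  The smallest k whose mean held-out accuracy
    is within one standard error of the best is selected.
    """
    data = E.data if isinstance(E, ExpressionMatrix) else pd.DataFrame(E)
    labels = pd.Series(labels).loc[data.columns]
    candidate_ks = sorted(candidate_ks)
    m = data.shape[1]
    n_test = max(1, int(round(test_frac * m)))
    if max(candidate_ks) >= m - n_test - 1:
        raise ValueError("candidate k too large for the inner sample count")

    root = np.random.SeedSequence(seed)
    accs = np.zeros((n_repeats, len(candidate_ks)))
    for r, ss in enumerate(root.spawn(n_repeats)):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(m)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train_cols = data.columns[np.sort(train_idx)]
        test_cols = data.columns[np.sort(test_idx)]
        sub_seed = int(ss.generate_state(1)[0] >> 1)
        for c, k in enumerate(candidate_ks):
            res = ConsensusICA(data[train_cols], n_components=k, n_runs=nt
                               ).fit(seed=sub_seed, n_jobs=n_jobs)
            clf = RandomForestClassifier(n_estimators=100, random_state=sub_seed)
            clf.fit(res.weights.to_numpy().T, labels.loc[train_cols].to_numpy())
            W_test = res.project(data[test_cols])
            pred = clf.predict(W_test.to_numpy().T)
            accs[r, c] = (pred == labels.loc[test_cols].to_numpy()).mean()

    mean_acc = accs.mean(axis=0)
    se = accs.std(axis=0, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 \
        else np.zeros(len(candidate_ks))
    best = int(np.argmax(mean_acc))
    threshold = mean_acc[best] - se[best]
    chosen = next(k for k, a in zip(candidate_ks, mean_acc) if a >= threshold)
    profile = pd.DataFrame({"k": candidate_ks, "mean_accuracy": mean_acc,
                            "se": se}).set_index("k")
    return {"k": chosen, "profile": profile}
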