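"""Feature ranking and selection, MLP/LDA classifiers, per-condition
metrics, and the descriptor-range applicability domain.

Deviation features are ranked by entropy-based class discrimination
(mutual information of the binned feature against the activity label, with
the Jeffreys divergence between the class-conditional histograms as a
tie-break), then admitted greedily under a Pearson-correlation redundancy
bound with the constraint that every condition-element kind (ma, tg, ei)
contributes at least one feature.

Classifiers are a single-hidden-layer perceptron (logistic activation,
full-batch LBFGS, fixed seed; topology reportable as "MLP d-h-2") and a
closed-form linear discriminant baseline on the same features.  Fitted
weights live in a JSON-serializable bundle that performs its own forward
pass, together with the applicability domain: per-feature closed training
[min, max] ranges.  A case's TSAD is the number of its features inside
their range; it is in-domain iff TSAD equals the feature count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier

from .specs import feature_kind

# ---------------------------------------------------------------------------
# feature ranking and selection


def _class_histograms(
    x: np.ndarray, y: np.ndarray, bins: int, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(x.min(), x.max(), bins + 1)
    c_a, _ = np.histogram(x[y == 1], bins=edges)
    c_i, _ = np.histogram(x[y == -1], bins=edges)
    p = (c_a + alpha) / (c_a.sum() + alpha * bins)
    q = (c_i + alpha) / (c_i.sum() + alpha * bins)
    return p, q


def jeffreys_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized Kullback-Leibler divergence, sum((p - q) ln(p / q))."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sum((p - q) * np.log(p / q)))


def mutual_information(p: np.ndarray, q: np.ndarray, w_active: float) -> float:
    """Mutual information between the binned feature and the class label,
    from the smoothed class-conditional bin distributions and the active
    class prior."""
    priors = np.array([w_active, 1.0 - w_active])
    joint = np.vstack([p * priors[0], q * priors[1]])
    marginal = joint.sum(axis=0)
    mi = 0.0
    for c in range(2):
        for b in range(joint.shape[1]):
            if joint[c, b] > 0:
                mi += joint[c, b] * np.log(joint[c, b] / (priors[c] * marginal[b]))
    return float(max(mi, 0.0))


def rank_features(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    *,
    bins: int = 24,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Score every feature by MI-DSE (primary) and Jeffreys divergence
    (tie-break); constant features score 0.  Returns a frame sorted by
    rank with columns ``midse``, ``jeffreys``, ``rank``."""
    y = np.asarray(labels)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("ranking needs at least 2 cases per class")
    w_active = float((y == 1).mean())
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((name, 0.0, 0.0))
            continue
        p, q = _class_histograms(x, y, bins, alpha)
        rows.append((name, mutual_information(p, q, w_active), jeffreys_divergence(p, q)))
    out = pd.DataFrame(rows, columns=["feature", "midse", "jeffreys"]).set_index(
        "feature"
    )
    out = out.sort_values(["midse", "jeffreys"], ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


class SelectionError(ValueError):
    """The per-element-kind selection constraint cannot be satisfied."""


def select_features(
    ranking: pd.DataFrame,
    features: pd.DataFrame,
    *,
    pcc_bound: float = 0.7,
    target_size: int = 15,
    require_kinds: bool = True,
) -> list[str]:
    """Greedy rank-ordered selection under |PCC| < ``pcc_bound``, forcing
    at least one feature per condition-element kind when present."""
    corr = features.corr().abs()

    def admissible(name: str, chosen: list[str]) -> bool:
        return all(corr.loc[name, c] < pcc_bound for c in chosen)

    ordered = list(ranking.index)
    chosen: list[str] = []
    for name in ordered:
        if len(chosen) >= target_size:
            break
        if admissible(name, chosen):
            chosen.append(name)

    if require_kinds:
        chosen_kinds = {feature_kind(n) for n in chosen}
        missing = [k for k in ("ma", "tg", "ei") if k not in chosen_kinds]
        for kind in missing:
            candidates = [n for n in ordered if feature_kind(n) == kind and n not in chosen]
            placed = False
            for cand in candidates:
                # drop the lowest-ranked chosen feature of an over-represented
                # kind to make room, then try to admit the candidate
                for victim in reversed(chosen):
                    vk = feature_kind(victim)
                    if sum(1 for c in chosen if feature_kind(c) == vk) < 2:
                        continue
                    trial = [c for c in chosen if c != victim]
                    if admissible(cand, trial):
                        chosen = trial + [cand]
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise SelectionError(
                    f"cannot satisfy the one-feature-per-element constraint for kind {kind!r}"
                )
        chosen.sort(key=ordered.index)
    return chosen


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierBundle:
    """A trained classifier, its feature list and applicability domain.

    ``weights``/``biases`` hold the layer parameters; the bundle performs
    its own forward pass (logistic hidden units and a logistic output for
    the MLP, a logistic-calibrated linear discriminant for the LDA), so a
    JSON round-trip fully reproduces predictions.
    """

    algorithm: str  # "mlp" | "lda"
    feature_names: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_width: int
    seed: int
    ad_ranges: dict[str, tuple[float, float]]
    feature_means: dict[str, float] = field(default_factory=dict)

    @property
    def topology(self) -> str:
        d = len(self.feature_names)
        if self.algorithm == "mlp":
            return f"MLP {d}-{self.hidden_width}-2"
        return f"LDA {d}-2"

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise KeyError(f"feature columns missing: {missing}")
            return features[self.feature_names].to_numpy(dtype=float)
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        return x

    def predict_proba(self, features) -> np.ndarray:
        """Probability of the active class (IA = 1) per case."""
        x = self._matrix(features)
        if self.algorithm == "mlp":
            h = expit(x @ self.weights[0] + self.biases[0])
            return expit(h @ self.weights[1] + self.biases[1]).ravel()
        return expit(x @ self.weights[0] + self.biases[0]).ravel()

    def predict(self, features) -> np.ndarray:
        return np.where(self.predict_proba(features) >= 0.5, 1, -1)

    # -- applicability domain -------------------------------------------
    def tsad(self, features) -> np.ndarray:
        """Number of features inside their closed training [min, max]
        interval, per case."""
        x = self._matrix(features)
        lo = np.array([self.ad_ranges[f][0] for f in self.feature_names])
        hi = np.array([self.ad_ranges[f][1] for f in self.feature_names])
        return ((x >= lo) & (x <= hi)).sum(axis=1)

    def in_ad(self, features) -> np.ndarray:
        return self.tsad(features) == len(self.feature_names)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "feature_names": self.feature_names,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "hidden_width": self.hidden_width,
            "seed": self.seed,
            "ad_ranges": {k: list(v) for k, v in self.ad_ranges.items()},
            "feature_means": self.feature_means,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassifierBundle":
        return cls(
            algorithm=payload["algorithm"],
            feature_names=list(payload["feature_names"]),
            weights=[np.asarray(w) for w in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            hidden_width=int(payload["hidden_width"]),
            seed=int(payload["seed"]),
            ad_ranges={k: (float(v[0]), float(v[1])) for k, v in payload["ad_ranges"].items()},
            feature_means={k: float(v) for k, v in payload.get("feature_means", {}).items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClassifierBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ad(features: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Training [min, max] range per feature (the descriptor-space AD)."""
    return {
        name: (float(features[name].min()), float(features[name].max()))
        for name in features.columns
    }


def train_classifier(
    features: pd.DataFrame,
    labels,
    algorithm: str = "mlp",
    *,
    hidden_width: int = 45,
    seed: int = 0,
    max_iter: int = 500,
    alpha: float = 1.0,
) -> ClassifierBundle:
    """Fit an MLP (one logistic hidden layer, LBFGS, deterministic for a
    fixed seed) or an LDA baseline on the selected features, and freeze
    the training-range applicability domain into the bundle.

    ``alpha`` is the L2 weight-decay penalty on the perceptron: a wide
    hidden layer relative to the training-set size memorizes label noise
    without it, so the default is deliberately non-negligible.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if algorithm not in ("mlp", "lda"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    x = features.to_numpy(dtype=float)
    if algorithm == "mlp":
        if hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_width,),
            activation="logistic",
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
            alpha=alpha,
        )
        clf.fit(x, y)
        weights = [np.asarray(w) for w in clf.coefs_]
        biases = [np.asarray(b) for b in clf.intercepts_]
    else:
        clf = LinearDiscriminantAnalysis()
        clf.fit(x, y)
        weights = [np.asarray(clf.coef_).reshape(-1, 1)]
        biases = [np.asarray(clf.intercept_).ravel()]
    return ClassifierBundle(
        algorithm=algorithm,
        feature_names=list(features.columns),
        weights=weights,
        biases=biases,
        hidden_width=hidden_width if algorithm == "mlp" else 0,
        seed=seed,
        ad_ranges=fit_ad(features),
        feature_means={c: float(features[c].mean()) for c in features.columns},
    )


# ---------------------------------------------------------------------------
# metrics


def matthews_corrcoef_counts(tp: int, fn: int, tn: int, fp: int) -> float:
    """MCC from confusion counts; 0 when the denominator vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


@dataclass
class MetricsReport:
    n_active: int
    ccc_active: int
    n_inactive: int
    ccc_inactive: int
    local: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        if self.ccc_active > self.n_active or self.ccc_inactive > self.n_inactive:
            raise ValueError("correctly-classified counts cannot exceed class sizes")

    @property
    def sn(self) -> float:
        return 100.0 * self.ccc_active / self.n_active if self.n_active else float("nan")

    @property
    def sp(self) -> float:
        return (
            100.0 * self.ccc_inactive / self.n_inactive
            if self.n_inactive
            else float("nan")
        )

    @property
    def ac(self) -> float:
        return 100.0 * (self.ccc_active + self.ccc_inactive) / (
            self.n_active + self.n_inactive
        )

    @property
    def mcc(self) -> float:
        return matthews_corrcoef_counts(
            tp=self.ccc_active,
            fn=self.n_active - self.ccc_active,
            tn=self.ccc_inactive,
            fp=self.n_inactive - self.ccc_inactive,
        )

    def to_dict(self) -> dict:
        payload = {
            "n_active": self.n_active,
            "ccc_active": self.ccc_active,
            "n_inactive": self.n_inactive,
            "ccc_inactive": self.ccc_inactive,
            "sn_pct": self.sn,
            "sp_pct": self.sp,
            "ac_pct": self.ac,
            "mcc": self.mcc,
        }
        if self.local:
            payload["local"] = {
                kind: table.reset_index().to_dict(orient="records")
                for kind, table in self.local.items()
            }
        return payload


def metrics_from_counts(
    n_active: int, ccc_active: int, n_inactive: int, ccc_inactive: int
) -> MetricsReport:
    """Build a report directly from per-class counts (the worked-example
    path: no model involved)."""
    return MetricsReport(n_active, ccc_active, n_inactive, ccc_inactive)


def evaluate(
    bundle: ClassifierBundle,
    features: pd.DataFrame,
    labels,
    conditions: pd.DataFrame | None = None,
) -> MetricsReport:
    """Global Sn/Sp/Ac/MCC plus, when condition columns are supplied,
    local sensitivity/specificity per ma, tg and ei element value."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = bundle.predict(features)
    report = MetricsReport(
        n_active=int((y == 1).sum()),
        ccc_active=int(((y == 1) & (pred == 1)).sum()),
        n_inactive=int((y == -1).sum()),
        ccc_inactive=int(((y == -1) & (pred == -1)).sum()),
    )
    if conditions is not None:
        for kind in ("ma", "tg", "ei"):
            if kind not in conditions.columns:
                continue
            rows = []
            values = conditions[kind].to_numpy()
            for element in pd.unique(values):
                mask = values == element
                na = int((y[mask] == 1).sum())
                ni = int((y[mask] == -1).sum())
                sn = (
                    100.0 * ((y[mask] == 1) & (pred[mask] == 1)).sum() / na
                    if na
                    else np.nan
                )
                sp = (
                    100.0 * ((y[mask] == -1) & (pred[mask] == -1)).sum() / ni
                    if ni
                    else np.nan
                )
                rows.append(
                    {"element": element, "n_active": na, "n_inactive": ni, "sn_pct": sn, "sp_pct": sp}
                )
            report.local[kind] = pd.DataFrame(rows).set_index("element")
    return report
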