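"""SVM regression on window features with family-grouped cross-validation.

The predictor is an epsilon-SVR trained on real relative-accessibility
targets (0-100%).  Hyper-parameters come from a grid search over the
error/margin trade-off C (0.25-50), polynomial exponents {2, 3, 4} and
rbf gamma (0.0005-0.05); each grid point is scored by out-of-fold MCC
after the real-to-binary cutoff has itself been optimised, and the best
point is refit on all data.  Cross-validation folds are grouped by
protein family so homologous chains never straddle a train/test split.

A trained model carries its feature schema, labelling probe radius and
the optimised binary cutoff, and persists as JSON metadata plus an opaque
serialized-regressor blob.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC, SVR

from .accessibility import BurialState, binarize, DEFAULT_CUTOFF
from .errors import DomainError, MprapError, SchemaError
from .evaluation import confusion, metrics
from .features import DEFAULT_WINDOW, SLOT_WIDTH, FeatureVector, feature_matrix

DEFAULT_Z_COMBINE_CUTOFF = 12.5  # A: inside this, trust the membrane predictor
CUTOFF_LATTICE = np.arange(0.5, 100.0, 1.0)
DEFAULT_EPSILON = 0.1  # epsilon-insensitive width on the 0-100 RSA scale


@dataclass
class GridSpec:
    """Hyper-parameter grid: C 0.25-50, poly exponents {2,3,4}, rbf gamma
    0.0005-0.05 (log-spaced, density configurable)."""

    c_values: np.ndarray
    poly_exponents: tuple = (2, 3, 4)
    gamma_values: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.0005, 0.05, 8))

    def __post_init__(self):
        self.c_values = np.asarray(self.c_values, dtype=float)
        self.gamma_values = np.asarray(self.gamma_values, dtype=float)
        if (self.c_values <= 0).any() or (self.gamma_values <= 0).any():
            raise DomainError("grid values must be positive")

    @classmethod
    def default(cls, c_count: int = 16, gamma_count: int = 8) -> "GridSpec":
        # sub-sample the 0.25-step C lattice; snap back onto it
        c = np.round(np.linspace(0.25, 50.0, c_count) / 0.25) * 0.25
        return cls(c_values=np.unique(c),
                   gamma_values=np.geomspace(0.0005, 0.05, gamma_count))

    @classmethod
    def full(cls) -> "GridSpec":
        return cls(c_values=np.arange(0.25, 50.0 + 1e-9, 0.25))

    @classmethod
    def coarse(cls) -> "GridSpec":
        """Small grid for desk-scale experiments and tests."""
        return cls(c_values=np.array([5.0, 50.0]),
                   gamma_values=np.array([0.0005, 0.0015]))

    def points(self, kernel: str):
        """(C, kernel_param) pairs in deterministic order."""
        if kernel == "linear":
            return [(c, None) for c in self.c_values]
        if kernel == "polynomial":
            return [(c, int(d)) for c in self.c_values
                    for d in self.poly_exponents]
        if kernel == "rbf":
            return [(c, float(g)) for c in self.c_values
                    for g in self.gamma_values]
        raise DomainError(f"unknown kernel {kernel!r}")


@dataclass
class CvSplit:
    """Fold assignment with whole families kept together."""

    group_of: dict  # chain_key -> fold index
    family_of: dict  # chain_key -> family label
    k: int

    def __post_init__(self):
        fold_of_family: dict = {}
        for key, fold in self.group_of.items():
            fam = self.family_of[key]
            if fold_of_family.setdefault(fam, fold) != fold:
                raise MprapError(
                    f"family {fam!r} spans folds "
                    f"{fold_of_family[fam]} and {fold}")

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for fold in self.group_of.values():
            sizes[fold] += 1
        return sizes


def make_cv_split(chains, k: int = 5, seed: int = 0) -> CvSplit:
    """Assign chains to k folds, whole families together, sizes balanced.

    ``chains`` is a sequence of (chain_key, family_label).  Families are
    shuffled by the seed, then greedily placed (largest first) into the
    currently smallest fold, so fold sizes differ by at most the largest
    family size.  Deterministic for a given seed.
    """
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    families: dict = {}
    for key, fam in chains:
        families.setdefault(fam, []).append(key)
    if len(families) < k:
        raise MprapError(
            f"need at least {k} distinct families for {k} folds, "
            f"found {len(families)}")
    rng = np.random.default_rng(seed)
    fam_names = sorted(families)
    rng.shuffle(fam_names)
    fam_names.sort(key=lambda f: -len(families[f]))  # stable: keeps shuffle ties
    group_of, family_of = {}, {}
    sizes = [0] * k
    for fam in fam_names:
        fold = int(np.argmin(sizes))
        for key in families[fam]:
            group_of[key] = fold
            family_of[key] = fam
        sizes[fold] += len(families[fam])
    return CvSplit(group_of=group_of, family_of=family_of, k=k)


@dataclass
class ChainData:
    """Training/evaluation payload for one protein chain."""

    chain_key: str
    family: str
    X: np.ndarray          # (n_residues, n_features)
    y_rsa: np.ndarray      # true RSA percent
    z: np.ndarray | None = None  # membrane-frame z per residue


@dataclass
class MprapModel:
    kernel: str
    C: float
    kernel_param: float | None
    regressor: object
    binary_cutoff: float
    feature_schema: dict
    probe_radius: float
    metadata: dict = field(default_factory=dict)

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        meta = {
            "kernel": self.kernel, "C": self.C,
            "kernel_param": self.kernel_param,
            "binary_cutoff": self.binary_cutoff,
            "feature_schema": self.feature_schema,
            "probe_radius": self.probe_radius,
            "metadata": self.metadata,
            "schema_version": 1,
        }
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.mprap.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.regressor, f"{prefix}.mprap.bin")

    @classmethod
    def load(cls, prefix) -> "MprapModel":
        meta = json.loads(Path(f"{prefix}.mprap.json").read_text())
        reg = joblib.load(f"{prefix}.mprap.bin")
        return cls(kernel=meta["kernel"], C=meta["C"],
                   kernel_param=meta["kernel_param"], regressor=reg,
                   binary_cutoff=meta["binary_cutoff"],
                   feature_schema=meta["feature_schema"],
                   probe_radius=meta["probe_radius"],
                   metadata=meta.get("metadata", {}))


def _make_estimator(kernel: str, C: float, param, epsilon: float,
                    mode: str):
    if mode == "regression":
        if kernel == "linear":
            return SVR(kernel="linear", C=C, epsilon=epsilon)
        if kernel == "polynomial":
            return SVR(kernel="poly", C=C, degree=param, gamma="scale",
                       coef0=1.0, epsilon=epsilon)
        if kernel == "rbf":
            return SVR(kernel="rbf", C=C, gamma=param, epsilon=epsilon)
    else:  # binary screening mode
        if kernel == "linear":
            return SVC(kernel="linear", C=C)
        if kernel == "polynomial":
            return SVC(kernel="poly", C=C, degree=param, gamma="scale",
                       coef0=1.0)
        if kernel == "rbf":
            return SVC(kernel="rbf", C=C, gamma=param)
    raise DomainError(f"unknown kernel {kernel!r}")


def optimize_cutoff(predicted, true_states) -> tuple[float, float]:
    """Best real-to-binary cutoff on the half-integer lattice 0.5..99.5.

    Returns (cutoff, mcc); ties go to the smallest cutoff.  Requires both
    burial classes in the truth.
    """
    pred = np.asarray(predicted, dtype=float)
    truth = np.array([
        (s.value if isinstance(s, BurialState) else str(s)) == "buried"
        for s in true_states])
    if len(pred) != len(truth):
        raise DomainError("prediction/truth length mismatch")
    if truth.all() or (~truth).all():
        raise DomainError("cutoff optimisation needs both burial classes")
    best_cutoff, best_mcc = None, -np.inf
    for c in CUTOFF_LATTICE:
        p = pred < c
        tp = int((p & truth).sum())
        fp = int((p & ~truth).sum())
        fn = int((~p & truth).sum())
        tn = int((~p & ~truth).sum())
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        if mcc > best_mcc + 1e-12:
            best_cutoff, best_mcc = float(c), float(mcc)
    return best_cutoff, best_mcc


def train(chain_data: list, split: CvSplit, grid: GridSpec,
          kernel: str = "rbf", label_cutoff: float = DEFAULT_CUTOFF,
          epsilon: float = DEFAULT_EPSILON, probe_radius: float = 1.4,
          window: int = DEFAULT_WINDOW, seed: int = 0,
          mode: str = "regression"):
    """Grid-searched, family-grouped 5-fold training.

    Returns (model, oof) where ``oof`` maps chain_key to a dict with the
    selected grid point's out-of-fold predictions (``pred``), truth
    (``y``) and fold index.  The model is refit on all data at the grid
    point whose out-of-fold MCC (after cutoff optimisation) is highest.
    """
    if mode not in ("regression", "classification"):
        raise DomainError(f"unknown training mode {mode!r}")
    for cd in chain_data:
        if cd.chain_key not in split.group_of:
            raise MprapError(f"chain {cd.chain_key} missing from CV split")
    X_all = np.vstack([cd.X for cd in chain_data])
    y_all = np.concatenate([cd.y_rsa for cd in chain_data])
    if np.ptp(y_all) == 0:
        raise DomainError("degenerate labels: all RSA values identical")
    folds = np.concatenate([
        np.full(len(cd.y_rsa), split.group_of[cd.chain_key])
        for cd in chain_data])
    truth_states = [binarize(v, label_cutoff) for v in y_all]
    truth_bool = np.array([s is BurialState.BURIED for s in truth_states])

    n_feat = X_all.shape[1]
    results = []  # (mcc, cutoff, C, param, oof_pred)
    for C, param in grid.points(kernel):
        oof = np.empty(len(y_all))
        for fold in range(split.k):
            test = folds == fold
            if not test.any():
                continue
            est = _make_estimator(kernel, C, param, epsilon, mode)
            if mode == "regression":
                est.fit(X_all[~test], y_all[~test])
                oof[test] = np.clip(est.predict(X_all[test]), 0.0, 100.0)
            else:
                est.fit(X_all[~test], truth_bool[~test])
                # buried -> 0, exposed -> 100 so the same cutoff logic applies
                oof[test] = np.where(est.predict(X_all[test]), 0.0, 100.0)
        if mode == "regression":
            cutoff, mcc = optimize_cutoff(oof, truth_states)
        else:
            cutoff = label_cutoff
            pred_states = [BurialState.BURIED if v < cutoff
                           else BurialState.EXPOSED for v in oof]
            mcc = metrics(confusion(pred_states, truth_states)).mcc
        results.append((mcc, cutoff, C, param, oof.copy()))

    best = max(results, key=lambda r: r[0])  # ties: first grid point wins
    best_mcc, best_cutoff, best_C, best_param, best_oof = best

    final = _make_estimator(kernel, best_C, best_param, epsilon, mode)
    if mode == "regression":
        final.fit(X_all, y_all)
    else:
        final.fit(X_all, truth_bool)

    model = MprapModel(
        kernel=kernel, C=best_C, kernel_param=best_param, regressor=final,
        binary_cutoff=best_cutoff,
        feature_schema={"window": window, "dimension": n_feat,
                        "slot_width": SLOT_WIDTH,
                        "inputs": ["pssm", "rate", "z", "padding"],
                        "mode": mode},
        probe_radius=probe_radius,
        metadata={"n_chains": len(chain_data), "n_residues": len(y_all),
                  "seed": seed, "oof_mcc": best_mcc,
                  "label_cutoff": label_cutoff,
                  "grid_size": len(results)},
    )
    oof_by_chain = {}
    offset = 0
    for cd in chain_data:
        n = len(cd.y_rsa)
        oof_by_chain[cd.chain_key] = {
            "pred": best_oof[offset:offset + n],
            "y": cd.y_rsa.copy(),
            "fold": split.group_of[cd.chain_key],
        }
        offset += n
    return model, oof_by_chain


def predict(model: MprapModel, features):
    """Real-valued RSA (clamped to [0, 100]) and burial states."""
    if isinstance(features, (list, tuple)) and features \
            and isinstance(features[0], FeatureVector):
        X = feature_matrix(features)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_schema["dimension"]:
        raise SchemaError(
            f"feature dimension {X.shape} does not match model schema "
            f"{model.feature_schema['dimension']}")
    if model.feature_schema.get("mode") == "classification":
        values = np.where(model.regressor.predict(X), 0.0, 100.0)
    else:
        values = np.clip(model.regressor.predict(X), 0.0, 100.0)
    states = [BurialState.BURIED if v < model.binary_cutoff
              else BurialState.EXPOSED for v in values]
    return values, states


def combine(pred_mem, pred_sol, z, z_cutoff: float = DEFAULT_Z_COMBINE_CUTOFF):
    """Merge a membrane-specialised and a soluble-specialised prediction:
    trust the membrane predictor strictly inside |z| < z_cutoff."""
    if not (len(pred_mem) == len(pred_sol) == len(z)):
        raise DomainError("combine inputs must have equal lengths")
    z = np.asarray(z, dtype=float)
    return [m if abs(zi) < z_cutoff else s
            for m, s, zi in zip(pred_mem, pred_sol, z)]
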