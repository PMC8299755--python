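"""Feature assembly, DX-score feature selection, and the linear SVR risk model.

The per-patient feature vector stacks the conduction-zone stress block
(von Mises stress at every conduction-zone mesh node, complete frame,
theta = 0), the total calcified volume, and the encoded clinical factors.
The DX score ranks features by between-class mean separation over pooled
within-class spread, ``|mu1 - mu0| / (s1 + s0)``; the top 16 are retained.
Risk is a linear support vector regression ``g(x) = <w, x> + b`` on z-scored
selected features, clipped to [0, 1], with AVB called above a 0.5 threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .fem import wrap_angle_deg
from .forward import ForwardModel
from .records import PatientRecord
from .remodel import remodel_all
from .valves import ValveDesign

__all__ = [
    "CLINICAL_FEATURE_NAMES",
    "feature_names",
    "assemble_features",
    "assemble_matrix",
    "DXReport",
    "dx_score",
    "VBPRModel",
    "fit",
    "predict_risk",
    "predict_many",
    "classify",
    "save_model",
    "load_model",
]

#: Clinical factors appended after the stress block and calcified volume.
#: "cz_calcium_fraction" (share of calcified volume inside the conduction
#: sector) and "angular_entropy" (Shannon entropy of the volume-weighted
#: angular placement) encode calcium location and distribution.
CLINICAL_FEATURE_NAMES = (
    "sex_male",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "lvef",
    "diabetes",
    "afib_history",
    "stroke_history",
    "icb_history",
    "cz_calcium_fraction",
    "angular_entropy",
)

_ENTROPY_SECTORS = 12


def feature_names(n_stress: int) -> list[str]:
    names = [f"stress_{i:03d}" for i in range(n_stress)]
    names.append("calcified_volume")
    names.extend(CLINICAL_FEATURE_NAMES)
    return names


def _calcium_location_features(record: PatientRecord, half_angle_deg: float) -> tuple[float, float]:
    remodeled = remodel_all(record.deposits, record.geometry)
    volumes = np.array([rd.deposit.volume for rd in remodeled])
    phis = np.array([rd.deposit.center[1] for rd in remodeled])
    total = volumes.sum()
    if total <= 0 or volumes.size == 0:
        return 0.0, 0.0
    in_zone = np.abs(wrap_angle_deg(phis)) < half_angle_deg
    fraction = float(volumes[in_zone].sum() / total)
    sector = (np.floor(phis / (360.0 / _ENTROPY_SECTORS)).astype(int)) % _ENTROPY_SECTORS
    mass = np.zeros(_ENTROPY_SECTORS)
    np.add.at(mass, sector, volumes)
    p = mass[mass > 0] / total
    entropy = float(-(p * np.log(p)).sum() / np.log(_ENTROPY_SECTORS))
    return fraction, entropy


def assemble_features(
    record: PatientRecord,
    resolution: tuple[int, int, int],
    band_height: float = 4.0,
    half_angle_deg: float = 45.0,
    theta_deg: float = 0.0,
    valve_size: float | None = None,
    forward: ForwardModel | None = None,
) -> np.ndarray:
    """Assemble one patient's feature vector (stress block, V, clinical)."""
    fm = forward or ForwardModel(
        record.geometry,
        record.deposits,
        resolution=resolution,
        band_height=band_height,
        half_angle_deg=half_angle_deg,
    )
    size = record.applied_valve_size if valve_size is None else valve_size
    stress = fm.features(ValveDesign(size=size, theta_deg=theta_deg))
    fraction, entropy = _calcium_location_features(record, half_angle_deg)
    clinical = np.array(
        [
            1.0 if record.sex == "male" else 0.0,
            record.bmi,
            record.systolic_bp,
            record.diastolic_bp,
            record.lvef,
            float(record.diabetes),
            float(record.afib_history),
            float(record.stroke_history),
            float(record.icb_history),
            fraction,
            entropy,
        ]
    )
    return np.concatenate([stress, [record.calcified_volume], clinical])


def assemble_matrix(
    cohort: list[PatientRecord],
    resolution: tuple[int, int, int],
    band_height: float = 4.0,
    half_angle_deg: float = 45.0,
    theta_deg: float = 0.0,
    forwards: list[ForwardModel] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors for a cohort; training uses theta = 0 throughout."""
    if forwards is None:
        forwards = [None] * len(cohort)
    rows = [
        assemble_features(
            r, resolution, band_height, half_angle_deg, theta_deg=theta_deg,
            forward=fm,
        )
        for r, fm in zip(cohort, forwards)
    ]
    X = np.vstack(rows)
    n_stress = X.shape[1] - 1 - len(CLINICAL_FEATURE_NAMES)
    return X, feature_names(n_stress)


@dataclass
class DXReport:
    """Per-feature discrimination scores and the selected subset."""

    scores: np.ndarray
    ranking: np.ndarray  # feature indices, descending score
    selected: np.ndarray  # top-k indices, ascending
    impact_percent: float  # 100 * sum(selected scores) / sum(all scores)


_DX_CAP = 1e12


def dx_score(X: np.ndarray, y: np.ndarray, select_k: int = 16) -> DXReport:
    """Rank features by ``|mu1 - mu0| / (s1 + s0)`` and keep the top k.

    Ties break deterministically by feature index.  A feature with zero
    spread in both classes scores 0 when the class means agree and is capped
    at 1e12 otherwise.
    """
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("DX score needs both classes present")
    if np.min(np.bincount(y)) < 2:
        raise ValueError("DX score needs at least 2 patients per class")
    x0, x1 = X[y == 0], X[y == 1]
    sep = np.abs(x1.mean(axis=0) - x0.mean(axis=0))
    spread = x1.std(axis=0, ddof=1) + x0.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            spread > 0, sep / np.where(spread > 0, spread, 1.0),
            np.where(sep > 0, _DX_CAP, 0.0),
        )
    scores = np.minimum(scores, _DX_CAP)
    ranking = np.lexsort((np.arange(scores.size), -scores))
    k = min(select_k, scores.size)
    selected = np.sort(ranking[:k])
    total = scores.sum()
    impact = 100.0 * scores[selected].sum() / total if total > 0 else 0.0
    return DXReport(
        scores=scores, ranking=ranking, selected=selected, impact_percent=float(impact)
    )


@dataclass
class VBPRModel:
    """Fitted linear SVR risk model with its preprocessing statistics."""

    selected_indices: np.ndarray
    weights: np.ndarray  # on z-scored selected features
    bias: float
    lam: float  # ridge penalty; SVR cost C = 1 / (2 lam)
    epsilon: float
    feature_means: np.ndarray  # over selected features, training data only
    feature_sds: np.ndarray
    threshold: float = 0.5
    feature_names: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size


_LAMBDA_GRID = tuple(10.0 ** np.arange(-3, 3).astype(float))


def _fit_svr(Z: np.ndarray, y: np.ndarray, lam: float, epsilon: float) -> tuple[np.ndarray, float]:
    # objective: lam * ||w||^2 + mean epsilon-insensitive loss, i.e. the
    # per-sample convention C = 1 / (2 * lam * n), so lam is comparable
    # across cohort sizes
    svr = SVR(kernel="linear", C=1.0 / (2.0 * lam * len(y)), epsilon=epsilon, tol=1e-6)
    svr.fit(Z, y)
    return svr.coef_.ravel().copy(), float(svr.intercept_[0])


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    epsilon: float = 0.01,
    select_k: int | None = 16,
    seed: int = 0,
    threshold: float = 0.5,
    names: list[str] | None = None,
) -> VBPRModel:
    """Fit the risk model: DX selection, z-scoring, linear epsilon-SVR.

    ``lam`` is the ridge penalty (SVR cost C = 1 / (2 lam)); when None it is
    chosen by an inner seeded 5-fold cross-validation over a log grid.
    ``select_k=None`` keeps every feature (no DX selection).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 8:
        raise ValueError(f"need at least 8 patients to fit, got {X.shape[0]}")
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")

    if select_k is None:
        selected = np.arange(X.shape[1])
    else:
        selected = dx_score(X, y.astype(int), select_k).selected
    Xs = X[:, selected]
    means = Xs.mean(axis=0)
    sds = Xs.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (Xs - means) / sds

    if lam is None:
        folds = KFold(n_splits=min(5, len(y)), shuffle=True, random_state=seed)
        best, best_err = None, np.inf
        for cand in _LAMBDA_GRID:
            err = 0.0
            for tr, te in folds.split(Z):
                w, b = _fit_svr(Z[tr], y[tr], cand, epsilon)
                err += float(np.mean((Z[te] @ w + b - y[te]) ** 2))
            if err < best_err - 1e-12:
                best, best_err = cand, err
        lam = best
    w, b = _fit_svr(Z, y, lam, epsilon)
    return VBPRModel(
        selected_indices=selected,
        weights=w,
        bias=b,
        lam=float(lam),
        epsilon=float(epsilon),
        feature_means=means,
        feature_sds=sds,
        threshold=threshold,
        feature_names=list(names) if names is not None else None,
    )


def predict_risk(model: VBPRModel, x: np.ndarray) -> float:
    """Predicted AVB risk in [0, 1] for one assembled feature vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= int(model.selected_indices.max()):
        raise ValueError(
            f"feature vector of length {x.size} does not cover selected index "
            f"{int(model.selected_indices.max())}"
        )
    z = (x[model.selected_indices] - model.feature_means) / model.feature_sds
    raw = float(model.weights @ z + model.bias)
    return float(np.clip(raw, 0.0, 1.0))


def predict_many(model: VBPRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Z = (X[:, model.selected_indices] - model.feature_means) / model.feature_sds
    return np.clip(Z @ model.weights + model.bias, 0.0, 1.0)


def classify(risk: float, threshold: float = 0.5) -> str:
    """Dichotomize a risk score: 'AVB' strictly above the threshold."""
    if not (0.0 <= risk <= 1.0):
        raise ValueError(f"risk must lie in [0, 1], got {risk}")
    return "AVB" if risk > threshold else "no-AVB"


def save_model(model: VBPRModel, path) -> None:
    """Serialize to a plain-text JSON key-value file (exact round-trip)."""
    payload = {
        "selected_indices": model.selected_indices.tolist(),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "lam": model.lam,
        "epsilon": model.epsilon,
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "threshold": model.threshold,
        "feature_names": model.feature_names,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> VBPRModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return VBPRModel(
        selected_indices=np.asarray(payload["selected_indices"], dtype=int),
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        lam=float(payload["lam"]),
        epsilon=float(payload["epsilon"]),
        feature_means=np.asarray(payload["feature_means"], dtype=float),
        feature_sds=np.asarray(payload["feature_sds"], dtype=float),
        threshold=float(payload["threshold"]),
        feature_names=payload["feature_names"],
    )
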