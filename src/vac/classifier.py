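"""Stepwise linear discriminant vigilance classifier.

Training regresses 0/1 vigilance labels on the spectral features with
forward/backward stepwise selection that stops on its own: a candidate
enters when its partial-F p-value is the smallest and below ``p_enter``
(default 0.05); after every insertion, included features whose p-value has
risen above ``p_remove`` (default 0.10) are dropped; selection halts when no
candidate qualifies or a hard cap is reached.  The fitted coefficients and
intercept then score unseen epochs as

    y(t) = Σ_i w_i · f_i(t) + b,

values near 1 meaning high vigilance and near 0 low vigilance.  A trailing
30-s moving average turns the noisy per-epoch y(t) into the vigilance index
V_SCORE, which a calibrated threshold binarizes into {Low, High}.

Labels come from the calibration protocol: a monotonous high-automation
monitoring run whose first five minutes are taken as High vigilance and
whose last five minutes as Low (sustained monotonous monitoring degrades
vigilance measurably after about ten minutes); the transition region in the
middle is left unlabelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (IncompatibilityError, LabelError, ParameterError,
                     UnderdeterminedError)
from .spectral import BandSet, FeatureIndexMap

HIGH, LOW = 1, 0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CalibrationSet:
    """Labelled feature vectors from the calibration run."""

    features: np.ndarray
    labels: np.ndarray
    index_map: FeatureIndexMap | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.ndim != 2 or len(self.labels) != self.features.shape[0]:
            raise ParameterError("features must be (n, p) with one label per row")
        if not np.isfinite(self.features).all():
            raise ParameterError("features must be finite")
        classes = np.unique(self.labels)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise LabelError("labels must be 0 (Low) or 1 (High)")
        if len(classes) < 2:
            raise LabelError("both vigilance classes must be present")

    @classmethod
    def from_protocol(cls, features: np.ndarray, starts: np.ndarray,
                      total_duration: float,
                      index_map: FeatureIndexMap | None = None,
                      high_window: float = 300.0,
                      low_window: float = 300.0) -> "CalibrationSet":
        """Label epochs by the calibration protocol.

        Epochs starting in the first ``high_window`` seconds are High (1),
        those starting in the final ``low_window`` seconds are Low (0); the
        middle of the run is discarded.
        """
        starts = np.asarray(starts, dtype=float)
        hi = starts < high_window
        lo = starts >= total_duration - low_window
        keep = hi | lo
        if not hi.any() or not lo.any():
            raise LabelError("calibration run does not cover both protocol windows")
        return cls(features[keep], hi[keep].astype(float), index_map)

    def class_counts(self) -> tuple[int, int]:
        n_high = int((self.labels == 1).sum())
        return n_high, len(self.labels) - n_high


@dataclass
class VigilanceModel:
    """Selected features, weights, bias and decision threshold."""

    selected: list[int]
    weights: np.ndarray
    bias: float
    threshold: float
    index_map: FeatureIndexMap
    bands: BandSet | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.selected):
            raise ParameterError("one weight per selected feature required")

    @property
    def n_features(self) -> int:
        return len(self.index_map)

    def to_dict(self) -> dict:
        return {
            "selected": [int(j) for j in self.selected],
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "threshold": float(self.threshold),
            "index_map": self.index_map.to_list(),
            "bands": self.bands.to_dict() if self.bands is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VigilanceModel":
        bands = d.get("bands")
        return cls(
            selected=[int(j) for j in d["selected"]],
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            threshold=float(d["threshold"]),
            index_map=FeatureIndexMap.from_list(d["index_map"]),
            bands=BandSet.from_dict(bands) if bands is not None else None,
        )


@dataclass
class VigilanceTrace:
    """Per-epoch discriminant output, smoothed V_SCORE and binary state."""

    t: np.ndarray
    y: np.ndarray
    v_score: np.ndarray
    state: np.ndarray       # True = High
    artifact: np.ndarray    # True = artifact-gap epoch
    threshold: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.v_score = np.asarray(self.v_score, dtype=float)
        self.state = np.asarray(self.state, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# stepwise training
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray, sel: list[int]):
    """Least-squares fit of y on [1, X[:, sel]]; returns (coef, resid, design)."""
    n = len(y)
    A = np.column_stack([np.ones(n)] + [X[:, j] for j in sel])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, resid, A


def _coef_pvalues(A: np.ndarray, coef: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values per coefficient (intercept included)."""
    n, k = A.shape
    df = n - k
    if df < 1:
        return np.zeros(k)
    sigma2 = float(resid @ resid) / df
    cov = np.linalg.pinv(A.T @ A) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    tstat = np.abs(coef) / se
    return 2 * stats.t.sf(tstat, df)


def _ortho_state(X: np.ndarray, y: np.ndarray, sel: list[int]):
    """Residualize y and all columns of X against [1, X[:, sel]]."""
    Xr = X - X.mean(axis=0)
    yr = y - y.mean()
    for j in sel:
        q = Xr[:, j].copy()
        nq = np.linalg.norm(q)
        if nq <= 1e-12:
            continue
        q /= nq
        yr = yr - (q @ yr) * q
        Xr = Xr - np.outer(q, q @ Xr)
    return Xr, yr


def train_asswlda(calib: CalibrationSet, bands: BandSet | None = None,
                  p_enter: float = 0.05, p_remove: float = 0.10,
                  max_features: int = 30,
                  threshold_mode: str = "midpoint") -> VigilanceModel:
    """Fit the automatic-stop stepwise discriminant on calibration data.

    Forward steps add the candidate with the smallest partial-F p-value when
    it is below ``p_enter``; backward steps drop included features whose
    p-value exceeds ``p_remove``; selection stops by itself when no candidate
    qualifies or ``max_features`` is reached.  The decision threshold is the
    midpoint of the two training class-mean scores (or a fixed 0.5).
    """
    X, y = calib.features, calib.labels
    n, p = X.shape
    if n < 4:
        raise UnderdeterminedError(
            f"{n} epochs cannot support a model with even 2 features")
    if p < 1:
        raise ParameterError("at least one candidate feature required")

    selected: list[int] = []
    Xr, yr = _ortho_state(X, y, selected)
    col_scale = np.maximum(np.einsum("ij,ij->j", Xr, Xr), 0.0)
    guard = 0
    while len(selected) < max_features and guard < 10 * max_features:
        guard += 1
        rss = float(yr @ yr)
        df = n - len(selected) - 2  # candidate + intercept consume 2 more dof
        if df < 1 or rss <= 1e-12:
            break
        norms2 = np.einsum("ij,ij->j", Xr, Xr)
        usable = np.ones(p, dtype=bool)
        usable[selected] = False
        usable &= norms2 > 1e-10 * np.maximum(col_scale, 1e-30)
        if not usable.any():
            break
        proj = Xr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            ss = np.where(usable, proj ** 2 / norms2, -np.inf)
        ss = np.where(usable, np.minimum(ss, rss * (1 - 1e-12)), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = ss / np.maximum((rss - ss) / df, 1e-300)
        pvals = np.where(usable, stats.f.sf(np.maximum(fstat, 0.0), 1, df), np.inf)
        j = int(np.argmin(pvals))
        if not (pvals[j] < p_enter):
            break
        selected.append(j)
        q = Xr[:, j] / math.sqrt(norms2[j])
        yr = yr - (q @ yr) * q
        Xr = Xr - np.outer(q, q @ Xr)

        # backward sweep on the included set
        removed_any = False
        while len(selected) > 1:
            coef, resid, A = _ols(X, y, selected)
            pv = _coef_pvalues(A, coef, resid)[1:]
            worst = int(np.argmax(pv))
            if pv[worst] <= p_remove:
                break
            del selected[worst]
            removed_any = True
        if removed_any:
            Xr, yr = _ortho_state(X, y, selected)

    coef, _, _ = _ols(X, y, selected)
    bias = float(coef[0])
    weights = np.asarray(coef[1:], dtype=float)

    scores = bias + (X[:, selected] @ weights if selected else 0.0)
    scores = np.broadcast_to(np.asarray(scores, dtype=float), (n,))
    if threshold_mode == "midpoint":
        thr = float((scores[y == 1].mean() + scores[y == 0].mean()) / 2)
    elif threshold_mode == "fixed0.5":
        thr = 0.5
    else:
        raise ParameterError(f"unknown threshold mode {threshold_mode!r}")

    imap = calib.index_map if calib.index_map is not None else FeatureIndexMap(
        [("?", float(i)) for i in range(p)])
    return VigilanceModel(selected=selected, weights=weights, bias=bias,
                          threshold=thr, index_map=imap, bands=bands)


# ---------------------------------------------------------------------------
# scoring / smoothing / state
# ---------------------------------------------------------------------------

def score(model: VigilanceModel, f: np.ndarray) -> float | np.ndarray:
    """Apply the trained discriminant: y = Σ w_i·f_i + b (not clipped)."""
    f = np.asarray(f, dtype=float)
    p = f.shape[-1]
    if p != model.n_features:
        raise IncompatibilityError(
            f"feature vector has {p} entries, model expects {model.n_features}")
    y = f[..., model.selected] @ model.weights + model.bias if model.selected \
        else np.broadcast_to(model.bias, f.shape[:-1]).copy()
    return float(y) if np.ndim(y) == 0 else y


def smooth_trace(t: np.ndarray, y: np.ndarray, window: float = 30.0,
                 threshold: float = 0.5,
                 artifact: np.ndarray | None = None) -> VigilanceTrace:
    """Trailing moving average of the discriminant output.

    V_SCORE(t) averages y over the window (t − window, t], skipping
    artifact-gap epochs; during the first ``window`` seconds the partial
    history is used.  If the whole window is artifactual, the last V_SCORE
    is carried forward and the epoch is flagged as a gap.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ParameterError("t and y must align")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ParameterError("trace times must be strictly increasing")
    artifact = (np.zeros(len(t), dtype=bool) if artifact is None
                else np.asarray(artifact, dtype=bool).copy())
    ok = ~artifact & np.isfinite(y)

    v = np.empty(len(t))
    j0 = 0
    run_sum, run_cnt = 0.0, 0
    last = math.nan
    for i in range(len(t)):
        if ok[i]:
            run_sum += y[i]
            run_cnt += 1
        while t[j0] <= t[i] - window:
            if ok[j0]:
                run_sum -= y[j0]
                run_cnt -= 1
            j0 += 1
        if run_cnt:
            last = run_sum / run_cnt
            v[i] = last
        else:
            v[i] = last  # carry forward across an all-artifact window
            artifact[i] = True
    state = classify_state(v, threshold)
    return VigilanceTrace(t=t, y=y, v_score=v, state=state,
                          artifact=artifact, threshold=threshold)


def classify_state(v, threshold: float):
    """High iff V_SCORE ≥ threshold (ties favour the high-automation default)."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    v = np.asarray(v, dtype=float)
    out = v >= threshold
    return bool(out) if out.ndim == 0 else out
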