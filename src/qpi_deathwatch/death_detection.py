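"""Death-timepoint detection from per-cell feature time series.

The detector regresses, per frame, a Gaussian target curve centred on the
annotated death timepoint (peak 1, sigma 50 frames; identically zero for
survivors) with a bidirectional LSTM, so the network response encodes
where — and whether — a death occurred.  At inference the death frame is
the (earliest) maximum of the response when that maximum exceeds the
detection threshold (0.4); otherwise the cell is called alive.

A detection is scored correct when it lies within ±100 frames (±5 h at
3 min/frame) of the annotated death, or when both the prediction and the
annotation say alive.  Survival curves accumulate the detected deaths
(all cells alive at the start) and IT50 is the first time at which half
the population has died.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._bilstm import AdamState, BiLSTMNet, masked_mse, pad_sequences
from .io_formats import FEATURE_COLUMNS, AnnotationRecord

__all__ = [
    "DeathDetector",
    "make_target_signal",
    "augment_clip",
    "series_from_table",
    "train_detector",
    "save_detector",
    "load_detector",
    "detect_death",
    "evaluate_detection",
    "leave_one_fov_out_splits",
    "survival_curve_and_it50",
]


def make_target_signal(death_frame, T: int, sigma: float = 50.0) -> np.ndarray:
    """Gaussian regression target: peak 1 at the death frame, zeros if alive."""
    if death_frame is None or (isinstance(death_frame, float) and np.isnan(death_frame)):
        return np.zeros(T)
    t = np.arange(T, dtype=float)
    return np.exp(-((t - float(death_frame)) ** 2) / (2.0 * sigma**2))


def augment_clip(
    series: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    death_frame=None,
    max_frac: float = 1.0 / 3.0,
):
    """Randomly shorten a training sample by at most ``max_frac`` of its length.

    A uniformly drawn prefix or suffix is removed from both the series and
    the target.  If the death annotation falls inside the removed span the
    sample becomes "alive-so-far" (all-zero target).

    Returns (series, target, death_frame) after clipping.
    """
    L = len(series)
    if L < 3:
        return series, target, death_frame
    amount = int(rng.integers(0, int(L * max_frac) + 1))
    if amount == 0:
        return series, target, death_frame
    suffix = bool(rng.integers(0, 2))
    if suffix:
        series, target = series[: L - amount], target[: L - amount]
        if death_frame is not None and death_frame >= L - amount:
            death_frame = None
            target = np.zeros(len(target))
    else:
        series, target = series[amount:], target[amount:]
        if death_frame is not None:
            if death_frame < amount:
                death_frame = None
                target = np.zeros(len(target))
            else:
                death_frame = death_frame - amount
    return series, target, death_frame


def series_from_table(
    table: pd.DataFrame, feature_columns: list[str] | None = None
) -> tuple[list[int], list[np.ndarray]]:
    """Per-cell (T, n_features) arrays from a long-form feature table.

    Missing values (CDS at frame 0, dropped frames) are forward- then
    back-filled so the network sees finite inputs.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    ids, series = [], []
    for cid, grp in table.sort_values(["cell_id", "frame"]).groupby("cell_id"):
        X = grp[feature_columns].ffill().bfill().fillna(0.0).to_numpy(dtype=float)
        ids.append(int(cid))
        series.append(X)
    return ids, series


class DeathDetector(BaseEstimator):
    """BiLSTM regressor of Gaussian death-target curves.

    Parameters (defaults follow the reference training recipe)
    ----------------------------------------------------------
    hidden_units : LSTM units per direction per layer (100).
    n_lstm_layers : stacked BiLSTM layers (2).
    fc_sizes : fully connected head sizes with ReLU (100, 50, 100),
        followed by a 1-d linear output per frame.
    dropout : dropout probability (0.5).
    learning_rate, beta1, beta2 : Adam settings (1e-3, 0.9, 0.999).
    clip_norm : global gradient-norm clip (1.0).
    weight_decay : decoupled weight decay (1e-3).
    batch_size, epochs : 256, 40.
    target_sigma : Gaussian target width in frames (50).
    threshold : detection threshold on the response maximum (0.4, strict).
    augment : apply random clipping augmentation (by at most 1/3 of the
        signal length) during training.
    augment_factor : number of randomly clipped variants of each signal
        per epoch (1 = one pass over the data; >1 enlarges the augmented
        dataset, useful when the training population is small).
    random_state : seed for initialization, shuffling, dropout, clipping.

    Fitted attributes: ``net_``, ``norm_mean_``, ``norm_std_``,
    ``loss_history_`` (mean training MSE per epoch).
    """

    def __init__(
        self,
        hidden_units: int = 100,
        n_lstm_layers: int = 2,
        fc_sizes: tuple[int, ...] = (100, 50, 100),
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        clip_norm: float = 1.0,
        weight_decay: float = 1e-3,
        batch_size: int = 256,
        epochs: int = 40,
        target_sigma: float = 50.0,
        threshold: float = 0.4,
        augment: bool = True,
        augment_factor: int = 1,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.n_lstm_layers = n_lstm_layers
        self.fc_sizes = fc_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.target_sigma = target_sigma
        self.threshold = threshold
        self.augment = augment
        self.augment_factor = augment_factor
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_X(self, X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = [X]
        X = [np.asarray(x, dtype=float) for x in X]
        if len(X) == 0:
            raise ValueError("empty input")
        d = X[0].shape[1]
        for x in X:
            if x.ndim != 2 or x.shape[1] != d:
                raise ValueError("all series must be (T_i, n_features) with equal n_features")
            if x.shape[0] == 0:
                raise ValueError("zero-length series")
        return X

    def fit(self, X, y):
        """Fit on per-cell series ``X`` (list of (T_i, F)) and death frames
        ``y`` (array; NaN/None = alive)."""
        X = self._validate_X(X)
        y = [None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v) for v in y]
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)

        flat = np.concatenate(X, axis=0)
        self.norm_mean_ = flat.mean(axis=0)
        self.norm_std_ = np.maximum(flat.std(axis=0), 1e-8)
        Xn = [(x - self.norm_mean_) / self.norm_std_ for x in X]
        targets = [make_target_signal(d, len(x), self.target_sigma) for d, x in zip(y, X)]

        self.net_ = BiLSTMNet(
            d_in=X[0].shape[1],
            hidden_units=self.hidden_units,
            n_lstm_layers=self.n_lstm_layers,
            fc_sizes=tuple(self.fc_sizes),
            dropout=self.dropout,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        params = self.net_.named_params()
        opt = AdamState(
            params,
            lr=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            weight_decay=self.weight_decay,
            clip_norm=self.clip_norm,
        )
        n = len(Xn)
        factor = max(1, int(self.augment_factor)) if self.augment else 1
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(np.repeat(np.arange(n), factor))
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                batch_x, batch_t = [], []
                for i in idx:
                    xs, ts, d = Xn[i], targets[i], y[i]
                    if self.augment:
                        xs, ts, d = augment_clip(xs, ts, rng, death_frame=d)
                    batch_x.append(xs)
                    batch_t.append(ts)
                xp, lengths = pad_sequences(batch_x)
                tp = np.zeros(xp.shape[:2])
                for b, ts in enumerate(batch_t):
                    tp[b, : len(ts)] = ts
                pred, caches = self.net_.forward(xp, lengths, train=True, rng=rng)
                loss, dy = masked_mse(pred, tp, lengths)
                grads = self.net_.backward(dy, caches)
                opt.step(params, grads)
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        return self

    def predict_response(self, X) -> list[np.ndarray]:
        """Raw per-frame network response for each series."""
        X = self._validate_X(X)
        Xn = [(x - self.norm_mean_) / self.norm_std_ for x in X]
        responses = []
        for x in Xn:  # one at a time: no padding effects, modest memory
            xp, lengths = pad_sequences([x])
            pred, _ = self.net_.forward(xp, lengths, train=False)
            responses.append(pred[0, : len(x)])
        return responses

    def predict(self, X) -> np.ndarray:
        """Death frame per series; NaN = alive.  Strict threshold, earliest
        maximal frame wins."""
        out = []
        for resp in self.predict_response(X):
            frame, conf = detect_death(resp, self.threshold)
            out.append(np.nan if frame is None else float(frame))
        return np.asarray(out)

    def score(self, X, y, window: int = 100) -> float:
        """±window-frame detection accuracy against annotated death frames."""
        pred = self.predict(X)
        truth = np.asarray(
            [np.nan if v is None else float(v) for v in y], dtype=float
        )
        return evaluate_detection(pred, truth, window=window)


def detect_death(response: np.ndarray, threshold: float = 0.4):
    """(death_frame | None, confidence) from a response curve.

    The death frame is the earliest maximum of the response if the maximum
    strictly exceeds the threshold; otherwise None (alive).
    """
    response = np.asarray(response, dtype=float)
    if response.size == 0:
        raise ValueError("empty response")
    conf = float(response.max())
    if conf > threshold:
        return int(np.argmax(response)), conf
    return None, conf


def train_detector(table: pd.DataFrame, annotations: list[AnnotationRecord], **params) -> tuple[DeathDetector, list[int]]:
    """Fit a :class:`DeathDetector` from a feature table + annotations.

    Returns (fitted detector, cell ids in series order)."""
    ids, X = series_from_table(table)
    ann = {a.cell_id: a.death_frame for a in annotations}
    y = [ann.get(cid) for cid in ids]
    det = DeathDetector(**params)
    det.fit(X, y)
    return det, ids


def save_detector(det: DeathDetector, path) -> None:
    """Write a trained detector as a directory bundle: weights.npz +
    config.json (hyperparameters, normalization stats, format version)."""
    from pathlib import Path
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = {
        "format_version": 1,
        "params": {
            **{k: (list(v) if isinstance(v, tuple) else v) for k, v in det.get_params().items()}
        },
        "norm_mean": det.norm_mean_.tolist(),
        "norm_std": det.norm_std_.tolist(),
    }
    (path / "config.json").write_text(json.dumps(cfg, indent=2))
    np.savez(path / "weights.npz", **det.net_.named_params())


def load_detector(path) -> DeathDetector:
    from pathlib import Path
    import json

    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    params = dict(cfg["params"])
    params["fc_sizes"] = tuple(params["fc_sizes"])
    det = DeathDetector(**params)
    det.norm_mean_ = np.asarray(cfg["norm_mean"], dtype=float)
    det.norm_std_ = np.asarray(cfg["norm_std"], dtype=float)
    with np.load(path / "weights.npz") as weights:
        flat = {k: weights[k] for k in weights.files}
    d_in = flat["lstm0f.Wx"].shape[0]
    det.net_ = BiLSTMNet(
        d_in=d_in,
        hidden_units=det.hidden_units,
        n_lstm_layers=det.n_lstm_layers,
        fc_sizes=tuple(det.fc_sizes),
        dropout=det.dropout,
        seed=0,
    )
    det.net_.set_params_from(flat)
    det.loss_history_ = []
    return det


def evaluate_detection(predictions, truths, window: int = 100) -> float:
    """Fraction of cells whose detection is correct under the ±window rule."""
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("predictions and annotations must align")
    correct = 0
    for p, t in zip(pred, truth):
        if np.isnan(p) and np.isnan(t):
            correct += 1
        elif not np.isnan(p) and not np.isnan(t) and abs(p - t) <= window:
            correct += 1
    return correct / len(pred) if len(pred) else float("nan")


def leave_one_fov_out_splits(fov_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_idx, test_idx) split per field of view held out."""
    fov_ids = np.asarray(fov_ids)
    unique = np.unique(fov_ids)
    if len(unique) < 2:
        raise ValueError("need at least 2 FOVs for leave-one-FOV-out")
    splits = []
    for fov in unique:
        test = np.flatnonzero(fov_ids == fov)
        train = np.flatnonzero(fov_ids != fov)
        splits.append((train, test))
    return splits


def survival_curve_and_it50(
    death_frames, T: int, frame_interval: float
) -> tuple[np.ndarray, float | None]:
    """Cumulative dead fraction per frame and IT50 (hours).

    All cells count as alive at frame 0's start; the curve at frame t is
    the fraction with a detected death at or before t (monotone
    non-decreasing).  IT50 is the first frame where the dead fraction
    reaches 0.5, in hours; None if never reached.
    """
    deaths = np.asarray(
        [np.nan if d is None else float(d) for d in np.ravel(death_frames)],
        dtype=float,
    )
    n = len(deaths)
    frames = np.arange(T)
    curve = np.array(
        [np.sum(deaths[~np.isnan(deaths)] <= t) / n for t in frames]
        if n
        else np.zeros(T)
    )
    reached = np.flatnonzero(curve >= 0.5)
    it50 = float(reached[0] * frame_interval / 60.0) if reached.size else None
    return curve, it50
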