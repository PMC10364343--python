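"""Frame-level severity scoring with per-frame error prediction.

Two interchangeable backends sit behind one contract (``score_frame``):

* :class:`OracleScorer` — a training-free estimator that inverts the
  synthetic texture statistic and adds seeded Gaussian read noise.  It is
  the default backend for pipeline runs: it exercises every downstream
  stage (ensembling, error-weighted curve fitting, agreement analysis)
  without a trained model.

* :class:`ResidualRegressor` — a trainable regressor: a fixed multi-scale
  texture stem (contrast-normalized gradient/Laplacian energies across a
  pooling pyramid, plus the decoded position stamp) feeding a residual
  multilayer perceptron whose four stages follow a configurable residual
  block schedule.  Training has two phases: phase 1 regresses the severity
  target with a mean-squared-error loss; phase 2 adds an error-prediction
  head and minimizes the combined loss

      L = |y - yhat| + w * | |y - yhat| - ehat |

  with the weight ``w`` ramped from 0 to 100 over the phase, so that by the
  end the quality of the *error* prediction dominates the objective.  The
  error head makes the scorer heteroscedastic: each frame carries its own
  predicted uncertainty, which the ensembling and curve-fitting stages use
  as inverse-variance weights.

Predicted severities are clipped to [0, 3] at inference only (never inside
the loss); predicted errors are floored at a small ``eps`` so that
inverse-squared-error weights stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import estimate_severity_from_texture, frame_content_seed

__all__ = [
    "DEFAULT_ERROR_FLOOR",
    "FrameScore",
    "ScorerConfig",
    "phase2_loss",
    "ramp_weight",
    "OracleScorer",
    "ResidualRegressor",
    "train_scorer",
    "score_frame",
    "texture_features",
]

#: default floor on predicted error (severity units)
DEFAULT_ERROR_FLOOR = 0.01


@dataclass
class FrameScore:
    """Scorer output for one frame."""

    severity: float  # predicted severity, clipped to [0, 3]
    error: float  # predicted error, >= floor
    orientation_spread: float | None = None  # filled by the ensemble stage


def phase2_loss(y, y_hat, e_hat, w):
    """Severity + error-prediction loss, elementwise.

    ``|y - y_hat| + w * | |y - y_hat| - e_hat |``; zero iff the prediction
    is exact and the predicted error equals the realized absolute error.
    """
    if np.any(np.asarray(w) < 0):
        raise ValueError("ramp weight w must be >= 0")
    abs_err = np.abs(np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float))
    return abs_err + np.asarray(w, dtype=float) * np.abs(abs_err - np.asarray(e_hat, dtype=float))


def ramp_weight(step, total_steps, w_max: float = 100.0):
    """Linear ramp of the error-loss weight: 0 at step 0, ``w_max`` at the end."""
    step = np.asarray(step, dtype=float)
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if np.any(step < 0) or np.any(step > total_steps):
        raise ValueError("step must lie in [0, total_steps]")
    return w_max * step / total_steps


# --------------------------------------------------------------------------
# Oracle scorer
# --------------------------------------------------------------------------


class OracleScorer:
    """Training-free scorer that inverts the synthetic texture statistic.

    ``score = clip(T_inverse(T(image)) + N(0, noise_sd), 0, 3)`` with
    predicted error ``max(noise_sd, eps)``.  The noise draw is seeded from
    the frame's pixel content, so scoring the same frame twice is
    deterministic while distinct frames (including distinct orientations of
    one frame) draw independent noise.
    """

    def __init__(self, noise_sd: float = 0.0, seed: int = 0, eps: float = DEFAULT_ERROR_FLOOR):
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.noise_sd = float(noise_sd)
        self.seed = int(seed)
        self.eps = float(eps)

    def score_frame(self, frame) -> FrameScore:
        img = frame.image if hasattr(frame, "image") else np.asarray(frame)
        y = estimate_severity_from_texture(img)
        if self.noise_sd > 0:
            rng = np.random.default_rng(frame_content_seed(img, salt=self.seed))
            y += rng.normal(0.0, self.noise_sd)
        return FrameScore(
            severity=float(np.clip(y, 0.0, 3.0)),
            error=max(self.noise_sd, self.eps),
        )


# --------------------------------------------------------------------------
# Trainable residual regressor
# --------------------------------------------------------------------------


@dataclass
class ScorerConfig:
    """Configuration of the trainable scorer.

    ``blocks`` is the residual block schedule of the four stages (the
    full-scale reference schedule is ``(3, 4, 6, 3)`` with base width 64;
    the desk-scale default ``(1, 1, 1, 1)`` with base width 8 trains in
    seconds on a CPU).  Stage widths double at each stage.
    """

    blocks: tuple[int, int, int, int] = (1, 1, 1, 1)
    base_width: int = 8
    input_size: int = 64
    phase1_epochs: int = 200
    phase2_epochs: int = 400
    learning_rate: float = 3e-3
    phase2_lr_scale: float = 0.3  # phase 2 uses a smaller step
    w_max: float = 100.0
    weight_decay: float = 1e-3  # decoupled L2 on weight matrices
    error_floor: float = DEFAULT_ERROR_FLOOR
    seed: int = 0

    def validate(self) -> None:
        if len(self.blocks) != 4:
            raise ValueError("block schedule must have exactly 4 stages")
        if any(b < 0 for b in self.blocks):
            raise ValueError("block counts must be >= 0")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")


def _avg_pool2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def texture_features(gray: np.ndarray, stamp_block: int = 16) -> np.ndarray:
    """Fixed multi-scale stem: roughness statistics over a pooling pyramid.

    The position-stamp rows are excluded from the texture statistics; the
    decoded stamp value (if present) is appended as the final feature.
    """
    from .preprocessing import decode_position

    img = np.asarray(gray, dtype=float)
    try:
        pos = decode_position(img, block=stamp_block)
    except ValueError:
        pos = 0.5
    body = img[stamp_block:, :]  # drop stamped rows
    mu, sd = body.mean(), body.std()
    z = (body - mu) / max(sd, 1e-9)
    feats = [mu / 255.0, sd / 255.0]
    level = z
    for _ in range(4):
        dx = np.abs(np.diff(level, axis=1)).mean()
        dy = np.abs(np.diff(level, axis=0)).mean()
        lap = np.abs(
            level[1:-1, 1:-1] * 4
            - level[:-2, 1:-1]
            - level[2:, 1:-1]
            - level[1:-1, :-2]
            - level[1:-1, 2:]
        ).mean()
        feats += [0.5 * (dx + dy), lap, level.std()]
        level = _avg_pool2(level)
    feats.append(pos)
    return np.asarray(feats)


def _softplus(z):
    return np.logaddexp(0.0, z)


class _Adam:
    """Adam with decoupled weight decay on 2-D weight matrices."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)
            if self.wd and params[k].ndim == 2:
                params[k] -= self.lr * self.wd * params[k]


class ResidualRegressor:
    """Residual MLP over the fixed texture stem, with severity + error heads.

    The network is a 4-stage residual trunk: stage ``i`` has
    ``config.blocks[i]`` residual blocks of width ``base_width * 2**i``,
    each block ``h -> h + W2 relu(W1 h)``, with a linear+relu transition
    between stages.  Heads: a linear severity output and an error output
    ``ehat = eps + softplus(z)`` initialized at the floor (weights zero,
    large negative bias), so an untrained error head predicts ``~eps``.
    """

    def __init__(self, config: ScorerConfig):
        config.validate()
        self.config = config
        self.eps = config.error_floor
        rng = np.random.default_rng(config.seed)
        d_in = texture_features(np.zeros((config.input_size, config.input_size))).size
        widths = [config.base_width * 2**i for i in range(4)]
        P: dict[str, np.ndarray] = {}

        def init(shape, scale):
            return rng.normal(0.0, scale, size=shape)

        P["Win"] = init((d_in, widths[0]), 1.0 / np.sqrt(d_in))
        P["bin"] = np.zeros(widths[0])
        for s in range(4):
            w = widths[s]
            for b in range(config.blocks[s]):
                P[f"W1_{s}_{b}"] = init((w, w), np.sqrt(2.0 / w))
                P[f"b1_{s}_{b}"] = np.zeros(w)
                P[f"W2_{s}_{b}"] = init((w, w), 0.1 * np.sqrt(2.0 / w))
                P[f"b2_{s}_{b}"] = np.zeros(w)
            if s < 3:
                P[f"Wt_{s}"] = init((w, widths[s + 1]), np.sqrt(2.0 / w))
                P[f"bt_{s}"] = np.zeros(widths[s + 1])
        P["Wy"] = init((widths[3], 1), 1.0 / np.sqrt(widths[3]))
        P["by"] = np.array([1.5])  # mid-scale output at init
        P["We"] = np.zeros((widths[3], 1))
        # error head starts just above the floor (softplus(-4) ~ 0.018) while
        # keeping a live gradient for phase 2
        P["be"] = np.array([-4.0])
        self.params = P
        self._feat_mu = np.zeros(d_in)
        self._feat_sd = np.ones(d_in)
        self._widths = widths

    # ---- forward / backward -------------------------------------------

    def _forward(self, X):
        P, cache = self.params, {}
        h = X @ P["Win"] + P["bin"]
        cache["X"] = X
        cache["h0_pre"] = h
        h = np.maximum(h, 0.0)
        cache["h"] = [h]
        for s in range(4):
            for b in range(self.config.blocks[s]):
                a_pre = h @ P[f"W1_{s}_{b}"] + P[f"b1_{s}_{b}"]
                a = np.maximum(a_pre, 0.0)
                h = h + a @ P[f"W2_{s}_{b}"] + P[f"b2_{s}_{b}"]
                cache[f"a_{s}_{b}"] = (a_pre, a)
                cache["h"].append(h)
            if s < 3:
                t_pre = h @ P[f"Wt_{s}"] + P[f"bt_{s}"]
                h = np.maximum(t_pre, 0.0)
                cache[f"t_{s}"] = t_pre
                cache["h"].append(h)
        y = (h @ P["Wy"] + P["by"])[:, 0]
        z = (h @ P["We"] + P["be"])[:, 0]
        cache["h_top"] = h
        cache["z"] = z
        return y, self.eps + _softplus(z), cache

    def _backward(self, cache, dy, dz):
        """Backprop given d(loss)/d(y_hat) and d(loss)/d(z)."""
        P = self.params
        G = {k: np.zeros_like(v) for k, v in P.items()}
        h_top = cache["h_top"]
        G["Wy"] = h_top.T @ dy[:, None]
        G["by"] = np.array([dy.sum()])
        G["We"] = h_top.T @ dz[:, None]
        G["be"] = np.array([dz.sum()])
        dh = dy[:, None] @ P["Wy"].T + dz[:, None] @ P["We"].T
        hs = cache["h"]
        idx = len(hs) - 1
        for s in range(3, -1, -1):
            if s < 3:
                t_pre = cache[f"t_{s}"]
                dt = dh * (t_pre > 0)
                h_prev = hs[idx - 1]
                G[f"Wt_{s}"] = h_prev.T @ dt
                G[f"bt_{s}"] = dt.sum(axis=0)
                dh = dt @ P[f"Wt_{s}"].T
                idx -= 1
            for b in range(self.config.blocks[s] - 1, -1, -1):
                a_pre, a = cache[f"a_{s}_{b}"]
                h_prev = hs[idx - 1]
                G[f"W2_{s}_{b}"] = a.T @ dh
                G[f"b2_{s}_{b}"] = dh.sum(axis=0)
                da = (dh @ P[f"W2_{s}_{b}"].T) * (a_pre > 0)
                G[f"W1_{s}_{b}"] = h_prev.T @ da
                G[f"b1_{s}_{b}"] = da.sum(axis=0)
                dh = dh + da @ P[f"W1_{s}_{b}"].T
                idx -= 1
        dh = dh * (cache["h0_pre"] > 0)
        G["Win"] = cache["X"].T @ dh
        G["bin"] = dh.sum(axis=0)
        return G

    # ---- training ------------------------------------------------------

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ResidualRegressor":
        cfg = self.config
        y = np.asarray(labels, dtype=float)
        if np.unique(y).size < 2:
            warnings.warn("degenerate labels (all equal); model returned untrained-ish")
        self._feat_mu = features.mean(axis=0)
        self._feat_sd = np.maximum(features.std(axis=0), 1e-9)
        X = (features - self._feat_mu) / self._feat_sd
        n = X.shape[0]

        # phase 1: mean squared severity error, severity path only
        opt = _Adam(self.params, cfg.learning_rate, cfg.weight_decay)
        for _ in range(cfg.phase1_epochs):
            y_hat, _, cache = self._forward(X)
            dy = 2.0 * (y_hat - y) / n
            G = self._backward(cache, dy, np.zeros(n))
            opt.step(self.params, G)

        # phase 2: add the error head; |err| + w * ||err| - ehat|, w ramps 0 -> w_max
        if cfg.phase2_epochs > 0:
            opt = _Adam(self.params, cfg.learning_rate * cfg.phase2_lr_scale, cfg.weight_decay)
            for step in range(1, cfg.phase2_epochs + 1):
                w = ramp_weight(step, cfg.phase2_epochs, cfg.w_max)
                y_hat, e_hat, cache = self._forward(X)
                r = y - y_hat
                abs_err = np.abs(r)
                s_outer = np.sign(abs_err - e_hat)
                dy = (-np.sign(r) * (1.0 + w * s_outer)) / n
                # d ehat/dz = sigmoid(z)
                dz = (w * (-s_outer) * (1.0 / (1.0 + np.exp(-cache["z"])))) / n
                G = self._backward(cache, dy, dz)
                opt.step(self.params, G)
        return self

    # ---- inference -----------------------------------------------------

    def score_features(self, features: np.ndarray):
        X = (np.atleast_2d(features) - self._feat_mu) / self._feat_sd
        y_hat, e_hat, _ = self._forward(X)
        return np.clip(y_hat, 0.0, 3.0), np.maximum(e_hat, self.eps)

    def score_frame(self, frame) -> FrameScore:
        img = frame.image if hasattr(frame, "image") else np.asarray(frame)
        gray = img if img.ndim == 2 else np.cbrt(img[..., 0] * img[..., 1] * img[..., 2])
        if gray.shape[0] != self.config.input_size or gray.shape[1] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}x{self.config.input_size} input, "
                f"got {gray.shape[0]}x{gray.shape[1]}"
            )
        y, e = self.score_features(texture_features(gray))
        return FrameScore(severity=float(y[0]), error=float(e[0]))


def train_scorer(frames, labels, config: ScorerConfig | None = None) -> ResidualRegressor:
    """Train the residual regressor on preprocessed grayscale frames.

    ``frames`` is a sequence of 2-D rasters at the configured input size;
    ``labels`` the continuous severity targets in [0, 3].  Training is
    deterministic given ``config.seed``.
    """
    config = config or ScorerConfig()
    model = ResidualRegressor(config)
    feats = np.stack([texture_features(np.asarray(f, dtype=float)) for f in frames])
    return model.fit(feats, np.asarray(labels, dtype=float))


def score_frame(model, frame) -> FrameScore:
    """Score one preprocessed frame with any backend exposing ``score_frame``."""
    return model.score_frame(frame)
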