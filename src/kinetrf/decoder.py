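"""Backward temporal response function: envelope reconstruction by ridge.

The decoder is a linear map from lagged multichannel kinematics to the
speech amplitude envelope,

    env(t) ≈ b + Σ_c Σ_τ w[c, τ] · kin_c(t + τ),

with lags τ spanning −1000 … +200 ms (negative lag = motion *precedes*
the envelope sample). Weights are estimated by ridge regression on
z-scored inputs; performance is the Pearson correlation between predicted
and actual envelope on held-out ~15 s folds, with the regularization
strength chosen by inner leave-one-fold-out cross-validation.

Cross-validation pools training data across files within a condition and
rotates every fold through the test role, so each fold of each file
contributes one correlation coefficient. For efficiency the normal
equations are accumulated per fold (Gram matrices), so any train/test
split is a sum of precomputed blocks and each ridge solve is a single
Cholesky factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import pearsonr

from .containers import EnvelopeSeries, KinematicSeries

#: Default regularization grid: decade steps on z-scored data.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 7))

DEFAULT_FOLD_SECONDS = 15.0
MIN_FOLD_SECONDS = 10.0


@dataclass(frozen=True)
class LagWindow:
    """Decoder lag window in milliseconds relative to the envelope sample.

    ``t_min_ms = -1000`` reaches one second of motion *before* the envelope
    sample, ``t_max_ms = +200`` reaches 200 ms after it.
    """

    t_min_ms: float = -1000.0
    t_max_ms: float = 200.0
    rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.t_min_ms >= self.t_max_ms:
            raise ValueError("t_min_ms must be below t_max_ms")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def lags_samples(self) -> np.ndarray:
        lo = int(round(self.t_min_ms / 1000.0 * self.rate_hz))
        hi = int(round(self.t_max_ms / 1000.0 * self.rate_hz))
        return np.arange(lo, hi + 1)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags_samples / self.rate_hz * 1000.0

    @property
    def n_lags(self) -> int:
        return self.lags_samples.size


def make_folds(n_samples: int, rate_hz: float,
               fold_seconds: float = DEFAULT_FOLD_SECONDS) -> list[tuple[int, int]]:
    """Partition ``n_samples`` into ⌊duration / fold_seconds⌋ contiguous,
    near-equal folds covering every sample; each fold is ≥ 10 s."""
    duration = n_samples / rate_hz
    n_folds = int(duration // fold_seconds)
    if n_folds < 1:
        raise ValueError(f"recording of {duration:.1f} s too short for "
                         f"{fold_seconds:.0f} s folds")
    bounds = np.linspace(0, n_samples, n_folds + 1).round().astype(int)
    folds = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    if min(b - a for a, b in folds) < MIN_FOLD_SECONDS * rate_hz:
        raise ValueError("fold shorter than 10 s; adjust fold_seconds")
    return folds


def build_lagged_design(kin: KinematicSeries, window: LagWindow) -> np.ndarray:
    """Time-lagged design matrix, shape (n_samples, n_channels * n_lags).

    Row ``t`` holds, for each channel, the series value at ``t + lag`` for
    every lag in the window; out-of-range lags are zero-padded. Column
    order is channel-major with lags ascending: column ``c * n_lags + l``.
    """
    if kin.rate_hz != window.rate_hz:
        raise ValueError("kinematics rate does not match window rate")
    lags = window.lags_samples
    n, c = kin.values.shape
    if n <= lags.max() - lags.min():
        raise ValueError("series shorter than the lag window")
    out = np.zeros((n, c * lags.size))
    for li, lag in enumerate(lags):
        if lag >= 0:
            src = slice(lag, n)
            dst = slice(0, n - lag)
        else:
            src = slice(0, n + lag)
            dst = slice(-lag, n)
        out[dst, li::lags.size] = kin.values[src, :]
    return out


@dataclass
class DecoderModel:
    """A fitted backward decoder: weights over channels × lags plus the
    training normalization that must be reapplied verbatim at prediction."""

    weights: np.ndarray               # (n_channels, n_lags)
    intercept: float
    lam: float
    x_mean: np.ndarray                # per design column
    x_sd: np.ndarray
    channel_meta: list[tuple[str, str]]
    window: LagWindow

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.ravel()


def _zscore_stats(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mu, sd


def _ridge_solve(gram: np.ndarray, cross: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G + λI) w = c; falls back to pseudoinverse if singular."""
    a = gram.copy()
    a[np.diag_indices_from(a)] += lam
    if lam == 0.0:
        sv = np.linalg.svd(a, compute_uv=False, hermitian=True)
        if sv[-1] < sv[0] * a.shape[0] * np.finfo(float).eps:
            warnings.warn("singular system at lambda=0; solving via "
                          "pseudoinverse", RuntimeWarning, stacklevel=2)
            return np.linalg.pinv(a, hermitian=True) @ cross
    try:
        return cho_solve(cho_factor(a, lower=True, check_finite=False),
                         cross, check_finite=False)
    except np.linalg.LinAlgError:
        warnings.warn("singular system; solving via pseudoinverse",
                      RuntimeWarning, stacklevel=2)
        return np.linalg.pinv(a) @ cross


def fit_ridge(design: np.ndarray, envelope: np.ndarray, lam: float,
              channel_meta: list[tuple[str, str]] | None = None,
              window: LagWindow | None = None) -> DecoderModel:
    """Ridge regression of the envelope on a lagged design matrix.

    Inputs are z-scored with training statistics and the envelope centered;
    weights solve ``(XᵀX + λI) w = Xᵀy`` on the normalized data, with the
    intercept recovered from the means. ``λ = 0`` is ordinary least squares
    (pseudoinverse with a warning if the design is rank-deficient).
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(envelope, dtype=float).ravel()
    if design.shape[0] != y.size:
        raise ValueError("design rows must match envelope length")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    mu, sd = _zscore_stats(design)
    xz = (design - mu) / sd
    y_mean = y.mean()
    w = _ridge_solve(xz.T @ xz, xz.T @ (y - y_mean), lam)
    if window is None:
        window = LagWindow(0.0, 1.0, rate_hz=1.0)  # placeholder single-lag window
        n_lags = 1
    else:
        n_lags = window.n_lags
    n_channels = design.shape[1] // n_lags
    if channel_meta is None:
        channel_meta = [(f"ch{i}", "x") for i in range(n_channels)]
    return DecoderModel(w.reshape(n_channels, n_lags), float(y_mean),
                        float(lam), mu, sd, channel_meta, window)


def predict_envelope(model: DecoderModel, kin: KinematicSeries,
                     window: LagWindow | None = None) -> EnvelopeSeries:
    """Apply a fitted decoder to kinematics; returns the predicted envelope
    (a linear readout, so values may be negative)."""
    window = window or model.window
    if list(kin.channel_meta) != list(model.channel_meta):
        raise ValueError("channel metadata does not match the trained model")
    design = build_lagged_design(kin, window)
    pred = ((design - model.x_mean) / model.x_sd) @ model.flat_weights \
        + model.intercept
    return EnvelopeSeries(pred, kin.rate_hz)


def score_pearson(predicted, actual) -> float:
    """Pearson correlation between predicted and actual envelope."""
    p = predicted.values if isinstance(predicted, EnvelopeSeries) else np.asarray(predicted, float)
    a = actual.values if isinstance(actual, EnvelopeSeries) else np.asarray(actual, float)
    if p.size != a.size:
        raise ValueError("length mismatch")
    if p.size < 3:
        raise ValueError("need at least 3 samples")
    if p.std() == 0 or a.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    return float(pearsonr(p, a)[0])


# ---------------------------------------------------------------------------
# Gram-block cross-validation machinery


class _FoldBlocks:
    """Per-fold sufficient statistics for pooled ridge fits.

    The design is built on the continuous per-file series (zero-padded only
    at file boundaries) and folds are row slices of it, so fold lengths are
    exact and no envelope values cross fold boundaries.
    """

    def __init__(self, kin_list: list[KinematicSeries],
                 env_list: list[EnvelopeSeries], window: LagWindow,
                 fold_seconds: float) -> None:
        if len(kin_list) != len(env_list):
            raise ValueError("kinematics and envelope lists differ in length")
        self.window = window
        self.channel_meta = list(kin_list[0].channel_meta)
        self.designs: list[np.ndarray] = []      # per file
        self.targets: list[np.ndarray] = []
        self.folds: list[list[tuple[int, int]]] = []
        p = kin_list[0].n_channels * window.n_lags
        self.gram: dict[tuple[int, int], np.ndarray] = {}
        self.cross: dict[tuple[int, int], np.ndarray] = {}
        self.xsum: dict[tuple[int, int], np.ndarray] = {}
        self.ysum: dict[tuple[int, int], float] = {}
        self.count: dict[tuple[int, int], int] = {}
        for f, (kin, env) in enumerate(zip(kin_list, env_list)):
            if list(kin.channel_meta) != self.channel_meta:
                raise ValueError("inconsistent channels across files")
            if kin.n_samples != env.n_samples:
                raise ValueError(f"file {f}: kinematics and envelope lengths "
                                 "differ; align first")
            design = build_lagged_design(kin, window)
            y = env.values
            folds = make_folds(kin.n_samples, kin.rate_hz, fold_seconds)
            self.designs.append(design)
            self.targets.append(y)
            self.folds.append(folds)
            for j, (a, b) in enumerate(folds):
                xf = design[a:b]
                yf = y[a:b]
                self.gram[f, j] = xf.T @ xf
                self.cross[f, j] = xf.T @ yf
                self.xsum[f, j] = xf.sum(axis=0)
                self.ysum[f, j] = float(yf.sum())
                self.count[f, j] = b - a
        self.n_files = len(kin_list)
        self.n_folds = [len(f) for f in self.folds]
        self.p = p

    def train_stats(self, held_out: dict[int, int]):
        """Aggregate z-scoring statistics and normalized normal equations
        over all folds except the held-out fold of each file."""
        keys = [(f, j) for f in range(self.n_files)
                for j in range(self.n_folds[f])
                if not _held_out_contains(held_out, f, j)]
        n = sum(self.count[k] for k in keys)
        xs = sum(self.xsum[k] for k in keys)
        ys = sum(self.ysum[k] for k in keys)
        g = sum(self.gram[k] for k in keys)
        c = sum(self.cross[k] for k in keys)
        mu = xs / n
        var = np.maximum(np.diag(g) / n - mu ** 2, 0.0)
        sd = np.sqrt(var)
        sd[sd < 1e-12] = 1.0
        y_mean = ys / n
        # center then scale: Gram and cross of ((X - mu) / sd, y - y_mean)
        gc = (g - np.outer(mu, xs) - np.outer(xs, mu) + n * np.outer(mu, mu))
        gc /= np.outer(sd, sd)
        cc = (c - mu * ys - xs * y_mean + n * mu * y_mean) / sd
        return mu, sd, y_mean, gc, cc

    def solve(self, held_out: dict[int, int], lam: float) -> DecoderModel:
        mu, sd, y_mean, gc, cc = self.train_stats(held_out)
        w = _ridge_solve(gc, cc, lam)
        n_channels = len(self.channel_meta)
        return DecoderModel(w.reshape(n_channels, self.window.n_lags),
                            float(y_mean), float(lam), mu, sd,
                            self.channel_meta, self.window)

    def score_fold(self, model: DecoderModel, file: int, fold: int,
                   column_signs: np.ndarray | None = None) -> tuple[float, int]:
        """Pearson r on the held-out fold, scored on its interior.

        Guard bands of one lag-window width at each fold edge are excluded
        from scoring: edge rows share feature windows with adjacent training
        rows, which would otherwise let the decoder's fit to neighboring
        training samples bleed into the held-out score.
        """
        a, b = self.folds[file][fold]
        lags = self.window.lags_samples
        a_s = a + max(-int(lags.min()), 0)
        b_s = b - max(int(lags.max()), 0)
        if b_s - a_s < 3:
            a_s, b_s = a, b  # degenerate: fold barely longer than the window
        x = self.designs[file][a_s:b_s]
        if column_signs is not None:
            x = x * column_signs
        pred = ((x - model.x_mean) / model.x_sd) @ model.flat_weights \
            + model.intercept
        return score_pearson(pred, self.targets[file][a_s:b_s]), b_s - a_s


def tune_lambda(blocks: _FoldBlocks, grid, outer_held_out: dict[int, int]):
    """Inner leave-one-fold-out selection of the ridge parameter.

    For each λ in ``grid``, every remaining training fold is held out in
    turn, the decoder is refitted on the rest, and the held-out folds are
    scored; the λ with the best mean Pearson r wins (ties → smaller λ).
    Returns ``(lambda, scores_by_lambda)``.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty lambda grid")
    inner_sets = []
    max_folds = max(blocks.n_folds)
    for j in range(max_folds):
        inner = {}
        for f in range(blocks.n_files):
            candidates = [q for q in range(blocks.n_folds[f])
                          if q != outer_held_out.get(f)]
            if not candidates:
                raise ValueError("need at least 2 folds per file to tune")
            inner[f] = candidates[j % len(candidates)]
        if inner not in inner_sets:
            inner_sets.append(inner)
    if len(inner_sets) < 2 and len(grid) > 1:
        raise ValueError("need at least 2 training folds per file to tune "
                         "lambda")
    scores = {}
    for lam in grid:
        rs = []
        for inner in inner_sets:
            # exclude both the outer test fold and the inner validation fold
            model = blocks.solve(_merge_held_out(outer_held_out, inner,
                                                 blocks.n_folds), lam)
            for f, j in inner.items():
                rs.append(blocks.score_fold(model, f, j)[0])
        scores[lam] = float(np.mean(rs))
    best = max(grid, key=lambda l: (scores[l], -l))
    return best, scores


def _merge_held_out(outer: dict[int, int], inner: dict[int, int],
                    n_folds: list[int]) -> dict[int, set]:
    merged: dict[int, set] = {}
    for f in range(len(n_folds)):
        s = set()
        if f in outer:
            s.add(outer[f])
        if f in inner:
            s.add(inner[f])
        merged[f] = s
    return merged


# _FoldBlocks.train_stats uses `held_out.get(f) != j`; support sets too.
def _held_out_contains(held_out, f, j) -> bool:
    v = held_out.get(f)
    if isinstance(v, set):
        return j in v
    return v == j


def crossvalidate(kin_list: list[KinematicSeries],
                  env_list: list[EnvelopeSeries],
                  window: LagWindow | None = None,
                  lambda_grid=DEFAULT_LAMBDA_GRID,
                  fold_seconds: float = DEFAULT_FOLD_SECONDS,
                  test_transforms: dict[str, np.ndarray | None] | None = None,
                  file_ids: list | None = None,
                  condition: dict | None = None,
                  lam: float | None = None,
                  n_rotations: int | None = None):
    """Full fold-rotation cross-validation of the backward decoder.

    One decoder per rotation is trained on the pooled training folds of all
    files; the held-out fold of each file is scored by Pearson correlation.
    ``n_rotations`` limits how many folds rotate through the test role
    (default: all). With ``n_rotations=1`` a single fold per file is scored
    — fewer scores, but they are statistically independent across files,
    whereas full rotation makes fold scores covary (each rotation's model
    is trained on the other rotations' test folds).
    λ is tuned once (inner leave-one-fold-out on the first rotation's
    training folds) unless ``lam`` is given. ``test_transforms`` maps an
    orientation label to per-column sign flips applied to *test* features
    only (``None`` = preserved).

    Returns ``(results, mean_model, info)``: a tidy DataFrame with one row
    per fold × file × transform, the across-rotation mean decoder (for
    weight maps), and a dict with the selected λ and fold boundaries.
    """
    window = window or LagWindow(rate_hz=kin_list[0].rate_hz)
    blocks = _FoldBlocks(kin_list, env_list, window, fold_seconds)
    if min(blocks.n_folds) < 2:
        raise ValueError("need at least 2 folds per file for cross-validation")
    if test_transforms is None:
        test_transforms = {"preserved": None}
    rotation0 = {f: 0 for f in range(blocks.n_files)}
    if lam is None:
        if len(lambda_grid) == 1:
            lam, lam_scores = float(next(iter(lambda_grid))), {}
        else:
            lam, lam_scores = tune_lambda(blocks, lambda_grid, rotation0)
    else:
        lam_scores = {}
    if file_ids is None:
        file_ids = list(range(blocks.n_files))
    rows = []
    weight_sum = None
    if n_rotations is None:
        n_rotations = max(blocks.n_folds)
    n_rotations = min(n_rotations, max(blocks.n_folds))
    for k in range(n_rotations):
        held = {f: k % blocks.n_folds[f] for f in range(blocks.n_files)}
        model = blocks.solve(held, lam)
        weight_sum = model.weights if weight_sum is None \
            else weight_sum + model.weights
        for f in range(blocks.n_files):
            j = held[f]
            if k >= blocks.n_folds[f]:
                continue  # fold already scored in an earlier rotation
            for label, signs in test_transforms.items():
                r, n = blocks.score_fold(model, f, j, column_signs=signs)
                row = {"file": file_ids[f], "fold": j, "orientation": label,
                       "r": r, "n_samples": n}
                if condition:
                    row.update(condition)
                rows.append(row)
    mean_model = blocks.solve({}, lam)  # normalization from all data
    mean_model.weights = weight_sum / n_rotations
    results = pd.DataFrame(rows)
    if len(test_transforms) == 1 and "preserved" in test_transforms:
        results = results.drop(columns=["orientation"])
    info = {"lambda": lam, "lambda_scores": lam_scores,
            "folds": blocks.folds, "n_rotations": n_rotations}
    return results, mean_model, info


def column_signs_for_axis(channel_meta: list[tuple[str, str]],
                          window: LagWindow, axis: str) -> np.ndarray:
    """Per-design-column sign vector that inverts one spatial axis."""
    signs = np.ones(len(channel_meta) * window.n_lags)
    for c, (_, ax) in enumerate(channel_meta):
        if ax == axis:
            signs[c * window.n_lags:(c + 1) * window.n_lags] = -1.0
    return signs


def summarize_weights(model: DecoderModel) -> pd.DataFrame:
    """Per-segment importance: mean over lags of |weight|, by channel."""
    imp = np.abs(model.weights).mean(axis=1)
    rows = [{"segment": seg, "axis": ax, "importance": v}
            for (seg, ax), v in zip(model.channel_meta, imp)]
    return pd.DataFrame(rows)
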