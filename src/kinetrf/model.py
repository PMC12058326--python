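"""Model/Results front end for the backward envelope decoder.

``EnvelopeDecoder`` is constructed from data (kinematic feature series and
matched envelopes) plus the decoding hyper-structure (lag window, fold
length, λ grid); ``fit()`` runs the full fold-rotation cross-validation
and returns a ``DecodingResults`` object carrying per-fold correlations,
the across-rotation mean weights, and summary/plot helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EnvelopeSeries, KinematicSeries
from .decoder import (DEFAULT_FOLD_SECONDS, DEFAULT_LAMBDA_GRID, DecoderModel,
                      LagWindow, column_signs_for_axis, crossvalidate,
                      predict_envelope, summarize_weights)


class EnvelopeDecoder:
    """Backward TRF decoder of the speech envelope from body kinematics.

    Parameters
    ----------
    kinematics : KinematicSeries or list of KinematicSeries
        Decoder inputs, one series per recording (file). All series must
        share rate and channel layout.
    envelopes : EnvelopeSeries or list of EnvelopeSeries
        Matched amplitude envelopes at the same rate and length.
    window : LagWindow, optional
        Lag window; defaults to −1000 … +200 ms at the data rate.
    fold_seconds : float
        Cross-validation fold length (contiguous spans, default 15 s).
    lambda_grid : sequence of float
        Ridge grid searched by inner cross-validation.

    Examples
    --------
    >>> model = EnvelopeDecoder(kin_list, env_list)
    >>> res = model.fit()
    >>> res.mean_r
    0.8...
    >>> print(res.summary())
    """

    def __init__(self, kinematics, envelopes, window: LagWindow | None = None,
                 fold_seconds: float = DEFAULT_FOLD_SECONDS,
                 lambda_grid=DEFAULT_LAMBDA_GRID,
                 file_ids: list | None = None) -> None:
        if isinstance(kinematics, KinematicSeries):
            kinematics = [kinematics]
        if isinstance(envelopes, EnvelopeSeries):
            envelopes = [envelopes]
        self.kinematics = list(kinematics)
        self.envelopes = list(envelopes)
        if len(self.kinematics) != len(self.envelopes):
            raise ValueError("need one envelope per kinematic series")
        rate = self.kinematics[0].rate_hz
        self.window = window or LagWindow(rate_hz=rate)
        if self.window.rate_hz != rate:
            raise ValueError("window rate must match the data rate")
        self.fold_seconds = fold_seconds
        self.lambda_grid = tuple(lambda_grid)
        self.file_ids = file_ids

    @classmethod
    def from_dataframes(cls, kin_frames: list[pd.DataFrame],
                        env_frames: list[pd.DataFrame], rate_hz: float,
                        **kwargs) -> "EnvelopeDecoder":
        """Build from wide kinematic tables (``SEG_axis`` columns) and
        two-column envelope tables (time, amplitude)."""
        kins, envs = [], []
        for kf, ef in zip(kin_frames, env_frames):
            cols = [c for c in kf.columns if c != "time"]
            meta = [tuple(c.rsplit("_", 1)) for c in cols]
            kins.append(KinematicSeries(kf[cols].to_numpy(), meta, rate_hz,
                                        1, "velocity"))
            envs.append(EnvelopeSeries(ef["amplitude"].to_numpy(), rate_hz))
        return cls(kins, envs, **kwargs)

    def fit(self, lam: float | None = None, orientations: bool = False,
            n_rotations: int | None = None) -> "DecodingResults":
        """Cross-validate the decoder.

        With ``orientations=True`` each held-out fold is additionally scored
        on horizontally and vertically mirrored test features (training data
        untouched), as in the inversion generalization analysis.
        """
        transforms = None
        if orientations:
            transforms = {
                "preserved": None,
                "horizontal_inversion": column_signs_for_axis(
                    self.kinematics[0].channel_meta, self.window, "x"),
                "vertical_inversion": column_signs_for_axis(
                    self.kinematics[0].channel_meta, self.window, "y"),
            }
        table, mean_model, info = crossvalidate(
            self.kinematics, self.envelopes, self.window, self.lambda_grid,
            self.fold_seconds, test_transforms=transforms,
            file_ids=self.file_ids, lam=lam, n_rotations=n_rotations)
        return DecodingResults(self, table, mean_model, info)


class DecodingResults:
    """Fitted decoder results: per-fold correlations and mean weights."""

    def __init__(self, model: EnvelopeDecoder, table: pd.DataFrame,
                 mean_model: DecoderModel, info: dict) -> None:
        self.model = model
        self.table = table
        self.mean_model = mean_model
        self.lambda_ = info["lambda"]
        self.info = info

    @property
    def mean_r(self) -> float:
        t = self.table
        if "orientation" in t.columns:
            t = t[t["orientation"] == "preserved"]
        return float(t["r"].mean())

    def mean_r_by(self, *cols: str) -> pd.Series:
        return self.table.groupby(list(cols))["r"].mean()

    def predict(self, kin: KinematicSeries) -> EnvelopeSeries:
        """Predict an envelope with the across-rotation mean decoder."""
        return predict_envelope(self.mean_model, kin)

    def weight_map(self) -> pd.DataFrame:
        """Per-segment, per-axis importance (mean |weight| over lags)."""
        return summarize_weights(self.mean_model)

    def plot_weight_map(self, ax=None):
        """Bar plot of decoder weight importance by segment and axis."""
        import matplotlib.pyplot as plt

        wm = self.weight_map()
        pivot = wm.pivot(index="segment", columns="axis", values="importance")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("mean |weight| over lags")
        ax.set_title("Decoder weight importance by body segment")
        return ax

    def summary(self) -> str:
        lines = ["Backward envelope decoder (ridge TRF)",
                 "=" * 44,
                 f"files:            {len(self.model.kinematics)}",
                 f"channels:         {self.model.kinematics[0].n_channels}",
                 f"lag window:       {self.model.window.t_min_ms:.0f} to "
                 f"{self.model.window.t_max_ms:.0f} ms "
                 f"({self.model.window.n_lags} lags)",
                 f"fold length:      {self.model.fold_seconds:.0f} s",
                 f"lambda:           {self.lambda_:g}",
                 f"folds scored:     {len(self.table)}"]
        if "orientation" in self.table.columns:
            for label, r in self.mean_r_by("orientation").items():
                lines.append(f"mean r ({label}): {r:+.3f}")
        else:
            r = self.table["r"]
            sem = r.std(ddof=1) / np.sqrt(len(r))
            lines.append(f"mean r:           {r.mean():+.3f} "
                         f"(± {1.96 * sem:.3f} 95% CI)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DecodingResults: mean r = {self.mean_r:.3f}>"
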