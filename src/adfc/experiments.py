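"""Analysis layer for OFF-ON-OFF stimulation experiments.

Covers the study design around the controllers: per-segment metric
triplets for 5-min OFF/ON/OFF trials, fold-change normalisation to the
pre-stimulation baseline (ratio for synchrony and firing rate,
difference for the dB-scaled oscillation intensity), MANOVA-based
controllability classification across stimulation protocols,
PC1 projection of baseline dynamics, Gaussian-mixture state clustering
of sliding-window metrics, and time spent in the asynchronous state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.multivariate.manova import MANOVA

from . import metrics as _metrics
from .types import MetricsTriplet, SpikeTrainSet

__all__ = [
    "TrialResult",
    "NetworkStudy",
    "StateClustering",
    "run_protocol_trial",
    "fold_change",
    "classify_controllability",
    "baseline_pc1_projection",
    "cluster_network_states",
    "time_in_asynchronous_state",
]

#: A cluster is an asynchronous state when its mean synchrony is below this.
AS_SYNCHRONY_THRESHOLD = 0.5


@dataclass
class TrialResult:
    """Metric triplets for the three segments of one OFF-ON-OFF trial."""

    protocol: str
    metrics_off_pre: MetricsTriplet
    metrics_on: MetricsTriplet
    metrics_off_post: MetricsTriplet
    mean_stim_frequency: float = float("nan")


@dataclass
class NetworkStudy:
    """All trials performed on one network (culture on one day)."""

    network_id: str
    trials: list[TrialResult] = field(default_factory=list)

    def trials_by_protocol(self) -> dict[str, list[TrialResult]]:
        out: dict[str, list[TrialResult]] = {}
        for tr in self.trials:
            out.setdefault(tr.protocol, []).append(tr)
        return out

    def fold_change_table(self) -> pd.DataFrame:
        """Per-trial ON fold changes with the protocol label."""
        rows = []
        for tr in self.trials:
            on, _ = fold_change(tr)
            rows.append({"protocol": tr.protocol, "synchrony": on[0],
                         "firing_rate": on[1], "oscillation_intensity": on[2]})
        return pd.DataFrame(rows)


def run_protocol_trial(
    spikes: SpikeTrainSet,
    protocol: str,
    segment_durations: tuple[float, float, float] = (300.0, 300.0, 300.0),
    mean_stim_frequency: float = float("nan"),
    **metric_kwargs,
) -> TrialResult:
    """Compute the per-segment metric triplets of one OFF-ON-OFF trial.

    ``segment_durations`` must tile the recording exactly (default three
    5-minute segments)."""
    d_pre, d_on, d_post = segment_durations
    total = d_pre + d_on + d_post
    if abs(total - spikes.duration) > 1e-6:
        raise ValueError(
            f"segments ({total} s) do not cover the recording ({spikes.duration} s)")
    t0 = spikes.t_start
    bounds = [t0, t0 + d_pre, t0 + d_pre + d_on, t0 + total]
    segs = [spikes.slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    triplets = [_metrics.compute_metrics(s, **metric_kwargs) for s in segs]
    return TrialResult(protocol, *triplets, mean_stim_frequency=mean_stim_frequency)


def fold_change(trial: TrialResult) -> tuple[tuple[float, float, float],
                                             tuple[float, float, float]]:
    """Normalise ON and post-OFF metrics to the pre-stimulation baseline.

    Synchrony and firing rate as ratios to the pre-OFF values;
    oscillation intensity as the difference in dB (the SNR scale is
    logarithmic, so the difference is the fold change). Returns
    ``(on, off_post)`` normalised triplets.
    """
    pre = trial.metrics_off_pre
    if not (pre.synchrony > 0 and pre.firing_rate > 0):
        raise ValueError("pre-stimulation synchrony and firing rate must be positive")

    def _norm(seg: MetricsTriplet) -> tuple[float, float, float]:
        return (seg.synchrony / pre.synchrony,
                seg.firing_rate / pre.firing_rate,
                seg.oscillation_intensity - pre.oscillation_intensity)

    return _norm(trial.metrics_on), _norm(trial.metrics_off_post)


def classify_controllability(
    study: NetworkStudy | pd.DataFrame,
    alpha: float = 0.05,
    min_trials: int = 3,
) -> tuple[float, str]:
    """MANOVA controllability gate across stimulation protocols.

    One-way MANOVA (Wilks' lambda) of the normalised ON metric triplets
    with the protocol as factor. A network whose protocols drive it to
    separable regions of the metric space (p < alpha) is *controllable*.

    Accepts a :class:`NetworkStudy` or a DataFrame with columns
    ``protocol, synchrony, firing_rate, oscillation_intensity``. Requires
    at least ``min_trials`` trials for each of at least 3 protocols.
    """
    table = study.fold_change_table() if isinstance(study, NetworkStudy) else study.copy()
    counts = table["protocol"].value_counts()
    if len(counts) < 3:
        raise ValueError(f"need at least 3 protocols, got {len(counts)}")
    if (counts < min_trials).any():
        low = counts[counts < min_trials].index.tolist()
        raise ValueError(f"need >= {min_trials} trials per protocol; too few for {low}")
    y = table[["synchrony", "firing_rate", "oscillation_intensity"]].to_numpy(float)
    groups = pd.get_dummies(table["protocol"], drop_first=True).to_numpy(float)
    exog = np.column_stack([np.ones(len(table)), groups])
    mv = MANOVA(endog=y, exog=exog)
    # hypothesis: the protocol-contrast rows are jointly zero
    n_contrast = groups.shape[1]
    contrast = np.column_stack([np.zeros((n_contrast, 1)), np.eye(n_contrast)])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = mv.mv_test(hypotheses=[("protocol", contrast)])
    stats = res.results["protocol"]["stat"]
    p_value = float(stats.loc["Wilks' lambda", "Pr > F"])
    label = "controllable" if p_value < alpha else "uncontrollable"
    return p_value, label


def baseline_pc1_projection(baseline: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, float]:
    """Project baseline (synchrony, firing rate) pairs on their PC1.

    Both features are standardised (z-score) before PCA; the component
    sign is fixed so PC1 loads positively on firing rate. Returns the
    per-experiment scores and the fraction of variance PC1 explains.
    Baseline dynamics of controllable networks concentrate at
    intermediate PC1 scores, flanked by the uncontrollable extremes.
    """
    if isinstance(baseline, pd.DataFrame):
        X = baseline[["synchrony", "firing_rate"]].to_numpy(float)
    else:
        X = np.asarray(baseline, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (synchrony, firing_rate)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 experiments")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature: PC1 undefined")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2).fit(Z)
    load = pca.components_[0]
    if load[1] < 0:  # orient PC1 toward increasing firing rate
        load = -load
    scores = Z @ load
    return scores, float(pca.explained_variance_ratio_[0])


@dataclass
class StateClustering:
    """GMM segmentation of sliding-window dynamics into network states."""

    windows: pd.DataFrame          # t, firing_rate, synchrony, label
    labels: np.ndarray
    cluster_means: pd.DataFrame    # per-cluster mean synchrony / firing rate
    n_components: int
    as_flags: np.ndarray           # per-cluster asynchronous-state flag
    bic: dict

    @property
    def window_as(self) -> np.ndarray:
        """Per-window asynchronous-state flag."""
        return self.as_flags[self.labels]


def cluster_network_states(
    windows: pd.DataFrame,
    max_components: int = 4,
    n_init: int = 10,
    seed: int = 0,
) -> StateClustering:
    """Identify network states from sliding-window (FR, synchrony) points.

    Fits full-covariance Gaussian mixtures with 1..``max_components``
    components (``n_init`` restarts each), selects the component count by
    BIC, labels every window, and flags clusters as asynchronous states
    (AS) when their mean synchrony is below 0.5 and their mean firing
    rate is below the network's average.
    """
    data = windows.dropna(subset=["firing_rate", "synchrony"])
    if len(data) < 10:
        raise ValueError("need at least 10 valid windows for state clustering")
    X = data[["firing_rate", "synchrony"]].to_numpy(float)
    bics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, random_state=seed)
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        fits[k] = gm
    best_k = min(bics, key=bics.get)
    gm = fits[best_k]
    labels = gm.predict(X)
    means = pd.DataFrame(gm.means_, columns=["firing_rate", "synchrony"])
    network_avg_fr = float(X[:, 0].mean())
    as_flags = ((means["synchrony"] < AS_SYNCHRONY_THRESHOLD)
                & (means["firing_rate"] < network_avg_fr)).to_numpy()
    out = data.copy()
    out["label"] = labels
    return StateClustering(windows=out, labels=labels, cluster_means=means,
                           n_components=best_k, as_flags=as_flags, bic=bics)


def time_in_asynchronous_state(
    clustering: StateClustering,
    segments: dict[str, tuple[float, float]],
) -> dict[str, float]:
    """Percentage of window time spent in the AS per recording segment.

    Windows are assigned to segments by their centre time; a segment with
    no windows gets NaN.
    """
    t = clustering.windows["t"].to_numpy(float)
    win_as = clustering.window_as
    out: dict[str, float] = {}
    for name, (t0, t1) in segments.items():
        mask = (t >= t0) & (t < t1)
        out[name] = float(100.0 * win_as[mask].mean()) if mask.any() else float("nan")
    return out
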