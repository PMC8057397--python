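"""Sleep episode detection from heart rate and actigraphy (step counts).

The pipeline mirrors the heuristic-seeded classifier approach: (1) label
epochs that are very likely asleep (long zero-step runs with depressed
heart rate) or very likely awake (high step counts); (2) train candidate
classifiers — a regularized logistic regression and a radial-kernel
support-vector machine — on those seed labels and pick the better by
stratified cross-validated balanced accuracy; (3) classify every epoch and
smooth the per-epoch labels into contiguous sleep episodes.

Because the seed labels come from the subject's own heart-rate distribution
and step counts rather than an assumed clock schedule, shifted sleep (e.g.
shift work) is detected at whatever hours it occurs; time-of-day features
enter only as sin/cos encodings learned from the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.calibration import CalibratedClassifierCV
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (ContractError, EmptyInputError, InsufficientDataError,
                     NoFeaturesError, UntrainableLabelsError)
from .timeseries_io import (BioSeries, Channel, align_series, default_bounds,
                            read_series, validate_series)

logger = logging.getLogger(__name__)

__all__ = ["SleepConfig", "Epoch", "SleepEpisode", "SleepResult",
           "build_epochs", "heuristic_label", "extract_features",
           "train_select_classifier", "classify_epochs", "smooth_to_episodes",
           "detect_sleep_series", "detect_sleep"]

LIKELY_SLEEP = "likely_sleep"
LIKELY_WAKE = "likely_wake"
UNLABELED = "unlabeled"

FEATURE_COLUMNS = ("hr_z", "hr_roll_mean", "hr_roll_sd", "step_roll_sum",
                   "tod_sin", "tod_cos")


@dataclass(frozen=True)
class SleepConfig:
    """Tunables for epoching, heuristic labeling, training, and smoothing.

    Defaults: 5-min epochs; likely-sleep = maximal zero-step runs of at
    least ``run_min`` minutes whose epochs all have mean HR below the
    subject's ``hr_quantile`` HR percentile; likely-wake = epochs with at
    least ``wake_step_min`` steps; 5-fold stratified CV; 5-epoch median
    smoothing; sleep runs separated by under ``merge_gap`` minutes merge;
    episodes shorter than ``min_episode`` minutes are dropped.
    """

    epoch_s: int = 300
    hr_quantile: float = 0.40
    run_min: int = 120
    wake_step_min: float = 50.0
    cv_folds: int = 5
    smooth_width: int = 5
    merge_gap: float = 30.0
    min_episode: float = 60.0
    min_hr_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epoch_s, self.run_min, self.cv_folds, self.smooth_width) <= 0:
            raise ContractError("epoch_s, run_min, cv_folds, smooth_width must be positive")
        if not 0 < self.hr_quantile < 1:
            raise ContractError("hr_quantile must be in (0, 1)")
        if min(self.wake_step_min, self.merge_gap, self.min_episode) < 0:
            raise ContractError("thresholds must be non-negative")


@dataclass(frozen=True)
class Epoch:
    start: pd.Timestamp
    duration: float            # seconds
    mean_hr: float             # bpm; NaN when HR coverage < min_hr_coverage
    step_sum: float            # counts

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ContractError("epoch duration must be > 0")
        if self.step_sum < 0:
            raise ContractError("epoch step_sum must be >= 0")


@dataclass(frozen=True)
class SleepEpisode:
    start: pd.Timestamp
    end: pd.Timestamp
    duration: float            # minutes
    mean_hr: float             # bpm over the episode's epochs (NaN if none)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ContractError("episode end must be after start")

    def to_dict(self) -> dict:
        return {"start": str(self.start), "end": str(self.end),
                "duration_min": self.duration, "mean_hr": self.mean_hr}


def build_epochs(hr: BioSeries, steps: BioSeries, config: SleepConfig) -> pd.DataFrame:
    """Aggregate aligned 1-minute HR/steps onto the epoch grid.

    Returns a DataFrame indexed by epoch start with columns ``mean_hr``
    (NaN when fewer than ``min_hr_coverage`` of the expected HR minutes are
    present) and ``step_sum`` (missing step minutes count 0).
    """
    common = hr.index.intersection(steps.index)
    if not len(common):
        raise EmptyInputError("heart-rate and step series do not overlap")
    per_epoch = int(config.epoch_s // 60)
    rule = pd.Timedelta(seconds=config.epoch_s)
    hr_c = hr.data.loc[common]
    st_c = steps.data.loc[common]
    grouper = dict(origin="epoch", label="left", closed="left")
    mean_hr = hr_c.resample(rule, **grouper).mean()
    hr_count = hr_c.resample(rule, **grouper).count()
    step_sum = st_c.resample(rule, **grouper).sum()
    epochs = pd.DataFrame({"mean_hr": mean_hr, "step_sum": step_sum.fillna(0.0)})
    epochs.loc[hr_count < config.min_hr_coverage * per_epoch, "mean_hr"] = np.nan
    return epochs


def heuristic_label(hr: BioSeries, steps: BioSeries,
                    config: SleepConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Seed-label epochs as likely_sleep / likely_wake / unlabeled.

    likely_sleep: epochs inside maximal runs of at least ``run_min`` minutes
    in which every epoch has zero steps AND mean HR below the subject's
    ``hr_quantile`` percentile of all HR samples. likely_wake: epochs with
    ``step_sum >= wake_step_min``. Everything else is unlabeled.
    """
    config = config or SleepConfig()
    common = hr.index.intersection(steps.index)
    if not len(common):
        raise EmptyInputError("heart-rate and step series do not overlap")
    span = common[-1] - common[0]
    if span < pd.Timedelta(hours=24):
        raise InsufficientDataError(
            f"need >= 24 h of overlapping data; got {span}")
    epochs = build_epochs(hr, steps, config)
    hr_threshold = float(np.quantile(hr.data.loc[common].to_numpy(), config.hr_quantile))

    eligible = (epochs["step_sum"] == 0) & (epochs["mean_hr"] < hr_threshold)
    labels = pd.Series(UNLABELED, index=epochs.index, dtype=object)

    run_epochs = int(np.ceil(config.run_min * 60 / config.epoch_s))
    elig = eligible.to_numpy()
    # contiguity on the epoch clock: a gap in the epoch index breaks a run
    step = pd.Timedelta(seconds=config.epoch_s)
    contiguous = np.ones(len(epochs), dtype=bool)
    contiguous[1:] = np.diff(epochs.index.to_numpy()) == step.to_numpy()
    run_id = np.full(len(elig), -1)
    current = -1
    for i in range(len(elig)):
        if elig[i]:
            if i == 0 or not elig[i - 1] or not contiguous[i]:
                current += 1
            run_id[i] = current
    if current >= 0:
        ids, counts = np.unique(run_id[run_id >= 0], return_counts=True)
        for rid, count in zip(ids, counts):
            if count >= run_epochs:
                labels.iloc[np.flatnonzero(run_id == rid)] = LIKELY_SLEEP
    labels[epochs["step_sum"] >= config.wake_step_min] = LIKELY_WAKE

    n_sleep = int((labels == LIKELY_SLEEP).sum())
    n_wake = int((labels == LIKELY_WAKE).sum())
    logger.info("heuristic_label: %d likely_sleep, %d likely_wake, %d unlabeled",
                n_sleep, n_wake, len(labels) - n_sleep - n_wake)
    if n_sleep == 0 or n_wake == 0:
        raise UntrainableLabelsError(
            f"heuristic produced {n_sleep} likely_sleep and {n_wake} likely_wake "
            "epochs; both classes are required to train")
    return epochs, labels


def extract_features(epochs: pd.DataFrame, hr: BioSeries, steps: BioSeries,
                     config: SleepConfig | None = None) -> pd.DataFrame:
    """Per-epoch feature records for classification.

    Features: ``hr_z`` (epoch mean HR z-scored against the subject's overall
    HR; 0 when the overall SD is 0), rolling mean/SD of epoch HR and rolling
    step sum over a centered +/-30-minute window, and sin/cos encodings of
    the 24-hour clock phase. Epochs without HR in the +/-30-minute window
    (or failing the coverage rule) are excluded and counted.
    """
    config = config or SleepConfig()
    if epochs.empty:
        raise EmptyInputError("no epochs to featurize")
    hr_all = hr.values
    mu = float(np.mean(hr_all))
    sd = float(np.std(hr_all, ddof=1)) if len(hr_all) > 1 else 0.0

    half_window = int(np.ceil(1800 / config.epoch_s))
    window = 2 * half_window + 1  # +/-30 min, centered
    roll = epochs["mean_hr"].rolling(window, center=True, min_periods=1)
    feats = pd.DataFrame(index=epochs.index)
    feats["hr_z"] = 0.0 if sd == 0 else (epochs["mean_hr"] - mu) / sd
    if sd == 0:
        feats.loc[epochs["mean_hr"].isna(), "hr_z"] = np.nan
    feats["hr_roll_mean"] = roll.mean()
    feats["hr_roll_sd"] = roll.std().fillna(0.0)
    feats.loc[feats["hr_roll_mean"].isna(), "hr_roll_sd"] = np.nan
    feats["step_roll_sum"] = epochs["step_sum"].rolling(window, center=True,
                                                        min_periods=1).sum()
    phase = 2 * np.pi * (epochs.index.hour * 3600 + epochs.index.minute * 60
                         + epochs.index.second) / 86400.0
    feats["tod_sin"] = np.sin(phase)
    feats["tod_cos"] = np.cos(phase)

    # an epoch with no usable HR of its own is still excluded (hr_z is NaN)
    feats.loc[epochs["mean_hr"].isna(), "hr_z"] = np.nan
    complete = feats.dropna()
    excluded = len(feats) - len(complete)
    if excluded:
        logger.info("extract_features: excluded %d epoch(s) without usable HR", excluded)
    if complete.empty:
        raise NoFeaturesError("every epoch was excluded during feature extraction")
    return complete


def _scaler() -> ColumnTransformer:
    # tod_sin/tod_cos stay unscaled: they are already unit-bounded, and
    # per-coordinate standardization would break the rotational symmetry of
    # the clock encoding (a time shift is a rotation of that pair)
    magnitude = [c for c in FEATURE_COLUMNS if not c.startswith("tod_")]
    return ColumnTransformer([("scale", StandardScaler(), magnitude)],
                             remainder="passthrough")


def _candidates(seed: int) -> dict[str, Pipeline]:
    # the SVM's decision scores are mapped to probabilities by Platt
    # calibration on internal training folds (monotone in the score)
    return {
        "logistic": Pipeline([
            ("scale", _scaler()),
            ("clf", LogisticRegression(max_iter=5000, tol=1e-8,
                                       random_state=seed)),
        ]),
        "svm_rbf": Pipeline([
            ("scale", _scaler()),
            ("clf", CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                           ensemble=False)),
        ]),
    }


def train_select_classifier(features: pd.DataFrame, labels: pd.Series,
                            config: SleepConfig | None = None
                            ) -> tuple[Pipeline, dict[str, float]]:
    """Train logistic-regression and RBF-SVM candidates on seed labels.

    Only ``likely_sleep``/``likely_wake`` epochs are used for training. The
    winner by mean stratified ``cv_folds``-fold cross-validated balanced
    accuracy is refit on all labeled epochs; ties prefer the logistic model
    (simpler, calibrated probabilities). Returns the fitted model and the
    per-candidate CV accuracy report.
    """
    config = config or SleepConfig()
    labeled = labels.reindex(features.index).isin([LIKELY_SLEEP, LIKELY_WAKE])
    X = features.loc[labeled, list(FEATURE_COLUMNS)]
    y = (labels.reindex(features.index)[labeled] == LIKELY_SLEEP).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise UntrainableLabelsError("training requires both sleep and wake seed labels")
    if counts.min() < config.cv_folds:
        raise UntrainableLabelsError(
            f"each class needs >= cv_folds={config.cv_folds} members; got {dict(zip(classes, counts))}")

    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    report: dict[str, float] = {}
    for name, model in _candidates(config.seed).items():
        scores = cross_val_score(model, X, y, cv=cv, scoring="balanced_accuracy")
        report[name] = float(np.mean(scores))
    # tie-break: logistic first, strict improvement required to displace it
    winner = "logistic" if report["logistic"] >= report["svm_rbf"] else "svm_rbf"
    model = _candidates(config.seed)[winner]
    model.fit(X, y)
    model.chosen_name_ = winner
    logger.info("train_select_classifier: chose %s (CV balanced accuracy %s)",
                winner, report)
    return model, report


def classify_epochs(model: Pipeline, features: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch sleep probability and binary label (threshold 0.5)."""
    if features.empty:
        raise EmptyInputError("no features to classify")
    complete = features.dropna(subset=list(FEATURE_COLUMNS))
    if len(complete) < len(features):
        logger.warning("classify_epochs: excluded %d incomplete feature record(s)",
                       len(features) - len(complete))
    prob = model.predict_proba(complete[list(FEATURE_COLUMNS)])[:, 1]
    return pd.DataFrame({"sleep_prob": prob, "sleep": prob >= 0.5}, index=complete.index)


def smooth_to_episodes(labels: pd.Series, config: SleepConfig | None = None,
                       epochs: pd.DataFrame | None = None) -> list[SleepEpisode]:
    """Median-smooth per-epoch sleep labels and emit contiguous episodes.

    A median filter of width ``smooth_width`` removes isolated flips; sleep
    runs separated by less than ``merge_gap`` minutes are merged; episodes
    shorter than ``min_episode`` minutes are dropped. Episodes never overlap
    and are time-ordered. ``epochs`` (if given) supplies per-episode mean HR.
    """
    config = config or SleepConfig()
    if labels.empty:
        return []
    if not labels.index.is_monotonic_increasing:
        raise ContractError("epoch labels must be time-ordered")
    step = pd.Timedelta(seconds=config.epoch_s)
    # place labels on the contiguous epoch clock; gaps count as wake
    grid = pd.date_range(labels.index[0], labels.index[-1], freq=step)
    on_grid = labels.astype(int).reindex(grid, fill_value=0).to_numpy()
    width = config.smooth_width | 1  # odd width
    smoothed = median_filter(on_grid, size=width, mode="nearest") > 0

    # contiguous runs of sleep epochs -> raw intervals
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    in_run = False
    for i, flag in enumerate(np.append(smoothed, False)):
        if flag and not in_run:
            run_start = grid[i]
            in_run = True
        elif not flag and in_run:
            intervals.append((run_start, grid[i - 1] + step))
            in_run = False

    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    gap = pd.Timedelta(minutes=config.merge_gap)
    for start, end in intervals:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    episodes = []
    for start, end in merged:
        duration = (end - start).total_seconds() / 60.0
        if duration < config.min_episode:
            continue
        if epochs is not None:
            inside = epochs.loc[(epochs.index >= start) & (epochs.index < end), "mean_hr"]
            mean_hr = float(inside.mean()) if inside.notna().any() else float("nan")
        else:
            mean_hr = float("nan")
        episodes.append(SleepEpisode(start, end, duration, mean_hr))
    return episodes


@dataclass(frozen=True)
class SleepResult:
    episodes: list[SleepEpisode]
    cv_report: dict[str, float]
    chosen_model: str
    stage_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "episodes": [e.to_dict() for e in self.episodes],
            "cv_report": self.cv_report,
            "chosen_model": self.chosen_model,
            "stage_counts": self.stage_counts,
        }


def detect_sleep_series(hr: BioSeries, steps: BioSeries,
                        config: SleepConfig | None = None) -> SleepResult:
    """Full five-stage pipeline on aligned 1-minute series.

    Deterministic for a fixed ``config.seed`` and inputs.
    """
    config = config or SleepConfig()
    epochs, labels = heuristic_label(hr, steps, config)
    features = extract_features(epochs, hr, steps, config)
    model, cv_report = train_select_classifier(features, labels, config)
    classified = classify_epochs(model, features)
    episodes = smooth_to_episodes(classified["sleep"], config, epochs)
    counts = {
        "epochs": len(epochs),
        "likely_sleep": int((labels == LIKELY_SLEEP).sum()),
        "likely_wake": int((labels == LIKELY_WAKE).sum()),
        "featurized": len(features),
        "classified_sleep": int(classified["sleep"].sum()),
        "episodes": len(episodes),
    }
    return SleepResult(episodes, cv_report, model.chosen_name_, counts)


def detect_sleep(hr_path, steps_path, config: SleepConfig | None = None,
                 out_json=None, time_column: str = "Time",
                 value_column: str = "Value", timezone: str | None = None) -> SleepResult:
    """File-level orchestration: read -> validate -> align -> detect."""
    hr = read_series(hr_path, Channel.HEART_RATE, time_column, value_column, timezone)
    steps = read_series(steps_path, Channel.STEPS, time_column, value_column, timezone)
    hr, _ = validate_series(hr, default_bounds(Channel.HEART_RATE))
    steps, _ = validate_series(steps, default_bounds(Channel.STEPS))
    paired = align_series(hr, steps, 60.0)
    hr_g = BioSeries(Channel.HEART_RATE, paired[Channel.HEART_RATE.value], 60.0)
    steps_g = BioSeries(Channel.STEPS, paired[Channel.STEPS.value], 60.0)
    result = detect_sleep_series(hr_g, steps_g, config)
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
    return result
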