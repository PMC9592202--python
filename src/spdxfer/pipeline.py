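"""Preprocessing and the cross-subject experiment protocol.

Preprocessing mirrors standard motor-imagery practice: zero-phase band-pass
filtering in the 8–30 Hz sensorimotor band (Butterworth order 5 or FIR order
50, shipped as the ``dataset1`` / ``dataset2`` presets) and epoch extraction
on a half-open sample window.

The experiment protocol is leave-one-subject-out and transductive: each
subject in turn is the target, all remaining subjects are concatenated (after
per-subject alignment and tangent mapping) into one labelled source domain,
and the target's trials are randomly partitioned into a small labelled
portion (balanced per class) and an unlabelled portion that both participates
in adaptation (where the variant uses it) and is scored.  Partitions are
re-drawn over repetitions; repetition r uses seed + r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .adaptation import (
    AdaptationConfig,
    fit_mekt,
    fit_smekt,
    fit_ssmekt,
)
from .classifier import slda_fit, slda_predict
from .riemann import TrialEpoch
from .tangent import DomainFeatures, domain_to_features

__all__ = [
    "FILTER_PRESETS",
    "WINDOW_PRESETS",
    "load_montage",
    "bandpass_filter",
    "epoch_window",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
]

#: Named preprocessing presets for the two public motor-imagery datasets.
FILTER_PRESETS: dict[str, dict] = {
    "dataset1": {"kind": "butter", "order": 5, "low": 8.0, "high": 30.0},
    "dataset2": {"kind": "fir", "order": 50, "low": 8.0, "high": 30.0},
}
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "dataset1": (0.5, 2.5),
    "dataset2": (0.5, 3.5),
}

VARIANTS = ("mekt", "smekt", "ssmekt", "baseline")


def load_montage(name: str) -> list[str]:
    """Return a named channel-subset preset (sensorimotor-area labels).

    The shipped presets are approximate reconstructions from standard
    10-20/10-10 motor-area labels (the published channel subsets are shown
    only graphically); treat them as sensible defaults, not ground truth.
    """
    text = resources.files("spdxfer").joinpath("data/montages.yaml").read_text()
    montages = yaml.safe_load(text)
    if name not in montages:
        raise KeyError(f"unknown montage {name!r}; available: {sorted(montages)}")
    return list(montages[name])


def bandpass_filter(
    epochs: list[TrialEpoch] | np.ndarray,
    fs: float,
    *,
    preset: str | None = None,
    kind: str = "butter",
    order: int = 5,
    low: float = 8.0,
    high: float = 30.0,
    zero_phase: bool = True,
):
    """Band-pass filter per channel; zero-phase (forward-backward) by default.

    ``preset`` selects one of :data:`FILTER_PRESETS`; otherwise ``kind``
    ("butter" or "fir"), ``order`` and the band edges are used directly.
    Accepts a list of epochs or a single channels-by-samples array and
    returns the same kind of object.
    """
    if preset is not None:
        p = FILTER_PRESETS[preset]
        kind, order, low, high = p["kind"], p["order"], p["low"], p["high"]
    if not (0 < low < high):
        raise ValueError(f"invalid band [{low}, {high}]")
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} too low for a {high} Hz band edge")

    if kind == "butter":
        sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")

        def apply(X: np.ndarray) -> np.ndarray:
            if zero_phase:
                return scipy.signal.sosfiltfilt(sos, X, axis=-1)
            return scipy.signal.sosfilt(sos, X, axis=-1)

    elif kind == "fir":
        b = scipy.signal.firwin(order + 1, [low, high], pass_zero=False, fs=fs)

        def apply(X: np.ndarray) -> np.ndarray:
            if zero_phase:
                return scipy.signal.filtfilt(b, [1.0], X, axis=-1)
            return scipy.signal.lfilter(b, [1.0], X, axis=-1)

    else:
        raise ValueError(f"unknown filter kind {kind!r}")

    if isinstance(epochs, np.ndarray):
        return apply(epochs)
    return [
        TrialEpoch(samples=apply(e.samples), subject_id=e.subject_id, label=e.label)
        for e in epochs
    ]


def epoch_window(
    trial: np.ndarray,
    t_start: float,
    t_end: float,
    fs: float,
    *,
    subject_id: str = "",
    label: int | None = None,
) -> TrialEpoch:
    """Cut the half-open sample window [round(t_start*fs), round(t_end*fs)).

    The ``dataset1`` window (0.5–2.5 s at 100 Hz) yields 200 samples, the
    ``dataset2`` window (0.5–3.5 s) 300.
    """
    X = np.asarray(trial, dtype=float)
    i0, i1 = round(t_start * fs), round(t_end * fs)
    if i0 < 0 or i1 > X.shape[-1]:
        raise IndexError(
            f"window [{i0}, {i1}) exceeds trial length {X.shape[-1]}"
        )
    if i1 <= i0:
        raise IndexError(f"empty window [{i0}, {i1})")
    return TrialEpoch(samples=X[..., i0:i1], subject_id=subject_id, label=label)


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Protocol settings for one leave-one-subject-out study.

    ``variant`` is one of mekt / smekt / ssmekt / baseline (the baseline is
    a no-transfer shrinkage LDA trained on the labelled target trials alone).
    ``n_labelled_target`` labelled trials are drawn balanced per class
    (the protocol sweeps 10–50 in steps of 10); repetition r partitions with
    seed + r.
    """

    variant: str = "ssmekt"
    n_labelled_target: int = 10
    n_repetitions: int = 20
    seed: int = 0
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_labelled_target < 2 or self.n_labelled_target % 2:
            raise ValueError("n_labelled_target must be even and >= 2")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")


@dataclass
class ExperimentResult:
    """Per-(subject, repetition) accuracy records plus summary helpers."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean ± std accuracy per subject, with an overall row appended."""
        per = (
            self.records.groupby("subject")["accuracy"]
            .agg(["mean", "std"])
            .reset_index()
        )
        overall = pd.DataFrame(
            [{
                "subject": "overall",
                "mean": self.records["accuracy"].mean(),
                "std": self.records["accuracy"].std(),
            }]
        )
        return pd.concat([per, overall], ignore_index=True)

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())


def _strip_labels(epochs: list[TrialEpoch]) -> list[TrialEpoch]:
    return [
        TrialEpoch(samples=e.samples, subject_id=e.subject_id, label=None)
        for e in epochs
    ]


def _balanced_partition(
    epochs: list[TrialEpoch], n_labelled: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Indices of a labelled subset balanced per class, and the remainder."""
    y = np.array([e.label for e in epochs])
    half = n_labelled // 2
    picked: list[int] = []
    for k in (1, 2):
        idx_k = np.flatnonzero(y == k)
        if idx_k.size < half:
            raise ValueError(
                f"class {k} has only {idx_k.size} trials, need {half} labelled"
            )
        picked.extend(rng.choice(idx_k, size=half, replace=False).tolist())
    picked = sorted(picked)
    rest = sorted(set(range(len(epochs))) - set(picked))
    return picked, rest


def evaluate_target(
    source_features: DomainFeatures,
    target_epochs: list[TrialEpoch],
    variant: str,
    n_labelled: int,
    rng: np.random.Generator,
    adaptation: AdaptationConfig,
) -> float:
    """One repetition: partition the target, adapt, score the unlabelled part.

    True labels of the unlabelled partition are used only here, for the final
    accuracy; the adaptation variants receive label-free feature sets.
    """
    lab_idx, unlab_idx = _balanced_partition(target_epochs, n_labelled, rng)
    labelled = [target_epochs[i] for i in lab_idx]
    unlabelled_truth = np.array([target_epochs[i].label for i in unlab_idx])
    unlabelled = _strip_labels([target_epochs[i] for i in unlab_idx])

    # labelled and unlabelled target partitions are aligned separately, each
    # with its own Riemannian mean
    if variant == "mekt":
        tu = domain_to_features(unlabelled, "target_all")
        proj = fit_mekt(source_features, tu, adaptation)
        pred = proj.pseudo_label_history[-1]
    elif variant == "smekt":
        tl = domain_to_features(labelled, "target_labelled")
        tu = domain_to_features(unlabelled, "target_unlabelled")
        proj = fit_smekt(source_features, tl, adaptation)
        X_fit = np.vstack(
            [source_features.vectors @ proj.P_S, tl.vectors @ proj.P_TL]
        )
        y_fit = np.concatenate([source_features.labels, tl.labels])
        model = slda_fit(X_fit, y_fit)
        pred, _ = slda_predict(model, tu.vectors @ proj.P_TU)
    elif variant == "ssmekt":
        tl = domain_to_features(labelled, "target_labelled")
        tu = domain_to_features(unlabelled, "target_unlabelled")
        proj = fit_ssmekt(source_features, tl, tu, adaptation)
        X_fit = np.vstack(
            [source_features.vectors @ proj.P_S, tl.vectors @ proj.P_TL]
        )
        y_fit = np.concatenate([source_features.labels, tl.labels])
        model = slda_fit(X_fit, y_fit)
        pred, _ = slda_predict(model, tu.vectors @ proj.P_TU)
    elif variant == "baseline":
        tl = domain_to_features(labelled, "target_labelled")
        tu = domain_to_features(unlabelled, "target_unlabelled")
        model = slda_fit(tl.vectors, tl.labels)
        pred, _ = slda_predict(model, tu.vectors)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(np.mean(pred == unlabelled_truth))


def source_domain_features(
    data: dict[str, list[TrialEpoch]],
    target_subject: str,
    _cache: dict[str, DomainFeatures] | None = None,
) -> DomainFeatures:
    """Per-subject aligned tangent features of all non-target subjects, stacked.

    Each source subject is aligned with its own Riemannian mean before the
    tangent map; the per-subject blocks are then concatenated into one
    labelled source domain.  ``_cache`` lets callers reuse per-subject
    features across target choices (alignment is per subject and does not
    depend on which subject is the target).
    """
    blocks = []
    for sid, epochs in data.items():
        if sid == target_subject:
            continue
        if _cache is not None and sid in _cache:
            blocks.append(_cache[sid])
            continue
        feats = domain_to_features(epochs, "source")
        if _cache is not None:
            _cache[sid] = feats
        blocks.append(feats)
    return DomainFeatures(
        vectors=np.vstack([b.vectors for b in blocks]),
        role="source",
        labels=np.concatenate([b.labels for b in blocks]),
    )


def run_experiment(
    config: ExperimentConfig, data: dict[str, list[TrialEpoch]]
) -> ExperimentResult:
    """Run the leave-one-subject-out protocol over all subjects and repetitions."""
    if len(data) < 2:
        raise ValueError("need at least two subjects (one target, one source)")
    for sid, epochs in data.items():
        if any(e.label is None for e in epochs):
            raise ValueError(f"subject {sid} has unlabelled trials")
    rows = []
    cache: dict = {}
    for sid in data:
        src = source_domain_features(data, sid, _cache=cache)
        for rep in range(config.n_repetitions):
            rng = np.random.default_rng(config.seed + rep)
            acc = evaluate_target(
                src,
                data[sid],
                config.variant,
                config.n_labelled_target,
                rng,
                config.adaptation,
            )
            rows.append(
                {
                    "subject": sid,
                    "repetition": rep,
                    "variant": config.variant,
                    "n_labelled": config.n_labelled_target,
                    "accuracy": acc,
                }
            )
    return ExperimentResult(records=pd.DataFrame(rows))


def transfer_study(
    variants: tuple[str, ...] = ("baseline", "mekt", "smekt", "ssmekt"),
    n_seeds: int = 20,
    base_seed: int = 0,
    spec=None,
    n_labelled: int = 10,
    adaptation: AdaptationConfig | None = None,
    targets_per_seed: int = 1,
) -> pd.DataFrame:
    """Synthetic transfer-recovery study over independently generated datasets.

    For each of ``n_seeds`` seeds a fresh multi-subject dataset is generated
    (``spec`` with the seed substituted); ``targets_per_seed`` subjects are
    rotated in as the target and each variant is evaluated on the identical
    partition, so comparisons between variants are paired.  Returns tidy
    records (seed, subject, variant, accuracy).
    """
    from dataclasses import replace

    from .synthetic import SyntheticSpec, generate_dataset

    adaptation = adaptation or AdaptationConfig()
    base_spec = spec or SyntheticSpec()
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        data = generate_dataset(replace(base_spec, seed=seed))
        sids = list(data)
        cache: dict = {}
        for j in range(targets_per_seed):
            sid = sids[(i + j) % len(sids)]
            src = source_domain_features(data, sid, _cache=cache)
            for variant in variants:
                rng = np.random.default_rng(seed + 10_000)
                acc = evaluate_target(
                    src, data[sid], variant, n_labelled, rng, adaptation
                )
                rows.append(
                    {"seed": seed, "subject": sid, "variant": variant, "accuracy": acc}
                )
    return pd.DataFrame(rows)
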