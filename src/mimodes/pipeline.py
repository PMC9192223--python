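"""End-to-end decoder: sub-band matrices -> CSP features -> discriminant
-> FPR-capped threshold."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    DecisionThreshold,
    DiscriminantModel,
    decision_density,
    decision_score,
    fit_discriminant,
    overlap_area,
    select_threshold,
)
from .emd import EmdConfig
from .errors import DegenerateInputError
from .features import CspModel, class_covariances, csp_features, csp_fit
from .signals import TrialSet
from .subband import ReconstructedMatrix, SubbandSelection, build_class_matrix

__all__ = ["TrainedDecoder", "train_decoder", "decode_trials", "trial_features"]


@dataclass
class TrainedDecoder:
    """Everything needed to score and classify new trials."""

    csp: CspModel
    discriminant: DiscriminantModel
    threshold: DecisionThreshold
    selection: SubbandSelection
    channels: tuple
    positive_label: str
    negative_label: str
    denoise: bool = False
    emd_config: EmdConfig | None = None
    report: dict = field(default_factory=dict)
    training_features: np.ndarray | None = None
    training_labels: list[str] | None = None
    training_scores: np.ndarray | None = None


def _matrices_to_features(csp: CspModel, mats: list[ReconstructedMatrix]) -> np.ndarray:
    return np.vstack([csp_features(csp, m.data) for m in mats])


def trial_features(
    trials: TrialSet,
    csp: CspModel,
    selection: SubbandSelection,
    channels=("C3", "C4"),
    denoise: bool = False,
    emd_config: EmdConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """CSP log-variance features for every trial, in trial order."""
    feats = []
    from .subband import build_trial_matrix

    for i in range(trials.n_trials):
        mat = build_trial_matrix(
            trials.trials[i],
            trials.channel_names,
            trials.sampling_rate,
            selection,
            channels=channels,
            class_label=trials.labels[i],
            emd_config=emd_config,
            denoise=denoise,
        )
        feats.append(csp_features(csp, mat.data))
    return np.vstack(feats), list(trials.labels)


def train_decoder(
    trials: TrialSet,
    selection: SubbandSelection | None = None,
    channels=("C3", "C4"),
    n_pairs: int = 2,
    fpr_max: float = 0.10,
    positive_label: str = "imagery",
    negative_label: str = "relaxed",
    denoise: bool = False,
    emd_config: EmdConfig | None = None,
) -> TrainedDecoder:
    """Fit the full decoding chain on labeled trials.

    The report records training accuracy, the achieved relaxed-state FPR at
    the selected threshold, and the overlap area of the two decision-score
    densities.
    """
    sel = selection or SubbandSelection()
    by_class = build_class_matrix(
        trials, sel, channels=channels, emd_config=emd_config, denoise=denoise
    )
    for lab in (negative_label, positive_label):
        if lab not in by_class:
            raise DegenerateInputError(f"no trials labeled {lab!r}")
    covs = class_covariances(
        [m.data for m in by_class[negative_label]],
        [m.data for m in by_class[positive_label]],
    )
    csp = csp_fit(covs[0], covs[1], n_pairs=n_pairs)

    feats, labels = [], []
    for lab in (negative_label, positive_label):
        f = _matrices_to_features(csp, by_class[lab])
        feats.append(f)
        labels.extend([lab] * f.shape[0])
    features = np.vstack(feats)
    model = fit_discriminant(features, labels)

    scores = np.array(
        [
            decision_score(model, features[i], positive_label, negative_label)
            for i in range(features.shape[0])
        ]
    )
    labels_arr = np.array(labels)
    neg_scores = scores[labels_arr == negative_label]
    pos_scores = scores[labels_arr == positive_label]
    threshold = select_threshold(neg_scores, fpr_max=fpr_max)

    predicted = np.where(scores >= threshold.value, positive_label, negative_label)
    accuracy = float(np.mean(predicted == labels_arr))
    tpr = float(np.mean(pos_scores >= threshold.value))
    overlap = overlap_area(
        decision_density(neg_scores), decision_density(pos_scores)
    )
    report = {
        "n_trials": trials.n_trials,
        "training_accuracy": accuracy,
        "true_positive_rate": tpr,
        "achieved_fpr": threshold.achieved_fpr,
        "threshold": threshold.value,
        "overlap_area": overlap,
    }
    return TrainedDecoder(
        csp=csp,
        discriminant=model,
        threshold=threshold,
        selection=sel,
        channels=tuple(channels),
        positive_label=positive_label,
        negative_label=negative_label,
        denoise=denoise,
        emd_config=emd_config,
        report=report,
        training_features=features,
        training_labels=labels,
        training_scores=scores,
    )


def decode_trials(decoder: TrainedDecoder, trials: TrialSet) -> tuple[list[str], np.ndarray]:
    """Decision labels and scores for a trial set under a trained decoder."""
    features, _ = trial_features(
        trials,
        decoder.csp,
        decoder.selection,
        channels=decoder.channels,
        denoise=decoder.denoise,
        emd_config=decoder.emd_config,
    )
    scores = np.array(
        [
            decision_score(
                decoder.discriminant,
                features[i],
                decoder.positive_label,
                decoder.negative_label,
            )
            for i in range(features.shape[0])
        ]
    )
    labels = [
        decoder.positive_label if s >= decoder.threshold.value else decoder.negative_label
        for s in scores
    ]
    return labels, scores
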