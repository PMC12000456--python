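"""Two-scenario ensemble vote over the three branch predictions.

Normal case: when two or all three members output the same class, that class
is the diagnosis (scenario ``consensus`` or ``majority``). Abnormal case:
when all three disagree, the member with the highest stored validation
accuracy decides (scenario ``accuracy_fallback``); in ``per_class`` mode the
member's validation recall on its own predicted class replaces the overall
accuracy. A Majority Fault Problem (MFP) — two weaker members outvoting a
strictly more accurate dissenter — is flagged and logged but never overrides
the majority.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnn import TrainedClassifier
from .data import DatasetManifest, load_split_arrays

log = logging.getLogger(__name__)

MEMBER_NAMES = ("CNN", "GAN", "XDL")
DEFAULT_PRECEDENCE = ("XDL", "GAN", "CNN")


@dataclass(frozen=True)
class MemberReport:
    """One branch's prediction plus the stored accuracy consumed by the vote."""

    name: str
    predicted_label: str
    accuracy: float
    per_class_recall: dict | None = None
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError(f"accuracy must be in [0,1], got {self.accuracy}")


@dataclass(frozen=True)
class VoteOutcome:
    final_label: str
    scenario: str  # consensus | majority | accuracy_fallback
    decisive_member: str | None
    mfp_flag: bool


def _check_reports(reports) -> list[MemberReport]:
    reports = list(reports)
    if len(reports) != 3:
        raise ValueError(f"exactly 3 member reports required, got {len(reports)}")
    names = [r.name for r in reports]
    if len(set(names)) != 3:
        raise ValueError(f"member names must be distinct, got {names}")
    return reports


def detect_mfp(reports) -> bool:
    """True iff exactly two members agree and the dissenter is strictly more
    accurate than both agreeing members."""
    reports = _check_reports(reports)
    counts = Counter(r.predicted_label for r in reports)
    if sorted(counts.values()) != [1, 2]:
        return False
    minority_label = next(lab for lab, c in counts.items() if c == 1)
    dissenter = next(r for r in reports if r.predicted_label == minority_label)
    pair = [r for r in reports if r.predicted_label != minority_label]
    return all(dissenter.accuracy > r.accuracy for r in pair)


def ensemble_vote(
    reports,
    mode: str = "overall",
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> VoteOutcome:
    """Combine exactly three member reports into a final diagnosis.

    * all three agree -> that class (``consensus``);
    * exactly two agree -> that class (``majority``);
    * all distinct -> the class of the member maximizing its overall accuracy
      (mode ``overall``) or its recall on its own predicted class (mode
      ``per_class``); accuracy ties break by the precedence order.
    """
    reports = _check_reports(reports)
    if mode not in ("overall", "per_class"):
        raise ValueError(f"unknown voting mode {mode!r}")
    if mode == "per_class":
        missing = [r.name for r in reports if r.per_class_recall is None]
        if missing:
            raise ValueError(f"per_class mode needs per_class_recall for {missing}")
    mfp = detect_mfp(reports)
    if mfp:
        log.warning("Majority Fault Problem: dissenting member %s is the most accurate",
                    max(reports, key=lambda r: r.accuracy).name)
    counts = Counter(r.predicted_label for r in reports)
    top_label, top_count = counts.most_common(1)[0]
    if top_count == 3:
        return VoteOutcome(top_label, "consensus", None, mfp)
    if top_count == 2:
        return VoteOutcome(top_label, "majority", None, mfp)

    def score(r: MemberReport) -> float:
        if mode == "per_class":
            return float(r.per_class_recall[r.predicted_label])
        return r.accuracy

    prec_rank = {name: len(precedence) - i for i, name in enumerate(precedence)}
    best = max(reports, key=lambda r: (score(r), prec_rank.get(r.name, 0)))
    return VoteOutcome(best.predicted_label, "accuracy_fallback", best.name, mfp)


class EnsembleVoteClassifier:
    """Prefit-member ensemble with the fit/predict surface.

    Members are three TrainedClassifier checkpoints (CNN, GAN, XDL); each
    resizes every input to its own branch resolution, so ``predict`` takes a
    list of [0,1] RGB arrays of any (per-image) size.
    """

    def __init__(self, members: list[TrainedClassifier],
                 mode: str = "overall",
                 precedence: tuple[str, ...] = DEFAULT_PRECEDENCE):
        self.members = list(members)
        self.mode = mode
        self.precedence = precedence
        if len(self.members) != 3:
            raise ValueError("need exactly 3 trained members")
        class_sets = {m.class_names for m in self.members}
        if len(class_sets) != 1:
            raise ValueError(f"members trained on different class sets: {class_sets}")
        self.classes_ = np.array(self.members[0].class_names)

    def get_params(self, deep: bool = True) -> dict:
        return {"members": self.members, "mode": self.mode, "precedence": self.precedence}

    def _reports_for(self, pixels: np.ndarray) -> list[MemberReport]:
        from .xdl import _resize_rgb

        reports = []
        for m in self.members:
            x = _resize_rgb(pixels, m.input_size)
            pv, label = m.predict_image(x)
            reports.append(MemberReport(
                name=m.name, predicted_label=label, accuracy=m.validation_accuracy,
                per_class_recall=dict(zip(m.class_names,
                                          m.per_class_validation_recall)),
                probs=pv.probs))
        return reports

    def vote_one(self, pixels: np.ndarray) -> tuple[VoteOutcome, list[MemberReport]]:
        reports = self._reports_for(pixels)
        return ensemble_vote(reports, self.mode, self.precedence), reports

    def predict(self, images) -> np.ndarray:
        return np.array([self.vote_one(img)[0].final_label for img in images])


def ensemble_predict(
    members: list[TrainedClassifier],
    manifest: DatasetManifest,
    mode: str = "overall",
    split: str = "test",
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Vote every image of one split; returns the predictions table.

    Columns: image_path, true label, one prediction and stored accuracy per
    member, the scenario, the MFP flag and the final label.
    """
    ens = EnsembleVoteClassifier(members, mode, precedence)
    classes = tuple(ens.classes_)
    rows = []
    # each member resizes independently; load once at native resolution
    from .data import load_image

    recs = manifest.subset(split)
    if not recs:
        raise ValueError(f"manifest has no records in split {split!r}")
    for rec in recs:
        pixels = load_image(rec.image_path)
        outcome, reports = ens.vote_one(pixels)
        row = {"image_path": rec.image_path, "label": rec.label}
        for rep in reports:
            row[f"pred_{rep.name}"] = rep.predicted_label
            row[f"acc_{rep.name}"] = rep.accuracy
        row["scenario"] = outcome.scenario
        row["mfp_flag"] = outcome.mfp_flag
        row["final_label"] = outcome.final_label
        rows.append(row)
    return pd.DataFrame(rows)


def vote_summary(table: pd.DataFrame) -> dict:
    return {
        "n_images": int(len(table)),
        "n_consensus": int((table["scenario"] == "consensus").sum()),
        "n_majority": int((table["scenario"] == "majority").sum()),
        "n_fallback": int((table["scenario"] == "accuracy_fallback").sum()),
        "n_mfp_flags": int(table["mfp_flag"].sum()),
    }
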