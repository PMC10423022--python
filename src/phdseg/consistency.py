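"""Human-consistency harness for two-alternative forced-choice trials.

Each trial shows a ground-truth membrane mask plus two candidate
segmentations (A and B); a panel of subjects votes for the candidate closer
to the truth.  A metric's *consistency* is the fraction of subject responses
that agree with the metric's own preference.  Per-response scoring (every
vote counts) is the default; a per-trial-majority variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core_io import BinaryMask, read_raster
from .metrics import METRIC_DIRECTIONS, evaluate_metric

__all__ = [
    "PreferenceTrial",
    "metric_preference",
    "consistency_score",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["trial_id", "gt", "pred_a", "pred_b", "votes_a", "votes_b"]


@dataclass
class PreferenceTrial:
    """One forced-choice trial: a ground truth, two predictions, vote counts.

    Masks may be given in memory or as file paths (loaded lazily); at least
    one vote must have been cast.
    """

    trial_id: str
    gt: BinaryMask | str | Path
    pred_a: BinaryMask | str | Path
    pred_b: BinaryMask | str | Path
    votes_a: int
    votes_b: int

    def __post_init__(self) -> None:
        if self.votes_a < 0 or self.votes_b < 0 or self.votes_a + self.votes_b < 1:
            raise ValueError(f"trial {self.trial_id}: needs >= 1 vote, non-negative counts")

    @staticmethod
    def _as_mask(obj: BinaryMask | str | Path) -> BinaryMask:
        if isinstance(obj, BinaryMask):
            return obj
        loaded = read_raster(obj)
        if not isinstance(loaded, BinaryMask):
            raise ValueError(f"{obj} is not a binary mask")
        return loaded

    def masks(self) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
        return (self._as_mask(self.gt), self._as_mask(self.pred_a), self._as_mask(self.pred_b))


def metric_preference(trial: PreferenceTrial, metric_id: str,
                      skeletonize: bool = False, tau: float | None = None) -> str:
    """Which candidate the metric prefers: 'A', 'B', or 'tie' on exact equality."""
    try:
        gt, pred_a, pred_b = trial.masks()
        va = evaluate_metric(metric_id, pred_a, gt, skeletonize=skeletonize, tau=tau)
        vb = evaluate_metric(metric_id, pred_b, gt, skeletonize=skeletonize, tau=tau)
    except Exception as exc:
        raise type(exc)(f"trial {trial.trial_id}: {exc}") from exc
    if va == vb:
        return "tie"
    higher_better = METRIC_DIRECTIONS[metric_id] == "higher"
    return "A" if (va > vb) == higher_better else "B"


def consistency_score(trials: list[PreferenceTrial], metric_id: str,
                      skeletonize: bool = False, tau: float | None = None,
                      per_majority: bool = False, drop_ties: bool = False) -> float:
    """Agreement between a metric's preferences and human votes, in [0, 1].

    Default (per-response): sum over trials of the votes cast for the
    metric-preferred side, divided by all votes; a metric tie contributes
    half of the trial's votes (or the trial is excluded with ``drop_ties``).
    With ``per_majority`` each trial counts once, scored 1 if the metric
    agrees with the human majority, 0.5 on either kind of tie.
    """
    if not trials:
        raise ValueError("need at least one trial")
    agree = 0.0
    total = 0.0
    for trial in trials:
        pref = metric_preference(trial, metric_id, skeletonize=skeletonize, tau=tau)
        if pref == "tie" and drop_ties:
            continue
        if per_majority:
            total += 1.0
            if pref == "tie" or trial.votes_a == trial.votes_b:
                agree += 0.5
            elif (pref == "A") == (trial.votes_a > trial.votes_b):
                agree += 1.0
        else:
            votes = trial.votes_a + trial.votes_b
            total += votes
            if pref == "tie":
                agree += votes / 2.0
            else:
                agree += trial.votes_a if pref == "A" else trial.votes_b
    if total == 0:
        raise ValueError("all trials were metric ties and drop_ties is set")
    return agree / total


def read_manifest(path: str | Path) -> list[PreferenceTrial]:
    """Load trials from a TSV manifest; relative raster paths resolve against it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    trials = []
    for row in df.itertuples(index=False):
        trials.append(PreferenceTrial(
            trial_id=str(row.trial_id),
            gt=base / str(row.gt),
            pred_a=base / str(row.pred_a),
            pred_b=base / str(row.pred_b),
            votes_a=int(row.votes_a),
            votes_b=int(row.votes_b),
        ))
    return trials


def write_manifest(trials: list[PreferenceTrial], path: str | Path) -> None:
    """Write a TSV manifest (masks must already be file paths)."""
    rows = []
    for t in trials:
        for side in (t.gt, t.pred_a, t.pred_b):
            if isinstance(side, BinaryMask):
                raise ValueError(f"trial {t.trial_id}: write rasters to disk before the manifest")
        rows.append([t.trial_id, str(t.gt), str(t.pred_a), str(t.pred_b), t.votes_a, t.votes_b])
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
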