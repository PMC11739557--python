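"""Prospective pattern-expression scoring and z-transformation.

A single scan's expression of a covariance pattern is the projection of
its row-centered log profile, minus the derivation control reference,
onto the pattern's voxel weights. The computation involves no other scan,
so prospective scoring of new subjects is order-independent and
batch-free. Scores are z-transformed against a reference group so that
group has mean 0 and SD 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes import Volume, vectorize
from .derive import CovariancePattern

__all__ = ["ScoreTable", "score_scan", "score_cohort", "z_transform"]


@dataclass
class ScoreTable:
    """Per-subject raw and z-transformed pattern-expression scores."""

    subject_ids: list[str]
    group_labels: list[str]
    raw_scores: np.ndarray
    z_scores: np.ndarray | None = None
    reference_group: str | None = None
    pattern_id: str = "pattern"

    def __post_init__(self) -> None:
        self.raw_scores = np.asarray(self.raw_scores, dtype=np.float64)
        n = len(self.subject_ids)
        if len(self.group_labels) != n or self.raw_scores.size != n:
            raise ValueError("subject_ids, group_labels and raw_scores must align")

    def group_mean_z(self, group: str) -> float:
        if self.z_scores is None:
            raise ValueError("z_scores not computed; call z_transform first")
        sel = np.array([g == group for g in self.group_labels])
        return float(self.z_scores[sel].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.group_labels,
                "raw_score": self.raw_scores,
                "z_score": self.z_scores if self.z_scores is not None else np.nan,
                "pattern_id": self.pattern_id,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def score_scan(v: Volume, p: CovariancePattern) -> float:
    """Raw pattern-expression score of a single scan.

    score = (log masked profile, row-centered, minus reference_offset) . weights

    Deterministic and independent of any other scan. Invariant to global
    multiplicative scaling of the scan (the log of a scale factor is a
    constant, removed by row centering).
    """
    profile = vectorize(v, p.mask)
    if np.any(profile <= 0):
        raise ValueError(f"non-positive masked voxel in scan {v.id!r}")
    log_profile = np.log(profile)
    centered = log_profile - log_profile.mean()
    return float((centered - p.reference_offset) @ p.weights)


def score_cohort(
    scans: Sequence[Volume],
    p: CovariancePattern,
    labels: Sequence[str],
) -> ScoreTable:
    """Score each scan independently; one row per subject, input order kept."""
    if len(scans) != len(labels):
        raise ValueError("one label per scan required")
    raw = np.array([score_scan(v, p) for v in scans])
    return ScoreTable(
        subject_ids=[v.id for v in scans],
        group_labels=list(labels),
        raw_scores=raw,
        pattern_id=p.id,
    )


def z_transform(
    scores: ScoreTable,
    reference: str = "control",
    reference_stats: tuple[float, float] | None = None,
) -> ScoreTable:
    """Standardize raw scores so the reference group has mean 0, SD 1.

    ``z = (raw - mean_ref) / sd_ref`` with the n-1 SD denominator. If
    ``reference_stats`` (mean, sd) is given — e.g. the derivation-control
    statistics stored on a pattern — those are used instead of computing
    them from this table, which is how validation cohorts without their
    own controls are standardized.
    """
    if reference_stats is not None:
        mean_ref, sd_ref = reference_stats
    else:
        sel = np.array([g == reference for g in scores.group_labels])
        if sel.sum() < 2:
            raise ValueError("need at least 2 reference subjects")
        ref = scores.raw_scores[sel]
        mean_ref, sd_ref = float(ref.mean()), float(ref.std(ddof=1))
    if sd_ref <= 0:
        raise ValueError("reference group has zero score variance")
    return ScoreTable(
        subject_ids=list(scores.subject_ids),
        group_labels=list(scores.group_labels),
        raw_scores=scores.raw_scores.copy(),
        z_scores=(scores.raw_scores - mean_ref) / sd_ref,
        reference_group=reference,
        pattern_id=scores.pattern_id,
    )
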