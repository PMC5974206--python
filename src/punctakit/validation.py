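"""Validation of detections against expert point annotations.

An expert marks each punctum with a single point; a detected object is
correctly detected when an expert point lies inside it, with at most one
point associated to any object (one-to-one matching).  Precision is the
fraction of detected objects that are correct, recall the fraction of expert
points accounted for, and the F1 score their harmonic mean.

For samples counted independently by two experts, the agreement between
counts is summarized by average relative errors against the expert mean:
per sample with expert counts E1, E2 and algorithm count A,

    expert term    = (|E1 - m| + |E2 - m|) / (2 m) = |E1 - E2| / (E1 + E2)
    algorithm term = |A - m| / m,            with m = (E1 + E2) / 2,

each averaged over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import LabelStack

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Outcome of matching expert points to detected objects."""

    n_algorithm: int
    n_expert: int
    n_correct: int
    precision: float
    recall: float
    f1: float


@dataclass
class CountTriple:
    """Counts of one validation sample: two experts and the algorithm."""

    sample: str
    expert1: int
    expert2: int
    algorithm: int


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def match_points(labels: LabelStack | np.ndarray, points) -> MatchResult:
    """Match expert points to detected objects, one-to-one.

    A point is admissible for exactly the object whose tag its voxel carries
    (points are rounded to the nearest voxel), so the maximum one-to-one
    matching pairs each distinctly-hit object with one point.  Empty-set
    conventions: precision, recall and F1 are 0 when undefined.
    """
    arr = labels.labels if isinstance(labels, LabelStack) else np.asarray(labels)
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n_expert = len(pts)
    tags_present = np.unique(arr)
    n_algorithm = int((tags_present > 0).sum())
    hit: set[int] = set()
    for x, y, z in pts:
        ix = (int(round(z)), int(round(y)), int(round(x)))
        if not all(0 <= i < n for i, n in zip(ix, arr.shape)):
            raise ValueError(f"point {(x, y, z)} outside the stack")
        tag = int(arr[ix])
        if tag > 0:
            hit.add(tag)
    n_correct = len(hit)
    precision = n_correct / n_algorithm if n_algorithm else 0.0
    recall = n_correct / n_expert if n_expert else 0.0
    return MatchResult(
        n_algorithm=n_algorithm,
        n_expert=n_expert,
        n_correct=n_correct,
        precision=precision,
        recall=recall,
        f1=f1(precision, recall),
    )


def relative_error_summary(triples) -> tuple[float, float]:
    """Average relative errors ``(expert_rel_err, algorithm_rel_err)``.

    ``triples`` is an iterable of :class:`CountTriple` or a DataFrame with
    columns ``expert1, expert2, algorithm``.  Samples whose expert mean is
    zero are skipped with a warning.
    """
    if isinstance(triples, pd.DataFrame):
        rows = [
            CountTriple(str(r.get("sample", i)), r["expert1"], r["expert2"], r["algorithm"])
            for i, r in triples.iterrows()
        ]
    else:
        rows = list(triples)
    expert_terms: list[float] = []
    algorithm_terms: list[float] = []
    for t in rows:
        m = 0.5 * (t.expert1 + t.expert2)
        if m == 0:
            logger.warning("sample %s skipped: zero expert mean", t.sample)
            continue
        expert_terms.append((abs(t.expert1 - m) + abs(t.expert2 - m)) / (2.0 * m))
        algorithm_terms.append(abs(t.algorithm - m) / m)
    if not expert_terms:
        raise ValueError("no usable samples")
    return float(np.mean(expert_terms)), float(np.mean(algorithm_terms))


# ---------------------------------------------------------------------------
# Packaged benchmark tables (hippocampal vGlut-1 / vGAT expert validation)
# ---------------------------------------------------------------------------


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("punctakit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_benchmark_counts(marker: str) -> pd.DataFrame:
    """Published per-sample count triples for ``marker`` ('vglut1' or 'vgat')."""
    if marker not in ("vglut1", "vgat"):
        raise ValueError("marker must be 'vglut1' or 'vgat'")
    return _load_csv(f"{marker}_counts.csv")


def load_benchmark_metrics(marker: str) -> pd.DataFrame:
    """Published per-sample precision/recall/F1 rows for ``marker``."""
    if marker not in ("vglut1", "vgat"):
        raise ValueError("marker must be 'vglut1' or 'vgat'")
    return _load_csv(f"{marker}_metrics.csv")
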