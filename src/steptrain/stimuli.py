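"""Individualized stimulus assessment.

A participant's elicited treatment-related thoughts are short text items,
each labelled with an emotional valence (positive / negative / neutral) and
a treatment orientation (approach / avoidance / neutral).  The participant
rates the similarity of every unordered pair of thoughts; the ratings are
reversed into dissimilarities and embedded in two dimensions with nonmetric
multidimensional scaling (SMACOF majorization, Kruskal stress-1) to produce
a "cognitive map" of how the thoughts relate.  The labels — not the map —
decide which thoughts become probe targets for attention training: items
that are treatment approach-oriented (or orientation-neutral) and carry a
neutral or positive emotional tone.  The map is retained as diagnostic
provenance.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import InvalidInputError

VALENCES = ("positive", "negative", "neutral")
ORIENTATIONS = ("approach", "avoidance", "neutral")


@dataclass(frozen=True)
class ThoughtStimulus:
    """One elicited thought: the atom of individualized training."""

    stimulus_id: str
    text: str
    valence: str
    orientation: str

    def __post_init__(self):
        if not self.text or not str(self.text).strip():
            raise InvalidInputError(f"stimulus {self.stimulus_id!r}: text must be non-empty")
        if self.valence not in VALENCES:
            raise InvalidInputError(
                f"stimulus {self.stimulus_id!r}: valence {self.valence!r} not in {VALENCES}"
            )
        if self.orientation not in ORIENTATIONS:
            raise InvalidInputError(
                f"stimulus {self.stimulus_id!r}: orientation {self.orientation!r} "
                f"not in {ORIENTATIONS}"
            )


@dataclass(frozen=True)
class SimilarityRatings:
    """Pairwise similarity ratings on a bounded scale.

    The matrix is symmetric with the self-similarity diagonal pinned at the
    scale maximum.  ``scale_bounds`` is ``(s_min, s_max)``.
    """

    stimulus_ids: tuple[str, ...]
    ratings: np.ndarray
    scale_bounds: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))
        r = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "ratings", r)
        n = len(self.stimulus_ids)
        s_min, s_max = self.scale_bounds
        if s_min >= s_max:
            raise InvalidInputError(f"scale bounds must satisfy s_min < s_max, got {self.scale_bounds}")
        if r.shape != (n, n):
            raise InvalidInputError(f"ratings shape {r.shape} does not match {n} stimuli")
        if not np.all(np.isfinite(r)):
            raise InvalidInputError("ratings contain non-finite values")
        if not np.allclose(r, r.T):
            raise InvalidInputError("ratings matrix is not symmetric")
        if not np.allclose(np.diag(r), s_max):
            raise InvalidInputError("diagonal must equal the scale maximum (self-similarity)")
        if r.min() < s_min - 1e-9 or r.max() > s_max + 1e-9:
            raise InvalidInputError(
                f"ratings outside scale bounds [{s_min}, {s_max}]: "
                f"range [{r.min()}, {r.max()}]"
            )

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)


@dataclass(frozen=True)
class CognitiveMap:
    """2D embedding of a participant's stimuli with its Kruskal stress-1."""

    stimulus_ids: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    n_iterations: int
    stress_history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self):
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InvalidInputError(f"coordinates must be n x 2, got shape {coords.shape}")
        if self.stress < 0:
            raise InvalidInputError("stress must be non-negative")

    def to_files(self, csv_path: str | Path, json_path: str | Path, seed: int | None = None) -> None:
        """Write coordinates as CSV plus a JSON sidecar with fit metadata."""
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stimulus_id", "dim1", "dim2"])
            for sid, (x, y) in zip(self.stimulus_ids, self.coordinates):
                w.writerow([sid, repr(float(x)), repr(float(y))])
        meta = {"stress": self.stress, "n_iterations": self.n_iterations, "seed": seed}
        Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class TrainingPartition:
    """Exhaustive, disjoint split of an inventory into probe targets and distractors."""

    probe_targets: tuple[ThoughtStimulus, ...]
    distractors: tuple[ThoughtStimulus, ...]
    cognitive_map: CognitiveMap | None = None


def pair_schedule(stimulus_ids: Sequence[str], seed: int) -> list[tuple[str, str]]:
    """All C(n, 2) unordered stimulus pairs in a seed-determined random order.

    This is the presentation order for the similarity-rating task: every pair
    of a participant's thoughts appears exactly once.
    """
    ids = list(stimulus_ids)
    if len(ids) < 2:
        raise InvalidInputError("need at least 2 stimuli to schedule pairs")
    if len(set(ids)) != len(ids):
        raise InvalidInputError("stimulus ids must be distinct")
    pairs = list(itertools.combinations(ids, 2))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def to_dissimilarity(ratings: SimilarityRatings) -> np.ndarray:
    """Linear reversal of similarities: d_ij = s_max - s_ij.

    Yields a symmetric, non-negative matrix with zero diagonal, the input
    shape expected by :func:`mds_embed`.
    """
    _, s_max = ratings.scale_bounds
    d = s_max - ratings.ratings
    np.fill_diagonal(d, 0.0)
    return d


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError(f"dissimilarity must be square, got shape {d.shape}")
    if d.shape[0] < 3:
        raise InvalidInputError("need at least 3 stimuli for a 2D embedding")
    if not np.all(np.isfinite(d)):
        raise InvalidInputError("dissimilarity contains non-finite values")
    if not np.allclose(d, d.T):
        raise InvalidInputError("dissimilarity matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise InvalidInputError("dissimilarity diagonal must be zero")
    if d.min() < 0:
        raise InvalidInputError("dissimilarities must be non-negative")
    return d


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center the squared distances, eigendecompose.

    Used as the deterministic initialization for SMACOF and as an exact
    solution whenever the dissimilarities are truly Euclidean.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _pairwise_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _stress1(dist: np.ndarray, disp: np.ndarray, iu) -> float:
    num = ((dist[iu] - disp[iu]) ** 2).sum()
    den = (dist[iu] ** 2).sum()
    if den == 0.0:
        return 0.0
    return float(np.sqrt(num / den))


def _smacof_single(
    d: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, int, list[float]]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    order = np.argsort(delta, kind="stable")
    x = init.copy()
    iso = IsotonicRegression()
    history: list[float] = []
    stress = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        dist = _pairwise_distances(x)
        dvec = dist[iu]
        if delta.max() == 0.0:
            # degenerate: all items identical; any coincident configuration is exact
            disp_vec = np.zeros_like(dvec)
        else:
            # monotone (rank-order) regression of distances on dissimilarities
            disp_vec = np.empty_like(dvec)
            disp_vec[order] = iso.fit_transform(np.arange(len(order)), dvec[order])
            ssd = (dvec ** 2).sum()
            ssdh = (disp_vec ** 2).sum()
            if ssdh > 0:
                disp_vec = disp_vec * np.sqrt(ssd / ssdh)
        disp = np.zeros_like(dist)
        disp[iu] = disp_vec
        disp = disp + disp.T
        new_stress = _stress1(dist, disp, iu)
        history.append(new_stress)
        if stress - new_stress < tol * max(stress, 1.0) and it > 1:
            stress = new_stress
            break
        stress = new_stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        b = -ratio
        b[np.diag_indices(n)] = 0.0
        b[np.diag_indices(n)] = -b.sum(axis=1)
        x = (b @ x) / n
    return x, stress, it, history


def mds_embed(
    dissimilarity: np.ndarray,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 4,
    stimulus_ids: Sequence[str] | None = None,
) -> CognitiveMap:
    """Nonmetric 2D MDS by SMACOF majorization.

    The first start is classical (Torgerson) scaling; the remaining
    ``n_init - 1`` starts are seed-governed random configurations.  Within
    each start the stress sequence is non-increasing (majorization plus
    monotone-regression update both decrease raw stress; disparities are
    rescaled to the current distance sum-of-squares so Kruskal stress-1 is
    comparable across iterations).  The lowest-stress solution wins;
    identical seeds give identical output.
    """
    d = _check_dissimilarity(dissimilarity)
    n = d.shape[0]
    if stimulus_ids is None:
        stimulus_ids = tuple(f"s{i}" for i in range(n))
    elif len(stimulus_ids) != n:
        raise InvalidInputError("stimulus_ids length does not match matrix size")

    rng = np.random.default_rng(seed)
    scale = d.max() if d.max() > 0 else 1.0
    inits = [classical_mds(d)]
    for _ in range(max(0, n_init - 1)):
        inits.append(rng.normal(scale=scale, size=(n, 2)))

    best: tuple[np.ndarray, float, int, list[float]] | None = None
    for init in inits:
        result = _smacof_single(d, init, max_iter=max_iter, tol=tol)
        if best is None or result[1] < best[1]:
            best = result
    x, stress, n_iter, history = best
    x = x - x.mean(axis=0)  # center for reproducible reporting
    return CognitiveMap(
        stimulus_ids=tuple(stimulus_ids),
        coordinates=x,
        stress=stress,
        n_iterations=n_iter,
        stress_history=tuple(history),
    )


def cognitive_map(ratings: SimilarityRatings, seed: int = 0, **kwargs) -> CognitiveMap:
    """Convenience wrapper: ratings -> dissimilarities -> 2D SMACOF embedding."""
    return mds_embed(
        to_dissimilarity(ratings), seed=seed, stimulus_ids=ratings.stimulus_ids, **kwargs
    )


def is_probe_target(stimulus: ThoughtStimulus) -> bool:
    """Training rule: probe targets are approach- or neutral-oriented thoughts
    with a positive or neutral emotional tone; everything else is a distractor."""
    return stimulus.orientation in ("approach", "neutral") and stimulus.valence in (
        "positive",
        "neutral",
    )


def classify_for_training(
    stimuli: Sequence[ThoughtStimulus], cognitive_map: CognitiveMap | None = None
) -> TrainingPartition:
    """Partition an inventory into probe targets and distractors.

    The elicited labels govern the classification; the cognitive map, when
    given, is attached as diagnostic provenance only.
    """
    stimuli = list(stimuli)
    if not stimuli:
        raise InvalidInputError("empty stimulus inventory")
    texts = [s.text for s in stimuli]
    if len(set(texts)) != len(texts):
        raise InvalidInputError("stimulus texts must be unique within an inventory")
    if cognitive_map is not None:
        if set(cognitive_map.stimulus_ids) != {s.stimulus_id for s in stimuli}:
            raise InvalidInputError("cognitive map does not cover the same stimulus ids")
    targets = tuple(s for s in stimuli if is_probe_target(s))
    distractors = tuple(s for s in stimuli if not is_probe_target(s))
    return TrainingPartition(
        probe_targets=targets, distractors=distractors, cognitive_map=cognitive_map
    )


def read_inventory(path: str | Path) -> list[ThoughtStimulus]:
    """Read a stimulus inventory CSV (stimulus_id, text, valence, orientation)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"stimulus_id", "text", "valence", "orientation"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise InvalidInputError(
                f"inventory CSV must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        return [
            ThoughtStimulus(
                stimulus_id=row["stimulus_id"],
                text=row["text"],
                valence=row["valence"],
                orientation=row["orientation"],
            )
            for row in reader
        ]


def write_inventory(stimuli: Sequence[ThoughtStimulus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stimulus_id", "text", "valence", "orientation"])
        for s in stimuli:
            w.writerow([s.stimulus_id, s.text, s.valence, s.orientation])


def read_similarity(
    path: str | Path, scale_bounds: tuple[float, float] = (1.0, 9.0)
) -> SimilarityRatings:
    """Read similarity ratings from CSV, accepting two dialects.

    Long form has header ``stimulus_a,stimulus_b,rating``; anything else is
    treated as a square matrix with stimulus ids in the header row and first
    column.  The dialect is auto-detected from the header.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise InvalidInputError(f"empty similarity file: {path}")
    header = [h.strip() for h in rows[0]]
    s_min, s_max = scale_bounds
    if header[:3] == ["stimulus_a", "stimulus_b", "rating"]:
        ids: list[str] = []
        entries: dict[tuple[str, str], float] = {}
        for row in rows[1:]:
            a, b, r = row[0], row[1], float(row[2])
            for sid in (a, b):
                if sid not in ids:
                    ids.append(sid)
            entries[(a, b)] = r
        n = len(ids)
        mat = np.full((n, n), np.nan)
        np.fill_diagonal(mat, s_max)
        index = {sid: i for i, sid in enumerate(ids)}
        for (a, b), r in entries.items():
            mat[index[a], index[b]] = r
            mat[index[b], index[a]] = r
        if np.isnan(mat).any():
            missing = int(np.isnan(mat).sum() // 2)
            raise InvalidInputError(f"long-form similarity file missing {missing} pair(s)")
        return SimilarityRatings(tuple(ids), mat, scale_bounds)
    # square-matrix dialect
    ids = header[1:]
    mat = np.array([[float(v) for v in row[1:]] for row in rows[1:]], dtype=float)
    return SimilarityRatings(tuple(ids), mat, scale_bounds)


def write_similarity_long(ratings: SimilarityRatings, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stimulus_a", "stimulus_b", "rating"])
        for i, a in enumerate(ratings.stimulus_ids):
            for j in range(i + 1, ratings.n):
                w.writerow([a, ratings.stimulus_ids[j], repr(float(ratings.ratings[i, j]))])
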