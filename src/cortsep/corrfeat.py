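"""Cohort correlation matrices, difference-based feature selection, and
subset-of-g feature matrices.

A "feature" is one interregional correlation, identified by a canonical
region pair (i, j) with i < j.  Features are ranked by the absolute
difference between the two cohorts' correlations at that pair; the
subset feature matrix re-evaluates each selected correlation within small
random subject subsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cortsep.io_atlas import RegionAtlas, ThicknessTable, AtlasError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric interregional Pearson correlation matrix for one cohort."""

    values: np.ndarray
    n_subjects: int
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.atlas.n_regions
        if self.values.shape != (p, p):
            raise ValueError(f"correlation matrix shape {self.values.shape}, expected ({p}, {p})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")


def cohort_correlation(table: ThicknessTable) -> CorrelationMatrix:
    """Pearson correlation across subjects for every region pair."""
    if table.n_subjects < 3:
        raise ValueError(f"need >= 3 subjects, got {table.n_subjects}")
    sds = table.values.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance region(s): {[table.atlas.region_names[i] for i in zero]}"
        )
    corr = np.corrcoef(table.values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, table.n_subjects, table.atlas)


def correlation_difference(
    case_cm: CorrelationMatrix, control_cm: CorrelationMatrix, fisher_z: bool = False
) -> np.ndarray:
    """Entrywise absolute correlation difference |r_case - r_control|.

    With ``fisher_z`` the difference is taken on arctanh-transformed
    correlations (off by default; the per-pair Euclidean distance between
    raw correlations reduces to the absolute difference).
    """
    if case_cm.atlas != control_cm.atlas:
        raise AtlasError("atlas mismatch between correlation matrices")
    # enforce bitwise symmetry before differencing
    a = (case_cm.values + case_cm.values.T) / 2.0
    b = (control_cm.values + control_cm.values.T) / 2.0
    if fisher_z:
        lim = 1.0 - 1e-12
        a = np.arctanh(np.clip(a, -lim, lim))
        b = np.arctanh(np.clip(b, -lim, lim))
    diff = np.abs(a - b)
    np.fill_diagonal(diff, 0.0)
    return diff


@dataclass
class FeatureSet:
    """Ranked region-pair features with their difference scores."""

    pairs: tuple[tuple[int, int], ...]
    scores: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores length mismatch")
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) not in canonical i < j order")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    @property
    def k(self) -> int:
        return len(self.pairs)

    def region_names(self) -> list[tuple[str, str]]:
        names = self.atlas.region_names
        return [(names[i], names[j]) for i, j in self.pairs]

    def regions_used(self) -> list[int]:
        """Sorted unique region indices appearing in any pair."""
        return sorted({r for pair in self.pairs for r in pair})

    def to_frame(self) -> pd.DataFrame:
        names = self.atlas.region_names
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.k + 1),
                "region_i": [names[i] for i, _ in self.pairs],
                "region_j": [names[j] for _, j in self.pairs],
                "score": self.scores,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_top_features(
    diff: np.ndarray, k: int = 15, atlas: RegionAtlas | None = None
) -> FeatureSet:
    """The k off-diagonal pairs with the largest difference score.

    Sorted by descending score; exact ties broken lexicographically by the
    canonical (i, j) pair so selection is deterministic.
    """
    diff = np.asarray(diff, dtype=float)
    p = diff.shape[0]
    if atlas is None:
        from cortsep.io_atlas import load_atlas

        atlas = (
            load_atlas("dk70")
            if p == 70
            else RegionAtlas(tuple(f"lh_r{i:03d}" for i in range(p)), ("lh",) * p)
        )
    n_pairs = p * (p - 1) // 2
    if not 0 < k <= n_pairs:
        raise ValueError(f"k must be in [1, {n_pairs}], got {k}")
    ii, jj = np.triu_indices(p, 1)
    scores = diff[ii, jj]
    # stable ordering: descending score, then ascending (i, j)
    order = np.lexsort((jj, ii, -scores))[:k]
    pairs = tuple((int(ii[o]), int(jj[o])) for o in order)
    return FeatureSet(pairs, scores[order], atlas)


def count_candidate_features(atlas: RegionAtlas | int, include_diagonal: bool = False) -> int:
    """Number of unique correlation-matrix entries available as features."""
    p = atlas if isinstance(atlas, int) else atlas.n_regions
    n = p * (p - 1) // 2
    return n + p if include_diagonal else n


@dataclass(frozen=True)
class SubsetDraw:
    """One random draw of g distinct subjects from a single cohort."""

    subject_ids: tuple[str, ...]
    cohort: str

    def __post_init__(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subset contains repeated subjects")


def sample_subsets(
    table: ThicknessTable,
    cohort: str,
    g: int = 6,
    n_subsets: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[SubsetDraw]:
    """Independent draws of g distinct subjects from one cohort.

    Subjects recur across draws (sampling is with replacement across
    draws, without replacement within a draw).
    """
    mask = table.cohort_mask(cohort)
    ids = [s for s, m in zip(table.subject_ids, mask) if m]
    if g > len(ids):
        raise ValueError(f"subset size g={g} exceeds cohort size {len(ids)}")
    if g < 2:
        raise ValueError("subset size g must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = []
    for _ in range(n_subsets):
        chosen = rng.choice(len(ids), size=g, replace=False)
        draws.append(SubsetDraw(tuple(ids[c] for c in chosen), cohort))
    return draws


def subset_feature_vector(
    table: ThicknessTable,
    draw: SubsetDraw,
    features: FeatureSet,
    nan_feature: bool = False,
) -> np.ndarray:
    """Within-subset Pearson correlation for each feature pair.

    A zero-variance region within the subset is an error unless
    ``nan_feature`` is set, in which case the affected coordinates are NaN
    (callers drop such rows downstream).
    """
    sub = table.subset(draw.subject_ids)
    regions = features.regions_used()
    vals = sub.values[:, regions]
    sds = vals.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size and not nan_feature:
        bad = [table.atlas.region_names[regions[z]] for z in zero]
        raise ValueError(f"zero within-subset variance for region(s) {bad} in draw {draw.subject_ids}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    pos = {r: c for c, r in enumerate(regions)}
    out = np.array([corr[pos[i], pos[j]] for i, j in features.pairs])
    return np.clip(out, -1.0, 1.0)


@dataclass
class FeatureMatrix:
    """Rows of subset feature vectors with cohort labels and provenance."""

    values: np.ndarray
    labels: tuple[str, ...]
    provenance: tuple[tuple[str, ...], ...]
    features: FeatureSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != self.features.k:
            raise ValueError(
                f"feature matrix shape {self.values.shape}, expected (*, {self.features.k})"
            )
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValueError("labels/provenance length mismatch")
        finite = self.values[np.isfinite(self.values)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("feature values outside [-1, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            self.values[idx],
            tuple(self.labels[i] for i in idx),
            tuple(self.provenance[i] for i in idx),
            self.features,
        )

    def subjects_used(self) -> set[str]:
        return {s for row in self.provenance for s in row}

    def to_csv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        cols = [f"f{r:02d}" for r in range(1, self.features.k + 1)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump({str(i): list(row) for i, row in enumerate(self.provenance)}, fh, indent=1)


def build_feature_matrix(
    case_table: ThicknessTable,
    control_table: ThicknessTable,
    features: FeatureSet,
    n_subsets_per_cohort: int = 500,
    g: int = 6,
    seed: int = 0,
    nan_feature: bool = False,
) -> FeatureMatrix:
    """Concatenated case-then-control subset feature matrix.

    Draws ``n_subsets_per_cohort`` subsets of ``g`` subjects from each
    cohort, computes the feature vector of each, and stacks them with
    labels and per-row subject provenance.  Rows with NaN features (only
    possible under ``nan_feature``) are dropped with a log entry.
    """
    from cortsep.io_atlas import CASE, CONTROL

    master = np.random.SeedSequence(seed)
    ss_case, ss_control = master.spawn(2)
    draws = sample_subsets(
        case_table, CASE, g, n_subsets_per_cohort, np.random.default_rng(ss_case)
    )
    draws += sample_subsets(
        control_table, CONTROL, g, n_subsets_per_cohort, np.random.default_rng(ss_control)
    )
    tables = {CASE: case_table, CONTROL: control_table}
    rows, labels, prov = [], [], []
    for draw in draws:
        vec = subset_feature_vector(tables[draw.cohort], draw, features, nan_feature=nan_feature)
        if np.any(~np.isfinite(vec)):
            logger.warning("dropping subset row with NaN features: %s", draw.subject_ids)
            continue
        rows.append(vec)
        labels.append(draw.cohort)
        prov.append(draw.subject_ids)
    return FeatureMatrix(np.array(rows), tuple(labels), tuple(prov), features)
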