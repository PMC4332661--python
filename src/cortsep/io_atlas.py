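"""Thickness-table I/O and the 70-region bilateral cortical atlas contract.

The canonical atlas is the bilateral Desikan-Killiany parcellation: 35
regions per hemisphere, left hemisphere first, alphabetical within each
hemisphere.  Region identifiers are ``"<hemi>_<label>"`` (e.g.
``"lh_bankssts"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
COHORTS = (CASE, CONTROL)

#: Desikan-Killiany cortical labels, one hemisphere (alphabetical, 35 labels).
DK_LABELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "corpuscallosum",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)


class AtlasError(ValueError):
    """Invalid atlas definition or atlas mismatch."""


class TableError(ValueError):
    """Invalid thickness table content."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered, named cortical parcellation.

    Parameters
    ----------
    region_names
        Unique region identifiers; the order is canonical and stable.
    hemispheres
        Per-region hemisphere tag, ``"lh"`` or ``"rh"``.
    """

    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.region_names) != len(self.hemispheres):
            raise AtlasError("region_names and hemispheres length mismatch")
        if len(set(self.region_names)) != len(self.region_names):
            dup = sorted(
                n for n in set(self.region_names) if list(self.region_names).count(n) > 1
            )
            raise AtlasError(f"duplicate region names in atlas: {dup}")
        bad = set(self.hemispheres) - {"lh", "rh"}
        if bad:
            raise AtlasError(f"unknown hemisphere tags: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def index(self, name: str) -> int:
        """Position of a region in canonical order."""
        try:
            return self.region_names.index(name)
        except ValueError:
            raise AtlasError(f"region {name!r} not in atlas") from None

    def __len__(self) -> int:
        return self.n_regions

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegionAtlas)
            and self.region_names == other.region_names
            and self.hemispheres == other.hemispheres
        )

    def __hash__(self) -> int:
        return hash((self.region_names, self.hemispheres))


def _dk70() -> RegionAtlas:
    names = tuple(f"{h}_{lab}" for h in ("lh", "rh") for lab in DK_LABELS)
    hemis = tuple(h for h in ("lh", "rh") for _ in DK_LABELS)
    return RegionAtlas(names, hemis)


def load_atlas(spec: str | Path = "dk70") -> RegionAtlas:
    """Load the built-in bilateral atlas or parse a region-per-line file.

    ``spec="dk70"`` returns the canonical 70-region bilateral
    Desikan-Killiany atlas (left hemisphere first, alphabetical within
    hemisphere).  Any other value is treated as a path to a text file with
    one region identifier per line (``lh_...``/``rh_...``); file order is
    preserved.
    """
    if isinstance(spec, str) and spec == "dk70":
        return _dk70()
    path = Path(spec)
    if not path.exists():
        raise AtlasError(f"unknown atlas name or missing file: {spec!r}")
    names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    hemis = []
    for name in names:
        hemi = name.split("_", 1)[0]
        if hemi not in ("lh", "rh"):
            raise AtlasError(f"cannot infer hemisphere for region {name!r}")
        hemis.append(hemi)
    return RegionAtlas(tuple(names), tuple(hemis))


@dataclass
class ThicknessTable:
    """Subjects x regions cortical thickness in mm, with cohort labels."""

    subject_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    values: np.ndarray
    atlas: RegionAtlas = field(default_factory=_dk70)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, self.atlas.n_regions):
            raise TableError(
                f"values shape {self.values.shape} does not match "
                f"{n} subjects x {self.atlas.n_regions} regions"
            )
        if len(self.cohort_labels) != n:
            raise TableError("cohort_labels length does not match subject count")
        if len(set(self.subject_ids)) != n:
            dup = sorted(s for s in set(self.subject_ids) if self.subject_ids.count(s) > 1)
            raise TableError(f"duplicate subject IDs: {dup}")
        bad = set(self.cohort_labels) - set(COHORTS)
        if bad:
            raise TableError(f"unknown cohort labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableError(
                f"non-finite thickness for subject {self.subject_ids[i]!r}, "
                f"region {self.atlas.region_names[j]!r}"
            )
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise TableError(
                f"non-positive thickness {self.values[i, j]!r} for subject "
                f"{self.subject_ids[i]!r}, region {self.atlas.region_names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def cohort_mask(self, cohort: str) -> np.ndarray:
        if cohort not in COHORTS:
            raise TableError(f"unknown cohort {cohort!r}")
        return np.array([lab == cohort for lab in self.cohort_labels])

    def subset(self, subject_ids: Sequence[str]) -> "ThicknessTable":
        """Rows for the given subjects, in the given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return ThicknessTable(
            tuple(subject_ids),
            tuple(self.cohort_labels[i] for i in idx),
            self.values[idx],
            self.atlas,
        )


def _region_from_column(col: str, dialect: str) -> str | None:
    """Map a file column name to a canonical region id, or None to skip."""
    if dialect == "aparcstats2table":
        if not col.endswith("_thickness"):
            return None
        return col[: -len("_thickness")]
    return col


def read_thickness_table(
    path: str | Path,
    dialect: str = "aparcstats2table",
    cohort_label: str | None = None,
    atlas: RegionAtlas | None = None,
    drop_incomplete_subjects: bool = False,
) -> ThicknessTable:
    """Parse a tab-separated thickness table.

    Parameters
    ----------
    path
        TSV file.  First column is the subject ID for the
        ``aparcstats2table`` dialect; the ``plain`` dialect requires a
        ``subject_id`` column and accepts an optional ``cohort`` column.
    dialect
        ``"aparcstats2table"`` (region columns named
        ``<hemi>_<label>_thickness``) or ``"plain"`` (region columns named
        ``<hemi>_<label>``).
    cohort_label
        Cohort assigned to every subject; overrides any ``cohort`` column.
    drop_incomplete_subjects
        Drop subjects with any missing region value instead of erroring.

    Columns not matching an atlas region (e.g. mean-thickness summaries,
    eTIV) are ignored with a logged warning.  Columns may appear in any
    order; the returned table is in canonical atlas order.
    """
    if dialect not in ("aparcstats2table", "plain"):
        raise TableError(f"unknown dialect {dialect!r}")
    atlas = atlas or _dk70()
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")

    if dialect == "plain":
        if "subject_id" not in df.columns:
            raise TableError("plain dialect requires a 'subject_id' column")
        id_col = "subject_id"
    else:
        id_col = df.columns[0]
    subject_ids = df[id_col].astype(str).tolist()

    cohort_col = None
    if dialect == "plain" and "cohort" in df.columns:
        cohort_col = df["cohort"].astype(str).tolist()

    region_cols: dict[str, str] = {}
    for col in df.columns:
        if col == id_col or col == "cohort":
            continue
        region = _region_from_column(col, dialect)
        if region is not None and region in atlas.region_names:
            region_cols[region] = col
        else:
            logger.warning("ignoring non-atlas column %r in %s", col, path)

    missing = [r for r in atlas.region_names if r not in region_cols]
    if missing:
        raise TableError(f"missing region column(s): {missing}")

    mat = df[[region_cols[r] for r in atlas.region_names]].to_numpy(dtype=float)

    if drop_incomplete_subjects:
        keep = np.all(np.isfinite(mat), axis=1)
        if not keep.all():
            dropped = [s for s, k in zip(subject_ids, keep) if not k]
            logger.warning("dropping %d incomplete subject(s): %s", len(dropped), dropped)
        mat = mat[keep]
        subject_ids = [s for s, k in zip(subject_ids, keep) if k]
        if cohort_col is not None:
            cohort_col = [c for c, k in zip(cohort_col, keep) if k]

    if cohort_label is not None:
        labels = tuple([cohort_label] * len(subject_ids))
    elif cohort_col is not None:
        labels = tuple(cohort_col)
    else:
        raise TableError("no cohort information: pass cohort_label or add a 'cohort' column")

    return ThicknessTable(tuple(subject_ids), labels, mat, atlas)


def write_thickness_table(table: ThicknessTable, path: str | Path) -> None:
    """Write the plain TSV dialect (round-trips bit-exactly)."""
    # repr() round-trips IEEE doubles exactly; pandas' default float
    # formatting does not
    df = pd.DataFrame(
        [[repr(float(v)) for v in row] for row in table.values],
        columns=list(table.atlas.region_names),
    )
    df.insert(0, "subject_id", list(table.subject_ids))
    df.insert(1, "cohort", list(table.cohort_labels))
    df.to_csv(path, sep="\t", index=False)


def concat_cohorts(case_table: ThicknessTable, control_table: ThicknessTable) -> ThicknessTable:
    """Stack two cohort tables into one, preserving per-subject labels."""
    if case_table.atlas != control_table.atlas:
        raise AtlasError("atlas mismatch between cohort tables")
    if case_table.n_subjects == 0 or control_table.n_subjects == 0:
        raise TableError("cannot concatenate an empty cohort table")
    shared = set(case_table.subject_ids) & set(control_table.subject_ids)
    if shared:
        raise TableError(f"overlapping subject IDs across cohorts: {sorted(shared)}")
    return ThicknessTable(
        case_table.subject_ids + control_table.subject_ids,
        case_table.cohort_labels + control_table.cohort_labels,
        np.vstack([case_table.values, control_table.values]),
        case_table.atlas,
    )
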