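"""FreeSurfer-style imaging phenotype schemas and feature tables.

The processed-image feature space modeled here is the concatenation of four
atlas parcellations of a T1-weighted scan:

* ``aseg`` (45 subcortical regions) and ``wmparc`` (70 white-matter regions),
  each summarized by six intensity statistics (volume, mean, sd, min, max,
  range), and
* the Desikan-Killiany-Tourville (62 cortical regions) and Desikan-Killiany
  (68 cortical regions) surface atlases, each summarized by nine surface
  statistics (vertex count, surface area, gray-matter volume, thickness
  mean/sd, mean and Gaussian curvature, folding index, curvature index),

for 270 + 420 + 558 + 612 = 1860 features per subject.  Actual image
processing (segmentation, parcellation, QC) is out of scope: only the shape
of its output table is modeled, so any table with the right columns -- real
FreeSurfer exports or synthetic data -- flows through the pipeline.

Feature matrices are oriented features x subjects internally (each subject is
a column), matching the multi-task regression convention downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INTENSITY_STATISTICS",
    "SURFACE_STATISTICS",
    "ATLAS_REGION_COUNTS",
    "FeatureSchema",
    "FeatureMatrix",
    "SchemaMismatchError",
    "build_default_schema",
    "read_feature_table",
    "write_feature_table",
]

#: Six per-region summaries of normalized T1 intensity (volumetric atlases).
INTENSITY_STATISTICS = ("volume", "mean", "sd", "min", "max", "range")

#: Nine per-region surface summaries (cortical atlases).
SURFACE_STATISTICS = (
    "n_vertices",
    "surface_area",
    "gm_volume",
    "thickness_mean",
    "thickness_sd",
    "curvature_mean",
    "curvature_gaussian",
    "folding_index",
    "curvature_index",
)

#: (region count, statistic tuple) for each atlas block, in canonical order.
ATLAS_REGION_COUNTS = {
    "aseg": (45, INTENSITY_STATISTICS),
    "wmparc": (70, INTENSITY_STATISTICS),
    "dkt": (62, SURFACE_STATISTICS),
    "dk": (68, SURFACE_STATISTICS),
}


class SchemaMismatchError(ValueError):
    """A feature table's columns do not match the expected schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of (atlas, region, statistic) entries defining a table layout."""

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("schema entries must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        """Flat column identifiers, ``atlas:region:statistic``."""
        return [f"{a}:{r}:{s}" for a, r, s in self.entries]

    def atlas_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a, _, _ in self.entries:
            counts[a] = counts.get(a, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["atlas", "region", "statistic"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "FeatureSchema":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(tuple(df.itertuples(index=False, name=None)))


def build_default_schema(region_names: dict[str, list[str]] | None = None) -> FeatureSchema:
    """Build the default 1860-feature four-atlas schema.

    Parameters
    ----------
    region_names
        Optional mapping from atlas name (``aseg``, ``wmparc``, ``dkt``, ``dk``)
        to a list of region names of the correct length.  Placeholders
        ``region_1..region_k`` are used otherwise (the region name lists are
        site-specific; only the counts and statistics are fixed).
    """
    region_names = region_names or {}
    entries: list[tuple[str, str, str]] = []
    for atlas, (n_regions, stats) in ATLAS_REGION_COUNTS.items():
        names = region_names.get(atlas, [f"region_{i + 1}" for i in range(n_regions)])
        if len(names) != n_regions:
            raise ValueError(
                f"atlas {atlas!r} requires {n_regions} region names, got {len(names)}"
            )
        for region in names:
            for stat in stats:
                entries.append((atlas, region, stat))
    return FeatureSchema(tuple(entries))


@dataclass
class FeatureMatrix:
    """A features x subjects real matrix with row and column identifiers.

    Holds any stage of the imaging phenotype: the raw processed-image table,
    network-extracted features, or covariate-adjusted responses.
    """

    values: np.ndarray
    feature_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x subjects)")
        if self.values.shape != (len(self.feature_ids), len(self.subject_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.subject_ids)} subjects"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, mask_or_ids) -> "FeatureMatrix":
        """Restrict to a boolean mask or an explicit subject-id list."""
        if isinstance(mask_or_ids, (list, tuple)) and mask_or_ids and isinstance(mask_or_ids[0], str):
            idx = [self.subject_ids.index(s) for s in mask_or_ids]
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return FeatureMatrix(
            self.values[:, idx],
            list(self.feature_ids),
            [self.subject_ids[i] for i in np.atleast_1d(idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Subjects x features table (the on-disk orientation)."""
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_ids,
        )


def write_feature_table(matrix: FeatureMatrix, path, sep: str = "\t") -> None:
    """Write a feature matrix as delimited text, one row per subject."""
    matrix.to_frame().to_csv(path, sep=sep)


def _sniff_sep(path) -> str:
    if isinstance(path, (str,)) or hasattr(path, "__fspath__"):
        with open(path, "r") as fh:
            header = fh.readline()
    else:  # file-like
        pos = path.tell()
        header = path.readline()
        path.seek(pos)
        if isinstance(header, bytes):
            header = header.decode()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(path, schema: FeatureSchema | None = None) -> FeatureMatrix:
    """Read a delimited subjects x features table into a :class:`FeatureMatrix`.

    The first column is the subject identifier.  When a schema is supplied the
    column set must match it exactly; columns are reordered to schema order.

    Raises
    ------
    SchemaMismatchError
        If columns are missing from / extra relative to the schema.
    ValueError
        On a non-numeric cell, reporting its row and column.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if schema is not None:
        want = schema.feature_ids
        have = list(df.columns)
        missing = [c for c in want if c not in set(have)]
        extra = [c for c in have if c not in set(want)]
        if missing or extra:
            raise SchemaMismatchError(
                f"feature table does not match schema: "
                f"missing={missing[:10]}{'...' if len(missing) > 10 else ''} "
                f"extra={extra[:10]}{'...' if len(extra) > 10 else ''}"
            )
        df = df[want]
    converted_cols = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        converted_cols[col] = converted
    numeric = pd.DataFrame(converted_cols, index=df.index)
    if numeric.isna().any().any():
        row, col = next(
            (r, c) for c in numeric.columns for r in numeric.index[numeric[c].isna()]
        )
        raise ValueError(f"missing value at row {row!r}, column {col!r}")
    return FeatureMatrix(
        numeric.to_numpy(dtype=float).T,
        list(numeric.columns),
        [str(s) for s in numeric.index],
    )
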