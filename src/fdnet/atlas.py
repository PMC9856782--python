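"""Cortical atlas bookkeeping and file I/O.

The pipeline works on a fixed 68-region cortical parcellation (a rearranged
Desikan-Killiany atlas): region ids run 1..68, odd ids lie in the left
hemisphere and even ids in the right, and the ids are grouped into four
anatomical lobes (frontal 1-28, temporal 29-46, parietal 47-60, occipital
61-68).  The region table fixes the row/column order of every matrix the
pipeline produces.

Volumes are NIfTI integer label grids (0 = background), cohort fractal
dimension matrices are CSV with one row per subject and one column per
region abbreviation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "LOBE_SIZES",
    "N_REGIONS",
    "RegionTable",
    "LabeledParcellation",
    "CohortFDMatrix",
    "load_region_table",
    "read_parcellation",
    "write_parcellation",
    "cohort_from_parcellations",
]

N_REGIONS = 68
LOBES = ("frontal", "temporal", "parietal", "occipital")
LOBE_SIZES = {"frontal": 28, "temporal": 18, "parietal": 14, "occipital": 8}


class RegionTable:
    """The canonical 68-region table (id, name, abbreviation, lobe, hemisphere).

    Wraps a :class:`pandas.DataFrame` sorted by region id; construction
    validates every structural invariant (row count, id range, hemisphere
    parity, lobe block sizes).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().sort_values("id").reset_index(drop=True)
        required = {"id", "name", "abbreviation", "lobe", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        if len(df) != N_REGIONS:
            raise ValueError(f"region table must have {N_REGIONS} rows, got {len(df)}")
        ids = df["id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, N_REGIONS + 1)):
            raise ValueError("region ids must be exactly 1..68 with no duplicates")
        unknown = set(df["lobe"]) - set(LOBES)
        if unknown:
            raise ValueError(f"unknown lobe(s): {sorted(unknown)}")
        for lobe, size in LOBE_SIZES.items():
            got = int((df["lobe"] == lobe).sum())
            if got != size:
                raise ValueError(f"lobe {lobe!r} must have {size} regions, got {got}")
        expect_hemi = np.where(ids % 2 == 1, "L", "R")
        if not np.array_equal(df["hemisphere"].to_numpy(), expect_hemi):
            raise ValueError("odd ids must be hemisphere L, even ids R")
        self.df = df

    def __len__(self) -> int:
        return N_REGIONS

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionTable) and self.df.equals(other.df)

    @property
    def abbreviations(self) -> list[str]:
        """Column labels in table order, disambiguated by hemisphere (e.g. 'CACg_L')."""
        return [
            f"{a}_{h}"
            for a, h in zip(self.df["abbreviation"], self.df["hemisphere"])
        ]

    @property
    def lobes(self) -> np.ndarray:
        return self.df["lobe"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.df["hemisphere"].to_numpy()

    def lobe_indices(self, lobe: str) -> np.ndarray:
        """0-based row positions of a lobe's regions."""
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r}")
        return np.flatnonzero(self.lobes == lobe)

    def lobe_partition(self) -> np.ndarray:
        """Module labels 1..4 with the four lobes playing the role of modules."""
        order = {lobe: i + 1 for i, lobe in enumerate(LOBES)}
        return np.array([order[l] for l in self.lobes], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionTable":
        return cls(pd.read_csv(path))


def load_region_table(source: str | Path | pd.DataFrame | None = None) -> RegionTable:
    """Load and validate the region table.

    ``source=None`` returns the packaged canonical table; a path loads a CSV
    with the same schema; a DataFrame is validated directly.
    """
    if source is None:
        ref = importlib.resources.files("fdnet.data") / "dk_regions.csv"
        with importlib.resources.as_file(ref) as p:
            return RegionTable.from_csv(p)
    if isinstance(source, pd.DataFrame):
        return RegionTable(source)
    return RegionTable.from_csv(source)


@dataclass
class LabeledParcellation:
    """A 3D integer label grid (0 background, 1..68 regions) plus its region table."""

    labels: np.ndarray
    region_table: RegionTable
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label grid must be 3-dimensional")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("label grid must contain integer labels")
            labels = labels.astype(np.int32)
        present = np.unique(labels)
        bad = present[(present < 0) | (present > N_REGIONS)]
        if bad.size:
            raise ValueError(f"labels outside 0..{N_REGIONS}: {bad.tolist()}")
        self.labels = labels

    def region_mask(self, region_id: int) -> np.ndarray:
        if not 1 <= region_id <= N_REGIONS:
            raise ValueError(f"region id {region_id} outside 1..{N_REGIONS}")
        return self.labels == region_id

    def present_regions(self) -> np.ndarray:
        present = np.unique(self.labels)
        return present[present > 0]


@dataclass
class CohortFDMatrix:
    """Subjects x regions fractal-dimension values for one group."""

    values: np.ndarray
    group_label: str = "group"
    subject_ids: Sequence[str] | None = None
    region_table: RegionTable = field(default_factory=load_region_table)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != N_REGIONS:
            raise ValueError(
                f"cohort matrix must be n_subjects x {N_REGIONS}, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("cohort matrix contains non-finite values")
        self.values = values
        if self.subject_ids is None:
            self.subject_ids = [
                f"{self.group_label}_{i + 1:03d}" for i in range(values.shape[0])
            ]
        elif len(self.subject_ids) != values.shape[0]:
            raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(list(self.subject_ids), name="subject"),
            columns=self.region_table.abbreviations,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        group_label: str = "group",
        region_table: RegionTable | None = None,
    ) -> "CohortFDMatrix":
        df = pd.read_csv(path, index_col=0)
        table = region_table or load_region_table()
        if list(df.columns) != table.abbreviations:
            raise ValueError("cohort CSV columns do not match the region table order")
        return cls(
            values=df.to_numpy(float),
            group_label=group_label,
            subject_ids=[str(s) for s in df.index],
            region_table=table,
        )


def read_parcellation(
    path: str | Path, region_table: RegionTable | None = None
) -> LabeledParcellation:
    """Read a NIfTI integer label volume and validate it against the atlas."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.all(data == np.round(data)):
        raise ValueError(f"{path}: parcellation volume is not integer-valued")
    zooms = img.header.get_zooms()[:3]
    return LabeledParcellation(
        labels=data.astype(np.int32),
        region_table=region_table or load_region_table(),
        voxel_size_mm=tuple(float(z) for z in zooms),
    )


def write_parcellation(parc: LabeledParcellation, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(parc.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int16), affine), str(path))


def cohort_from_parcellations(
    paths: Iterable[str | Path],
    group_label: str = "group",
    region_table: RegionTable | None = None,
    crop: bool = True,
) -> CohortFDMatrix:
    """Per-subject, per-region box-counting FD over a list of label volumes.

    Every subject must have all 68 regions non-empty; an empty region is
    reported with the subject path and region id.
    """
    from .fd import region_fd

    table = region_table or load_region_table()
    rows, ids = [], []
    for path in paths:
        parc = read_parcellation(path, table)
        row = np.empty(N_REGIONS)
        for rid in range(1, N_REGIONS + 1):
            if not parc.region_mask(rid).any():
                raise ValueError(f"subject {path}: region {rid} is empty")
            row[rid - 1] = region_fd(parc, rid, crop=crop).fd
        rows.append(row)
        ids.append(Path(path).stem)
    return CohortFDMatrix(
        values=np.vstack(rows),
        group_label=group_label,
        subject_ids=ids,
        region_table=table,
    )
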