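"""Node universe for the pain-network graphs.

The analysis operates on a fixed set of bilateral regions of interest
(ROIs) — 17 per hemisphere — selected for their known involvement in
acute pain processing, plus the primary auditory cortex (A1/Heschl),
which is added only when an auditory control condition is analysed
(18 nodes per hemisphere, 36 total).  Every matrix, graph and table in
the pipeline indexes nodes by the row order of this table: the left
hemisphere block first, then the right, each in fixed row order, with
A1 as the last row of its hemisphere block.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ROIDefinition",
    "ROITable",
    "load_roi_table",
    "load_ground_truth_partition",
    "node_index",
]

_REQUIRED_COLUMNS = ("name", "hcp_areas", "hemisphere", "x", "y", "z", "audio_only")


@dataclass(frozen=True)
class ROIDefinition:
    """One node: a named region in one hemisphere with an MNI centroid."""

    name: str
    atlas_areas: tuple[str, ...]
    hemisphere: str  # "left" or "right"
    mni: tuple[int, int, int]
    in_audio_only: bool = False

    @property
    def label(self) -> str:
        """Stable node label, e.g. ``"aI_left"``."""
        return f"{self.name}_{self.hemisphere}"


@dataclass(frozen=True)
class ROITable:
    """Ordered node table; indexing is stable across the whole pipeline."""

    rois: tuple[ROIDefinition, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def to_frame(self) -> pd.DataFrame:
        """Table as a DataFrame in the canonical on-disk column layout."""
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rois],
                "hcp_areas": [",".join(r.atlas_areas) for r in self.rois],
                "hemisphere": [r.hemisphere for r in self.rois],
                "x": [r.mni[0] for r in self.rois],
                "y": [r.mni[1] for r in self.rois],
                "z": [r.mni[2] for r in self.rois],
                "audio_only": [int(r.in_audio_only) for r in self.rois],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class ROITableError(ValueError):
    """Raised when an ROI table file fails validation."""


def packaged_roi_path() -> Path:
    """Path of the ROI table shipped with the package."""
    return Path(importlib.resources.files("painnet") / "data" / "roi_table.tsv")


def packaged_partition_path() -> Path:
    return Path(importlib.resources.files("painnet") / "data" / "ground_truth_partition.json")


def load_roi_table(path: str | Path | None = None, include_audio_nodes: bool = False) -> ROITable:
    """Load an ROI table from a TSV file.

    Parameters
    ----------
    path
        Delimited file with columns name, hcp_areas, hemisphere, x, y, z,
        audio_only.  Defaults to the packaged table.
    include_audio_nodes
        If False (pain-only network) rows flagged ``audio_only`` are
        dropped, giving the 34-node network; if True the A1 rows are kept
        (36 nodes).

    Raises
    ------
    ROITableError
        On a missing column, an empty table, or a duplicated
        (name, hemisphere) pair; the message names the offending row.
    """
    if path is None:
        path = packaged_roi_path()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "hemisphere": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ROITableError(f"ROI table {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ROITableError(f"ROI table {path} contains no rows")
    dup = df.duplicated(subset=["name", "hemisphere"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["name", "hemisphere"]].to_records(index=True)
        raise ROITableError(f"Duplicate (name, hemisphere) rows in {path}: {list(rows)}")
    bad_hemi = ~df["hemisphere"].isin(["left", "right"])
    if bad_hemi.any():
        raise ROITableError(
            f"Invalid hemisphere values in {path}: rows {df.index[bad_hemi].tolist()}"
        )
    if not include_audio_nodes:
        df = df[df["audio_only"] == 0]
    rois = []
    # Preserve file order but enforce the left-block-then-right-block layout.
    for hemi in ("left", "right"):
        for _, row in df[df["hemisphere"] == hemi].iterrows():
            for coord in ("x", "y", "z"):
                val = row[coord]
                if pd.isna(val) or int(val) != val:
                    raise ROITableError(
                        f"Non-integer MNI coordinate {coord}={val!r} for "
                        f"({row['name']}, {hemi}) in {path}"
                    )
            rois.append(
                ROIDefinition(
                    name=str(row["name"]),
                    atlas_areas=tuple(str(row["hcp_areas"]).split(",")),
                    hemisphere=hemi,
                    mni=(int(row["x"]), int(row["y"]), int(row["z"])),
                    in_audio_only=bool(row["audio_only"]),
                )
            )
    n_left = sum(r.hemisphere == "left" for r in rois)
    n_right = len(rois) - n_left
    if n_left != n_right:
        raise ROITableError(
            f"Hemisphere imbalance in {path}: {n_left} left vs {n_right} right rows"
        )
    return ROITable(rois=tuple(rois))


def node_index(table: ROITable, name: str, hemisphere: str) -> int:
    """Stable 0-based matrix index of (name, hemisphere).

    Raises ``KeyError`` listing the valid labels when the node is absent
    (e.g. A1 on the 34-node pain table).
    """
    for i, roi in enumerate(table.rois):
        if roi.name == name and roi.hemisphere == hemisphere:
            return i
    raise KeyError(
        f"Node ({name}, {hemisphere}) not in table; valid labels: {table.labels}"
    )


def load_ground_truth_partition(
    table: ROITable, path: str | Path | None = None
) -> dict[str, str]:
    """Reference module labels (node label -> module name) for ``table``.

    The packaged file holds the four-module solution (SM, med-FP, lat-FP,
    limbic) for all 36 candidate nodes; the returned dict is restricted to
    — and validated against — the nodes of ``table``.
    """
    if path is None:
        path = packaged_partition_path()
    with open(path) as fh:
        payload = json.load(fh)
    part = payload["partition"] if "partition" in payload else payload
    missing = [lab for lab in table.labels if lab not in part]
    if missing:
        raise ROITableError(f"Partition file {path} lacks nodes: {missing}")
    return {lab: part[lab] for lab in table.labels}
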