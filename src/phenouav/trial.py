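"""Field-trial data containers and their plain-text serializations.

Layouts travel as GeoJSON feature collections (one polygon per plot with
``plot_id``/``genotype``/``rep``/``block`` properties), height records as
CSV tables, ground targets as CSV, pedigrees as 3-column CSV
(``id,parent1,parent2`` with 0 meaning unknown parent).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "Plot",
    "FieldLayout",
    "GroundTarget",
    "Pedigree",
    "write_layout_geojson",
    "read_layout_geojson",
    "write_targets_csv",
    "read_targets_csv",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "HEIGHT_COLUMNS",
]

#: canonical column order of a height table
HEIGHT_COLUMNS = ["plot_id", "genotype", "rep", "block", "stage", "platform", "ph_cm"]


@dataclass
class Plot:
    plot_id: str
    genotype: str
    rep: int
    block: int
    polygon: Polygon


@dataclass
class FieldLayout:
    """Plot polygons plus the experimental-design attributes.

    ``bed_width_m``/``inter_bed_m`` describe the two-bed internal geometry
    of every plot (beds flush with the plot's left/right edges, furrow in
    between); they are needed to rasterize canopy surfaces.
    """

    plots: list[Plot]
    bed_width_m: float
    inter_bed_m: float
    crs_label: str = ""

    def __iter__(self):
        return iter(self.plots)

    def __len__(self) -> int:
        return len(self.plots)

    def frame(self) -> pd.DataFrame:
        """Design attributes as a DataFrame indexed by plot_id."""
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "genotype": [p.genotype for p in self.plots],
                "rep": [p.rep for p in self.plots],
                "block": [p.block for p in self.plots],
            }
        ).set_index("plot_id")

    def bed_footprints(self, plot: Plot) -> list[tuple[float, float, float, float]]:
        """Axis-aligned (xmin, ymin, xmax, ymax) of the plot's two beds."""
        xmin, ymin, xmax, ymax = plot.polygon.bounds
        b = self.bed_width_m
        return [
            (xmin, ymin, xmin + b, ymax),
            (xmax - b, ymin, xmax, ymax),
        ]


@dataclass
class GroundTarget:
    """A surveyed square target: bundle-adjustment GCP or independent checkpoint."""

    target_id: str
    role: str  # "gcp" | "checkpoint"
    surveyed_x: float
    surveyed_y: float
    surveyed_z: float  # height of the pillar top above ground, meters
    measured_x: float = float("nan")
    measured_y: float = float("nan")
    measured_z: float = float("nan")
    side_m: float = 0.3

    def __post_init__(self) -> None:
        if self.role not in ("gcp", "checkpoint"):
            raise ValueError(f"role must be gcp|checkpoint, got {self.role!r}")


@dataclass
class Pedigree:
    """Pedigree records in topological order (parents precede offspring).

    ``records`` maps individual id -> (parent1, parent2); parent ``None``
    is unknown (treated as an unrelated, non-inbred founder contribution).
    """

    records: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def add(self, individual: str, parent1: str | None = None, parent2: str | None = None):
        for p in (parent1, parent2):
            if p is not None and p not in self.records:
                raise ValueError(f"parent {p!r} of {individual!r} not yet defined (cycle or gap)")
        if individual in self.records:
            raise ValueError(f"duplicate individual {individual!r}")
        self.records[individual] = (parent1, parent2)

    @property
    def individuals(self) -> list[str]:
        return list(self.records)

    def founders(self) -> list[str]:
        return [i for i, (a, b) in self.records.items() if a is None and b is None]


# ---------------------------------------------------------------------------
# serialization


def write_layout_geojson(path: str | os.PathLike, layout: FieldLayout) -> None:
    features = []
    for p in layout.plots:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "plot_id": p.plot_id,
                    "genotype": p.genotype,
                    "rep": p.rep,
                    "block": p.block,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "bed_width_m": layout.bed_width_m,
            "inter_bed_m": layout.inter_bed_m,
            "crs_label": layout.crs_label,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_layout_geojson(path: str | os.PathLike) -> FieldLayout:
    with open(path) as fh:
        doc = json.load(fh)
    meta = doc.get("properties", {})
    plots = []
    for feat in doc["features"]:
        props = feat["properties"]
        plots.append(
            Plot(
                plot_id=str(props["plot_id"]),
                genotype=str(props["genotype"]),
                rep=int(props["rep"]),
                block=int(props["block"]),
                polygon=shape(feat["geometry"]),
            )
        )
    return FieldLayout(
        plots=plots,
        bed_width_m=float(meta.get("bed_width_m", 0.8)),
        inter_bed_m=float(meta.get("inter_bed_m", 0.36)),
        crs_label=str(meta.get("crs_label", "")),
    )


def write_targets_csv(path: str | os.PathLike, targets: list[GroundTarget]) -> None:
    pd.DataFrame(
        {
            "target_id": [t.target_id for t in targets],
            "role": [t.role for t in targets],
            "x_survey": [t.surveyed_x for t in targets],
            "y_survey": [t.surveyed_y for t in targets],
            "z_survey": [t.surveyed_z for t in targets],
            "x_meas": [t.measured_x for t in targets],
            "y_meas": [t.measured_y for t in targets],
            "z_meas": [t.measured_z for t in targets],
            "side_m": [t.side_m for t in targets],
        }
    ).to_csv(path, index=False)


def read_targets_csv(path: str | os.PathLike) -> list[GroundTarget]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            GroundTarget(
                target_id=str(r["target_id"]),
                role=str(r["role"]),
                surveyed_x=float(r["x_survey"]),
                surveyed_y=float(r["y_survey"]),
                surveyed_z=float(r["z_survey"]),
                measured_x=float(r.get("x_meas", float("nan"))),
                measured_y=float(r.get("y_meas", float("nan"))),
                measured_z=float(r.get("z_meas", float("nan"))),
                side_m=float(r.get("side_m", 0.3)),
            )
        )
    return out


def write_pedigree_csv(path: str | os.PathLike, pedigree: Pedigree) -> None:
    rows = [
        {"id": i, "parent1": a or "0", "parent2": b or "0"}
        for i, (a, b) in pedigree.records.items()
    ]
    pd.DataFrame(rows, columns=["id", "parent1", "parent2"]).to_csv(path, index=False)


def read_pedigree_csv(path: str | os.PathLike) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    ped = Pedigree()
    for _, r in df.iterrows():
        p1 = None if str(r["parent1"]) in ("0", "nan", "") else str(r["parent1"])
        p2 = None if str(r["parent2"]) in ("0", "nan", "") else str(r["parent2"])
        ped.add(str(r["id"]), p1, p2)
    return ped
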