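"""Electrode montage: 2-D scalp layout, adjacency, and region labels.

A montage assigns every electrode a schematic position on the scalp
(unit-disk coordinates, +y anterior), a spatial neighbour relation, and
one of five regional networks: occipital (O), frontal (F), left and
right temporal (T_L, T_R), and parietal (P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

REGIONS = ("O", "F", "T_L", "T_R", "P")

#: Canonical block order used when reordering adjacency matrices.
REGION_BLOCK_ORDER = ("O", "F", "T_L", "T_R", "P")


@dataclass(frozen=True)
class Montage:
    """Electrode ids 1..N with layout coordinates, regions, and adjacency.

    Parameters
    ----------
    ids : tuple of int
        Electrode ids, 1-based, unique.
    xy : ndarray, shape (N, 2)
        Schematic layout coordinates in the unit disk; +y is anterior.
    regions : tuple of str
        Region label per electrode, each one of ``REGIONS``.
    neighbors : frozenset of frozenset
        Symmetric, irreflexive adjacency as unordered id pairs.
    """

    ids: tuple
    xy: np.ndarray
    regions: tuple
    neighbors: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("electrode ids must be unique")
        if len(self.ids) != len(self.regions) or len(self.ids) != len(self.xy):
            raise ValueError("ids, xy and regions must have equal length")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        for pair in self.neighbors:
            if len(pair) != 2:
                raise ValueError("neighbor relation must be irreflexive")

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    def region_of(self, electrode_id: int) -> str:
        return self.regions[self.ids.index(electrode_id)]

    def electrodes_in_region(self, region: str) -> list:
        return [i for i, r in zip(self.ids, self.regions) if r == region]

    def are_neighbors(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.neighbors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "region": list(self.regions),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        """Load (id, x, y, region) rows; adjacency is rebuilt from the layout."""
        df = pd.read_csv(path)
        for col in ("id", "x", "y", "region"):
            if col not in df.columns:
                raise ValueError(f"montage file missing column {col!r}")
        xy = df[["x", "y"]].to_numpy(float)
        ids = tuple(int(i) for i in df["id"])
        return cls(
            ids=ids,
            xy=xy,
            regions=tuple(df["region"]),
            neighbors=delaunay_neighbors(ids, xy),
        )


def delaunay_neighbors(ids, xy) -> frozenset:
    """Adjacency from the Delaunay triangulation of the layout.

    Triangulation edges are the standard proximity graph for scattered
    sensor layouts; the relation is symmetric and irreflexive by
    construction.
    """
    xy = np.asarray(xy, float)
    if len(xy) < 3:
        return frozenset(
            frozenset((ids[i], ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        )
    tri = Delaunay(xy)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                pairs.add(frozenset((ids[simplex[a]], ids[simplex[b]])))
    return frozenset(pairs)


def _region_for_position(x: float, y: float) -> str:
    if y >= 0.30:
        return "F"
    if y <= -0.60:
        return "O"
    if x <= -0.45:
        return "T_L"
    if x >= 0.45:
        return "T_R"
    return "P"


def default_montage(n_channels: int = 128) -> Montage:
    """Schematic high-density montage on the unit disk.

    Electrodes are laid out with a sunflower (golden-angle) pattern,
    which spreads them nearly uniformly, then partitioned into the five
    regional networks by position: frontal ahead of y = 0.30, occipital
    behind y = -0.60, temporal strips beyond |x| = 0.45, parietal in
    the remaining centre. The layout is deterministic.
    """
    if n_channels < 5:
        raise ValueError("montage needs at least 5 electrodes")
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = i * golden
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    ids = tuple(range(1, n_channels + 1))
    regions = tuple(_region_for_position(x, y) for x, y in xy)
    return Montage(
        ids=ids, xy=xy, regions=regions, neighbors=delaunay_neighbors(ids, xy)
    )
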