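"""Randomized placement of replicate spots on the chip's s-pixel grid.

The synthesis grid is described in s-pixels (30 µm edge in the main screen);
one peptide spot is a square block of s-pixels (4×4 = 120 µm in the main
screen, 20×20 = 600 µm in the large-spot verification). Every library entry
occupies ``replicates`` spots at seeded, uniformly random grid positions so
that local effects on cell adhesion cannot bias a peptide's replicates;
unused positions are explicit blanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import BLANK_ID
from .library_design import PeptideEntry


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the synthesis grid.

    s_pixel_um: edge length of one synthesis pixel (µm).
    spot_side_spx: spot edge in s-pixels (spot edge = spot_side_spx * s_pixel_um).
    grid_cols/grid_rows: spot capacity of the chip region.
    """

    s_pixel_um: float = 30.0
    spot_side_spx: int = 4
    grid_cols: int = 10
    grid_rows: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_pixel_um <= 0:
            raise ValueError("s_pixel_um must be positive")
        if min(self.spot_side_spx, self.grid_cols, self.grid_rows) < 1:
            raise ValueError("spot_side_spx, grid_cols and grid_rows must be >= 1")

    @property
    def spot_edge_um(self) -> float:
        return self.spot_side_spx * self.s_pixel_um

    @property
    def capacity(self) -> int:
        return self.grid_cols * self.grid_rows

    def spots_per_cm2(self) -> float:
        """Packing density of abutting spots (pitch = spot edge)."""
        return (10_000.0 / self.spot_edge_um) ** 2


@dataclass(frozen=True)
class Spot:
    spot_id: str
    row: int
    col: int
    peptide_id: str


@dataclass
class ArrayLayout:
    grid: GridSpec
    spots: list[Spot] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        coords = [(s.row, s.col) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (row, col) positions in layout")
        for s in self.spots:
            if not (0 <= s.row < self.grid.grid_rows and 0 <= s.col < self.grid.grid_cols):
                raise ValueError(f"spot {s.spot_id} outside the grid")

    def spot_position_um(self, spot: Spot) -> tuple[float, float]:
        """Physical (x, y) of the spot's top-left corner in µm."""
        edge = self.grid.spot_edge_um
        return spot.col * edge, spot.row * edge

    def peptide_multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spots:
            counts[s.peptide_id] = counts.get(s.peptide_id, 0) + 1
        return counts


def build_layout(
    library: Sequence[PeptideEntry], grid: GridSpec, seed: int | None = None
) -> ArrayLayout:
    """Place every entry's replicate spots at seeded random grid positions.

    The placement is a uniform random bijection between the replicate-expanded
    library and a subset of grid cells; remaining cells become blank spots
    (peptide_id "BLANK").
    """
    seed = grid.seed if seed is None else seed
    expanded: list[str] = []
    for e in library:
        expanded.extend([e.peptide_id] * e.replicates)
    if len(expanded) > grid.capacity:
        raise ValueError(
            f"grid capacity insufficient: {len(expanded)} replicate spots required, "
            f"{grid.capacity} positions available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(grid.capacity)
    spots = []
    for idx, cell in enumerate(order):
        row, col = divmod(int(cell), grid.grid_cols)
        pid = expanded[idx] if idx < len(expanded) else BLANK_ID
        spots.append(Spot(spot_id=f"S{int(cell):06d}", row=row, col=col, peptide_id=pid))
    spots.sort(key=lambda s: (s.row, s.col))
    return ArrayLayout(grid=grid, spots=spots, seed=seed)


def serialize_layout(layout: ArrayLayout, path: str | Path, header_comment: str | None = None) -> None:
    """Write the layout as a GAL-dialect TSV: a metadata line, a column-name
    line, then one row per spot."""
    g = layout.grid
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"## {header_comment}\n")
        fh.write(
            "#pepscreen-layout\tversion=1"
            f"\ts_pixel_um={g.s_pixel_um}\tspot_side_spx={g.spot_side_spx}"
            f"\tgrid_rows={g.grid_rows}\tgrid_cols={g.grid_cols}\tseed={layout.seed}\n"
        )
        fh.write("spot_id\trow\tcol\tpeptide_id\n")
        for s in layout.spots:
            fh.write(f"{s.spot_id}\t{s.row}\t{s.col}\t{s.peptide_id}\n")


def parse_layout(path: str | Path) -> ArrayLayout:
    """Parse a GAL-dialect layout TSV; malformed rows raise with their line number."""
    meta: dict[str, str] = {}
    spots: list[Spot] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#pepscreen-layout"):
                for token in line.split("\t")[1:]:
                    key, _, value = token.partition("=")
                    meta[key] = value
                continue
            if not header_seen:
                if line.split("\t") != ["spot_id", "row", "col", "peptide_id"]:
                    raise ValueError(f"line {lineno}: unexpected column header {line!r}")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields, got {len(fields)}")
            try:
                spots.append(
                    Spot(
                        spot_id=fields[0],
                        row=int(fields[1]),
                        col=int(fields[2]),
                        peptide_id=fields[3],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    required = {"s_pixel_um", "spot_side_spx", "grid_rows", "grid_cols", "seed"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"layout metadata line missing keys: {sorted(missing)}")
    grid = GridSpec(
        s_pixel_um=float(meta["s_pixel_um"]),
        spot_side_spx=int(meta["spot_side_spx"]),
        grid_rows=int(meta["grid_rows"]),
        grid_cols=int(meta["grid_cols"]),
        seed=int(meta["seed"]),
    )
    try:
        return ArrayLayout(grid=grid, spots=spots, seed=int(meta["seed"]))
    except ValueError as exc:
        raise ValueError(f"invalid layout in {path}: {exc}") from exc
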