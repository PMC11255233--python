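"""Synthetic fluorescence-scan generator with known ground truth.

The screen's readout spans orders of magnitude and is plotted on a log
scale, so the latent per-peptide adhesion ``a_p`` is modelled log-normally
on an intensity scale, with planted repulsive peptides at exactly 0 and
planted adhesive peptides above every unplanted draw. Two observation
routes are provided:

* a spot-level intensity table ``I_s = b + a_p * eps_s`` with multiplicative
  log-normal replicate noise ``eps_s`` (the model the analysis assumes), and
* a rendered 16-bit scan image in which each spot receives a Poisson number
  of fluorescent cell disks proportional to ``a_p``, on top of additive
  background and Gaussian shot noise.

Blank spots carry zero adhesion and define the background floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .array_layout import ArrayLayout, GridSpec, build_layout
from .constants import AMINO_ACIDS, BLANK_ID
from .library_design import PeptideEntry, ProteinRecord


@dataclass
class AdhesionModel:
    """Latent ground-truth adhesion for every library peptide (scanner units)."""

    a: dict[str, float]
    planted_repulsive: frozenset[str] = frozenset()
    planted_adhesive: frozenset[str] = frozenset()
    median_intensity: float = 3000.0
    sigma_base: float = 1.0
    sigma_rep: float = 0.1
    background: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_repulsive & self.planted_adhesive:
            raise ValueError("planted repulsive and adhesive sets must be disjoint")
        for pid, value in self.a.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"latent adhesion for {pid!r} must be finite and >= 0")


def assign_latent_adhesion(
    library: Sequence[PeptideEntry],
    planted_repulsive: Iterable[str] = (),
    planted_adhesive: Iterable[str] = (),
    median_intensity: float = 3000.0,
    sigma_base: float = 1.0,
    sigma_rep: float = 0.1,
    background: float = 300.0,
    adhesive_margin: float = 4.0,
    seed: int = 0,
) -> AdhesionModel:
    """Draw latent adhesion values for a library.

    Unplanted peptides draw from a log-normal with median *median_intensity*
    and log-sd *sigma_base*; planted repulsive peptides (and blanks) get
    exactly 0; planted adhesive peptides get *adhesive_margin* times the
    maximum unplanted draw, so they top the distribution by construction.
    """
    repulsive = frozenset(planted_repulsive)
    adhesive = frozenset(planted_adhesive)
    ids = {e.peptide_id for e in library}
    unknown = (repulsive | adhesive) - ids
    if unknown:
        raise ValueError(f"planted ids not in library: {sorted(unknown)[:10]}")
    rng = np.random.default_rng(seed)
    mu = math.log(median_intensity)
    a: dict[str, float] = {}
    unplanted_max = 0.0
    for e in library:
        if e.group == "blank" or e.peptide_id in repulsive or e.peptide_id in adhesive:
            continue
        value = float(rng.lognormal(mean=mu, sigma=sigma_base))
        a[e.peptide_id] = value
        unplanted_max = max(unplanted_max, value)
    if unplanted_max == 0.0:
        unplanted_max = median_intensity
    for e in library:
        if e.group == "blank" or e.peptide_id in repulsive:
            a[e.peptide_id] = 0.0
        elif e.peptide_id in adhesive:
            a[e.peptide_id] = adhesive_margin * unplanted_max
    return AdhesionModel(
        a=a,
        planted_repulsive=repulsive,
        planted_adhesive=adhesive,
        median_intensity=median_intensity,
        sigma_base=sigma_base,
        sigma_rep=sigma_rep,
        background=background,
        seed=seed,
    )


def simulate_intensity_table(
    layout: ArrayLayout, adhesion: AdhesionModel, seed: int | None = None
) -> pd.DataFrame:
    """Spot-level intensities ``I_s = b + a_p * eps_s``.

    Replicate noise ``eps_s`` is log-normal(0, sigma_rep), independent across
    spots, and applies to the adhesion term only, so zero-adhesion spots read
    exactly the background. Blank filler spots have zero adhesion.
    """
    seed = adhesion.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    a_values = np.empty(len(layout.spots))
    for i, s in enumerate(layout.spots):
        if s.peptide_id == BLANK_ID:
            a_values[i] = 0.0
        elif s.peptide_id in adhesion.a:
            a_values[i] = adhesion.a[s.peptide_id]
        else:
            raise ValueError(f"no latent adhesion for layout peptide {s.peptide_id!r}")
    if adhesion.sigma_rep > 0:
        eps = rng.lognormal(mean=0.0, sigma=adhesion.sigma_rep, size=len(a_values))
    else:
        eps = np.ones_like(a_values)
    intensity = adhesion.background + a_values * eps
    return pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in layout.spots],
            "row": [s.row for s in layout.spots],
            "col": [s.col for s in layout.spots],
            "peptide_id": [s.peptide_id for s in layout.spots],
            "intensity": intensity,
        }
    )


def write_intensity_table(
    table: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a GPR-dialect spot-intensity TSV (comment header + grid rows)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("#pepscreen-gpr\tversion=1\n")
        table.to_csv(fh, sep="\t", index=False)


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class ScanImage:
    """A 16-bit grayscale scan with its physical pixel scale (µm per pixel).

    The origin convention is upper-left, row-major, matching the layout's
    (row, col) indexing.
    """

    data: np.ndarray
    um_per_pixel: float

    def __post_init__(self) -> None:
        if self.data.dtype != np.uint16:
            raise ValueError("scan images are 16-bit (uint16)")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")


@dataclass
class RenderParams:
    """Parameters of the synthetic confocal scan.

    cells_per_intensity converts latent adhesion (scanner units) into the
    Poisson rate of attached fluorescent cells per spot; cell_brightness is
    the additive per-pixel contribution of one cell disk. Defaults put the
    median peptide near full (stacked) cell coverage so the median spot
    pixel tracks the latent adhesion.
    """

    um_per_pixel: float = 2.0
    cells_per_intensity: float = 0.35
    cell_radius_um: float = 7.0
    cell_brightness: float = 250.0
    noise_sd: float = 20.0
    lawn_cells_per_mm2: float = 0.0
    max_bytes: int = 512 * 1024 * 1024
    island_peptides: frozenset[str] = frozenset()
    island_keep_fraction: float = 0.5


def _spot_pixels(grid: GridSpec, um_per_pixel: float) -> int:
    edge_px = grid.spot_edge_um / um_per_pixel
    if abs(edge_px - round(edge_px)) > 1e-9 or round(edge_px) < 1:
        raise ValueError(
            f"spot edge ({grid.spot_edge_um} um) must be an integer number of "
            f"image pixels at {um_per_pixel} um/pixel"
        )
    return int(round(edge_px))


def _disk_offsets(radius_um: float, um_per_pixel: float) -> np.ndarray:
    r_px = radius_um / um_per_pixel
    span = int(math.floor(r_px))
    offs = [
        (dy, dx)
        for dy in range(-span, span + 1)
        for dx in range(-span, span + 1)
        if dy * dy + dx * dx <= r_px * r_px
    ]
    if not offs:
        offs = [(0, 0)]
    return np.asarray(offs, dtype=np.int64)


def render_scan_image(
    layout: ArrayLayout,
    adhesion: AdhesionModel,
    params: RenderParams | None = None,
    seed: int | None = None,
) -> ScanImage:
    """Render the layout as a synthetic 16-bit fluorescence scan.

    Each spot receives ``Poisson(cells_per_intensity * a_p)`` cell disks at
    uniform positions inside its footprint; disk contributions accumulate
    additively (stacked cells brighten the pixel). An optional off-spot
    "lawn" scatters cells over the whole image. Background and Gaussian
    shot noise are added last, then the image is clipped to [0, 65535].
    """
    params = params or RenderParams()
    if params.um_per_pixel > layout.grid.s_pixel_um:
        raise ValueError("um_per_pixel must not exceed the s-pixel edge length")
    spot_px = _spot_pixels(layout.grid, params.um_per_pixel)
    height = layout.grid.grid_rows * spot_px
    width = layout.grid.grid_cols * spot_px
    if height * width * 8 > params.max_bytes:
        raise ValueError(
            f"rendered image ({height} x {width}) exceeds the memory budget of "
            f"{params.max_bytes} bytes"
        )
    seed = adhesion.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width), dtype=np.float64)

    rows = np.array([s.row for s in layout.spots])
    cols = np.array([s.col for s in layout.spots])
    a = np.array(
        [0.0 if s.peptide_id == BLANK_ID else adhesion.a[s.peptide_id] for s in layout.spots]
    )
    counts = rng.poisson(params.cells_per_intensity * a)

    # per-spot sub-rectangle for island (partial-fill) spots, full spot otherwise
    frac = math.sqrt(params.island_keep_fraction)
    is_island = np.array(
        [s.peptide_id in params.island_peptides for s in layout.spots], dtype=bool
    )
    x_lo = np.zeros(len(layout.spots))
    y_lo = np.zeros(len(layout.spots))
    x_span = np.full(len(layout.spots), float(spot_px))
    y_span = np.full(len(layout.spots), float(spot_px))
    if is_island.any():
        n_isl = int(is_island.sum())
        span = frac * spot_px
        x_lo[is_island] = rng.uniform(0, spot_px - span, size=n_isl)
        y_lo[is_island] = rng.uniform(0, spot_px - span, size=n_isl)
        x_span[is_island] = span
        y_span[is_island] = span

    rep = np.repeat(np.arange(len(layout.spots)), counts)
    n_cells = len(rep)
    if n_cells:
        u = rng.random(n_cells)
        v = rng.random(n_cells)
        cx = cols[rep] * spot_px + x_lo[rep] + u * x_span[rep]
        cy = rows[rep] * spot_px + y_lo[rep] + v * y_span[rep]
        _paint_disks(img, cx, cy, params)

    if params.lawn_cells_per_mm2 > 0:
        area_mm2 = (height * width) * (params.um_per_pixel / 1000.0) ** 2
        n_lawn = rng.poisson(params.lawn_cells_per_mm2 * area_mm2)
        if n_lawn:
            cx = rng.uniform(0, width, size=n_lawn)
            cy = rng.uniform(0, height, size=n_lawn)
            _paint_disks(img, cx, cy, params)

    img += adhesion.background
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0, 65535, out=img)
    return ScanImage(data=img.astype(np.uint16), um_per_pixel=params.um_per_pixel)


def _paint_disks(img: np.ndarray, cx: np.ndarray, cy: np.ndarray, params: RenderParams) -> None:
    height, width = img.shape
    px = np.floor(cx).astype(np.int64)
    py = np.floor(cy).astype(np.int64)
    for dy, dx in _disk_offsets(params.cell_radius_um, params.um_per_pixel):
        yy = py + dy
        xx = px + dx
        ok = (yy >= 0) & (yy < height) & (xx >= 0) & (xx < width)
        np.add.at(img, (yy[ok], xx[ok]), params.cell_brightness)


def write_scan_image(image: ScanImage, path: str | Path, description: str | None = None) -> None:
    tifffile.imwrite(
        str(path),
        image.data,
        resolution=(10_000.0 / image.um_per_pixel, 10_000.0 / image.um_per_pixel),
        metadata=None,
        description=description or f"pepscreen synthetic scan; um_per_pixel={image.um_per_pixel}",
    )


def read_scan_image(path: str | Path, um_per_pixel: float) -> ScanImage:
    data = tifffile.imread(str(path))
    return ScanImage(data=np.asarray(data, dtype=np.uint16), um_per_pixel=um_per_pixel)


# ---------------------------------------------------------------------------
# Synthetic inputs: random proteins / peptides and a ready-made planted screen
# ---------------------------------------------------------------------------


def random_proteins(
    lengths: Sequence[int] = (314, 266, 233), seed: int = 0, id_prefix: str = "SYN"
) -> list[ProteinRecord]:
    """Uniform-composition random proteins of the given lengths (synthetic
    stand-ins for the screen's source proteins)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    return [
        ProteinRecord(
            id=f"{id_prefix}{i + 1}",
            sequence="".join(rng.choice(alphabet, size=int(length))),
        )
        for i, length in enumerate(lengths)
    ]


def random_peptides(n: int, length: int = 15, seed: int = 0) -> list[str]:
    """n unique uniform random peptides of a fixed length."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(alphabet, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def make_synthetic_screen(
    n_peptides: int = 5000,
    n_repulsive: int = 50,
    n_adhesive: int = 10,
    replicates: int = 3,
    peptide_length: int = 15,
    grid: GridSpec | None = None,
    seed: int = 0,
    **model_kwargs,
) -> tuple[list[PeptideEntry], ArrayLayout, AdhesionModel]:
    """A planted-ground-truth screen: random library, random layout, latent model.

    The planted repulsive/adhesive peptides are chosen uniformly (disjointly)
    from the library. The grid is auto-sized to leave ~3% blank fill unless
    one is supplied.
    """
    root = np.random.SeedSequence(seed)
    s_lib, s_plant, s_layout, s_model = (
        int(s.generate_state(1)[0] % 2**31) for s in root.spawn(4)
    )
    library = [
        PeptideEntry(peptide_id=f"PEP_{i + 1:05d}", sequence=seq, group="random", replicates=replicates)
        for i, seq in enumerate(random_peptides(n_peptides, peptide_length, seed=s_lib))
    ]
    rng = np.random.default_rng(s_plant)
    chosen = rng.choice(len(library), size=n_repulsive + n_adhesive, replace=False)
    planted_repulsive = frozenset(library[i].peptide_id for i in chosen[:n_repulsive])
    planted_adhesive = frozenset(library[i].peptide_id for i in chosen[n_repulsive:])
    if grid is None:
        total = sum(e.replicates for e in library)
        side = math.ceil(math.sqrt(total / 0.97))
        grid = GridSpec(grid_rows=side, grid_cols=side, seed=s_layout)
    layout = build_layout(library, grid, seed=s_layout)
    adhesion = assign_latent_adhesion(
        library,
        planted_repulsive=planted_repulsive,
        planted_adhesive=planted_adhesive,
        seed=s_model,
        **model_kwargs,
    )
    return library, layout, adhesion
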