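"""Time-dependent suitability landscapes.

A landscape is a stack of gridded habitat-suitability layers (values in
[0, 1]), each valid over a contiguous interval of years BP.  The landscape
plays three roles in the simulation:

* it defines the potential ``V(x, t) = -w_env * s(x, t)`` whose negative
  gradient is the environmental drift of camp movement (attractive areas
  are potential minima);
* an optional friction layer scales the Brownian noise, with friction 1
  marking impassable terrain;
* integrated suitability within the foraging radius sets the local
  carrying capacity ``K_t(x)`` (linear in suitability).

Grids are planar, in km, with array row/column 0 at the lower-left
corner; cell values are located at cell centres.  Rasters are read and
written as ESRI ASCII grids (plain text), one file per time slice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class LandscapeFormatError(ValueError):
    """Raster grids are inconsistent or contain out-of-range values."""


class TimeIndexError(ValueError):
    """Slice validity intervals have gaps, overlaps or bad ordering."""


class TimeOutsideHorizonError(ValueError):
    """Queried time is not covered by any landscape slice."""


@dataclass
class LandscapeParams:
    """Scaling constants linking suitability to drift, noise and capacity.

    Parameters
    ----------
    w_env : float
        Dimensionless weight of the environmental potential,
        ``V = -w_env * s``.
    kappa : float
        Carrying-capacity coefficient, people per km^2 of fully suitable
        land.  The default (0.25, within the 0.1-0.3 people/km^2 bracket
        reported for Central African foragers) lets a fully suitable
        foraging disc of radius 20 km sustain ~315 people, i.e. about
        five camps at the fission threshold — enough local headroom for
        a persistent fission-fusion system.
    sigma0 : float
        Base noise scale of the Brownian motion, km / month^(1/2).
    barrier_sigma_floor : float
        Minimum sigma multiplier in passable terrain (friction < 1).
    """

    w_env: float = 1.0
    kappa: float = 0.25
    sigma0: float = 0.4
    barrier_sigma_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.w_env <= 0 or self.kappa <= 0 or self.sigma0 < 0:
            raise ValueError("w_env and kappa must be positive, sigma0 >= 0")


@dataclass
class BarrierSpec:
    """A straight impassable strip, optionally pierced by a corridor gap.

    ``orientation`` is ``"vertical"`` (strip of constant x) or
    ``"horizontal"``.  ``position_km`` is the strip centre along the
    perpendicular axis; ``gap_center_km``/``gap_width_km`` cut a passable
    corridor along the strip.
    """

    orientation: str = "vertical"
    position_km: float = 0.0
    width_km: float = 10.0
    gap_center_km: float | None = None
    gap_width_km: float = 0.0


@dataclass
class SuitabilityLandscape:
    origin: tuple[float, float]
    cell_size: float
    suitability: np.ndarray          # (n_slices, ny, nx), values in [0, 1]
    slice_times: np.ndarray          # (n_slices, 2): [t_start_bp, t_end_bp)
    friction: np.ndarray | None = None
    domain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.suitability = np.asarray(self.suitability, dtype=float)
        if self.suitability.ndim != 3:
            raise LandscapeFormatError("suitability must be (n_slices, ny, nx)")
        if np.any(self.suitability < 0) or np.any(self.suitability > 1):
            raise LandscapeFormatError("suitability values must lie in [0, 1]")
        self.slice_times = np.asarray(self.slice_times, dtype=float)
        if self.slice_times.shape != (self.suitability.shape[0], 2):
            raise TimeIndexError("slice_times must be (n_slices, 2)")
        starts, ends = self.slice_times[:, 0], self.slice_times[:, 1]
        if np.any(starts <= ends):
            raise TimeIndexError("each interval needs t_start_bp > t_end_bp")
        if np.any(~np.isclose(ends[:-1], starts[1:])):
            raise TimeIndexError("slice intervals must be contiguous (no gap/overlap)")
        if self.friction is not None:
            self.friction = np.asarray(self.friction, dtype=float)
            if self.friction.shape != self.suitability.shape[1:]:
                raise LandscapeFormatError("friction shape must match suitability layers")
        if self.domain_mask is None:
            self.domain_mask = np.ones(self.suitability.shape[1:], dtype=bool)
        else:
            self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
            if self.domain_mask.shape != self.suitability.shape[1:]:
                raise LandscapeFormatError("domain_mask shape must match suitability layers")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.suitability.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid, km."""
        ny, nx = self.shape
        x0, y0 = self.origin
        return x0, x0 + nx * self.cell_size, y0, y0 + ny * self.cell_size

    @property
    def t_start_bp(self) -> float:
        return float(self.slice_times[0, 0])

    @property
    def t_end_bp(self) -> float:
        return float(self.slice_times[-1, 1])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def slice_index(self, t_bp: float) -> int:
        starts, ends = self.slice_times[:, 0], self.slice_times[:, 1]
        hit = np.nonzero((t_bp <= starts) & (t_bp > ends))[0]
        if hit.size:
            return int(hit[0])
        if np.isclose(t_bp, ends[-1]):  # closed at the final endpoint
            return len(starts) - 1
        raise TimeOutsideHorizonError(
            f"t = {t_bp} BP outside covered horizon [{starts[0]}, {ends[-1]}]"
        )

    def masked_slice(self, k: int) -> np.ndarray:
        return self.suitability[k] * self.domain_mask

    def cell_of(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the cell containing each position, plus inside flag."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x0, y0 = self.origin
        ny, nx = self.shape
        col = np.floor((x[:, 0] - x0) / self.cell_size).astype(int)
        row = np.floor((x[:, 1] - y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        return row.clip(0, ny - 1), col.clip(0, nx - 1), inside


@dataclass
class TimeMap:
    """Mapping between the internal clock (months since start) and years BP."""

    start_bp: float

    def to_bp(self, t_months: float | np.ndarray):
        return self.start_bp - np.asarray(t_months, dtype=float) / 12.0

    def to_months(self, t_bp: float | np.ndarray):
        return (self.start_bp - np.asarray(t_bp, dtype=float)) * 12.0


# ---------------------------------------------------------------------------
# interpolation primitives
# ---------------------------------------------------------------------------

def _bilinear(grid: np.ndarray, origin: tuple[float, float], cell_size: float,
              x: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of cell-centre values; 0 outside the grid."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    ny, nx = grid.shape
    x0, y0 = origin
    inside = (
        (x[:, 0] >= x0) & (x[:, 0] <= x0 + nx * cell_size)
        & (x[:, 1] >= y0) & (x[:, 1] <= y0 + ny * cell_size)
    )
    u = np.clip((x[:, 0] - x0) / cell_size - 0.5, 0.0, nx - 1.0)
    v = np.clip((x[:, 1] - y0) / cell_size - 0.5, 0.0, ny - 1.0)
    i0 = np.clip(np.floor(u).astype(int), 0, max(nx - 2, 0))
    j0 = np.clip(np.floor(v).astype(int), 0, max(ny - 2, 0))
    i1 = np.minimum(i0 + 1, nx - 1)
    j1 = np.minimum(j0 + 1, ny - 1)
    fu = u - i0
    fv = v - j0
    val = (
        grid[j0, i0] * (1 - fu) * (1 - fv)
        + grid[j0, i1] * fu * (1 - fv)
        + grid[j1, i0] * (1 - fu) * fv
        + grid[j1, i1] * fu * fv
    )
    return np.where(inside, val, 0.0)


def suitability_at(L: SuitabilityLandscape, x, t_bp: float) -> np.ndarray | float:
    """Suitability at position(s) ``x`` (km) and time ``t_bp`` (years BP).

    Bilinear interpolation of the active slice; 0 outside the domain mask
    or grid.  Piecewise constant in time within a slice.
    """
    k = L.slice_index(t_bp)
    out = _bilinear(L.masked_slice(k), L.origin, L.cell_size, x)
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def potential_gradient(L: SuitabilityLandscape, params: LandscapeParams,
                       x, t_bp: float) -> np.ndarray:
    """Gradient of the potential ``V = -w_env * s`` by central differences.

    The drift of the mobility SDE is ``-grad V``, which points uphill in
    suitability.  Step size is ``cell_size / 2`` on the bilinear
    interpolant.
    """
    k = L.slice_index(t_bp)
    grid = L.masked_slice(k)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    n = X.shape[0]
    h = L.cell_size / 2.0
    offsets = np.array([[h, 0.0], [-h, 0.0], [0.0, h], [0.0, -h]])
    probe = (X[None, :, :] + offsets[:, None, :]).reshape(4 * n, 2)
    s = _bilinear(grid, L.origin, L.cell_size, probe).reshape(4, n)
    grad_s = np.stack([(s[0] - s[1]) / (2 * h), (s[2] - s[3]) / (2 * h)], axis=1)
    grad_v = -params.w_env * grad_s
    return grad_v[0] if np.asarray(x).ndim == 1 else grad_v


def sigma_at(L: SuitabilityLandscape, params: LandscapeParams, x) -> np.ndarray | float:
    """Friction-scaled noise amplitude sigma(x), km / month^(1/2).

    ``sigma0 * (1 - friction)``, floored at ``barrier_sigma_floor * sigma0``
    in passable cells and exactly 0 where friction = 1 or outside the
    domain.  Friction is looked up at the containing cell (barriers must
    be sharp).
    """
    X = np.asarray(x, dtype=float)
    row, col, inside = L.cell_of(X)
    n = row.shape[0]
    if L.friction is None:
        fric = np.zeros(n)
    else:
        fric = L.friction[row, col]
    ok = inside & L.domain_mask[row, col]
    sig = params.sigma0 * (1.0 - fric)
    floor = params.barrier_sigma_floor * params.sigma0
    passable = fric < 1.0
    sig = np.where(passable, np.maximum(sig, floor), 0.0)
    sig = np.where(ok, sig, 0.0)
    return float(sig[0]) if X.ndim == 1 else sig


def passable_at(L: SuitabilityLandscape, x) -> np.ndarray | bool:
    """True where a camp may stand: inside the domain, friction < 1."""
    X = np.asarray(x, dtype=float)
    row, col, inside = L.cell_of(X)
    ok = inside & L.domain_mask[row, col]
    if L.friction is not None:
        ok &= L.friction[row, col] < 1.0
    return bool(ok[0]) if X.ndim == 1 else ok


# ---------------------------------------------------------------------------
# carrying capacity
# ---------------------------------------------------------------------------

def disc_kernel(r: float, cell_size: float) -> np.ndarray:
    """Boolean stencil of cell-centre offsets within distance r."""
    m = int(np.floor(r / cell_size))
    off = np.arange(-m, m + 1) * cell_size
    dx, dy = np.meshgrid(off, off)
    return (dx**2 + dy**2) <= r**2


def carrying_capacity(L: SuitabilityLandscape, params: LandscapeParams,
                      x, t_bp: float, r1: float) -> np.ndarray | float:
    """Local carrying capacity K_t(x), people.

    ``K = kappa * sum_{cells within r1 of x} s(cell, t) * cell_area`` —
    the people sustainable by foraging within the short-range radius,
    linear in suitability.
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    k = L.slice_index(t_bp)
    grid = L.masked_slice(k)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    xs, ys = L.cell_centers()
    area = L.cell_size**2
    out = np.empty(X.shape[0])
    for i, (px, py) in enumerate(X):
        d2 = (xs[None, :] - px) ** 2 + (ys[:, None] - py) ** 2
        out[i] = params.kappa * area * grid[d2 <= r1**2].sum()
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def carrying_capacity_grid(L: SuitabilityLandscape, params: LandscapeParams,
                           slice_index: int, r1: float) -> np.ndarray:
    """K at every cell centre, by convolving the slice with a disc stencil.

    Matches :func:`carrying_capacity` exactly at cell centres; the engine
    caches one such grid per landscape slice.
    """
    kern = disc_kernel(r1, L.cell_size).astype(float)
    s = ndimage.convolve(L.masked_slice(slice_index), kern,
                         mode="constant", cval=0.0)
    return params.kappa * L.cell_size**2 * s


# ---------------------------------------------------------------------------
# initial placement
# ---------------------------------------------------------------------------

def sample_equilibrium_positions(L: SuitabilityLandscape, t_bp: float, n: int,
                                 seed: np.random.Generator | int) -> np.ndarray:
    """Draw camp positions from the suitability-weighted equilibrium.

    A cell is chosen with probability proportional to its suitability and
    the position is uniform within the cell.  ``seed`` may be an integer
    or an already-constructed generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(int(seed))
    k = L.slice_index(t_bp)
    grid = L.masked_slice(k)
    w = grid.ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("landscape has zero total suitability at this time")
    idx = rng.choice(w.size, size=n, p=w / total)
    ny, nx = L.shape
    row, col = np.divmod(idx, nx)
    x0, y0 = L.origin
    jitter = rng.random((n, 2))
    pos = np.column_stack([
        x0 + (col + jitter[:, 0]) * L.cell_size,
        y0 + (row + jitter[:, 1]) * L.cell_size,
    ])
    return pos


# ---------------------------------------------------------------------------
# synthetic landscapes
# ---------------------------------------------------------------------------

def _apply_barrier(suit: np.ndarray, friction: np.ndarray,
                   barrier: BarrierSpec, origin: tuple[float, float],
                   cell_size: float) -> None:
    ny, nx = friction.shape
    x0, y0 = origin
    xs = x0 + (np.arange(nx) + 0.5) * cell_size
    ys = y0 + (np.arange(ny) + 0.5) * cell_size
    if barrier.orientation == "vertical":
        across, along = xs[None, :], ys[:, None]
    elif barrier.orientation == "horizontal":
        across, along = ys[:, None], xs[None, :]
    else:
        raise ValueError(f"unknown barrier orientation {barrier.orientation!r}")
    in_strip = np.abs(across - barrier.position_km) <= barrier.width_km / 2.0
    in_strip = np.broadcast_to(in_strip, friction.shape).copy()
    if barrier.gap_center_km is not None and barrier.gap_width_km > 0:
        in_gap = np.abs(along - barrier.gap_center_km) <= barrier.gap_width_km / 2.0
        in_strip &= ~np.broadcast_to(in_gap, friction.shape)
    friction[in_strip] = 1.0
    suit[:, in_strip] = 0.0


def generate_synthetic_landscape(shape: tuple[int, int], cell_size: float,
                                 n_slices: int, smoothness: float,
                                 barrier: BarrierSpec | None = None,
                                 seed: int | np.random.Generator = 0,
                                 origin: tuple[float, float] = (0.0, 0.0),
                                 t_start_bp: float = 120_000.0,
                                 slice_years: float = 2_000.0,
                                 contrast: float = 2.0,
                                 slice_correlation: float = 0.7,
                                 richness_amplitude: float = 0.5,
                                 mean_logit: float = 0.0
                                 ) -> SuitabilityLandscape:
    """Synthesize a smooth, patchy suitability field, piecewise in time.

    Each slice is a Gaussian random field (white noise smoothed to the
    requested correlation length ``smoothness`` in km) squashed into
    (0, 1) with a logistic of gain ``contrast``.  Successive slices share
    an AR(1) latent field with coefficient ``slice_correlation`` and an
    AR(1) landscape-wide richness offset of standard deviation
    ``richness_amplitude`` (logit units), emulating climate-driven
    suitability series: abrupt changes at slice boundaries, but gradual
    reorganization and good/bad epochs rather than independent redraws.
    ``mean_logit`` shifts the field's overall richness: 0 gives mean
    suitability ~0.5; negative values give a sparse habitat-island
    regime where suitable patches sit in a low-suitability matrix.
    Set ``slice_correlation = 0`` for independent slices.  An optional
    barrier strip gets friction 1 and suitability 0.  Deterministic
    given ``seed``.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0 or n_slices <= 0:
        raise ValueError("shape and n_slices must be positive")
    if not 0 <= slice_correlation < 1:
        raise ValueError("slice_correlation must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_cells = max(smoothness / cell_size, 1e-6)

    def grf():
        z = ndimage.gaussian_filter(rng.standard_normal((ny, nx)),
                                    sigma_cells, mode="reflect")
        sd = z.std()
        return z / sd if sd > 0 else z

    rho = slice_correlation
    layers = np.empty((n_slices, ny, nx))
    z = grf()
    mu = rng.normal(0.0, richness_amplitude) if richness_amplitude > 0 else 0.0
    for k in range(n_slices):
        if k:
            z = rho * z + np.sqrt(1 - rho**2) * grf()
            if richness_amplitude > 0:
                mu = rho * mu + np.sqrt(1 - rho**2) * rng.normal(
                    0.0, richness_amplitude)
        layers[k] = 1.0 / (1.0 + np.exp(-(contrast * z + mu + mean_logit)))
    friction = None
    if barrier is not None:
        friction = np.zeros((ny, nx))
        _apply_barrier(layers, friction, barrier, origin, cell_size)
    starts = t_start_bp - slice_years * np.arange(n_slices)
    slice_times = np.column_stack([starts, starts - slice_years])
    return SuitabilityLandscape(origin=origin, cell_size=cell_size,
                                suitability=layers, slice_times=slice_times,
                                friction=friction)


def generate_patch_landscape(shape: tuple[int, int], cell_size: float,
                             centers: list[tuple[float, float]],
                             patch_sd_km: float,
                             n_slices: int = 1,
                             total_suitability: float | None = None,
                             peak: float = 0.9,
                             origin: tuple[float, float] = (0.0, 0.0),
                             t_start_bp: float = 120_000.0,
                             slice_years: float = 2_000.0,
                             barrier: BarrierSpec | None = None) -> SuitabilityLandscape:
    """Landscape of Gaussian suitability patches, constant across slices.

    Useful for controlled fragmentation experiments: with
    ``total_suitability`` fixed, a one-patch and a two-patch landscape
    support the same overall population but different spatial structure.
    """
    ny, nx = shape
    x0, y0 = origin
    xs = x0 + (np.arange(nx) + 0.5) * cell_size
    ys = y0 + (np.arange(ny) + 0.5) * cell_size
    field = np.zeros((ny, nx))
    for cx, cy in centers:
        field += np.exp(-((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2)
                        / (2 * patch_sd_km**2))
    field *= peak / field.max()
    if total_suitability is not None:
        field *= total_suitability / field.sum()
        if field.max() > 1.0:
            raise ValueError("requested total_suitability exceeds the [0,1] bound")
    layers = np.repeat(field[None], n_slices, axis=0)
    friction = None
    if barrier is not None:
        friction = np.zeros((ny, nx))
        _apply_barrier(layers, friction, barrier, origin, cell_size)
    starts = t_start_bp - slice_years * np.arange(n_slices)
    slice_times = np.column_stack([starts, starts - slice_years])
    return SuitabilityLandscape(origin=origin, cell_size=cell_size,
                                suitability=layers, slice_times=slice_times,
                                friction=friction)


def close_corridor(L: SuitabilityLandscape, barrier: BarrierSpec) -> SuitabilityLandscape:
    """Return a copy of ``L`` with the barrier's gap sealed (friction 1)."""
    sealed = BarrierSpec(orientation=barrier.orientation,
                         position_km=barrier.position_km,
                         width_km=barrier.width_km,
                         gap_center_km=None, gap_width_km=0.0)
    suit = L.suitability.copy()
    friction = np.zeros(L.shape) if L.friction is None else L.friction.copy()
    _apply_barrier(suit, friction, sealed, L.origin, L.cell_size)
    return SuitabilityLandscape(origin=L.origin, cell_size=L.cell_size,
                                suitability=suit, slice_times=L.slice_times.copy(),
                                friction=friction, domain_mask=L.domain_mask.copy())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str) -> tuple[np.ndarray, tuple[float, float], float, np.ndarray]:
    """Read an ESRI ASCII grid; returns (values, origin, cell_size, mask).

    Row 0 of the returned array is the *southern* row (we store grids
    bottom-up; the file format is top-down).  NODATA cells are masked and
    set to 0.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise LandscapeFormatError(f"{path}: missing header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.loadtxt(path, skiprows=i)
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise LandscapeFormatError(
            f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    data = data[::-1]  # file is north-to-south; store south row first
    nodata = header.get("nodata_value")
    mask = np.ones_like(data, dtype=bool)
    if nodata is not None:
        mask = data != nodata
        data = np.where(mask, data, 0.0)
    origin = (header["xllcorner"], header["yllcorner"])
    return data, origin, header["cellsize"], mask


def write_ascii_grid(path: str, values: np.ndarray, origin: tuple[float, float],
                     cell_size: float, mask: np.ndarray | None = None,
                     nodata: float = -9999.0) -> None:
    """Write a bottom-up grid array as an ESRI ASCII raster."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = nodata
    ny, nx = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.1f}\n")
        np.savetxt(fh, out[::-1], fmt="%.6f")


def load_landscape(raster_paths: list[str],
                   time_index: "str | pd.DataFrame",
                   friction_path: str | None = None) -> SuitabilityLandscape:
    """Assemble a landscape from per-slice ASCII rasters and a time index.

    ``time_index`` is a CSV path or DataFrame with columns
    ``slice_file, t_start_bp, t_end_bp``; slices are ordered by
    descending ``t_start_bp`` and must tile the horizon without gaps.
    """
    if isinstance(time_index, (str, os.PathLike)):
        time_index = pd.read_csv(time_index)
    required = {"slice_file", "t_start_bp", "t_end_bp"}
    if not required.issubset(time_index.columns):
        raise TimeIndexError(f"time index needs columns {sorted(required)}")
    by_name = {os.path.basename(p): p for p in raster_paths}
    order = time_index.sort_values("t_start_bp", ascending=False)
    layers, times = [], []
    origin = cell_size = mask = None
    for _, rec in order.iterrows():
        name = os.path.basename(str(rec["slice_file"]))
        if name not in by_name:
            raise LandscapeFormatError(f"time index references unknown raster {name!r}")
        vals, org, cs, m = read_ascii_grid(by_name[name])
        if origin is None:
            origin, cell_size, mask = org, cs, m
        else:
            if vals.shape != layers[0].shape or not np.allclose(org, origin) \
                    or not np.isclose(cs, cell_size):
                raise LandscapeFormatError("rasters disagree in shape/origin/cell size")
            mask = mask & m
        if np.any((vals < 0) | (vals > 1)):
            raise LandscapeFormatError(f"{name}: suitability outside [0, 1]")
        layers.append(vals)
        times.append((float(rec["t_start_bp"]), float(rec["t_end_bp"])))
    friction = None
    if friction_path is not None:
        friction, forg, fcs, _ = read_ascii_grid(friction_path)
        if friction.shape != layers[0].shape or not np.allclose(forg, origin) \
                or not np.isclose(fcs, cell_size):
            raise LandscapeFormatError("friction raster disagrees with suitability grids")
    return SuitabilityLandscape(origin=origin, cell_size=cell_size,
                                suitability=np.stack(layers),
                                slice_times=np.array(times),
                                friction=friction, domain_mask=mask)


def save_landscape(L: SuitabilityLandscape, directory: str,
                   prefix: str = "slice") -> str:
    """Write each slice as an ASCII raster plus a time-index CSV.

    Returns the path of the time-index CSV; round-trips through
    :func:`load_landscape`.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    for k in range(L.suitability.shape[0]):
        name = f"{prefix}_{k:03d}.asc"
        write_ascii_grid(os.path.join(directory, name), L.suitability[k],
                         L.origin, L.cell_size, mask=L.domain_mask)
        rows.append({"slice_file": name,
                     "t_start_bp": L.slice_times[k, 0],
                     "t_end_bp": L.slice_times[k, 1]})
    if L.friction is not None:
        write_ascii_grid(os.path.join(directory, f"{prefix}_friction.asc"),
                         L.friction, L.origin, L.cell_size)
    index_path = os.path.join(directory, f"{prefix}_index.csv")
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path
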