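"""Stream morphometrics: density probability rho(r), W/L, counts, speeds.

Streams are quantified by the NC density probability function

    rho(r) = < eta(R + r) >  over all reference sites R occupied by NC,

where ``eta(R) = 1`` iff site R is occupied by a NC cell — the probability
of finding two NC cells at relative offset r, akin to a pair correlation of
cell positions. Axis profiles of rho through the origin define the
characteristic stream width W (AP axis) and length L (DV axis) as the
distance between the two loci where the profile first falls below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .params import NC, ParameterSet
from .state import NC_ROWS, PATCH, PL_ROWS

_FFT_MIN_SIZE = 4096  # below this many sites, direct summation is exact & fast


@dataclass
class DensityMap:
    """rho(r) over offsets r, with per-offset sample counts.

    ``num[r]`` is the number of NC site pairs at offset r, ``counts[r]`` the
    number of NC reference sites R with R + r inside the lattice; offsets
    falling outside the lattice are excluded from both. Index ``[off + r]``
    addresses offset r; ``off`` is the origin index.
    """

    num: np.ndarray
    counts: np.ndarray
    defined: bool = True

    @property
    def origin(self) -> tuple[int, int]:
        return ((self.num.shape[0] - 1) // 2, (self.num.shape[1] - 1) // 2)

    @property
    def rho(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.num / np.maximum(self.counts, 1),
                            np.nan)

    def profile(self, axis: int) -> np.ndarray:
        """rho section through the origin along an axis (0 = AP, 1 = DV)."""
        ox, oy = self.origin
        return self.rho[:, oy] if axis == 0 else self.rho[ox, :]

    @classmethod
    def pool(cls, maps: "list[DensityMap]") -> "DensityMap":
        """Count-weighted ensemble pooling: numerators and counts summed."""
        defined = [m for m in maps if m.defined]
        if not defined:
            return cls(np.zeros((1, 1)), np.zeros((1, 1)), defined=False)
        shape = np.max([m.num.shape for m in defined], axis=0)
        num = np.zeros(shape)
        counts = np.zeros(shape)
        for m in defined:
            sx = (shape[0] - m.num.shape[0]) // 2
            sy = (shape[1] - m.num.shape[1]) // 2
            num[sx:sx + m.num.shape[0], sy:sy + m.num.shape[1]] += m.num
            counts[sx:sx + m.num.shape[0], sy:sy + m.num.shape[1]] += m.counts
        return cls(num, counts)


def _xcorr(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """c[off + r] = sum_R a(R) b(R + r) over in-lattice pairs."""
    return signal.correlate(b, a, mode="full", method=method)


def density_probability(nc_mask: np.ndarray) -> DensityMap:
    """NC density probability function of a binary occupancy lattice.

    For each offset r, the occupancy at R + r averaged over all NC-occupied
    reference sites R (both sites inside the lattice). Returns an undefined
    sentinel map for an empty mask.
    """
    m = np.ascontiguousarray(nc_mask, dtype=np.float64)
    if m.sum() == 0:
        full = (2 * m.shape[0] - 1, 2 * m.shape[1] - 1)
        return DensityMap(np.zeros(full), np.zeros(full), defined=False)
    method = "direct" if m.size <= _FFT_MIN_SIZE else "fft"
    num = np.rint(_xcorr(m, m, method))
    counts = np.rint(_xcorr(m, np.ones_like(m), method))
    return DensityMap(num=num, counts=counts)


# ----------------------------------------------------------------------
def _crossing(profile: np.ndarray, start: int, step: int) -> float:
    """Distance from ``start`` to the first sub-0.5 locus walking by ``step``;
    the crossing is linearly interpolated between the bracketing offsets.
    NaN when the profile never falls below 0.5 on that side."""
    prev = profile[start]
    if np.isnan(prev) or prev < 0.5:
        return 0.0
    k = start + step
    dist = 1
    while 0 <= k < len(profile):
        cur = profile[k]
        if np.isnan(cur):
            return np.nan
        if cur < 0.5:
            return dist - 1 + (prev - 0.5) / (prev - cur)
        prev = cur
        k += step
        dist += 1
    return np.nan


def width_length(dmap: DensityMap) -> tuple[float, float]:
    """Characteristic stream width W and length L from rho(r) [s.u.].

    W is measured on the AP-axis profile through the origin, L on the
    DV-axis profile; each is the distance between the two loci where the
    profile first falls below 0.5. A side on which the profile never drops
    below 0.5 yields a NaN sentinel for that measure (the no-streams /
    full-band outcome), reported rather than raised.
    """
    if not dmap.defined:
        return np.nan, np.nan
    out = []
    for axis in (0, 1):
        prof = dmap.profile(axis)
        o = dmap.origin[axis]
        out.append(_crossing(prof, o, +1) + _crossing(prof, o, -1))
    return float(out[0]), float(out[1])


# ----------------------------------------------------------------------
def interface_y() -> int:
    """DV coordinate of the initial NC/placode interface."""
    return NC_ROWS * PATCH


def count_streams(nc_mask: np.ndarray, depth: float = 0.5,
                  min_gap: int = 2) -> int:
    """Number of NC streams crossing a horizontal line in the placode region.

    The line sits ``depth`` (fraction of the placodal region height) below
    the initial NC/placode interface. Connected runs of NC occupancy along
    the line are counted, merging runs separated by fewer than ``min_gap``
    medium sites. Automates the count that was done by eye on rendered
    configurations.
    """
    if not 0.0 < depth < 1.0:
        raise ValueError("depth must lie in (0, 1)")
    y = interface_y() + int(round(depth * PL_ROWS * PATCH))
    y = min(y, nc_mask.shape[1] - 1)
    line = np.asarray(nc_mask[:, y], dtype=bool)
    idx = np.flatnonzero(line)
    if idx.size == 0:
        return 0
    separations = np.diff(idx) - 1  # medium sites between occupied neighbors
    return int(1 + np.count_nonzero(separations >= min_gap))


def connected_components(nc_mask: np.ndarray) -> int:
    """8-connected component count of the NC occupancy mask."""
    _, n = ndimage.label(nc_mask, structure=np.ones((3, 3)))
    return int(n)


# ----------------------------------------------------------------------
def mean_speed(trajectories: np.ndarray, cell_types=None,
               cell_type: int = NC, window: slice | None = None) -> float:
    """Mean per-MCS centroid displacement magnitude [s.u./MCS].

    ``trajectories`` is a (T, n_cells, 2) centroid series; positions may be
    NaN while a cell does not yet exist. ``cell_types`` filters to one cell
    type; ``window`` restricts the MCS range. NaN sentinel when no steps
    qualify.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[0] < 2:
        return np.nan
    if window is not None:
        traj = traj[window]
    if cell_types is not None:
        traj = traj[:, np.asarray(cell_types) == cell_type, :]
    if traj.shape[1] == 0:
        return np.nan
    d = np.diff(traj, axis=0)
    mags = np.hypot(d[..., 0], d[..., 1])
    if np.isnan(mags).all():
        return np.nan
    return float(np.nanmean(mags))


# ----------------------------------------------------------------------
def to_physical(value: float, quantity: str,
                params: ParameterSet | None = None) -> float:
    """Convert simulation units to physical units.

    length: s.u. -> um; time: MCS -> s; speed: s.u./MCS -> um/min.
    """
    p = params or ParameterSet()
    if quantity == "length":
        return value * p.microns_per_site
    if quantity == "time":
        return value * p.seconds_per_MCS
    if quantity == "speed":
        return value * p.microns_per_site / p.seconds_per_MCS * 60.0
    raise KeyError(f"unknown quantity {quantity!r}; "
                   "expected length, time or speed")


# ----------------------------------------------------------------------
@dataclass
class StreamMetrics:
    """Summary morphometrics of one configuration / replicate."""

    W: float = np.nan              # stream width [s.u.]
    L: float = np.nan              # stream length [s.u.]
    n_streams: int | None = None
    mean_nc_speed: float = np.nan  # [s.u./MCS]
    mean_conc: dict = field(default_factory=dict)

    @property
    def aspect(self) -> float:
        return self.L / self.W if self.W and np.isfinite(self.W) else np.nan


def measure_state(state, depth: float = 0.5) -> StreamMetrics:
    """W, L and stream count of a simulation state's NC configuration."""
    mask = state.nc_mask()
    W, L = width_length(density_probability(mask))
    return StreamMetrics(
        W=W, L=L, n_streams=count_streams(mask, depth),
        mean_conc={s: state.fields.mean_over_cells(s) for s in ("A", "S", "I")},
    )
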