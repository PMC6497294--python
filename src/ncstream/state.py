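"""Lattice/cell data model and construction of the initial tissue.

The tissue starts as a block of 5x5 cell patches spanning the lattice width:
two patch rows of neural crest (NC) at the dorsal edge (low y) and thirteen
patch rows of placodes beneath them; the remaining ventral strip is medium.
Cell ids are assigned row-major at initialization; cells inserted later by
EMT get fresh ``max+1`` ids.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .fields import FieldSet
from .params import MEDIUM, NC, PL, ParameterSet

#: side of the square init patches [s.u.]
PATCH = 5
#: patch rows of each type in the initial block
NC_ROWS = 2
PL_ROWS = 13
#: footprint of an EMT-inserted cell: one cell wide, half a cell tall
EMT_PATCH_W = 5
EMT_PATCH_H = 3


class ConfigurationError(ValueError):
    """Raised when a scenario configuration cannot produce a valid tissue."""


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's registry entry."""

    id: int
    type: str                    # "NC" or "PL"
    polarity: np.ndarray         # [s.u./MCS]
    cil_active: bool
    links: frozenset
    area: int                    # lattice sites
    centroid: np.ndarray         # [s.u.]
    last_displacement: np.ndarray


@dataclass
class SimulationState:
    """Label lattice, cell registry arrays, concentration fields and clock.

    Per-cell arrays are indexed directly by cell label; slot 0 is the
    medium and stays zeroed. ``n_cells`` is the highest live label (labels
    are contiguous 1..n_cells and cells never die).
    """

    sigma: np.ndarray            # (width, height) int64, 0 = medium
    fields: FieldSet
    params: ParameterSet
    rng_seed: int
    mcs: int = 0
    n_cells: int = 0

    cell_type: np.ndarray = None   # int64[cap]; 0/1/2 = medium/NC/PL
    area: np.ndarray = None        # int64[cap]
    sum_x: np.ndarray = None       # float64[cap]; centroid = sum / area
    sum_y: np.ndarray = None
    prev_cx: np.ndarray = None     # centroid cache from the last MCS
    prev_cy: np.ndarray = None
    pol: np.ndarray = None         # float64[cap, 2] polarity vectors
    disp: np.ndarray = None        # float64[cap, 2] last-MCS displacement

    link_list: np.ndarray = None   # int64[cap, MAX_DEG], symmetric
    link_cnt: np.ndarray = None
    contact_list: np.ndarray = None
    contact_cnt: np.ndarray = None
    prev_contact_list: np.ndarray = None
    prev_contact_cnt: np.ndarray = None
    cil_list: np.ndarray = None    # partners whose contact triggered CIL
    cil_cnt: np.ndarray = None

    counters: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def capacity(self) -> int:
        return self.cell_type.shape[0]

    def ensure_capacity(self, n: int) -> None:
        """Grow the per-cell arrays so at least ``n`` labels fit."""
        cap = self.capacity
        if n < cap:
            return
        new_cap = max(n + 1, cap * 2)
        for name in ("cell_type", "area", "sum_x", "sum_y",
                     "prev_cx", "prev_cy", "link_cnt", "contact_cnt",
                     "prev_contact_cnt", "cil_cnt"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[:cap] = old
            setattr(self, name, new)
        for name in ("pol", "disp"):
            old = getattr(self, name)
            new = np.zeros((new_cap, 2), dtype=old.dtype)
            new[:cap] = old
            setattr(self, name, new)
        for name in ("link_list", "contact_list", "prev_contact_list",
                     "cil_list"):
            old = getattr(self, name)
            new = np.zeros((new_cap, old.shape[1]), dtype=old.dtype)
            new[:cap] = old
            setattr(self, name, new)

    # ------------------------------------------------------------------
    def cell(self, cid: int) -> CellRecord:
        if not 1 <= cid <= self.n_cells:
            raise KeyError(f"no cell with id {cid}")
        a = int(self.area[cid])
        centroid = np.array([self.sum_x[cid] / a, self.sum_y[cid] / a])
        links = frozenset(int(j) for j in
                          self.link_list[cid, : self.link_cnt[cid]])
        return CellRecord(
            id=cid,
            type={NC: "NC", PL: "PL"}[int(self.cell_type[cid])],
            polarity=self.pol[cid].copy(),
            cil_active=bool(self.cil_cnt[cid] > 0),
            links=links,
            area=a,
            centroid=centroid,
            last_displacement=self.disp[cid].copy(),
        )

    def cells(self):
        """Iterate CellRecords for all live cells."""
        for cid in range(1, self.n_cells + 1):
            yield self.cell(cid)

    def type_ids(self, type_index: int) -> np.ndarray:
        ids = np.arange(1, self.n_cells + 1)
        return ids[self.cell_type[1:self.n_cells + 1] == type_index]

    def nc_mask(self) -> np.ndarray:
        """Boolean lattice of NC occupancy."""
        return self.cell_type[self.sigma] == NC

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) centroid array for live cells (row i-1 = cell i)."""
        n = self.n_cells
        a = self.area[1:n + 1].astype(float)
        return np.stack([self.sum_x[1:n + 1] / a,
                         self.sum_y[1:n + 1] / a], axis=1)

    # ------------------------------------------------------------------
    def check_consistency(self) -> None:
        """Assert lattice/registry invariants (test and debug aid)."""
        n = self.n_cells
        counts = np.bincount(self.sigma.ravel(), minlength=n + 1)
        if counts.shape[0] > n + 1 and counts[n + 1:].any():
            raise AssertionError("lattice carries labels outside the registry")
        if not np.array_equal(counts[1:n + 1], self.area[1:n + 1]):
            raise AssertionError("registry areas disagree with the lattice")
        xs, ys = np.nonzero(self.sigma)
        labels = self.sigma[xs, ys]
        sx = np.bincount(labels, weights=xs, minlength=n + 1)
        sy = np.bincount(labels, weights=ys, minlength=n + 1)
        if not (np.allclose(sx[1:n + 1], self.sum_x[1:n + 1])
                and np.allclose(sy[1:n + 1], self.sum_y[1:n + 1])):
            raise AssertionError("centroid sums disagree with the lattice")
        for i in range(1, n + 1):
            for j in self.link_list[i, :self.link_cnt[i]]:
                partners = self.link_list[j, :self.link_cnt[j]]
                if i not in partners:
                    raise AssertionError(f"asymmetric link {i}-{j}")

    def state_hash(self) -> str:
        """Digest of lattice + registry, for bit-reproducibility checks."""
        h = hashlib.sha256()
        n = self.n_cells
        h.update(self.sigma.tobytes())
        h.update(np.int64(n).tobytes())
        for arr in (self.cell_type[:n + 1], self.area[:n + 1],
                    self.pol[:n + 1], self.cil_cnt[:n + 1],
                    self.link_cnt[:n + 1]):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(self.fields.conc.tobytes())
        return h.hexdigest()


# ----------------------------------------------------------------------
def state_from_lattice(sigma: np.ndarray, cell_types,
                       params: ParameterSet | None = None,
                       seed: int = 0) -> SimulationState:
    """Build a consistent SimulationState from an explicit label lattice.

    ``cell_types`` maps label -> type index (entry 0 is the medium). The
    registry (areas, centroid sums, contacts) is derived from the lattice;
    polarities, links and CIL states start empty. Used for snapshot
    re-analysis and for constructing test configurations.
    """
    sigma = np.ascontiguousarray(sigma, dtype=np.int64)
    cell_types = np.asarray(cell_types, dtype=np.int64)
    params = params or ParameterSet()
    n = int(sigma.max())
    if cell_types.shape[0] < n + 1:
        raise ValueError("cell_types must cover every label on the lattice")
    cap = max(n + 64, 256)
    w, h = sigma.shape
    state = SimulationState(
        sigma=sigma,
        fields=FieldSet.zeros(w, h, params.halo),
        params=params,
        rng_seed=int(seed),
        n_cells=n,
        cell_type=np.zeros(cap, dtype=np.int64),
        area=np.zeros(cap, dtype=np.int64),
        sum_x=np.zeros(cap), sum_y=np.zeros(cap),
        prev_cx=np.zeros(cap), prev_cy=np.zeros(cap),
        pol=np.zeros((cap, 2)), disp=np.zeros((cap, 2)),
        link_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        link_cnt=np.zeros(cap, dtype=np.int64),
        contact_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        contact_cnt=np.zeros(cap, dtype=np.int64),
        prev_contact_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        prev_contact_cnt=np.zeros(cap, dtype=np.int64),
        cil_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        cil_cnt=np.zeros(cap, dtype=np.int64),
    )
    state.cell_type[:n + 1] = cell_types[:n + 1]
    state.cell_type[0] = MEDIUM
    counts = np.bincount(sigma.ravel(), minlength=n + 1)
    state.area[1:n + 1] = counts[1:n + 1]
    if (state.area[1:n + 1] == 0).any():
        raise ValueError("every label 1..n must occupy at least one site")
    xs, ys = np.nonzero(sigma)
    labels = sigma[xs, ys]
    state.sum_x[:n + 1] = np.bincount(labels, weights=xs, minlength=n + 1)
    state.sum_y[:n + 1] = np.bincount(labels, weights=ys, minlength=n + 1)
    live = state.area[1:n + 1].astype(float)
    state.prev_cx[1:n + 1] = state.sum_x[1:n + 1] / live
    state.prev_cy[1:n + 1] = state.sum_y[1:n + 1] / live
    _kernels.compute_contacts(sigma, state.contact_list, state.contact_cnt)
    state.prev_contact_list[:] = state.contact_list
    state.prev_contact_cnt[:] = state.contact_cnt
    _kernels.seed_rng(int(seed))
    return state


def init_simulation(params: ParameterSet, seed: int) -> SimulationState:
    """Build the initial tissue: NC and placode patch rows, zero fields.

    Deterministic given ``seed`` (which also seeds the single RNG stream
    that every later stochastic draw of the run consumes). Polarities are
    zero, no links, no CIL states, all concentrations zero.
    """
    w, h = params.lattice_width, params.lattice_height
    if w < PATCH or h < (NC_ROWS + PL_ROWS) * PATCH:
        raise ConfigurationError(
            f"lattice {w}x{h} cannot hold {NC_ROWS + PL_ROWS} patch rows of "
            f"{PATCH}x{PATCH} cells")
    if seed < 0:
        raise ConfigurationError("seed must be >= 0")
    n_cols = w // PATCH  # a partial rightmost column is truncated
    n_nc = n_cols * NC_ROWS
    n_pl = n_cols * PL_ROWS
    n = n_nc + n_pl

    sigma = np.zeros((w, h), dtype=np.int64)
    cid = 0
    for row in range(NC_ROWS + PL_ROWS):
        for col in range(n_cols):
            cid += 1
            x0, y0 = col * PATCH, row * PATCH
            sigma[x0:x0 + PATCH, y0:y0 + PATCH] = cid

    cap = n + 256
    state = SimulationState(
        sigma=sigma,
        fields=FieldSet.zeros(w, h, params.halo),
        params=params,
        rng_seed=int(seed),
        n_cells=n,
        cell_type=np.zeros(cap, dtype=np.int64),
        area=np.zeros(cap, dtype=np.int64),
        sum_x=np.zeros(cap), sum_y=np.zeros(cap),
        prev_cx=np.zeros(cap), prev_cy=np.zeros(cap),
        pol=np.zeros((cap, 2)), disp=np.zeros((cap, 2)),
        link_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        link_cnt=np.zeros(cap, dtype=np.int64),
        contact_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        contact_cnt=np.zeros(cap, dtype=np.int64),
        prev_contact_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        prev_contact_cnt=np.zeros(cap, dtype=np.int64),
        cil_list=np.zeros((cap, _kernels.MAX_DEG), dtype=np.int64),
        cil_cnt=np.zeros(cap, dtype=np.int64),
    )
    state.cell_type[1:n_nc + 1] = NC
    state.cell_type[n_nc + 1:n + 1] = PL
    counts = np.bincount(sigma.ravel(), minlength=n + 1)
    state.area[1:n + 1] = counts[1:n + 1]
    xs, ys = np.nonzero(sigma)
    labels = sigma[xs, ys]
    state.sum_x[:n + 1] = np.bincount(labels, weights=xs, minlength=n + 1)
    state.sum_y[:n + 1] = np.bincount(labels, weights=ys, minlength=n + 1)
    live = state.area[1:n + 1].astype(float)
    state.prev_cx[1:n + 1] = state.sum_x[1:n + 1] / live
    state.prev_cy[1:n + 1] = state.sum_y[1:n + 1] / live
    # Seed the contact cache with the initial adjacency so that the packed
    # starting tissue does not register every pre-existing contact as a new
    # collision (which would fire a synchronized CIL burst at MCS 1); CIL
    # starts from contacts formed by the dynamics.
    _kernels.compute_contacts(sigma, state.contact_list, state.contact_cnt)
    state.prev_contact_list[:] = state.contact_list
    state.prev_contact_cnt[:] = state.contact_cnt
    _kernels.seed_rng(int(seed))
    return state
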