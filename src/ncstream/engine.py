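"""Monte-Carlo lattice updates: energy change, work bias, acceptance, MCS loop.

A Monte Carlo step (MCS) is N copy attempts, N being the lattice site count.
Each attempt proposes to overwrite a random site with the label of a random
Moore neighbor (or with medium, in 10% of attempts) and is accepted with
probability ``min(1, exp(W - dH))`` where ``dH`` is the Hamiltonian change
(volume constraint + contact energies) and ``W`` the work bias (extension-only
chemotaxis + persistent-adhesion springs + polarized motility).

After the attempts of an MCS, the per-MCS state dynamics run in a fixed
order: contacts, links, CIL switching, polarity update, fields, EMT
insertion. The order is a model convention, fixed for reproducibility.

The production path is compiled (:mod:`ncstream._kernels`);
:func:`attempt_copy` additionally exposes a single, inspectable attempt for
analysis and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, behaviors, fields as fields_mod
from .params import NC, ParameterSet, polarity_mode_code
from .state import SimulationState, init_simulation

_NEIGHBORS = np.stack([_kernels._DX8, _kernels._DY8], axis=1)


@dataclass
class CopyAttempt:
    """One proposed lattice overwrite and its evaluation."""

    target: tuple[int, int]          # site r to overwrite
    source_value: int                # label x written on acceptance (0 = retraction)
    source_site: tuple[int, int] | None  # neighbor r' the label came from
    dH: float = 0.0
    W_bias: float = 0.0
    accepted: bool = False


# ----------------------------------------------------------------------
def delta_H(state: SimulationState, attempt: CopyAttempt,
            params: ParameterSet | None = None) -> float:
    """Energy change H(after) - H(before) of an attempt, incrementally."""
    params = params or state.params
    rx, ry = attempt.target
    return float(_kernels.delta_h_site(
        state.sigma, state.area, state.cell_type, params.J_matrix,
        params.lambda_V, params.V_T, rx, ry, attempt.source_value))


def work_bias(state: SimulationState, attempt: CopyAttempt,
              fieldset=None, params: ParameterSet | None = None) -> float:
    """Work bias W of an attempt (chemotaxis + springs + polarity)."""
    params = params or state.params
    fieldset = fieldset or state.fields
    rx, ry = attempt.target
    if attempt.source_site is None:
        spx = spy = -1
    else:
        spx, spy = attempt.source_site
    return float(_kernels.work_bias_site(
        state.sigma, state.area, state.sum_x, state.sum_y, state.cell_type,
        state.pol, state.link_list, state.link_cnt, fieldset.conc,
        params.chemotaxis_weights(), params.propulsion_weights(),
        params.lambda_M_pair, params.d0, fieldset.halo,
        rx, ry, spx, spy, attempt.source_value, polarity_mode_code(params)))


def attempt_copy(state: SimulationState, rng: np.random.Generator,
                 site: tuple[int, int] | None = None,
                 source_site: tuple[int, int] | None = None,
                 retract: bool | None = None,
                 apply: bool = True) -> CopyAttempt:
    """Draw, evaluate and (optionally) apply a single copy attempt.

    With ``site``/``source_site``/``retract`` given, the corresponding draws
    are skipped, which permits forcing identical attempts repeatedly (the
    acceptance uniform is always drawn). ``apply=False`` evaluates and
    decides without mutating the lattice. The compiled MCS loop uses its own
    RNG stream; this entry point is for analysis and tests.
    """
    w, h = state.sigma.shape
    if site is None:
        site = (int(rng.integers(0, w)), int(rng.integers(0, h)))
    rx, ry = site
    if retract is None and source_site is None:
        retract = bool(rng.random() < state.params.p_medium_retraction)
    if retract:
        x, src = 0, None
    elif source_site is not None:
        src = source_site
        x = int(state.sigma[src[0], src[1]])
    else:
        k = int(rng.integers(0, 8))
        sx, sy = rx + _NEIGHBORS[k, 0], ry + _NEIGHBORS[k, 1]
        if not (0 <= sx < w and 0 <= sy < h):
            return CopyAttempt(site, 0, None, accepted=False)
        src = (int(sx), int(sy))
        x = int(state.sigma[sx, sy])
    att = CopyAttempt(site, x, src)
    old = int(state.sigma[rx, ry])
    if x == old:
        return att
    if old > 0 and state.area[old] <= 1:
        return att  # never annihilate a cell's last site
    att.dH = delta_H(state, att)
    att.W_bias = work_bias(state, att)
    arg = (att.W_bias - att.dH) / state.params.temperature
    att.accepted = bool(arg >= 0.0 or rng.random() < np.exp(arg))
    if att.accepted and apply:
        state.sigma[rx, ry] = x
        if x > 0:
            state.area[x] += 1
            state.sum_x[x] += rx
            state.sum_y[x] += ry
        if old > 0:
            state.area[old] -= 1
            state.sum_x[old] -= rx
            state.sum_y[old] -= ry
    return att


# ----------------------------------------------------------------------
def run_mcs(state: SimulationState, params: ParameterSet | None = None) -> dict:
    """Advance the simulation by one MCS, in place.

    Performs N copy attempts, then updates contacts, links, CIL states,
    polarities, fields and EMT insertions, and increments the clock.
    Returns the per-MCS event counters.
    """
    p = params or state.params
    accepted, retractions = _kernels.run_attempts(
        state.sigma, state.area, state.sum_x, state.sum_y, state.cell_type,
        state.pol, state.link_list, state.link_cnt, state.fields.conc,
        p.chemotaxis_weights(), p.propulsion_weights(), p.lambda_M_pair,
        p.J_matrix, p.lambda_V, p.V_T, p.d0, p.p_medium_retraction,
        state.fields.halo, p.temperature, polarity_mode_code(p))

    behaviors.refresh_contacts(state)
    formed, broken = behaviors.update_links(state, p)
    entries, exits = behaviors.update_cil(state, p)
    behaviors.update_polarity(state, p)
    fields_mod.step_fields(state, p)
    inserted = behaviors.emt_insert(state, p) if p.emt_enabled else 0

    state.mcs += 1
    counters = {
        "accepted": int(accepted), "retraction_attempts": int(retractions),
        "links_formed": int(formed), "links_broken": int(broken),
        "cil_entries": int(entries), "cil_exits": int(exits),
        "emt_insertions": int(inserted),
    }
    state.counters = counters
    return counters


@dataclass
class RunLog:
    """Per-MCS time series recorded by :class:`Simulation`."""

    mcs: np.ndarray
    mean_conc: np.ndarray       # (T, 3) over the cell lattice, halo excluded
    nc_speed: np.ndarray        # (T,) mean |dr| of NC cells [s.u./MCS]
    counters: dict              # name -> (T,) int array


class Simulation:
    """Driver that owns a state and records per-MCS summary series."""

    def __init__(self, params: ParameterSet | None = None, seed: int = 0):
        self.params = params or ParameterSet()
        self.state = init_simulation(self.params, seed)
        self._mcs: list[int] = []
        self._conc: list[tuple[float, float, float]] = []
        self._speed: list[float] = []
        self._counters: dict[str, list[int]] = {}

    def step(self) -> dict:
        counters = run_mcs(self.state, self.params)
        st = self.state
        self._mcs.append(st.mcs)
        self._conc.append(tuple(st.fields.mean_over_cells(s)
                                for s in ("A", "S", "I")))
        nc = st.cell_type[1:st.n_cells + 1] == NC
        d = st.disp[1:st.n_cells + 1][nc]
        self._speed.append(float(np.hypot(d[:, 0], d[:, 1]).mean())
                           if nc.any() else np.nan)
        for k, v in counters.items():
            self._counters.setdefault(k, []).append(v)
        return counters

    def run(self, n_mcs: int | None = None, callback=None,
            callback_interval: int = 100, progress: bool = False):
        """Run ``n_mcs`` steps (default: params.total_MCS minus the clock)."""
        if n_mcs is None:
            n_mcs = self.params.total_MCS - self.state.mcs
        steps = range(n_mcs)
        if progress:
            from tqdm import tqdm
            steps = tqdm(steps, desc="MCS", unit="mcs")
        for _ in steps:
            self.step()
            if callback is not None and self.state.mcs % callback_interval == 0:
                callback(self.state)
        return self

    @property
    def log(self) -> RunLog:
        return RunLog(
            mcs=np.asarray(self._mcs),
            mean_conc=np.asarray(self._conc),
            nc_speed=np.asarray(self._speed),
            counters={k: np.asarray(v) for k, v in self._counters.items()},
        )
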