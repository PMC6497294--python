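"""Per-MCS cell-state dynamics: polarity, CIL, persistent links, EMT.

These are thin, documented entry points over the compiled kernels in
:mod:`ncstream._kernels`; the engine's MCS loop calls them in the fixed
order contacts -> links -> CIL -> polarity -> (fields) -> EMT.

The polarity persistence rule is ``p(t+1) = (1 - dP) p(t) + dr(t)`` with the
decay ``dP`` chosen by cell type and contact status; a cell in CIL state
additionally subtracts ``lambda_CIL`` times the normalized sum of vectors
toward its current contact partners, repolarizing it away from the contacts.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import ParameterSet
from .state import EMT_PATCH_H, EMT_PATCH_W, SimulationState


def polarity_step(polarity, displacement, decay: float,
                  contact_vectors=None, lambda_CIL: float = 0.0) -> np.ndarray:
    """One polarity update for a single cell (pure function).

    ``contact_vectors`` (sequence of vectors toward contact partners) is
    given only for cells in CIL state; a zero-magnitude sum skips the CIL
    bias for the step.
    """
    p = (1.0 - decay) * np.asarray(polarity, float) + np.asarray(displacement, float)
    if contact_vectors is not None and len(contact_vectors):
        s = np.sum(np.asarray(contact_vectors, float), axis=0)
        norm = np.hypot(s[0], s[1])
        if norm > 1e-12:
            p = p - lambda_CIL * s / norm
    return p


def refresh_contacts(state: SimulationState) -> None:
    """Rotate the contact cache and recompute 8-neighborhood contacts."""
    state.prev_contact_list, state.contact_list = \
        state.contact_list, state.prev_contact_list
    state.prev_contact_cnt, state.contact_cnt = \
        state.contact_cnt, state.prev_contact_cnt
    _kernels.compute_contacts(state.sigma, state.contact_list,
                              state.contact_cnt)


def update_links(state: SimulationState,
                 params: ParameterSet | None = None) -> tuple[int, int]:
    """Form/break persistent adhesion links for one MCS.

    Contacting unlinked pairs link with probability ``p_link_form``; linked
    pairs that lost lattice contact unlink deterministically; the rest break
    with probability clamp((|r_ij| - d0) / divisor, 0, 1). Returns
    (formed, broken).
    """
    p = params or state.params
    return _kernels.update_links(
        state.n_cells, state.area, state.sum_x, state.sum_y,
        state.contact_list, state.contact_cnt,
        state.link_list, state.link_cnt,
        p.p_link_form, p.d0, p.link_break_divisor)


def update_cil(state: SimulationState,
               params: ParameterSet | None = None) -> tuple[int, int]:
    """CIL switching for one MCS (requires contacts to be current).

    Each participant of a *new* NC-NC or NC-placode contact independently
    enters CIL state with its type's p(CIL); placode-placode contacts never
    trigger. A cell leaves CIL state when no triggering contact remains.
    Returns (entries, exits).
    """
    p = params or state.params
    return _kernels.update_cil(
        state.n_cells, state.cell_type,
        state.contact_list, state.contact_cnt,
        state.prev_contact_list, state.prev_contact_cnt,
        state.cil_list, state.cil_cnt, p.cil_probabilities())


def update_polarity(state: SimulationState,
                    params: ParameterSet | None = None) -> None:
    """Polarity persistence + CIL repolarization for every cell (in place)."""
    p = params or state.params
    dP_free, dP_contact = p.polarity_decay()
    _kernels.update_polarity(
        state.n_cells, state.area, state.sum_x, state.sum_y,
        state.prev_cx, state.prev_cy, state.cell_type, state.pol, state.disp,
        state.contact_list, state.contact_cnt, state.cil_cnt,
        dP_free, dP_contact, p.lambda_CIL)


def emt_insert(state: SimulationState,
               params: ParameterSet | None = None) -> int:
    """Insert new NC cells into qualifying dorsal-edge gaps.

    A gap qualifies when a 5-wide x 3-tall rectangle at the top edge is all
    medium (one cell wide, half a cell tall); each insertion creates one NC
    cell of area 15 that subsequently relaxes toward V_T. Returns the number
    of insertions.
    """
    state.ensure_capacity(state.n_cells
                          + state.sigma.shape[0] // EMT_PATCH_W + 1)
    new_n = _kernels.emt_insert(
        state.sigma, state.area, state.sum_x, state.sum_y,
        state.prev_cx, state.prev_cy, state.cell_type,
        state.pol, state.disp, state.n_cells, EMT_PATCH_W, EMT_PATCH_H)
    inserted = new_n - state.n_cells
    state.n_cells = new_n
    return inserted
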