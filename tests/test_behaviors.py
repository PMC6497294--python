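import numpy as np
import pytest

from ncstream import ParameterSet, init_simulation, polarity_step, run_mcs
from ncstream.behaviors import (emt_insert, refresh_contacts, update_cil,
                                update_links, update_polarity)
from ncstream.params import MEDIUM, NC, PL
from ncstream.state import EMT_PATCH_H, EMT_PATCH_W, state_from_lattice


# ---------------------------------------------------------------- polarity
def test_polarity_persistence_formula():
    # free NC: p = (1 - 0.3) * (1, 0) + 0 = (0.7, 0)
    p = polarity_step((1.0, 0.0), (0.0, 0.0), decay=0.3)
    assert np.allclose(p, (0.7, 0.0))


def test_polarity_decays_geometrically():
    p = np.array([1.0, 0.0])
    for k in range(1, 30):
        p = polarity_step(p, (0.0, 0.0), decay=0.3)
        assert np.hypot(*p) == pytest.approx(0.7 ** k)


def test_cil_bias_points_away_from_contact():
    # partner directly to the right, lambda_CIL = 0.5: p gains -0.5 in x
    base = polarity_step((1.0, 0.0), (0.0, 0.0), decay=0.3)
    biased = polarity_step((1.0, 0.0), (0.0, 0.0), decay=0.3,
                           contact_vectors=[(4.0, 0.0)], lambda_CIL=0.5)
    assert biased[0] == pytest.approx(base[0] - 0.5)
    assert biased[1] == pytest.approx(base[1])


def test_zero_contact_sum_skips_cil_bias():
    # partners on opposite sides cancel: bias skipped, not NaN
    p = polarity_step((1.0, 0.0), (0.0, 0.0), decay=0.3,
                      contact_vectors=[(3.0, 0.0), (-3.0, 0.0)],
                      lambda_CIL=0.5)
    assert np.allclose(p, (0.7, 0.0))


def _two_cell_state(params, types=(NC, NC), gap=0):
    w = 14 + gap
    sigma = np.zeros((w, 10), dtype=np.int64)
    sigma[2:7, 2:7] = 1
    sigma[7 + gap:12 + gap, 2:7] = 2
    return state_from_lattice(sigma, [MEDIUM, *types], params)


def test_state_level_polarity_uses_contact_decay(quiet_params):
    p = quiet_params.replace(deltaP_NC_free=0.3, deltaP_NC_contact=0.08)
    st = _two_cell_state(p)               # two NC cells in contact
    st.pol[1] = (1.0, 0.0)
    refresh_contacts(st)
    update_polarity(st, p)
    assert st.pol[1][0] == pytest.approx(1 - 0.08)   # contact decay
    st2 = _two_cell_state(p, gap=4)       # same cells, separated
    st2.pol[1] = (1.0, 0.0)
    refresh_contacts(st2)
    update_polarity(st2, p)
    assert st2.pol[1][0] == pytest.approx(1 - 0.3)   # free decay


# -------------------------------------------------------------------- CIL
def test_certain_cil_on_new_contact(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0)
    st = _two_cell_state(p)
    # the initial adjacency is cached at construction; clear it so this
    # contact counts as newly formed
    refresh_contacts(st)
    st.prev_contact_cnt[:] = 0
    update_cil(st, p)
    assert st.cil_cnt[1] > 0 and st.cil_cnt[2] > 0


def test_preexisting_contact_does_not_trigger(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0)
    st = _two_cell_state(p)
    refresh_contacts(st)   # same contacts as cached: nothing is new
    update_cil(st, p)
    assert st.cil_cnt[1] == 0 and st.cil_cnt[2] == 0


def test_placode_placode_contact_never_triggers(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0, p_CIL_PL=1.0)
    st = _two_cell_state(p, types=(PL, PL))
    refresh_contacts(st)
    st.prev_contact_cnt[:] = 0
    update_cil(st, p)
    assert st.cil_cnt[1] == 0 and st.cil_cnt[2] == 0


def test_zero_probability_placodes_stay_out_of_cil(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0, p_CIL_PL=0.0)
    st = _two_cell_state(p, types=(NC, PL))
    refresh_contacts(st)
    st.prev_contact_cnt[:] = 0
    update_cil(st, p)
    assert st.cil_cnt[1] > 0    # the NC partner responds
    assert st.cil_cnt[2] == 0   # the placode never does


def test_cil_state_cleared_when_contact_lost(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0)
    st = _two_cell_state(p)
    refresh_contacts(st)
    st.prev_contact_cnt[:] = 0
    update_cil(st, p)
    assert st.cil_cnt[1] > 0
    # separate the cells on the lattice and recompute
    st.sigma[st.sigma == 2] = 0
    st.sigma[12:17, 2:7] = 2
    st.area[2] = 25
    st.sum_x[2] = st.sigma[st.sigma == 2].size * 14.0
    refresh_contacts(st)
    update_cil(st, p)
    assert st.cil_cnt[1] == 0


def test_isolated_cell_never_in_cil(quiet_params):
    p = quiet_params.replace(p_CIL_NC=1.0)
    st = _two_cell_state(p, gap=6)
    refresh_contacts(st)
    st.prev_contact_cnt[:] = 0
    update_cil(st, p)
    assert st.cil_cnt[1] == 0 and st.cil_cnt[2] == 0


# ------------------------------------------------------------------- links
def test_link_break_probability_formula(quiet_params):
    """Linked contacting pairs at |r| <= d0 never break; at d0 + 2 they
    break at (|r| - d0)/100 = 2% per MCS (binomial 3 sigma)."""
    p = quiet_params.replace(p_link_form=0.0)
    st = _two_cell_state(p)   # centroid distance 5 < d0 = 5.64
    n = 20_000
    breaks_close = 0
    for _ in range(n):
        st.link_list[1, 0], st.link_cnt[1] = 2, 1
        st.link_list[2, 0], st.link_cnt[2] = 1, 1
        _, broken = update_links(st, p)
        breaks_close += broken
    assert breaks_close == 0

    # stretch to centroid distance d0 + 2 while keeping lattice contact
    st2 = _two_cell_state(p)
    target = p.d0 + 2.0
    st2.sum_x[2] += (target - 5.0) * st2.area[2]   # shift cached centroid
    breaks = 0
    for _ in range(n):
        st2.link_list[1, 0], st2.link_cnt[1] = 2, 1
        st2.link_list[2, 0], st2.link_cnt[2] = 1, 1
        _, broken = update_links(st2, p)
        breaks += broken
    expect = 0.02
    sigma3 = 3 * np.sqrt(expect * (1 - expect) / n)
    assert abs(breaks / n - expect) < sigma3


def test_link_removed_when_contact_lost(quiet_params):
    p = quiet_params.replace(p_link_form=0.0)
    st = _two_cell_state(p, gap=6)   # never in contact
    st.link_list[1, 0], st.link_cnt[1] = 2, 1
    st.link_list[2, 0], st.link_cnt[2] = 1, 1
    _, broken = update_links(st, p)
    assert broken == 1
    assert st.link_cnt[1] == 0 and st.link_cnt[2] == 0


def test_links_form_only_between_contacting_cells(quiet_params):
    p = quiet_params.replace(p_link_form=1.0)
    st = _two_cell_state(p)
    formed, _ = update_links(st, p)
    assert formed == 1
    assert set(st.link_list[1, :st.link_cnt[1]]) == {2}
    st2 = _two_cell_state(p, gap=6)
    formed, _ = update_links(st2, p)
    assert formed == 0


# -------------------------------------------------------------------- EMT
def _emt_state(params, top_gap_cols=()):
    sigma = np.zeros((20, 12), dtype=np.int64)
    sigma[:, 0:EMT_PATCH_H] = 1   # one wide NC cell occupying the top strip
    for x0 in top_gap_cols:
        sigma[x0:x0 + EMT_PATCH_W, 0:EMT_PATCH_H] = 0
    return state_from_lattice(sigma, [MEDIUM, NC], params)


def test_no_insertion_when_top_strip_occupied(quiet_params):
    st = _emt_state(quiet_params)
    assert emt_insert(st, quiet_params) == 0


def test_single_gap_inserts_one_half_height_cell(quiet_params):
    st = _emt_state(quiet_params, top_gap_cols=(5,))
    inserted = emt_insert(st, quiet_params)
    assert inserted == 1
    new = st.n_cells
    assert st.area[new] == EMT_PATCH_W * EMT_PATCH_H == 15
    assert st.cell_type[new] == NC
    assert (st.pol[new] == 0).all()
    st.check_consistency()


def test_disjoint_gaps_insert_distinct_cells(quiet_params):
    st = _emt_state(quiet_params, top_gap_cols=(2, 12))
    before = st.n_cells
    assert emt_insert(st, quiet_params) == 2
    assert st.n_cells == before + 2
    labels = set(np.unique(st.sigma)) - {0}
    assert len(labels) == before + 2


def test_emt_cell_grows_toward_target_area():
    p = ParameterSet(lattice_width=60, lattice_height=75, halo=10)
    st = init_simulation(p, seed=2)
    # carve a dorsal 5x3 gap (cell 3 keeps its lower rows) and fix its entry
    st.sigma[10:15, 0:3] = 0
    gap_label = 3
    st.area[gap_label] = np.count_nonzero(st.sigma == gap_label)
    xs, ys = np.nonzero(st.sigma == gap_label)
    st.sum_x[gap_label], st.sum_y[gap_label] = float(xs.sum()), float(ys.sum())
    assert emt_insert(st, p) == 1
    new = st.n_cells
    area0 = 15
    st.check_consistency()
    for _ in range(60):
        run_mcs(st)
    # the volume constraint inflates the half-height cell toward V_T = 25
    assert abs(st.area[new] - st.params.V_T) < abs(area0 - st.params.V_T)


def test_cell_count_only_grows_via_emt():
    p = ParameterSet(lattice_width=60, lattice_height=75, halo=10,
                     emt_enabled=False)
    st = init_simulation(p, seed=4)
    n0 = st.n_cells
    for _ in range(20):
        run_mcs(st)
    assert st.n_cells == n0
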