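import numpy as np
import pytest

from ncstream import (CopyAttempt, ParameterSet, Simulation, attempt_copy,
                      delta_H, init_simulation, run_mcs, work_bias)
from ncstream.params import MEDIUM, NC, PL
from ncstream.state import state_from_lattice

from conftest import full_hamiltonian, random_cell_lattice, single_cell_state


def test_noop_copy_has_zero_energy(random_state):
    # overwriting a site with its own label changes nothing
    x, y = 5, 5
    att = CopyAttempt((x, y), int(random_state.sigma[x, y]), (x, y))
    assert delta_H(random_state, att) == 0.0


def test_volume_term_of_single_site_loss(quiet_params):
    # isolated cell at V = V_T = 25 losing one site, lambda_V = 5, J = 0:
    # dH = 5 * ((24-25)^2 - 0) = +5
    p = quiet_params.replace(J_matrix=np.zeros((3, 3)), lambda_V=5.0,
                             V_T=25.0)
    st = single_cell_state(p)
    att = CopyAttempt((6, 6), 0, None)
    assert delta_H(st, att) == pytest.approx(5.0)


def test_incremental_dh_matches_full_hamiltonian(quiet_params):
    """1000 random attempts on a random 30x30 configuration: the
    incremental energy change equals brute-force H(after) - H(before)."""
    rng = np.random.default_rng(42)
    sigma, types = random_cell_lattice(30, 30, 12, rng)
    p = quiet_params
    st = state_from_lattice(sigma, types, p)
    J, lam_V, V_T = p.J_matrix, p.lambda_V, p.V_T
    checked = 0
    while checked < 1000:
        x = int(rng.integers(0, 30))
        y = int(rng.integers(0, 30))
        dx, dy = rng.integers(-1, 2, size=2)
        nx, ny = x + dx, y + dy
        if (dx == dy == 0) or not (0 <= nx < 30 and 0 <= ny < 30):
            continue
        new = int(st.sigma[nx, ny]) if rng.random() > 0.1 else 0
        old = int(st.sigma[x, y])
        if new == old or (old > 0 and st.area[old] <= 1):
            continue
        att = CopyAttempt((x, y), new, (nx, ny))
        dh = delta_H(st, att)
        before = full_hamiltonian(st.sigma, types, J, lam_V, V_T)
        after_sigma = st.sigma.copy()
        after_sigma[x, y] = new
        after = full_hamiltonian(after_sigma, types, J, lam_V, V_T)
        assert dh == pytest.approx(after - before, abs=1e-9)
        # keep walking the configuration so attempts stay diverse
        st.sigma[x, y] = new
        if new > 0:
            st.area[new] += 1
            st.sum_x[new] += x
            st.sum_y[new] += y
        if old > 0:
            st.area[old] -= 1
            st.sum_x[old] -= x
            st.sum_y[old] -= y
        checked += 1


# ---------------------------------------------------------------- work W
def test_chemotaxis_on_free_extension(params):
    # NC extending into medium up a gradient dc_S = 0.01 with weight 150
    p = params.replace(halo=4, lambda_A=0.0, lambda_I=0.0,
                       lambda_P_NC=0.0, lambda_P_PL=0.0,
                       lambda_M_pair=np.zeros((3, 3)))
    st = single_cell_state(p, cell_type=NC)
    h = st.fields.halo
    target, source = (9, 6), (8, 6)
    st.fields.conc[1][target[0] + h, target[1] + h] = 0.06
    st.fields.conc[1][source[0] + h, source[1] + h] = 0.05
    att = CopyAttempt(target, 1, source)
    assert work_bias(st, att) == pytest.approx(150 * 0.01)


def test_placodes_do_not_chemotax(params):
    p = params.replace(halo=4, lambda_P_NC=0.0, lambda_P_PL=0.0,
                       lambda_M_pair=np.zeros((3, 3)))
    st = single_cell_state(p, cell_type=PL)
    h = st.fields.halo
    st.fields.conc[1][9 + h, 6 + h] = 1.0   # steep Sdf1 gradient
    att = CopyAttempt((9, 6), 1, (8, 6))
    assert work_bias(st, att) == 0.0


def test_retraction_gets_no_chemotaxis(params):
    p = params.replace(halo=4, lambda_P_NC=0.0,
                       lambda_M_pair=np.zeros((3, 3)))
    st = single_cell_state(p, cell_type=NC)
    h = st.fields.halo
    st.fields.conc[:, :, :] = 0.0
    st.fields.conc[0][6 + h, 6 + h] = 1.0   # gradient at an occupied site
    att = CopyAttempt((6, 6), 0, None)
    assert work_bias(st, att) == 0.0


def test_polarity_work_follows_unit_polarity(params):
    p = params.replace(halo=4, lambda_A=0.0, lambda_S_eff=0.0, lambda_I=0.0,
                       lambda_M_pair=np.zeros((3, 3)), lambda_P_NC=6.0)
    st = single_cell_state(p, cell_type=NC)
    st.pol[1] = (10.0, 0.0)   # polarized along +x; magnitude must not matter
    att = CopyAttempt((9, 6), 1, (8, 6))   # extension along +x
    assert work_bias(st, att) == pytest.approx(6.0)
    st.pol[1] = (0.5, 0.0)
    assert work_bias(st, att) == pytest.approx(6.0)


def test_spring_work_pulls_stretched_pair_together(params):
    # two linked NC cells stretched beyond d0: moving the left cell toward
    # its partner is favored, moving it away is penalized symmetrically
    p = params.replace(halo=4, lambda_A=0.0, lambda_S_eff=0.0, lambda_I=0.0,
                       lambda_P_NC=0.0)
    sigma = np.zeros((24, 10), dtype=np.int64)
    sigma[2:7, 2:7] = 1
    sigma[12:17, 2:7] = 2
    st = state_from_lattice(sigma, [MEDIUM, NC, NC], p)
    st.link_list[1, 0] = 2
    st.link_list[2, 0] = 1
    st.link_cnt[1] = st.link_cnt[2] = 1
    toward = work_bias(st, CopyAttempt((7, 4), 1, (6, 4)))
    away = work_bias(st, CopyAttempt((1, 4), 1, (2, 4)))
    dist = 10.0
    expected = p.lambda_M_pair[NC, NC] * (dist - p.d0)
    assert toward == pytest.approx(expected)
    assert away == pytest.approx(-expected)


# ------------------------------------------------------------- acceptance
def test_acceptance_certain_when_arg_nonnegative(random_state):
    rng = np.random.default_rng(0)
    # a no-op-energy retraction of a medium site is impossible; craft a
    # favorable attempt instead: any accepted probability-1 case
    st = random_state
    st.params = st.params.replace(J_matrix=np.zeros((3, 3)), lambda_V=0.0)
    big = int(np.argmax(st.area[1:st.n_cells + 1])) + 1
    xs, ys = np.nonzero(st.sigma == big)
    att = attempt_copy(st, rng, site=(int(xs[0]), int(ys[0])), retract=True,
                       apply=False)
    assert att.dH == 0.0 and att.W_bias == 0.0
    assert att.accepted


def test_acceptance_rate_matches_boltzmann_factor(quiet_params):
    """Forced identical attempts with W - dH = -2 are accepted at a rate
    compatible with exp(-2) (binomial 3 sigma over 1e5 trials)."""
    p = quiet_params.replace(J_matrix=np.zeros((3, 3)), lambda_V=1.0,
                             V_T=2.5, temperature=1.0, halo=2)
    sigma = np.zeros((6, 6), dtype=np.int64)
    sigma[2, 2] = sigma[2, 3] = 1
    st = state_from_lattice(sigma, [MEDIUM, NC], p)
    probe = attempt_copy(st, np.random.default_rng(0), site=(2, 3),
                         retract=True, apply=False)
    assert probe.W_bias - probe.dH == pytest.approx(-2.0)
    rng = np.random.default_rng(123)
    n = 100_000
    hits = sum(attempt_copy(st, rng, site=(2, 3), retract=True,
                            apply=False).accepted for _ in range(n))
    expect = np.exp(-2.0)
    sigma3 = 3 * np.sqrt(expect * (1 - expect) / n)
    assert abs(hits / n - expect) < sigma3


def test_last_site_annihilation_rejected(quiet_params):
    p = quiet_params.replace(halo=2)
    sigma = np.zeros((6, 6), dtype=np.int64)
    sigma[3, 3] = 1
    st = state_from_lattice(sigma, [MEDIUM, NC], p)
    att = attempt_copy(st, np.random.default_rng(0), site=(3, 3),
                       retract=True)
    assert not att.accepted
    assert st.sigma[3, 3] == 1


# ----------------------------------------------------------------- run_mcs
def test_run_mcs_deterministic_for_fixed_seed():
    p = ParameterSet(lattice_width=60, lattice_height=75, halo=20)
    hashes = []
    for _ in range(2):
        st = init_simulation(p, seed=9)
        for _ in range(5):
            run_mcs(st)
        hashes.append(st.state_hash())
    assert hashes[0] == hashes[1]


def test_registry_consistent_after_mcs():
    p = ParameterSet(lattice_width=60, lattice_height=75, halo=20)
    st = init_simulation(p, seed=3)
    for _ in range(10):
        run_mcs(st)
        st.check_consistency()


def test_no_spurious_drift_without_biases():
    """With propulsion, springs and chemotaxis off, cell motion is pure
    Metropolis noise: the population's mean displacement is ~zero."""
    p = ParameterSet(lattice_width=60, lattice_height=75, halo=20,
                     lambda_A=0.0, lambda_S_eff=0.0, lambda_I=0.0,
                     lambda_P_NC=0.0, lambda_P_PL=0.0, lambda_CIL=0.0,
                     lambda_M_pair=np.zeros((3, 3)),
                     p_CIL_NC=0.0, p_CIL_PL=0.0, emt_enabled=False,
                     S_A=0.0, S_S=0.0, S_I=0.0, U_S=0.0,
                     D_A=0.0, D_S=0.0, D_I=0.0)
    st = init_simulation(p, seed=17)
    start = st.centroids()
    for _ in range(500):
        run_mcs(st)
    drift = st.centroids() - start
    mean_drift = np.hypot(*drift.mean(axis=0))
    assert mean_drift < 2.0  # a real bias would accumulate tens of sites
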