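import numpy as np
import pytest

from ncstream.params import MEDIUM, NC, PL, ParameterSet
from ncstream.state import state_from_lattice


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def quiet_params():
    """Parameters with every bias off: pure volume + contact Hamiltonian."""
    return ParameterSet(
        lambda_A=0.0, lambda_S_eff=0.0, lambda_I=0.0,
        lambda_P_NC=0.0, lambda_P_PL=0.0, lambda_CIL=0.0,
        lambda_M_pair=np.zeros((3, 3)),
        p_CIL_NC=0.0, p_CIL_PL=0.0,
        S_A=0.0, S_S=0.0, S_I=0.0, U_S=0.0,
        halo=4, temperature=1.0,
    )


def random_cell_lattice(width, height, n_cells, rng, patch=4):
    """Scatter square patches for ``n_cells`` labels; types alternate NC/PL."""
    sigma = np.zeros((width, height), dtype=np.int64)
    for cid in range(1, n_cells + 1):
        x = int(rng.integers(0, width - patch))
        y = int(rng.integers(0, height - patch))
        sigma[x:x + patch, y:y + patch] = cid
    # a later patch may fully overwrite an earlier one; re-seed lost labels
    for cid in range(1, n_cells + 1):
        if not (sigma == cid).any():
            x = int(rng.integers(0, width))
            y = int(rng.integers(0, height))
            sigma[x, y] = cid
    types = np.zeros(n_cells + 1, dtype=np.int64)
    types[1::2] = NC
    types[2::2] = PL
    return sigma, types


@pytest.fixture
def random_state(quiet_params):
    """30x30 mixed NC/placode configuration with a consistent registry."""
    rng = np.random.default_rng(7)
    sigma, types = random_cell_lattice(30, 30, 12, rng)
    return state_from_lattice(sigma, types, quiet_params, seed=3)


def single_cell_state(params, width=12, height=12, x0=4, y0=4, side=5,
                      cell_type=NC):
    sigma = np.zeros((width, height), dtype=np.int64)
    sigma[x0:x0 + side, y0:y0 + side] = 1
    return state_from_lattice(sigma, [MEDIUM, cell_type], params)


def full_hamiltonian(sigma, types, J, lam_V, V_T):
    """Brute-force H over the whole lattice (independent oracle).

    Volume term over all cells plus contact energies over every unordered
    Moore-neighbor site pair inside the lattice (bonds within one cell are
    zero).
    """
    n = int(sigma.max())
    counts = np.bincount(sigma.ravel(), minlength=n + 1)
    H = float(lam_V) * float(((counts[1:n + 1] - V_T) ** 2).sum())
    w, h = sigma.shape
    H_contact = 0.0
    for x in range(w):
        for y in range(h):
            a = sigma[x, y]
            for dx, dy in ((1, 0), (0, 1), (1, 1), (1, -1)):
                nx, ny = x + dx, y + dy
                if 0 <= nx < w and 0 <= ny < h:
                    b = sigma[nx, ny]
                    if a != b:
                        H_contact += J[types[a], types[b]]
    return H + H_contact
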