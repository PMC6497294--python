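"""Concentration fields: diffusion, decay, secretion and uptake.

Three substances live on a halo-extended lattice (the cell lattice plus 100
sites in each direction, so that the open space around the tissue is
represented without cells ever entering it): the NC co-attractant ``A``, the
placode chemokine ``S`` (Sdf1, taken up by NC cells) and the short-range
inhibitor ``I``. Each MCS the fields advance by explicit forward-Euler
substeps of

    dc/dt = D lap(c) - delta c + S(sigma, c)

with a 5-point Laplacian, zero-flux outer boundary, and per-substance
substep counts that satisfy the D*dt <= 0.25 stability bound (see
:meth:`ncstream.params.ParameterSet.substeps_for`).

Concentrations are occupancy fractions of a local carrying capacity:
secretion is logistic, ``S_i * (1 - c)`` at secreting sites, and uptake is
proportional, ``-U * c``, so every field lives in [0, 1]. This keeps the
chemotaxis work terms (weights of order 1-150 times nearest-neighbor
concentration differences) on the same scale as the adhesion, volume and
motility terms of the acceptance rule, and it reproduces the saturation of
the chemokine field that stabilizes the emergent stream geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import SUB_INDEX, SUBSTANCES, ParameterSet


class FieldNumericsError(RuntimeError):
    """Raised when a field develops NaN/inf values."""


@dataclass
class FieldSet:
    """Concentration grids for (A, S, I) on the halo-extended lattice."""

    conc: np.ndarray   # (3, width + 2*halo, height + 2*halo), float64
    halo: int

    @classmethod
    def zeros(cls, width: int, height: int, halo: int) -> "FieldSet":
        return cls(conc=np.zeros((3, width + 2 * halo, height + 2 * halo)),
                   halo=halo)

    def grid(self, substance: str) -> np.ndarray:
        """Full extended grid of one substance (mutable view)."""
        return self.conc[SUB_INDEX[substance]]

    def cell_view(self, substance: str) -> np.ndarray:
        """View of one substance restricted to the cell lattice."""
        h = self.halo
        g = self.grid(substance)
        if h == 0:
            return g
        return g[h:-h, h:-h]

    def mean_over_cells(self, substance: str) -> float:
        """Mean concentration over the cell lattice (halo excluded)."""
        return float(self.cell_view(substance).mean())

    def total_mass(self, substance: str) -> float:
        return float(self.grid(substance).sum())

    def copy(self) -> "FieldSet":
        return FieldSet(conc=self.conc.copy(), halo=self.halo)


# ----------------------------------------------------------------------
def source_map(state, substance: str) -> np.ndarray:
    """Per-site net source grid for one substance on the extended lattice,
    evaluated at the current concentrations.

    NC sites secrete A at rate ``S_A * (1 - c_A)`` and take up S at rate
    ``U_S * c_S`` (so c_S can never go negative); placode sites secrete S
    and I at ``S_S * (1 - c_S)`` and ``S_I * (1 - c_I)``; medium and halo
    sites contribute 0. On zero fields the secreting sites therefore carry
    exactly their Table-rate values.
    """
    if substance not in SUB_INDEX:
        raise KeyError(f"unknown substance {substance!r}; expected one of "
                       f"{SUBSTANCES}")
    s = SUB_INDEX[substance]
    rates = state.params.source_rates()[:, s].copy()
    src = np.empty_like(state.fields.grid(substance))
    _kernels.build_source(state.sigma, state.cell_type, rates,
                          state.fields.halo, src)
    c = state.fields.grid(substance)
    K = state.params.capacity(substance)
    return np.where(src > 0, src * (1.0 - c / K), src * c)


def step_fields(state, params: ParameterSet | None = None) -> None:
    """Advance all three fields of ``state`` by one MCS, in place.

    Sources are frozen at the current lattice configuration for the whole
    MCS. Raises :class:`FieldNumericsError` if a field leaves the finite
    range, naming the substance.
    """
    params = params or state.params
    rates = params.source_rates()
    src = np.empty_like(state.fields.conc[0])
    for name in SUBSTANCES:
        s = SUB_INDEX[name]
        _kernels.build_source(state.sigma, state.cell_type, rates[:, s],
                              state.fields.halo, src)
        _kernels.step_field(state.fields.conc[s], src,
                            params.diffusion(name), params.decay(name),
                            params.substeps_for(name),
                            params.capacity(name))
        if not np.isfinite(state.fields.conc[s]).all():
            raise FieldNumericsError(
                f"substance {name} became non-finite at MCS {state.mcs} "
                f"(substeps={params.substeps_for(name)})")


def decay_length(substance: str, params: ParameterSet) -> float:
    """Characteristic diffusion range sqrt(D / delta) [s.u.].

    Returns ``inf`` when the substance does not decay (infinite range) and
    0 when it does not diffuse.
    """
    D = params.diffusion(substance)
    delta = params.decay(substance)
    if delta <= 0:
        return math.inf if D > 0 else 0.0
    return math.sqrt(D / delta)
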