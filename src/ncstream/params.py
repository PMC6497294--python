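"""Model parameters for the neural-crest / placode chase-and-run simulator.

The simulation couples a two-cell-type cellular Potts model (CPM) to three
diffusible substances: a neural-crest co-attractant ``A`` (C3a-like), the
placode-secreted chemokine ``S`` (Sdf1) and a short-range inhibitor ``I``.
:class:`ParameterSet` collects every model constant with the published default
values, plus engine knobs (lattice geometry, field substepping, calibration to
physical units) that the model definition leaves open.

Cell types are indexed throughout the package as ``0 = medium``, ``1 = NC``
(neural crest), ``2 = PL`` (placode); substances as ``0 = A``, ``1 = S``,
``2 = I``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

MEDIUM, NC, PL = 0, 1, 2
TYPE_NAMES = {MEDIUM: "medium", NC: "NC", PL: "PL"}
SUBSTANCES = ("A", "S", "I")
SUB_INDEX = {"A": 0, "S": 1, "I": 2}

#: explicit-scheme stability bound for the 5-point Laplacian on unit spacing
STABILITY_LIMIT = 0.25


def _default_J() -> np.ndarray:
    # J[type_a, type_b]; medium-medium bonds carry no energy
    J = np.zeros((3, 3), dtype=np.float64)
    J[NC, MEDIUM] = J[MEDIUM, NC] = 5.0
    J[NC, NC] = 3.0
    J[PL, MEDIUM] = J[MEDIUM, PL] = 5.0
    J[PL, NC] = J[NC, PL] = 20.0
    J[PL, PL] = 10.0
    return J


def _default_lambda_M() -> np.ndarray:
    # persistent-adhesion spring strength per (type_i, type_j) pair
    lam = np.zeros((3, 3), dtype=np.float64)
    lam[NC:, NC:] = 5.0
    return lam


@dataclass
class ParameterSet:
    """All model constants, with published defaults.

    Units: lengths in lattice sites (s.u.), time in Monte Carlo steps (MCS),
    concentrations in arbitrary units. Calibration: 1 s.u. = 3.5 um,
    1 MCS = 10 s.
    """

    # --- diffusible substances -------------------------------------------
    S_A: float = 5.0        # co-attractant secretion by NC sites [1/MCS]
    S_S: float = 20.0       # Sdf1 secretion by placode sites [1/MCS]
    S_I: float = 0.7        # inhibitor secretion by placode sites [1/MCS]
    D_A: float = 8.0        # diffusion [s.u.^2/MCS]
    D_S: float = 8.0
    D_I: float = 0.005
    delta_A: float = 0.006  # decay [1/MCS]
    delta_S: float = 0.006
    delta_I: float = 0.0006
    U_S: float = 20.0       # Sdf1 uptake by NC sites [1/MCS]; clamped at c>=0
    capacity_A: float = 400.0   # co-attractant carrying capacity [a.u.]
    capacity_S: float = 1.0     # Sdf1 carrying capacity [a.u.]
    capacity_I: float = 1.0     # inhibitor carrying capacity [a.u.]

    # --- chemotaxis weights (NC only; placodes do not chemotax) ----------
    lambda_A: float = 1.0
    lambda_S_eff: float = 150.0  # effective Sdf1 weight (150 * lambda_S, lambda_S = 1)
    lambda_I: float = -100.0     # negative: inhibitor repels NC

    # --- self-propulsion and polarity persistence ------------------------
    lambda_P_NC: float = 6.0
    lambda_P_PL: float = 12.0
    deltaP_NC_free: float = 0.3
    deltaP_NC_contact: float = 0.08
    deltaP_PL_free: float = 0.5
    deltaP_PL_contact: float = 0.1

    # --- contact inhibition of locomotion --------------------------------
    lambda_CIL: float = 0.5
    p_CIL_NC: float = 0.3   # switching probability per new contact, NC cells
    p_CIL_PL: float = 1.0   # same for placodes (sweeps lower this)

    # --- adhesion and volume ---------------------------------------------
    lambda_M_pair: np.ndarray = field(default_factory=_default_lambda_M)
    lambda_V: float = 5.0
    V_T: float = 25.0       # target area [s.u.^2]
    J_matrix: np.ndarray = field(default_factory=_default_J)

    # --- geometry, time, engine knobs ------------------------------------
    temperature: float = 2.5    # Boltzmann temperature T of the acceptance rule
    polarity_mode: str = "unit"  # W motility: "unit" p-hat (as published),
                                 # "raw" p, or "capped" (raw below |p|=1)
    lattice_width: int = 180    # AP axis (x)
    lattice_height: int = 95    # DV axis (y); NC start at low y (dorsal)
    halo: int = 100             # field-only extension on all four sides
    total_MCS: int = 3600
    field_substeps_per_MCS: int = 40  # substeps for the stiffest substance
    p_medium_retraction: float = 0.1
    p_link_form: float = 0.1
    link_break_divisor: float = 100.0
    emt_enabled: bool = True    # continuous dorsal insertion of new NC cells

    # --- calibration to physical units -----------------------------------
    microns_per_site: float = 3.5
    seconds_per_MCS: float = 10.0

    def __post_init__(self) -> None:
        self.lambda_M_pair = np.asarray(self.lambda_M_pair, dtype=np.float64)
        self.J_matrix = np.asarray(self.J_matrix, dtype=np.float64)

    # ------------------------------------------------------------------
    @property
    def d0(self) -> float:
        """Equilibrium distance of persistently linked cells, 2*sqrt(V_T/pi)."""
        return 2.0 * math.sqrt(self.V_T / math.pi)

    def diffusion(self, substance: str) -> float:
        return {"A": self.D_A, "S": self.D_S, "I": self.D_I}[substance]

    def decay(self, substance: str) -> float:
        return {"A": self.delta_A, "S": self.delta_S, "I": self.delta_I}[substance]

    def capacity(self, substance: str) -> float:
        return {"A": self.capacity_A, "S": self.capacity_S,
                "I": self.capacity_I}[substance]

    def substeps_for(self, substance: str) -> int:
        """Substep count for one substance.

        ``field_substeps_per_MCS`` applies to the substance with the largest
        diffusion coefficient; substances with smaller D use proportionally
        fewer substeps under the same D*dt stability bound.
        """
        d_max = max(self.D_A, self.D_S, self.D_I)
        if d_max <= 0:
            return 1
        n = math.ceil(self.field_substeps_per_MCS * self.diffusion(substance) / d_max)
        return max(1, min(self.field_substeps_per_MCS, n))

    # --- packed views consumed by the numba kernels -------------------
    def chemotaxis_weights(self) -> np.ndarray:
        """lam[type, substance]; only NC cells chemotax."""
        lam = np.zeros((3, 3), dtype=np.float64)
        lam[NC] = (self.lambda_A, self.lambda_S_eff, self.lambda_I)
        return lam

    def propulsion_weights(self) -> np.ndarray:
        return np.array([0.0, self.lambda_P_NC, self.lambda_P_PL])

    def polarity_decay(self) -> tuple[np.ndarray, np.ndarray]:
        free = np.array([0.0, self.deltaP_NC_free, self.deltaP_PL_free])
        contact = np.array([0.0, self.deltaP_NC_contact, self.deltaP_PL_contact])
        return free, contact

    def cil_probabilities(self) -> np.ndarray:
        return np.array([0.0, self.p_CIL_NC, self.p_CIL_PL])

    def source_rates(self) -> np.ndarray:
        """rate[type, substance]; negative values are uptake."""
        rates = np.zeros((3, 3), dtype=np.float64)
        rates[NC, 0] = self.S_A
        rates[NC, 1] = -self.U_S
        rates[PL, 1] = self.S_S
        rates[PL, 2] = self.S_I
        return rates

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "ParameterSet":
        """Return a copy with named fields replaced.

        Two virtual names address single entries of the pair matrices:
        ``lambda_M_NC_NC`` and ``lambda_M_NC_PL``.
        """
        virt = {}
        for key in ("lambda_M_NC_NC", "lambda_M_NC_PL", "lambda_M_PL_PL"):
            if key in overrides:
                virt[key] = float(overrides.pop(key))
        names = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - names
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        new = dataclasses.replace(self, **overrides)
        if "lambda_M_pair" not in overrides:
            new.lambda_M_pair = self.lambda_M_pair.copy()
        if "J_matrix" not in overrides:
            new.J_matrix = self.J_matrix.copy()
        pairs = {"lambda_M_NC_NC": (NC, NC), "lambda_M_NC_PL": (NC, PL),
                 "lambda_M_PL_PL": (PL, PL)}
        for key, (a, b) in pairs.items():
            if key in virt:
                new.lambda_M_pair[a, b] = new.lambda_M_pair[b, a] = virt[key]
        return new

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_M_pair"] = self.lambda_M_pair.tolist()
        d["J_matrix"] = self.J_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        if "lambda_M_pair" in d:
            d["lambda_M_pair"] = np.asarray(d["lambda_M_pair"], dtype=np.float64)
        if "J_matrix" in d:
            d["J_matrix"] = np.asarray(d["J_matrix"], dtype=np.float64)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(yaml_dump(self))

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_YAML_COMMENTS = {
    "S_A": "S_A: co-attractant (C3a) secretion rate [1/MCS]",
    "S_S": "S_S: Sdf1 secretion rate [1/MCS]",
    "S_I": "S_I: inhibitor secretion rate [1/MCS]",
    "D_A": "D_A: co-attractant diffusion [s.u.^2/MCS]",
    "D_S": "D_S: Sdf1 diffusion [s.u.^2/MCS]",
    "D_I": "D_I: inhibitor diffusion [s.u.^2/MCS]",
    "delta_A": "delta_A: co-attractant decay [1/MCS]",
    "delta_S": "delta_S: Sdf1 decay [1/MCS]",
    "delta_I": "delta_I: inhibitor decay [1/MCS]",
    "U_S": "Sdf1 uptake by NC sites [1/MCS] (model leaves the rate open)",
    "lambda_A": "lambda_A: co-attraction chemotaxis weight (NC)",
    "lambda_S_eff": "lambda_S*: effective Sdf1 chemotaxis weight, 150 * lambda_S with lambda_S = 1",
    "lambda_I": "lambda_I: inhibitor chemotaxis weight (NC; negative = repulsion)",
    "lambda_P_NC": "lambda_P(NC): self-propulsion strength",
    "lambda_P_PL": "lambda_P(PL): self-propulsion strength",
    "deltaP_NC_free": "delta_P(NC, free): polarity decay without contact",
    "deltaP_NC_contact": "delta_P(NC, contact): polarity decay with contact",
    "deltaP_PL_free": "delta_P(PL, free): polarity decay without contact",
    "deltaP_PL_contact": "delta_P(PL, contact): polarity decay with contact",
    "lambda_CIL": "lambda_CIL: CIL repolarization strength",
    "p_CIL_NC": "p(CIL) for NC cells, per new contact",
    "p_CIL_PL": "p(CIL) for placode cells, per new contact",
    "lambda_M_pair": "lambda_M: persistent-adhesion strength per (medium, NC, PL) pair",
    "lambda_V": "lambda_V: cell incompressibility",
    "V_T": "V_T: target cell area [s.u.^2]",
    "J_matrix": "J: contact energies over (medium, NC, PL) pairs",
    "halo": "field-only lattice extension on all four sides [s.u.]",
    "microns_per_site": "1 lattice site = 3.5 um",
    "seconds_per_MCS": "1 MCS = 10 s",
}


def yaml_dump(params: ParameterSet) -> str:
    """Render a ParameterSet as YAML with a comment per model symbol."""
    lines = ["# ncstream parameter set"]
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if isinstance(value, np.ndarray):
            value = value.tolist()
        comment = _YAML_COMMENTS.get(f.name)
        if comment:
            lines.append(f"# {comment}")
        rendered = yaml.safe_dump(value, default_flow_style=True).strip()
        if rendered.endswith("..."):
            rendered = rendered[:-3].strip()
        lines.append(f"{f.name}: {rendered}")
    return "\n".join(lines) + "\n"


def validate_params(params: ParameterSet) -> list[str]:
    """Check ParameterSet invariants; returns violations (empty list = valid).

    Reports, never raises: each entry names the offending field and rule.
    """
    v: list[str] = []
    for name in ("S_A", "S_S", "S_I", "D_A", "D_S", "D_I",
                 "delta_A", "delta_S", "delta_I", "U_S"):
        if getattr(params, name) < 0:
            v.append(f"{name}: must be >= 0")
    if params.V_T <= 0:
        v.append("V_T: must be > 0")
    if params.lambda_V < 0:
        v.append("lambda_V: must be >= 0")
    if not np.allclose(params.J_matrix, params.J_matrix.T):
        v.append("J_matrix: must be symmetric")
    if not np.allclose(params.lambda_M_pair, params.lambda_M_pair.T):
        v.append("lambda_M_pair: must be symmetric")
    for name in ("p_CIL_NC", "p_CIL_PL", "p_medium_retraction", "p_link_form"):
        p = getattr(params, name)
        if not 0.0 <= p <= 1.0:
            v.append(f"{name}: must lie in [0, 1]")
    if params.lattice_width <= 0 or params.lattice_height <= 0:
        v.append("lattice_width/lattice_height: must be positive")
    if params.field_substeps_per_MCS < 1:
        v.append("field_substeps_per_MCS: must be >= 1")
    else:
        for s in SUBSTANCES:
            D = params.diffusion(s)
            n = params.substeps_for(s)
            if D * (1.0 / n) > STABILITY_LIMIT:
                v.append(
                    f"field_substeps_per_MCS: explicit-scheme stability violated for "
                    f"substance {s}: D*dt = {D / n:.3g} > {STABILITY_LIMIT}"
                )
    if params.temperature <= 0:
        v.append("temperature: must be > 0")
    if params.polarity_mode not in ("unit", "raw", "capped"):
        v.append("polarity_mode: must be unit, raw or capped")
    if params.total_MCS < 0:
        v.append("total_MCS: must be >= 0")
    if params.halo < 0:
        v.append("halo: must be >= 0")
    return v


_POLARITY_MODES = {"unit": 0, "raw": 1, "capped": 2}


def polarity_mode_code(params: ParameterSet) -> int:
    """Integer code of the polarity mode for the compiled kernels."""
    return _POLARITY_MODES[params.polarity_mode]
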