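"""Scenario presets, replicate management, parameter sweeps, morphology maps.

A *scenario* is a named parameter configuration run for several replicate
seeds; its morphology is summarized by the ensemble density-probability map
and the stream width/length measured from it. The presets mirror the
perturbation experiments of the study this simulator reproduces:

``control``
    published defaults.
``no_sdf1_chemotaxis``
    Sdf1 chemotaxis removed from NC (lambda_S_eff = 0) — no streams form.
``no_placode_cil``
    CIL removed from placodes (p_CIL_PL = 0) — uniform broad-front invasion.
``low_adhesion`` / ``high_adhesion``
    NC-NC persistent-adhesion spring endpoints (lambda_M = 0 / 2).
``width_0.5`` / ``width_1.5`` / ``width_2``
    relative system widths with the initial cell rows (linear densities)
    kept constant.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .engine import Simulation
from .fields import FieldNumericsError
from .metrics import DensityMap, density_probability, width_length
from .params import ParameterSet
from .state import PATCH

PRESETS: dict[str, dict] = {
    "control": {},
    "no_sdf1_chemotaxis": {"lambda_S_eff": 0.0},
    "no_placode_cil": {"p_CIL_PL": 0.0},
    "low_adhesion": {"lambda_M_NC_NC": 0.0},
    "high_adhesion": {"lambda_M_NC_NC": 2.0},
    "width_0.5": {"width_factor": 0.5},
    "width_1.5": {"width_factor": 1.5},
    "width_2": {"width_factor": 2.0},
}


@dataclass
class ScenarioConfig:
    """One scenario: base parameters, overrides, replicates, sampling."""

    overrides: dict = dc_field(default_factory=dict)
    width_factor: float = 1.0        # scales lattice_width; cell rows fixed
    n_replicates: int = 5
    base_seed: int = 1
    seeds: list[int] | None = None   # explicit list wins over base_seed
    mcs: int | None = None           # None: params.total_MCS
    sample_interval: int = 200       # MCS between W/L samples
    base: ParameterSet = dc_field(default_factory=ParameterSet)

    @classmethod
    def from_preset(cls, name: str, **kwargs) -> "ScenarioConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        overrides = dict(PRESETS[name])
        wf = overrides.pop("width_factor", 1.0)
        overrides.update(kwargs.pop("overrides", {}))
        return cls(overrides=overrides, width_factor=wf, **kwargs)

    def resolve_params(self) -> ParameterSet:
        p = self.base.replace(**self.overrides)
        if self.width_factor != 1.0:
            if self.width_factor <= 0:
                raise ValueError("width_factor must be > 0")
            w = int(round(self.base.lattice_width * self.width_factor
                          / PATCH)) * PATCH
            p = p.replace(lattice_width=max(PATCH, w))
        return p

    def resolve_seeds(self) -> list[int]:
        if self.seeds is not None:
            seeds = list(self.seeds)
        else:
            seeds = [self.base_seed + i for i in range(self.n_replicates)]
        if len(set(seeds)) != len(seeds):
            raise ValueError("replicate seeds must be distinct")
        return seeds

    def digest(self) -> str:
        p = self.resolve_params().to_dict()
        blob = json.dumps({"params": p, "seeds": self.resolve_seeds(),
                           "mcs": self.mcs, "version": _version},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReplicateResult:
    """Outcome of one replicate run."""

    seed: int
    W: float
    L: float
    n_streams: int
    mean_nc_speed: float
    mean_pl_speed: float
    density: DensityMap
    final_sigma: np.ndarray
    final_types: np.ndarray
    series: pd.DataFrame          # sampled W/L/stream-count time series
    log: object = None            # engine RunLog (per-MCS conc and speed)
    error: str | None = None


@dataclass
class ScenarioResult:
    """Replicate-aggregated scenario outcome."""

    config: ScenarioConfig
    replicates: list[ReplicateResult]
    pooled_density: DensityMap
    W: float                      # from the pooled (count-weighted) rho
    L: float
    W_values: np.ndarray          # per-replicate (NaN = no-stream sentinel)
    L_values: np.ndarray
    provenance: dict

    @staticmethod
    def _sem(values: np.ndarray) -> float:
        v = values[np.isfinite(values)]
        if v.size < 2:
            return np.nan
        return float(v.std(ddof=1) / np.sqrt(v.size))

    @property
    def W_sem(self) -> float:
        return self._sem(self.W_values)

    @property
    def L_sem(self) -> float:
        return self._sem(self.L_values)

    @property
    def no_stream_fraction(self) -> float:
        """Fraction of replicates with an undefined stream width."""
        return float(np.mean(~np.isfinite(self.W_values)))

    @property
    def mean_stream_count(self) -> float:
        return float(np.mean([r.n_streams for r in self.replicates
                              if r.error is None]))


def run_replicate(params: ParameterSet, seed: int, mcs: int | None = None,
                  sample_interval: int = 200) -> ReplicateResult:
    """Run one replicate to ``mcs`` and measure it."""
    from .metrics import count_streams  # local import to avoid cycle noise
    from .params import NC, PL

    sim = Simulation(params, seed)
    rows = []

    def sample(st):
        mask = st.nc_mask()
        w, l = width_length(density_probability(mask))
        rows.append({"mcs": st.mcs, "W": w, "L": l,
                     "n_streams": count_streams(mask)})

    sim.run(mcs, callback=sample, callback_interval=sample_interval)
    st = sim.state
    mask = st.nc_mask()
    dmap = density_probability(mask)
    W, L = width_length(dmap)
    log = sim.log
    pl_speed = np.nan
    d = st.disp[1:st.n_cells + 1]
    pl = st.cell_type[1:st.n_cells + 1] == PL
    if pl.any():
        pl_speed = float(np.hypot(d[pl, 0], d[pl, 1]).mean())
    return ReplicateResult(
        seed=seed, W=W, L=L, n_streams=count_streams(mask),
        mean_nc_speed=float(np.nanmean(log.nc_speed)),
        mean_pl_speed=pl_speed,
        density=dmap,
        final_sigma=st.sigma.copy(),
        final_types=st.cell_type[:st.n_cells + 1].copy(),
        series=pd.DataFrame(rows),
        log=log,
    )


def run_scenario(config: ScenarioConfig, progress: bool = False) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate.

    A replicate that fails numerically is recorded with its error and the
    scenario continues with the remaining seeds.
    """
    params = config.resolve_params()
    seeds = config.resolve_seeds()
    t_start = time.time()
    reps: list[ReplicateResult] = []
    for seed in seeds:
        try:
            reps.append(run_replicate(params, seed, config.mcs,
                                      config.sample_interval))
        except FieldNumericsError as exc:  # pragma: no cover - defensive
            reps.append(ReplicateResult(
                seed=seed, W=np.nan, L=np.nan, n_streams=0,
                mean_nc_speed=np.nan, mean_pl_speed=np.nan,
                density=DensityMap(np.zeros((1, 1)), np.zeros((1, 1)),
                                   defined=False),
                final_sigma=np.zeros((0, 0), dtype=np.int64),
                final_types=np.zeros(0, dtype=np.int64),
                series=pd.DataFrame(), error=str(exc)))
    ok = [r for r in reps if r.error is None]
    pooled = DensityMap.pool([r.density for r in ok])
    W, L = width_length(pooled)
    return ScenarioResult(
        config=config, replicates=reps, pooled_density=pooled, W=W, L=L,
        W_values=np.array([r.W for r in ok]),
        L_values=np.array([r.L for r in ok]),
        provenance={"config_hash": config.digest(), "seeds": seeds,
                    "version": _version,
                    "wall_seconds": round(time.time() - t_start, 1)},
    )


# ----------------------------------------------------------------------
def width_sweep(widths, config: ScenarioConfig, depth: float = 0.5):
    """Stream count vs relative system width, with a linear fit.

    The initial number of cell rows is kept constant across widths, so the
    linear cell density along the AP axis is identical. Returns
    ``(table, fit)`` where ``fit`` is (slope, intercept) of an ordinary
    least-squares line through the ensemble-mean counts, or None when fewer
    than two widths are given (counts are still reported).
    """
    rows = []
    for w in widths:
        cfg = ScenarioConfig(
            overrides=dict(config.overrides), width_factor=float(w),
            n_replicates=config.n_replicates, base_seed=config.base_seed,
            seeds=config.seeds, mcs=config.mcs,
            sample_interval=config.sample_interval, base=config.base)
        res = run_scenario(cfg)
        counts = [r.n_streams for r in res.replicates if r.error is None]
        rows.append({"w": float(w), "mean_streams": float(np.mean(counts)),
                     "sem_streams": ScenarioResult._sem(np.asarray(counts, float)),
                     "n": len(counts)})
    table = pd.DataFrame(rows)
    fit = None
    if len(table) >= 2:
        slope, intercept = np.polyfit(table["w"], table["mean_streams"], 1)
        fit = (float(slope), float(intercept))
    return table, fit


def sweep_1d(param: str, values, config: ScenarioConfig) -> pd.DataFrame:
    """Ensemble W/L (with SEM) along one parameter axis.

    Replicates whose width is undefined (no-stream outcomes) are tallied in
    ``no_stream_fraction`` and excluded from the means rather than imputed.
    """
    rows = []
    for v in values:
        overrides = dict(config.overrides)
        overrides[param] = float(v)
        cfg = ScenarioConfig(
            overrides=overrides, width_factor=config.width_factor,
            n_replicates=config.n_replicates, base_seed=config.base_seed,
            seeds=config.seeds, mcs=config.mcs,
            sample_interval=config.sample_interval, base=config.base)
        res = run_scenario(cfg)
        rows.append({
            "value": float(v),
            "W": float(np.nanmean(res.W_values)) if np.isfinite(res.W_values).any() else np.nan,
            "W_sem": res.W_sem,
            "L": float(np.nanmean(res.L_values)) if np.isfinite(res.L_values).any() else np.nan,
            "L_sem": res.L_sem,
            "W_pooled": res.W, "L_pooled": res.L,
            "no_stream_fraction": res.no_stream_fraction,
            "n": len(res.replicates),
        })
    return pd.DataFrame(rows)


def morphology_map(param_x: str, values_x, param_y: str, values_y,
                   config: ScenarioConfig) -> pd.DataFrame:
    """Full-factorial W/L grid over two parameters (box-glyph map data).

    Each row carries the ensemble stream width and length plus their
    relative standard errors (the shading axis of the published maps).
    """
    rows = []
    for vy in values_y:
        for vx in values_x:
            overrides = dict(config.overrides)
            overrides[param_x] = float(vx)
            overrides[param_y] = float(vy)
            cfg = ScenarioConfig(
                overrides=overrides, width_factor=config.width_factor,
                n_replicates=config.n_replicates, base_seed=config.base_seed,
                seeds=config.seeds, mcs=config.mcs,
                sample_interval=config.sample_interval, base=config.base)
            res = run_scenario(cfg)
            W = float(np.nanmean(res.W_values)) if np.isfinite(res.W_values).any() else np.nan
            L = float(np.nanmean(res.L_values)) if np.isfinite(res.L_values).any() else np.nan
            rows.append({
                param_x: float(vx), param_y: float(vy), "W": W, "L": L,
                "W_rel_sem": res.W_sem / W if W and np.isfinite(W) else np.nan,
                "L_rel_sem": res.L_sem / L if L and np.isfinite(L) else np.nan,
                "no_stream_fraction": res.no_stream_fraction,
            })
    return pd.DataFrame(rows)
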