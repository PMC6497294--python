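"""Snapshots, rendering, metrics files and run manifests.

Snapshot files are compressed numpy archives holding the label lattice, the
per-cell registry arrays and the three concentration grids — enough to
re-measure any morphometric offline. Rendering follows the published color
convention: NC orange, placodes red, medium black; concentration fields as
normalized heatmaps.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .params import NC, PL, ParameterSet, SUB_INDEX
from .state import SimulationState

NC_COLOR = (255, 140, 0)
PL_COLOR = (217, 26, 26)


def write_snapshot(state: SimulationState, path) -> Path:
    """Save lattice, registry and fields as one compressed archive."""
    path = Path(path)
    n = state.n_cells
    try:
        np.savez_compressed(
            path,
            sigma=state.sigma,
            cell_type=state.cell_type[:n + 1],
            area=state.area[:n + 1],
            sum_x=state.sum_x[:n + 1], sum_y=state.sum_y[:n + 1],
            pol=state.pol[:n + 1],
            cil_cnt=state.cil_cnt[:n + 1],
            link_list=state.link_list[:n + 1],
            link_cnt=state.link_cnt[:n + 1],
            conc=state.fields.conc,
            halo=np.int64(state.fields.halo),
            mcs=np.int64(state.mcs),
            rng_seed=np.int64(state.rng_seed),
        )
    except OSError as exc:
        raise OSError(f"cannot write snapshot to {path}: {exc}") from exc
    return path.with_suffix(".npz") if path.suffix != ".npz" else path


def load_snapshot(path) -> dict:
    """Load a snapshot archive into a plain dict of arrays."""
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def type_image(sigma: np.ndarray, cell_type: np.ndarray) -> np.ndarray:
    """RGB image (height x width x 3, uint8) of the cell configuration."""
    tm = cell_type[sigma]
    img = np.zeros(tm.shape + (3,), dtype=np.uint8)
    img[tm == NC] = NC_COLOR
    img[tm == PL] = PL_COLOR
    return img.transpose(1, 0, 2)


def field_image(conc: np.ndarray, halo: int, cmap: str = "magma") -> np.ndarray:
    """RGB heatmap (uint8) of one concentration grid, normalized to its max,
    cropped to the cell lattice."""
    import matplotlib

    grid = conc[halo:-halo, halo:-halo] if halo else conc
    peak = grid.max()
    norm = grid / peak if peak > 0 else grid
    rgba = matplotlib.colormaps[cmap](norm.T)
    return (rgba[..., :3] * 255).astype(np.uint8)


def render_snapshot(snapshot: dict, out_prefix) -> list[Path]:
    """Write cell-configuration and per-substance field PNGs."""
    import imageio.v3 as iio

    out_prefix = Path(out_prefix)
    paths = []
    p = out_prefix.with_name(out_prefix.name + "_cells.png")
    iio.imwrite(p, type_image(snapshot["sigma"], snapshot["cell_type"]))
    paths.append(p)
    halo = int(snapshot["halo"])
    for name, idx in SUB_INDEX.items():
        p = out_prefix.with_name(f"{out_prefix.name}_field_{name}.png")
        iio.imwrite(p, field_image(snapshot["conc"][idx], halo))
        paths.append(p)
    return paths


def write_movie(frames: list[np.ndarray], path, fps: int = 20) -> Path:
    """Write an image sequence as a movie (container from the extension)."""
    import imageio.v2 as iio

    path = Path(path)
    iio.mimwrite(path, frames, fps=fps)
    return path


# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Provenance record written before and finalized after a run.

    Carries the fully-resolved parameter dump, the seed list and a checksum
    inventory of every output file, sufficient for exact re-execution and
    for detecting post-hoc modification.
    """

    def __init__(self, out_dir, params: ParameterSet, seeds: list[int],
                 command: str = "", extra: dict | None = None):
        self.path = Path(out_dir) / "manifest.json"
        self.data = {
            "command": command,
            "params": params.to_dict(),
            "seeds": list(map(int, seeds)),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "finished": None,
            "files": {},
        }
        if extra:
            self.data.update(extra)

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)

    def finalize(self, files) -> None:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.data["files"] = {
            str(Path(f).name): _sha256(Path(f)) for f in files
        }
        self.write()

    @staticmethod
    def verify(manifest_path) -> dict:
        """Re-hash the inventoried files; returns {name: ok?}."""
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            data = json.load(fh)
        out = {}
        for name, digest in data.get("files", {}).items():
            p = manifest_path.parent / name
            out[name] = p.exists() and _sha256(p) == digest
        return out
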