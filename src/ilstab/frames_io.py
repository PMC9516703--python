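"""FrameSet interchange as multi-frame XYZ plus a JSON label sidecar.

XYZ carries only element symbols and coordinates, so species labels,
molecule ids, the periodic box and named selections travel in a JSON
sidecar written next to the coordinate file.  Coordinate frames are read
and written through MDAnalysis, which also accepts multi-model PDB input
for externally produced trajectories.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .errors import IntegrityError
from .trajectory import FrameSet

__all__ = ["save_frameset", "load_frameset"]

_ELEMENT = {"solute": "C", "cation": "N", "anion": "Cl", "water": "O"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def save_frameset(frames: FrameSet, path: Union[str, Path]) -> None:
    """Write frames as multi-frame XYZ with a JSON sidecar of labels."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(frames.n_atoms, trajectory=True)
    elements = [_ELEMENT.get(str(s), "X") for s in frames.species]
    u.add_TopologyAttr("names", elements)
    with mda.Writer(str(path), frames.n_atoms) as writer:
        for fr in range(frames.n_frames):
            u.atoms.positions = frames.frames[fr]
            writer.write(u.atoms)
    sidecar = {
        "species": [str(s) for s in frames.species],
        "molecule_ids": frames.molecule_ids.tolist(),
        "box": frames.box.tolist(),
        "selections": {k: np.asarray(v).tolist() for k, v in frames.selections.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def load_frameset(path: Union[str, Path]) -> FrameSet:
    """Read a multi-frame XYZ (or multi-model PDB) and its label sidecar."""
    import MDAnalysis as mda

    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise IntegrityError(f"label sidecar {sidecar_file} not found")
    sidecar = json.loads(sidecar_file.read_text())
    u = mda.Universe(str(path))
    frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
    if frames and frames[0].shape[0] != len(sidecar["species"]):
        raise IntegrityError("sidecar species count does not match atom count")
    return FrameSet(
        frames=frames,
        species=np.array(sidecar["species"], dtype=object),
        molecule_ids=np.array(sidecar["molecule_ids"]),
        box=np.array(sidecar["box"]),
        selections={k: np.array(v, dtype=int) for k, v in sidecar["selections"].items()},
    )
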