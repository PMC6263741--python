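"""On-disk containers for scenes, observation stacks, dictionaries, estimates.

Observation stacks and dictionaries are stored as NumPy ``.npz`` archives
with a JSON header carrying the acquisition/training metadata; scenes and
estimates are stored as paired 32-bit float planes (amplitude, phase) in
multi-page TIFF plus a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .dictlearn import Dictionary
from .forward import MaskSet, ObservationSet
from .scenes import AmplitudeMap, ComplexScene, PhaseSurface

__all__ = [
    "save_observations",
    "load_observations",
    "save_dictionary",
    "load_dictionary",
    "save_scene",
    "load_scene",
    "save_estimate",
    "load_estimate",
]


def save_observations(path: str | Path, obs: ObservationSet, masks: MaskSet) -> None:
    header = {
        "S": int(obs.S),
        "shape": list(masks.image_shape),
        "noise_model": obs.noise_model,
        "chi": obs.chi,
        "sigma": obs.sigma,
        "seed": obs.seed,
        "mask_seed": masks.seed,
    }
    np.savez(path, z=obs.z, mask_phases=masks.phases, header=json.dumps(header))


def load_observations(path: str | Path) -> tuple[ObservationSet, MaskSet]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        obs = ObservationSet(
            z=data["z"],
            noise_model=header["noise_model"],
            chi=header.get("chi"),
            sigma=header.get("sigma"),
            seed=header.get("seed"),
        )
        masks = MaskSet(phases=data["mask_phases"], seed=header.get("mask_seed"))
    return obs, masks


def save_dictionary(path: str | Path, dictionary: Dictionary, provenance: str = "") -> None:
    w2, k = dictionary.atoms.shape
    header = {"patch_dim": w2, "k": k, "provenance": provenance}
    np.savez(path, atoms=dictionary.atoms, header=json.dumps(header))


def load_dictionary(path: str | Path) -> Dictionary:
    with np.load(path, allow_pickle=False) as data:
        return Dictionary(atoms=data["atoms"])


def save_scene(path: str | Path, scene: ComplexScene) -> None:
    path = Path(path)
    planes = np.stack(
        [scene.amplitude.values.astype(np.float32), scene.phase.values.astype(np.float32)]
    )
    tifffile.imwrite(path, planes)
    sidecar = {
        "kind": scene.phase.kind,
        "group": scene.group,
        "seed": scene.phase.seed,
        "peak": scene.phase.peak,
        "name": scene.name,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_scene(path: str | Path) -> ComplexScene:
    path = Path(path)
    planes = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    amp = AmplitudeMap(values=planes[0].astype(float), group=meta.get("group", 0))
    phase = PhaseSurface(
        values=planes[1].astype(float),
        kind=meta.get("kind", "custom"),
        peak=meta.get("peak", float("nan")),
        seed=meta.get("seed"),
    )
    return ComplexScene.from_parts(amp, phase, meta.get("group", 0), name=meta.get("name", ""))


def save_estimate(prefix: str | Path, x: np.ndarray) -> None:
    """Amplitude/phase float TIFF pair plus the complex field as .npz."""
    prefix = Path(prefix)
    planes = np.stack([np.abs(x).astype(np.float32), np.angle(x).astype(np.float32)])
    tifffile.imwrite(prefix.with_suffix(".tif"), planes)
    np.savez(prefix.with_suffix(".npz"), field=x)


def load_estimate(prefix: str | Path) -> np.ndarray:
    with np.load(Path(prefix).with_suffix(".npz"), allow_pickle=False) as data:
        return data["field"]
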