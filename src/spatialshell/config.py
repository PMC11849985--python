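"""Run configuration: validation, defaults and serialization.

A run is fully described by a flat mapping (YAML file or CLI flags): input
paths, lattice pitch, marker lists, denoise kernel, shell geometry,
clustering parameters and seeds.  Validation is all-at-once — every problem
is reported in a single aggregated error — and the normalized config is
serialized alongside the outputs for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "load_config"]

_KNOWN_KEYS = {
    "matrix", "cells", "outdir", "pitch", "positive_markers", "negative_markers",
    "kernel", "shell_width", "shell_lower", "shell_upper", "n_pcs", "k_neighbors",
    "resolution", "embedding", "seed", "cluster", "trajectory_root",
}


@dataclass
class RunConfig:
    matrix: str
    cells: str
    outdir: str
    positive_markers: list[str]
    negative_markers: list[str] = field(default_factory=list)
    pitch: float = 10.0
    kernel: int = 3
    shell_width: float = 30.0
    shell_lower: float = -120.0
    shell_upper: float = 150.0
    n_pcs: int = 50
    k_neighbors: int = 15
    resolution: float = 1.0
    embedding: str = "umap"
    seed: int = 0
    cluster: bool = False
    trajectory_root: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def validate_config(raw: dict) -> RunConfig:
    """Normalize, default and type-check a raw config mapping.

    All violations are aggregated into one ``ValueError`` so a user fixes a
    config in a single pass; no pipeline stage runs on an invalid config.
    """
    errors: list[str] = []
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        errors.append(f"unknown keys: {unknown}")

    def need(key):
        if key not in raw or raw[key] in (None, ""):
            errors.append(f"missing required key: {key}")
            return None
        return raw[key]

    matrix = need("matrix")
    cells = need("cells")
    outdir = raw.get("outdir", "spatialshell_out")
    positive = raw.get("positive_markers") or []
    if isinstance(positive, str):
        positive = [positive]
    if not positive:
        errors.append("positive_markers must list at least one gene")
    negative = raw.get("negative_markers") or []
    if isinstance(negative, str):
        negative = [negative]
    if set(positive) & set(negative):
        errors.append("positive and negative marker lists overlap")

    pitch = float(raw.get("pitch", 10.0))
    if pitch <= 0:
        errors.append(f"pitch must be positive, got {pitch}")
    kernel = int(raw.get("kernel", 3))
    if kernel < 3 or kernel % 2 == 0:
        errors.append(f"kernel must be an odd integer >= 3, got {kernel}")
    width = float(raw.get("shell_width", 30.0))
    lower = float(raw.get("shell_lower", -120.0))
    upper = float(raw.get("shell_upper", 150.0))
    if width <= 0:
        errors.append("shell_width must be positive")
    elif lower >= upper:
        errors.append("shell_lower must be below shell_upper")
    elif abs((upper - lower) / width - round((upper - lower) / width)) > 1e-6:
        errors.append("shell range must be an integer multiple of shell_width")
    n_pcs = int(raw.get("n_pcs", 50))
    k_neighbors = int(raw.get("k_neighbors", 15))
    resolution = float(raw.get("resolution", 1.0))
    if min(n_pcs, k_neighbors) < 1 or resolution <= 0:
        errors.append("n_pcs, k_neighbors and resolution must be positive")
    embedding = str(raw.get("embedding", "umap"))
    if embedding not in ("umap", "tsne"):
        errors.append(f"embedding must be 'umap' or 'tsne', got {embedding!r}")
    seed = int(raw.get("seed", 0))
    root = raw.get("trajectory_root")

    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        matrix=str(matrix),
        cells=str(cells),
        outdir=str(outdir),
        positive_markers=[str(g) for g in positive],
        negative_markers=[str(g) for g in negative],
        pitch=pitch,
        kernel=kernel,
        shell_width=width,
        shell_lower=lower,
        shell_upper=upper,
        n_pcs=n_pcs,
        k_neighbors=k_neighbors,
        resolution=resolution,
        embedding=embedding,
        seed=seed,
        cluster=bool(raw.get("cluster", False)),
        trajectory_root=None if root is None else int(root),
    )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    return validate_config(raw)
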