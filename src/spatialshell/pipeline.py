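"""End-to-end pipeline: grid → detect → distance → stratify → profile (→ cluster).

Each stage's artifact is written under the configured output directory and
listed with a checksum in ``manifest.json`` next to a snapshot of the
validated config, so a run can be audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics, detect, distance, grid_io, profiles, stratify
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_mask_images(mask: np.ndarray, labels: np.ndarray, dist: np.ndarray, outdir: Path) -> list[Path]:
    """Raster artifacts: 0/255 mask PNG, 16-bit label TIFF, float32 distance TIFF."""
    import imageio.v3 as iio
    import tifffile

    paths = []
    p = outdir / "domain_mask.png"
    iio.imwrite(p, (mask.astype(np.uint8) * 255))
    paths.append(p)
    p = outdir / "domain_labels.tif"
    tifffile.imwrite(p, labels.astype(np.uint16))
    paths.append(p)
    p = outdir / "distance_um.tif"
    tifffile.imwrite(p, dist.astype(np.float32))
    paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the artifact manifest.

    Any stage failure aborts with the stage name prepended to the error.
    Deterministic stages produce identical checksums on rerun with the same
    config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "load"
    try:
        cells = grid_io.load_cells(config.matrix, config.cells)

        stage = "grid"
        grid = grid_io.build_grid(cells, pitch=config.pitch)
        artifacts.append(grid_io.write_grid(grid, outdir / "grid.csv"))
        artifacts.append(outdir / "grid.csv.json")

        stage = "detect"
        markers = detect.MarkerSpec(config.positive_markers, config.negative_markers)
        pre = detect.detect_pre_domain(grid, markers)
        mask = detect.median_denoise(pre, kernel=config.kernel)
        boundary = detect.extract_boundary(mask)
        labeling = detect.segment_domains(mask)
        logger.info("detected %d spatial domains", labeling.n_domains)

        stage = "distance"
        field = distance.compute_distance_field(mask, boundary, pitch=config.pitch)
        artifacts += _write_mask_images(mask, labeling.labels, field.values, outdir)

        stage = "stratify"
        shells = stratify.stratify_shells(
            field, width=config.shell_width,
            lower=config.shell_lower, upper=config.shell_upper,
        )
        rows = []
        for interval in shells.intervals:
            shell_mask = shells.mask(interval)
            r, c = np.nonzero(shell_mask)
            rows.append(pd.DataFrame(
                {"section_low": interval[0], "section_high": interval[1],
                 "col": c, "row": r}
            ))
        sections_path = outdir / "sections.csv"
        pd.concat(rows, ignore_index=True).to_csv(sections_path, index=False)
        artifacts.append(sections_path)

        stage = "profile"
        prof = profiles.domain_expression(grid, labeling)

        if config.cluster and prof.n_domains >= 2:
            stage = "cluster"
            clustering = analytics.cluster_domains(
                prof, n_pcs=config.n_pcs, k_neighbors=config.k_neighbors,
                resolution=config.resolution, seed=config.seed,
                embedding=config.embedding,
            )
            emb_path = outdir / "embedding.csv"
            clustering.embedding.assign(cluster=clustering.labels).to_csv(emb_path)
            artifacts.append(emb_path)
            if config.trajectory_root is not None:
                stage = "trajectory"
                traj = analytics.trajectory(prof, clustering, config.trajectory_root)
                edges_path = outdir / "paga_edges.csv"
                traj.connectivities.stack().rename("confidence").to_csv(edges_path)
                artifacts.append(edges_path)

        profile_path = outdir / "domain_profiles.csv"
        pd.concat([prof.meta, prof.expression], axis=1).to_csv(profile_path)
        artifacts.append(profile_path)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    manifest = {
        "config": config.to_dict(),
        "n_domains": int(labeling.n_domains),
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in artifacts
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
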