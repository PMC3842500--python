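#!/usr/bin/env python
"""Probabilistic tracking from the seed spheres and connectivity matrices.

Reads the FOD fields and target labels, places a spherical seed ROI at the
centre of gravity of each bundle's "A" endpoint (clipped to the tracking
mask), initiates the configured number of Monte-Carlo streamlines from
every seed voxel, and writes one seed-by-target maximum-connectivity TSV
per participant plus a small QC tractogram for the first participant.
"""

import argparse
from pathlib import Path

import numpy as np

from pictract import io
from pictract.config import PipelineConfig
from pictract.connectivity import build_connectivity_matrix
from pictract.phantom import make_bundle_phantom
from pictract.pipeline import seed_rois_from_truth
from pictract.tracking import (
    AmplitudeField,
    TrackingParams,
    propagate_streamline,
    track_roi,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--fods", type=Path, default=Path("results/fods"))
    ap.add_argument("--out", type=Path, default=Path("results/connectivity"))
    ap.add_argument("--n-streamlines", type=int, default=None,
                    help="override the configured streamlines per seed voxel")
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.cohort / "config_resolved.yaml")
    n_streamlines = args.n_streamlines or cfg.tracking.n_streamlines_per_voxel
    labels, _ = io.read_labels(args.cohort / "targets.nii.gz")
    truth = make_bundle_phantom(
        cfg.phantom.preset,
        voxel_size=cfg.phantom.voxel_size,
        shape=cfg.phantom.shape,
        tube_radius=cfg.phantom.tube_radius,
    )
    params = TrackingParams(
        n_streamlines_per_voxel=n_streamlines,
        step_size=cfg.tracking.step_size,
        max_path_length=cfg.tracking.max_path_length,
        curvature_limit_deg=cfg.tracking.curvature_limit_deg,
        fod_amplitude_threshold=cfg.tracking.fod_amplitude_threshold,
        rng_seed=cfg.seed,
    )

    args.out.mkdir(parents=True, exist_ok=True)
    for p in range(cfg.phantom.n_participants):
        fod = io.read_fod_field(
            args.fods / f"fod_{p:02d}.nii.gz",
            args.fods / f"fod_{p:02d}_mask.nii.gz",
        )
        amp = AmplitudeField(fod)
        rois = seed_rois_from_truth(
            truth, cfg.connectivity.seed_radius, clip_mask=fod.mask
        )
        roi_maps = {}
        for r, (name, roi) in enumerate(sorted(rois.items())):
            seed = int(
                np.random.SeedSequence([cfg.seed, 7001 + p, r]).generate_state(1)[0]
                % (2**31)
            )
            roi_maps[name] = track_roi(amp, roi.voxels, params, seed=seed)
        matrix = build_connectivity_matrix(roi_maps, labels, n_streamlines)
        io.write_matrix(matrix, args.out / f"connectivity_{p:02d}.tsv")
        print(f"participant {p:02d}: max connectivity {matrix.values.max()}")
        if p == 0:  # QC tractogram: 50 streamlines from the first seed voxel
            rng = np.random.default_rng(cfg.seed)
            roi = rois[sorted(rois)[0]]
            start_vox = np.asarray(roi.voxels[0], dtype=float)
            streams = []
            for _ in range(50):
                start = amp.voxel_to_world(start_vox + rng.random(3) - 0.5)
                streams.append(propagate_streamline(amp, start, params, rng))
            io.write_streamlines(streams, args.out / "qc_participant_00.tck")


if __name__ == "__main__":
    main()
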