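"""End-to-end run: phantom cohort -> CSD -> tracking -> connectivity ->
group profile.

Seed regions are spheres centred on the centre of gravity of each bundle's
"A" endpoint (clipped to the tracking mask), mirroring seed placement at a
region's centre of gravity; targets are the phantom endpoint labels plus a
configurable number of unconnected background regions standing in for a
whole-hemisphere parcellation.  Every stage draws its randomness from
streams derived from the single master seed, so a full run is
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .connectivity import (
    ConnectivityMatrix,
    LabelVolume,
    SeedROI,
    build_connectivity_matrix,
    make_spherical_roi,
)
from .csd import ResponseFunction, estimate_response, fit_fod_field
from .group_stats import GroupProfile, PoissonModel, apply_individual_threshold, group_consistency
from .io import write_matrix, write_profile
from .phantom import (
    DWIVolume,
    PhantomTruth,
    TissueModel,
    make_bundle_phantom,
    make_cohort,
    make_gradient_scheme,
    make_label_volume,
)
from .tracking import AmplitudeField, TrackingParams, track_roi

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "response_from_truth", "seed_rois_from_truth"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: PhantomTruth
    labels: LabelVolume
    seed_rois: dict[str, SeedROI]
    matrices: list[ConnectivityMatrix]
    models: list[PoissonModel]
    profile: GroupProfile

    def designed_pairs(self) -> set[tuple[str, str]]:
        """(seed ROI label, far-endpoint label) of each bundle."""
        out = set()
        for b in self.truth.bundles.values():
            a, bb = b.connection
            out.add((f"seed_{a}", bb))
        return out

    def spurious_pairs(self) -> set[tuple[str, str]]:
        """Cross-bundle and background pairs: none should be connected.

        A seed's own endpoint labels are excluded (the seed sphere sits in
        its bundle's "A" region, so those are trivially or designedly
        connected).
        """
        out = set()
        for b in self.truth.bundles.values():
            own = set(b.endpoints)
            seed = f"seed_{b.connection[0]}"
            for t in self.profile.target_labels:
                if t not in own:
                    out.add((seed, t))
        return out


def response_from_truth(
    dwi: DWIVolume,
    truth: PhantomTruth,
    lmax: int = 8,
    axis_tol_deg: float = 10.0,
) -> ResponseFunction:
    """Single-fibre response from ground-truth coherent voxels.

    Picks the most populous orientation among single-fibre voxels and
    estimates the response from all voxels within ``axis_tol_deg`` of it.
    """
    sf = truth.single_fibre_mask()
    if not sf.any():
        raise ValueError("no single-fibre voxels")
    orient, _, _ = truth.populations()
    axes = orient[sf][:, 0, :]  # (n, 3)
    # modal orientation: the axis with the most near-parallel neighbours
    dots = np.abs(axes @ axes.T)
    counts = (dots >= np.cos(np.radians(axis_tol_deg))).sum(axis=1)
    axis = axes[int(np.argmax(counts))]
    aligned = np.zeros_like(sf)
    aligned[sf] = np.abs(axes @ axis) >= np.cos(np.radians(axis_tol_deg))
    return estimate_response(dwi, aligned, axis, lmax=lmax)


def seed_rois_from_truth(
    truth: PhantomTruth,
    radius: float,
    clip_mask: np.ndarray | None = None,
) -> dict[str, SeedROI]:
    """One spherical seed ROI at the centre of gravity of each "A" endpoint."""
    rois: dict[str, SeedROI] = {}
    aff = truth.affine
    for b in truth.bundles.values():
        label_a = b.connection[0]
        idx = np.argwhere(b.endpoints[label_a])
        centre = (idx.mean(axis=0) @ aff[:3, :3].T) + aff[:3, 3]
        rois[f"seed_{label_a}"] = make_spherical_roi(
            centre,
            radius,
            truth.shape,
            aff,
            clip_mask=None if clip_mask is None else clip_mask.astype(float),
            threshold=0.0,
            label=f"seed_{label_a}",
        )
    return rois


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic cohort and return the group profile.

    With ``out_dir`` set, writes the resolved configuration, per-participant
    connectivity matrices, and the group profile TSV.
    """
    cfg = config or PipelineConfig()
    ph = cfg.phantom
    truth = make_bundle_phantom(
        ph.preset,
        voxel_size=ph.voxel_size,
        shape=ph.shape,
        tube_radius=ph.tube_radius,
        crossing_angle_deg=ph.crossing_angle_deg,
    )
    gradients = make_gradient_scheme(
        cfg.scheme.n_directions, cfg.scheme.b_value, seed=cfg.seed
    )
    model = TissueModel(
        S0=ph.S0,
        lambda_parallel=ph.lambda_parallel,
        lambda_perp=ph.lambda_perp,
        snr=ph.snr,
        rng_seed=cfg.seed,
        iso_diffusivity=ph.iso_diffusivity,
    )
    presence = None
    if ph.presence is not None:
        by_name = {n: b.connection for n, b in truth.bundles.items()}
        presence = {by_name[n]: list(v) for n, v in ph.presence.items()}
    volumes, truths = make_cohort(
        truth,
        ph.n_participants,
        presence,
        model,
        seed=cfg.seed,
        gradients=gradients,
    )
    labels = make_label_volume(
        truth, n_distractors=cfg.connectivity.n_distractor_regions
    )
    rois = seed_rois_from_truth(
        truth, cfg.connectivity.seed_radius, clip_mask=volumes[0].brain_mask
    )
    params = TrackingParams(
        n_streamlines_per_voxel=cfg.tracking.n_streamlines_per_voxel,
        step_size=cfg.tracking.step_size,
        max_path_length=cfg.tracking.max_path_length,
        curvature_limit_deg=cfg.tracking.curvature_limit_deg,
        fod_amplitude_threshold=cfg.tracking.fod_amplitude_threshold,
        rng_seed=cfg.seed,
    )
    matrices: list[ConnectivityMatrix] = []
    models: list[PoissonModel] = []
    binaries: list[np.ndarray] = []
    for p, (dwi, truth_p) in enumerate(zip(volumes, truths)):
        if truth_p.bundles:
            response = response_from_truth(
                dwi, truth_p, lmax=cfg.csd.lmax,
                axis_tol_deg=cfg.csd.response_axis_tol_deg,
            )
        else:  # no bundles left for this participant: analytic fallback
            from .csd import tensor_response

            response = tensor_response(
                cfg.scheme.b_value,
                ph.lambda_parallel,
                ph.lambda_perp,
                lmax=cfg.csd.lmax,
            )
        fod = fit_fod_field(
            dwi, response, lmax=cfg.csd.lmax, tau=cfg.csd.tau,
            max_iter=cfg.csd.max_iter,
        )
        amp = AmplitudeField(fod)
        roi_maps = {}
        for r, (name, roi) in enumerate(sorted(rois.items())):
            track_seed = int(
                np.random.SeedSequence([cfg.seed, 7001 + p, r]).generate_state(1)[0]
                % (2**31)
            )
            roi_maps[name] = track_roi(amp, roi.voxels, params, seed=track_seed)
        matrix = build_connectivity_matrix(
            roi_maps, labels, params.n_streamlines_per_voxel
        )
        matrices.append(matrix)
        pm = PoissonModel.fit(matrix.values.ravel(), alpha=cfg.group.alpha)
        models.append(pm)
        binaries.append(apply_individual_threshold(matrix, pm))
        logger.info(
            "participant %d: lambda=%.2f threshold=%d retained=%d",
            p, pm.lam, pm.threshold, int(binaries[-1].sum()),
        )
    profile = group_consistency(
        binaries,
        matrices[0].seed_labels,
        matrices[0].target_labels,
        strict_frac=cfg.group.strict_frac,
        relaxed_frac=cfg.group.relaxed_frac,
    )
    result = PipelineResult(
        config=cfg,
        truth=truth,
        labels=labels,
        seed_rois=rois,
        matrices=matrices,
        models=models,
        profile=profile,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.save(out / "config_resolved.yaml")
        for p, m in enumerate(matrices):
            write_matrix(m, out / f"connectivity_participant_{p:02d}.tsv")
        write_profile(profile, out / "group_profile.tsv")
    return result
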