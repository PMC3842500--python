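"""Digital fibre phantoms and multi-tensor diffusion-signal simulation.

Everything downstream (CSD, tracking, connectivity, group statistics) is
exercised on volumes produced here: known bundle geometries with known
endpoint regions and known seed-target connections, simulated with the
standard multi-tensor forward model and Rician noise.

The emulated acquisition is a single-shell scheme of 61 unique gradient
directions at b = 1200 s/mm^2 plus one b = 0 volume; bundle presets include
two parallel arc-shaped bundles (nested crescents) and straight tubes
crossing at a controlled angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .sphere import hemisphere_points_electrostatic

logger = logging.getLogger(__name__)

__all__ = [
    "GradientTable",
    "Bundle",
    "PhantomTruth",
    "TissueModel",
    "DWIVolume",
    "make_gradient_scheme",
    "make_bundle_phantom",
    "simulate_dwi",
    "make_cohort",
    "make_label_volume",
]

#: default isotropic diffusivity of the non-fibre compartment (mm^2/s)
ISO_DIFFUSIVITY = 7e-4


# --------------------------------------------------------------------------
# gradient scheme


@dataclass
class GradientTable:
    """Acquisition geometry: unit gradient directions and b-values."""

    directions: np.ndarray  # (n, 3)
    bvalues: np.ndarray  # (n,)

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if len(self.directions) != len(self.bvalues):
            raise ValueError(
                f"{len(self.directions)} directions vs "
                f"{len(self.bvalues)} b-values"
            )
        norms = np.linalg.norm(self.directions[self.b_weighted], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted gradient directions must be unit norm")
        if not np.any(self.bvalues == 0):
            raise ValueError("gradient table needs at least one b=0 entry")

    @property
    def b_weighted(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) entries."""
        return np.asarray(self.bvalues) > 0

    def __len__(self) -> int:
        return len(self.bvalues)


def make_gradient_scheme(
    n_directions: int, b_value: float, seed: int, n_iter: int = 500
) -> GradientTable:
    """Uniform hemisphere gradient scheme plus one b = 0 entry.

    Directions are spread by electrostatic repulsion (antipodally
    symmetrised), the standard construction for single-shell DWI schemes.
    Deterministic given ``seed``.
    """
    if n_directions < 6:
        raise ValueError("insufficient directions for even-order SH fitting")
    dirs = hemisphere_points_electrostatic(n_directions, seed, n_iter=n_iter)
    directions = np.vstack([np.zeros(3), dirs])
    bvalues = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    return GradientTable(directions, bvalues)


# --------------------------------------------------------------------------
# phantom geometry


@dataclass
class Bundle:
    """One fibre bundle: member voxels, local tangents, endpoint regions."""

    name: str
    mask: np.ndarray  # (X, Y, Z) bool
    orientations: np.ndarray  # (X, Y, Z, 3) unit tangents inside mask
    endpoints: dict[str, np.ndarray]  # endpoint label -> bool mask

    @property
    def connection(self) -> tuple[str, str]:
        a, b = sorted(self.endpoints)
        return (a, b)


@dataclass
class PhantomTruth:
    """Ground-truth fibre configuration of a phantom volume.

    ``bundles`` carries per-bundle voxel masks and tangent fields; voxels
    shared by k bundles hold k fibre populations with fraction 1/k each.
    ``truth_connections`` lists the (seed_label, target_label) endpoint pairs
    that are connected by construction.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    bundles: dict[str, Bundle] = field(default_factory=dict)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff

    @property
    def truth_connections(self) -> set[tuple[str, str]]:
        return {b.connection for b in self.bundles.values()}

    @property
    def bundle_labels(self) -> dict[str, np.ndarray]:
        """Per-bundle voxel membership masks."""
        return {name: b.mask for name, b in self.bundles.items()}

    def fibre_mask(self) -> np.ndarray:
        """Union of all bundle masks."""
        out = np.zeros(self.shape, dtype=bool)
        for b in self.bundles.values():
            out |= b.mask
        return out

    def populations(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked per-voxel populations.

        Returns
        -------
        orientations : (X, Y, Z, P, 3) with P the max population count
        fractions : (X, Y, Z, P), zero-padded; sums to 1 inside bundles
        n_pop : (X, Y, Z) int
        """
        n_pop = np.zeros(self.shape, dtype=int)
        for b in self.bundles.values():
            n_pop += b.mask
        pmax = max(1, int(n_pop.max()))
        orient = np.zeros(self.shape + (pmax, 3))
        frac = np.zeros(self.shape + (pmax,))
        slot = np.zeros(self.shape, dtype=int)
        for b in self.bundles.values():
            idx = np.nonzero(b.mask)
            s = slot[idx]
            orient[idx + (s,)] = b.orientations[idx]
            frac[idx + (s,)] = 1.0 / n_pop[idx]
            slot[idx] = s + 1
        return orient, frac, n_pop

    def single_fibre_mask(self) -> np.ndarray:
        """Voxels containing exactly one population (response-function mask)."""
        n_pop = np.zeros(self.shape, dtype=int)
        for b in self.bundles.values():
            n_pop += b.mask
        return n_pop == 1

    def subset(self, keep: set[str] | list[str]) -> "PhantomTruth":
        """Copy of the truth retaining only the named bundles."""
        return PhantomTruth(
            shape=self.shape,
            voxel_size=self.voxel_size,
            bundles={n: b for n, b in self.bundles.items() if n in keep},
        )


def _voxel_centres(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """World-mm coordinates of all voxel centres, shape (X, Y, Z, 3)."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return np.stack(grids, axis=-1) * voxel_size


def _tube_bundle(
    name: str,
    path: np.ndarray,
    tangents: np.ndarray,
    radius: float,
    shape: tuple[int, int, int],
    voxel_size: float,
    cap_length: float,
) -> Bundle:
    """Rasterise a tube of given radius around a densely sampled path.

    Each in-tube voxel takes the tangent of the nearest path sample; the
    first/last ``cap_length`` mm of the tube become the two endpoint regions.
    """
    extent = np.array(shape) * voxel_size
    if np.any(path - radius < -0.5 * voxel_size) or np.any(
        path + radius > extent - 0.5 * voxel_size
    ):
        raise ValueError("geometry out of bounds")
    centres = _voxel_centres(shape, voxel_size).reshape(-1, 3)
    # distance from every voxel centre to every path sample
    d2 = (
        np.sum(centres**2, axis=1)[:, None]
        - 2.0 * centres @ path.T
        + np.sum(path**2, axis=1)[None, :]
    )
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(np.maximum(d2[np.arange(len(centres)), nearest], 0.0))
    inside = dist <= radius
    mask = inside.reshape(shape)
    orientations = np.zeros(shape + (3,))
    orientations.reshape(-1, 3)[inside] = tangents[nearest[inside]]
    # arc-length parameter of the nearest sample, for endpoint caps
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    t = arclen[nearest]
    end_a = np.zeros(shape, dtype=bool)
    end_b = np.zeros(shape, dtype=bool)
    end_a.reshape(-1)[inside & (t <= cap_length)] = True
    end_b.reshape(-1)[inside & (t >= total - cap_length)] = True
    return Bundle(
        name=name,
        mask=mask,
        orientations=orientations,
        endpoints={f"{name}_A": end_a, f"{name}_B": end_b},
    )


def _arc_path(
    centre: np.ndarray, radius: float, deg0: float, deg1: float, ds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Circular arc in the x-z plane with tangents, sampled every ``ds`` mm."""
    n = max(2, int(np.ceil(radius * np.radians(abs(deg1 - deg0)) / ds)) + 1)
    t = np.radians(np.linspace(deg0, deg1, n))
    path = centre + radius * np.stack(
        [np.cos(t), np.zeros_like(t), np.sin(t)], axis=1
    )
    tang = np.stack([-np.sin(t), np.zeros_like(t), np.cos(t)], axis=1)
    return path, tang


def _line_path(
    centre: np.ndarray, direction: np.ndarray, half_length: float, ds: float
) -> tuple[np.ndarray, np.ndarray]:
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    n = max(2, int(np.ceil(2 * half_length / ds)) + 1)
    s = np.linspace(-half_length, half_length, n)
    path = centre + s[:, None] * direction
    tang = np.tile(direction, (n, 1))
    return path, tang


def make_bundle_phantom(
    preset: str,
    voxel_size: float = 1.0,
    shape: tuple[int, int, int] = (40, 40, 40),
    tube_radius: float = 2.0,
    crossing_angle_deg: float = 90.0,
    cap_length: float = 3.0,
) -> PhantomTruth:
    """Build a ground-truth phantom from a named geometry preset.

    Presets
    -------
    ``straight``
        one tube along z through the volume centre.
    ``arc``
        one circular arc in the x-z plane.
    ``two_arcs``
        two nested, non-touching arcs sharing a centre — a stand-in for a
        pair of parallel crescent-shaped association bundles.
    ``crossing``
        two straight tubes crossing at ``crossing_angle_deg`` in the x-z
        plane; overlap voxels carry both populations at fraction 1/2.
    """
    shape = tuple(int(s) for s in shape)
    extent = np.array(shape) * voxel_size
    c = extent / 2.0
    ds = voxel_size / 4.0
    truth = PhantomTruth(shape=shape, voxel_size=voxel_size)

    def scaled(x):  # geometry presets are drawn for a 40 mm extent
        return x * float(np.min(extent)) / 40.0

    if preset == "straight":
        margin = scaled(4.0)
        path, tang = _line_path(
            c, (0, 0, 1.0), c[2] - margin - tube_radius, ds
        )
        truth.bundles["straight"] = _tube_bundle(
            "straight", path, tang, tube_radius, shape, voxel_size, cap_length
        )
    elif preset == "arc":
        centre = np.array([c[0], c[1], scaled(8.0)])
        path, tang = _arc_path(centre, scaled(13.0), 15.0, 165.0, ds)
        truth.bundles["arc"] = _tube_bundle(
            "arc", path, tang, tube_radius, shape, voxel_size, cap_length
        )
    elif preset == "two_arcs":
        centre = np.array([c[0], c[1], scaled(8.0)])
        for name, radius in (("inner", scaled(10.0)), ("outer", scaled(16.5))):
            path, tang = _arc_path(centre, radius, 15.0, 165.0, ds)
            truth.bundles[name] = _tube_bundle(
                name, path, tang, tube_radius, shape, voxel_size, cap_length
            )
        if np.any(truth.bundles["inner"].mask & truth.bundles["outer"].mask):
            raise ValueError("two_arcs preset produced overlapping tubes")
    elif preset == "crossing":
        half = np.radians(crossing_angle_deg) / 2.0
        half_len = scaled(14.0)
        for name, ang in (("cross1", half), ("cross2", -half)):
            d = np.array([np.cos(ang), 0.0, np.sin(ang)])
            path, tang = _line_path(c, d, half_len, ds)
            truth.bundles[name] = _tube_bundle(
                name, path, tang, tube_radius, shape, voxel_size, cap_length
            )
    else:
        raise ValueError(f"unknown phantom preset {preset!r}")
    return truth


# --------------------------------------------------------------------------
# signal simulation


@dataclass
class TissueModel:
    """Multi-tensor forward-model parameters.

    Diffusivities in mm^2/s; ``snr`` is S0 over the Gaussian channel noise
    sigma (Rician magnitude noise), ``math.inf`` for noise-free.
    """

    S0: float = 1000.0
    lambda_parallel: float = 1.7e-3
    lambda_perp: float = 3e-4
    snr: float = 30.0
    rng_seed: int = 0
    iso_diffusivity: float = ISO_DIFFUSIVITY

    def __post_init__(self):
        if not (self.lambda_parallel >= self.lambda_perp > 0):
            raise ValueError("need lambda_parallel >= lambda_perp > 0")
        if self.S0 <= 0 or self.snr <= 0:
            raise ValueError("S0 and snr must be positive")


@dataclass
class DWIVolume:
    """A simulated (or loaded) diffusion-weighted acquisition."""

    signal: np.ndarray  # (X, Y, Z, n_gradients), >= 0
    gradients: GradientTable
    affine: np.ndarray  # 4x4 voxel-to-mm
    brain_mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self):
        if self.signal.shape[-1] != len(self.gradients):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but gradient "
                f"table has {len(self.gradients)} entries"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size(self) -> float:
        return float(np.cbrt(abs(np.linalg.det(np.asarray(self.affine)[:3, :3]))))


def _multi_tensor_signal(
    truth: PhantomTruth, gradients: GradientTable, model: TissueModel
) -> np.ndarray:
    """Noise-free normalised (S/S0 = 1 at b = 0) multi-tensor signal."""
    orient, frac, _ = truth.populations()
    g = gradients.directions  # (G, 3)
    b = gradients.bvalues  # (G,)
    # g' D g for an axially symmetric tensor about u:
    #   lambda_perp + (lambda_par - lambda_perp) (g.u)^2
    dots = np.einsum("xyzpk,gk->xyzpg", orient, g)
    dl = model.lambda_parallel - model.lambda_perp
    expo = -b[None, None, None, None, :] * (
        model.lambda_perp + dl * dots**2
    )
    expo = np.clip(expo, -700.0, 0.0)
    fibre = np.einsum("xyzp,xyzpg->xyzg", frac, np.exp(expo))
    f_total = frac.sum(axis=-1)
    iso = np.exp(np.clip(-b * model.iso_diffusivity, -700.0, 0.0))
    return fibre + (1.0 - f_total)[..., None] * iso[None, None, None, :]


def simulate_dwi(
    truth: PhantomTruth,
    gradients: GradientTable,
    model: TissueModel,
    mask_dilation: int = 2,
) -> DWIVolume:
    """Simulate a DWI volume from a phantom truth.

    Noise-free signal per voxel v and gradient g is

        S(v, g) = S0 [ sum_j f_j exp(-b g'D_j g) + (1 - sum_j f_j) e^{-b l_iso} ]

    with D_j the axially symmetric tensor of population j.  Rician noise is
    then applied as ``sqrt((S + n1)^2 + n2^2)`` with n1, n2 ~ N(0, sigma^2),
    sigma = S0/snr (skipped when snr is infinite).  The tracking/brain mask
    is the fibre mask dilated by ``mask_dilation`` voxels (whole volume when
    the phantom has no bundles and ``mask_dilation`` < 0).
    """
    clean = model.S0 * _multi_tensor_signal(truth, gradients, model)
    if math.isinf(model.snr):
        signal = clean
    else:
        sigma = model.S0 / model.snr
        rng = np.random.default_rng(model.rng_seed)
        n1 = rng.normal(0.0, sigma, size=clean.shape)
        n2 = rng.normal(0.0, sigma, size=clean.shape)
        signal = np.sqrt((clean + n1) ** 2 + n2**2)
    if mask_dilation < 0:
        brain_mask = np.ones(truth.shape, dtype=bool)
    else:
        fibre = truth.fibre_mask()
        brain_mask = (
            binary_dilation(fibre, iterations=mask_dilation)
            if mask_dilation and fibre.any()
            else fibre.copy()
        )
    return DWIVolume(
        signal=signal,
        gradients=gradients,
        affine=truth.affine,
        brain_mask=brain_mask,
    )


def make_cohort(
    truth: PhantomTruth,
    n_participants: int,
    presence: dict[tuple[str, str], "list[bool]"] | None,
    model: TissueModel,
    seed: int,
    gradients: GradientTable | None = None,
    mask_dilation: int = 2,
) -> tuple[list[DWIVolume], list[PhantomTruth]]:
    """Simulate a cohort with designed per-participant connection presence.

    ``presence`` maps each truth connection to a length-``n_participants``
    boolean sequence; bundles whose connection is absent for a participant
    are removed from that participant's truth before simulation (``None``
    means all connections present in everyone).  Participant noise streams
    use seeds ``seed + participant_index``.

    The tracking mask of every participant is derived from the *full* truth,
    so absent bundles are undetectable from the mask alone.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if gradients is None:
        gradients = make_gradient_scheme(61, 1200.0, seed)
    conns = truth.truth_connections
    if presence is None:
        presence = {c: [True] * n_participants for c in conns}
    missing = conns - set(presence)
    if missing:
        raise ValueError(f"presence not defined for connections {missing}")
    by_conn = {b.connection: name for name, b in truth.bundles.items()}
    full_fibre = truth.fibre_mask()
    full_mask = (
        binary_dilation(full_fibre, iterations=mask_dilation)
        if mask_dilation and full_fibre.any()
        else full_fibre
    )
    volumes: list[DWIVolume] = []
    truths: list[PhantomTruth] = []
    for p in range(n_participants):
        keep = {by_conn[c] for c in conns if presence[c][p]}
        truth_p = truth.subset(keep)
        model_p = TissueModel(
            S0=model.S0,
            lambda_parallel=model.lambda_parallel,
            lambda_perp=model.lambda_perp,
            snr=model.snr,
            rng_seed=seed + p,
            iso_diffusivity=model.iso_diffusivity,
        )
        dwi = simulate_dwi(truth_p, gradients, model_p, mask_dilation=0)
        dwi.brain_mask = full_mask.copy()
        volumes.append(dwi)
        truths.append(truth_p)
    return volumes, truths


def make_label_volume(truth: PhantomTruth, n_distractors: int = 0):
    """Integer label volume over the phantom's endpoint regions.

    Each bundle-endpoint region receives a unique positive label (0 is
    background); regions are kept disjoint by first-come assignment in
    sorted label-name order.  ``n_distractors`` additional small cubic
    "background" regions, placed deterministically away from any bundle,
    emulate the many unconnected parcels of a whole-hemisphere atlas — they
    give the pooled connectivity-value distribution its realistic
    zero-dominated shape.
    """
    from .connectivity import LabelVolume

    labels = np.zeros(truth.shape, dtype=np.int32)
    names: dict[int, str] = {}
    next_label = 1
    regions: dict[str, np.ndarray] = {}
    for b in truth.bundles.values():
        regions.update(b.endpoints)
    for name in sorted(regions):
        mask = regions[name] & (labels == 0)
        labels[mask] = next_label
        names[next_label] = name
        next_label += 1
    if n_distractors:
        keepout = binary_dilation(truth.fibre_mask(), iterations=3)
        side = max(2, int(round(3.0 / truth.voxel_size)))
        placed = 0
        stride = max(side + 2, int(round(6.0 / truth.voxel_size)))
        for x in range(1, truth.shape[0] - side, stride):
            for y in range(1, truth.shape[1] - side, stride):
                for z in range(1, truth.shape[2] - side, stride):
                    if placed >= n_distractors:
                        break
                    block = (
                        slice(x, x + side),
                        slice(y, y + side),
                        slice(z, z + side),
                    )
                    if keepout[block].any() or (labels[block] != 0).any():
                        continue
                    labels[block] = next_label
                    names[next_label] = f"background_{placed:02d}"
                    next_label += 1
                    placed += 1
        if placed < n_distractors:
            logger.warning(
                "placed only %d of %d distractor regions", placed, n_distractors
            )
    return LabelVolume(labels=labels, names=names)
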