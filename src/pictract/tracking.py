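"""Monte-Carlo probabilistic streamline tracking through an FOD field.

Each streamline is propagated bidirectionally from a jittered start point in
a seed voxel: at every 0.5 mm step a direction is drawn from the trilinearly
interpolated FOD, with probability proportional to the (non-negative) FOD
amplitude over a fixed 724-direction sphere set, restricted to the
hemisphere within 90 degrees of the previous step.  Tracking stops when the
cumulative in-voxel turning angle exceeds the curvature limit (180 degrees
per voxel by default), the 500 mm physical path limit is reached, the
streamline leaves the tracking mask, or no direction reaches the FOD
amplitude threshold.  Repeating this 10,000 times per seed voxel and
recording which voxels each streamline visits (binary per streamline)
yields the visitation map whose per-voxel counts are the connectivity
values.

Two engines implement the identical algorithm: a readable pure-Python path
(`propagate_streamline`) and a numba kernel used for batch tracking; both
consume the same per-streamline uniform stream, so they are
cross-checkable draw for draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .csd import FODField, _peak_basis

__all__ = [
    "TrackingParams",
    "Streamline",
    "VisitationMap",
    "AmplitudeField",
    "sample_direction",
    "propagate_streamline",
    "track_seed_voxel",
    "track_roi",
]

TERMINATION_REASONS = ("curvature", "max_length", "exited_mask", "low_fod")


@dataclass
class TrackingParams:
    """Streamline propagation parameters (defaults are the printed protocol:
    10,000 streamlines per seed voxel, 0.50 mm steps, 500 mm physical path
    limit, 180 degrees-per-voxel curvature limit)."""

    n_streamlines_per_voxel: int = 10_000
    step_size: float = 0.50  # mm
    max_path_length: float = 500.0  # mm
    curvature_limit_deg: float = 180.0  # per voxel
    fod_amplitude_threshold: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if min(
            self.n_streamlines_per_voxel,
            self.step_size,
            self.max_path_length,
            self.curvature_limit_deg,
        ) <= 0:
            raise ValueError("tracking parameters must be positive")

    @property
    def step_budget(self) -> int:
        """Total number of steps allowed by the physical path limit."""
        return int(math.floor(self.max_path_length / self.step_size + 1e-9))


@dataclass
class Streamline:
    """One trajectory: ordered mm coordinates and why tracking stopped."""

    points: np.ndarray  # (n, 3) mm
    termination_reason: str
    half_reasons: tuple[str, str] | None = None

    @property
    def arc_length(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1))
        )


@dataclass
class VisitationMap:
    """Per-voxel count of distinct streamlines from one seed voxel."""

    counts: np.ndarray  # (X, Y, Z) int
    n_initiated: int
    seed_voxel: tuple[int, int, int]


class AmplitudeField:
    """FOD amplitudes precomputed on the tracking direction set.

    Trilinear interpolation commutes with SH evaluation (both linear), so
    interpolating precomputed per-voxel amplitudes equals evaluating the
    interpolated SH coefficients; precomputing makes the per-step work a
    weighted 8-corner gather.
    """

    def __init__(self, fod: FODField, n_dirs: int = 724):
        dirs, basis = _peak_basis(fod.lmax, n_dirs)
        self.directions = dirs
        self.mask = np.ascontiguousarray(fod.mask.astype(np.uint8))
        amp = np.zeros(fod.mask.shape + (n_dirs,), dtype=np.float32)
        idx = np.nonzero(fod.mask)
        amp[idx] = (fod.coefficients[idx] @ basis.T).astype(np.float32)
        self.amplitudes = amp
        self.affine = np.asarray(fod.affine, dtype=float)
        inv = np.linalg.inv(self.affine)
        self.world_to_vox = np.ascontiguousarray(inv[:3, :3])
        self.world_to_vox_offset = np.ascontiguousarray(inv[:3, 3])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_coords(self, position: np.ndarray) -> np.ndarray:
        return self.world_to_vox @ np.asarray(position, float) + self.world_to_vox_offset

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        return self.affine[:3, :3] @ np.asarray(vox, float) + self.affine[:3, 3]

    def nearest_voxel(self, position: np.ndarray) -> tuple[int, int, int]:
        v = self.voxel_coords(position)
        return tuple(int(math.floor(x + 0.5)) for x in v)

    def in_mask(self, voxel: tuple[int, int, int]) -> bool:
        return all(0 <= voxel[a] < self.shape[a] for a in range(3)) and bool(
            self.mask[voxel]
        )

    def interpolated_amplitudes(self, position: np.ndarray) -> np.ndarray:
        """Trilinear 8-corner blend of the amplitude grid at ``position``.

        Corner accumulation order matches the numba kernel bit for bit.
        """
        v = self.voxel_coords(position)
        i0 = [int(math.floor(x)) for x in v]
        f = [v[a] - i0[a] for a in range(3)]
        out = np.zeros(self.directions.shape[0])
        for corner in range(8):
            ci = (corner >> 2) & 1
            cj = (corner >> 1) & 1
            ck = corner & 1
            ii, jj, kk = i0[0] + ci, i0[1] + cj, i0[2] + ck
            if not (
                0 <= ii < self.shape[0]
                and 0 <= jj < self.shape[1]
                and 0 <= kk < self.shape[2]
            ):
                continue
            w = (
                (f[0] if ci else 1.0 - f[0])
                * (f[1] if cj else 1.0 - f[1])
                * (f[2] if ck else 1.0 - f[2])
            )
            out += w * self.amplitudes[ii, jj, kk].astype(np.float64)
        return out


def sample_direction(
    amp_field: AmplitudeField,
    position: np.ndarray,
    previous_direction: np.ndarray | None,
    rng: np.random.Generator,
    fod_amplitude_threshold: float = 0.2,
) -> np.ndarray | None:
    """Draw one propagation direction at ``position``.

    Probability is proportional to the FOD amplitude over the 724
    directions, restricted to the hemisphere within 90 degrees of
    ``previous_direction`` (full sphere when ``None``); directions whose
    amplitude falls below ``fod_amplitude_threshold`` carry zero
    probability — a streamline never steps along sub-threshold amplitude,
    which keeps the band-limited FOD's low side-lobe ring from randomising
    propagation.  Returns ``None`` (no uniform consumed) when every
    admissible amplitude is below the threshold — the low-FOD termination
    signal.
    """
    amp = amp_field.interpolated_amplitudes(position)
    w = np.where(amp >= fod_amplitude_threshold, amp, 0.0)
    if previous_direction is not None:
        w = np.where(amp_field.directions @ previous_direction > 0.0, w, 0.0)
    if w.max() <= 0.0:
        return None
    cdf = np.cumsum(w)
    u = rng.random()
    j = int(np.searchsorted(cdf, u * cdf[-1], side="right"))
    j = min(j, len(w) - 1)
    return amp_field.directions[j]


def _half_track(
    amp_field: AmplitudeField,
    start: np.ndarray,
    prev_dir: np.ndarray | None,
    budget: int,
    params: TrackingParams,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], str, np.ndarray | None]:
    """Propagate one half-track; returns (points, reason, first_direction)."""
    points: list[np.ndarray] = []
    pos = np.asarray(start, dtype=float)
    prev = None if prev_dir is None else np.asarray(prev_dir, dtype=float)
    cur_voxel = amp_field.nearest_voxel(pos)
    cum_angle = 0.0
    first_dir = None
    steps = 0
    while True:
        if steps >= budget:
            return points, "max_length", first_dir
        d = sample_direction(
            amp_field, pos, prev, rng, params.fod_amplitude_threshold
        )
        if d is None:
            return points, "low_fod", first_dir
        if first_dir is None:
            first_dir = d
        ang = 0.0
        if prev is not None:
            ang = math.degrees(
                math.acos(min(1.0, max(-1.0, float(prev @ d))))
            )
        new_pos = pos + params.step_size * d
        nv = amp_field.nearest_voxel(new_pos)
        if not amp_field.in_mask(nv):
            return points, "exited_mask", first_dir
        if nv == cur_voxel:
            cum_angle += ang
            if cum_angle > params.curvature_limit_deg:
                return points, "curvature", first_dir
        else:
            cur_voxel = nv
            cum_angle = 0.0
        points.append(new_pos)
        pos = new_pos
        prev = d
        steps += 1


def propagate_streamline(
    amp_field: AmplitudeField,
    seed_point: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> Streamline:
    """Bidirectional Monte-Carlo propagation from ``seed_point``.

    The first half-track starts with a full-sphere draw; the second starts
    from the seed with the first half's initial direction reversed, so the
    two halves leave through opposite hemispheres.  The physical path limit
    binds on the concatenated streamline: the second half only receives the
    step budget the first half left unused.
    """
    seed_point = np.asarray(seed_point, dtype=float)
    sv = amp_field.nearest_voxel(seed_point)
    if not amp_field.in_mask(sv):
        raise ValueError("seed not in tracking domain")
    budget = params.step_budget
    pts1, r1, d0 = _half_track(amp_field, seed_point, None, budget, params, rng)
    if d0 is None:  # no direction was ever drawn; the seed FOD is dead
        return Streamline(
            points=seed_point[None, :],
            termination_reason=r1,
            half_reasons=(r1, r1),
        )
    pts2, r2, _ = _half_track(
        amp_field, seed_point, -d0, budget - len(pts1), params, rng
    )
    points = np.vstack(
        [np.array(pts2[::-1]).reshape(-1, 3), seed_point[None, :],
         np.array(pts1).reshape(-1, 3)]
    )
    return Streamline(points=points, termination_reason=r2, half_reasons=(r1, r2))


# --------------------------------------------------------------------------
# numba batch kernel


@njit(cache=True)
def _kernel_half(
    amp,
    dirs,
    mask,
    w2v,
    w2v_off,
    pos,
    prev,
    has_prev,
    budget,
    step_size,
    curv_limit,
    threshold,
    uniforms,
    k_start,
    counts,
    stamp,
    sid,
    weights,
):
    """One half-track; marks visited voxels and returns
    (steps_taken, reason_code, uniforms_consumed, first_dir_index).

    Reason codes: 0 curvature, 1 max_length, 2 exited_mask, 3 low_fod.
    """
    nx, ny, nz, nd = amp.shape
    cvx = int(math.floor(w2v[0, 0] * pos[0] + w2v[0, 1] * pos[1] + w2v[0, 2] * pos[2] + w2v_off[0] + 0.5))
    cvy = int(math.floor(w2v[1, 0] * pos[0] + w2v[1, 1] * pos[1] + w2v[1, 2] * pos[2] + w2v_off[1] + 0.5))
    cvz = int(math.floor(w2v[2, 0] * pos[0] + w2v[2, 1] * pos[1] + w2v[2, 2] * pos[2] + w2v_off[2] + 0.5))
    cum_angle = 0.0
    steps = 0
    used = 0
    first_dir = -1
    px, py, pz = prev[0], prev[1], prev[2]
    while True:
        if steps >= budget:
            return steps, 1, used, first_dir
        # trilinear blend of amplitudes at pos
        vx = w2v[0, 0] * pos[0] + w2v[0, 1] * pos[1] + w2v[0, 2] * pos[2] + w2v_off[0]
        vy = w2v[1, 0] * pos[0] + w2v[1, 1] * pos[1] + w2v[1, 2] * pos[2] + w2v_off[1]
        vz = w2v[2, 0] * pos[0] + w2v[2, 1] * pos[1] + w2v[2, 2] * pos[2] + w2v_off[2]
        i0 = int(math.floor(vx))
        j0 = int(math.floor(vy))
        k0 = int(math.floor(vz))
        fx = vx - i0
        fy = vy - j0
        fz = vz - k0
        for d in range(nd):
            weights[d] = 0.0
        for corner in range(8):
            ci = (corner >> 2) & 1
            cj = (corner >> 1) & 1
            ck = corner & 1
            ii = i0 + ci
            jj = j0 + cj
            kk = k0 + ck
            if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                continue
            wx = fx if ci == 1 else 1.0 - fx
            wy = fy if cj == 1 else 1.0 - fy
            wz = fz if ck == 1 else 1.0 - fz
            w = wx * wy * wz
            for d in range(nd):
                weights[d] += w * np.float64(amp[ii, jj, kk, d])
        # amplitude floor, hemisphere restriction, max
        wmax = 0.0
        for d in range(nd):
            wd = weights[d]
            if wd < threshold:
                wd = 0.0
            if has_prev:
                dot = dirs[d, 0] * px + dirs[d, 1] * py + dirs[d, 2] * pz
                if dot <= 0.0:
                    wd = 0.0
            weights[d] = wd
            if wd > wmax:
                wmax = wd
        if wmax <= 0.0:
            return steps, 3, used, first_dir
        total = 0.0
        for d in range(nd):
            total += weights[d]
        u = uniforms[k_start + used]
        used += 1
        target = u * total
        acc = 0.0
        jsel = nd - 1
        for d in range(nd):
            acc += weights[d]
            if acc > target:
                jsel = d
                break
        dx = dirs[jsel, 0]
        dy = dirs[jsel, 1]
        dz = dirs[jsel, 2]
        if first_dir < 0:
            first_dir = jsel
        ang = 0.0
        if has_prev:
            dot = px * dx + py * dy + pz * dz
            if dot > 1.0:
                dot = 1.0
            if dot < -1.0:
                dot = -1.0
            ang = math.degrees(math.acos(dot))
        nxp = pos[0] + step_size * dx
        nyp = pos[1] + step_size * dy
        nzp = pos[2] + step_size * dz
        nvx = int(math.floor(w2v[0, 0] * nxp + w2v[0, 1] * nyp + w2v[0, 2] * nzp + w2v_off[0] + 0.5))
        nvy = int(math.floor(w2v[1, 0] * nxp + w2v[1, 1] * nyp + w2v[1, 2] * nzp + w2v_off[1] + 0.5))
        nvz = int(math.floor(w2v[2, 0] * nxp + w2v[2, 1] * nyp + w2v[2, 2] * nzp + w2v_off[2] + 0.5))
        if (
            nvx < 0 or nvx >= nx or nvy < 0 or nvy >= ny or nvz < 0
            or nvz >= nz or mask[nvx, nvy, nvz] == 0
        ):
            return steps, 2, used, first_dir
        if nvx == cvx and nvy == cvy and nvz == cvz:
            cum_angle += ang
            if cum_angle > curv_limit:
                return steps, 0, used, first_dir
        else:
            cvx, cvy, cvz = nvx, nvy, nvz
            cum_angle = 0.0
        # accept the step; mark visitation (binary per streamline)
        if stamp[nvx, nvy, nvz] != sid:
            stamp[nvx, nvy, nvz] = sid
            counts[nvx, nvy, nvz] += 1
        pos[0] = nxp
        pos[1] = nyp
        pos[2] = nzp
        px, py, pz = dx, dy, dz
        has_prev = True
        steps += 1


@njit(cache=True)
def _track_batch(
    amp,
    dirs,
    mask,
    w2v,
    w2v_off,
    affine33,
    affine_off,
    seed_voxel,
    uniforms,
    step_size,
    budget,
    curv_limit,
    threshold,
    counts,
    stamp,
):
    n_streamlines = uniforms.shape[0]
    nd = amp.shape[3]
    weights = np.empty(nd, dtype=np.float64)
    pos = np.empty(3, dtype=np.float64)
    prev = np.empty(3, dtype=np.float64)
    for i in range(n_streamlines):
        # jittered start point, uniform within the seed voxel
        jx = seed_voxel[0] + uniforms[i, 0] - 0.5
        jy = seed_voxel[1] + uniforms[i, 1] - 0.5
        jz = seed_voxel[2] + uniforms[i, 2] - 0.5
        pos[0] = affine33[0, 0] * jx + affine33[0, 1] * jy + affine33[0, 2] * jz + affine_off[0]
        pos[1] = affine33[1, 0] * jx + affine33[1, 1] * jy + affine33[1, 2] * jz + affine_off[1]
        pos[2] = affine33[2, 0] * jx + affine33[2, 1] * jy + affine33[2, 2] * jz + affine_off[2]
        # seed voxel is always encountered
        if stamp[seed_voxel[0], seed_voxel[1], seed_voxel[2]] != i:
            stamp[seed_voxel[0], seed_voxel[1], seed_voxel[2]] = i
            counts[seed_voxel[0], seed_voxel[1], seed_voxel[2]] += 1
        prev[0] = 0.0
        prev[1] = 0.0
        prev[2] = 0.0
        sx, sy, sz = pos[0], pos[1], pos[2]
        steps1, r1, used1, fdir = _kernel_half(
            amp, dirs, mask, w2v, w2v_off, pos, prev, False, budget,
            step_size, curv_limit, threshold, uniforms[i], 3, counts,
            stamp, i, weights,
        )
        if fdir < 0:
            continue  # dead seed FOD: single-point streamline
        pos[0] = sx
        pos[1] = sy
        pos[2] = sz
        prev[0] = -dirs[fdir, 0]
        prev[1] = -dirs[fdir, 1]
        prev[2] = -dirs[fdir, 2]
        _kernel_half(
            amp, dirs, mask, w2v, w2v_off, pos, prev, True,
            budget - steps1, step_size, curv_limit, threshold,
            uniforms[i], 3 + used1, counts, stamp, i, weights,
        )
    return counts


def _streamline_uniforms(
    master_seed: int, n_streamlines: int, budget: int
) -> np.ndarray:
    """Pregenerated per-streamline uniform streams.

    Stream i is ``default_rng(SeedSequence(master_seed).spawn(...)[i])``, so
    the first k streamlines of a larger run coincide with a smaller run —
    visitation counts are monotone in the streamline count.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_streamlines)
    out = np.empty((n_streamlines, 3 + budget + 2), dtype=np.float64)
    for i, child in enumerate(children):
        out[i] = np.random.default_rng(child).random(out.shape[1])
    return out


def track_seed_voxel(
    amp_field: AmplitudeField,
    voxel: tuple[int, int, int],
    params: TrackingParams,
    seed: int | None = None,
    engine: str = "numba",
) -> VisitationMap:
    """Initiate ``params.n_streamlines_per_voxel`` streamlines in ``voxel``.

    Start points are uniformly jittered inside the voxel; every streamline
    increments a voxel's count at most once.  Fully deterministic given the
    seed (``params.rng_seed`` unless overridden).
    """
    voxel = tuple(int(v) for v in voxel)
    if not amp_field.in_mask(voxel):
        raise ValueError("seed not in tracking domain")
    if seed is None:
        seed = params.rng_seed
    n = params.n_streamlines_per_voxel
    budget = params.step_budget
    counts = np.zeros(amp_field.shape, dtype=np.int64)
    if engine == "numba":
        uniforms = _streamline_uniforms(seed, n, budget)
        stamp = np.full(amp_field.shape, -1, dtype=np.int64)
        _track_batch(
            amp_field.amplitudes,
            amp_field.directions,
            amp_field.mask,
            amp_field.world_to_vox,
            amp_field.world_to_vox_offset,
            np.ascontiguousarray(amp_field.affine[:3, :3]),
            np.ascontiguousarray(amp_field.affine[:3, 3]),
            np.asarray(voxel, dtype=np.int64),
            uniforms,
            params.step_size,
            budget,
            params.curvature_limit_deg,
            params.fod_amplitude_threshold,
            counts,
            stamp,
        )
    elif engine == "python":
        children = np.random.SeedSequence(seed).spawn(n)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            jitter = rng.random(3)
            start = amp_field.voxel_to_world(np.asarray(voxel) + jitter - 0.5)
            sl = propagate_streamline(amp_field, start, params, rng)
            visited = {voxel}
            for p in sl.points:
                visited.add(amp_field.nearest_voxel(p))
            for v in visited:
                if all(0 <= v[a] < amp_field.shape[a] for a in range(3)):
                    counts[v] += 1
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return VisitationMap(counts=counts, n_initiated=n, seed_voxel=voxel)


def track_roi(
    amp_field: AmplitudeField,
    voxels: np.ndarray,
    params: TrackingParams,
    seed: int | None = None,
) -> list[VisitationMap]:
    """One visitation map per seed voxel of an ROI.

    Per-voxel streams are derived as ``SeedSequence([seed, voxel_index])``
    entropy so maps are independent and individually reproducible.
    """
    if seed is None:
        seed = params.rng_seed
    maps = []
    for idx, vox in enumerate(np.asarray(voxels, dtype=int)):
        voxel_seed = np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        maps.append(
            track_seed_voxel(amp_field, tuple(vox), params, seed=int(voxel_seed))
        )
    return maps
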