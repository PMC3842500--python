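"""File formats: NIfTI volumes, FSL bval/bvec tables, TCK tractograms, TSV
profiles.

Conventions: NIfTI affines define world (mm) space; voxel indices are
0-based with the voxel-centre convention; bvec files are the FSL dialect
(3 whitespace-separated rows of x, y, z components); streamlines are stored
as TCK (world-mm coordinates, float32).
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, LabelVolume
from .group_stats import GroupProfile
from .phantom import DWIVolume, GradientTable, PhantomTruth
from .tracking import Streamline

logger = logging.getLogger(__name__)

__all__ = [
    "write_dwi",
    "read_dwi",
    "write_labels",
    "read_labels",
    "write_truth_orientations",
    "write_streamlines",
    "read_streamlines",
    "write_matrix",
    "read_matrix",
    "write_profile",
    "read_profile",
]


# --------------------------------------------------------------------------
# DWI + gradient tables


def write_dwi(dwi: DWIVolume, prefix: str | Path) -> dict[str, Path]:
    """Write signal as NIfTI plus FSL-dialect bval/bvec text files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = prefix.with_suffix(".nii.gz")
    img = nib.Nifti1Image(np.asarray(dwi.signal, dtype=np.float32), dwi.affine)
    nib.save(img, nii)
    mask_path = prefix.parent / (prefix.name + "_mask.nii.gz")
    nib.save(
        nib.Nifti1Image(dwi.brain_mask.astype(np.uint8), dwi.affine), mask_path
    )
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    np.savetxt(bval, dwi.gradients.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec, dwi.gradients.directions.T, fmt="%.8f")
    return {"nifti": nii, "bval": bval, "bvec": bvec, "mask": mask_path}


def read_dwi(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    mask_path: str | Path | None = None,
) -> DWIVolume:
    """Load a DWI volume, validating signal/gradient consistency.

    Non-unit weighted bvecs are renormalised with a warning (within a 1e-2
    tolerance of unit norm); a gradient count that does not match the
    image's 4th dimension is an error.
    """
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.get_fdata())
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if signal.ndim != 4:
        raise ValueError("DWI image must be 4-dimensional")
    if signal.shape[3] != len(bvals) or len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient table has {len(bvals)} entries but image has "
            f"{signal.shape[3]} volumes"
        )
    weighted = bvals > 0
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    off = np.abs(norms - 1.0) > 1e-6
    if np.any(off):
        logger.warning(
            "renormalising %d non-unit gradient direction(s)", int(off.sum())
        )
        bvecs[weighted] = bvecs[weighted] / norms[:, None]
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    else:
        mask = np.ones(signal.shape[:3], dtype=bool)
    return DWIVolume(
        signal=np.clip(signal, 0.0, None),
        gradients=GradientTable(bvecs, bvals),
        affine=np.asarray(img.affine),
        brain_mask=mask,
    )


# --------------------------------------------------------------------------
# label volumes and truth


def write_labels(labels: LabelVolume, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int32), affine), path)
    names = path.with_suffix("").with_suffix(".tsv") if path.suffix == ".gz" \
        else path.with_suffix(".tsv")
    pd.DataFrame(
        {"label": list(labels.names), "name": list(labels.names.values())}
    ).to_csv(names, sep="\t", index=False)
    return path


def read_labels(path: str | Path) -> tuple[LabelVolume, np.ndarray]:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    names_path = path.with_suffix("").with_suffix(".tsv") if path.suffix == ".gz" \
        else path.with_suffix(".tsv")
    if names_path.exists():
        df = pd.read_csv(names_path, sep="\t")
        names = dict(zip(df["label"].astype(int), df["name"].astype(str)))
    else:
        names = {int(l): f"region_{int(l)}" for l in np.unique(labels) if l}
    return LabelVolume(labels=labels, names=names), np.asarray(img.affine)


def write_truth_orientations(truth: PhantomTruth, path: str | Path) -> Path:
    """Primary per-voxel fibre orientation as a 4D (x, y, z, 3) NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    orient, frac, _ = truth.populations()
    primary = orient[..., 0, :] * (frac[..., 0, None] > 0)
    nib.save(
        nib.Nifti1Image(primary.astype(np.float32), truth.affine), path
    )
    return path


# --------------------------------------------------------------------------
# TCK tractograms (own writer; nibabel serves as the independent reader)


def write_streamlines(streamlines: list[Streamline], path: str | Path) -> Path:
    """Write streamlines to a TCK file in world-mm coordinates.

    The TCK layout is a text header terminated by ``END`` followed by
    little-endian float32 point triplets, one (nan, nan, nan) separator per
    track and an (inf, inf, inf) terminator.  An empty list writes a valid
    zero-track file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    count = len(streamlines)
    body = bytearray()
    for sl in streamlines:
        pts = np.asarray(sl.points, dtype=np.float32)
        body += pts.tobytes()
        body += struct.pack("<3f", np.nan, np.nan, np.nan)
    body += struct.pack("<3f", np.inf, np.inf, np.inf)
    header_fields = (
        "mrtrix tracks\n"
        "datatype: Float32LE\n"
        f"count: {count}\n"
    )
    # the offset counts the header's own digits; iterate to a fixed point
    offset = len(header_fields) + len("file: . 0\nEND\n")
    while True:
        header = header_fields + f"file: . {offset}\nEND\n"
        if len(header.encode()) == offset:
            break
        offset = len(header.encode())
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(bytes(body))
    return path


def read_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a TCK file via nibabel (independent of the writer above)."""
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in tck.streamlines]


# --------------------------------------------------------------------------
# matrices and profiles


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        matrix.values, index=matrix.seed_labels, columns=matrix.target_labels
    )
    df.index.name = "seed"
    df.to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path, n_initiated: int) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=np.int64),
        seed_labels=list(df.index),
        target_labels=list(df.columns),
        n_initiated=n_initiated,
    )


def write_profile(profile: GroupProfile, path: str | Path) -> Path:
    """Write the group connectivity profile as TSV.

    Columns: seed, target, participant_count, strict_pass, relaxed_pass —
    the machine-readable analogue of a per-connection participant-count
    table.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile.to_dataframe().to_csv(path, sep="\t", index=False)
    return path


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# FOD fields and responses (stage hand-off between analysis scripts)


def write_fod_field(fod, prefix: str | Path) -> dict[str, Path]:
    from .csd import FODField  # noqa: F401  (type reference)

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = prefix.with_suffix(".nii.gz")
    nib.save(
        nib.Nifti1Image(fod.coefficients.astype(np.float32), fod.affine), nii
    )
    mask_path = prefix.parent / (prefix.name + "_mask.nii.gz")
    nib.save(nib.Nifti1Image(fod.mask.astype(np.uint8), fod.affine), mask_path)
    return {"nifti": nii, "mask": mask_path}


def read_fod_field(nifti_path: str | Path, mask_path: str | Path):
    from .csd import FODField
    from .sphere import n_sh_coeffs

    img = nib.load(str(nifti_path))
    coeffs = np.asarray(img.get_fdata())
    n_coef = coeffs.shape[-1]
    lmax = int(round((-3 + np.sqrt(1 + 8 * n_coef)) / 2))
    if n_sh_coeffs(lmax) != n_coef:
        raise ValueError(f"no even lmax matches {n_coef} coefficients")
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    return FODField(
        coefficients=coeffs, lmax=lmax, mask=mask, affine=np.asarray(img.affine)
    )


def write_response(response, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, response.zonal[None, :], fmt="%.10e",
               header="zonal even-order response coefficients (l = 0, 2, ...)")
    return path


def read_response(path: str | Path):
    from .csd import ResponseFunction

    zonal = np.atleast_1d(np.loadtxt(path))
    return ResponseFunction(zonal=zonal, lmax=2 * (len(zonal) - 1))
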