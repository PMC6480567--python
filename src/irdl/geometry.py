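"""Low-level 3-D geometry: internal-coordinate atom placement, torsions, rigid motions.

All coordinates are Cartesian Angstroms.  Rotations use scipy's Rotation class;
the only hand-written primitive is NeRF (natural extension reference frame)
placement, the standard way to convert internal coordinates (bond, angle,
dihedral) to Cartesian positions when building polymers atom by atom.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def place_atom(a, b, c, bond: float, angle: float,
               dihedral: float) -> np.ndarray:
    """Place atom X given three reference atoms using NeRF.

    X is at distance ``bond`` from ``c``, with angle X-c-b equal to ``angle``
    (degrees) and dihedral X-c-b-a equal to ``dihedral`` (degrees).
    Scalar implementation: this is the innermost loop of coordinate
    generation.
    """
    theta = math.radians(angle)
    chi = math.radians(dihedral)
    st = math.sin(theta)
    dx = -bond * math.cos(theta)
    dy = bond * st * math.cos(chi)
    dz = bond * st * math.sin(chi)
    ax, ay, az = a[0], a[1], a[2]
    bx, by, bz = b[0], b[1], b[2]
    cx, cy, cz = c[0], c[1], c[2]
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        # colinear references: pick an arbitrary perpendicular
        nx, ny, nz = 0.0, bcz, -bcy
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-10:
            nx, ny, nz = -bcz, 0.0, bcx
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    inv = 1.0 / nn
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return np.array([
        cx + bcx * dx + mx * dy + nx * dz,
        cy + bcy * dx + my * dy + ny * dz,
        cz + bcz * dx + mz * dy + nz * dz,
    ])


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v = p0 - p1
    w = p2 - p1
    c = np.dot(v, w) / (np.linalg.norm(v) * np.linalg.norm(w))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate ``coords`` (N,3) about the line through ``origin`` along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_degrees) * axis)
    return rot.apply(coords - origin) + origin


def rotate_about_bond(coords: np.ndarray, i: int, j: int,
                      moving: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate the atoms indexed by ``moving`` about the i->j bond axis."""
    out = coords.copy()
    out[moving] = rotate_about_axis(coords[moving], coords[j],
                                    coords[j] - coords[i], angle_degrees)
    return out


def rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between matched coordinate sets without superposition."""
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between coordinate sets over all rigid superpositions."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def kabsch_rmsd_many(a: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Minimum superposition RMSD of ``a`` (N,3) against each of (M,N,3)."""
    if len(batch) == 0:
        return np.zeros(0)
    ac = a - a.mean(axis=0)
    bc = batch - batch.mean(axis=1, keepdims=True)
    h = np.einsum("ni,mnj->mij", ac, bc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", u, vt)))
    s[:, -1] *= sign
    n = len(a)
    msd = ((ac * ac).sum() + (bc * bc).sum(axis=(1, 2))
           - 2.0 * s.sum(axis=1)) / n
    return np.sqrt(np.maximum(msd, 0.0))


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random 3-D rotation from the supplied generator."""
    return Rotation.from_quat(_random_unit_quat(rng))


def _random_unit_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
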