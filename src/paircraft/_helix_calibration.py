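"""Derive the regular-duplex residue template from the constants table.

A backbone chain built from exactly repeating internal coordinates is an
exact helix: the rigid transform carrying residue i onto residue i+1 is the
same screw motion for every interior i.  This module builds a short chain
with the reference torsions of :data:`paircraft.ideal_geometry.HELIX`,
extracts that screw (axis, twist, rise), re-expresses one interior residue
in the helix frame (z = axis) and fixes the remaining gauge freedom
(rotation about z, shift along z) so that C1' sits at height 0 with its y
coordinate at half the tabulated paired-strand C1'-C1' distance.  The dyad
image (rotation by pi about x) of the template then gives the partner
strand with exactly that C1'-C1' separation.

Everything here is deterministic arithmetic on the frozen constants; no
randomness, no fitting at run time.
"""

from __future__ import annotations

import math

import numpy as np

from . import ideal_geometry as ig
from .errors import GeometryError


def _reference_chain(polymer_class: str, n: int = 6):
    from .geometry import TorsionSet, build_backbone

    par = ig.HELIX[polymer_class]
    ts = TorsionSet.uniform(n, par["torsions"], pucker=par["pucker"])
    return build_backbone(ts, [polymer_class] * n)


def screw_parameters(polymer_class: str) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(axis unit vector, point on axis, twist deg, rise A) of the
    reference chain's repeat transform, oriented so rise > 0."""
    from .geometry import kabsch_superpose

    chain = _reference_chain(polymer_class)
    names = sorted(chain.residues[2].keys())
    X = np.array([chain.residues[2][nm] for nm in names])
    Y = np.array([chain.residues[3][nm] for nm in names])
    R, t, fit_rmsd = kabsch_superpose(X, Y)
    if fit_rmsd > 1e-6:
        raise GeometryError(
            f"repeat transform is not rigid (rmsd {fit_rmsd:.2e}); "
            "non-uniform torsions?"
        )
    # rotation axis and signed angle from R
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w) / 2.0
    c = (np.trace(R) - 1.0) / 2.0
    if s < 1e-12:
        raise GeometryError("repeat transform has no rotation; degenerate helix")
    axis = w / (2.0 * s)
    angle = math.atan2(s, c)
    rise = float(np.dot(t, axis))
    if rise < 0:
        axis, rise, angle = -axis, -rise, -angle
    # point on the axis: (I - R) p = t_perp
    t_perp = t - np.dot(t, axis) * axis
    p0 = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)[0]
    p0 = p0 - np.dot(p0, axis) * axis + np.dot(X.mean(axis=0), axis) * axis
    return axis, p0, math.degrees(angle), rise


def residue_template(polymer_class: str) -> dict[str, np.ndarray]:
    """Interior-residue atom coordinates in the gauged helix frame."""
    par = ig.HELIX[polymer_class]
    axis, p0, twist, rise = screw_parameters(polymer_class)
    if abs(twist - par["twist"]) > 1e-4 or abs(rise - par["rise"]) > 1e-4:
        raise GeometryError(
            f"reference torsions give twist {twist:.6f} deg / rise {rise:.6f} A, "
            f"but the table declares {par['twist']} / {par['rise']}"
        )
    chain = _reference_chain(polymer_class)
    # orthonormal helix frame with z along the axis
    z = axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, z)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    x = seed - np.dot(seed, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    M = np.column_stack([x, y, z])
    local = {nm: M.T @ (xyz - p0) for nm, xyz in chain.residues[2].items()}
    # gauge: rotate about z and shift along z so C1' -> (x0, half_sep, 0)
    c1 = local["C1'"]
    r = math.hypot(c1[0], c1[1])
    half_sep = par["c1_c1_distance"] / 2.0
    if r <= half_sep:
        half_sep = r  # radius-limited; partner placed diametrically
    phi_target = math.asin(half_sep / r) if r > 0 else 0.0
    # choose the solution with positive x (cos > 0)
    dphi = phi_target - math.atan2(c1[1], c1[0])
    cz, sz = math.cos(dphi), math.sin(dphi)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([0.0, 0.0, -c1[2]])
    out = {nm: Rz @ xyz + shift for nm, xyz in local.items()}
    # the table's twist/rise regenerate the chain exactly; declare the
    # template with the phosphate group (interior residue)
    return out
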