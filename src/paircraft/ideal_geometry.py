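"""Ideal nucleic-acid geometry constants.

Bond lengths and angles follow standard small-molecule ideal-geometry
compilations for ribo- and deoxyribonucleotides (values in angstroms and
degrees).  The sugar-ring placement constants (``PUCKER_TEMPLATES``) are
internal coordinates measured from a least-squares closed furanose ring at
the canonical pucker phase of each mode (C3'-endo, pseudorotation phase
P = 18 deg; C2'-endo, P = 162 deg; amplitude 38 deg): placing ring atoms
with these constants reproduces that closed ring exactly, so the implied
C2'-C3' closure bond is consistent with the tabulated value to the ring-fit
residual (< 0.01 A).

``HELIX`` holds regular-duplex parameters: per-step twist and rise for
A-form RNA and B-form DNA, the reference backbone torsions that reproduce
exactly that twist and rise under this table's bonds and angles, and the
frozen per-residue atom template in the helix frame (z = helix axis, the
strand-pairing dyad along x).  The torsions were fitted once so that the
internal-coordinate chain they generate is an exact helix with the
canonical fibre-model twist/rise; the template is one residue of that chain
expressed in the helix frame.

Derivation script: the package's own internal-coordinate builder; see the
methods note for the fitting procedure.
"""

from __future__ import annotations

import numpy as np

# -- bond lengths (A) --------------------------------------------------------

BOND_LENGTHS: dict[str, float] = {
    "O3'-P": 1.607,
    "P-O5'": 1.593,
    "P-OP1": 1.485,
    "P-OP2": 1.485,
    "O5'-C5'": 1.440,
    "C5'-C4'": 1.510,
    "C4'-C3'": 1.524,
    "C3'-O3'": 1.423,
    "C4'-O4'": 1.453,
    "O4'-C1'": 1.414,
    "C1'-C2'": 1.528,
    "C2'-C3'": 1.525,   # ring closure; implied, not directly constructed
    "C2'-O2'": 1.413,
}

# -- bond angles (deg) -------------------------------------------------------

BOND_ANGLES: dict[str, float] = {
    "C3'-O3'-P": 119.7,
    "O3'-P-O5'": 104.0,
    "P-O5'-C5'": 120.9,
    "O5'-C5'-C4'": 111.5,
    "C5'-C4'-C3'": 115.5,
    "C4'-C3'-O3'": 110.6,
    "OP1-P-OP2": 119.6,
    # furanose ring angles
    "O4'-C4'-C3'": 105.5,
    "C1'-O4'-C4'": 109.7,
    "C2'-C1'-O4'": 106.4,
    "C1'-C2'-C3'": 101.5,  # implied by ring fit, not directly constructed
    "C2'-C3'-C4'": 102.7,  # implied by ring fit, not directly constructed
    "O2'-C2'-C1'": 110.8,
}

# -- sugar pucker placement templates ---------------------------------------
# Internal coordinates for the ring atoms placed after the main chain
# (which provides C5', C4', C3').  Entries are NeRF placements
#   atom: (ref_a, ref_b, ref_c, bond key, angle key, dihedral in deg)
# where the dihedral is measured over (ref_a, ref_b, ref_c, atom).
# Dihedral values are filled per pucker mode below (calibrated).

PUCKER_MODES = ("C3'-endo", "C2'-endo")

#: pseudorotation phase (deg) and amplitude (deg) defining each mode
PUCKER_PHASES: dict[str, tuple[float, float]] = {
    "C3'-endo": (18.0, 38.0),
    "C2'-endo": (162.0, 38.0),
}

# dihedral constants measured from the least-squares closed ring of each
# mode: tau_O4 = improper C5'-C3'-C4'-O4' (sugar chirality), nu4 and nu0 the
# endocyclic torsions used to place C1' and C2', tau_O2 the exocyclic
# O4'-C1'-C2'-O2' placement.  Values injected below by the calibration
# constants PUCKER_TEMPLATES.
PUCKER_TEMPLATES: dict[str, dict[str, float]] = {
    "C3'-endo": {
        "tau_O4": 121.5758220,
        "nu4": 22.7000060,
        "nu0": 0.3634779,
        "tau_O2": 96.8532838,
        "closure_C2C3": 1.5217052,
    },
    "C2'-endo": {
        "tau_O4": 121.5758220,
        "nu4": -0.3282591,
        "nu0": -22.8065986,
        "tau_O2": 155.8863140,
        "closure_C2C3": 1.5237322,
    },
}

#: default pucker per polymer class
DEFAULT_PUCKER: dict[str, str] = {"RNA": "C3'-endo", "DNA": "C2'-endo"}

# -- regular duplex parameters ----------------------------------------------
# twist (deg/bp), rise (A/bp): canonical fibre-model values.
# torsions: backbone torsions (alpha..zeta, deg) fitted so the built chain
#   is an exact helix with that twist and rise.
# template: per-residue backbone atom coordinates in the helix frame,
#   filled in by the calibration below (see _HELIX_TEMPLATES).

HELIX: dict[str, dict] = {
    "RNA": {
        "form": "A",
        "twist": 32.7,
        "rise": 2.81,
        "pucker": "C3'-endo",
        "torsions": {
            "alpha": -69.6661453,
            "beta": 178.0,
            "gamma": 54.0,
            "delta": 82.0,
            "epsilon": -153.0,
            "zeta": -73.0044628,
        },
        "c1_c1_distance": 10.4,
    },
    "DNA": {
        "form": "B",
        "twist": 36.0,
        "rise": 3.38,
        "pucker": "C2'-endo",
        "torsions": {
            "alpha": -53.9243117,
            "beta": 171.0,
            "gamma": 54.0,
            "delta": 128.0,
            "epsilon": -176.0,
            "zeta": -106.5527543,
        },
        "c1_c1_distance": 10.5,
    },
}

# Frozen helix-frame residue templates (atom name -> xyz), one per polymer
# class; generated by the calibration procedure described in the module
# docstring and injected here.  z is the helix axis; residue k of the
# leading strand is this template rotated by k*twist about z and raised by
# k*rise; the lagging strand is the dyad image (rotation by pi about x).
_HELIX_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {}


def helix_template(polymer_class: str) -> dict[str, np.ndarray]:
    """Per-residue helix-frame atom template for ``ideal_duplex``."""
    from . import _helix_calibration

    if polymer_class not in _HELIX_TEMPLATES:
        _HELIX_TEMPLATES[polymer_class] = _helix_calibration.residue_template(polymer_class)
    return {k: np.asarray(v, dtype=float) for k, v in _HELIX_TEMPLATES[polymer_class].items()}
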