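"""Full-atom nucleic-acid backbone construction and superposition metrics.

Backbones are built residue-by-residue with internal coordinates (NeRF):
each atom is placed from a bond length, bond angle and dihedral relative to
three previously placed atoms, following the sugar-phosphate connectivity
graph.  The six standard backbone torsions alpha..zeta drive the main chain
P-O5'-C5'-C4'-C3'-O3'; the furanose ring (O4', C1', C2', plus O2' for RNA)
is closed with a fixed pucker template (C3'-endo or C2'-endo by default).
Base atoms are out of scope: the glycosidic torsion chi is carried as
metadata but nothing is built beyond the sugar.

Per-residue rigid frames use the O4'-C1'-C2' atom triple: origin at C1',
first axis toward O4', second axis the orthogonalized C2' direction.

Also here: ideal A-/B-form duplex fixtures, Kabsch superposition,
TM-score and alignment coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import ideal_geometry as ig
from .errors import GeometryError, ValidationError

BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'")
_CORE_CHAIN = ("O5'", "C5'", "C4'", "C3'", "O3'")

# -- primitives --------------------------------------------------------------


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) over points a-b-c-d."""
    b0 = np.asarray(a, float) - np.asarray(b, float)
    b1 = np.asarray(c, float) - np.asarray(b, float)
    b2 = np.asarray(d, float) - np.asarray(c, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: the point d with |d-c| = bond, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# -- frames ------------------------------------------------------------------


@dataclass(frozen=True)
class Frame:
    """Rigid per-residue coordinate system: origin plus proper rotation."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        R = self.rotation
        if R.shape != (3, 3) or self.origin.shape != (3,):
            raise ValidationError("Frame needs a 3-vector origin and 3x3 rotation")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation is not orthonormal within 1e-8")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation is improper (det -1)")

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))


def frame_from_atoms(o4, c1, c2) -> Frame:
    """Frame from the O4'-C1'-C2' atom triple.

    Origin at C1'; x axis the unit vector toward O4'; y axis the component
    of C1'->C2' orthogonal to x, normalized; z = x cross y.  Equivariant
    under rigid motion of the three atoms.
    """
    o4, c1, c2 = (np.asarray(p, float) for p in (o4, c1, c2))
    e1 = o4 - c1
    n1 = np.linalg.norm(e1)
    if n1 < 1e-8:
        raise GeometryError("O4' coincides with C1'")
    e1 = e1 / n1
    v = c2 - c1
    e2 = v - np.dot(v, e1) * e1
    n2 = np.linalg.norm(e2)
    if n2 < 1e-8:
        raise GeometryError("O4', C1', C2' are collinear or coincident")
    e2 = e2 / n2
    e3 = np.cross(e1, e2)
    return Frame(origin=c1, rotation=np.column_stack([e1, e2, e3]))


# -- torsions ----------------------------------------------------------------

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@dataclass
class TorsionSet:
    """Per-residue backbone torsions (degrees) plus pucker mode labels.

    ``alpha``/``beta`` of the first residue and ``epsilon``/``zeta`` of the
    last are undefined (the flanking phosphate does not exist) and are held
    as NaN; ``chi`` is metadata only since base atoms are not built.  All
    defined angles must lie in (-180, 180].
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray
    zeta: np.ndarray
    chi: np.ndarray | None = None
    pucker: list[str] | None = None

    def __post_init__(self) -> None:
        arrays = []
        for name in TORSION_NAMES[:6]:
            arr = np.asarray(getattr(self, name), float).ravel()
            setattr(self, name, arr)
            arrays.append(arr)
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValidationError("torsion arrays have unequal lengths")
        if self.chi is None:
            self.chi = np.full(n, np.nan)
        else:
            self.chi = np.asarray(self.chi, float).ravel()
            if len(self.chi) != n:
                raise ValidationError("chi length mismatch")
        if self.pucker is None:
            self.pucker = ["C3'-endo"] * n
        if len(self.pucker) != n:
            raise ValidationError("pucker label count mismatch")
        for name in TORSION_NAMES:
            arr = getattr(self, name)
            finite = arr[np.isfinite(arr)]
            if np.any((finite <= -180.0) | (finite > 180.0)):
                raise ValidationError(f"torsion {name} outside (-180, 180]")
        for p in self.pucker:
            if p not in ig.PUCKER_MODES:
                raise GeometryError(f"unknown pucker mode {p!r}")

    def __len__(self) -> int:
        return len(self.alpha)

    @classmethod
    def uniform(
        cls,
        n: int,
        values: dict[str, float],
        pucker: str = "C3'-endo",
    ) -> "TorsionSet":
        """Repeat one torsion dictionary over ``n`` residues."""
        cols = {k: np.full(n, float(values.get(k, np.nan))) for k in TORSION_NAMES[:6]}
        ts = cls(**cols, chi=np.full(n, float(values.get("chi", np.nan))), pucker=[pucker] * n)
        ts.alpha[0] = np.nan
        ts.beta[0] = np.nan
        ts.epsilon[-1] = np.nan
        ts.zeta[-1] = np.nan
        return ts

    # tab-separated table I/O -------------------------------------------------

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# residue\t" + "\t".join(TORSION_NAMES) + "\tpucker\n")
            for i in range(len(self)):
                vals = "\t".join(
                    f"{getattr(self, nm)[i]:.6f}" if np.isfinite(getattr(self, nm)[i]) else "NA"
                    for nm in TORSION_NAMES
                )
                fh.write(f"{i}\t{vals}\t{self.pucker[i]}\n")

    @classmethod
    def from_table(cls, path) -> "TorsionSet":
        rows: list[tuple[list[float], str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                vals = [float("nan") if f == "NA" else float(f) for f in fields[1:8]]
                pucker = fields[8] if len(fields) > 8 else "C3'-endo"
                rows.append((vals, pucker))
        if not rows:
            raise ValidationError("empty torsion table")
        cols = np.array([r[0] for r in rows], float)
        return cls(
            alpha=cols[:, 0], beta=cols[:, 1], gamma=cols[:, 2], delta=cols[:, 3],
            epsilon=cols[:, 4], zeta=cols[:, 5], chi=cols[:, 6],
            pucker=[r[1] for r in rows],
        )


# -- chains ------------------------------------------------------------------


@dataclass
class NucleicChain:
    """One 5'->3' nucleic-acid strand with per-residue atom coordinates."""

    residues: list[dict[str, np.ndarray]]
    polymer_class: list[str]
    sequence: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.polymer_class):
            raise ValidationError("residue and polymer-class counts differ")
        for pc in self.polymer_class:
            if pc not in ("RNA", "DNA"):
                raise ValidationError(f"polymer class must be RNA or DNA, got {pc!r}")
        self.residues = [
            {name: np.asarray(xyz, float) for name, xyz in res.items()}
            for res in self.residues
        ]

    def __len__(self) -> int:
        return len(self.residues)

    def atom(self, i: int, name: str) -> np.ndarray:
        try:
            return self.residues[i][name]
        except KeyError:
            raise GeometryError(f"residue {i} lacks atom {name}") from None

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack selected atom coordinates over all residues (default C1')."""
        names = names or ("C1'",)
        return np.array([self.atom(i, nm) for i in range(len(self)) for nm in names])

    def frames(self) -> list[Frame]:
        """O4'-C1'-C2' frame of every residue."""
        return [
            frame_from_atoms(self.atom(i, "O4'"), self.atom(i, "C1'"), self.atom(i, "C2'"))
            for i in range(len(self))
        ]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "NucleicChain":
        """Rigidly transformed copy (x -> R x + t)."""
        return NucleicChain(
            residues=[{nm: R @ xyz + t for nm, xyz in res.items()} for res in self.residues],
            polymer_class=list(self.polymer_class),
            sequence=list(self.sequence) if self.sequence else None,
        )

    def validate(self, bond_tol: float = 0.1) -> None:
        """Check polymer-class chemistry and backbone connectivity.

        RNA residues must carry O2' and DNA residues must not; every residue
        needs the full backbone atom set (the 5'-terminal residue may lack
        the phosphate group); consecutive O3'(i)-P(i+1) bonds must be within
        ``bond_tol`` of the ideal phosphodiester length.
        """
        required = {"O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}
        for i, (res, pc) in enumerate(zip(self.residues, self.polymer_class)):
            if pc == "RNA" and "O2'" not in res:
                raise ValidationError(f"RNA residue {i} lacks O2'")
            if pc == "DNA" and "O2'" in res:
                raise ValidationError(f"DNA residue {i} carries O2'")
            need = required | ({"P", "OP1", "OP2"} if i > 0 else set())
            missing = need - set(res)
            if missing:
                raise ValidationError(f"residue {i} missing atoms {sorted(missing)}")
        ideal = ig.BOND_LENGTHS["O3'-P"]
        for i in range(len(self) - 1):
            d = float(np.linalg.norm(self.atom(i + 1, "P") - self.atom(i, "O3'")))
            if abs(d - ideal) > bond_tol:
                raise ValidationError(
                    f"O3'({i})-P({i + 1}) bond {d:.3f} A deviates more than "
                    f"{bond_tol} A from ideal {ideal} A"
                )


# -- backbone construction ---------------------------------------------------


def _ring_atoms(res: dict[str, np.ndarray], pucker: str, polymer_class: str) -> None:
    """Close the furanose ring (and O2' for RNA) onto a placed main chain."""
    tpl = ig.PUCKER_TEMPLATES[pucker]
    res["O4'"] = place_atom(
        res["C5'"], res["C3'"], res["C4'"],
        ig.BOND_LENGTHS["C4'-O4'"], ig.BOND_ANGLES["O4'-C4'-C3'"], tpl["tau_O4"],
    )
    res["C1'"] = place_atom(
        res["C3'"], res["C4'"], res["O4'"],
        ig.BOND_LENGTHS["O4'-C1'"], ig.BOND_ANGLES["C1'-O4'-C4'"], tpl["nu4"],
    )
    res["C2'"] = place_atom(
        res["C4'"], res["O4'"], res["C1'"],
        ig.BOND_LENGTHS["C1'-C2'"], ig.BOND_ANGLES["C2'-C1'-O4'"], tpl["nu0"],
    )
    if polymer_class == "RNA":
        res["O2'"] = place_atom(
            res["O4'"], res["C1'"], res["C2'"],
            ig.BOND_LENGTHS["C2'-O2'"], ig.BOND_ANGLES["O2'-C2'-C1'"], tpl["tau_O2"],
        )


def _phosphate_oxygens(res: dict[str, np.ndarray], prev_o3: np.ndarray) -> None:
    """Place the non-bridging OP1/OP2 symmetric about the O3'-P-O5' plane."""
    p = res["P"]
    u = prev_o3 - p
    u /= np.linalg.norm(u)
    v = res["O5'"] - p
    v /= np.linalg.norm(v)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    half = math.radians(ig.BOND_ANGLES["OP1-P-OP2"] / 2.0)
    bond = ig.BOND_LENGTHS["P-OP1"]
    res["OP1"] = p + bond * (math.cos(half) * bis + math.sin(half) * perp)
    res["OP2"] = p + bond * (math.cos(half) * bis - math.sin(half) * perp)


def build_backbone(
    torsions: TorsionSet,
    polymer_classes: Sequence[str],
    start_frame: Frame | None = None,
) -> NucleicChain:
    """Build a full sugar-phosphate backbone by torsion propagation.

    The first residue is anchored by ``start_frame`` (identity by default):
    its O5' sits at the frame origin, C5' along the frame x axis and C4' in
    the frame xy plane; it carries no phosphate group.  Subsequent residues
    are propagated through epsilon(i-1), zeta(i-1), alpha(i), beta(i),
    gamma(i), delta(i); the sugar ring is closed with the residue's pucker
    template and O2' is added for RNA residues only.
    """
    n = len(torsions)
    if n != len(polymer_classes):
        raise ValidationError(
            f"{n} torsion rows but {len(polymer_classes)} polymer classes"
        )
    if n == 0:
        raise ValidationError("empty torsion set")
    frame = start_frame or Frame.identity()
    R, o = frame.rotation, frame.origin
    bl, ba = ig.BOND_LENGTHS, ig.BOND_ANGLES

    residues: list[dict[str, np.ndarray]] = []
    res: dict[str, np.ndarray] = {}
    # 5'-terminal residue, anchored in the start frame without a phosphate
    res["O5'"] = o.copy()
    res["C5'"] = o + bl["O5'-C5'"] * R[:, 0]
    ang = math.radians(ba["O5'-C5'-C4'"])
    res["C4'"] = res["C5'"] + bl["C5'-C4'"] * (
        -math.cos(ang) * R[:, 0] + math.sin(ang) * R[:, 1]
    )
    res["C3'"] = place_atom(
        res["O5'"], res["C5'"], res["C4'"], bl["C4'-C3'"], ba["C5'-C4'-C3'"],
        _need(torsions.gamma[0], "gamma", 0),
    )
    res["O3'"] = place_atom(
        res["C5'"], res["C4'"], res["C3'"], bl["C3'-O3'"], ba["C4'-C3'-O3'"],
        _need(torsions.delta[0], "delta", 0),
    )
    _ring_atoms(res, torsions.pucker[0], polymer_classes[0])
    residues.append(res)

    for i in range(1, n):
        prev = residues[-1]
        res = {}
        res["P"] = place_atom(
            prev["C4'"], prev["C3'"], prev["O3'"], bl["O3'-P"], ba["C3'-O3'-P"],
            _need(torsions.epsilon[i - 1], "epsilon", i - 1),
        )
        res["O5'"] = place_atom(
            prev["C3'"], prev["O3'"], res["P"], bl["P-O5'"], ba["O3'-P-O5'"],
            _need(torsions.zeta[i - 1], "zeta", i - 1),
        )
        res["C5'"] = place_atom(
            prev["O3'"], res["P"], res["O5'"], bl["O5'-C5'"], ba["P-O5'-C5'"],
            _need(torsions.alpha[i], "alpha", i),
        )
        res["C4'"] = place_atom(
            res["P"], res["O5'"], res["C5'"], bl["C5'-C4'"], ba["O5'-C5'-C4'"],
            _need(torsions.beta[i], "beta", i),
        )
        res["C3'"] = place_atom(
            res["O5'"], res["C5'"], res["C4'"], bl["C4'-C3'"], ba["C5'-C4'-C3'"],
            _need(torsions.gamma[i], "gamma", i),
        )
        res["O3'"] = place_atom(
            res["C5'"], res["C4'"], res["C3'"], bl["C3'-O3'"], ba["C4'-C3'-O3'"],
            _need(torsions.delta[i], "delta", i),
        )
        _phosphate_oxygens(res, prev["O3'"])
        _ring_atoms(res, torsions.pucker[i], polymer_classes[i])
        residues.append(res)
    return NucleicChain(residues=residues, polymer_class=list(polymer_classes))


def _need(value: float, name: str, i: int) -> float:
    if not np.isfinite(value):
        raise ValidationError(f"torsion {name}[{i}] is required but undefined (NaN)")
    return float(value)


def extract_torsions(chain: NucleicChain) -> TorsionSet:
    """Measure backbone torsions from coordinates (inverse of build).

    alpha/beta of residue 0 and epsilon/zeta of the last residue come back
    NaN; the pucker label is inferred from the sign of the endocyclic
    nu2 torsion (C1'-C2'-C3'-C4').
    """
    n = len(chain)
    cols = {nm: np.full(n, np.nan) for nm in TORSION_NAMES[:6]}
    pucker: list[str] = []

    def at(i: int, name: str) -> np.ndarray:
        res = chain.residues[i]
        if name not in res:
            raise GeometryError(f"extraction failed: residue {i} lacks atom {name}")
        return res[name]

    for i in range(n):
        if i > 0:
            cols["alpha"][i] = dihedral(at(i - 1, "O3'"), at(i, "P"), at(i, "O5'"), at(i, "C5'"))
            cols["beta"][i] = dihedral(at(i, "P"), at(i, "O5'"), at(i, "C5'"), at(i, "C4'"))
        cols["gamma"][i] = dihedral(at(i, "O5'"), at(i, "C5'"), at(i, "C4'"), at(i, "C3'"))
        cols["delta"][i] = dihedral(at(i, "C5'"), at(i, "C4'"), at(i, "C3'"), at(i, "O3'"))
        if i < n - 1:
            cols["epsilon"][i] = dihedral(at(i, "C4'"), at(i, "C3'"), at(i, "O3'"), at(i + 1, "P"))
            cols["zeta"][i] = dihedral(at(i, "C3'"), at(i, "O3'"), at(i + 1, "P"), at(i + 1, "O5'"))
        nu2 = dihedral(at(i, "C1'"), at(i, "C2'"), at(i, "C3'"), at(i, "C4'"))
        pucker.append("C3'-endo" if nu2 > 0 else "C2'-endo")
    return TorsionSet(**cols, pucker=pucker)


# -- ideal duplex fixture ----------------------------------------------------


@dataclass(frozen=True)
class Duplex:
    """Two antiparallel strands plus their per-chain base-pair map."""

    strand_a: NucleicChain
    strand_b: NucleicChain
    pairs: frozenset[tuple[int, int]]


def ideal_duplex(polymer_class: str, n_bp: int) -> Duplex:
    """Idealized regular duplex: A-form for RNA, B-form for DNA.

    Residue ``k`` of the leading strand is the helix-frame residue template
    rotated by ``k * twist`` about the helix axis and raised by
    ``k * rise``; the lagging strand is the dyad image (rotation by pi about
    the x axis), listed 5'->3'.  Base pair ``k`` joins leading-strand
    residue ``k`` with lagging-strand residue ``n_bp - 1 - k``.
    """
    if polymer_class not in ig.HELIX:
        raise ValidationError(f"polymer class must be RNA or DNA, got {polymer_class!r}")
    if n_bp < 1:
        raise ValidationError(f"n_bp must be >= 1, got {n_bp}")
    par = ig.HELIX[polymer_class]
    template = ig.helix_template(polymer_class)
    twist = math.radians(par["twist"])
    rise = par["rise"]
    dyad = np.diag([1.0, -1.0, -1.0])

    def rz(theta: float) -> np.ndarray:
        c, s = math.cos(theta), math.sin(theta)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def residue(k: int, flip: bool) -> dict[str, np.ndarray]:
        R = rz(k * twist)
        t = np.array([0.0, 0.0, k * rise])
        out = {}
        for nm, xyz in template.items():
            p = dyad @ xyz if flip else xyz
            out[nm] = R @ p + t
        return out

    lead = [residue(k, False) for k in range(n_bp)]
    # lagging strand 5'->3': dyad image of leading residues k, k-1, ... built
    # by walking k downward keeps its own O3'->P connectivity intact
    lag = [residue(k, True) for k in range(n_bp - 1, -1, -1)]
    for strand in (lead, lag):
        strand[0].pop("P", None)
        strand[0].pop("OP1", None)
        strand[0].pop("OP2", None)
    pc = [polymer_class] * n_bp
    return Duplex(
        strand_a=NucleicChain(residues=lead, polymer_class=pc),
        strand_b=NucleicChain(residues=lag, polymer_class=list(pc)),
        pairs=frozenset((k, n_bp - 1 - k) for k in range(n_bp)),
    )


# -- superposition metrics ---------------------------------------------------


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y.

    Returns ``(R, t, rmsd)`` minimizing ``||R X + t - Y||``; reflections are
    excluded (proper rotation, det +1).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError(f"point sets must both be (n, 3); got {X.shape} and {Y.shape}")
    if len(X) < 3:
        raise ValidationError("need at least 3 points for superposition")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / len(X)))
    return R, t, rmsd


def rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD after optimal superposition of X onto Y."""
    return kabsch_superpose(X, Y)[2]


def d0_length_scale(L_norm: int, mode: str = "RNA") -> float:
    """TM-score distance scale d0 as a function of normalization length.

    RNA mode uses ``0.6 * sqrt(L - 0.5) - 2.5`` floored at 1.0 A; protein
    mode uses ``1.24 * cbrt(L - 15) - 1.8`` floored at 0.5 A.  Both formulas
    are the published length-dependent normalizations of the structure-
    alignment literature; the floors keep d0 positive for short chains.
    """
    if L_norm < 1:
        raise ValidationError(f"L_norm must be >= 1, got {L_norm}")
    mode = mode.upper()
    if mode in ("RNA", "DNA", "NA"):
        return max(1.0, 0.6 * math.sqrt(L_norm - 0.5) - 2.5)
    if mode == "PROTEIN":
        return max(0.5, 1.24 * np.cbrt(L_norm - 15.0) - 1.8)
    raise ValidationError(f"unknown d0 mode {mode!r}")


#: inlier-selection schedule for the TM-score superposition search:
#: distance cutoffs in multiples of d0, iterated to a fixed point each.
_TM_CUTOFF_SCHEDULE = (8.0, 4.0, 2.0, 1.0)


def tm_score(
    X: np.ndarray,
    Y: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
    L_norm: int | None = None,
    d0_mode: str = "RNA",
    d0: float | None = None,
) -> float:
    """Length-normalized template-modelling score in (0, 1].

    ``score = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2)`` over the
    corresponded pairs, after the score-optimal superposition.  The
    correspondence is an explicit input (this is not an alignment search);
    by default it is the identity over equal-length point sets and
    ``L_norm`` defaults to the correspondence size.  The superposition is
    searched by iterated Kabsch fits on shrinking inlier sets (cutoffs
    ``8, 4, 2, 1 x d0``, each iterated to a fixed point), keeping the best
    score seen; with fewer than 3 corresponded pairs the points are scored
    in place (no superposition is defined).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if correspondence is None:
        if len(X) != len(Y):
            raise ValidationError("equal-length point sets required for default correspondence")
        correspondence = [(i, i) for i in range(len(X))]
    correspondence = list(correspondence)
    if not correspondence:
        raise ValidationError("empty correspondence: TM-score undefined")
    ix = np.array([i for i, _ in correspondence], int)
    iy = np.array([j for _, j in correspondence], int)
    if ix.max() >= len(X) or iy.max() >= len(Y) or ix.min() < 0 or iy.min() < 0:
        raise ValidationError("correspondence index out of range")
    n = len(correspondence)
    if L_norm is None:
        L_norm = n
    if L_norm < n:
        raise ValidationError(f"L_norm {L_norm} smaller than correspondence size {n}")
    scale = d0 if d0 is not None else d0_length_scale(L_norm, d0_mode)
    P, Q = X[ix], Y[iy]

    def score_of(dists: np.ndarray) -> float:
        return float(np.sum(1.0 / (1.0 + (dists / scale) ** 2)) / L_norm)

    if n < 3:
        return score_of(np.linalg.norm(P - Q, axis=1))

    best = 0.0
    sel = np.ones(n, bool)
    for mult in _TM_CUTOFF_SCHEDULE:
        cutoff = mult * scale
        for _ in range(50):
            if sel.sum() < 3:
                break
            R, t, _ = kabsch_superpose(P[sel], Q[sel])
            dists = np.linalg.norm((P @ R.T + t) - Q, axis=1)
            best = max(best, score_of(dists))
            new_sel = dists < cutoff
            if new_sel.sum() < 3 or np.array_equal(new_sel, sel):
                break
            sel = new_sel
        sel = np.ones(n, bool)  # restart each cutoff from the full set
        for _ in range(50):
            R, t, _ = kabsch_superpose(P[sel], Q[sel])
            dists = np.linalg.norm((P @ R.T + t) - Q, axis=1)
            best = max(best, score_of(dists))
            new_sel = dists < cutoff
            if new_sel.sum() < 3 or np.array_equal(new_sel, sel):
                break
            sel = new_sel
    return best


def coverage(L_aligned: int, L_design: int) -> float:
    """Alignment coverage: aligned length over design length."""
    if L_design < 1:
        raise ValidationError(f"L_design must be >= 1, got {L_design}")
    if L_aligned < 0:
        raise ValidationError(f"L_aligned must be >= 0, got {L_aligned}")
    return L_aligned / L_design


# -- PDB I/O -----------------------------------------------------------------

_DEFAULT_RESNAME = {"RNA": "A", "DNA": "DA"}


def write_pdb(path, chains: Sequence[NucleicChain], chain_ids: Sequence[str] | None = None) -> None:
    """Write chains to PDB with standard primed atom names and TER records."""
    import gemmi

    st = gemmi.Structure()
    st.name = "paircraft"
    model = gemmi.Model("1")
    ids = chain_ids or [chr(ord("A") + k) for k in range(len(chains))]
    serial = 1
    for chain, cid in zip(chains, ids):
        gchain = gemmi.Chain(str(cid))
        seq = chain.sequence or [_DEFAULT_RESNAME[pc] for pc in chain.polymer_class]
        for i, res in enumerate(chain.residues):
            gres = gemmi.Residue()
            gres.name = seq[i]
            gres.seqid = gemmi.SeqId(i + 1, " ")
            for nm in sorted(res, key=_atom_order):
                at = gemmi.Atom()
                at.name = nm
                at.element = gemmi.Element(nm[0])
                x, y, z = res[nm]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                at.serial = serial
                serial += 1
                gres.add_atom(at)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _atom_order(name: str) -> int:
    order = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")
    return order.index(name) if name in order else len(order)


def read_pdb(path) -> list[NucleicChain]:
    """Read nucleic-acid chains from a PDB file.

    Polymer class is inferred per residue: O2' present (or a D-prefixed
    residue name absent) means RNA, otherwise DNA.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    chains: list[NucleicChain] = []
    for gchain in st[0]:
        residues: list[dict[str, np.ndarray]] = []
        classes: list[str] = []
        seq: list[str] = []
        for gres in gchain:
            atoms = {
                at.name: np.array([at.pos.x, at.pos.y, at.pos.z])
                for at in gres
            }
            if "C1'" not in atoms:
                continue  # skip non-nucleotide residues (ions, ligands)
            residues.append(atoms)
            is_dna = gres.name.startswith("D") or ("O2'" not in atoms)
            classes.append("DNA" if is_dna else "RNA")
            seq.append(gres.name)
        if residues:
            chains.append(NucleicChain(residues=residues, polymer_class=classes, sequence=seq))
    return chains
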