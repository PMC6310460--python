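"""Canonical triphosphate-chain model and geometric primitives.

The chain is described by twelve canonical atom labels (three phosphorus
atoms and nine oxygens, CHARMM/IUPAC naming) plus the ester oxygen O5' and
optional Mg.  Five scalar descriptors characterise one chain:

* ``d_pa_pg``      -- the PA-PG distance (Angstrom),
* ``theta_bridge`` -- the PB-O3B-PG bridge angle (degrees),
* ``psi_ab``       -- dihedral O2A-PA-PB-O2B,
* ``psi_bg``       -- dihedral O1B-PB-PG-O1G,
* ``psi_ag``       -- dihedral O1A-PA-PG-O3G.

Dihedrals are signed, IUPAC convention (clockwise positive looking from the
second to the third atom), reported in (-180, 180].  0 deg is the eclipsed
arrangement, +/-60 deg the staggered one.

``InternalChainSpec`` + ``embed_chain`` provide the inverse operation:
construct 3D coordinates realising requested descriptor values, used for
synthetic fixtures and round-trip validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CHAIN_LABELS",
    "ALPHA_OXYGENS",
    "BETA_OXYGENS",
    "GAMMA_OXYGENS",
    "NONBRIDGING",
    "DegenerateGeometryError",
    "MissingAtomError",
    "InfeasibleGeometryError",
    "PhosphateChain",
    "GeometryDescriptors",
    "InternalChainSpec",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "compute_descriptors",
    "embed_chain",
    "kabsch_superpose",
]

#: The twelve canonical chain labels (completeness is judged against these).
CHAIN_LABELS = (
    "PA", "PB", "PG",
    "O1A", "O2A", "O3A",
    "O1B", "O2B", "O3B",
    "O1G", "O2G", "O3G",
)

#: Oxygens assigned to each phosphate group for ion-distance measurements.
#: Bridging oxygens are included with the group whose label they carry
#: (O3A with alpha, O3B with beta); the ester O5' counts as an alpha oxygen
#: when present.
ALPHA_OXYGENS = ("O1A", "O2A", "O3A", "O5'")
BETA_OXYGENS = ("O1B", "O2B", "O3B")
GAMMA_OXYGENS = ("O1G", "O2G", "O3G")

#: Non-bridging oxygens per group, used for Mg coordination classification.
NONBRIDGING = {
    "A": ("O1A", "O2A"),
    "B": ("O1B", "O2B"),
    "G": ("O1G", "O2G", "O3G"),
}

#: Bonded P-O pairs checked for physically plausible lengths.
BONDED_PAIRS = (
    ("PA", "O1A"), ("PA", "O2A"), ("PA", "O3A"), ("PA", "O5'"),
    ("PB", "O1B"), ("PB", "O2B"), ("PB", "O3A"), ("PB", "O3B"),
    ("PG", "O1G"), ("PG", "O2G"), ("PG", "O3G"), ("PG", "O3B"),
)

#: Collinearity threshold on the cross-product norm (Angstrom^2).
COLLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when an angle or dihedral is undefined (collinear atoms)."""


class MissingAtomError(KeyError):
    """Raised when required chain atoms are absent; carries their labels."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        super().__init__(f"missing chain atoms: {', '.join(self.labels)}")


class InfeasibleGeometryError(ValueError):
    """Raised when requested descriptors cannot be realised in 3D."""


# ---------------------------------------------------------------------------
# geometric primitives (broadcast over leading dimensions)
# ---------------------------------------------------------------------------

def measure_distance(p1, p2):
    """Euclidean distance; broadcasts over leading axes of (..., 3) input."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return np.linalg.norm(p2 - p1, axis=-1)


def measure_angle(p1, p2, p3):
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise DegenerateGeometryError("coincident atoms in angle measurement")
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def measure_dihedral(p1, p2, p3, p4, atom_names=None):
    """Signed dihedral p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of p4 relative to p1 is positive.  Raises
    :class:`DegenerateGeometryError` when either bounding triple is
    collinear (cross-product norm below ``COLLINEAR_TOL``).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    bad = (np.linalg.norm(n1, axis=-1) < COLLINEAR_TOL) | (
        np.linalg.norm(n2, axis=-1) < COLLINEAR_TOL
    )
    if np.any(bad):
        names = "" if atom_names is None else f" ({', '.join(atom_names)})"
        raise DegenerateGeometryError(
            f"collinear atom triple, dihedral undefined{names}"
        )
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 into the half-open interval (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang if ang.ndim else float(ang)


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return w if w.ndim else float(w)


def nerf_place(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d).

    Natural-extension reference frame construction; ``angle_deg`` and
    ``dihedral_deg`` may be arrays (broadcast, returning stacked points).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = np.radians(np.asarray(angle_deg, dtype=float))
    dih = np.radians(np.asarray(dihedral_deg, dtype=float))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("collinear reference frame in placement")
    n /= nn
    m = np.cross(n, bc)
    c0, c1, c2 = np.broadcast_arrays(
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dih),
        bond * np.sin(angle) * np.sin(dih),
    )
    d_local = np.stack([c0, c1, c2], axis=-1)
    frame = np.stack([bc, m, n], axis=-1)  # columns
    return c + d_local @ frame.T


def kabsch_superpose(mobile, reference):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need two equally sized (n>=3, 3) point sets")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=-1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhosphateChain:
    """Labeled 3D coordinates of one triphosphate chain (one frame/site).

    ``coords`` maps canonical labels to (3,) arrays; extra labels (O5', MG,
    N1, F4 of a tetrafluoride mimic, ...) are allowed.  ``is_mimic`` flags
    atoms that stand in for a gamma-phosphate mimic (Al/Be/Mg centre, F).
    """

    coords: dict
    is_mimic: dict = field(default_factory=dict)
    source: Optional[str] = None

    def __post_init__(self):
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}

    def __contains__(self, label):
        return label in self.coords

    def __getitem__(self, label):
        try:
            return self.coords[label]
        except KeyError:
            raise MissingAtomError([label]) from None

    @property
    def mg(self):
        return self.coords.get("MG")

    @property
    def has_mimic(self) -> bool:
        return any(self.is_mimic.values())

    def missing_labels(self):
        return tuple(l for l in CHAIN_LABELS if l not in self.coords)

    @property
    def is_complete(self) -> bool:
        return not self.missing_labels()

    def oxygens(self, group: str):
        """Coordinates of all present oxygens of group 'A', 'B' or 'G'."""
        labels = {"A": ALPHA_OXYGENS, "B": BETA_OXYGENS, "G": GAMMA_OXYGENS}[group]
        pts = [self.coords[l] for l in labels if l in self.coords]
        # a tetrafluoride mimic contributes its fourth fluorine to gamma
        if group == "G" and "F4" in self.coords:
            pts.append(self.coords["F4"])
        return np.array(pts)

    def bond_violations(self, lo: float = 1.2, hi: float = 2.2):
        """P-O bonds outside [lo, hi] Angstrom for non-mimic atoms.

        Returns a list of ``(label_p, label_o, distance)``; violations are
        reported, never silently dropped.
        """
        out = []
        for lp, lo_ in BONDED_PAIRS:
            if lp not in self.coords or lo_ not in self.coords:
                continue
            if self.is_mimic.get(lp) or self.is_mimic.get(lo_):
                continue
            d = float(measure_distance(self.coords[lp], self.coords[lo_]))
            if not lo <= d <= hi:
                out.append((lp, lo_, d))
        return out

    def transformed(self, rotation, translation):
        """Return a copy with ``x -> rotation @ x + translation`` applied."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return PhosphateChain(
            coords={k: R @ v + t for k, v in self.coords.items()},
            is_mimic=dict(self.is_mimic),
            source=self.source,
        )


@dataclass(frozen=True)
class GeometryDescriptors:
    """The five scalar descriptors of one chain."""

    d_pa_pg: float
    theta_bridge: float
    psi_ab: float
    psi_bg: float
    psi_ag: float
    mimic_derived: bool = False

    def __post_init__(self):
        if not self.d_pa_pg > 0:
            raise ValueError("d_pa_pg must be positive")
        if not 0.0 <= self.theta_bridge <= 180.0:
            raise ValueError("theta_bridge must lie in [0, 180]")
        for name in ("psi_ab", "psi_bg", "psi_ag"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} must lie in (-180, 180]")

    def abs_psis(self):
        """Magnitudes of the three dihedrals (printed convention)."""
        return (abs(self.psi_ab), abs(self.psi_bg), abs(self.psi_ag))

    def as_dict(self):
        return {
            "d_pa_pg": self.d_pa_pg,
            "theta_bridge": self.theta_bridge,
            "psi_ab": self.psi_ab,
            "psi_bg": self.psi_bg,
            "psi_ag": self.psi_ag,
            "mimic_derived": self.mimic_derived,
        }


def compute_descriptors(chain: PhosphateChain) -> GeometryDescriptors:
    """Measure all five descriptors of a complete chain.

    Mimic-mapped atoms are used where present and the result is flagged
    ``mimic_derived``.  Raises :class:`MissingAtomError` listing absent
    labels for incomplete chains and :class:`DegenerateGeometryError` for
    undefined angles.
    """
    missing = chain.missing_labels()
    if missing:
        raise MissingAtomError(missing)
    c = chain.coords
    d = float(measure_distance(c["PA"], c["PG"]))
    theta = float(measure_angle(c["PB"], c["O3B"], c["PG"]))
    psi_ab = float(
        measure_dihedral(c["O2A"], c["PA"], c["PB"], c["O2B"],
                         atom_names=("O2A", "PA", "PB", "O2B"))
    )
    psi_bg = float(
        measure_dihedral(c["O1B"], c["PB"], c["PG"], c["O1G"],
                         atom_names=("O1B", "PB", "PG", "O1G"))
    )
    psi_ag = float(
        measure_dihedral(c["O1A"], c["PA"], c["PG"], c["O3G"],
                         atom_names=("O1A", "PA", "PG", "O3G"))
    )
    return GeometryDescriptors(
        d_pa_pg=d,
        theta_bridge=theta,
        psi_ab=psi_ab,
        psi_bg=psi_bg,
        psi_ag=psi_ag,
        mimic_derived=chain.has_mimic,
    )


# ---------------------------------------------------------------------------
# internal-coordinate embedding
# ---------------------------------------------------------------------------

@dataclass
class InternalChainSpec:
    """Internal coordinates (+ optional descriptor targets) for embedding.

    The backbone PA-O3A-PB-O3B-PG is built from bond lengths, the two
    backbone angles, the bridge angle and two backbone dihedrals ``d1``
    (PA-O3A-PB-O3B) and ``d2`` (O3A-PB-O3B-PG).  Terminal oxygens are
    attached tetrahedrally; the alpha and gamma groups carry free rotations
    ``tau_a`` / ``tau_g``, the beta group orientation is fixed by the
    backbone.  When descriptor targets are set, :func:`embed_chain` solves
    for the free parameters that realise them:

    ======================  ==================
    target                  adjusted parameter
    ======================  ==================
    ``target_d_pa_pg``      ``d2``
    ``target_psi_ab``       ``tau_a``
    ``target_psi_bg``       ``tau_g``
    ``target_psi_ag``       ``d1``
    ======================  ==================

    ``theta_bridge`` is an internal coordinate and is realised exactly.
    """

    bond_po_bridge: float = 1.60
    bond_po_terminal: float = 1.50
    angle_pa: float = 130.0       # PA-O3A-PB
    angle_pb: float = 105.0       # O3A-PB-O3B
    angle_terminal: float = 109.5
    theta_bridge: float = 130.0   # PB-O3B-PG
    d1: float = -60.0
    d2: float = 170.0
    tau_a: float = 60.0
    tau_g: float = 60.0
    #: azimuthal distortion of O3G away from the ideal tau_g + 240 slot
    #: (degrees).  Kept at 0 for ideal tetrahedra; used as a last-resort
    #: degree of freedom when a rigid-group solve cannot reach a requested
    #: psi triple (e.g. the fully eclipsed arrangement).
    gamma_split: float = 0.0
    target_d_pa_pg: Optional[float] = None
    target_psi_ab: Optional[float] = None
    target_psi_bg: Optional[float] = None
    target_psi_ag: Optional[float] = None

    def __post_init__(self):
        for name in ("bond_po_bridge", "bond_po_terminal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_pa", "angle_pb", "angle_terminal", "theta_bridge"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must lie in (0, 180)")
        if self.target_d_pa_pg is not None and self.target_d_pa_pg <= 0:
            raise ValueError("target_d_pa_pg must be positive")

    @property
    def has_targets(self) -> bool:
        return any(
            t is not None
            for t in (self.target_d_pa_pg, self.target_psi_ab,
                      self.target_psi_bg, self.target_psi_ag)
        )


def _embed_internal(spec: InternalChainSpec, d1, d2, tau_a, tau_g,
                    gamma_split=0.0) -> dict:
    """Build coordinates from explicit internal parameters."""
    b = spec.bond_po_bridge
    bt = spec.bond_po_terminal
    at = spec.angle_terminal
    ang_pa = np.radians(spec.angle_pa)

    pa = np.zeros(3)
    o3a = np.array([b, 0.0, 0.0])
    pb = o3a + b * np.array([-np.cos(ang_pa), np.sin(ang_pa), 0.0])
    o3b = nerf_place(pa, o3a, pb, b, spec.angle_pb, d1)
    pg = nerf_place(o3a, pb, o3b, b, spec.theta_bridge, d2)

    o1a, o2a, o5p = nerf_place(
        pb, o3a, pa,
        np.array([bt, bt, b]), at, np.array([tau_a, tau_a + 120.0, tau_a + 240.0]),
    )
    o1b, o2b = nerf_place(
        pg, o3b, pb, bt, at, np.array([d2 + 120.0, d2 - 120.0])
    )
    o1g, o2g, o3g = nerf_place(
        pb, o3b, pg,
        bt, at, np.array([tau_g, tau_g + 120.0, tau_g + 240.0 + gamma_split]),
    )
    return {
        "PA": pa, "O3A": o3a, "PB": pb, "O3B": o3b, "PG": pg,
        "O1A": o1a, "O2A": o2a, "O5'": o5p,
        "O1B": o1b, "O2B": o2b,
        "O1G": o1g, "O2G": o2g, "O3G": o3g,
    }


def _backbone_d_pa_pg(spec: InternalChainSpec, d1, d2):
    """PA-PG distance from backbone parameters only (vectorised over d1/d2)."""
    b = spec.bond_po_bridge
    ang_pa = np.radians(spec.angle_pa)
    pa = np.zeros(3)
    o3a = np.array([b, 0.0, 0.0])
    pb = o3a + b * np.array([-np.cos(ang_pa), np.sin(ang_pa), 0.0])
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    o3b = nerf_place(pa, o3a, pb, b, spec.angle_pb, d1)
    if o3b.ndim == 1:
        pg = nerf_place(o3a, pb, o3b, b, spec.theta_bridge, d2)
        return measure_distance(pa, pg)
    # grid case: one PG circle per O3B position
    out = np.empty(o3b.shape[:-1] + d2.shape)
    for i, o3b_i in enumerate(o3b):
        pg = nerf_place(o3a, pb, o3b_i, b, spec.theta_bridge, d2)
        out[i] = measure_distance(pa, pg)
    return out


def attainable_d_range(spec: InternalChainSpec, n_grid: int = 73):
    """(min, max) PA-PG distance attainable by varying d1 and d2."""
    grid = np.linspace(-180.0, 180.0, n_grid)
    d = _backbone_d_pa_pg(spec, grid, grid)
    return float(d.min()), float(d.max())


# -- fast scalar path used inside the embedding solver ----------------------
# (plain-float re-implementation of the placement/measurement chain; the
# numpy versions above stay the single source of truth and the round-trip
# tests pin both paths together)

def _fnerf(a, b, c, bond, angle_deg, dih_deg):
    import math
    ang = math.radians(angle_deg)
    dih = math.radians(dih_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    n = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / n, bcy / n, bcz / n
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(ang)
    d1_ = bond * math.sin(ang) * math.cos(dih)
    d2_ = bond * math.sin(ang) * math.sin(dih)
    return (
        c[0] + d0 * bcx + d1_ * mx + d2_ * nx,
        c[1] + d0 * bcy + d1_ * my + d2_ * ny,
        c[2] + d0 * bcz + d1_ * mz + d2_ * nz,
    )


def _fdih(p1, p2, p3, p4):
    import math
    b1 = (p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2])
    b2 = (p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2])
    b3 = (p4[0] - p3[0], p4[1] - p3[1], p4[2] - p3[2])
    n1 = (b1[1] * b2[2] - b1[2] * b2[1], b1[2] * b2[0] - b1[0] * b2[2],
          b1[0] * b2[1] - b1[1] * b2[0])
    n2 = (b2[1] * b3[2] - b2[2] * b3[1], b2[2] * b3[0] - b2[0] * b3[2],
          b2[0] * b3[1] - b2[1] * b3[0])
    nb = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    b2n = (b2[0] / nb, b2[1] / nb, b2[2] / nb)
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    c12 = (n1[1] * n2[2] - n1[2] * n2[1], n1[2] * n2[0] - n1[0] * n2[2],
           n1[0] * n2[1] - n1[1] * n2[0])
    y = c12[0] * b2n[0] + c12[1] * b2n[1] + c12[2] * b2n[2]
    return math.degrees(math.atan2(y, x))


def _fast_measure(spec, d1, d2, tau_a, tau_g, gamma_split=0.0):
    """(d_pa_pg, psi_ab, psi_bg, psi_ag) from internal parameters (scalar)."""
    import math
    b = spec.bond_po_bridge
    bt = spec.bond_po_terminal
    at = spec.angle_terminal
    ang_pa = math.radians(spec.angle_pa)
    pa = (0.0, 0.0, 0.0)
    o3a = (b, 0.0, 0.0)
    pb = (b - b * math.cos(ang_pa), b * math.sin(ang_pa), 0.0)
    o3b = _fnerf(pa, o3a, pb, b, spec.angle_pb, d1)
    pg = _fnerf(o3a, pb, o3b, b, spec.theta_bridge, d2)
    o1a = _fnerf(pb, o3a, pa, bt, at, tau_a)
    o2a = _fnerf(pb, o3a, pa, bt, at, tau_a + 120.0)
    o1b = _fnerf(pg, o3b, pb, bt, at, d2 + 120.0)
    o2b = _fnerf(pg, o3b, pb, bt, at, d2 - 120.0)
    o1g = _fnerf(pb, o3b, pg, bt, at, tau_g)
    o3g = _fnerf(pb, o3b, pg, bt, at, tau_g + 240.0 + gamma_split)
    d = math.dist(pa, pg)
    return (
        d,
        _fdih(o2a, pa, pb, o2b),
        _fdih(o1b, pb, pg, o1g),
        _fdih(o1a, pa, pg, o3g),
    )


def _measure_params(spec, x, unknowns, base_params=None):
    if base_params is None:
        base_params = {"d1": spec.d1, "d2": spec.d2, "tau_a": spec.tau_a,
                       "tau_g": spec.tau_g, "gamma_split": spec.gamma_split}
    params = dict(base_params)
    params.update(dict(zip(unknowns, x)))
    coords = _embed_internal(spec, **params)
    return coords, params


_TARGET_KNOB = (
    ("target_d_pa_pg", "d2"),
    ("target_psi_ab", "tau_a"),
    ("target_psi_bg", "tau_g"),
    ("target_psi_ag", "d1"),
)

#: weight making 1e-8 solver residual correspond to ~1e-10 Angstrom
_D_WEIGHT = 100.0


def embed_chain(spec: InternalChainSpec, max_starts: int = 60) -> PhosphateChain:
    """Embed a chain in 3D from an :class:`InternalChainSpec`.

    Without targets the internal parameters are used directly.  With
    targets, the corresponding free parameters are solved so that
    ``compute_descriptors(embed_chain(spec))`` reproduces every target to
    within 1e-6 (multi-start damped least squares; deterministic).  Raises
    :class:`InfeasibleGeometryError` when a target distance lies outside
    the attainable range or the solver cannot reach the targets.
    """
    if not spec.has_targets:
        coords = _embed_internal(spec, spec.d1, spec.d2, spec.tau_a, spec.tau_g)
        return PhosphateChain(coords=coords, source="embedded")

    if spec.target_d_pa_pg is not None:
        lo, hi = attainable_d_range(spec)
        if not lo - 1e-9 <= spec.target_d_pa_pg <= hi + 1e-9:
            raise InfeasibleGeometryError(
                f"target d_pa_pg={spec.target_d_pa_pg:.3f} outside attainable "
                f"range [{lo:.3f}, {hi:.3f}] for this spec"
            )

    targets = [(t, k) for t, k in _TARGET_KNOB if getattr(spec, t) is not None]

    base_params = {"d1": spec.d1, "d2": spec.d2, "tau_a": spec.tau_a,
                   "tau_g": spec.tau_g, "gamma_split": spec.gamma_split}
    if spec.target_d_pa_pg is not None and spec.target_psi_ag is None:
        # d1 is not adjusted by the solver; seat it (and the d2 start) on the
        # coarse-grid point closest to the target distance
        grid = np.linspace(-180.0, 180.0, 73)
        dgrid = _backbone_d_pa_pg(spec, grid, grid)
        i, j = np.unravel_index(
            np.argmin(np.abs(dgrid - spec.target_d_pa_pg)), dgrid.shape
        )
        base_params["d1"] = float(grid[i])
        base_params["d2"] = float(grid[j])

    def solve(unknowns, regularized):
        idx = {k: i for i, k in enumerate(unknowns)}

        def residuals(x):
            p = dict(base_params)
            for k, i in idx.items():
                p[k] = x[i]
            d, psi_ab, psi_bg, psi_ag = _fast_measure(
                spec, p["d1"], p["d2"], p["tau_a"], p["tau_g"], p["gamma_split"]
            )
            got = {"target_d_pa_pg": d, "target_psi_ab": psi_ab,
                   "target_psi_bg": psi_bg, "target_psi_ag": psi_ag}
            res = []
            for tname, _ in targets:
                tval = getattr(spec, tname)
                if tname == "target_d_pa_pg":
                    res.append((got[tname] - tval) * _D_WEIGHT)
                else:
                    res.append(float(wrap_angle(got[tname] - tval)))
            for k in regularized:
                res.append(1e-7 * float(wrap_angle(x[idx[k]] - base_params[k])))
            return np.array(res)

        # deterministic multi-start: seated values first, then a coarse grid
        starts = [[base_params[k] for k in unknowns]]
        grid_vals = (-150.0, -90.0, -30.0, 30.0, 90.0, 150.0)
        reg_zero = {k: 0.0 for k in regularized}
        for combo in itertools.product(
            *((grid_vals,) * (len(unknowns) - len(regularized)))
        ):
            starts.append(list(combo) + [reg_zero[k] + base_params[k]
                                         for k in regularized])
        starts = starts[: max_starts + 1]

        best = None
        for x0 in starts:
            sol = least_squares(residuals, x0, method="lm", xtol=1e-14,
                                ftol=1e-14, gtol=1e-14, max_nfev=400)
            err = float(np.max(np.abs(sol.fun[: len(targets)])))
            if best is None or err < best[0]:
                best = (err, sol.x)
            if err < 1e-8:
                break
        return best[0], dict(zip(unknowns, best[1]))

    unknowns = [k for _, k in targets]
    regularized = []
    if spec.target_psi_ag is not None and spec.target_d_pa_pg is None:
        # free d2 as well (weakly pulled to its spec value) -- some psi
        # triples need the extra backbone freedom
        unknowns.append("d2")
        regularized.append("d2")
    err, solved = solve(unknowns, regularized)
    if err > 1e-7 and spec.target_psi_ag is not None:
        # rigid tetrahedral groups cannot realise every psi triple (the
        # fully eclipsed one included); allow azimuthal distortion of O3G
        err, solved = solve(unknowns + ["gamma_split"],
                            regularized + ["gamma_split"])
    if err > 1e-7:
        raise InfeasibleGeometryError(
            f"could not realise descriptor targets (best residual {err:.2e})"
        )
    params = dict(base_params)
    params.update(solved)
    coords = _embed_internal(spec, **params)
    return PhosphateChain(coords=coords, source="embedded")


def spec_from_descriptors(
    desc: GeometryDescriptors, base: Optional[InternalChainSpec] = None
) -> InternalChainSpec:
    """Spec targeting the given descriptors (bridge angle set directly)."""
    base = base if base is not None else InternalChainSpec()
    return replace(
        base,
        theta_bridge=desc.theta_bridge,
        target_d_pa_pg=desc.d_pa_pg,
        target_psi_ab=desc.psi_ab,
        target_psi_bg=desc.psi_bg,
        target_psi_ag=desc.psi_ag,
    )
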