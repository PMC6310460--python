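"""Per-frame and per-segment analysis of Mg-NTP trajectories.

Covers Mg coordination classification (bidentate beta-gamma vs tridentate
alpha-beta-gamma), monovalent-cation site assignment (BG / AG / G),
occupancy series, state segmentation with dwell-time filtering, moving
averages and labeled atom-pair distance tracking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ntpchain.chain_model import (
    ALPHA_OXYGENS,
    BETA_OXYGENS,
    CHAIN_LABELS,
    GAMMA_OXYGENS,
    NONBRIDGING,
    PhosphateChain,
    measure_angle,
    measure_dihedral,
    measure_distance,
)

__all__ = [
    "CoordinationState",
    "Site",
    "DEFAULT_BINDING_DISTANCES",
    "MissingIonError",
    "IonTrack",
    "Trajectory",
    "IonBindingRecord",
    "StateSegment",
    "OccupancySeries",
    "classify_mg_coordination",
    "classify_frames",
    "detect_curled",
    "assign_ion_sites",
    "assign_ion_sites_frames",
    "occupancy",
    "segment_trajectory",
    "moving_average",
    "track_pair_distance",
    "compute_descriptor_series",
    "load_trajectory",
    "write_multimodel_pdb",
]


class CoordinationState(str, Enum):
    BETA_GAMMA = "BETA_GAMMA"
    BETA_GAMMA_CURLED = "BETA_GAMMA_CURLED"
    ALPHA_BETA_GAMMA = "ALPHA_BETA_GAMMA"
    OTHER = "OTHER"


class Site(str, Enum):
    BG = "BG"
    AG = "AG"
    G = "G"
    UNBOUND = "unbound"


#: Species-specific cation-oxygen binding distances (Angstrom).
DEFAULT_BINDING_DISTANCES = {"K": 3.2, "NA": 2.4, "NH4": 3.2}

#: Default Mg-O coordination cutoff (Angstrom); first-shell Mg-O ~ 2.1 A.
DEFAULT_MG_CUTOFF = 2.5

#: Default whole-chain proximity radius for cation counting (Angstrom).
DEFAULT_CHAIN_RADIUS = 4.0

#: Segment-mean PA-PG distance below which a beta-gamma segment counts as
#: curled.  Heuristic (the published analysis used visual inspection); set
#: between the curled regimes (~4.56-4.60 A) and the shortest non-curled
#: one (~4.69 A).
DEFAULT_CURL_THRESHOLD = 4.65


class MissingIonError(ValueError):
    """Raised when a required ion (e.g. Mg) is absent."""


class ConfigurationError(ValueError):
    """Raised for unusable analysis configuration (e.g. unknown species)."""


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class IonTrack:
    """One monovalent ion across all frames (NH4+ by its N position)."""

    ion_id: str
    species: str  # 'K', 'NA', 'NH4' or other
    positions: np.ndarray  # (n_frames, 3)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = self.species.upper()


@dataclass
class Trajectory:
    """Uniformly spaced frames of one chain plus Mg and monovalent ions.

    ``chain`` maps canonical labels to (n_frames, 3) coordinate arrays in
    Angstrom; ``extra`` holds additional tracked atoms (protein atoms for
    H-bond tracking etc.) under free-form labels.
    """

    chain: Dict[str, np.ndarray]
    dt_ps: float
    mg: Optional[np.ndarray] = None
    ions: List[IonTrack] = field(default_factory=list)
    extra: Dict[str, np.ndarray] = field(default_factory=dict)
    source: Optional[str] = None

    def __post_init__(self):
        self.chain = {k: np.asarray(v, dtype=float) for k, v in self.chain.items()}
        if self.mg is not None:
            self.mg = np.asarray(self.mg, dtype=float)
        if self.dt_ps <= 0:
            raise ValueError("frame spacing dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.chain.values())).shape[0]

    def frame_chain(self, i: int) -> PhosphateChain:
        coords = {k: v[i] for k, v in self.chain.items()}
        if self.mg is not None:
            coords["MG"] = self.mg[i]
        return PhosphateChain(coords=coords, source=f"frame {i}")

    def resolve(self, label: str) -> np.ndarray:
        """Coordinate series for a chain, extra, MG or ion label."""
        if label in self.chain:
            return self.chain[label]
        if label in self.extra:
            return self.extra[label]
        if label == "MG":
            if self.mg is None:
                raise MissingIonError("trajectory has no Mg ion")
            return self.mg
        for ion in self.ions:
            if ion.ion_id == label:
                return ion.positions
        raise KeyError(f"atom label {label!r} not found in trajectory")

    def group_oxygens(self, group: str) -> np.ndarray:
        """(n_frames, n_oxy, 3) stack of the group's oxygens (incl. bridging)."""
        labels = {"A": ALPHA_OXYGENS, "B": BETA_OXYGENS, "G": GAMMA_OXYGENS}[group]
        return np.stack([self.chain[l] for l in labels if l in self.chain], axis=1)

    def chain_atoms(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stack of all phosphate-chain atoms."""
        labels = [l for l in CHAIN_LABELS if l in self.chain]
        if "O5'" in self.chain:
            labels.append("O5'")
        return np.stack([self.chain[l] for l in labels], axis=1)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonBindingRecord:
    frame: int
    ion_id: str
    species: str
    r_a: float
    r_b: float
    r_g: float
    r_ag: float  # (nearest alpha-O + nearest gamma-O) / 2
    r_bg: float
    site: Site

    def as_dict(self):
        d = self.__dict__.copy()
        d["site"] = self.site.value
        return d


@dataclass
class StateSegment:
    start: int  # inclusive frame index
    end: int    # exclusive
    state: CoordinationState
    stats: Dict[str, float] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class OccupancySeries:
    site: Optional[Site]
    counts: np.ndarray          # per-frame ion count assigned to the site
    chain_counts: np.ndarray    # per-frame ion count within chain radius
    chain_radius: float

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.counts))

    @property
    def chain_occupancy(self) -> float:
        return float(np.mean(self.chain_counts))


# ---------------------------------------------------------------------------
# per-frame operations
# ---------------------------------------------------------------------------

def _min_dist_to_group(point, chain: PhosphateChain, labels) -> float:
    pts = np.array([chain.coords[l] for l in labels if l in chain.coords])
    return float(np.min(np.linalg.norm(pts - point, axis=-1)))


def classify_mg_coordination(
    chain: PhosphateChain, mg_cutoff: float = DEFAULT_MG_CUTOFF
) -> CoordinationState:
    """Classify the Mg coordination mode of one frame.

    BETA_GAMMA: Mg within ``mg_cutoff`` of at least one non-bridging oxygen
    of both the beta and gamma groups but of none of the alpha group;
    ALPHA_BETA_GAMMA: within cutoff of at least one from each group;
    OTHER otherwise.  The curled refinement is a segment-level operation
    (:func:`detect_curled`).
    """
    if chain.mg is None:
        raise MissingIonError("no Mg ion in chain")
    near = {
        g: _min_dist_to_group(chain.mg, chain, NONBRIDGING[g]) <= mg_cutoff
        for g in ("A", "B", "G")
    }
    if near["B"] and near["G"]:
        if near["A"]:
            return CoordinationState.ALPHA_BETA_GAMMA
        return CoordinationState.BETA_GAMMA
    return CoordinationState.OTHER


def classify_frames(
    traj: Trajectory, mg_cutoff: float = DEFAULT_MG_CUTOFF
) -> List[CoordinationState]:
    """Vectorised per-frame Mg coordination classification."""
    if traj.mg is None:
        raise MissingIonError("trajectory has no Mg ion")
    mg = traj.mg[:, None, :]
    near = {}
    for g in ("A", "B", "G"):
        oxy = np.stack([traj.chain[l] for l in NONBRIDGING[g]], axis=1)
        near[g] = np.min(np.linalg.norm(oxy - mg, axis=-1), axis=1) <= mg_cutoff
    out = np.empty(traj.n_frames, dtype=object)
    out[:] = CoordinationState.OTHER
    bg = near["B"] & near["G"]
    out[bg & ~near["A"]] = CoordinationState.BETA_GAMMA
    out[bg & near["A"]] = CoordinationState.ALPHA_BETA_GAMMA
    return list(out)


def detect_curled(
    segment: StateSegment,
    d_pa_pg_series: np.ndarray,
    curl_threshold: float = DEFAULT_CURL_THRESHOLD,
) -> StateSegment:
    """Relabel a BETA_GAMMA segment as curled when its mean PA-PG distance
    falls strictly below ``curl_threshold`` (heuristic threshold; the mean
    is taken over the segment's own frames)."""
    if segment.state is not CoordinationState.BETA_GAMMA:
        return segment
    mean_d = float(np.mean(d_pa_pg_series[segment.start:segment.end]))
    if mean_d < curl_threshold:
        segment.state = CoordinationState.BETA_GAMMA_CURLED
    segment.stats.setdefault("d_pa_pg_mean", mean_d)
    return segment


def assign_ion_sites(
    chain: PhosphateChain,
    ions: Sequence,  # (ion_id, species, position) triples or IonTrack at frame
    binding_distances: Optional[Dict[str, float]] = None,
    frame: int = 0,
) -> List[IonBindingRecord]:
    """Assign each ion to BG / AG / G / unbound for a single frame.

    BG requires contact (within the species binding distance) with >= 1
    beta oxygen and >= 1 gamma oxygen; AG analogously for alpha + gamma;
    both qualifying resolves to the site with the smaller mean distance
    (R_BG vs R_AG); gamma-only contact gives G.  Distances are measured to
    any oxygen of the group, bridging oxygens included.
    """
    bd = dict(DEFAULT_BINDING_DISTANCES)
    if binding_distances:
        bd.update({k.upper(): v for k, v in binding_distances.items()})
    records = []
    for ion_id, species, pos in ions:
        species = species.upper()
        if species not in bd:
            raise ConfigurationError(
                f"no binding distance configured for species {species!r}"
            )
        cut = bd[species]
        pos = np.asarray(pos, dtype=float)
        r_a = _min_dist_to_group(pos, chain, ALPHA_OXYGENS)
        r_b = _min_dist_to_group(pos, chain, BETA_OXYGENS)
        r_g = _min_dist_to_group(pos, chain, GAMMA_OXYGENS)
        r_ag = 0.5 * (r_a + r_g)
        r_bg = 0.5 * (r_b + r_g)
        bg_ok = r_b <= cut and r_g <= cut
        ag_ok = r_a <= cut and r_g <= cut
        if bg_ok and ag_ok:
            site = Site.BG if r_bg <= r_ag else Site.AG
        elif bg_ok:
            site = Site.BG
        elif ag_ok:
            site = Site.AG
        elif r_g <= cut and r_a > cut and r_b > cut:
            site = Site.G
        else:
            site = Site.UNBOUND
        records.append(
            IonBindingRecord(frame, ion_id, species, r_a, r_b, r_g, r_ag, r_bg, site)
        )
    return records


def assign_ion_sites_frames(
    traj: Trajectory, binding_distances: Optional[Dict[str, float]] = None
) -> List[List[IonBindingRecord]]:
    """Site assignment for every ion in every frame (vectorised distances)."""
    bd = dict(DEFAULT_BINDING_DISTANCES)
    if binding_distances:
        bd.update({k.upper(): v for k, v in binding_distances.items()})
    n = traj.n_frames
    groups = {g: traj.group_oxygens(g) for g in ("A", "B", "G")}
    per_ion = []
    for ion in traj.ions:
        if ion.species not in bd:
            raise ConfigurationError(
                f"no binding distance configured for species {ion.species!r}"
            )
        cut = bd[ion.species]
        pos = ion.positions[:, None, :]
        r = {
            g: np.min(np.linalg.norm(groups[g] - pos, axis=-1), axis=1)
            for g in ("A", "B", "G")
        }
        r_ag = 0.5 * (r["A"] + r["G"])
        r_bg = 0.5 * (r["B"] + r["G"])
        bg_ok = (r["B"] <= cut) & (r["G"] <= cut)
        ag_ok = (r["A"] <= cut) & (r["G"] <= cut)
        g_only = (r["G"] <= cut) & (r["A"] > cut) & (r["B"] > cut)
        sites = np.empty(n, dtype=object)
        sites[:] = Site.UNBOUND
        sites[g_only] = Site.G
        sites[ag_ok] = Site.AG
        sites[bg_ok] = Site.BG
        both = bg_ok & ag_ok
        sites[both & (r_ag < r_bg)] = Site.AG
        per_ion.append((ion, r, r_ag, r_bg, sites))
    out = []
    for i in range(n):
        frame_records = [
            IonBindingRecord(
                i, ion.ion_id, ion.species,
                float(r["A"][i]), float(r["B"][i]), float(r["G"][i]),
                float(r_ag[i]), float(r_bg[i]), sites[i],
            )
            for ion, r, r_ag, r_bg, sites in per_ion
        ]
        out.append(frame_records)
    return out


def occupancy(
    records_or_counts,
    site: Optional[Site] = None,
    traj: Optional[Trajectory] = None,
    chain_radius: float = DEFAULT_CHAIN_RADIUS,
) -> OccupancySeries:
    """Time-averaged site occupancy from per-frame records or counts.

    Accepts either a per-frame indicator/count series, or nested
    ``assign_ion_sites_frames`` output together with ``site``.  When a
    trajectory is supplied, also counts ions within ``chain_radius`` of any
    phosphate-chain atom per frame.
    """
    if len(records_or_counts) == 0:
        raise ValueError("empty series: cannot compute occupancy")
    first = records_or_counts[0]
    if isinstance(first, (list, tuple)) and (not first or isinstance(first[0], IonBindingRecord)):
        if site is None:
            raise ValueError("site must be given with binding records")
        counts = np.array(
            [sum(1 for r in frame if r.site is site) for frame in records_or_counts],
            dtype=float,
        )
    else:
        counts = np.asarray(records_or_counts, dtype=float)
    if traj is not None:
        atoms = traj.chain_atoms()[:, None, :, :]
        if traj.ions:
            ion_pos = np.stack([i.positions for i in traj.ions], axis=1)[:, :, None, :]
            dmin = np.min(np.linalg.norm(atoms - ion_pos, axis=-1), axis=-1)
            chain_counts = np.sum(dmin <= chain_radius, axis=1).astype(float)
        else:
            chain_counts = np.zeros(len(counts))
    else:
        chain_counts = np.full(len(counts), np.nan)
    return OccupancySeries(site, counts, chain_counts, chain_radius)


# ---------------------------------------------------------------------------
# segmentation and series operations
# ---------------------------------------------------------------------------

def segment_trajectory(states: Sequence, min_dwell: int = 10) -> List[StateSegment]:
    """Partition per-frame states into maximal runs; absorb short runs.

    Runs shorter than ``min_dwell`` are merged into the flanking run with
    the longer duration (ties and first-run cases merge into the preceding
    run when one exists).  Merging repeats until stable, so flicker shorter
    than the dwell never survives.
    """
    states = list(states)
    if not states:
        return []
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append([start, i, states[start]])
            start = i
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, run in enumerate(runs):
            if run[1] - run[0] >= min_dwell:
                continue
            prev_len = runs[k - 1][1] - runs[k - 1][0] if k > 0 else -1
            next_len = runs[k + 1][1] - runs[k + 1][0] if k < len(runs) - 1 else -1
            if prev_len < 0 and next_len < 0:
                continue
            absorb_prev = prev_len >= next_len  # tie -> preceding
            if absorb_prev:
                runs[k - 1][1] = run[1]
            else:
                runs[k + 1][0] = run[0]
            del runs[k]
            # coalesce equal-state neighbours created by the merge
            m = 0
            while m < len(runs) - 1:
                if runs[m][2] == runs[m + 1][2] and runs[m][1] == runs[m + 1][0]:
                    runs[m][1] = runs[m + 1][1]
                    del runs[m + 1]
                else:
                    m += 1
            changed = True
            break
    return [StateSegment(s, e, st) for s, e, st in runs]


def moving_average(series, window: int = 1) -> np.ndarray:
    """Centered moving mean with a shrinking window at the edges.

    ``window`` is in frames (use ``window_ps / dt_ps``); even windows are
    treated as the next odd size (symmetric half-width).
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    half = int(window) // 2
    if half == 0:
        return series.copy()
    n = len(series)
    csum = np.concatenate([[0.0], np.cumsum(series)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class PairDistanceResult:
    distances: np.ndarray
    mean: float
    sd: float
    hbond_fraction: float
    cutoff: float


def track_pair_distance(
    traj: Trajectory, label_a: str, label_b: str, hbond_cutoff: float = 3.5
) -> PairDistanceResult:
    """Per-frame distance between two labeled atoms plus summary stats."""
    try:
        a = traj.resolve(label_a)
        b = traj.resolve(label_b)
    except KeyError as e:
        raise KeyError(f"cannot track pair ({label_a}, {label_b}): {e}") from e
    d = np.linalg.norm(b - a, axis=-1)
    return PairDistanceResult(
        distances=d,
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        hbond_fraction=float(np.mean(d <= hbond_cutoff)),
        cutoff=hbond_cutoff,
    )


def compute_descriptor_series(traj: Trajectory) -> Dict[str, np.ndarray]:
    """Vectorised per-frame descriptor series for a whole trajectory."""
    c = traj.chain
    return {
        "d_pa_pg": measure_distance(c["PA"], c["PG"]),
        "theta_bridge": measure_angle(c["PB"], c["O3B"], c["PG"]),
        "psi_ab": np.atleast_1d(measure_dihedral(c["O2A"], c["PA"], c["PB"], c["O2B"])),
        "psi_bg": np.atleast_1d(measure_dihedral(c["O1B"], c["PB"], c["PG"], c["O1G"])),
        "psi_ag": np.atleast_1d(measure_dihedral(c["O1A"], c["PA"], c["PG"], c["O3G"])),
    }


def segment_statistics(
    segments: List[StateSegment], series: Dict[str, np.ndarray]
) -> List[StateSegment]:
    """Attach per-segment mean/SD of every descriptor series."""
    for seg in segments:
        for name, values in series.items():
            chunk = values[seg.start:seg.end]
            seg.stats[f"{name}_mean"] = float(np.mean(chunk))
            seg.stats[f"{name}_sd"] = (
                float(np.std(chunk, ddof=1)) if len(chunk) > 1 else 0.0
            )
    return segments


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

_ION_RESNAMES = {"K": "K", "NA": "NA", "NH4": "NH4"}
_NUCLEOTIDE_RESNAMES = ("ATP", "GTP", "ADP", "GDP")


def load_trajectory(
    path,
    topology=None,
    dt_ps: Optional[float] = None,
    in_nm: bool = False,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, or topology + coordinate series).

    Uses MDAnalysis for format handling; coordinates are normalised to
    Angstrom (``in_nm`` converts).  Frame spacing is read from the
    trajectory metadata and must be supplied explicitly when absent.
    """
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
    scale = 10.0 if in_nm else 1.0

    nuc = u.select_atoms("resname " + " ".join(_NUCLEOTIDE_RESNAMES))
    if len(nuc) == 0:
        raise ValueError(f"no nucleotide residue found in {path}")
    labels = {}
    for atom in nuc:
        if atom.name in labels:
            continue
        labels[atom.name] = atom.index
    mg_sel = u.select_atoms("resname MG")
    ion_sel = []
    for species, resname in _ION_RESNAMES.items():
        sel = u.select_atoms(f"resname {resname}")
        if species == "NH4":
            sel = sel.select_atoms("name N")
        for atom in sel:
            ion_sel.append((f"{species}_{atom.index}", species, atom.index))

    n = len(u.trajectory)
    chain = {l: np.empty((n, 3)) for l in labels}
    mg = np.empty((n, 3)) if len(mg_sel) else None
    ion_pos = {iid: np.empty((n, 3)) for iid, _, _ in ion_sel}
    for i, _ts in enumerate(u.trajectory):
        pos = u.atoms.positions * scale
        for l, idx in labels.items():
            chain[l][i] = pos[idx]
        if mg is not None:
            mg[i] = pos[mg_sel[0].index]
        for iid, _sp, idx in ion_sel:
            ion_pos[iid][i] = pos[idx]

    if dt_ps is None:
        dt_ps = getattr(u.trajectory, "dt", 0.0) or 0.0
        if dt_ps <= 0:
            raise ValueError(
                "frame spacing not present in trajectory metadata; pass dt_ps"
            )
    ions = [IonTrack(iid, sp, ion_pos[iid]) for iid, sp, _ in ion_sel]
    return Trajectory(chain=chain, dt_ps=float(dt_ps), mg=mg, ions=ions,
                      source=str(path))


def _pdb_atom_line(serial, name, resname, chain_id, resseq, xyz, element,
                   hetatm=True):
    record = "HETATM" if hetatm else "ATOM  "
    # columns per PDB v3.3; 4-char names start in column 13
    if len(name) < 4 and not name[:1].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field} {resname:<3s} {chain_id}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}\n"
    )


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write the trajectory as a multi-model PDB (deterministic output)."""
    path = Path(path)
    chain_labels = [l for l in CHAIN_LABELS if l in traj.chain]
    if "O5'" in traj.chain:
        chain_labels.append("O5'")
    with open(path, "w") as fh:
        fh.write("REMARK   1 ntpchain synthetic trajectory\n")
        fh.write(f"REMARK   1 FRAME SPACING {traj.dt_ps:.6f} PS\n")
        for i in range(traj.n_frames):
            fh.write(f"MODEL {i + 1:>8d}\n")
            serial = 1
            for l in chain_labels:
                elem = "P" if l.startswith("P") else "O"
                fh.write(_pdb_atom_line(serial, l, "ATP", "A", 1,
                                        traj.chain[l][i], elem))
                serial += 1
            if traj.mg is not None:
                fh.write(_pdb_atom_line(serial, "MG", "MG", "B", 2,
                                        traj.mg[i], "MG"))
                serial += 1
            resseq = 3
            for ion in traj.ions:
                resname = _ION_RESNAMES.get(ion.species, ion.species[:3])
                name = "N" if ion.species == "NH4" else ion.species
                elem = "N" if ion.species == "NH4" else ion.species
                fh.write(_pdb_atom_line(serial, name, resname, "C", resseq,
                                        ion.positions[i], elem))
                serial += 1
                resseq += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# bundle analysis (used by the CLI)
# ---------------------------------------------------------------------------

def analyze_trajectory(
    traj: Trajectory,
    mg_cutoff: float = DEFAULT_MG_CUTOFF,
    curl_threshold: float = DEFAULT_CURL_THRESHOLD,
    min_dwell: int = 10,
    binding_distances: Optional[Dict[str, float]] = None,
    chain_radius: float = DEFAULT_CHAIN_RADIUS,
):
    """Full per-frame + per-segment analysis; returns a results dict."""
    series = compute_descriptor_series(traj)
    states = classify_frames(traj, mg_cutoff=mg_cutoff)
    segments = segment_trajectory(states, min_dwell=min_dwell)
    for seg in segments:
        detect_curled(seg, series["d_pa_pg"], curl_threshold=curl_threshold)
    segment_statistics(segments, series)
    records = assign_ion_sites_frames(traj, binding_distances) if traj.ions else []
    occupancies = {}
    if records:
        for site in (Site.BG, Site.AG, Site.G):
            occ = occupancy(records, site=site, traj=traj, chain_radius=chain_radius)
            occupancies[site.value] = occ
    per_frame_states = []
    for seg in segments:
        per_frame_states.extend([seg.state] * seg.n_frames)
    return {
        "series": series,
        "states": per_frame_states,
        "segments": segments,
        "records": records,
        "occupancies": occupancies,
    }


def frames_table(result, traj: Trajectory) -> pd.DataFrame:
    """Per-frame TSV-ready table (descriptors, state, per-ion sites)."""
    series = result["series"]
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "time_ps": np.arange(traj.n_frames) * traj.dt_ps,
        **{k: v for k, v in series.items()},
        "state": [s.value for s in result["states"]],
    })
    for records in zip(*result["records"]) if result["records"] else []:
        ion_id = records[0].ion_id
        df[f"{ion_id}_site"] = [r.site.value for r in records]
        df[f"{ion_id}_r_ag"] = [r.r_ag for r in records]
        df[f"{ion_id}_r_bg"] = [r.r_bg for r in records]
    return df


def segments_table(result) -> pd.DataFrame:
    rows = []
    for seg in result["segments"]:
        row = {"start": seg.start, "end": seg.end, "state": seg.state.value,
               "n_frames": seg.n_frames}
        row.update(seg.stats)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_json(result, traj: Trajectory) -> str:
    """Deterministic JSON summary of an analysis result."""
    occ = {
        k: {"occupancy": round(v.occupancy, 6),
            "chain_occupancy": round(v.chain_occupancy, 6)
            if not np.isnan(v.chain_occupancy) else None}
        for k, v in result["occupancies"].items()
    }
    segs = [
        {"start": s.start, "end": s.end, "state": s.state.value,
         "d_pa_pg_mean": round(s.stats.get("d_pa_pg_mean", float("nan")), 6),
         "theta_mean": round(s.stats.get("theta_bridge_mean", float("nan")), 6)}
        for s in result["segments"]
    ]
    return json.dumps(
        {"n_frames": traj.n_frames, "dt_ps": traj.dt_ps,
         "segments": segs, "occupancies": occ},
        indent=2, sort_keys=True,
    )
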