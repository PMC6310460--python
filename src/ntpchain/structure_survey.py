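"""Comparative survey of P-loop NTPase structures.

Screens PDB/mmCIF files for Mg-bound NTP-like ligands near a Lys residue,
maps analogs (imido/methylene/thio substitutions, metal-fluoride
gamma-phosphate mimics) onto the canonical triphosphate frame, measures
chain geometry, characterises the AG-site occupant and superposes P-loops
onto a reference structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ntpchain.chain_model import (
    GeometryDescriptors,
    PhosphateChain,
    compute_descriptors,
    kabsch_superpose,
)

__all__ = [
    "LigandAtlas",
    "LigandCandidate",
    "SurveyRecord",
    "load_structure",
    "screen_structure",
    "measure_structure",
    "survey_structures",
    "superpose_ploops",
    "collect_overlay_sets",
]

#: Atoms considered as potential AG-site occupants, in search priority.
_CATION_ELEMENTS = {"K": "K", "NA": "NA", "RB": "RB", "CS": "CS"}
_WATER_RESNAMES = {"HOH", "WAT", "H2O"}

#: Coordination-range cutoff for the AG occupant search (Angstrom).
AG_OCCUPANT_CUTOFF = 3.5

#: Default screening cutoffs (Angstrom).
DEFAULT_MG_CUTOFF = 4.0
DEFAULT_LYS_CUTOFF = 4.0

#: Maximum central-atom-to-O3B distance linking a mimic moiety to an NDP.
MIMIC_LINK_CUTOFF = 3.5


# ---------------------------------------------------------------------------
# ligand atlas
# ---------------------------------------------------------------------------

_CHAIN_ATOMS_NTP = (
    "PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B",
    "PG", "O1G", "O2G", "O3G", "O5'",
)
_CHAIN_ATOMS_NDP = (
    "PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B", "O5'",
)


class LigandAtlas:
    """Mapping from ligand chemical IDs to canonical chain labels.

    Shipped as an editable TSV table; each entry carries an analog class
    and the atom-name substitutions relative to the canonical naming
    (e.g. the ANP imido nitrogen N3B occupies the O3B slot).
    """

    def __init__(self, table: pd.DataFrame):
        self.classes: Dict[str, str] = {}
        self.substitutions: Dict[str, Dict[str, str]] = {}
        for _, row in table.iterrows():
            lid = row["ligand_id"].strip().upper()
            self.classes[lid] = row["analog_class"].strip()
            subs = {}
            raw = row["substitutions"].strip()
            if raw and raw != "-":
                for pair in raw.split(";"):
                    src, dst = pair.split(">")
                    subs[src.strip()] = dst.strip()
            self.substitutions[lid] = subs

    @classmethod
    def default(cls) -> "LigandAtlas":
        with resources.files("ntpchain.data").joinpath("ligand_atlas.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#")
        return cls(table)

    @classmethod
    def from_file(cls, path) -> "LigandAtlas":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @property
    def nucleotide_ids(self):
        return tuple(l for l, c in self.classes.items() if c != "gamma_mimic")

    @property
    def mimic_ids(self):
        return tuple(l for l, c in self.classes.items() if c == "gamma_mimic")

    def is_product(self, ligand_id: str) -> bool:
        return self.classes.get(ligand_id.upper()) == "product"

    def map_atoms(self, ligand_id: str, atoms: Dict[str, np.ndarray]):
        """Map ligand atom names onto canonical labels.

        Returns ``(coords, is_mimic, substitutions)``; substitution atoms
        (thio/imido/methylene) land on the oxygen slot they replace and are
        reported.  Mimic moieties flag every mapped atom.
        """
        lid = ligand_id.upper()
        if lid not in self.classes:
            raise KeyError(f"unknown ligand id {lid!r}")
        subs = self.substitutions[lid]
        is_gamma_mimic = self.classes[lid] == "gamma_mimic"
        wanted = (
            set(subs) | set(_CHAIN_ATOMS_NTP)
            if not is_gamma_mimic
            else set(subs)
        )
        coords, mimic_flags, applied = {}, {}, []
        for name, pos in atoms.items():
            if name not in wanted:
                continue
            label = subs.get(name, name)
            coords[label] = pos
            if is_gamma_mimic:
                mimic_flags[label] = True
            elif name in subs:
                applied.append(f"{name}>{label}")
        return coords, mimic_flags, applied


# ---------------------------------------------------------------------------
# structure loading (Bio.PDB; PDB and mmCIF)
# ---------------------------------------------------------------------------

def load_structure(path, structure_id: Optional[str] = None):
    """Parse a PDB or mmCIF file (format chosen by extension)."""
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    sid = structure_id or path.stem
    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    try:
        return parser.get_structure(sid, str(path))
    except Exception as e:  # noqa: BLE001 - wrap any parser failure
        raise ValueError(f"cannot parse structure file {path}: {e}") from e


def _atom_position(atom) -> np.ndarray:
    """Coordinate of an atom, resolving altlocs by highest occupancy
    (ties break towards altloc 'A')."""
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = children[0]
    return np.asarray(atom.get_coord(), dtype=float)


def _residue_atoms(residue) -> Dict[str, np.ndarray]:
    return {a.get_id(): _atom_position(a) for a in residue}


def _resname(residue) -> str:
    return residue.get_resname().strip().upper()


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class LigandCandidate:
    structure_id: str
    model_index: int
    chain_id: str
    resseq: int
    ligand_id: str
    analog_class: str
    chain: PhosphateChain
    complete: bool
    mimic_id: Optional[str] = None
    substitutions: List[str] = field(default_factory=list)
    lys_contacts: List[str] = field(default_factory=list)
    mg_distance: Optional[float] = None
    model: object = None  # Bio.PDB model, kept for the occupant search

    @property
    def label(self) -> str:
        lig = self.ligand_id + (f"-{self.mimic_id}" if self.mimic_id else "")
        return f"{self.structure_id}/{self.chain_id}/{lig}{self.resseq}"


def _phosphate_oxygens(chain: PhosphateChain) -> np.ndarray:
    labels = [l for l in chain.coords
              if l.startswith("O") or l == "F4" or chain.is_mimic.get(l)]
    labels = [l for l in labels if l not in ("MG",)]
    return np.array([chain.coords[l] for l in labels])


def screen_structure(
    path_or_structure,
    atlas: Optional[LigandAtlas] = None,
    mg_cutoff: float = DEFAULT_MG_CUTOFF,
    lys_cutoff: float = DEFAULT_LYS_CUTOFF,
    model_index: int = 0,
    all_models: bool = False,
    structure_id: Optional[str] = None,
) -> Tuple[List[LigandCandidate], List[dict]]:
    """Screen one structure for P-loop-bound Mg-NTP-like ligand sites.

    A candidate needs (i) a ligand with a known chemical ID, (ii) a Mg ion
    within ``mg_cutoff`` of any phosphate oxygen and (iii) at least one Lys
    NZ within ``lys_cutoff`` of any phosphate oxygen.  Every non-candidate
    is excluded with exactly one logged reason (first failed criterion in
    the order above).
    """
    atlas = atlas or LigandAtlas.default()
    if isinstance(path_or_structure, (str, Path)):
        structure = load_structure(path_or_structure, structure_id)
    else:
        structure = path_or_structure
    sid = structure_id or structure.get_id()

    models = list(structure)
    if not all_models:
        models = [models[model_index]]

    candidates: List[LigandCandidate] = []
    exclusions: List[dict] = []
    for mi, model in enumerate(models):
        mg_positions = []
        lys_nz = []
        mimic_residues = []
        ligand_residues = []
        for pchain in model:
            for residue in pchain:
                name = _resname(residue)
                if name == "MG":
                    mg_positions.extend(_residue_atoms(residue).values())
                elif name == "LYS" and "NZ" in residue:
                    lys_nz.append(
                        (f"{pchain.get_id()}:LYS{residue.get_id()[1]}",
                         _atom_position(residue["NZ"]))
                    )
                elif name in atlas.mimic_ids:
                    mimic_residues.append((pchain.get_id(), residue))
                elif name in atlas.nucleotide_ids:
                    ligand_residues.append((pchain.get_id(), residue))

        for chain_id, residue in ligand_residues:
            lid = _resname(residue)
            resseq = residue.get_id()[1]
            coords, mimic_flags, subs = atlas.map_atoms(
                lid, _residue_atoms(residue)
            )
            if "PA" not in coords:
                exclusions.append({
                    "structure": sid, "ligand": f"{chain_id}/{lid}{resseq}",
                    "reason": "no PA atom: not a phosphate-chain ligand",
                })
                continue
            mimic_id = None
            analog_class = atlas.classes[lid]
            if atlas.is_product(lid) and "O3B" in coords:
                # look for a gamma-phosphate mimic moiety bonded to O3B
                best = None
                for mchain_id, mres in mimic_residues:
                    mcoords, mflags, _ = atlas.map_atoms(
                        _resname(mres), _residue_atoms(mres)
                    )
                    if "PG" not in mcoords:
                        continue
                    dist = float(np.linalg.norm(mcoords["PG"] - coords["O3B"]))
                    if dist <= MIMIC_LINK_CUTOFF and (best is None or dist < best[0]):
                        best = (dist, _resname(mres), mcoords, mflags)
                if best is not None:
                    _, mimic_id, mcoords, mflags = best
                    coords.update(mcoords)
                    mimic_flags.update(mflags)
                    analog_class = "transition_state"

            chain = PhosphateChain(coords=coords, is_mimic=mimic_flags,
                                   source=f"{sid}/{chain_id}/{lid}{resseq}")
            oxy = _phosphate_oxygens(chain)

            mg_dist = None
            if mg_positions:
                dmat = np.linalg.norm(
                    np.asarray(mg_positions)[:, None, :] - oxy[None, :, :], axis=-1
                )
                mg_dist = float(dmat.min())
            if mg_dist is None or mg_dist > mg_cutoff:
                exclusions.append({
                    "structure": sid, "ligand": f"{chain_id}/{lid}{resseq}",
                    "reason": f"no Mg within {mg_cutoff} A of a phosphate oxygen",
                })
                continue

            contacts = [
                tag for tag, pos in lys_nz
                if np.min(np.linalg.norm(oxy - pos, axis=-1)) <= lys_cutoff
            ]
            if not contacts:
                exclusions.append({
                    "structure": sid, "ligand": f"{chain_id}/{lid}{resseq}",
                    "reason": f"no Lys NZ within {lys_cutoff} A of a phosphate oxygen",
                })
                continue

            candidates.append(LigandCandidate(
                structure_id=sid, model_index=mi, chain_id=chain_id,
                resseq=resseq, ligand_id=lid, analog_class=analog_class,
                chain=chain, complete=chain.is_complete, mimic_id=mimic_id,
                substitutions=subs, lys_contacts=contacts,
                mg_distance=mg_dist, model=model,
            ))
    return candidates, exclusions


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

@dataclass
class SurveyRecord:
    structure_id: str
    model_index: int
    chain_id: str
    ligand: str
    analog_class: str
    descriptors: Optional[GeometryDescriptors]
    occupant: str                      # K/NA/RB/NH4/water/LYS-NZ/ARG-N/none
    occupant_dist_alpha: Optional[float]
    occupant_dist_gamma: Optional[float]
    lys_contact: bool
    substitutions: List[str] = field(default_factory=list)
    complete: bool = True

    def as_row(self) -> dict:
        d = self.descriptors
        return {
            "structure": self.structure_id,
            "chain": self.chain_id,
            "ligand": self.ligand,
            "analog_class": self.analog_class,
            "occupant": self.occupant,
            "dist_alpha": self.occupant_dist_alpha,
            "dist_gamma": self.occupant_dist_gamma,
            "d_pa_pg": None if d is None else round(d.d_pa_pg, 3),
            "theta_bridge": None if d is None else round(d.theta_bridge, 2),
            "psi_ab": None if d is None else round(d.psi_ab, 2),
            "psi_bg": None if d is None else round(d.psi_bg, 2),
            "psi_ag": None if d is None else round(d.psi_ag, 2),
            "mimic_derived": None if d is None else d.mimic_derived,
            "substitutions": ";".join(self.substitutions) or "-",
        }


def _gamma_alpha_points(chain: PhosphateChain):
    gamma = chain.oxygens("G")
    alpha = np.array([chain.coords[l] for l in ("O1A", "O2A", "O3A")
                      if l in chain.coords])
    return gamma, alpha


def measure_structure(
    candidate: LigandCandidate,
    occupant_cutoff: float = AG_OCCUPANT_CUTOFF,
) -> SurveyRecord:
    """Measure chain geometry and find the AG-site occupant of a candidate.

    The occupant is the nearest entity within ``occupant_cutoff`` of a
    gamma oxygen (F for tetrafluoride mimics, per the closest-F rule),
    searching cations first, then water, then Arg/Lys side-chain nitrogens;
    entities in BG-site contact (within cutoff of a beta oxygen) are not
    AG occupants.  Ties resolve to the smallest mean alpha/gamma distance.
    Incomplete chains (NDP without a gamma mimic) yield a record without
    descriptors.
    """
    chain = candidate.chain
    descriptors = None
    if chain.is_complete:
        descriptors = compute_descriptors(chain)

    gamma, alpha = _gamma_alpha_points(chain)
    beta = np.array([chain.coords[l] for l in ("O1B", "O2B", "O3B")
                     if l in chain.coords])

    occupant, d_a, d_g = "none", None, None
    if candidate.model is not None and len(gamma):
        pools = {"cation": [], "water": [], "amine": []}
        for pchain in candidate.model:
            for residue in pchain:
                name = _resname(residue)
                if name in _CATION_ELEMENTS:
                    for pos in _residue_atoms(residue).values():
                        pools["cation"].append((name, pos))
                elif name == "NH4":
                    atoms = _residue_atoms(residue)
                    if "N" in atoms:
                        pools["cation"].append(("NH4", atoms["N"]))
                elif name in _WATER_RESNAMES:
                    atoms = _residue_atoms(residue)
                    if "O" in atoms:
                        pools["water"].append(("water", atoms["O"]))
                elif name == "LYS" and "NZ" in residue:
                    pools["amine"].append(("LYS-NZ", _atom_position(residue["NZ"])))
                elif name == "ARG":
                    atoms = _residue_atoms(residue)
                    for nm in ("NH1", "NH2", "NE"):
                        if nm in atoms:
                            pools["amine"].append(("ARG-N", atoms[nm]))
        for category in ("cation", "water", "amine"):
            qualifying = []
            for species, pos in pools[category]:
                dg = float(np.min(np.linalg.norm(gamma - pos, axis=-1)))
                if dg > occupant_cutoff:
                    continue
                if len(beta):
                    db = float(np.min(np.linalg.norm(beta - pos, axis=-1)))
                    if db <= occupant_cutoff and db < dg:
                        continue  # BG-site entity (e.g. the P-loop Lys)
                da = (float(np.min(np.linalg.norm(alpha - pos, axis=-1)))
                      if len(alpha) else np.inf)
                qualifying.append(((da + dg) / 2.0, species, da, dg))
            if qualifying:
                qualifying.sort(key=lambda q: q[0])
                _, occupant, d_a, d_g = qualifying[0]
                break

    ligand = candidate.ligand_id + (
        f"-{candidate.mimic_id}" if candidate.mimic_id else ""
    )
    return SurveyRecord(
        structure_id=candidate.structure_id,
        model_index=candidate.model_index,
        chain_id=candidate.chain_id,
        ligand=ligand,
        analog_class=candidate.analog_class,
        descriptors=descriptors,
        occupant=occupant,
        occupant_dist_alpha=None if d_a in (None, np.inf) else round(d_a, 2),
        occupant_dist_gamma=None if d_g is None else round(d_g, 2),
        lys_contact=bool(candidate.lys_contacts),
        substitutions=list(candidate.substitutions),
        complete=candidate.complete,
    )


def survey_structures(
    paths: Sequence,
    atlas: Optional[LigandAtlas] = None,
    mg_cutoff: float = DEFAULT_MG_CUTOFF,
    lys_cutoff: float = DEFAULT_LYS_CUTOFF,
    all_models: bool = False,
) -> Tuple[List[SurveyRecord], List[dict]]:
    """Run screen + measure over a list of structure files."""
    atlas = atlas or LigandAtlas.default()
    records, exclusions = [], []
    for path in paths:
        path = Path(path)
        if not path.exists():
            exclusions.append({"structure": str(path), "ligand": "-",
                               "reason": "file not found"})
            warnings.warn(f"structure file missing: {path}")
            continue
        try:
            cands, excl = screen_structure(
                path, atlas=atlas, mg_cutoff=mg_cutoff,
                lys_cutoff=lys_cutoff, all_models=all_models,
            )
        except ValueError as e:
            exclusions.append({"structure": str(path), "ligand": "-",
                               "reason": str(e)})
            continue
        exclusions.extend(excl)
        records.extend(measure_structure(c) for c in cands)
    return records, exclusions


def records_table(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Table-style summary (one row per measured ligand site)."""
    return pd.DataFrame([r.as_row() for r in records])


# ---------------------------------------------------------------------------
# P-loop superposition
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def _backbone_coords(model, chain_id: str, first: int, last: int) -> np.ndarray:
    pts = []
    for pchain in model:
        if pchain.get_id() != chain_id:
            continue
        for residue in pchain:
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip():
                continue
            if first <= resseq <= last:
                for nm in _BACKBONE:
                    if nm in residue:
                        pts.append(_atom_position(residue[nm]))
    return np.array(pts)


def superpose_ploops(
    mobile_model,
    reference_model,
    mobile_range: Tuple[str, int, int],
    reference_range: Tuple[str, int, int],
):
    """Rigid superposition of backbone atoms of two residue ranges.

    ``*_range`` is ``(chain_id, first_resseq, last_resseq)`` in author
    numbering.  Uses backbone N/CA/C/O and Kabsch least squares; returns
    ``(rotation, translation, rmsd)``.
    """
    P = _backbone_coords(mobile_model, *mobile_range)
    Q = _backbone_coords(reference_model, *reference_range)
    if len(P) != len(Q):
        raise ValueError(
            f"backbone atom counts differ: {len(P)} (mobile) vs {len(Q)} "
            "(reference); adjust the residue ranges"
        )
    if len(P) < 3:
        raise ValueError("fewer than 3 paired backbone atoms")
    return kabsch_superpose(P, Q)


def collect_overlay_sets(records: Sequence[SurveyRecord]) -> Dict[str, np.ndarray]:
    """(d_pa_pg, theta) point sets per analog class for heat-map overlays."""
    out: Dict[str, list] = {}
    for rec in records:
        if rec.descriptors is None:
            continue
        out.setdefault(rec.analog_class, []).append(
            (rec.descriptors.d_pa_pg, rec.descriptors.theta_bridge)
        )
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}
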