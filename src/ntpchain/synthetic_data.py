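"""Synthetic trajectories and fixture structures with known ground truth.

Trajectories are generated by drawing per-frame descriptor values (AR(1)
noise around per-segment means), embedding a chain realising each draw,
then placing Mg to realise the segment's coordination state and monovalent
ions according to a two-state (bound/unbound) plan.  A JSON-able sidecar
records the true states, switch frames, occupancies and parameters, so
every analysis stage can be validated against generator truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from ntpchain.chain_model import (
    InternalChainSpec,
    PhosphateChain,
    _backbone_d_pa_pg,
    _embed_internal,
    compute_descriptors,
    embed_chain,
)
from ntpchain.chain_model import nerf_place
from ntpchain.trajectory_analysis import (
    DEFAULT_BINDING_DISTANCES,
    CoordinationState,
    IonTrack,
    Site,
    Trajectory,
    write_multimodel_pdb,
)

__all__ = [
    "TABLE_STATS",
    "SegmentPlan",
    "IonPlan",
    "SyntheticTrajectoryConfig",
    "FixtureStructureSpec",
    "generate_trajectory",
    "generate_fixture_structure",
]

#: Per-conformation (d_pa_pg mean/sd, theta mean/sd) reference statistics
#: for the Mg-ATP chain with different added cations, used as generator
#: defaults: keys are (cation, conformation).
TABLE_STATS: Dict[Tuple[str, str], Tuple[float, float, float, float]] = {
    ("NONE", "BETA_GAMMA"): (5.46, 0.34, 122.3, 3.5),
    ("NONE", "ALPHA_BETA_GAMMA"): (4.76, 0.18, 124.9, 3.3),
    ("K", "BETA_GAMMA"): (4.91, 0.24, 122.0, 3.3),
    ("K", "ALPHA_BETA_GAMMA"): (4.32, 0.24, 128.0, 3.5),
    ("NA", "BETA_GAMMA"): (4.69, 0.22, 122.9, 3.2),
    ("NA", "BETA_GAMMA_CURLED"): (4.60, 0.22, 124.0, 3.3),
    ("NA", "ALPHA_BETA_GAMMA"): (4.26, 0.37, 127.7, 3.6),
    ("NH4", "BETA_GAMMA"): (4.85, 0.22, 122.3, 3.3),
    ("NH4", "BETA_GAMMA_CURLED"): (4.56, 0.21, 124.6, 3.3),
    ("NH4", "ALPHA_BETA_GAMMA"): (4.22, 0.16, 127.8, 3.5),
}

#: Target cation-oxygen coordination bond lengths per species (Angstrom).
COORDINATION_LENGTHS = {"NA": 2.2, "K": 2.6, "NH4": 2.7}

_MG_BOND = 2.0  # Mg-O coordination length used for placement


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SegmentPlan:
    """One contiguous stretch of frames sharing a coordination state."""

    state: str                      # CoordinationState name
    n_frames: int
    d_mean: float
    d_sd: float
    theta_mean: float
    theta_sd: float

    @classmethod
    def from_reference(cls, cation: str, state: str, n_frames: int) -> "SegmentPlan":
        d_mean, d_sd, t_mean, t_sd = TABLE_STATS[(cation.upper(), state)]
        return cls(state=state, n_frames=n_frames, d_mean=d_mean, d_sd=d_sd,
                   theta_mean=t_mean, theta_sd=t_sd)


@dataclass
class IonPlan:
    """Two-state (bound/unbound) Markov plan for one monovalent ion."""

    species: str                    # 'K', 'NA', 'NH4'
    site: str = "BG"                # target site when bound: BG / AG / G
    bound_fraction: float = 0.9
    noise_sd: float = 0.1           # binding-distance noise (Angstrom)
    mean_dwell: int = 10            # mean bound-run length in frames


@dataclass
class SyntheticTrajectoryConfig:
    segments: List[SegmentPlan]
    dt_ps: float = 50.0
    phi: float = 0.8                # AR(1) persistence of descriptor noise
    ions: List[IonPlan] = field(default_factory=list)
    seed: int = 0
    psi_noise_sd: float = 3.0       # jitter on terminal-group rotations
    match_fraction: bool = True     # trim runs to hit bound_fraction exactly

    def __post_init__(self):
        if not self.segments:
            raise ConfigError("need at least one segment")
        for seg in self.segments:
            if seg.n_frames <= 0:
                raise ConfigError("segment durations must be positive")
            if seg.d_sd < 0 or seg.theta_sd < 0:
                raise ConfigError("segment SDs must be non-negative")
        for ion in self.ions:
            if not 0.0 <= ion.bound_fraction <= 1.0:
                raise ConfigError("bound fractions must lie in [0, 1]")
            if ion.noise_sd < 0:
                raise ConfigError("binding noise SD must be non-negative")
        if not 0.0 <= self.phi < 1.0:
            raise ConfigError("AR(1) persistence must lie in [0, 1)")
        if self.dt_ps <= 0:
            raise ConfigError("frame spacing must be positive")

    @property
    def n_frames(self) -> int:
        return sum(s.n_frames for s in self.segments)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ar1(rng, n, mean, sd, phi):
    """Stationary AR(1) series with the given marginal mean/sd."""
    if sd == 0 or n == 0:
        return np.full(n, float(mean))
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1) * innov_sd
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + eps[i - 1]
    return x


_CIRCLE_ANGLES = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)


def _circle_candidates(p1, p2, r):
    """Points at distance ~r from both p1 and p2 (the intersection circle;
    collapses to the midpoint when the spheres barely touch)."""
    mid = 0.5 * (p1 + p2)
    axis = p2 - p1
    h = 0.5 * np.linalg.norm(axis)
    axis = axis / (2.0 * h)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    rho = math.sqrt(max(r * r - h * h, 0.0))
    return (mid[None, :]
            + rho * np.cos(_CIRCLE_ANGLES)[:, None] * u[None, :]
            + rho * np.sin(_CIRCLE_ANGLES)[:, None] * v[None, :])


def _two_sphere_point(p1, p2, r, avoid=(), attract=None):
    """A point at distance ~r from p1 and p2, picked on the intersection
    circle to maximise clearance from ``avoid`` points (or, when
    ``attract`` is given, to minimise the distance to it)."""
    cands = _circle_candidates(p1, p2, r)
    if attract is not None:
        score = -np.linalg.norm(cands - attract[None, :], axis=-1)
    elif len(avoid):
        av = np.asarray(avoid, dtype=float)
        score = np.min(
            np.linalg.norm(cands[:, None, :] - av[None, :, :], axis=-1), axis=1
        )
    else:
        score = np.zeros(len(cands))
    return cands[int(np.argmax(score))]


def _fbackbone_d(spec: InternalChainSpec, d1: float, d2: float) -> float:
    """Scalar fast path for the backbone PA-PG distance."""
    from ntpchain.chain_model import _fnerf

    b = spec.bond_po_bridge
    ang_pa = math.radians(spec.angle_pa)
    pa = (0.0, 0.0, 0.0)
    o3a = (b, 0.0, 0.0)
    pb = (b - b * math.cos(ang_pa), b * math.sin(ang_pa), 0.0)
    o3b = _fnerf(pa, o3a, pb, b, spec.angle_pb, d1)
    pg = _fnerf(o3a, pb, o3b, b, spec.theta_bridge, d2)
    return math.dist(pa, pg)


_D2_SCAN = np.linspace(-180.0, 180.0, 49)


def _solve_d2(spec: InternalChainSpec, d1: float, target_d: float):
    """1D solve of the backbone dihedral d2 for a target PA-PG distance.

    Returns ``(d2, realized_d, clipped)``; targets outside the attainable
    range at this ``d1`` are clipped to the nearest attainable value.
    """
    vals = _backbone_d_pa_pg(spec, np.array([d1]), _D2_SCAN)[0]
    lo, hi = float(vals.min()), float(vals.max())
    clipped = False
    t = target_d
    if not lo + 1e-6 <= t <= hi - 1e-6:
        t = float(np.clip(t, lo + 1e-6, hi - 1e-6))
        clipped = True
    diff = vals - t
    sign = np.sign(diff)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) == 0:
        k = int(np.argmin(np.abs(diff)))
        return float(_D2_SCAN[k]), float(vals[k]), True
    k = crossings[0]
    d2 = float(brentq(lambda x: _fbackbone_d(spec, d1, x) - t,
                      _D2_SCAN[k], _D2_SCAN[k + 1], xtol=1e-10))
    return d2, t, clipped


_D1_CANDIDATES = np.arange(-180.0, 180.0, 30.0)


def _choose_d1(spec: InternalChainSpec, theta: float, d_mean: float) -> float:
    """Backbone dihedral d1 giving the most margin around a target mean."""
    s = replace(spec, theta_bridge=theta)
    best = (-np.inf, spec.d1)
    for d1 in _D1_CANDIDATES:
        vals = _backbone_d_pa_pg(s, np.array([d1]), _D2_SCAN)[0]
        margin = min(float(vals.max()) - d_mean, d_mean - float(vals.min()))
        if margin > best[0]:
            best = (margin, float(d1))
    return best[1]


def _choose_d1_tridentate(spec: InternalChainSpec, theta: float,
                          d_mean: float) -> float:
    """Backbone dihedral d1 for tridentate segments: the chain must wrap
    around the Mg site so that an alpha oxygen can reach its first shell."""
    s = replace(spec, theta_bridge=theta)
    best = (np.inf, spec.d1)
    for d1 in _D1_CANDIDATES:
        vals = _backbone_d_pa_pg(s, np.array([d1]), _D2_SCAN)[0]
        margin = min(float(vals.max()) - d_mean, d_mean - float(vals.min()))
        if margin < 2.0 * 0.24:  # needs headroom for the draws
            continue
        d2, _, _ = _solve_d2(s, float(d1), d_mean)
        coords = _embed_internal(s, float(d1), d2, s.tau_a, s.tau_g)
        tau_g = _orient_near(coords, s, "G", 120.0, coords["O1B"], 0.0)
        _update_group(coords, s, "G", tau_g)
        mg_pos = _two_sphere_point(coords["O1B"], coords["O2G"], _MG_BOND,
                                   attract=coords["PA"])
        ring = _ring_positions(coords, s, "A", _RING_TAUS)
        reach = float(np.min(np.abs(
            np.linalg.norm(ring - mg_pos[None, :], axis=-1) - _MG_BOND)))
        if reach < best[0]:
            best = (reach, float(d1))
    return best[1]


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _match_count(mask: np.ndarray, k: int, rng) -> np.ndarray:
    """Flip run-boundary frames until exactly k frames are True."""
    mask = mask.copy()
    while mask.sum() != k:
        excess = int(mask.sum()) - k
        boundary = np.nonzero(mask[:-1] != mask[1:])[0]
        if excess > 0:
            flips = [i for i in boundary if mask[i]] + \
                    [i + 1 for i in boundary if mask[i + 1]]
            flips = [i for i in flips if mask[i]]
        else:
            flips = [i for i in boundary if not mask[i]] + \
                    [i + 1 for i in boundary if not mask[i + 1]]
            flips = [i for i in flips if not mask[i]]
        if not flips:
            idx = np.nonzero(mask if excess > 0 else ~mask)[0]
            flips = list(idx)
        i = flips[int(rng.integers(len(flips)))]
        mask[i] = not mask[i]
    return mask


def _bound_mask(rng, n, plan: IonPlan, match: bool) -> np.ndarray:
    f = plan.bound_fraction
    if f <= 0.0:
        return np.zeros(n, dtype=bool)
    if f >= 1.0:
        return np.ones(n, dtype=bool)
    p_unbind = 1.0 / max(plan.mean_dwell, 1)
    p_bind = f * p_unbind / (1.0 - f)
    p_bind = min(p_bind, 1.0)
    mask = np.empty(n, dtype=bool)
    mask[0] = rng.random() < f
    u = rng.random(n - 1)
    for i in range(1, n):
        if mask[i - 1]:
            mask[i] = u[i - 1] >= p_unbind
        else:
            mask[i] = u[i - 1] < p_bind
    if match:
        mask = _match_count(mask, int(round(f * n)), rng)
    return mask


_SITE_ANCHORS = {
    "BG": ("O2B", "O3G"),
    "AG": ("O2A", "O3G"),
    "G": ("O1G",),
}

_RING_TAUS = np.arange(0.0, 360.0, 1.0)


def _ring_positions(coords, spec, group: str, taus):
    """Candidate positions of a terminal oxygen as its group rotates."""
    if group == "G":
        a, b, c = coords["PB"], coords["O3B"], coords["PG"]
    else:
        a, b, c = coords["PB"], coords["O3A"], coords["PA"]
    return nerf_place(a, b, c, spec.bond_po_terminal, spec.angle_terminal, taus)


def _orient_near(coords, spec, group, slot_offset, target, bond) -> float:
    """Group rotation placing the slot_offset oxygen at ~bond from target."""
    ring = _ring_positions(coords, spec, group, _RING_TAUS + slot_offset)
    k = int(np.argmin(np.abs(
        np.linalg.norm(ring - target[None, :], axis=-1) - bond)))
    return float(_RING_TAUS[k])


def _orient_far(coords, spec, group, target) -> float:
    """Group rotation maximising the two non-bridging oxygens' clearance."""
    r0 = _ring_positions(coords, spec, group, _RING_TAUS)
    r1 = _ring_positions(coords, spec, group, _RING_TAUS + 120.0)
    score = np.minimum(np.linalg.norm(r0 - target[None, :], axis=-1),
                       np.linalg.norm(r1 - target[None, :], axis=-1))
    return float(_RING_TAUS[int(np.argmax(score))])


def _update_group(coords, spec, group: str, tau: float) -> None:
    """Recompute a terminal group's oxygens at rotation ``tau``."""
    if group == "G":
        o1, o2, o3 = nerf_place(
            coords["PB"], coords["O3B"], coords["PG"],
            spec.bond_po_terminal, spec.angle_terminal,
            np.array([tau, tau + 120.0, tau + 240.0]))
        coords["O1G"], coords["O2G"], coords["O3G"] = o1, o2, o3
    else:
        o1, o2, o5 = nerf_place(
            coords["PB"], coords["O3A"], coords["PA"],
            np.array([spec.bond_po_terminal, spec.bond_po_terminal,
                      spec.bond_po_bridge]),
            spec.angle_terminal,
            np.array([tau, tau + 120.0, tau + 240.0]))
        coords["O1A"], coords["O2A"], coords["O5'"] = o1, o2, o5


def _closest_pair(group1, group2, exclude=()):
    """The (p1, p2) pair across two point lists with minimal separation,
    skipping excluded (identical) points."""
    best = None
    for p1 in group1:
        if any(p1 is e for e in exclude):
            continue
        for p2 in group2:
            if any(p2 is e for e in exclude):
                continue
            d = float(np.linalg.norm(p1 - p2))
            if best is None or d < best[0]:
                best = (d, p1, p2)
    return best[1], best[2]


def generate_trajectory(
    config: SyntheticTrajectoryConfig,
    base_spec: Optional[InternalChainSpec] = None,
) -> Tuple[Trajectory, dict]:
    """Generate a synthetic trajectory and its ground-truth sidecar.

    Deterministic for a given config (seed included).  Raises
    :class:`ConfigError` when more than 1% of descriptor draws have to be
    clipped to the feasible geometry range.
    """
    rng = np.random.default_rng(config.seed)
    spec = base_spec if base_spec is not None else InternalChainSpec()
    n = config.n_frames

    # per-frame descriptor draws
    d_series = np.empty(n)
    theta_series = np.empty(n)
    states: List[str] = []
    switches = []
    pos = 0
    for seg in config.segments:
        d_series[pos:pos + seg.n_frames] = _ar1(
            rng, seg.n_frames, seg.d_mean, seg.d_sd, config.phi)
        theta_series[pos:pos + seg.n_frames] = _ar1(
            rng, seg.n_frames, seg.theta_mean, seg.theta_sd, config.phi)
        states.extend([seg.state] * seg.n_frames)
        pos += seg.n_frames
        if pos < n:
            switches.append(pos)
    theta_series = np.clip(theta_series, 90.0, 179.0)

    tau_a = _ar1(rng, n, spec.tau_a, config.psi_noise_sd, config.phi)
    tau_g = _ar1(rng, n, spec.tau_g, config.psi_noise_sd, config.phi)

    # ion bound masks drawn before per-frame geometry so that frame loops
    # do not perturb the ion stream
    masks = [_bound_mask(rng, n, plan, config.match_fraction)
             for plan in config.ions]
    noise = [rng.standard_normal(n) * plan.noise_sd for plan in config.ions]
    unbound_dirs = rng.standard_normal((len(config.ions), n, 3))
    unbound_dirs /= np.linalg.norm(unbound_dirs, axis=-1, keepdims=True)

    # per-frame d1: the segment's preferred value, with a per-frame
    # fallback scan when a draw falls outside that slice of the range
    d1_frames = np.empty(n)
    pos = 0
    for seg in config.segments:
        chooser = (_choose_d1_tridentate
                   if seg.state == "ALPHA_BETA_GAMMA" else _choose_d1)
        d1_frames[pos:pos + seg.n_frames] = chooser(
            spec, seg.theta_mean, seg.d_mean)
        pos += seg.n_frames

    chain = {}
    mg = np.empty((n, 3))
    ion_positions = [np.empty((n, 3)) for _ in config.ions]
    clipped = 0
    frame_spec = replace(spec)
    for i in range(n):
        frame_spec.theta_bridge = float(theta_series[i])
        d_t = d_series[i]
        d2, realized, clip = _solve_d2(frame_spec, d1_frames[i], d_t)
        if clip:
            # try other backbone slices before accepting the clipped value
            for d1_alt in _D1_CANDIDATES:
                d2_alt, realized_alt, clip_alt = _solve_d2(
                    frame_spec, float(d1_alt), d_t)
                if not clip_alt:
                    d1_frames[i], d2, realized, clip = (
                        float(d1_alt), d2_alt, realized_alt, False)
                    break
        if clip:
            clipped += 1
        d_series[i] = realized
        coords = _embed_internal(frame_spec, d1_frames[i], d2,
                                 tau_a[i], tau_g[i])

        state = states[i]
        p_atoms = (coords["PA"] + coords["PB"] + coords["PG"]) / 3.0
        mg_bound = state in ("BETA_GAMMA", "BETA_GAMMA_CURLED",
                             "ALPHA_BETA_GAMMA")
        if mg_bound:
            # orient the gamma group so O2G converges towards O1B (the
            # bidentate coordination geometry), then seat Mg on the
            # O1B/O2G two-sphere circle
            tau_g[i] = _orient_near(coords, frame_spec, "G", 120.0,
                                    coords["O1B"], 0.0)
            _update_group(coords, frame_spec, "G", tau_g[i])
            avoid_or_attract = {}
            if state == "ALPHA_BETA_GAMMA":
                avoid_or_attract["attract"] = coords["PA"]
            else:
                avoid_or_attract["avoid"] = [coords["O1A"], coords["O2A"]]
            mg[i] = _two_sphere_point(coords["O1B"], coords["O2G"],
                                      _MG_BOND, **avoid_or_attract)
            if state == "ALPHA_BETA_GAMMA":
                # rotate the alpha group so O2A joins the Mg first shell
                tau_a[i] = _orient_near(coords, frame_spec, "A", 120.0,
                                        mg[i], _MG_BOND)
                _update_group(coords, frame_spec, "A", tau_a[i])
                if np.linalg.norm(coords["O2A"] - mg[i]) > 2.4:
                    # this draw needs a different backbone slice to wrap
                    # the chain around the Mg site
                    d1_frames[i] = _choose_d1_tridentate(
                        spec, float(theta_series[i]), realized)
                    d2, realized, _ = _solve_d2(frame_spec, d1_frames[i],
                                                realized)
                    d_series[i] = realized
                    coords = _embed_internal(frame_spec, d1_frames[i], d2,
                                             tau_a[i], tau_g[i])
                    tau_g[i] = _orient_near(coords, frame_spec, "G", 120.0,
                                            coords["O1B"], 0.0)
                    _update_group(coords, frame_spec, "G", tau_g[i])
                    mg[i] = _two_sphere_point(coords["O1B"], coords["O2G"],
                                              _MG_BOND, attract=coords["PA"])
                    tau_a[i] = _orient_near(coords, frame_spec, "A", 120.0,
                                            mg[i], _MG_BOND)
                    _update_group(coords, frame_spec, "A", tau_a[i])
            else:
                # keep alpha oxygens out of the Mg shell
                if min(np.linalg.norm(coords["O1A"] - mg[i]),
                       np.linalg.norm(coords["O2A"] - mg[i])) <= 2.6:
                    tau_a[i] = _orient_far(coords, frame_spec, "A", mg[i])
                    _update_group(coords, frame_spec, "A", tau_a[i])
        else:
            mg[i] = p_atoms + np.array([0.0, 0.0, 8.0])

        for label, xyz in coords.items():
            chain.setdefault(label, np.empty((n, 3)))[i] = xyz

        alpha_all = [coords[l] for l in ("O1A", "O2A", "O3A", "O5'")]
        beta_all = [coords[l] for l in ("O1B", "O2B", "O3B")]
        gamma_all = [coords[l] for l in ("O1G", "O2G", "O3G")]
        for k, plan in enumerate(config.ions):
            if masks[k][i]:
                cutoff = DEFAULT_BINDING_DISTANCES.get(plan.species.upper(), 3.2)
                r = COORDINATION_LENGTHS.get(plan.species.upper(), 2.6)
                r = float(np.clip(r + noise[k][i], 1.8, cutoff - 0.05))
                site = plan.site.upper()
                if site == "BG":
                    a1, a2 = _closest_pair(beta_all, gamma_all,
                                           exclude=(coords["O1B"], coords["O2G"]))
                    ion_positions[k][i] = _two_sphere_point(
                        a1, a2, r, avoid=[mg[i]] + alpha_all)
                elif site == "AG":
                    a1, a2 = _closest_pair([coords["O1A"], coords["O2A"]],
                                           gamma_all,
                                           exclude=(coords["O2G"],))
                    ion_positions[k][i] = _two_sphere_point(
                        a1, a2, r, avoid=[mg[i]] + beta_all)
                else:
                    a1 = max(gamma_all,
                             key=lambda o: np.linalg.norm(o - coords["PB"]))
                    out = a1 - coords["PG"]
                    out /= np.linalg.norm(out)
                    ion_positions[k][i] = a1 + r * out
            else:
                ion_positions[k][i] = p_atoms + 9.0 * unbound_dirs[k, i]

    if n and clipped / n > 0.01:
        raise ConfigError(
            f"{clipped}/{n} descriptor draws infeasible (> 1%); "
            "check segment means against the attainable geometry range"
        )

    ions = [
        IonTrack(f"{plan.species.upper()}{k + 1}", plan.species, ion_positions[k])
        for k, plan in enumerate(config.ions)
    ]
    traj = Trajectory(chain=chain, dt_ps=config.dt_ps, mg=mg, ions=ions,
                      source=f"synthetic(seed={config.seed})")

    truth = {
        "seed": config.seed,
        "dt_ps": config.dt_ps,
        "n_frames": n,
        "clipped_draws": clipped,
        "segments": [
            {
                "state": seg.state,
                "start": sum(s.n_frames for s in config.segments[:j]),
                "end": sum(s.n_frames for s in config.segments[:j + 1]),
                "d_mean": seg.d_mean, "d_sd": seg.d_sd,
                "theta_mean": seg.theta_mean, "theta_sd": seg.theta_sd,
            }
            for j, seg in enumerate(config.segments)
        ],
        "switch_frames": switches,
        "ions": [
            {
                "ion_id": ions[k].ion_id,
                "species": plan.species.upper(),
                "site": plan.site.upper(),
                "configured_fraction": plan.bound_fraction,
                "realized_occupancy": float(np.mean(masks[k])),
                "bound_runs": _runs(masks[k]),
            }
            for k, plan in enumerate(config.ions)
        ],
    }
    return traj, truth


def _runs(mask: np.ndarray) -> List[List[int]]:
    """[start, end) intervals of True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append([start, i])
            start = None
    if start is not None:
        out.append([start, len(mask)])
    return out


def write_trajectory_files(traj: Trajectory, truth: dict, outdir,
                           stem: str = "synthetic") -> Tuple[Path, Path]:
    """Write the multi-model PDB and the JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_path = outdir / f"{stem}.pdb"
    sidecar_path = outdir / f"{stem}.truth.json"
    write_multimodel_pdb(traj, pdb_path)
    with open(sidecar_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return pdb_path, sidecar_path


# ---------------------------------------------------------------------------
# fixture structures
# ---------------------------------------------------------------------------

@dataclass
class FixtureStructureSpec:
    """A minimal crystal-structure-like fixture with known geometry."""

    ligand_id: str = "ATP"
    chain_spec: InternalChainSpec = field(default_factory=InternalChainSpec)
    include_mg: bool = True
    cation: Optional[str] = None        # 'K' / 'NA' / 'RB'
    cation_site: str = "AG"
    cation_distance: float = 2.7
    water_at_ag: bool = False
    lys_nz_distance: Optional[float] = 2.8
    arg_at_ag: bool = False
    mimic_id: Optional[str] = None      # 'ALF' etc. (ligand must be an NDP)

    def __post_init__(self):
        if self.cation is not None and self.water_at_ag:
            raise ConfigError("place either a cation or a water, not both")


_SUB_REVERSE = {
    "ANP": {"O3B": "N3B"}, "GNP": {"O3B": "N3B"},
    "ACP": {"O3B": "C3B"}, "GCP": {"O3B": "C3B"},
    "ASP": {"O1G": "S1G"}, "AGS": {"O1G": "S1G"}, "GSP": {"O1G": "S1G"},
}

_MIMIC_CENTRE = {"ALF": "AL", "AF3": "AL", "MGF": "MG", "BEF": "BE"}


def _element_of(name: str) -> str:
    if name.startswith("P"):
        return "P"
    if name in ("AL",):
        return "AL"
    if name in ("BE",):
        return "BE"
    if name.startswith("F"):
        return "F"
    if name.startswith("N"):
        return "N"
    if name.startswith("S"):
        return "S"
    if name.startswith("C") and name != "CL":
        return "C"
    return "O"


def generate_fixture_structure(spec: FixtureStructureSpec, path) -> dict:
    """Write a minimal PDB fixture and return its ground truth.

    The file contains a HETATM ligand (optionally split into NDP + mimic
    moiety), the Mg ion, any placed cation/water and ATOM-record Lys/Arg
    stubs.  Returns ground truth (descriptors, expected occupant, expected
    analog class) computed from the embedded coordinates.  Raises
    :class:`ConfigError` on a steric clash (< 1.5 A) between placed
    entities.
    """
    chain = embed_chain(spec.chain_spec)
    coords = dict(chain.coords)
    p_centroid = (coords["PA"] + coords["PB"] + coords["PG"]) / 3.0

    placed = {}
    if spec.include_mg:
        # orient the gamma group so O2G can coordinate Mg together with
        # O1B (leaves d_pa_pg and theta_bridge untouched)
        tau_g = _orient_near(coords, spec.chain_spec, "G", 120.0,
                             coords["O1B"], 0.0)
        _update_group(coords, spec.chain_spec, "G", tau_g)
        chain = PhosphateChain(coords=dict(coords), source=chain.source)
        b_star, g_star = _closest_pair(
            [coords["O1B"], coords["O2B"]],
            [coords["O1G"], coords["O2G"], coords["O3G"]])
        # widen the coordination radius when the oxygens cannot converge,
        # so the ion sits off the backbone instead of on top of it
        half_sep = 0.5 * float(np.linalg.norm(b_star - g_star))
        r_mg = max(_MG_BOND, half_sep + 0.45)
        placed["MG"] = _two_sphere_point(
            b_star, g_star, r_mg,
            avoid=[coords[l] for l in ("O1A", "O2A", "PA", "PB", "PG",
                                       "O3A", "O3B")])
    mg_pos = placed.get("MG", p_centroid + np.array([0, 0, 8.0]))

    def _ag_point(dist):
        # bridge the gamma oxygen most distal from the beta group with an
        # alpha oxygen rotated towards it; the entity is seated as close
        # to the requested bridging distance as the rigid chain allows,
        # with a steric penalty keeping it clear of Mg, the backbone and
        # the beta group (realized distances are recorded as truth)
        from scipy.optimize import minimize

        g_star = max((coords["O1G"], coords["O3G"]),
                     key=lambda g: np.linalg.norm(g - coords["PB"]))
        tau_a = _orient_near(coords, spec.chain_spec, "A", 120.0, g_star, 0.0)
        _update_group(coords, spec.chain_spec, "A", tau_a)
        a_star = min((coords["O1A"], coords["O2A"]),
                     key=lambda a: np.linalg.norm(a - g_star))
        beta = np.array([coords[l] for l in ("O1B", "O2B", "O3B")])
        others = np.array(
            [mg_pos] + [v for k, v in coords.items()
                        if v is not a_star and v is not g_star
                        and k not in ("O1B", "O2B", "O3B")])

        def cost(x):
            da = np.linalg.norm(x - a_star)
            dg = np.linalg.norm(x - g_star)
            # target distances, hard preference for a detectable gamma
            # contact (< 3.5 A) and clearance from the beta group so the
            # entity reads as an AG occupant, not a BG one
            c = (da - dist) ** 2 + (dg - dist) ** 2
            c += 60.0 * max(0.0, dg - 3.3) ** 2
            db = np.linalg.norm(beta - x, axis=-1)
            close_b = db < 3.6
            c += 40.0 * float(np.sum((3.6 - db[close_b]) ** 2))
            dd = np.linalg.norm(others - x, axis=-1)
            close = dd < 2.3
            c += 25.0 * float(np.sum((2.3 - dd[close]) ** 2))
            return c

        best = None
        for x0 in _circle_candidates(a_star, g_star, max(dist, 2.8))[::9]:
            sol = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-10,
                                    "maxiter": 2000})
            if best is None or sol.fun < best.fun:
                best = sol
        return best.x

    if spec.cation is not None:
        if spec.cation_site.upper() == "AG":
            placed["CATION"] = _ag_point(spec.cation_distance)
        elif spec.cation_site.upper() == "BG":
            gamma_all = [coords[l] for l in ("O1G", "O3G")]
            a1, a2 = _closest_pair([coords["O1B"], coords["O2B"]], gamma_all)
            alpha_all = [coords[l] for l in ("O1A", "O2A", "O3A", "O5'")]
            placed["CATION"] = _two_sphere_point(
                a1, a2, spec.cation_distance, avoid=[mg_pos] + alpha_all)
        else:
            a1 = coords["O1G"]
            out = a1 - coords["PG"]
            out /= np.linalg.norm(out)
            placed["CATION"] = a1 + spec.cation_distance * out
    if spec.water_at_ag:
        placed["WATER"] = _ag_point(spec.cation_distance)
    if spec.arg_at_ag:
        placed["ARG_NH1"] = _ag_point(spec.cation_distance)
    if spec.lys_nz_distance is not None:
        out = coords["O2B"] - p_centroid
        out /= np.linalg.norm(out)
        placed["NZ"] = coords["O2B"] + spec.lys_nz_distance * out

    chain = PhosphateChain(coords=dict(coords), source=chain.source)

    # clash check: placed entities against chain atoms and each other
    # (chain-internal bonded pairs are legitimate short distances)
    if placed:
        chain_pts = np.array(list(coords.values()))
        placed_pts = np.array(list(placed.values()))
        d_pc = np.linalg.norm(
            placed_pts[:, None, :] - chain_pts[None, :, :], axis=-1)
        closest = float(d_pc.min())
        if len(placed_pts) > 1:
            d_pp = np.linalg.norm(
                placed_pts[:, None, :] - placed_pts[None, :, :], axis=-1)
            np.fill_diagonal(d_pp, np.inf)
            closest = min(closest, float(d_pp.min()))
        if closest < 1.5:
            raise ConfigError(
                f"placement clash: two entities {closest:.2f} A apart"
            )

    lines = []
    serial = 1

    def emit(name, resname, chain_id, resseq, xyz, element, hetatm=True):
        nonlocal serial
        record = "HETATM" if hetatm else "ATOM  "
        if len(name) < 4 and not name[:1].isdigit():
            name_field = f" {name:<3s}"
        else:
            name_field = f"{name:<4s}"
        lines.append(
            f"{record}{serial:>5d} {name_field} {resname:<3s} {chain_id}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
        serial += 1

    lid = spec.ligand_id.upper()
    reverse = _SUB_REVERSE.get(lid, {})
    gamma_labels = ("PG", "O1G", "O2G", "O3G")
    is_product = lid in ("ADP", "GDP")
    ligand_labels = [l for l in coords
                     if not (is_product and l in gamma_labels)]
    for label in ligand_labels:
        name = reverse.get(label, label)
        emit(name, lid, "A", 401, coords[label], _element_of(name))
    if spec.mimic_id is not None:
        mid = spec.mimic_id.upper()
        centre = _MIMIC_CENTRE[mid]
        emit(centre, mid, "A", 402, coords["PG"], centre)
        for j, l in enumerate(("O1G", "O2G", "O3G"), start=1):
            emit(f"F{j}", mid, "A", 402, coords[l], "F")
        if mid == "ALF":
            f4 = coords["PG"] + (coords["PG"] - coords["O3B"]) / np.linalg.norm(
                coords["PG"] - coords["O3B"]) * 1.7
            emit("F4", mid, "A", 402, f4, "F")
    if "MG" in placed:
        emit("MG", "MG", "A", 403, placed["MG"], "MG")
    if "CATION" in placed:
        sp = spec.cation.upper()
        emit(sp[:2], sp[:2], "A", 404, placed["CATION"], sp[:2])
    if "WATER" in placed:
        emit("O", "HOH", "A", 405, placed["WATER"], "O")
    if "NZ" in placed:
        # Lys stub: backbone + CB laid out away from the chain
        nz = placed["NZ"]
        out = nz - p_centroid
        out /= np.linalg.norm(out)
        offsets = {"CB": 1.5, "CA": 3.0, "N": 3.8, "C": 3.9, "O": 5.0}
        for j, (nm, off) in enumerate(offsets.items()):
            perp = np.array([0.0, 0.0, 1.0]) * (0.4 * j)
            emit(nm, "LYS", "B", 50 + 0, nz + off * out + perp, nm[0], hetatm=False)
        emit("NZ", "LYS", "B", 50, nz, "N", hetatm=False)
    if "ARG_NH1" in placed:
        nh1 = placed["ARG_NH1"]
        out = nh1 - p_centroid
        out /= np.linalg.norm(out)
        emit("NH1", "ARG", "B", 60, nh1, "N", hetatm=False)
        emit("NE", "ARG", "B", 60, nh1 + 1.4 * out, "N", hetatm=False)

    path = Path(path)
    with open(path, "w") as fh:
        fh.write("REMARK   1 ntpchain fixture structure\n")
        fh.write("\n".join(lines))
        fh.write("\nEND\n")

    desc = compute_descriptors(chain)
    occupant_pos = placed.get("CATION", placed.get("WATER",
                                                   placed.get("ARG_NH1")))
    realized = {}
    if occupant_pos is not None:
        alpha = np.array([coords[l] for l in ("O1A", "O2A", "O3A")])
        gamma = np.array([coords[l] for l in ("O1G", "O2G", "O3G")])
        realized = {
            "occupant_dist_alpha": float(
                np.min(np.linalg.norm(alpha - occupant_pos, axis=-1))),
            "occupant_dist_gamma": float(
                np.min(np.linalg.norm(gamma - occupant_pos, axis=-1))),
        }
    if spec.cation is not None and spec.cation_site.upper() == "AG":
        expected_occupant = spec.cation.upper()[:2]
    elif spec.water_at_ag:
        expected_occupant = "water"
    elif spec.arg_at_ag:
        expected_occupant = "ARG-N"
    else:
        expected_occupant = "none"
    if spec.mimic_id is not None:
        expected_class = "transition_state"
    else:
        expected_class = {
            "ATP": "substrate", "GTP": "substrate",
            "ADP": "product", "GDP": "product",
        }.get(lid, "non_hydrolyzable")
    return {
        "descriptors": desc.as_dict(),
        "expected_occupant": expected_occupant,
        "expected_class": expected_class,
        "expected_complete": (not is_product) or spec.mimic_id is not None,
        "has_mg": spec.include_mg,
        "lys_nz_distance": spec.lys_nz_distance,
        **realized,
    }
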