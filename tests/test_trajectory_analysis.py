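import numpy as np
import pytest

from ntpchain.chain_model import (
    ALPHA_OXYGENS,
    BETA_OXYGENS,
    GAMMA_OXYGENS,
    PhosphateChain,
)
from ntpchain.trajectory_analysis import (
    ConfigurationError,
    CoordinationState,
    IonTrack,
    MissingIonError,
    Site,
    StateSegment,
    Trajectory,
    assign_ion_sites,
    assign_ion_sites_frames,
    classify_frames,
    classify_mg_coordination,
    compute_descriptor_series,
    detect_curled,
    load_trajectory,
    moving_average,
    occupancy,
    segment_trajectory,
    track_pair_distance,
    write_multimodel_pdb,
)

from conftest import random_rotation


def toy_chain(mg=None):
    """A schematic chain: labels placed for distance logic, not physics."""
    far = 50.0
    coords = {
        "PA": [0.0, 0, 0], "O1A": [0.0, 1.5, 0], "O2A": [0.0, -1.5, 0],
        "O3A": [1.6, 0, 0], "O5'": [-1.6, 0, 0],
        "PB": [3.0, 0, 0], "O1B": [3.0, 1.5, 0], "O2B": [3.0, -1.5, 0],
        "O3B": [4.6, 0, 0],
        "PG": [6.0, 0, 0], "O1G": [6.0, 1.5, 0], "O2G": [6.0, -1.5, 0],
        "O3G": [7.5, 0, 0],
    }
    if mg is not None:
        coords["MG"] = mg
    return PhosphateChain(coords={k: np.array(v, float)
                                  for k, v in coords.items()})


class TestMgCoordination:
    def test_beta_gamma(self):
        # Mg 2.0 A from O1B and O2G equivalents, far from alpha
        chain = toy_chain(mg=[4.5, 1.55, 1.3])
        d_o1b = np.linalg.norm(chain["MG"] - chain["O1B"])
        d_o1g = np.linalg.norm(chain["MG"] - chain["O1G"])
        assert d_o1b < 2.5 and d_o1g < 2.5
        assert classify_mg_coordination(chain) is CoordinationState.BETA_GAMMA

    def test_alpha_beta_gamma(self):
        # equidistant from the three +y oxygens (x = 3.0 is the middle)
        chain = toy_chain(mg=[3.0, 2.5, 0.0])
        # O1A/O1B/O1G all within 2.5 sqrt((3)^2+1)^... check distances
        for lab in ("O1A", "O1B", "O1G"):
            assert np.linalg.norm(chain["MG"] - chain[lab]) < 3.5
        chain = toy_chain(mg=[3.0, 2.2, 0.0])
        assert classify_mg_coordination(chain, mg_cutoff=3.9) \
            is CoordinationState.ALPHA_BETA_GAMMA

    def test_other_when_far(self):
        chain = toy_chain(mg=[3.0, 20.0, 0.0])
        assert classify_mg_coordination(chain) is CoordinationState.OTHER

    def test_missing_mg(self):
        with pytest.raises(MissingIonError):
            classify_mg_coordination(toy_chain())

    def test_generator_states_recovered(self, k_trajectory):
        traj, truth, _ = k_trajectory
        states = classify_frames(traj)
        for seg in truth["segments"]:
            want = (CoordinationState.BETA_GAMMA
                    if seg["state"].startswith("BETA_GAMMA")
                    else CoordinationState[seg["state"]])
            got = states[seg["start"]:seg["end"]]
            frac = np.mean([s is want for s in got])
            assert frac > 0.98

    def test_rigid_transform_stability(self, k_trajectory, rng):
        traj, _, _ = k_trajectory
        R = random_rotation(rng)
        t = rng.standard_normal(3) * 15
        moved = Trajectory(
            chain={k: v @ R.T + t for k, v in traj.chain.items()},
            dt_ps=traj.dt_ps, mg=traj.mg @ R.T + t,
            ions=[IonTrack(i.ion_id, i.species, i.positions @ R.T + t)
                  for i in traj.ions],
        )
        assert classify_frames(traj) == classify_frames(moved)
        a = assign_ion_sites_frames(traj)
        b = assign_ion_sites_frames(moved)
        for fa, fb in zip(a, b):
            assert [r.site for r in fa] == [r.site for r in fb]


class TestCurled:
    def test_curled_regime_detected(self):
        seg = StateSegment(0, 100, CoordinationState.BETA_GAMMA)
        d = np.full(100, 4.56)
        assert detect_curled(seg, d).state \
            is CoordinationState.BETA_GAMMA_CURLED

    def test_extended_regime_stays(self):
        seg = StateSegment(0, 100, CoordinationState.BETA_GAMMA)
        assert detect_curled(seg, np.full(100, 5.46)).state \
            is CoordinationState.BETA_GAMMA

    def test_tie_stays_beta_gamma(self):
        seg = StateSegment(0, 10, CoordinationState.BETA_GAMMA)
        assert detect_curled(seg, np.full(10, 4.65),
                             curl_threshold=4.65).state \
            is CoordinationState.BETA_GAMMA

    def test_non_bg_untouched(self):
        seg = StateSegment(0, 10, CoordinationState.ALPHA_BETA_GAMMA)
        assert detect_curled(seg, np.full(10, 2.0)).state \
            is CoordinationState.ALPHA_BETA_GAMMA


class TestIonSites:
    def test_bg_example(self):
        chain = toy_chain()
        # within K binding distance of a beta and a gamma oxygen, far from
        # alpha oxygens
        ion_pos = np.array([4.5, 1.55, 2.1])
        for lab in ("O1B", "O1G"):
            assert np.linalg.norm(ion_pos - chain[lab]) < 3.2
        recs = assign_ion_sites(chain, [("K1", "K", ion_pos)])
        assert recs[0].site is Site.BG

    def test_ag_example(self):
        chain = toy_chain()
        # a schematic compressed geometry: alpha and gamma oxygens brought
        # together so a Na ion can touch both at 2.3 A
        coords = dict(chain.coords)
        coords["O2A"] = np.array([2.0, -2.0, 0.0])
        coords["O3G"] = np.array([2.0, -2.0, 4.6])
        chain = PhosphateChain(coords=coords)
        # on the bisector plane, 2.35 A from both anchors
        ion = np.array([2.0, -2.0 - np.sqrt(2.35**2 - 2.3**2), 2.3])
        d_a = np.linalg.norm(ion - coords["O2A"])
        d_g = np.linalg.norm(ion - coords["O3G"])
        assert d_a < 2.4 and d_g < 2.4
        recs = assign_ion_sites(chain, [("NA1", "NA", ion)])
        assert recs[0].site is Site.AG
        assert recs[0].r_ag == pytest.approx((d_a + d_g) / 2, abs=1e-9)

    def test_g_only(self):
        chain = toy_chain()
        ion = chain["O3G"] + np.array([3.0, 0, 0])
        recs = assign_ion_sites(chain, [("K1", "K", ion)])
        assert recs[0].site is Site.G

    def test_unbound(self):
        chain = toy_chain()
        recs = assign_ion_sites(chain, [("K1", "K", [0.0, 30.0, 0.0])])
        assert recs[0].site is Site.UNBOUND

    def test_both_qualify_smaller_r_wins(self):
        chain = toy_chain()
        # place within K distance of alpha, beta and gamma oxygens: the
        # chain spans x=0..7.5, y rows at +-1.5; sit above the middle
        ion = np.array([3.0, 2.0, 0.0])
        rec = assign_ion_sites(chain, [("K1", "K", ion)])[0]
        assert rec.r_a <= 3.2 and r_ok(rec)
        assert rec.r_bg < rec.r_ag
        assert rec.site is Site.BG

    def test_unknown_species(self):
        with pytest.raises(ConfigurationError):
            assign_ion_sites(toy_chain(), [("X1", "CS", [0.0, 0, 0])])

    def test_brute_force_oracle(self, rng):
        """Exhaustive distance enumeration must match the pipeline on 100
        random frames."""
        bd = {"K": 3.2, "NA": 2.4, "NH4": 3.2}
        species = ["K", "NA", "NH4"]
        for _ in range(100):
            coords = {l: rng.uniform(-4, 4, 3)
                      for l in (ALPHA_OXYGENS + BETA_OXYGENS + GAMMA_OXYGENS
                                + ("PA", "PB", "PG"))}
            chain = PhosphateChain(coords=coords)
            ions = [(f"I{j}", species[j % 3], rng.uniform(-6, 6, 3))
                    for j in range(4)]
            recs = assign_ion_sites(chain, ions)
            for (iid, sp, pos), rec in zip(ions, recs):
                cut = bd[sp]
                r = {}
                for g, labels in (("A", ALPHA_OXYGENS), ("B", BETA_OXYGENS),
                                  ("G", GAMMA_OXYGENS)):
                    r[g] = min(np.linalg.norm(np.asarray(pos) - coords[l])
                               for l in labels if l in coords)
                bg = r["B"] <= cut and r["G"] <= cut
                ag = r["A"] <= cut and r["G"] <= cut
                if bg and ag:
                    expect = (Site.BG if (r["B"] + r["G"]) <= (r["A"] + r["G"])
                              else Site.AG)
                elif bg:
                    expect = Site.BG
                elif ag:
                    expect = Site.AG
                elif r["G"] <= cut and r["A"] > cut and r["B"] > cut:
                    expect = Site.G
                else:
                    expect = Site.UNBOUND
                assert rec.site is expect
                assert rec.r_a == pytest.approx(r["A"], abs=1e-9)
                assert rec.r_ag == pytest.approx((r["A"] + r["G"]) / 2, abs=1e-9)

    def test_vectorised_matches_per_frame(self, k_trajectory):
        traj, _, _ = k_trajectory
        frames = assign_ion_sites_frames(traj)
        for i in (0, 100, 500, 1999):
            chain = traj.frame_chain(i)
            singles = assign_ion_sites(
                chain, [(ion.ion_id, ion.species, ion.positions[i])
                        for ion in traj.ions])
            for a, b in zip(singles, frames[i]):
                assert a.site is b.site
                assert a.r_ag == pytest.approx(b.r_ag, abs=1e-9)

    def test_mutually_exclusive_per_ion(self, k_trajectory):
        traj, _, _ = k_trajectory
        frames = assign_ion_sites_frames(traj)
        for frame in frames[::50]:
            assert len(frame) == len(traj.ions)
            per_site = sum(1 for r in frame if r.site is not Site.UNBOUND)
            assert per_site <= len(traj.ions)


def r_ok(rec):
    return rec.r_b <= 3.2 and rec.r_g <= 3.2


class TestOccupancy:
    def test_indicator_mean(self):
        occ = occupancy([1, 1, 0, 1])
        assert occ.occupancy == pytest.approx(0.75)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            occupancy([])

    def test_all_unbound_zero(self):
        assert occupancy([0, 0, 0]).occupancy == 0.0

    def test_generator_fraction_recovered(self, k_trajectory):
        traj, truth, _ = k_trajectory
        records = assign_ion_sites_frames(traj)
        occ_bg = occupancy(records, site=Site.BG, traj=traj)
        assert occ_bg.occupancy == pytest.approx(
            truth["ions"][0]["configured_fraction"], abs=0.02)
        # ~0.75-1.5 cations near the chain on time average
        assert 0.5 < occ_bg.chain_occupancy <= len(traj.ions)


class TestSegmentation:
    def test_three_runs(self):
        segs = segment_trajectory(list("AAABBBAAA"), min_dwell=2)
        assert [(s.start, s.end, s.state) for s in segs] == \
            [(0, 3, "A"), (3, 6, "B"), (6, 9, "A")]

    def test_flicker_absorbed(self):
        segs = segment_trajectory(list("AAABAAA"), min_dwell=2)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 7)

    def test_tie_merges_into_preceding(self):
        segs = segment_trajectory(list("AABCC"), min_dwell=2)
        assert [(s.start, s.end, s.state) for s in segs] == \
            [(0, 3, "A"), (3, 5, "C")]

    def test_partition_property(self, rng):
        for _ in range(30):
            states = rng.choice(list("ABC"), size=rng.integers(1, 60)).tolist()
            segs = segment_trajectory(states, min_dwell=3)
            assert segs[0].start == 0
            assert segs[-1].end == len(states)
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start
                assert a.state != b.state

    def test_generator_boundaries_recovered(self, k_trajectory):
        traj, truth, _ = k_trajectory
        states = classify_frames(traj)
        segs = segment_trajectory(states, min_dwell=10)
        boundaries = sorted(s.start for s in segs[1:])
        for want in truth["switch_frames"]:
            assert min(abs(b - want) for b in boundaries) <= 1


class TestSeriesOps:
    def test_constant_unchanged(self):
        x = np.full(20, 3.3)
        assert np.allclose(moving_average(x, 5), x)

    def test_window_one_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(moving_average(x, 1), x)

    def test_spike_smoothing_matches_naive(self):
        x = np.zeros(21)
        x[10] = 7.0
        got = moving_average(x, 5)
        naive = np.array([
            np.mean(x[max(i - 2, 0):min(i + 3, 21)]) for i in range(21)
        ])
        assert np.allclose(got, naive)
        assert got[10] == pytest.approx(7.0 / 5.0)

    def test_pair_distance_trivial(self):
        traj = Trajectory(
            chain={"PA": np.zeros((5, 3)), "PG": np.zeros((5, 3))},
            dt_ps=1.0)
        res = track_pair_distance(traj, "PA", "PG")
        assert res.mean == 0.0 and res.hbond_fraction == 1.0

    def test_pair_distance_constant(self):
        pg = np.zeros((8, 3))
        pg[:, 0] = 4.7
        traj = Trajectory(chain={"PA": np.zeros((8, 3)), "PG": pg}, dt_ps=1.0)
        res = track_pair_distance(traj, "PA", "PG")
        assert res.mean == pytest.approx(4.7)
        assert res.sd == 0.0
        assert res.hbond_fraction == 0.0  # 4.7 > default 3.5 cutoff

    def test_pair_distance_sampling(self, rng):
        n = 4000
        d = rng.normal(3.0, 0.2, n)
        b = np.zeros((n, 3))
        b[:, 0] = d
        traj = Trajectory(chain={"PA": np.zeros((n, 3))}, dt_ps=1.0,
                          extra={"N_ASN226": b})
        res = track_pair_distance(traj, "PA", "N_ASN226")
        assert res.mean == pytest.approx(3.0, abs=3 * 0.2 / np.sqrt(n))

    def test_pair_distance_missing_label(self, k_trajectory):
        traj, _, _ = k_trajectory
        with pytest.raises(KeyError, match="NOPE"):
            track_pair_distance(traj, "PA", "NOPE")


class TestTrajectoryIO:
    def test_multimodel_pdb_round_trip(self, k_trajectory, tmp_path):
        traj, _, _ = k_trajectory
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = load_trajectory(path, dt_ps=traj.dt_ps)
        assert back.n_frames == traj.n_frames
        assert back.mg is not None
        assert len(back.ions) == len(traj.ions)
        s1 = compute_descriptor_series(traj)
        s2 = compute_descriptor_series(back)
        # PDB coordinates carry 3 decimals
        assert np.max(np.abs(s1["d_pa_pg"] - s2["d_pa_pg"])) < 5e-3
        assert np.max(np.abs(s1["theta_bridge"] - s2["theta_bridge"])) < 0.2

    def test_missing_dt_requires_argument(self, k_trajectory, tmp_path):
        traj, _, _ = k_trajectory
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        loaded = load_trajectory(path, dt_ps=2.0)
        assert loaded.dt_ps == 2.0
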