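"""Cross-link detection, lifetimes and aggregate statistics."""

from itertools import product

import numpy as np
import pytest

from pectoporo.quench import DomainError
from pectoporo.synth import LinkSchedule, gen_trajectory
from pectoporo.xlink import (
    ROLE_CALCIUM,
    ROLE_CARBON_METHYL,
    ROLE_HYDROGEN_CARBOXYL,
    ROLE_OXYGEN_CARBONYL,
    ROLE_OXYGEN_CARBOXYL,
    ROLE_OXYGEN_CARBOXYLATE,
    ChainTopology,
    Contact,
    Frame,
    Trajectory,
    detect_all,
    detect_ca_bridges,
    detect_hb_ch3_o,
    detect_hb_cooh,
    largest_aggregate,
    link_timeseries,
    mean_counts,
    min_image_distance,
    per_frame_contacts,
    summarize,
)


def brute_force_distance(p1, p2, box):
    """Exhaustive 27-image search — the minimum-image oracle."""
    best = np.inf
    for sx, sy, sz in product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * np.asarray(box)
        best = min(best, float(np.linalg.norm(
            np.asarray(p2) + shift - np.asarray(p1))))
    return best


def test_min_image_basics():
    box = [10.0, 10.0, 10.0]
    assert min_image_distance([1, 1, 1], [1, 1, 1], box) == 0.0
    assert min_image_distance([0.1, 0, 0], [9.9, 0, 0], box) == pytest.approx(0.2)
    with pytest.raises(DomainError):
        min_image_distance([0, 0, 0], [1, 1, 1], [0, 1, 1])


def test_min_image_matches_image_enumeration():
    rng = np.random.default_rng(17)
    box = np.array([4.0, 5.5, 3.2])
    for _ in range(100):
        p1, p2 = rng.uniform(0, box, (2, 3))
        assert min_image_distance(p1, p2, box) == pytest.approx(
            brute_force_distance(p1, p2, box), abs=1e-12)


def _toy_topology():
    """Two chains, 3 atoms each (carboxylate O, methyl C, carboxyl H/O
    stand-ins), plus one ion."""
    roles = [ROLE_OXYGEN_CARBOXYLATE, ROLE_CARBON_METHYL, ROLE_HYDROGEN_CARBOXYL,
             ROLE_OXYGEN_CARBOXYLATE, ROLE_OXYGEN_CARBONYL, ROLE_OXYGEN_CARBOXYL,
             ROLE_CALCIUM]
    chain = np.array([0, 0, 0, 1, 1, 1, -1])
    residue = np.array([0, 1, 2, 0, 1, 2, -1])
    return ChainTopology(2, 3, "DMP", chain, residue, roles, np.array([6]))


def test_ca_bridge_geometry():
    topo = _toy_topology()
    box = np.array([10.0, 10.0, 10.0])
    coords = np.full((7, 3), 5.0)
    coords[0] = [4.75, 5.0, 5.0]   # O on chain 0, 0.25 nm from the ion
    coords[3] = [5.25, 5.0, 5.0]   # O on chain 1, 0.25 nm on the other side
    coords[1] = [1.0, 1.0, 1.0]
    coords[2] = [1.5, 1.0, 1.0]
    coords[4] = [9.0, 1.0, 1.0]
    coords[5] = [9.5, 1.0, 1.0]
    coords[6] = [5.0, 5.0, 5.0]    # the ion, equidistant
    bridges = detect_ca_bridges(Frame(coords, box), topo)
    assert len(bridges) == 1
    assert bridges[0].chain_pair == (0, 1)
    # beyond cutoff: no bridge
    coords2 = coords.copy()
    coords2[6] = [5.0, 5.0, 6.0]   # 0.5+ nm from everything
    assert detect_ca_bridges(Frame(coords2, box), topo) == []


def test_ca_bridge_intra_chain_excluded():
    roles = [ROLE_OXYGEN_CARBOXYLATE, ROLE_OXYGEN_CARBOXYLATE, ROLE_CALCIUM]
    topo = ChainTopology(1, 1, "D", np.array([0, 0, -1]),
                         np.array([0, 0, -1]), roles, np.array([2]))
    coords = np.array([[4.8, 5, 5], [5.2, 5, 5], [5.0, 5, 5]])
    assert detect_ca_bridges(Frame(coords, [10, 10, 10]), topo) == []


def test_ca_bridge_strict_zipper_mode():
    roles = [ROLE_OXYGEN_CARBOXYLATE] * 4 + [ROLE_CALCIUM]
    topo = ChainTopology(2, 1, "D", np.array([0, 0, 1, 1, -1]),
                         np.array([0, 0, 0, 0, -1]), roles, np.array([4]))
    coords = np.array([[4.8, 5, 5], [4.8, 5.1, 5], [5.2, 5, 5],
                       [3.0, 3, 3], [5.0, 5, 5]])
    frame = Frame(coords, [10, 10, 10])
    assert len(detect_ca_bridges(frame, topo)) == 1
    # strict zipper requires two oxygens on each chain within the cutoff
    assert detect_ca_bridges(frame, topo, min_oxygens_per_chain=2) == []


def test_no_ions_gives_no_bridges():
    topo = ChainTopology.from_pattern(2, 4, "DDDD", n_ca=0)
    coords = np.zeros((topo.n_atoms, 3))
    coords[:, 0] = np.arange(topo.n_atoms) * 0.5
    assert detect_ca_bridges(Frame(coords, [50, 50, 50]), topo) == []


def test_hb_detectors_cutoffs():
    topo = _toy_topology()
    box = np.array([10.0, 10.0, 10.0])
    coords = np.array([[1, 1, 1], [5.0, 5, 5], [3, 1, 1],
                       [9, 9, 9], [5.35, 5, 5], [7, 7, 7], [2, 9, 2]],
                      dtype=float)
    assert len(detect_hb_ch3_o(Frame(coords, box), topo)) == 1  # 0.35 < 0.40
    coords[4] = [5.45, 5, 5]
    assert detect_hb_ch3_o(Frame(coords, box), topo) == []      # 0.45 > 0.40
    # carboxyl H (chain 0) to carboxyl O (chain 1)
    coords[2] = [5.0, 5, 5]
    coords[5] = [5.18, 5, 5]
    assert len(detect_hb_cooh(Frame(coords, box), topo)) == 1   # 0.18 < 0.25
    coords[5] = [5.30, 5, 5]
    assert detect_hb_cooh(Frame(coords, box), topo) == []
    # an all-M topology has no donors: empty result, not an error
    allm = ChainTopology.from_pattern(2, 4, "MMMM")
    c = np.zeros((allm.n_atoms, 3))
    c[:, 0] = np.arange(allm.n_atoms) * 0.5
    assert detect_hb_cooh(Frame(c, [50, 50, 50]), allm) == []


def test_hb_cooh_optional_angle_criterion():
    # donor O, its H, and an acceptor O on another chain: the O-H...O angle
    # is ~180 deg in-line and ~0 deg when the acceptor sits behind the donor
    roles = [ROLE_OXYGEN_CARBOXYL, ROLE_HYDROGEN_CARBOXYL, ROLE_OXYGEN_CARBOXYL]
    topo = ChainTopology(2, 1, "P", np.array([0, 0, 1]), np.array([0, 0, 0]),
                         roles, np.array([], dtype=int))
    box = [10.0, 10.0, 10.0]
    inline = np.array([[4.9, 5, 5], [5.0, 5, 5], [5.2, 5, 5]])
    assert len(detect_hb_cooh(Frame(inline, box), topo,
                              angle_min_deg=120.0)) == 1
    behind = np.array([[5.1, 5, 5], [5.0, 5, 5], [5.2, 5, 5]])
    assert detect_hb_cooh(Frame(behind, box), topo, angle_min_deg=120.0) == []
    # distance-only default keeps both geometries
    assert len(detect_hb_cooh(Frame(behind, box), topo)) == 1


def _random_system(rng, n_atoms=50, n_chains=4, box=(3.0, 3.0, 3.0)):
    roles = rng.choice(
        [ROLE_OXYGEN_CARBOXYLATE, ROLE_OXYGEN_CARBOXYL, ROLE_HYDROGEN_CARBOXYL,
         ROLE_CARBON_METHYL, ROLE_OXYGEN_CARBONYL, ROLE_CALCIUM],
        size=n_atoms).tolist()
    chain = rng.integers(0, n_chains, n_atoms)
    ions = np.array([i for i, r in enumerate(roles) if r == ROLE_CALCIUM])
    chain[ions] = -1
    topo = ChainTopology(n_chains, 1, "D", chain, np.zeros(n_atoms, dtype=int),
                         roles, ions)
    coords = rng.uniform(0, box, (n_atoms, 3))
    return Frame(coords, np.array(box)), topo


def _brute_force_contacts(frame, topo, link_type, cutoff):
    """Triple-loop detector over all atom pairs with the 27-image oracle."""
    out = set()
    if link_type == "CA_BRIDGE":
        oxy = [i for i, r in enumerate(topo.atom_role)
               if r == ROLE_OXYGEN_CARBOXYLATE]
        for ion in topo.ca_ions:
            chains = set()
            for o in oxy:
                if brute_force_distance(frame.coordinates[ion],
                                        frame.coordinates[o],
                                        frame.box) <= cutoff:
                    chains.add(int(topo.atom_chain[o]))
            for a in chains:
                for b in chains:
                    if a < b:
                        out.add(Contact("CA_BRIDGE", (a, b), (int(ion),)))
        return out
    if link_type == "HB_CH3_O":
        donors = [i for i, r in enumerate(topo.atom_role)
                  if r == ROLE_CARBON_METHYL]
        acceptors = [i for i, r in enumerate(topo.atom_role)
                     if r == ROLE_OXYGEN_CARBONYL]
    else:
        donors = [i for i, r in enumerate(topo.atom_role)
                  if r == ROLE_HYDROGEN_CARBOXYL]
        acceptors = [i for i, r in enumerate(topo.atom_role)
                     if r in (ROLE_OXYGEN_CARBOXYL, ROLE_OXYGEN_CARBOXYLATE)]
    for d in donors:
        for a in acceptors:
            if topo.atom_chain[d] == topo.atom_chain[a]:
                continue
            if brute_force_distance(frame.coordinates[d],
                                    frame.coordinates[a],
                                    frame.box) <= cutoff:
                out.add(Contact(link_type,
                                tuple(sorted((int(topo.atom_chain[d]),
                                              int(topo.atom_chain[a])))),
                                (d, a)))
    return out


@pytest.mark.parametrize("link_type,detector,cutoff", [
    ("CA_BRIDGE", detect_ca_bridges, 0.30),
    ("HB_CH3_O", detect_hb_ch3_o, 0.40),
    ("HB_COOH", detect_hb_cooh, 0.25),
])
def test_detectors_match_brute_force_on_random_frames(link_type, detector,
                                                      cutoff):
    rng = np.random.default_rng(23)
    for _ in range(30):
        frame, topo = _random_system(rng)
        got = set(detector(frame, topo))
        want = _brute_force_contacts(frame, topo, link_type, cutoff)
        assert got == want


def test_detection_invariant_under_translation_and_box_shift():
    rng = np.random.default_rng(31)
    frame, topo = _random_system(rng)
    base = {lt: _brute_force_contacts(frame, topo, lt, c)
            for lt, c in [("CA_BRIDGE", 0.30), ("HB_CH3_O", 0.40),
                          ("HB_COOH", 0.25)]}
    for shift in (np.array([0.37, -1.2, 5.1]), frame.box * [1, -2, 3]):
        moved = Frame(frame.coordinates + shift, frame.box)
        assert set(detect_ca_bridges(moved, topo)) == base["CA_BRIDGE"]
        assert set(detect_hb_ch3_o(moved, topo)) == base["HB_CH3_O"]
        assert set(detect_hb_cooh(moved, topo)) == base["HB_COOH"]


def _static_trajectory(presence, topo_coords):
    """Trajectory in which a single planted contact is toggled per frame."""
    on, off = topo_coords
    frames = [Frame(on if p else off, [10.0, 10.0, 10.0], time=float(i))
              for i, p in enumerate(presence)]
    return Trajectory(frames, 1.0)


def _single_contact_system():
    roles = [ROLE_CARBON_METHYL, ROLE_OXYGEN_CARBONYL]
    topo = ChainTopology(2, 1, "M", np.array([0, 1]), np.array([0, 0]),
                         roles, np.array([], dtype=int))
    on = np.array([[5.0, 5, 5], [5.3, 5, 5]])
    off = np.array([[5.0, 5, 5], [7.0, 5, 5]])
    return topo, on, off


@pytest.mark.parametrize("presence,tol,expected_lifetimes", [
    ([1, 1, 1, 1], 0, [4]),
    ([1, 1, 0, 1], 0, [2, 1]),
    ([1, 1, 0, 1], 1, [4]),
    ([0, 0, 0, 0], 0, []),
])
def test_link_timeseries_gap_tolerance(presence, tol, expected_lifetimes):
    topo, on, off = _single_contact_system()
    traj = _static_trajectory(presence, (on, off))
    events = link_timeseries(traj, topo, detect_hb_ch3_o,
                             gap_tolerance_frames=tol)
    assert sorted(e.lifetime(1.0) for e in events) == sorted(expected_lifetimes)


def test_event_count_equals_rise_transitions_when_strict():
    rng = np.random.default_rng(41)
    topo, on, off = _single_contact_system()
    presence = rng.integers(0, 2, 60).tolist()
    traj = _static_trajectory(presence, (on, off))
    events = link_timeseries(traj, topo, detect_hb_ch3_o)
    rises = sum(1 for i, p in enumerate(presence)
                if p and (i == 0 or not presence[i - 1]))
    assert len(events) == rises
    # lifetimes can never exceed the trajectory duration
    assert sum(e.lifetime(1.0) for e in events) <= traj.duration


def test_mean_counts():
    topo, on, off = _single_contact_system()
    traj = _static_trajectory([1] * 20 + [0] * 20, (on, off))
    fc = per_frame_contacts(traj, topo, detect_hb_ch3_o)
    assert mean_counts(fc)["HB_CH3_O"] == pytest.approx(0.5)
    assert mean_counts([[]], 1)["CA_BRIDGE"] == 0.0


def _contacts(pairs):
    return [Contact("CA_BRIDGE", p, (0,)) for p in pairs]


def test_largest_aggregate():
    # no links: every chain is its own aggregate
    assert largest_aggregate([[]], 8) == 1.0
    # full ring joins all chains
    ring = _contacts([(i, (i + 1) % 8) for i in range(8)])
    assert largest_aggregate([ring], 8) == 8.0
    # alternating 5-cluster / 3-cluster: max is constant 5
    five = _contacts([(0, 1), (1, 2), (2, 3), (3, 4)])
    three = _contacts([(5, 6), (6, 7)])
    frames = [five + three, three] * 4
    assert largest_aggregate(frames, 8) == pytest.approx((5 + 3) / 2)
    assert largest_aggregate(frames, 8, mode="max") == 5.0
    # adding an edge never decreases the instantaneous largest component
    assert largest_aggregate([five], 8) <= largest_aggregate(
        [five + _contacts([(4, 5)])], 8)


def test_summarize_planted_schedule_exact():
    n = 8
    schedule = [LinkSchedule("CA_BRIDGE", c, (c + 1) % n, 0, 39, 0, 1)
                for c in range(n)]
    for jitter in (0.0, 0.02):
        traj, topo, _ = gen_trajectory("DDDDDDDD", schedule=schedule,
                                       jitter_sd=jitter, seed=13)
        s = summarize(traj, topo)
        assert s.mean_counts["CA_BRIDGE"] == pytest.approx(8.0)
        assert s.mean_lifetimes["CA_BRIDGE"] == pytest.approx(40.0)
        assert s.n_agg == pytest.approx(8.0)
        assert s.mean_counts["HB_CH3_O"] is None  # no M residues -> dash
        assert s.site_counts["CA_BRIDGE"] == 32   # 64 D residues / 2


def test_summarize_single_frame_lifetime():
    schedule = [LinkSchedule("CA_BRIDGE", 0, 1, 0, 0, 0, 1)]
    traj, topo, _ = gen_trajectory("DDDDDDDD", schedule=schedule,
                                   n_frames=1, frame_spacing=0.5, seed=1)
    s = summarize(traj, topo)
    assert s.mean_lifetimes["CA_BRIDGE"] == pytest.approx(0.5)


def test_site_counts_tile_patterns():
    # 4-letter code tiling a 40-unit chain: half of each state's residues
    topo = ChainTopology.from_pattern(8, 40, "ddpp")
    assert topo.site_count("CA_BRIDGE") == 80   # 160 D residues / 2
    assert topo.site_count("HB_COOH") == 80
    assert topo.site_count("HB_CH3_O") == 0
    assert topo.ca_ions.size == 80              # charge balance
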