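"""Cross-link detection and statistics for multi-chain homogalacturonan
(HG) trajectories.

Three inter-chain link types are tracked, one per carboxyl functionalisation
of the galacturonic-acid (GalA) monomer:

* ``CA_BRIDGE`` — a calcium bridge -COO⁻ ∥ Ca²⁺ ∥ -COO⁻: one Ca²⁺ ion within
  a cutoff of carboxylate oxygens on two *different* chains (zipper-type
  coordination; D residues).
* ``HB_CH3_O`` — hydrogen-bond-like contact between a methyl carbon and a
  carbonyl oxygen of methyl-esterified groups (M residues).
* ``HB_COOH`` — hydrogen bond from a carboxyl hydrogen (P residue) to a
  carboxyl/carboxylate oxygen on another chain.

Criteria are distance-only under the minimum-image convention (the
free-energy coordinates that motivate the cutoffs are themselves distances);
an optional donor–H···acceptor angle criterion is available for the hydrogen
bonds.  Per-system statistics mirror a cross-linking summary table: mean
instantaneous counts per type, mean event lifetimes, and the time-averaged
size of the largest cross-linked chain aggregate, N_agg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .quench import ConfigurationError, DomainError

LINK_TYPES = ("CA_BRIDGE", "HB_CH3_O", "HB_COOH")

# atom roles used by the detectors; BB is an inert backbone bead
ROLE_OXYGEN_CARBOXYLATE = "O_carboxylate"  # D residues (two per residue)
ROLE_OXYGEN_CARBOXYL = "O_carboxyl"        # P residues (acceptor)
ROLE_HYDROGEN_CARBOXYL = "H_carboxyl"      # P residues (donor)
ROLE_CARBON_METHYL = "C_methyl"            # M residues
ROLE_OXYGEN_CARBONYL = "O_carbonyl"        # M residues
ROLE_BACKBONE = "BB"
ROLE_CALCIUM = "CA"

_RESIDUE_ROLES = {
    "D": (ROLE_OXYGEN_CARBOXYLATE, ROLE_OXYGEN_CARBOXYLATE),
    "P": (ROLE_OXYGEN_CARBOXYL, ROLE_HYDROGEN_CARBOXYL),
    "M": (ROLE_CARBON_METHYL, ROLE_OXYGEN_CARBONYL),
}


@dataclass
class ChainTopology:
    """Atom-to-role/chain mapping for an n-chain HG system plus Ca²⁺ ions.

    ``pattern`` is the per-residue functionalisation string over {P, D, M}
    for one chain (all chains share it); patterns shorter than
    ``residues_per_chain`` tile by repetition, so a 4-letter code describes a
    40-unit chain.  Lowercase letters are accepted and upcased.
    """

    n_chains: int
    residues_per_chain: int
    pattern: str
    atom_chain: np.ndarray   # (n_atoms,) chain index, -1 for ions
    atom_residue: np.ndarray  # (n_atoms,) residue index within chain, -1 for ions
    atom_role: list[str]
    ca_ions: np.ndarray      # atom indices of Ca²⁺

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        if self.residues_per_chain % len(self.pattern) != 0:
            raise DomainError(
                "pattern length must equal or divide residues_per_chain"
            )
        self.atom_chain = np.asarray(self.atom_chain, dtype=int)
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        self.ca_ions = np.asarray(self.ca_ions, dtype=int)
        if len(self.atom_role) != self.atom_chain.size:
            raise DomainError("atom_role and atom_chain must have equal length")

    @property
    def full_pattern(self) -> str:
        """Pattern tiled to the full chain length."""
        return self.pattern * (self.residues_per_chain // len(self.pattern))

    @property
    def n_atoms(self) -> int:
        return self.atom_chain.size

    def atoms_with_role(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.atom_role) if r == role], dtype=int
        )

    def residue_count(self, state: str) -> int:
        """Total residues of functionalisation ``state`` across all chains."""
        return self.full_pattern.count(state.upper()) * self.n_chains

    def site_count(self, link_type: str) -> int:
        """Eligible-site tally reported next to each mean count.

        Half the number of residues of the link's functionalisation; for
        calcium bridges this equals the charge-balancing Ca²⁺ count.
        """
        state = {"CA_BRIDGE": "D", "HB_CH3_O": "M", "HB_COOH": "P"}[link_type]
        return self.residue_count(state) // 2

    @classmethod
    def from_pattern(
        cls,
        n_chains: int,
        residues_per_chain: int,
        pattern: str,
        n_ca: int | None = None,
    ) -> "ChainTopology":
        """Standard layout: per residue one backbone bead plus two functional
        atoms set by the pattern letter; ions appended last.

        ``n_ca`` defaults to half the total deprotonated (D) residue count,
        the charge-balancing number.
        """
        pattern = pattern.upper()
        if residues_per_chain % len(pattern) != 0:
            raise DomainError("pattern length must divide residues_per_chain")
        full = pattern * (residues_per_chain // len(pattern))
        if any(s not in _RESIDUE_ROLES for s in full):
            raise DomainError("pattern letters must be in {P, D, M}")
        chains, residues, roles = [], [], []
        for c in range(n_chains):
            for r, state in enumerate(full):
                for role in (ROLE_BACKBONE,) + _RESIDUE_ROLES[state]:
                    chains.append(c)
                    residues.append(r)
                    roles.append(role)
        if n_ca is None:
            n_ca = full.count("D") * n_chains // 2
        first_ion = len(chains)
        for _ in range(n_ca):
            chains.append(-1)
            residues.append(-1)
            roles.append(ROLE_CALCIUM)
        return cls(
            n_chains,
            residues_per_chain,
            pattern,
            np.array(chains),
            np.array(residues),
            roles,
            np.arange(first_ion, len(chains)),
        )


@dataclass
class Frame:
    """One trajectory frame: positions (nm) in an orthorhombic periodic box."""

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray          # (3,) box lengths, nm
    time: float = 0.0        # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise DomainError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise DomainError("box must be three positive lengths")


@dataclass
class Trajectory:
    frames: list[Frame]
    frame_spacing: float = 1.0  # ns

    def __post_init__(self) -> None:
        if self.frame_spacing <= 0:
            raise DomainError("frame_spacing must be positive")
        times = [f.time for f in self.frames]
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise DomainError("frame times must increase with constant spacing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_spacing


class Contact(NamedTuple):
    """Instantaneous inter-chain contact; ``atoms`` identifies the link.

    For a calcium bridge the identity is the ion (the coordinated oxygens may
    exchange without breaking the bridge); for hydrogen bonds it is the
    (donor/carbon, acceptor) atom pair.
    """

    link_type: str
    chain_pair: tuple[int, int]  # sorted, distinct
    atoms: tuple[int, ...]


@dataclass
class CrossLinkEvent:
    link_type: str
    chain_pair: tuple[int, int]
    atoms: tuple[int, ...]
    start_frame: int
    end_frame: int

    def lifetime(self, frame_spacing: float) -> float:
        return (self.end_frame - self.start_frame + 1) * frame_spacing


@dataclass
class LinkSummary:
    """One summary-table row: per-type mean counts, site tallies, mean
    lifetimes (ns; None when the type has no eligible sites) and N_agg."""

    label: str
    mean_counts: dict[str, float | None]
    site_counts: dict[str, int]
    mean_lifetimes: dict[str, float | None]
    n_agg: float
    n_chains: int


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def min_image_displacement(p1, p2, box) -> np.ndarray:
    """Displacement p2 − p1 mapped to the nearest periodic image."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise DomainError("box lengths must be positive")
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p1, p2, box) -> float:
    """Euclidean distance under the minimum-image convention."""
    return float(np.linalg.norm(min_image_displacement(p1, p2, box)))


def _pairwise_min_image(coords_a: np.ndarray, coords_b: np.ndarray, box) -> np.ndarray:
    """(n_a, n_b) distance matrix under minimum image (vectorised)."""
    box = np.asarray(box, dtype=float)
    d = coords_a[:, None, :] - coords_b[None, :, :]
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


# --------------------------------------------------------------------------
# Detectors (instantaneous, one frame)
# --------------------------------------------------------------------------

def detect_ca_bridges(
    frame: Frame,
    topology: ChainTopology,
    cutoff_nm: float = 0.30,
    min_oxygens_per_chain: int = 1,
) -> list[Contact]:
    """Calcium bridges: one ion coordinating carboxylate oxygens on two
    distinct chains.

    ``min_oxygens_per_chain=2`` gives the strict zipper criterion in which
    the ion engages both oxygens of each carboxylate.
    Returns one contact per (ion, chain pair); no ions → empty.
    """
    ions = topology.ca_ions
    oxy = topology.atoms_with_role(ROLE_OXYGEN_CARBOXYLATE)
    if ions.size == 0 or oxy.size == 0:
        return []
    dmat = _pairwise_min_image(
        frame.coordinates[ions], frame.coordinates[oxy], frame.box
    )
    oxy_chain = topology.atom_chain[oxy]
    contacts = []
    for k, ion in enumerate(ions):
        near = dmat[k] <= cutoff_nm
        chains, per_chain = np.unique(oxy_chain[near], return_counts=True)
        bound = chains[per_chain >= min_oxygens_per_chain]
        for a_i in range(bound.size):
            for b_i in range(a_i + 1, bound.size):
                contacts.append(
                    Contact("CA_BRIDGE",
                            (int(bound[a_i]), int(bound[b_i])), (int(ion),))
                )
    return contacts


def _detect_pair_contacts(
    frame: Frame,
    topology: ChainTopology,
    link_type: str,
    role_a: str,
    role_b: str,
    cutoff_nm: float,
    acceptors_extra: str | None = None,
) -> list[Contact]:
    atoms_a = topology.atoms_with_role(role_a)
    atoms_b = topology.atoms_with_role(role_b)
    if acceptors_extra is not None:
        atoms_b = np.concatenate([atoms_b, topology.atoms_with_role(acceptors_extra)])
    if atoms_a.size == 0 or atoms_b.size == 0:
        return []
    dmat = _pairwise_min_image(
        frame.coordinates[atoms_a], frame.coordinates[atoms_b], frame.box
    )
    ia, ib = np.nonzero(dmat <= cutoff_nm)
    contacts = []
    for i, j in zip(ia, ib):
        ca = int(topology.atom_chain[atoms_a[i]])
        cb = int(topology.atom_chain[atoms_b[j]])
        if ca == cb:
            continue  # intra-chain contacts are not cross-links
        contacts.append(
            Contact(link_type, tuple(sorted((ca, cb))),
                    (int(atoms_a[i]), int(atoms_b[j])))
        )
    return contacts


def detect_hb_ch3_o(
    frame: Frame, topology: ChainTopology, cutoff_nm: float = 0.40
) -> list[Contact]:
    """Methyl-carbon ↔ carbonyl-oxygen contacts between distinct chains."""
    return _detect_pair_contacts(
        frame, topology, "HB_CH3_O", ROLE_CARBON_METHYL, ROLE_OXYGEN_CARBONYL,
        cutoff_nm,
    )


def detect_hb_cooh(
    frame: Frame,
    topology: ChainTopology,
    cutoff_nm: float = 0.25,
    angle_min_deg: float | None = None,
) -> list[Contact]:
    """Carboxyl-hydrogen ↔ carboxyl/carboxylate-oxygen contacts between
    distinct chains (donor on P residues; acceptors on P or D residues).

    The criterion is distance-only by default.  ``angle_min_deg`` adds an
    optional donor-H···acceptor angle requirement (e.g. 120°), using the
    donor's own carboxyl oxygen (same chain and residue as the hydrogen);
    hydrogens without a resolvable donor oxygen fall back to distance-only.
    """
    contacts = _detect_pair_contacts(
        frame, topology, "HB_COOH", ROLE_HYDROGEN_CARBOXYL, ROLE_OXYGEN_CARBOXYL,
        cutoff_nm, acceptors_extra=ROLE_OXYGEN_CARBOXYLATE,
    )
    if angle_min_deg is None:
        return contacts
    donor_oxygen: dict[int, int] = {}
    for i, role in enumerate(topology.atom_role):
        if role == ROLE_OXYGEN_CARBOXYL:
            key = (int(topology.atom_chain[i]), int(topology.atom_residue[i]))
            donor_oxygen.setdefault(key, i)
    kept = []
    for c in contacts:
        h, acc = c.atoms
        d = donor_oxygen.get(
            (int(topology.atom_chain[h]), int(topology.atom_residue[h])))
        if d is None:
            kept.append(c)
            continue
        v1 = min_image_displacement(frame.coordinates[h],
                                    frame.coordinates[d], frame.box)
        v2 = min_image_displacement(frame.coordinates[h],
                                    frame.coordinates[acc], frame.box)
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) >= angle_min_deg:
            kept.append(c)
    return kept


_DETECTORS: dict[str, Callable[..., list[Contact]]] = {
    "CA_BRIDGE": detect_ca_bridges,
    "HB_CH3_O": detect_hb_ch3_o,
    "HB_COOH": detect_hb_cooh,
}


def detect_all(
    frame: Frame,
    topology: ChainTopology,
    cutoffs: dict[str, float] | None = None,
) -> list[Contact]:
    """Run all three detectors on one frame with per-type cutoffs."""
    cutoffs = cutoffs or {}
    out: list[Contact] = []
    for link_type, det in _DETECTORS.items():
        kwargs = {}
        if link_type in cutoffs:
            kwargs["cutoff_nm"] = cutoffs[link_type]
        out.extend(det(frame, topology, **kwargs))
    return out


# --------------------------------------------------------------------------
# Time resolution and statistics
# --------------------------------------------------------------------------

def link_timeseries(
    trajectory: Trajectory,
    topology: ChainTopology,
    detector: Callable[[Frame, ChainTopology], list[Contact]] = detect_all,
    gap_tolerance_frames: int = 0,
) -> list[CrossLinkEvent]:
    """Resolve per-frame contacts into events with start/end frames.

    An event is a maximal run of frames in which the same contact (identical
    link type, chain pair and identifying atoms) is present, allowing
    interruptions of at most ``gap_tolerance_frames`` frames.
    """
    if gap_tolerance_frames < 0:
        raise DomainError("gap tolerance must be non-negative")
    presence: dict[Contact, list[int]] = {}
    for fi, frame in enumerate(trajectory.frames):
        for contact in set(detector(frame, topology)):
            presence.setdefault(contact, []).append(fi)
    events = []
    for contact, frames_on in presence.items():
        start = prev = frames_on[0]
        for fi in frames_on[1:]:
            if fi - prev - 1 > gap_tolerance_frames:
                events.append(CrossLinkEvent(
                    contact.link_type, contact.chain_pair, contact.atoms,
                    start, prev))
                start = fi
            prev = fi
        events.append(CrossLinkEvent(
            contact.link_type, contact.chain_pair, contact.atoms, start, prev))
    events.sort(key=lambda e: (e.start_frame, e.link_type, e.chain_pair, e.atoms))
    return events


def per_frame_contacts(
    trajectory: Trajectory,
    topology: ChainTopology,
    detector: Callable[[Frame, ChainTopology], list[Contact]] = detect_all,
) -> list[list[Contact]]:
    return [list(set(detector(f, topology))) for f in trajectory.frames]


def mean_counts(
    frames_contacts: Sequence[Sequence[Contact]],
    n_frames: int | None = None,
) -> dict[str, float]:
    """Mean over frames of the instantaneous distinct-contact count per type."""
    if n_frames is None:
        n_frames = len(frames_contacts)
    if n_frames < 1:
        raise DomainError("need at least one frame")
    totals = dict.fromkeys(LINK_TYPES, 0)
    for contacts in frames_contacts:
        for c in set(contacts):
            totals[c.link_type] += 1
    return {lt: totals[lt] / n_frames for lt in LINK_TYPES}


def largest_aggregate(
    frames_contacts: Sequence[Sequence[Contact]],
    n_chains: int,
    mode: str = "mean",
) -> float:
    """Size of the largest cross-linked chain aggregate, N_agg.

    Per frame, chains are graph nodes and any active cross-link an edge
    (multiple links between a pair collapse to one edge); the frame value is
    the largest connected component.  ``mode="mean"`` (default) averages over
    frames — hence fractional values; ``mode="max"`` takes the trajectory
    maximum.  With no links every chain is its own aggregate: N_agg = 1.
    """
    if mode not in ("mean", "max"):
        raise ConfigurationError(f"unknown N_agg mode {mode!r}")
    sizes = []
    for contacts in frames_contacts:
        g = nx.Graph()
        g.add_nodes_from(range(n_chains))
        g.add_edges_from(c.chain_pair for c in contacts)
        sizes.append(max(len(cc) for cc in nx.connected_components(g)))
    if not sizes:
        raise DomainError("need at least one frame")
    return float(np.mean(sizes)) if mode == "mean" else float(max(sizes))


def mean_lifetimes(
    events: Sequence[CrossLinkEvent],
    frame_spacing: float,
) -> dict[str, float | None]:
    """Event-averaged lifetime (ns) per link type; None where no events."""
    out: dict[str, float | None] = {}
    for lt in LINK_TYPES:
        lts = [e.lifetime(frame_spacing) for e in events if e.link_type == lt]
        out[lt] = float(np.mean(lts)) if lts else None
    return out


def summarize(
    trajectory: Trajectory,
    topology: ChainTopology,
    cutoffs: dict[str, float] | None = None,
    gap_tolerance_frames: int = 0,
    n_agg_mode: str = "mean",
    label: str = "",
) -> LinkSummary:
    """Full per-system cross-linking statistics (one summary-table row).

    Link types with no eligible sites in the topology report None (rendered
    as an em-dash in tabular output).
    """
    detector = lambda f, t: detect_all(f, t, cutoffs)  # noqa: E731
    frames_contacts = per_frame_contacts(trajectory, topology, detector)
    events = link_timeseries(trajectory, topology, detector, gap_tolerance_frames)
    counts = mean_counts(frames_contacts, trajectory.n_frames)
    lifetimes = mean_lifetimes(events, trajectory.frame_spacing)
    available = {
        "CA_BRIDGE": topology.residue_count("D") > 0 and topology.ca_ions.size > 0,
        "HB_CH3_O": topology.residue_count("M") > 0,
        "HB_COOH": topology.residue_count("P") > 0,
    }
    return LinkSummary(
        label=label or topology.pattern,
        mean_counts={lt: (counts[lt] if available[lt] else None)
                     for lt in LINK_TYPES},
        site_counts={lt: topology.site_count(lt) for lt in LINK_TYPES},
        mean_lifetimes={lt: (lifetimes[lt] if available[lt] else None)
                        for lt in LINK_TYPES},
        n_agg=largest_aggregate(frames_contacts, topology.n_chains, n_agg_mode),
        n_chains=topology.n_chains,
    )
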