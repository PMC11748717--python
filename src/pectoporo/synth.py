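"""Seedable synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study designs the analysis stages consume:

* fluorescence-quenching series — 6 time points at 3-min intervals over
  0–15 min, ~40 replicate regions of interest per genotype, additive
  Gaussian noise on F/F0;
* calibrated pore micrographs — dark elliptical pores on a light background
  inside a 750 nm × 500 nm region, in-range areas spanning 5–300 nm²;
* multi-chain bead trajectories — eight functionalised chains plus Ca²⁺
  ions, with cross-link events planted on an explicit schedule.

Every generator is a deterministic function of its arguments and the seed,
and returns the planted ground truth alongside the data so recovery can be
scored without external references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian as gaussian_blur

from .pores import CalibratedImage, PoreRecord
from .quench import (
    DomainError,
    FluorescenceSeries,
    QuencherBath,
    SternVolmerParams,
    forward_decay,
)
from .xlink import (
    LINK_TYPES,
    ROLE_CALCIUM,
    ROLE_CARBON_METHYL,
    ROLE_HYDROGEN_CARBOXYL,
    ROLE_OXYGEN_CARBONYL,
    ROLE_OXYGEN_CARBOXYL,
    ROLE_OXYGEN_CARBOXYLATE,
    ChainTopology,
    Frame,
    Trajectory,
)

DEFAULT_TIMES_MIN = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)

#: Default replicate counts per genotype (reference, mutant): the ROI tallies
#: of the emulated experiment.
DEFAULT_REPLICATES = (39, 42)

#: Default reference-genotype characteristic time, s.  Chosen so the 15-min
#: observation window spans about three characteristic times.
DEFAULT_T_REF = 300.0


class GenerationError(RuntimeError):
    """The requested synthetic scene could not be constructed."""


# --------------------------------------------------------------------------
# Fluorescence
# --------------------------------------------------------------------------

def gen_fluorescence(
    K: float,
    T: float,
    q_b: float,
    times_min=DEFAULT_TIMES_MIN,
    noise_sd: float = 0.02,
    n_replicates: int = 40,
    seed: int = 0,
    label: str = "sample",
    floor: float = 1e-6,
) -> tuple[list[FluorescenceSeries], dict]:
    """Replicate F/F0 decay series with additive Gaussian noise.

    Noise is truncated below at ``floor`` so intensities stay positive.
    Returns (replicates, ground_truth).
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times_s = np.asarray(times_min, dtype=float) * 60.0
    clean = forward_decay(times_s, SternVolmerParams(K), T, QuencherBath(q_b))
    reps = []
    for r in range(n_replicates):
        noisy = clean.intensities + rng.normal(0.0, noise_sd, times_s.size) \
            if noise_sd > 0 else clean.intensities.copy()
        reps.append(FluorescenceSeries(
            times_s.copy(), np.maximum(noisy, floor),
            label=label, replicate_id=f"{label}_roi{r:03d}",
        ))
    truth = {"K": K, "T": T, "q_b": q_b, "noise_sd": noise_sd,
             "n_replicates": n_replicates, "times_min": list(times_min),
             "label": label, "seed": seed}
    return reps, truth


def gen_two_genotypes(
    phi_ratio: float,
    T_ref: float = DEFAULT_T_REF,
    K: float = 1e4,
    q_b: float = 0.5e-3,
    noise_sd: float = 0.02,
    n_replicates=DEFAULT_REPLICATES,
    times_min=DEFAULT_TIMES_MIN,
    seed: int = 0,
    labels: tuple[str, str] = ("Col0", "sfr8"),
) -> tuple[dict[str, list[FluorescenceSeries]], dict]:
    """Two-genotype design with a planted porosity ratio (alt/ref).

    The alternative genotype's characteristic time follows from inverting
    the two-thirds law: ``T_alt = T_ref * phi_ratio**(-3/2)`` — a more
    porous wall fills the membrane faster.
    """
    if phi_ratio <= 0:
        raise DomainError("phi_ratio must be positive")
    T_alt = T_ref * phi_ratio ** -1.5
    n_ref, n_alt = (n_replicates, n_replicates) \
        if np.isscalar(n_replicates) else n_replicates
    ref, truth_ref = gen_fluorescence(
        K, T_ref, q_b, times_min, noise_sd, n_ref, seed, labels[0])
    alt, truth_alt = gen_fluorescence(
        K, T_alt, q_b, times_min, noise_sd, n_alt, seed + 1, labels[1])
    truth = {"phi_ratio": phi_ratio, "T_ref": T_ref, "T_alt": T_alt,
             "reference": labels[0], "genotypes": [truth_ref, truth_alt],
             "seed": seed}
    return {labels[0]: ref, labels[1]: alt}, truth


# --------------------------------------------------------------------------
# Pore micrographs
# --------------------------------------------------------------------------

def gen_pore_image(
    width_nm: float = 750.0,
    height_nm: float = 500.0,
    nm_per_px: float = 1.0,
    n_pores: int = 100,
    area_range_nm2: tuple[float, float] = (5.0, 300.0),
    area_sampler=None,
    pore_intensity: float = 0.2,
    background_intensity: float = 0.8,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    min_gap_px: int = 2,
    max_tries: int = 2000,
    seed: int = 0,
) -> tuple[CalibratedImage, list[PoreRecord]]:
    """Calibrated micrograph of dark elliptical pores on a light background.

    Pore target areas are drawn uniformly over ``area_range_nm2`` unless
    ``area_sampler(rng) -> nm²`` is given; aspect ratios are sampled in
    [1, 3].  Pores are placed by rejection sampling with a ``min_gap_px``
    exclusion margin so components remain separable; exceeding ``max_tries``
    consecutive rejections raises :class:`GenerationError` (ask for fewer or
    smaller pores).  Ground-truth records carry the exact rasterised pixel
    counts, so area recovery can be scored exactly on clean images.
    """
    rng = np.random.default_rng(seed)
    h_px = int(round(height_nm / nm_per_px))
    w_px = int(round(width_nm / nm_per_px))
    img = np.full((h_px, w_px), background_intensity, dtype=float)
    occupied = np.zeros((h_px, w_px), dtype=bool)
    truth: list[PoreRecord] = []
    for k in range(n_pores):
        placed = False
        for _ in range(max_tries):
            area_nm2 = (rng.uniform(*area_range_nm2) if area_sampler is None
                        else float(area_sampler(rng)))
            area_px = area_nm2 / nm_per_px ** 2
            aspect = rng.uniform(1.0, 3.0)
            a = np.sqrt(area_px * aspect / np.pi)  # semi-axes, px
            b = a / aspect
            theta = rng.uniform(0.0, np.pi)
            r0 = rng.uniform(a + 1, h_px - a - 1)
            c0 = rng.uniform(a + 1, w_px - a - 1)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(h_px, w_px),
                                  rotation=theta)
            if rr.size == 0:
                continue
            # reject if within the exclusion margin of an existing pore
            rlo = max(rr.min() - min_gap_px, 0)
            rhi = min(rr.max() + min_gap_px + 1, h_px)
            clo = max(cc.min() - min_gap_px, 0)
            chi = min(cc.max() + min_gap_px + 1, w_px)
            if occupied[rlo:rhi, clo:chi].any():
                continue
            img[rr, cc] = pore_intensity
            occupied[rr, cc] = True
            truth.append(PoreRecord(
                label_id=k + 1,
                pixel_count=int(rr.size),
                area_nm2=float(rr.size) * nm_per_px ** 2,
                centroid=(float(rr.mean()), float(cc.mean())),
            ))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place pore {k + 1}/{n_pores} after {max_tries} "
                "tries; request fewer or smaller pores"
            )
    if blur_sigma > 0:
        img = gaussian_blur(img, sigma=blur_sigma, preserve_range=True)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    image = CalibratedImage(np.clip(img, 0.0, 1.0), nm_per_px)
    return image, truth


def gen_two_pore_populations(
    crossover_nm2: float = 70.0,
    n_pores: int = 120,
    small_fraction_a: float = 0.8,
    small_fraction_b: float = 0.4,
    seed: int = 0,
    **image_kwargs,
) -> tuple[dict[str, tuple[CalibratedImage, list[PoreRecord]]], dict]:
    """Two "genotype" scenes mixing small (<crossover) and large (>crossover)
    pores in different proportions, so their size distributions cross at the
    planted boundary."""

    def sampler(small_frac):
        def draw(rng):
            if rng.uniform() < small_frac:
                return rng.uniform(5.0, crossover_nm2)
            return rng.uniform(crossover_nm2, 300.0)
        return draw

    scenes = {
        "A": gen_pore_image(n_pores=n_pores, area_sampler=sampler(small_fraction_a),
                            seed=seed, **image_kwargs),
        "B": gen_pore_image(n_pores=n_pores, area_sampler=sampler(small_fraction_b),
                            seed=seed + 1, **image_kwargs),
    }
    truth = {"crossover_nm2": crossover_nm2,
             "small_fractions": {"A": small_fraction_a, "B": small_fraction_b},
             "seed": seed}
    return scenes, truth


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkSchedule:
    """One planted cross-link: type, chain pair, frame span, and the residue
    on each chain providing the participating atoms."""

    link_type: str
    chain_a: int
    chain_b: int
    start_frame: int
    end_frame: int
    residue_a: int = 0
    residue_b: int = 0

    def __post_init__(self) -> None:
        if self.link_type not in LINK_TYPES:
            raise DomainError(f"unknown link type {self.link_type!r}")
        if self.chain_a == self.chain_b:
            raise DomainError("cross-links connect distinct chains")
        if self.start_frame > self.end_frame:
            raise DomainError("start_frame must not exceed end_frame")


# per-type (atom-role requirements, planted separation nm) — separations sit
# well inside the detection cutoffs so jitter cannot break a planted link
_EVENT_GEOMETRY = {
    "CA_BRIDGE": 0.12,   # ion-to-oxygen distance (cutoff 0.30)
    "HB_CH3_O": 0.24,    # carbon-to-oxygen (cutoff 0.40)
    "HB_COOH": 0.10,     # hydrogen-to-oxygen (cutoff 0.25)
}

_CHAIN_SPACING_NM = 2.0
_RESIDUE_SPACING_NM = 0.5


def _residue_atom(topology, chain, residue, role):
    idx = [
        i for i in range(topology.n_atoms)
        if topology.atom_chain[i] == chain
        and topology.atom_residue[i] == residue
        and topology.atom_role[i] == role
    ]
    if not idx:
        raise GenerationError(
            f"chain {chain} residue {residue} has no atom with role {role}"
        )
    return idx[0]


def gen_trajectory(
    pattern: str = "DDDDDDDD",
    n_chains: int = 8,
    residues_per_chain: int | None = None,
    schedule: list[LinkSchedule] | None = None,
    n_frames: int = 40,
    frame_spacing: float = 1.0,
    jitter_sd: float = 0.02,
    box=None,
    seed: int = 0,
) -> tuple[Trajectory, ChainTopology, list[LinkSchedule]]:
    """Bead trajectory of parallel chains with cross-links planted on a
    schedule.

    Chains run along x, spaced 2 nm apart in y — far beyond every detection
    cutoff — so the only inter-chain contacts are the scheduled ones.  During
    a scheduled event the participating atoms (and ion, for a calcium
    bridge) meet at a rendezvous point between the two chains at the
    planted separation; outside the event every atom sits at its home
    position.  Isotropic Gaussian jitter (default 0.02 nm, well under the
    cutoffs) models thermal motion.  Ca²⁺ ions are allocated to bridge
    events round-robin; an ion scheduled in two overlapping events is a
    :class:`GenerationError`.

    Returns (trajectory, topology, schedule) — the schedule is the ground
    truth.
    """
    if residues_per_chain is None:
        residues_per_chain = len(pattern)
    topo = ChainTopology.from_pattern(n_chains, residues_per_chain, pattern)
    schedule = list(schedule or [])
    rng = np.random.default_rng(seed)

    # home coordinates: backbone along x, functional atoms offset in z
    home = np.zeros((topo.n_atoms, 3))
    z_off = {"BB": 0.0, ROLE_OXYGEN_CARBOXYLATE: 0.15, ROLE_OXYGEN_CARBOXYL: 0.15,
             ROLE_HYDROGEN_CARBOXYL: 0.30, ROLE_CARBON_METHYL: 0.15,
             ROLE_OXYGEN_CARBONYL: 0.30}
    margin = 1.0
    for i in range(topo.n_atoms):
        c, r, role = topo.atom_chain[i], topo.atom_residue[i], topo.atom_role[i]
        if role == ROLE_CALCIUM:
            continue
        # pairs of same-role atoms in one residue get a small x split
        x_split = 0.05 * sum(
            1 for j in range(i)
            if topo.atom_chain[j] == c and topo.atom_residue[j] == r
            and topo.atom_role[j] == role
        )
        home[i] = (margin + r * _RESIDUE_SPACING_NM + x_split,
                   margin + c * _CHAIN_SPACING_NM,
                   margin + z_off.get(role, 0.0))
    for k, ion in enumerate(topo.ca_ions):
        home[ion] = (margin + k * 1.0,
                     margin + n_chains * _CHAIN_SPACING_NM + 1.5,
                     margin)
    if box is None:
        box = home.max(axis=0) + margin + np.array([1.0, 3.0, 3.0])
    box = np.asarray(box, dtype=float)

    # assign ions to bridge events; reject double-booking
    bridge_events = [e for e in schedule if e.link_type == "CA_BRIDGE"]
    if len(bridge_events) > topo.ca_ions.size:
        raise GenerationError("more bridge events than Ca²⁺ ions")
    ion_of = {id(e): topo.ca_ions[k] for k, e in enumerate(bridge_events)}

    # participating atoms per event, and conflict detection
    atoms_of: dict[int, tuple[int, ...]] = {}
    claimed: dict[int, LinkSchedule] = {}
    for e in schedule:
        if e.link_type == "CA_BRIDGE":
            a = _residue_atom(topo, e.chain_a, e.residue_a, ROLE_OXYGEN_CARBOXYLATE)
            b = _residue_atom(topo, e.chain_b, e.residue_b, ROLE_OXYGEN_CARBOXYLATE)
            atoms = (a, b, int(ion_of[id(e)]))
        elif e.link_type == "HB_CH3_O":
            a = _residue_atom(topo, e.chain_a, e.residue_a, ROLE_CARBON_METHYL)
            b = _residue_atom(topo, e.chain_b, e.residue_b, ROLE_OXYGEN_CARBONYL)
            atoms = (a, b)
        else:  # HB_COOH: donor H on chain_a, acceptor O on chain_b
            a = _residue_atom(topo, e.chain_a, e.residue_a, ROLE_HYDROGEN_CARBOXYL)
            role_b = (ROLE_OXYGEN_CARBOXYL
                      if topo.full_pattern[e.residue_b] == "P"
                      else ROLE_OXYGEN_CARBOXYLATE)
            b = _residue_atom(topo, e.chain_b, e.residue_b, role_b)
            atoms = (a, b)
        for at in atoms:
            prev = claimed.get(at)
            if prev is not None and not (e.end_frame < prev.start_frame
                                         or prev.end_frame < e.start_frame):
                raise GenerationError(
                    f"atom {at} scheduled in two overlapping events"
                )
            claimed[at] = e
        atoms_of[id(e)] = atoms

    # per-event rendezvous: minimum-image midpoint between the two chains
    # (in y) at the x of residue_a, lifted above the chain plane so displaced
    # atoms cannot graze a chain lying between the linked pair; a cycling z
    # offset separates events whose xy rendezvous would coincide
    rendezvous: dict[int, np.ndarray] = {}
    for ei, e in enumerate(schedule):
        y_a = margin + e.chain_a * _CHAIN_SPACING_NM
        y_b = margin + e.chain_b * _CHAIN_SPACING_NM
        dy = (y_b - y_a) - box[1] * np.round((y_b - y_a) / box[1])
        rendezvous[id(e)] = np.array([
            margin + e.residue_a * _RESIDUE_SPACING_NM,
            (y_a + 0.5 * dy) % box[1],
            margin + 1.5 + 0.5 * (ei % 4),
        ])

    frames = []
    for fi in range(n_frames):
        coords = home.copy()
        for e in schedule:
            if not e.start_frame <= fi <= e.end_frame:
                continue
            sep = _EVENT_GEOMETRY[e.link_type]
            atoms = atoms_of[id(e)]
            m = rendezvous[id(e)]
            if e.link_type == "CA_BRIDGE":
                a, b, ion = atoms
                coords[a] = m + (0.0, -sep, 0.0)
                coords[b] = m + (0.0, +sep, 0.0)
                coords[ion] = m
            else:
                a, b = atoms
                coords[a] = m + (0.0, -sep / 2, 0.0)
                coords[b] = m + (0.0, +sep / 2, 0.0)
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
        frames.append(Frame(coords, box.copy(), time=fi * frame_spacing))
    return Trajectory(frames, frame_spacing), topo, schedule
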