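"""Readers and writers for the package's table, image, topology and
trajectory formats.

Fluorescence tables are CSV with columns ``time_min, intensity, label`` and
optional ``replicate_id`` (times in minutes in files, seconds in memory).
Trajectories are XYZ-style frame blocks whose comment line carries the
time and the orthorhombic box, with coordinates in nm::

    <n_atoms>
    t= 3.0 ns box= 21.5 22.5 5.3 nm
    O_carboxylate 1.000 3.000 1.150
    ...

the companion topology JSON maps every atom index to (chain, residue, role)
and lists the Ca²⁺ ions.  A GRO-subset reader (via MDAnalysis) is provided
for single-frame snapshots.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pores import CalibratedImage
from .quench import DomainError, FluorescenceSeries, QuenchFit
from .xlink import ChainTopology, Frame, LinkSummary, Trajectory


class ParseError(ValueError):
    """Input file violates the documented format."""


# --------------------------------------------------------------------------
# Fluorescence tables
# --------------------------------------------------------------------------

def read_series(path) -> dict[str, list[FluorescenceSeries]]:
    """Read a fluorescence CSV into replicate series grouped by label."""
    df = pd.read_csv(path)
    required = {"time_min", "intensity", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    bad = df.index[df["intensity"] <= 0]
    if len(bad):
        raise ParseError(
            f"{path}: non-positive intensity at row {int(bad[0]) + 2} "
            "(intensities must be > 0)"
        )
    if "replicate_id" not in df.columns:
        df = df.assign(replicate_id=df["label"])
    out: dict[str, list[FluorescenceSeries]] = {}
    for (label, rep), grp in df.groupby(["label", "replicate_id"], sort=False):
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ParseError(
                f"{path}: times not strictly increasing for label={label!r} "
                f"replicate={rep!r}"
            )
        out.setdefault(str(label), []).append(
            FluorescenceSeries.from_minutes(
                times, grp["intensity"].to_numpy(dtype=float),
                label=str(label), replicate_id=str(rep))
        )
    return out


def write_series(collection: dict[str, list[FluorescenceSeries]], path) -> None:
    rows = []
    for label, reps in collection.items():
        for s in reps:
            for t, i in zip(s.times, s.intensities):
                rows.append({"time_min": t / 60.0, "intensity": i,
                             "label": label,
                             "replicate_id": s.replicate_id or label})
    pd.DataFrame(rows).to_csv(path, index=False)


def fits_to_frame(fits: dict[str, QuenchFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"label": label, "K_hat": f.K_hat, "T_hat": f.T_hat,
         "se_K": f.se_K, "se_T": f.se_T, "rss": f.rss, "n": f.n_obs,
         "converged": f.converged}
        for label, f in fits.items()
    ])


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------

def read_image(path, nm_per_px: float, roi_nm=None) -> CalibratedImage:
    """Load a grayscale TIFF/PNG with its calibration (nm per pixel)."""
    import imageio.v3 as iio

    px = np.asarray(iio.imread(path), dtype=float)
    if px.ndim == 3:  # collapse an RGB(A) image to luminance
        px = px[..., :3].mean(axis=-1)
    return CalibratedImage(px, nm_per_px, tuple(roi_nm) if roi_nm else None)


def write_image(image: CalibratedImage, path) -> None:
    import imageio.v3 as iio

    path = Path(path)
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, px.astype(np.float32))
    else:
        iio.imwrite(path, (scaled * 255).astype(np.uint8))


# --------------------------------------------------------------------------
# Topology + trajectory
# --------------------------------------------------------------------------

def write_topology(topo: ChainTopology, path, box=None) -> None:
    doc = {
        "n_chains": topo.n_chains,
        "residues_per_chain": topo.residues_per_chain,
        "pattern": topo.pattern,
        "atoms": [
            {"index": i, "chain": int(topo.atom_chain[i]),
             "residue": int(topo.atom_residue[i]), "role": topo.atom_role[i]}
            for i in range(topo.n_atoms)
        ],
        "ca_ions": [int(i) for i in topo.ca_ions],
    }
    if box is not None:
        doc["box_nm"] = [float(b) for b in box]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_topology(path) -> tuple[ChainTopology, np.ndarray | None]:
    doc = json.loads(Path(path).read_text())
    atoms = doc["atoms"]
    n = len(atoms)
    chain = np.full(n, -2, dtype=int)
    residue = np.full(n, -2, dtype=int)
    roles = [""] * n
    for a in atoms:
        i = a["index"]
        if not 0 <= i < n:
            raise ParseError(f"{path}: atom index {i} out of range")
        chain[i] = a["chain"]
        residue[i] = a["residue"]
        roles[i] = a["role"]
    if np.any(chain == -2):
        raise ParseError(f"{path}: topology does not cover every atom index")
    topo = ChainTopology(
        doc["n_chains"], doc["residues_per_chain"], doc["pattern"],
        chain, residue, roles, np.array(doc.get("ca_ions", []), dtype=int),
    )
    box = np.array(doc["box_nm"], dtype=float) if "box_nm" in doc else None
    return topo, box


def write_trajectory(traj: Trajectory, topo: ChainTopology, path) -> None:
    """One XYZ block per frame; comment line carries time and box (nm)."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{topo.n_atoms}\n")
            fh.write(f"t= {f.time:g} ns box= "
                     f"{f.box[0]:.6f} {f.box[1]:.6f} {f.box[2]:.6f} nm\n")
            for i in range(topo.n_atoms):
                x, y, z = f.coordinates[i]
                fh.write(f"{topo.atom_role[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(xyz_path, topology_path,
                    frame_spacing: float | None = None
                    ) -> tuple[Trajectory, ChainTopology]:
    """Read an XYZ trajectory with its topology JSON.

    The box is taken from each frame's comment line, falling back to the
    topology's ``box_nm``.  Atom counts must match the topology in every
    frame.
    """
    topo, topo_box = read_topology(topology_path)
    lines = Path(xyz_path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"{xyz_path}: frame {frame_no}: expected an atom count at "
                f"line {pos + 1}"
            ) from exc
        if n != topo.n_atoms:
            raise ParseError(
                f"{xyz_path}: frame {frame_no} has {n} atoms, topology "
                f"defines {topo.n_atoms}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time, box = _parse_comment(comment)
        if box is None:
            box = topo_box
        if box is None:
            raise ParseError(
                f"{xyz_path}: frame {frame_no}: no box on the comment line "
                "and none in the topology"
            )
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise ParseError(
                f"{xyz_path}: frame {frame_no} is truncated "
                f"({len(block)}/{n} atom lines)"
            )
        coords = np.empty((n, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{xyz_path}: frame {frame_no}, atom {k}: malformed line"
                )
            coords[k] = [float(p) for p in parts[1:4]]
        frames.append(Frame(coords, np.asarray(box, dtype=float),
                            time=time if time is not None else float(frame_no)))
        pos += 2 + n
        frame_no += 1
    if not frames:
        raise ParseError(f"{xyz_path}: no frames found")
    if frame_spacing is None:
        frame_spacing = (frames[1].time - frames[0].time
                         if len(frames) > 1 else 1.0)
    return Trajectory(frames, frame_spacing), topo


def _parse_comment(comment: str) -> tuple[float | None, list[float] | None]:
    tokens = comment.split()
    time = box = None
    for k, tok in enumerate(tokens):
        if tok == "t=" and k + 1 < len(tokens):
            time = float(tokens[k + 1])
        if tok == "box=" and k + 3 < len(tokens):
            box = [float(tokens[k + 1]), float(tokens[k + 2]),
                   float(tokens[k + 3])]
    return time, box


def read_gro_frame(path) -> Frame:
    """Read a single-frame GRO snapshot (positions and box, nm)."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    coords = u.atoms.positions / 10.0  # MDAnalysis works in Å
    box = u.dimensions[:3] / 10.0
    return Frame(np.asarray(coords, dtype=float),
                 np.asarray(box, dtype=float))


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

def summaries_to_frame(summaries: list[LinkSummary]) -> pd.DataFrame:
    """Cross-link summaries as one table row per system; absent link types
    render as the em-dash used in print."""
    rows = []
    for s in summaries:
        row = {"system": s.label}
        for lt in ("CA_BRIDGE", "HB_CH3_O", "HB_COOH"):
            c = s.mean_counts[lt]
            row[f"mean_{lt}"] = "–" if c is None else round(c, 2)
            row[f"sites_{lt}"] = s.site_counts[lt]
            tau = s.mean_lifetimes[lt]
            row[f"tau_{lt}_ns"] = "–" if tau is None else round(tau, 2)
        row["N_agg"] = round(s.n_agg, 2)
        rows.append(row)
    return pd.DataFrame(rows)
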