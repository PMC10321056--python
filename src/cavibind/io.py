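"""File formats: window time series, multi-frame XYZ, TSV outputs.

Window files are whitespace-delimited text with '#' header lines carrying the
restraint and units (``time_ps z_A x_A y_A``).  Solvent frames are multi-frame
XYZ with element labels "X" (ion), "C" (host atoms) and "O" (pseudo-water
oxygens); the comment line stores the frame time.  GROMACS-style pull output
(time in ps, coordinate in nm) is read with an explicit unit declaration.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import HostGeometry, RestraintSpec, cavity_center
from .solvation import SolventFrame
from .wham import PMFProfile, UmbrellaWindow

__all__ = [
    "write_window",
    "read_window",
    "read_pull_file",
    "write_dataset",
    "write_xyz_frames",
    "read_xyz_frames",
    "write_pmf_tsv",
    "read_pmf_tsv",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision


def write_window(path, window: UmbrellaWindow) -> None:
    path = Path(path)
    lines = ["# cavibind umbrella window"]
    if window.label:
        lines.append(f"# label: {window.label}")
    if window.restraint is not None:
        r = window.restraint
        lines.append(
            f"# restraint: z_center={r.z_center!r} k_z={r.k_z!r} r_cyl={r.r_cyl!r} k_fb={r.k_fb!r}"
        )
    lines.append("# columns: time_ps z_A x_A y_A")
    cols = [window.times, window.z]
    if window.x is not None and window.y is not None:
        cols += [window.x, window.y]
    data = np.column_stack(cols)
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, fmt=_FLOAT_FMT)


def read_window(path) -> UmbrellaWindow:
    """Read a window file; malformed or non-finite lines abort with the line number."""
    path = Path(path)
    label = ""
    restraint: Optional[RestraintSpec] = None
    rows: List[List[float]] = []
    ncols: Optional[int] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("label:"):
                    label = body.split(":", 1)[1].strip()
                elif body.startswith("restraint:"):
                    kv = dict(
                        item.split("=") for item in body.split(":", 1)[1].split()
                    )
                    restraint = RestraintSpec(
                        z_center=float(kv["z_center"]),
                        k_z=float(kv["k_z"]),
                        r_cyl=float(kv["r_cyl"]),
                        k_fb=float(kv["k_fb"]),
                    )
                continue
            fields = line.split()
            try:
                vals = [float(v) for v in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            if any(not math.isfinite(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            if ncols is None:
                ncols = len(vals)
                if ncols not in (2, 4):
                    raise ValueError(f"{path}:{lineno}: expected 2 or 4 columns, got {ncols}")
            elif len(vals) != ncols:
                raise ValueError(f"{path}:{lineno}: expected {ncols} columns, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.array(rows)
    return UmbrellaWindow(
        restraint=restraint,
        times=data[:, 0],
        z=data[:, 1],
        x=data[:, 2] if data.shape[1] == 4 else None,
        y=data[:, 3] if data.shape[1] == 4 else None,
        label=label,
    )


def read_pull_file(path, coord_unit: str = "nm", time_unit: str = "ps",
                   restraint: Optional[RestraintSpec] = None) -> UmbrellaWindow:
    """Read a GROMACS-style pull file (columns: time, coordinate).

    '#' and '@' lines are skipped; coordinates declared in nm are converted to
    angstrom (x10).
    """
    if coord_unit not in ("nm", "A"):
        raise ValueError(f"unknown coordinate unit {coord_unit!r}")
    if time_unit != "ps":
        raise ValueError(f"unknown time unit {time_unit!r}")
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line[0] in "#@":
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                t, c = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line") from exc
            if not (math.isfinite(t) and math.isfinite(c)):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            rows.append((t, c))
    data = np.array(rows)
    scale = 10.0 if coord_unit == "nm" else 1.0
    return UmbrellaWindow(restraint=restraint, times=data[:, 0], z=data[:, 1] * scale)


def write_dataset(outdir, windows: Sequence[UmbrellaWindow], manifest: Dict) -> List[Path]:
    """Write one file per window plus a JSON manifest with provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, w in enumerate(windows):
        p = outdir / f"window_{i:03d}.dat"
        write_window(p, w)
        paths.append(p)
    manifest = dict(manifest)
    manifest["windows"] = [
        {
            "file": p.name,
            "label": w.label,
            "z_center": w.restraint.z_center if w.restraint else None,
            "k_z": w.restraint.k_z if w.restraint else None,
            "n_samples": int(w.n_samples),
        }
        for p, w in zip(paths, windows)
    ]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def write_xyz_frames(path, frames: Sequence[SolventFrame]) -> None:
    """Multi-frame XYZ: ion "X" first, host atoms "C", pseudo-waters "O"."""
    with Path(path).open("w") as fh:
        for f in frames:
            n = 1 + f.host.all_atoms.shape[0] + f.waters.shape[0]
            fh.write(f"{n}\n")
            fh.write(f"t= {f.time!r} ps\n")
            fh.write("X " + " ".join(_FLOAT_FMT % v for v in f.ion) + "\n")
            for a in f.host.all_atoms:
                fh.write("C " + " ".join(_FLOAT_FMT % v for v in a) + "\n")
            for w in f.waters:
                fh.write("O " + " ".join(_FLOAT_FMT % v for v in w) + "\n")


def read_xyz_frames(path, host: Optional[HostGeometry] = None) -> List[SolventFrame]:
    """Read multi-frame XYZ written by :func:`write_xyz_frames`.

    If ``host`` is None it is rebuilt from the "C" atoms of each frame (all of
    them treated as cavity atoms).
    """
    frames = []
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        time = float(comment.split()[1]) if comment.startswith("t=") else 0.0
        ion = None
        hosts, waters = [], []
        for line in lines[i + 2 : i + 2 + n]:
            label, *coords = line.split()
            xyz = [float(v) for v in coords]
            if label == "X":
                ion = xyz
            elif label == "C":
                hosts.append(xyz)
            elif label == "O":
                waters.append(xyz)
            else:
                raise ValueError(f"unknown atom label {label!r} in {path}")
        if ion is None:
            raise ValueError(f"frame at line {i + 1} of {path} has no ion record")
        frame_host = host
        if frame_host is None:
            atoms = np.asarray(hosts)
            frame_host = HostGeometry(cavity_atoms=atoms, all_atoms=atoms)
        z_dist = ion[2] - cavity_center(frame_host)[2]
        frames.append(
            SolventFrame(
                time=time,
                ion=np.asarray(ion),
                waters=np.asarray(waters).reshape(-1, 3),
                host=frame_host,
                z_dist=float(z_dist),
            )
        )
        i += 2 + n
    return frames


def write_pmf_tsv(path, profile: PMFProfile) -> None:
    df = pd.DataFrame(
        {
            "z": profile.z_grid,
            "W": profile.W,
            "W_sd": profile.W_sd if profile.W_sd is not None else np.nan,
            "n_samples": profile.counts,
        }
    )
    with Path(path).open("w") as fh:
        lo, hi = profile.reference_region
        fh.write(f"# reference_region: {lo!r} {hi!r}\n")
        fh.write("# units: z A, W kcal/mol\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_pmf_tsv(path) -> PMFProfile:
    path = Path(path)
    reference = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("# reference_region:"):
                lo, hi = line.split(":", 1)[1].split()
                reference = (float(lo), float(hi))
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    w = df["W"].to_numpy()
    sd = df["W_sd"].to_numpy()
    return PMFProfile(
        z_grid=df["z"].to_numpy(),
        W=w,
        W_sd=None if np.all(np.isnan(sd)) else sd,
        reference_region=reference or (float(df["z"].max() - 2.0), float(df["z"].max())),
        occupied_mask=~np.isnan(w),
        counts=df["n_samples"].to_numpy(dtype=float),
    )
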