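"""File formats: centers (CSV/PDB), scatterers (PDB), curves (two-column
text), detector images (TIFF or plain-text matrix + JSON geometry sidecar),
reflection lists (CSV) and flat TOML configuration.

PDB conventions: centers are written as one pseudo-atom per trimer (HETATM,
element C, one residue each); scatterer weight goes in the occupancy column
and the Gaussian width (Angstrom) in the B-factor column.  PDB coordinates
are Angstrom-native and taken verbatim.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile

from .cell import Reflection, ScatteringGeometry
from .synthetic import CenterSet, Curve1D, DetectorImage, ScattererSet

__all__ = [
    "read_centers",
    "write_centers_csv",
    "write_centers_pdb",
    "read_scatterers_pdb",
    "write_scatterers_pdb",
    "read_curve",
    "write_curve",
    "read_detector_image",
    "write_detector_image",
    "write_reflections_csv",
    "read_config",
]


# -- centers ----------------------------------------------------------------

def read_centers(path, format: str | None = None) -> CenterSet:
    """Read a CenterSet from CSV (columns x,y,z in Angstrom) or PDB."""
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for col in ("x", "y", "z"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                line = int(np.argmax((bad | df[col].isna()).values)) + 2  # header is line 1
                raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        return CenterSet(df[["x", "y", "z"]].to_numpy(float), label=str(path))
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
        pts = [
            [at.pos.x, at.pos.y, at.pos.z]
            for model in st
            for chain in model
            for res in chain
            for at in res
        ]
        if not pts:
            raise ValueError(f"{path}: no atom records")
        return CenterSet(np.array(pts), label=str(path))
    raise ValueError(f"unknown centers format {fmt!r}")


def write_centers_csv(centers: CenterSet, path) -> None:
    # %.17g round-trips float64 exactly
    pd.DataFrame(centers.points, columns=["x", "y", "z"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def _new_structure(name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    model.add_chain(chain)
    st.add_model(model)
    return st


def write_centers_pdb(centers: CenterSet, path) -> None:
    """Centers as pseudo-atoms, one residue per trimer center."""
    st = _new_structure("centers")
    chain = st[0]["A"]
    for i, p in enumerate(centers.points, start=1):
        res = gemmi.Residue()
        res.name = "TRM"
        res.seqid = gemmi.SeqId(i, " ")
        at = gemmi.Atom()
        at.name = "C"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(*p)
        at.occ = 1.0
        res.add_atom(at)
        chain.add_residue(res)
    st.setup_entities()
    st.write_pdb(str(path))


def write_scatterers_pdb(scatterers: ScattererSet, path) -> None:
    """Scatterers as pseudo-atoms: weight -> occupancy, width (A) -> B-factor."""
    st = _new_structure("scatterers")
    chain = st[0]["A"]
    for i, (p, w, s) in enumerate(
        zip(scatterers.sites, scatterers.weights, scatterers.widths), start=1
    ):
        res = gemmi.Residue()
        res.name = "SCT"
        res.seqid = gemmi.SeqId(i, " ")
        at = gemmi.Atom()
        at.name = "C"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(*p)
        at.occ = float(w)
        at.b_iso = float(s)
        res.add_atom(at)
        chain.add_residue(res)
    st.setup_entities()
    st.write_pdb(str(path))


def read_scatterers_pdb(path) -> ScattererSet:
    st = gemmi.read_pdb(str(path))
    sites, weights, widths = [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    sites.append([at.pos.x, at.pos.y, at.pos.z])
                    weights.append(at.occ)
                    widths.append(at.b_iso)
    if not sites:
        raise ValueError(f"{path}: no atom records")
    return ScattererSet(
        np.array(sites), np.array(weights), np.array(widths), label=str(path)
    )


# -- 1D curves --------------------------------------------------------------

def write_curve(curve: Curve1D, path) -> None:
    """Two-column whitespace text with a comment header carrying units."""
    with open(path, "w") as fh:
        fh.write(f"# x_kind: {curve.x_kind}\n")
        fh.write(f"# wavelength_angstrom: {curve.wavelength}\n")
        for xv, yv, ok in zip(curve.x, curve.y, curve.valid):
            fh.write(f"{xv:.10g} {yv:.10g}{'' if ok else '  # invalid'}\n")


def read_curve(path) -> Curve1D:
    x_kind, wavelength = "two_theta_deg", 1.542
    xs, ys, valid = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# x_kind:"):
                x_kind = line.split(":", 1)[1].strip()
            elif line.startswith("# wavelength_angstrom:"):
                wavelength = float(line.split(":", 1)[1])
            elif line and not line.startswith("#"):
                parts = line.split()
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
                valid.append("invalid" not in line)
    return Curve1D(
        x=np.array(xs),
        y=np.array(ys),
        x_kind=x_kind,
        wavelength=wavelength,
        valid=np.array(valid, dtype=bool),
    )


# -- detector images --------------------------------------------------------

def write_detector_image(image: DetectorImage, path) -> None:
    """32-bit float TIFF plus a JSON geometry sidecar (<path>.geom.json)."""
    path = Path(path)
    tifffile.imwrite(path, image.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".geom.json")
    sidecar.write_text(json.dumps(image.geometry.to_dict(), indent=1))


def read_detector_image(path, geometry_path=None) -> DetectorImage:
    """Read a TIFF or plain-text matrix raster plus its geometry sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
    else:
        data = np.loadtxt(path)
    geom_path = Path(geometry_path) if geometry_path else path.with_suffix(
        path.suffix + ".geom.json"
    )
    geometry = ScatteringGeometry.from_dict(json.loads(Path(geom_path).read_text()))
    return DetectorImage(data=data, geometry=geometry)


# -- reflections ------------------------------------------------------------

def write_reflections_csv(reflections: list[Reflection], path) -> None:
    pd.DataFrame(
        [
            {"h": r.h, "k": r.k, "l": r.l, "d_angstrom": r.d, "weight": r.weight}
            for r in reflections
        ]
    ).to_csv(path, index=False)


def write_xy(x, y, path, header: str = "") -> None:
    """Generic two-column whitespace text (e.g. distribution functions)."""
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        for xv, yv in zip(np.asarray(x, float), np.asarray(y, float)):
            fh.write(f"{xv:.10g} {yv:.10g}\n")


# -- configuration ----------------------------------------------------------

def read_config(path) -> dict:
    """Flat TOML configuration; unit-bearing key names (..._angstrom, ..._deg)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
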