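"""File formats: extended-XYZ configurations, unit-headed tables,
parameter files.

All formats are plain text.  Tables are tab-separated with a header row
naming each column together with its unit (e.g. ``T_K``, ``P_bar``); readers
validate the header against the expected column set and fail loudly on
mismatch rather than guessing units.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import Configuration, ForceFieldParams, PairParams
from .slab import DensityProfile, PressureTensorSeries
from .thermo import CoexistenceCurve, VaporPressureCurve


class FormatError(ValueError):
    """Malformed file or unit-header mismatch."""


# ---------------------------------------------------------------------------
# Extended-XYZ configurations
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_configuration(cfg: Configuration, path) -> None:
    """Extended-XYZ dialect: comment line carries the box, periodicity and
    bond list; per-atom columns are element, position, molecule id, type."""
    lines = [str(cfg.n_atoms)]
    fields = []
    if cfg.box is not None:
        lx, ly, lz = cfg.box
        fields.append(f'Lattice="{lx:.12g} 0 0 0 {ly:.12g} 0 0 0 {lz:.12g}"')
    fields.append("Properties=species:S:1:pos:R:3:molid:I:1:type:S:1")
    fields.append(f"Periodic={'T' if cfg.periodic else 'F'}")
    if cfg.bonds:
        fields.append("Bonds=" + ",".join(f"{i}-{j}" for i, j in cfg.bonds))
    lines.append(" ".join(fields))
    for i in range(cfg.n_atoms):
        x, y, z = cfg.coords[i]
        lines.append(
            f"{cfg.elements[i]} {x:.12g} {y:.12g} {z:.12g} "
            f"{cfg.molecule_id[i]} {cfg.type_labels[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_configuration(path) -> Configuration:
    text = Path(path).read_text().splitlines()
    if len(text) < 2:
        raise FormatError("truncated configuration file")
    try:
        n = int(text[0].strip())
    except ValueError:
        raise FormatError("first line must be the atom count")
    comment = text[1]
    box = None
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(v) for v in m.group(1).split()]
        if len(vals) != 9:
            raise FormatError("Lattice must have 9 components")
        box = np.array([vals[0], vals[4], vals[8]])
    periodic = "Periodic=T" in comment
    bonds = []
    m = re.search(r"Bonds=(\S+)", comment)
    if m:
        for token in m.group(1).split(","):
            i, j = token.split("-")
            bonds.append((int(i), int(j)))
    elements, coords, mol_id, labels = [], [], [], []
    for line in text[2:2 + n]:
        parts = line.split()
        if len(parts) != 6:
            raise FormatError(f"expected 6 columns, got {len(parts)}")
        elements.append(parts[0])
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        mol_id.append(int(parts[4]))
        labels.append(parts[5])
    if len(elements) != n:
        raise FormatError("atom count does not match rows")
    return Configuration(
        coords=np.array(coords), elements=elements,
        molecule_id=np.array(mol_id), type_labels=labels, bonds=bonds,
        box=box, periodic=periodic,
    )


# ---------------------------------------------------------------------------
# Unit-headed tab-separated tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV with unit-bearing column names; optional ``# key = value`` meta
    lines before the header."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v:.12g}\n" if isinstance(v, float)
                     else f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path, required_columns: list[str] | None = None
               ) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            m = re.match(r"#\s*(\S+)\s*=\s*(\S+)", line)
            if m:
                try:
                    meta[m.group(1)] = float(m.group(2))
                except ValueError:
                    meta[m.group(1)] = m.group(2)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if required_columns is not None:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise FormatError(
                f"table {path} lacks unit-headed columns {sorted(missing)}; "
                f"found {list(df.columns)}"
            )
    return df, meta


def write_pressure_series(series: PressureTensorSeries, path) -> None:
    df = pd.DataFrame({
        "time_ps": series.time, "P_X_bar": series.p_x,
        "P_Y_bar": series.p_y, "P_Z_bar": series.p_z,
    })
    write_table(df, path, meta={"L_Z_nm": float(series.box_lz)})


def read_pressure_series(path) -> PressureTensorSeries:
    df, meta = read_table(path, ["time_ps", "P_X_bar", "P_Y_bar", "P_Z_bar"])
    if "L_Z_nm" not in meta:
        raise FormatError("pressure series lacks the L_Z_nm meta line")
    return PressureTensorSeries(
        time=df["time_ps"].to_numpy(), p_x=df["P_X_bar"].to_numpy(),
        p_y=df["P_Y_bar"].to_numpy(), p_z=df["P_Z_bar"].to_numpy(),
        box_lz=float(meta["L_Z_nm"]),
    )


def write_density_profile(profile: DensityProfile, path) -> None:
    df = pd.DataFrame({"z_nm": profile.bin_centers,
                       "density_g_per_L": profile.density})
    write_table(df, path, meta={"n_frames": profile.n_frames})


def read_density_profile(path) -> DensityProfile:
    df, meta = read_table(path, ["z_nm", "density_g_per_L"])
    return DensityProfile(
        bin_centers=df["z_nm"].to_numpy(),
        density=df["density_g_per_L"].to_numpy(),
        n_frames=int(meta.get("n_frames", 1)),
    )


def write_coexistence_curve(curve: CoexistenceCurve, path) -> None:
    write_table(curve.to_frame(), path)


def read_coexistence_curve(path) -> CoexistenceCurve:
    df, _ = read_table(path, ["T_K", "rho_l_g_per_L", "rho_g_g_per_L"])
    return CoexistenceCurve(T=df["T_K"].to_numpy(),
                            rho_l=df["rho_l_g_per_L"].to_numpy(),
                            rho_g=df["rho_g_g_per_L"].to_numpy())


def write_vapor_pressure_curve(curve: VaporPressureCurve, path) -> None:
    write_table(curve.to_frame(), path)


def read_vapor_pressure_curve(path) -> VaporPressureCurve:
    df, _ = read_table(path, ["T_K", "P_bar"])
    return VaporPressureCurve(T=df["T_K"].to_numpy(), P=df["P_bar"].to_numpy())


# ---------------------------------------------------------------------------
# Force tables and parameter files
# ---------------------------------------------------------------------------

def write_force_table(forces: np.ndarray, path) -> None:
    df = pd.DataFrame({
        "atom_index": np.arange(len(forces)),
        "fx_kcal_mol_A": forces[:, 0],
        "fy_kcal_mol_A": forces[:, 1],
        "fz_kcal_mol_A": forces[:, 2],
    })
    write_table(df, path)


def read_force_table(path) -> np.ndarray:
    df, _ = read_table(
        path, ["atom_index", "fx_kcal_mol_A", "fy_kcal_mol_A", "fz_kcal_mol_A"]
    )
    df = df.sort_values("atom_index")
    return df[["fx_kcal_mol_A", "fy_kcal_mol_A", "fz_kcal_mol_A"]].to_numpy()


def params_to_dict(params: ForceFieldParams) -> dict:
    return {
        "pairs": {"|".join(k): {"A": p.A, "b": p.b, "C6": p.C6, "C8": p.C8}
                  for k, p in params.pairs.items()},
        "charges": dict(params.charges),
        "bonds": {"|".join(k): list(v) for k, v in params.bonds.items()},
        "angles": {"|".join(k): list(v) for k, v in params.angles.items()},
        "dihedrals": {"|".join(k): list(v) for k, v in params.dihedrals.items()},
        "charges_enabled": params.charges_enabled,
        "dispersion_frozen": params.dispersion_frozen,
        "scale_14": params.scale_14,
    }


def params_from_dict(d: dict) -> ForceFieldParams:
    return ForceFieldParams(
        pairs={tuple(k.split("|")): PairParams(**v)
               for k, v in d.get("pairs", {}).items()},
        charges=dict(d.get("charges", {})),
        bonds={tuple(k.split("|")): tuple(v)
               for k, v in d.get("bonds", {}).items()},
        angles={tuple(k.split("|")): tuple(v)
                for k, v in d.get("angles", {}).items()},
        dihedrals={tuple(k.split("|")): tuple(v)
                   for k, v in d.get("dihedrals", {}).items()},
        charges_enabled=bool(d.get("charges_enabled", True)),
        dispersion_frozen=bool(d.get("dispersion_frozen", True)),
        scale_14=float(d.get("scale_14", 1.0)),
    )


def write_params(params: ForceFieldParams, path,
                 provenance: dict | None = None) -> None:
    """Human-readable parameter file with a provenance header."""
    doc = {"provenance": provenance or {}, "force_field": params_to_dict(params)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_params(path) -> tuple[ForceFieldParams, dict]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "force_field" not in doc:
        raise FormatError("not a parameter file (missing force_field block)")
    return params_from_dict(doc["force_field"]), doc.get("provenance", {})


def data_hash(obj) -> str:
    """Stable short hash for provenance lines."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
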