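"""Table and image file formats with schema validation.

Comma-separated text is the canonical interchange dialect (inspectable and
language-neutral); parquet is available as an optional binary container for
large runs (chosen by file suffix).  All tables are schema-validated on
read and write: missing columns, extra columns and non-finite numeric
values are hard errors that name the offending column/row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImagePlane, ReconstructedImage
from .range_stats import DepthProfile

EVENT_TABLE = "event"
CONE_TABLE = "cone"
PROFILE_TABLE = "profile"

SCHEMAS: dict[str, dict[str, str]] = {
    # merged one-row-per-collision table; production columns repeat per row
    EVENT_TABLE: {
        "event_id": "int", "species": "str",
        "prod_x_mm": "float", "prod_y_mm": "float", "prod_z_mm": "float",
        "E0_MeV": "float", "hit_index": "int", "bar_id": "int",
        "x_mm": "float", "y_mm": "float", "z_mm": "float",
        "t_ns": "float", "edep_MeV": "float", "kind": "str",
    },
    CONE_TABLE: {
        "event_id": "int", "species": "str",
        "apex_x_mm": "float", "apex_y_mm": "float", "apex_z_mm": "float",
        "axis_x": "float", "axis_y": "float", "axis_z": "float",
        "half_angle_rad": "float", "E_MeV": "float",
    },
    PROFILE_TABLE: {
        "bin_center_mm": "float", "value": "float", "species": "str",
    },
}


class SchemaError(ValueError):
    pass


def merge_event_table(events: pd.DataFrame, collisions: pd.DataFrame) -> pd.DataFrame:
    """Join phase-space events and collisions into the canonical event table."""
    merged = collisions.merge(
        events[["event_id", "prod_x_mm", "prod_y_mm", "prod_z_mm", "E0_MeV"]],
        on="event_id", how="left", validate="many_to_one",
    )
    return merged[list(SCHEMAS[EVENT_TABLE])]


def _validate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    schema = SCHEMAS[kind]
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{kind} table missing column(s): {sorted(missing)}")
    extra = set(df.columns) - set(schema)
    if extra:
        raise SchemaError(f"{kind} table has unknown column(s): {sorted(extra)}")
    out = df[list(schema)].copy()
    for col, dtype in schema.items():
        if dtype == "str":
            out[col] = out[col].astype(str)
            continue
        values = pd.to_numeric(out[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if np.any(bad):
            row = int(np.nonzero(bad)[0][0])
            raise SchemaError(f"non-finite value in column '{col}' at row {row}")
        out[col] = values.astype(np.int64 if dtype == "int" else float)
    return out


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Schema-validated write; dialect chosen by suffix (.csv or .parquet)."""
    path = Path(path)
    out = _validate(df, kind)
    if path.suffix == ".parquet":
        out.to_parquet(path, index=False)
    else:
        out.to_csv(path, index=False)


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return _validate(df, kind)


def profile_to_frame(profile: DepthProfile, species: str | None = None) -> pd.DataFrame:
    return pd.DataFrame({
        "bin_center_mm": profile.centers,
        "value": np.asarray(profile.counts, dtype=float),
        "species": species if species is not None else profile.species,
    })


def frame_to_profile(df: pd.DataFrame) -> DepthProfile:
    centers = df["bin_center_mm"].to_numpy(dtype=float)
    if len(centers) < 2:
        raise SchemaError("profile needs at least two bins")
    width = centers[1] - centers[0]
    if not np.allclose(np.diff(centers), width):
        raise SchemaError("profile bins must be uniform")
    edges = np.concatenate([centers - width / 2.0, [centers[-1] + width / 2.0]])
    species = df["species"].iloc[0] if len(df) else ""
    return DepthProfile(edges=edges, counts=df["value"].to_numpy(dtype=float),
                        species=str(species))


def write_image(image: ReconstructedImage, path: str | Path) -> None:
    """Dense matrix with a JSON metadata header (origin, basis, grid)."""
    plane = image.plane
    meta = {
        "origin": plane.origin.tolist(),
        "u_hat": plane.u_hat.tolist(),
        "v_hat": plane.v_hat.tolist(),
        "normal": plane.normal.tolist(),
        "n_pixels": plane.n_pixels,
        "pixel_mm": plane.pixel_mm,
        "n_iterations": image.n_iterations,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        np.savetxt(fh, image.values)


def read_image(path: str | Path) -> ReconstructedImage:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise SchemaError("image file missing metadata header")
        meta = json.loads(header[2:])
        values = np.loadtxt(fh)
    plane = ImagePlane(
        origin=np.asarray(meta["origin"]), u_hat=np.asarray(meta["u_hat"]),
        v_hat=np.asarray(meta["v_hat"]), normal=np.asarray(meta["normal"]),
        n_pixels=int(meta["n_pixels"]), pixel_mm=float(meta["pixel_mm"]),
    )
    values = values.reshape(plane.n_pixels, plane.n_pixels)
    return ReconstructedImage(values=values, plane=plane,
                              n_iterations=int(meta.get("n_iterations", 0)))
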