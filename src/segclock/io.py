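"""Plain-text serialization: kymograph TSV/PGM, series CSV, point-pattern CSV,
flat key=value configs and manifests.

Everything here is diffable text; the only image format is ASCII PGM (P2).
"""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import pandas as pd

from .embryo import PointPattern
from .model import Kymograph
from .zonetest import ZoneTestResult

__all__ = [
    "write_kymograph_tsv",
    "write_kymograph_pgm",
    "write_length_series",
    "write_point_pattern",
    "read_point_pattern",
    "write_zone_result",
    "write_manifest",
    "read_config",
]

NA = "NA"


def write_kymograph_tsv(kymo: Kymograph, path) -> None:
    """Cell-state matrix, rows = sample times, columns = space bins.

    First column is the sample time; the header row carries the bin centres.
    Bins outside the tissue hold the sentinel ``NA``.
    """
    df = pd.DataFrame(kymo.z_grid, columns=[f"{c:.6g}" for c in kymo.space_centers])
    df.insert(0, "time", kymo.times)
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def write_kymograph_pgm(kymo: Kymograph, path) -> None:
    """8-bit grayscale space-time diagram as ASCII PGM (P2).

    Black is ``z = -z_max``, white ``z = +z_max``; rows run top to bottom in
    time.  Out-of-tissue bins are rendered at gray level 0 (the colour
    sentinel has no grayscale slot).
    """
    z = kymo.z_grid
    zmax = kymo.params.z_max
    gray = np.rint((z + zmax) / (2.0 * zmax) * 255.0)
    gray = np.where(np.isnan(z), 0, np.clip(gray, 0, 255)).astype(int)
    lines = [f"P2", f"{gray.shape[1]} {gray.shape[0]}", "255"]
    lines += [" ".join(map(str, row)) for row in gray]
    Path(path).write_text("\n".join(lines) + "\n")


def write_length_series(kymo: Kymograph, path) -> None:
    """time, L(t), frozen-region extent and frozen-phase span as CSV."""
    pd.DataFrame(
        {
            "time": kymo.times,
            "length": kymo.lengths,
            "front_lo": kymo.front_lo,
            "front_hi": kymo.front_hi,
            "frozen_span_cycles": kymo.frozen_span_cycles,
        }
    ).to_csv(path, index=False, na_rep=NA, float_format="%.8g")


def write_point_pattern(pattern: PointPattern, path, meta_path=None) -> None:
    """Nuclei CSV (ap, lat, mitotic 0/1) plus a key=value metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "ap": pattern.ap,
            "lat": pattern.lat,
            "mitotic": pattern.mitotic.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round-trip
    meta = {"scenario": pattern.scenario, "seed": pattern.seed, **pattern.params}
    write_manifest(meta, Path(meta_path) if meta_path else path.with_suffix(".meta"))


def read_point_pattern(path, meta_path=None) -> PointPattern:
    """Inverse of :func:`write_point_pattern`; metadata sidecar is optional."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_file = Path(meta_path) if meta_path else path.with_suffix(".meta")
    scenario, seed, params = "uniform", None, {}
    if meta_file.exists():
        meta = read_config(meta_file)
        scenario = meta.pop("scenario", "uniform")
        seed = meta.pop("seed", None)
        params = meta
    return PointPattern(
        ap=df["ap"].to_numpy(float),
        lat=df["lat"].to_numpy(float),
        mitotic=df["mitotic"].to_numpy(int).astype(bool),
        scenario=scenario,
        params=params,
        seed=seed,
    )


def write_zone_result(result: ZoneTestResult, txt_path=None, csv_path=None) -> str:
    """Key=value text block (returned; optionally written) and one-row CSV."""
    d = result.as_dict()
    text = "\n".join(f"{k}={v}" for k, v in d.items()) + "\n"
    if txt_path:
        Path(txt_path).write_text(text)
    if csv_path:
        pd.DataFrame([d]).to_csv(csv_path, index=False)
    return text


def write_manifest(config: dict, path) -> None:
    """Flat key=value file echoing a fully resolved configuration."""
    lines = [f"{k}={v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(v: str):
    try:
        return ast.literal_eval(v)
    except (ValueError, SyntaxError):
        return v


def read_config(path) -> dict:
    """Parse a flat key=value file; values are literal-eval'd when possible."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        out[k.strip()] = _coerce(v.strip())
    return out
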