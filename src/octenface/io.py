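"""Readers and writers for all on-disk formats, plus run configuration.

Volumes travel as multi-page TIFF (one page per B-scan; page rows = depth,
page columns = A-scans) or as raw little-endian unsigned 8/16-bit binary,
in both cases with a JSON sidecar carrying the :class:`ScanMetadata` (and,
for raw, the dtype).  Integer input is normalized to [0, 1] by dividing by
the dtype maximum; float TIFF pages are taken as already normalized.

Enface maps are written as 32-bit float TIFF plus CSV, with a grayscale
preview PNG and a sidecar JSON recording the preview's min-max scale.
Boundary tables are long-format CSV (bscan, ascan, interface, row, valid)
or the equivalent JSON; correction polylines are read from CSV/JSON.
Deviation maps are paletted PNGs plus integer-label CSVs.  Every product run
emits a JSON manifest with per-file SHA-256 checksums so runs can be
verified byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import __version__
from .core import (
    Boundary,
    BoundarySet,
    ConfigError,
    EnfaceMap,
    FormatError,
    InterfaceId,
    OCTVolume,
    ScanMetadata,
)
from .normative import PALETTE, DeviationLabel, DeviationMap, NormativeAtlas
from .segmentation import GraphParams

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_boundaries",
    "write_boundaries",
    "read_corrections",
    "write_map",
    "read_map_csv",
    "write_atlas",
    "read_atlas",
    "write_deviation",
    "write_products",
]

log = logging.getLogger(__name__)

_RAW_DTYPES = {"uint8": np.uint8, "uint16": np.uint16}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration loadable from YAML or JSON."""

    graph: GraphParams = dataclasses.field(default_factory=GraphParams)
    meta: ScanMetadata | None = None
    coverage: float = 0.95
    outdir: str = "."
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "graph" in kwargs and kwargs["graph"] is not None:
            gknown = {f.name for f in dataclasses.fields(GraphParams)}
            gunknown = set(kwargs["graph"]) - gknown
            if gunknown:
                raise ConfigError(f"unknown graph keys: {sorted(gunknown)}")
            kwargs["graph"] = GraphParams(**kwargs["graph"])
        if "meta" in kwargs and kwargs["meta"] is not None:
            kwargs["meta"] = ScanMetadata.from_dict(kwargs["meta"])
        return cls(**kwargs)


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype in (np.uint8, np.uint16):
        return arr.astype(np.float32) / np.iinfo(arr.dtype).max
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float32)
    raise FormatError(f"unsupported volume dtype {arr.dtype}")


def _load_sidecar(sidecar: "str | Path | dict | None", path: Path) -> dict | None:
    if isinstance(sidecar, dict):
        return sidecar
    if sidecar is not None:
        return json.loads(Path(sidecar).read_text())
    default = path.with_suffix(path.suffix + ".json")
    if default.exists():
        return json.loads(default.read_text())
    return None


def read_volume(path: str | Path,
                sidecar: "str | Path | dict | None" = None) -> OCTVolume:
    """Load an SDOCT volume from multi-page TIFF or raw binary + sidecar.

    The sidecar JSON holds ``{"meta": {...ScanMetadata...}}`` and, for raw
    input, ``"dtype"``.  For TIFF the sidecar is optional; metadata defaults
    are then inferred with the page geometry.
    """
    path = Path(path)
    side = _load_sidecar(sidecar, path)

    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"expected a 3-D TIFF stack, got shape {arr.shape}")
        n_b, n_d, n_a = arr.shape
        if side and "meta" in side:
            meta = ScanMetadata.from_dict(side["meta"])
            if meta.volume_shape != arr.shape:
                raise FormatError(
                    f"TIFF shape {arr.shape} does not match sidecar "
                    f"{meta.volume_shape}"
                )
        else:
            meta = ScanMetadata(n_bscans=n_b, n_ascans=n_a, n_depth=n_d)
        return OCTVolume(intensity=np.clip(_normalize(arr), 0.0, 1.0), meta=meta)

    if path.suffix.lower() in (".raw", ".bin"):
        if not side:
            raise ConfigError("raw volumes require a JSON metadata sidecar")
        meta = ScanMetadata.from_dict(side["meta"])
        dtype_name = side.get("dtype", "uint16")
        if dtype_name not in _RAW_DTYPES:
            raise FormatError(f"raw dtype must be uint8/uint16, got {dtype_name}")
        dtype = np.dtype(_RAW_DTYPES[dtype_name]).newbyteorder("<")
        arr = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(meta.volume_shape))
        if arr.size != expected:
            raise FormatError(
                f"raw file holds {arr.size} samples, sidecar implies {expected}"
            )
        arr = arr.reshape(meta.volume_shape)
        return OCTVolume(intensity=_normalize(arr), meta=meta)

    raise FormatError(f"unrecognized volume extension {path.suffix!r}")


def write_volume(vol: OCTVolume, path: str | Path,
                 dtype: str = "float32") -> Path:
    """Write a volume as multi-page TIFF (+ JSON sidecar); returns the path.

    ``dtype`` is ``float32`` (lossless round-trip) or ``uint8``/``uint16``
    (quantized by the dtype maximum).
    """
    path = Path(path)
    if dtype == "float32":
        data = vol.intensity.astype(np.float32)
    elif dtype in _RAW_DTYPES:
        m = np.iinfo(_RAW_DTYPES[dtype]).max
        data = np.round(vol.intensity * m).astype(_RAW_DTYPES[dtype])
    else:
        raise FormatError(f"unsupported write dtype {dtype}")
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "meta": vol.meta.to_dict(),
        "axes": "bscan,depth,ascan",
        "dtype": dtype,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_boundaries(bs: BoundarySet, path: str | Path) -> Path:
    """Write a boundary set as long-format CSV (or JSON for .json paths)."""
    path = Path(path)
    n_b, n_a = bs.meta.grid_shape
    if path.suffix == ".json":
        payload = {
            "meta": bs.meta.to_dict(),
            "interfaces": {
                iid.value: {
                    "rows": bs[iid].rows.tolist(),
                    "valid": bs[iid].valid.tolist(),
                }
                for iid in InterfaceId
            },
        }
        path.write_text(json.dumps(payload))
        return path
    yy, xx = np.meshgrid(np.arange(n_b), np.arange(n_a), indexing="ij")
    frames = []
    for iid in InterfaceId:
        b = bs[iid]
        frames.append(pd.DataFrame({
            "bscan": yy.ravel(),
            "ascan": xx.ravel(),
            "interface": iid.value,
            "row": b.rows.ravel(),
            "valid": b.valid.ravel().astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_boundaries(path: str | Path, meta: ScanMetadata) -> BoundarySet:
    """Read a boundary set written by :func:`write_boundaries`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        meta = ScanMetadata.from_dict(payload["meta"])
        boundaries = {
            InterfaceId(k): Boundary(
                rows=np.asarray(v["rows"], dtype=float),
                valid=np.asarray(v["valid"], dtype=bool),
            )
            for k, v in payload["interfaces"].items()
        }
        return BoundarySet(boundaries=boundaries, meta=meta)
    df = pd.read_csv(path)
    required = {"bscan", "ascan", "interface", "row", "valid"}
    if not required <= set(df.columns):
        raise FormatError(f"boundary CSV must have columns {sorted(required)}")
    shape = meta.grid_shape
    boundaries = {}
    for iid in InterfaceId:
        sub = df[df["interface"] == iid.value]
        rows = np.zeros(shape)
        valid = np.zeros(shape, dtype=bool)
        rows[sub["bscan"], sub["ascan"]] = sub["row"]
        valid[sub["bscan"], sub["ascan"]] = sub["valid"].astype(bool)
        boundaries[iid] = Boundary(rows=rows, valid=valid)
    return BoundarySet(boundaries=boundaries, meta=meta)


def read_corrections(path: str | Path) -> list[dict]:
    """Read operator correction polylines.

    JSON: a list of ``{"bscan": int, "interface": str,
    "vertices": [[x, row], ...]}``.  CSV: long format with columns
    ``bscan, interface, x, row`` — vertices grouped by (bscan, interface)
    in file order.
    """
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        required = {"bscan", "interface", "x", "row"}
        if not required <= set(df.columns):
            raise FormatError(f"correction CSV must have columns {sorted(required)}")
        records = [
            {
                "bscan": int(b),
                "interface": i,
                "vertices": sub[["x", "row"]].values.tolist(),
            }
            for (b, i), sub in df.groupby(["bscan", "interface"], sort=False)
        ]
    for r in records:
        InterfaceId(r["interface"])  # validates the tag
        if len(r["vertices"]) < 1:
            raise FormatError("correction polyline with no vertices")
    return records


def write_map(m: EnfaceMap, basepath: str | Path) -> list[Path]:
    """Write one enface map: float TIFF, CSV, preview PNG and scale JSON."""
    base = Path(basepath)
    values = np.where(m.valid, m.values, np.nan).astype(np.float32)
    paths = []

    tif = base.with_suffix(".tiff")
    tifffile.imwrite(tif, values, photometric="minisblack")
    paths.append(tif)

    csv = base.with_suffix(".csv")
    pd.DataFrame(values).to_csv(csv, index=False, header=False)
    paths.append(csv)

    finite = values[np.isfinite(values)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    scale = vmax - vmin if vmax > vmin else 1.0
    gray = np.clip((values - vmin) / scale, 0, 1)
    gray = np.where(np.isfinite(values), gray, 0.0)
    png = base.with_suffix(".png")
    Image.fromarray((gray * 255).astype(np.uint8), mode="L").save(png)
    paths.append(png)

    meta = base.with_suffix(".scale.json")
    meta.write_text(json.dumps({
        "layer": m.layer, "kind": m.kind, "vmin": vmin, "vmax": vmax,
        "units": "um" if m.kind == "thickness_um" else "normalized",
    }, indent=1))
    paths.append(meta)
    return paths


def read_map_csv(path: str | Path, kind: str, layer: str) -> EnfaceMap:
    """Read an enface map back from its CSV (NaN marks invalid pixels)."""
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    valid = np.isfinite(values)
    return EnfaceMap(values=np.where(valid, values, 0.0), kind=kind,
                     layer=layer, valid=valid)


def write_atlas(atlas: NormativeAtlas, outdir: str | Path) -> list[Path]:
    """Write an atlas as a directory of four float TIFFs + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ("mean", "sd", "lower", "upper"):
        arr = np.where(atlas.valid, getattr(atlas, name), np.nan).astype(np.float32)
        p = outdir / f"{name}.tiff"
        tifffile.imwrite(p, arr, photometric="minisblack")
        paths.append(p)
    meta = outdir / "atlas.json"
    meta.write_text(json.dumps({
        "n_subjects": atlas.n_subjects,
        "coverage": atlas.coverage,
        "layer": atlas.layer,
    }, indent=1))
    paths.append(meta)
    return paths


def read_atlas(outdir: str | Path) -> NormativeAtlas:
    outdir = Path(outdir)
    info = json.loads((outdir / "atlas.json").read_text())
    arrays = {}
    for name in ("mean", "sd", "lower", "upper"):
        arrays[name] = tifffile.imread(outdir / f"{name}.tiff").astype(float)
    valid = np.isfinite(arrays["mean"])
    return NormativeAtlas(
        mean=np.where(valid, arrays["mean"], 0.0),
        sd=np.where(valid, arrays["sd"], 0.0),
        lower=np.where(valid, arrays["lower"], 0.0),
        upper=np.where(valid, arrays["upper"], 0.0),
        valid=valid,
        n_subjects=info["n_subjects"],
        coverage=info["coverage"],
        layer=info["layer"],
    )


def write_deviation(dm: DeviationMap, basepath: str | Path) -> list[Path]:
    """Write a deviation map as paletted PNG plus an integer-label CSV."""
    base = Path(basepath)
    png = base.with_suffix(".png")
    img = Image.fromarray(dm.labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for label, (r, g, b) in PALETTE.items():
        palette[3 * int(label) : 3 * int(label) + 3] = [r, g, b]
    img.putpalette(palette)
    img.save(png)
    csv = base.with_suffix(".csv")
    pd.DataFrame(dm.labels.astype(int)).to_csv(csv, index=False, header=False)
    return [png, csv]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_products(
    maps: "dict[str, dict[str, EnfaceMap]] | None",
    boundaries: BoundarySet | None,
    deviations: "dict[str, DeviationMap] | None",
    outdir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write a full product set and a manifest with per-file checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if maps:
        for layer, pair in maps.items():
            for kind, m in pair.items():
                written += write_map(m, outdir / f"{layer}_{kind}")
    if boundaries is not None:
        written.append(write_boundaries(boundaries, outdir / "boundaries.csv"))
        written.append(write_boundaries(boundaries, outdir / "boundaries.json"))
    if deviations:
        for layer, dm in deviations.items():
            written += write_deviation(dm, outdir / f"{layer}_deviation")
    manifest = {
        "software": {"name": "octenface", "version": __version__},
        "config": config or {},
        "seed": seed,
        "files": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
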