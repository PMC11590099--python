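"""Round-trippable on-disk formats for every pipeline artifact.

* TCSPC stacks: NPZ archives (counts + acquisition parameters + metadata)
  or multi-page TIFF (pages = time bins) with a JSON sidecar;
* phasor images: 3-plane TIFF (g, s, photons) + JSON sidecar;
* ground truth and granule records: CSV (one row per granule, 0-based pixel
  coordinates, x before y);
* calibration curves and run manifests: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve
from .phasor import PhasorImage, TCSPCStack
from .segmentation import ISGRecord
from .simulate import CellScene

__all__ = [
    "write_stack",
    "read_stack",
    "write_phasor_image",
    "read_phasor_image",
    "write_truth_csv",
    "write_records_csv",
    "read_records_csv",
    "write_curve_json",
    "read_curve_json",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: TCSPCStack, path) -> Path:
    """Write a TCSPC stack as .npz or multi-page .tif with a JSON sidecar."""
    path = Path(path)
    meta = {
        "bin_width": stack.bin_width,
        "rep_rate": stack.rep_rate,
        "metadata": stack.metadata,
    }
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            counts=stack.counts,
            bin_width=stack.bin_width,
            rep_rate=stack.rep_rate,
            metadata=json.dumps(stack.metadata),
        )
    elif path.suffix in (".tif", ".tiff"):
        # pages = time bins
        tifffile.imwrite(path, np.moveaxis(stack.counts, 2, 0))
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    return path


def read_stack(path) -> TCSPCStack:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return TCSPCStack(
                counts=z["counts"],
                bin_width=float(z["bin_width"]),
                rep_rate=float(z["rep_rate"]),
                metadata=json.loads(str(z["metadata"])),
            )
    if path.suffix in (".tif", ".tiff"):
        counts = np.moveaxis(tifffile.imread(path), 0, 2)
        meta = json.loads(_sidecar(path).read_text())
        return TCSPCStack(
            counts=counts,
            bin_width=meta["bin_width"],
            rep_rate=meta["rep_rate"],
            metadata=meta.get("metadata", {}),
        )
    raise ValueError(f"unsupported stack format: {path.suffix}")


def write_phasor_image(image: PhasorImage, path) -> Path:
    """3-plane TIFF (g, s, photons) + JSON sidecar (harmonic, omega)."""
    path = Path(path)
    planes = np.stack([image.g, image.s, image.photons.astype(float)])
    tifffile.imwrite(path, planes.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"harmonic": image.harmonic, "omega": image.omega}, indent=1)
    )
    return path


def read_phasor_image(path) -> PhasorImage:
    path = Path(path)
    planes = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    g, s, photons = planes
    return PhasorImage(
        g=g,
        s=s,
        photons=photons,
        harmonic=int(meta["harmonic"]),
        omega=float(meta["omega"]),
        valid=photons > 0,
    )


def write_truth_csv(scene: CellScene, path) -> Path:
    """Ground-truth granule table: one row per granule."""
    rows = [
        {
            "id": gr.id,
            "x_px": gr.centroid[1],
            "y_px": gr.centroid[0],
            "diameter_nm": gr.diameter_nm,
            "true_ph": gr.true_ph,
            "mobility_nm": gr.mobility,
            "population": gr.population_label,
            "brightness": gr.brightness,
            "timepoint_min": scene.timepoint,
        }
        for gr in scene.granules
    ]
    pd.DataFrame(
        rows,
        columns=[
            "id", "x_px", "y_px", "diameter_nm", "true_ph",
            "mobility_nm", "population", "brightness", "timepoint_min",
        ],
    ).to_csv(path, index=False)
    return Path(path)


_RECORD_COLUMNS = [
    "granule_id", "cell_id", "timepoint_min", "x_px", "y_px",
    "percent_protonation", "ph", "norm_distance", "photons",
    "phasor_iqr", "qc_pass", "ph_valid",
]


def write_records_csv(records: list[ISGRecord], path) -> Path:
    rows = [
        {
            "granule_id": r.granule_id,
            "cell_id": r.cell_id,
            "timepoint_min": r.timepoint,
            "x_px": r.centroid[1],
            "y_px": r.centroid[0],
            "percent_protonation": r.percent_protonation,
            "ph": r.ph,
            "norm_distance": r.norm_distance,
            "photons": r.photons,
            "phasor_iqr": r.phasor_iqr,
            "qc_pass": r.qc_pass,
            "ph_valid": r.ph_valid,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_records_csv(path) -> list[ISGRecord]:
    df = pd.read_csv(path)
    return [
        ISGRecord(
            granule_id=int(row.granule_id),
            cell_id=int(row.cell_id),
            timepoint=float(row.timepoint_min),
            centroid=(float(row.y_px), float(row.x_px)),
            percent_protonation=float(row.percent_protonation),
            ph=float(row.ph),
            norm_distance=float(row.norm_distance),
            photons=float(row.photons),
            phasor_iqr=float(row.phasor_iqr),
            qc_pass=bool(row.qc_pass),
            ph_valid=bool(row.ph_valid),
        )
        for row in df.itertuples()
    ]


def write_curve_json(curve: CalibrationCurve, path) -> Path:
    Path(path).write_text(
        json.dumps(
            {
                "poly_coeffs": list(map(float, curve.poly_coeffs)),
                "apparent_pka": curve.apparent_pka,
                "valid_range": list(curve.valid_range),
                "provenance": curve.provenance,
            },
            indent=1,
        )
    )
    return Path(path)


def read_curve_json(path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(
        poly_coeffs=np.asarray(d["poly_coeffs"], float),
        apparent_pka=float(d["apparent_pka"]),
        valid_range=tuple(d["valid_range"]),
        provenance=d.get("provenance", {}),
    )


def write_manifest(path, **entries) -> Path:
    """Run manifest: parameters, seeds and package version, as JSON."""
    from . import __version__

    payload = {"phasorph_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
    return Path(path)
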