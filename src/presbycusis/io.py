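"""File formats: threshold CSV, marker CSV / Cell Counter XML, ROI CSV, TIFF.

All CSVs are comma-separated UTF-8 with "." decimals.  Coordinates are
0-based pixel centers with y increasing downward.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .abr import LEVEL_MAX_DB, STANDARD_FREQUENCIES_KHZ, ThresholdGrid
from .cochleogram import MARKER_TYPES, Cytocochleogram, Marker, PlaceFrequencyMap, SegmentTrace
from .fluorquant import FluorImage, RoiSpec

NO_RESPONSE_TOKEN = "NR"

THRESHOLD_COLUMNS = (["subject_id", "ear", "age_days", "age_group"]
                     + [f"thr_{f}" for f in STANDARD_FREQUENCIES_KHZ])


class FormatError(ValueError):
    """Malformed input file; message carries line numbers."""


# ---------------------------------------------------------------------------
# Threshold CSV
# ---------------------------------------------------------------------------

def write_threshold_csv(grids: list[ThresholdGrid], path) -> None:
    rows = []
    for g in grids:
        row = {"subject_id": g.subject_id, "ear": g.ear,
               "age_days": g.age_days, "age_group": g.age_group}
        for f, t, nr in zip(g.frequencies_khz, g.thresholds_db, g.no_response):
            row[f"thr_{f}"] = NO_RESPONSE_TOKEN if nr else (
                "" if math.isnan(t) else f"{t:g}")
        rows.append(row)
    pd.DataFrame(rows, columns=THRESHOLD_COLUMNS).to_csv(path, index=False)


def read_threshold_csv(path, no_response_db: float = LEVEL_MAX_DB) -> list[ThresholdGrid]:
    """Read one grid per row; "NR" cells become flagged no-response thresholds
    at the ceiling level.  Malformed rows are reported with line numbers."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c.startswith("thr_")
                   and c not in THRESHOLD_COLUMNS]
        if unknown:
            raise FormatError(f"{path.name}: unknown frequency columns {unknown}")
        missing = [c for c in THRESHOLD_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path.name}: missing columns {missing}")
        grids, errors = [], []
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in THRESHOLD_COLUMNS):
                errors.append(f"line {lineno}: truncated row")
                continue
            try:
                thr, nr = [], []
                for f in STANDARD_FREQUENCIES_KHZ:
                    cell = row[f"thr_{f}"].strip()
                    if cell == NO_RESPONSE_TOKEN:
                        thr.append(no_response_db)
                        nr.append(True)
                    elif cell == "":
                        thr.append(math.nan)
                        nr.append(False)
                    else:
                        thr.append(float(cell))
                        nr.append(False)
                grids.append(ThresholdGrid(
                    row["subject_id"], row["ear"], float(row["age_days"]),
                    row["age_group"], np.array(thr), np.array(nr)))
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path.name}: " + "; ".join(errors))
    return grids


# ---------------------------------------------------------------------------
# Marker CSV (PATH rows define the polyline) and Cell Counter XML
# ---------------------------------------------------------------------------

MARKER_CSV_COLUMNS = ("segment", "type", "x", "y", "order")


def write_marker_csv(traces: list[SegmentTrace], path) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.path):
            rows.append((t.label, "PATH", x, y, i))
        for i, m in enumerate(t.markers):
            rows.append((t.label, m.type, m.x, m.y, i))
    pd.DataFrame(rows, columns=MARKER_CSV_COLUMNS).to_csv(path, index=False)


def write_invalid_spans_csv(traces: list[SegmentTrace], path) -> None:
    rows = [(t.label, a, b) for t in traces for a, b in t.invalid_spans_um]
    pd.DataFrame(rows, columns=["segment", "start_um", "end_um"]).to_csv(
        path, index=False)


def read_marker_csv(path, scale_um_per_px: float = 1.0,
                    invalid_spans: dict[str, list[tuple[float, float]]] | None = None,
                    ) -> list[SegmentTrace]:
    """Read segment traces: PATH rows (sorted by ``order``) are the polyline;
    other rows are typed cell markers."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MARKER_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    bad = set(df["type"]) - set(MARKER_TYPES) - {"PATH"}
    if bad:
        raise FormatError(f"{path.name}: unknown marker types {sorted(bad)}")
    traces = []
    for seg, sub in df.groupby("segment", sort=False):
        pts = sub[sub["type"] == "PATH"].sort_values("order")
        if len(pts) < 2:
            raise FormatError(f"{path.name}: segment {seg!r} has <2 PATH points")
        markers = [Marker(r.type, float(r.x), float(r.y))
                   for r in sub[sub["type"] != "PATH"].itertuples()]
        spans = (invalid_spans or {}).get(str(seg), [])
        traces.append(SegmentTrace(str(seg), pts[["x", "y"]].to_numpy(float),
                                   scale_um_per_px, markers, spans))
    return traces


def read_invalid_spans_csv(path) -> dict[str, list[tuple[float, float]]]:
    df = pd.read_csv(path)
    out: dict[str, list[tuple[float, float]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.segment), []).append((float(r.start_um), float(r.end_um)))
    return out


def read_cellcounter_xml(path, type_map: dict[int, str]) -> list[Marker]:
    """Parse an ImageJ Cell Counter XML file into typed markers.

    ``type_map`` maps the plugin's numeric marker types to OHC/OHx/IHC/IHx.
    The polyline is not part of this format and must come from a marker CSV.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    markers, unmapped = [], set()
    for mt in root.iter("Marker_Type"):
        type_el = mt.find("Type")
        if type_el is None:
            continue
        code = int(type_el.text)
        for mk in mt.iter("Marker"):
            x = float(mk.findtext("MarkerX"))
            y = float(mk.findtext("MarkerY"))
            if code not in type_map:
                unmapped.add(code)
                continue
            markers.append(Marker(type_map[code], x, y))
    if unmapped:
        raise FormatError(
            f"{path.name}: unmapped Cell Counter marker types {sorted(unmapped)}")
    return markers


def write_cellcounter_xml(markers: list[Marker], path,
                          type_map: dict[int, str]) -> None:
    root = ET.Element("CellCounter_Marker_File")
    data = ET.SubElement(root, "Marker_Data")
    for code, tok in sorted(type_map.items()):
        mt = ET.SubElement(data, "Marker_Type")
        ET.SubElement(mt, "Type").text = str(code)
        for m in markers:
            if m.type == tok:
                mk = ET.SubElement(mt, "Marker")
                ET.SubElement(mk, "MarkerX").text = f"{m.x:.10g}"
                ET.SubElement(mk, "MarkerY").text = f"{m.y:.10g}"
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Cytocochleogram CSV, ROI CSV, TIFF
# ---------------------------------------------------------------------------

def write_cytocochleogram_csv(cyto: Cytocochleogram, pfmap: PlaceFrequencyMap,
                              path) -> None:
    t = cyto.table.copy()
    centers = (t["bin_start"] + t["bin_end"]) / 2.0
    t["center_freq_khz"] = pfmap.to_frequency(centers.to_numpy())
    t.rename(columns={"cell_class": "class"}).to_csv(path, index=False)


ROI_CSV_COLUMNS = ("kind", "cx", "cy", "diameter", "x0", "y0", "width", "height")


def write_roi_csv(rois: list[RoiSpec], path) -> None:
    rows = [(r.kind, r.cx, r.cy, r.diameter, r.x0, r.y0, r.width, r.height)
            for r in rois]
    pd.DataFrame(rows, columns=ROI_CSV_COLUMNS).to_csv(path, index=False)


def read_roi_csv(path) -> list[RoiSpec]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("kind",) if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    rois = []
    for r in df.itertuples():
        if r.kind == "circle":
            rois.append(RoiSpec("circle", cx=float(r.cx), cy=float(r.cy),
                                diameter=float(r.diameter)))
        elif r.kind == "rectangle":
            rois.append(RoiSpec("rectangle", x0=float(r.x0), y0=float(r.y0),
                                width=float(r.width), height=float(r.height)))
        else:
            raise FormatError(f"{path.name}: unknown ROI kind {r.kind!r}")
    return rois


def read_tiff(path, bit_depth: int | None = None, channel: str = "") -> FluorImage:
    import tifffile

    data = tifffile.imread(path)
    if data.ndim != 2:
        raise FormatError(f"{Path(path).name}: expected a single-channel 2D TIFF")
    if bit_depth is None:
        bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return FluorImage(data, bit_depth, channel)


def write_tiff(image: FluorImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, image.data)
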