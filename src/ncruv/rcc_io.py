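"""Reading and writing NanoString RCC lane files and count-matrix CSVs.

An RCC file is the per-lane text format emitted by nCounter instruments:
sectioned INI-like blocks ``<Header>``, ``<Sample_Attributes>``,
``<Lane_Attributes>`` and a ``<Code_Summary>`` CSV block with one
``CodeClass,Name,Accession,Count`` row per probe.  One file corresponds to
one assay (one sample in one lane of one cartridge).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ncruv.core_data import CountMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


class RCCFormatError(ValueError):
    """Raised when an RCC file violates the lane-file format."""


@dataclass
class ProbeRecord:
    code_class: str  # Endogenous | Housekeeping | Negative | Positive
    name: str
    accession: str
    count: int


@dataclass
class RCCLane:
    """One parsed RCC lane: header/lane metadata plus ordered probe records."""

    sample_id: str
    lane_attributes: dict[str, str] = field(default_factory=dict)
    sample_attributes: dict[str, str] = field(default_factory=dict)
    header: dict[str, str] = field(default_factory=dict)
    probe_records: list[ProbeRecord] = field(default_factory=list)


# CodeClass strings vary across CodeSet versions; normalise case-insensitively.
_CLASS_MAP = {
    "housekeeping": "Housekeeping",
    "control": "Housekeeping",
    "hk": "Housekeeping",
    "negative": "Negative",
    "positive": "Positive",
}


def map_code_class(raw: str) -> str:
    """Map an RCC CodeClass string to the four canonical classes.

    Unrecognised classes (including 'Endogenous1' style variants) fall back
    to Endogenous.
    """
    return _CLASS_MAP.get(raw.strip().lower(), "Endogenous")


_SECTION_RE = re.compile(r"^<\s*(/?)\s*([A-Za-z_]+)\s*>\s*$")


def parse_rcc(path) -> RCCLane:
    """Parse one RCC lane file.

    Raises :class:`RCCFormatError` if the Code_Summary section is missing or
    empty, or if any count field is not a non-negative integer.
    """
    path = Path(path)
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        m = _SECTION_RE.match(line)
        if m:
            closing, name = m.group(1), m.group(2)
            current = None if closing else name
            if current is not None:
                sections.setdefault(current, [])
            continue
        if current is not None and line:
            sections[current].append(line)

    if "Code_Summary" not in sections:
        raise RCCFormatError(f"{path}: missing Code_Summary section")

    def kv(section: str) -> dict[str, str]:
        out = {}
        for line in sections.get(section, []):
            key, _, value = line.partition(",")
            out[key] = value
        return out

    header = kv("Header")
    sample_attrs = kv("Sample_Attributes")
    lane_attrs = kv("Lane_Attributes")

    rows = sections["Code_Summary"]
    if rows and rows[0].lower().startswith("codeclass"):
        rows = rows[1:]
    if not rows:
        raise RCCFormatError(f"{path}: Code_Summary section has no probe rows")

    records: list[ProbeRecord] = []
    seen = set()
    for lineno, row in enumerate(rows, start=1):
        parts = row.split(",")
        if len(parts) != 4:
            raise RCCFormatError(
                f"{path}: Code_Summary row {lineno} has {len(parts)} fields, expected 4"
            )
        raw_class, name, accession, count_str = (p.strip() for p in parts)
        if not re.fullmatch(r"\d+", count_str):
            raise RCCFormatError(
                f"{path}: probe {name!r} (Code_Summary row {lineno}) has "
                f"non-integer count {count_str!r}"
            )
        if name in seen:
            raise RCCFormatError(f"{path}: duplicated probe name {name!r}")
        seen.add(name)
        records.append(ProbeRecord(map_code_class(raw_class), name, accession, int(count_str)))

    lane_no = lane_attrs.get("ID")
    if lane_no is not None and lane_no.isdigit() and not 1 <= int(lane_no) <= 12:
        raise RCCFormatError(f"{path}: lane number {lane_no} outside 1..12")

    sample_id = sample_attrs.get("ID") or path.stem
    return RCCLane(
        sample_id=sample_id,
        lane_attributes=lane_attrs,
        sample_attributes=sample_attrs,
        header=header,
        probe_records=records,
    )


def write_rcc(lane: RCCLane, path) -> None:
    """Write a lane back out in the standard sectioned format."""
    path = Path(path)
    lines: list[str] = []

    def block(name: str, mapping: dict[str, str]) -> None:
        lines.append(f"<{name}>")
        for k, v in mapping.items():
            lines.append(f"{k},{v}")
        lines.append(f"</{name}>")
        lines.append("")

    block("Header", lane.header or {"FileVersion": "1.7", "SoftwareVersion": "ncruv"})
    sample_attrs = dict(lane.sample_attributes)
    sample_attrs.setdefault("ID", lane.sample_id)
    block("Sample_Attributes", sample_attrs)
    block("Lane_Attributes", lane.lane_attributes)
    lines.append("<Code_Summary>")
    lines.append("CodeClass,Name,Accession,Count")
    for rec in lane.probe_records:
        lines.append(f"{rec.code_class},{rec.name},{rec.accession},{rec.count}")
    lines.append("</Code_Summary>")
    lines.append("")
    path.write_text("\n".join(lines))


def assemble_matrix(
    lanes: list[RCCLane], reorder: bool = False
) -> tuple[CountMatrix, ProbeAnnotation]:
    """Stack lanes into a samples x probes count matrix.

    All lanes must share an identical ordered probe list (name and code
    class); pass ``reorder=True`` to instead match probes by name across
    lanes.  Silent reordering is a classic corruption source, so strict
    order checking is the default.
    """
    if not lanes:
        raise ValueError("no lanes given")
    ref = [(r.name, r.code_class) for r in lanes[0].probe_records]
    ordered_lanes = []
    for lane in lanes:
        key = [(r.name, r.code_class) for r in lane.probe_records]
        if key == ref:
            ordered_lanes.append(lane.probe_records)
            continue
        if not reorder:
            ref_names = [k[0] for k in ref]
            names = [k[0] for k in key]
            if sorted(ref_names) == sorted(names):
                first = next(
                    n for n, r in zip(names, ref_names) if n != r
                )
                raise ValueError(
                    f"lane {lane.sample_id!r}: probe order differs starting at "
                    f"{first!r}; pass reorder=True to match probes by name"
                )
            discordant = next(
                iter(set(ref_names).symmetric_difference(names))
            )
            raise ValueError(
                f"lane {lane.sample_id!r}: probe set mismatch (first discordant "
                f"probe: {discordant!r})"
            )
        by_name = {r.name: r for r in lane.probe_records}
        try:
            reordered = [by_name[name] for name, _ in ref]
        except KeyError as e:
            raise ValueError(
                f"lane {lane.sample_id!r}: probe set mismatch (first discordant "
                f"probe: {e.args[0]!r})"
            ) from None
        ordered_lanes.append(reordered)

    values = np.array(
        [[rec.count for rec in records] for records in ordered_lanes], dtype=float
    )
    counts = CountMatrix(values, [lane.sample_id for lane in lanes], [n for n, _ in ref])
    annotation = ProbeAnnotation([n for n, _ in ref], [c for _, c in ref])
    return counts, annotation


# ---------------------------------------------------------------------------
# count-matrix CSV: header row = probe names, optional second header row of
# code classes (first cell "CodeClass"), first column = sample ids.

_CODE_CLASS_SENTINEL = "CodeClass"


def write_count_csv(counts: CountMatrix, annotation: ProbeAnnotation | None, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id," + ",".join(counts.probe_names) + "\n")
        if annotation is not None:
            if annotation.probe_names != counts.probe_names:
                raise ValueError("annotation probe names differ from matrix columns")
            fh.write(_CODE_CLASS_SENTINEL + "," + ",".join(annotation.code_classes) + "\n")
        for sid, row in zip(counts.sample_ids, counts.values):
            fh.write(sid + "," + ",".join(_format_number(v) for v in row) + "\n")


def _format_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_count_csv(path) -> tuple[CountMatrix, ProbeAnnotation]:
    """Read a samples x probes CSV; defaults all probes to Endogenous when no
    code-class row is present (logged as a warning)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicated probe column")
    df = pd.read_csv(path, header=0, index_col=0, dtype=str)
    df.columns = header
    probe_names = header
    if len(df.index) and str(df.index[0]) == _CODE_CLASS_SENTINEL:
        classes = [str(c) for c in df.iloc[0]]
        annotation = ProbeAnnotation(probe_names, [map_code_class(c) for c in classes])
        df = df.iloc[1:]
    else:
        logger.warning("%s: no code-class row; defaulting all probes to Endogenous", path)
        annotation = ProbeAnnotation(probe_names, ["Endogenous"] * len(probe_names))
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicated sample identifier")
    values = df.to_numpy(dtype=float)
    return CountMatrix(values, sample_ids, probe_names), annotation
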