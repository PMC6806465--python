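"""Automated acquisition sequences and their XML serialization.

Two canonical templates drive the weekly single-setup workflow:

* ``planar`` — four control points at the cardinal gantry angles, each
  acquiring MV and kV simultaneously (MV 100x100 mm MLC field, kV
  110x110 mm blades);
* ``winston_lutz`` — twelve 2.5 MV control points with a 25x25 mm field:
  gantry 0/45/90/180/225/270 at collimator and couch 0, collimator 45/315
  at gantry 0, and couch 45/90/315/270 at gantry 0.

Sequences are written as a small documented XML dialect (a ``sequence``
element holding ``controlPoint`` elements; schema shipped as
``acquisition_sequence.xsd``).  The dialect is deliberately minimal and is
*not* ingestible by any treatment machine — it preserves the automation
artifact in an inspectable, lossless, versioned form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from lxml import etree

from .errors import ConfigError, XMLFormatError
from .phantom import FieldAperture, KV_FIELD_MM, MV_FIELD_MM, WL_FIELD_MM

__all__ = ["ControlPoint", "AcquisitionSequence", "build_sequence",
           "export_sequence_xml", "import_sequence_xml"]

SCHEMA_VERSION = "1.0"
_VALID_MODES = ("MV", "kV", "MV+kV")


@dataclass(frozen=True)
class ControlPoint:
    """One acquisition: machine angles, imaging mode, field and beam quality."""

    gantry_deg: float
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    imaging_mode: str = "MV"
    field: FieldAperture = field(default_factory=lambda: FieldAperture(100.0, 100.0))
    beam_quality: str = "6MV"

    def __post_init__(self) -> None:
        for name in ("gantry_deg", "collimator_deg", "couch_deg"):
            v = float(getattr(self, name))
            if not (0.0 <= v < 360.0):
                raise ConfigError(f"{name}={v} outside [0, 360)")
        if self.imaging_mode not in _VALID_MODES:
            raise ConfigError(f"imaging_mode must be one of {_VALID_MODES}")


@dataclass(frozen=True)
class AcquisitionSequence:
    name: str
    control_points: tuple
    metadata: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_points", tuple(self.control_points))


def build_sequence(kind: str) -> AcquisitionSequence:
    """Return one of the canonical acquisition templates.

    ``planar`` gives the 4-point cardinal-angle MV+kV sequence;
    ``winston_lutz`` the 12-point ball-and-field sequence.  Templates are
    constants: building twice yields identical sequences.
    """
    if kind == "planar":
        cps = tuple(
            ControlPoint(gantry_deg=g, imaging_mode="MV+kV",
                         field=FieldAperture(MV_FIELD_MM, MV_FIELD_MM),
                         beam_quality="MV/90kVp")
            for g in (0.0, 90.0, 180.0, 270.0))
        meta = ("Four cardinal-angle MV+kV pairs from a single phantom setup; "
                f"MV MLC {MV_FIELD_MM:.0f} mm, kV blades {KV_FIELD_MM:.0f} mm.")
        return AcquisitionSequence("planar", cps, meta)
    if kind == "winston_lutz":
        wl = FieldAperture(WL_FIELD_MM, WL_FIELD_MM)

        def cp(g=0.0, c=0.0, t=0.0):
            return ControlPoint(gantry_deg=g, collimator_deg=c, couch_deg=t,
                                imaging_mode="MV", field=wl,
                                beam_quality="2.5MV")

        cps = tuple(
            [cp(g=g) for g in (0.0, 45.0, 90.0, 180.0, 225.0, 270.0)]
            + [cp(c=c) for c in (45.0, 315.0)]
            + [cp(t=t) for t in (45.0, 90.0, 315.0, 270.0)])
        meta = ("Twelve-image ball-and-field series: gantry sweep at "
                "couch/collimator 0, collimator 45/315 at gantry 0, couch "
                "45/90/315/270 at gantry 0; 2.5 MV, 25 mm MLC field.")
        return AcquisitionSequence("winston_lutz", cps, meta)
    raise ConfigError(f"unknown sequence kind {kind!r}")


def _schema() -> etree.XMLSchema:
    text = (resources.files("isoqa") / "acquisition_sequence.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def export_sequence_xml(seq: AcquisitionSequence, destination) -> Path:
    """Serialize a sequence to the documented XML dialect (UTF-8)."""
    root = etree.Element("sequence", name=seq.name, schemaVersion=SCHEMA_VERSION)
    if seq.metadata:
        meta = etree.SubElement(root, "metadata")
        meta.text = seq.metadata
    for p in seq.control_points:
        etree.SubElement(
            root, "controlPoint",
            gantry=repr(p.gantry_deg), collimator=repr(p.collimator_deg),
            couch=repr(p.couch_deg), imagingMode=p.imaging_mode,
            fieldWidth=repr(p.field.width_mm), fieldHeight=repr(p.field.height_mm),
            penumbraSigma=repr(p.field.penumbra_sigma_mm),
            beamQuality=p.beam_quality)
    _schema().assertValid(root)
    dest = Path(destination)
    dest.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="UTF-8", pretty_print=True))
    return dest


def import_sequence_xml(source) -> AcquisitionSequence:
    """Parse and validate a sequence document; lossless vs export."""
    try:
        tree = etree.parse(str(source))
    except etree.XMLSyntaxError as exc:
        raise XMLFormatError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    schema = _schema()
    if not schema.validate(root):
        raise XMLFormatError(f"schema validation failed: {schema.error_log}")
    meta_el = root.find("metadata")
    cps = []
    for el in root.findall("controlPoint"):
        try:
            cps.append(ControlPoint(
                gantry_deg=float(el.get("gantry")),
                collimator_deg=float(el.get("collimator")),
                couch_deg=float(el.get("couch")),
                imaging_mode=el.get("imagingMode"),
                field=FieldAperture(float(el.get("fieldWidth")),
                                    float(el.get("fieldHeight")),
                                    float(el.get("penumbraSigma"))),
                beam_quality=el.get("beamQuality")))
        except ConfigError as exc:
            line = el.sourceline
            raise XMLFormatError(f"invalid controlPoint at line {line}: {exc}") from exc
    return AcquisitionSequence(name=root.get("name"),
                               control_points=tuple(cps),
                               metadata=(meta_el.text or "") if meta_el is not None else "")
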