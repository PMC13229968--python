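"""Organ-level plant architecture data model and its XML dialect.

The shoot system is modelled the way functional-structural plant models do:
the repeating unit is the *phytomer* — one internode carrying one petiole and
its leaf or leaflets. Phytomers stack end-to-end into shoots, and shoots nest
into a branching hierarchy up to order 3 (primary shoot = order 0). Cowpea's
first node carries a pair of unifoliate leaves on one petiole; every later
phytomer is trifoliate (three leaflets per petiole).

One plant per XML document. All angles are stored in degrees, lengths in
metres; floats are serialized with 6 significant digits so that canonical
documents round-trip byte-identically.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

__all__ = [
    "ParameterSpec",
    "Leaf",
    "Petiole",
    "Internode",
    "Phytomer",
    "Shoot",
    "PlantArchitecture",
    "PlantMetadata",
    "ValidationError",
    "TopologyError",
    "XMLDialectError",
    "read_architecture_xml",
    "write_architecture_xml",
    "validate_architecture",
]

MAX_BRANCHING_ORDER = 3

UNIFOLIATE = 1
TRIFOLIATE = 3


class ValidationError(ValueError):
    """A plant violates a data-model invariant."""


class TopologyError(ValueError):
    """Shoot parent references are dangling, cyclic or mis-ordered."""


class XMLDialectError(ValueError):
    """The document is not in the documented plant-architecture dialect."""


@dataclass(frozen=True)
class ParameterSpec:
    """One architectural parameter's sampling rule.

    ``distribution`` is one of ``constant`` (args = (value,)), ``uniform``
    (args = (low, high), low < high) or ``normal`` (args = (mean, sd), sd > 0).
    ``context`` selects the leaf-composition variant the rule applies to:
    ``unifoliate``, ``trifoliate`` or ``both``. ``units`` is one of
    deg / m / days / index / dimensionless.
    """

    name: str
    distribution: str
    args: tuple[float, ...]
    context: str = "both"
    units: str = "dimensionless"

    def __post_init__(self):
        if self.distribution not in ("constant", "uniform", "normal"):
            raise ValueError(f"{self.name}: unknown distribution '{self.distribution}'")
        if self.distribution == "constant" and len(self.args) != 1:
            raise ValueError(f"{self.name}: constant takes exactly one argument")
        if self.distribution == "uniform":
            if len(self.args) != 2 or not self.args[0] < self.args[1]:
                raise ValueError(f"{self.name}: uniform requires low < high")
        if self.distribution == "normal":
            if len(self.args) != 2 or not self.args[1] > 0:
                raise ValueError(f"{self.name}: normal requires sd > 0")
        if self.context not in ("unifoliate", "trifoliate", "both"):
            raise ValueError(f"{self.name}: unknown context '{self.context}'")


@dataclass
class Leaf:
    scale: float            # dimensionless lamina scale, > 0
    pitch: float            # deg
    yaw: float              # deg
    roll: float             # deg


@dataclass
class Petiole:
    length: float           # m, > 0
    radius: float           # m, > 0
    pitch: float            # deg
    curvature: float        # signed bend over the petiole length (raw number)
    leaflet_scale: float | None = None   # trifoliate only


@dataclass
class Internode:
    length: float           # m, > 0
    radius: float           # m, > 0
    pitch: float            # deg
    phyllotactic_angle: float  # deg, azimuth increment along the shoot


@dataclass
class Phytomer:
    internode: Internode
    petiole: Petiole
    leaves: list[Leaf]      # 2 unifoliate leaves, or 3 trifoliate leaflets

    @property
    def is_trifoliate(self) -> bool:
        return len(self.leaves) == 3


@dataclass
class Shoot:
    shoot_id: int
    parent_shoot_id: int        # -1 for the primary shoot
    parent_node_index: int      # 0-based phytomer index on the parent; -1 for primary
    branching_order: int        # 0..3
    shoot_type_label: int       # 1 unifoliate, 3 trifoliate
    base_pitch: float           # deg
    base_yaw: float             # deg
    base_roll: float            # deg
    phytomers: list[Phytomer] = field(default_factory=list)


@dataclass
class PlantArchitecture:
    base_position: tuple[float, float, float]    # m
    base_rotation: tuple[float, float, float]    # (pitch, yaw, roll) deg
    plant_age: float                             # days >= 0
    shoots: list[Shoot] = field(default_factory=list)   # depth-first order


@dataclass
class PlantMetadata:
    """Plant-level image-window metadata carried in the token preamble."""

    width_m: float
    height_m: float
    vegetation_fraction: float   # fraction of the top-view window covered


def _fmt(x: float) -> str:
    """6-significant-digit float formatting, locale independent."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(float(x), ".6g")


def validate_architecture(plant: PlantArchitecture) -> list[str]:
    """Check every data-model invariant; violations are data, not exceptions.

    Returns a list of human-readable violation strings, each naming the organ
    path (e.g. ``shoot[2].phytomer[0].petiole``). Empty list means valid.
    """
    v: list[str] = []
    if plant.plant_age < 0:
        v.append(f"plant: plant_age {plant.plant_age} < 0")
    roots = [s for s in plant.shoots if s.parent_shoot_id == -1]
    if len(roots) != 1:
        v.append(f"plant: expected exactly one primary shoot, found {len(roots)}")
    seen: dict[int, Shoot] = {}
    for i, s in enumerate(plant.shoots):
        path = f"shoot[{i}](id={s.shoot_id})"
        if s.shoot_id in seen:
            v.append(f"{path}: duplicate shoot_id")
        if not (0 <= s.branching_order <= MAX_BRANCHING_ORDER):
            v.append(f"{path}: branching_order {s.branching_order} outside 0..{MAX_BRANCHING_ORDER}")
        if s.shoot_type_label not in (UNIFOLIATE, TRIFOLIATE):
            v.append(f"{path}: shoot_type_label {s.shoot_type_label} not in {{1, 3}}")
        if s.parent_shoot_id == -1:
            if s.branching_order != 0:
                v.append(f"{path}: primary shoot must have branching_order 0")
        else:
            parent = seen.get(s.parent_shoot_id)
            if parent is None:
                v.append(f"{path}: parent_shoot_id {s.parent_shoot_id} dangling or ordered after child")
            else:
                if s.branching_order != parent.branching_order + 1:
                    v.append(f"{path}: branching_order must be parent's + 1")
                if not (0 <= s.parent_node_index < max(len(parent.phytomers), 1)):
                    v.append(f"{path}: parent_node_index {s.parent_node_index} outside parent's phytomers")
        seen[s.shoot_id] = s
        for j, ph in enumerate(s.phytomers):
            ppath = f"{path}.phytomer[{j}]"
            n_leaves = len(ph.leaves)
            if n_leaves == 3:
                if ph.petiole.leaflet_scale is None:
                    v.append(f"{ppath}.petiole: trifoliate phytomer missing leaflet_scale")
            elif n_leaves == 2:
                if ph.petiole.leaflet_scale is not None:
                    v.append(f"{ppath}.petiole: unifoliate phytomer carries leaflet_scale")
            else:
                v.append(f"{ppath}: expected 2 (unifoliate) or 3 (trifoliate) leaves, found {n_leaves}")
            if ph.internode.length <= 0:
                v.append(f"{ppath}.internode: length {ph.internode.length} <= 0")
            if ph.internode.radius <= 0:
                v.append(f"{ppath}.internode: radius {ph.internode.radius} <= 0")
            if ph.petiole.length <= 0:
                v.append(f"{ppath}.petiole: length {ph.petiole.length} <= 0")
            if ph.petiole.radius <= 0:
                v.append(f"{ppath}.petiole: radius {ph.petiole.radius} <= 0")
            for k, leaf in enumerate(ph.leaves):
                if leaf.scale <= 0:
                    v.append(f"{ppath}.leaf[{k}]: scale {leaf.scale} <= 0")
            for name, val in (("internode.length", ph.internode.length),
                              ("petiole.length", ph.petiole.length)):
                if not math.isfinite(val):
                    v.append(f"{ppath}.{name}: non-finite value")
    return v


def write_architecture_xml(plant: PlantArchitecture) -> str:
    """Serialize a plant to the documented XML dialect.

    Deterministic: fixed element and attribute order, floats at 6 significant
    digits. Raises :class:`ValidationError` if the plant breaks an invariant.
    """
    violations = validate_architecture(plant)
    if violations:
        raise ValidationError("invalid plant architecture: " + "; ".join(violations[:5]))
    root = ET.Element("plant_architecture", {"age": _fmt(plant.plant_age)})
    x, y, z = plant.base_position
    ET.SubElement(root, "base_position", {"x": _fmt(x), "y": _fmt(y), "z": _fmt(z)})
    p, yw, r = plant.base_rotation
    ET.SubElement(root, "base_rotation", {"pitch": _fmt(p), "yaw": _fmt(yw), "roll": _fmt(r)})
    for s in plant.shoots:
        se = ET.SubElement(root, "shoot", {
            "id": str(s.shoot_id),
            "parent_shoot": str(s.parent_shoot_id),
            "parent_node": str(s.parent_node_index),
            "type": str(s.shoot_type_label),
            "order": str(s.branching_order),
            "base_pitch": _fmt(s.base_pitch),
            "base_yaw": _fmt(s.base_yaw),
            "base_roll": _fmt(s.base_roll),
        })
        for ph in s.phytomers:
            pe = ET.SubElement(se, "phytomer")
            ET.SubElement(pe, "internode", {
                "length": _fmt(ph.internode.length),
                "radius": _fmt(ph.internode.radius),
                "pitch": _fmt(ph.internode.pitch),
                "phyllotactic_angle": _fmt(ph.internode.phyllotactic_angle),
            })
            pet_attrs = {
                "length": _fmt(ph.petiole.length),
                "radius": _fmt(ph.petiole.radius),
                "pitch": _fmt(ph.petiole.pitch),
                "curvature": _fmt(ph.petiole.curvature),
            }
            if ph.petiole.leaflet_scale is not None:
                pet_attrs["leaflet_scale"] = _fmt(ph.petiole.leaflet_scale)
            ET.SubElement(pe, "petiole", pet_attrs)
            for leaf in ph.leaves:
                ET.SubElement(pe, "leaf", {
                    "scale": _fmt(leaf.scale),
                    "pitch": _fmt(leaf.pitch),
                    "yaw": _fmt(leaf.yaw),
                    "roll": _fmt(leaf.roll),
                })
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def _req(elem: ET.Element, attr: str, conv=float):
    val = elem.get(attr)
    if val is None:
        raise XMLDialectError(f"element <{elem.tag}> missing required attribute '{attr}'")
    try:
        return conv(val)
    except ValueError as exc:
        raise XMLDialectError(f"element <{elem.tag}> attribute '{attr}': {exc}") from None


def read_architecture_xml(text: str) -> PlantArchitecture:
    """Parse a plant-architecture document; inverse of :func:`write_architecture_xml`.

    Raises ``xml.etree.ElementTree.ParseError`` (with line/column) on malformed
    XML, :class:`XMLDialectError` on missing elements/attributes, and
    :class:`TopologyError` on dangling parent references.
    """
    root = ET.fromstring(text)
    if root.tag != "plant_architecture":
        raise XMLDialectError(f"expected root <plant_architecture>, found <{root.tag}>")
    pos_e = root.find("base_position")
    rot_e = root.find("base_rotation")
    if pos_e is None or rot_e is None:
        raise XMLDialectError("missing <base_position> or <base_rotation>")
    plant = PlantArchitecture(
        base_position=(_req(pos_e, "x"), _req(pos_e, "y"), _req(pos_e, "z")),
        base_rotation=(_req(rot_e, "pitch"), _req(rot_e, "yaw"), _req(rot_e, "roll")),
        plant_age=_req(root, "age"),
        shoots=[],
    )
    seen_ids: set[int] = set()
    for se in root.iter("shoot"):
        s = Shoot(
            shoot_id=_req(se, "id", int),
            parent_shoot_id=_req(se, "parent_shoot", int),
            parent_node_index=_req(se, "parent_node", int),
            branching_order=_req(se, "order", int),
            shoot_type_label=_req(se, "type", int),
            base_pitch=_req(se, "base_pitch"),
            base_yaw=_req(se, "base_yaw"),
            base_roll=_req(se, "base_roll"),
        )
        if s.parent_shoot_id != -1 and s.parent_shoot_id not in seen_ids:
            raise TopologyError(
                f"shoot {s.shoot_id}: parent_shoot {s.parent_shoot_id} "
                "is dangling or appears after its child")
        seen_ids.add(s.shoot_id)
        for pe in se.iter("phytomer"):
            ie = pe.find("internode")
            pte = pe.find("petiole")
            if ie is None or pte is None:
                raise XMLDialectError(
                    f"shoot {s.shoot_id}: phytomer missing <internode> or <petiole>")
            leaflet = pte.get("leaflet_scale")
            petiole = Petiole(
                length=_req(pte, "length"), radius=_req(pte, "radius"),
                pitch=_req(pte, "pitch"), curvature=_req(pte, "curvature"),
                leaflet_scale=float(leaflet) if leaflet is not None else None,
            )
            leaves = [Leaf(scale=_req(le, "scale"), pitch=_req(le, "pitch"),
                           yaw=_req(le, "yaw"), roll=_req(le, "roll"))
                      for le in pe.iter("leaf")]
            s.phytomers.append(Phytomer(
                internode=Internode(
                    length=_req(ie, "length"), radius=_req(ie, "radius"),
                    pitch=_req(ie, "pitch"),
                    phyllotactic_angle=_req(ie, "phyllotactic_angle")),
                petiole=petiole,
                leaves=leaves,
            ))
        plant.shoots.append(s)
    return plant


def copy_plant(plant: PlantArchitecture) -> PlantArchitecture:
    """Deep copy via dataclass reconstruction (cheaper than copy.deepcopy)."""
    return PlantArchitecture(
        base_position=plant.base_position,
        base_rotation=plant.base_rotation,
        plant_age=plant.plant_age,
        shoots=[replace(
            s,
            phytomers=[Phytomer(internode=replace(ph.internode),
                                petiole=replace(ph.petiole),
                                leaves=[replace(l) for l in ph.leaves])
                       for ph in s.phytomers],
        ) for s in plant.shoots],
    )
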