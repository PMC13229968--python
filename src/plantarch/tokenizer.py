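"""Lossless (post-quantization) codec between plant architectures and token IDs.

A plant serializes to one flat integer sequence::

    SOS  META_OPEN w h vf META_CLOSE  p y r age  [shoot blocks...]  EOS

* the three metadata tokens are the plant's width, height (m) and top-view
  vegetation fraction, quantized on the shared grid;
* the four-token *plant header* carries the base rotation (pitch, yaw, roll)
  and plant age;
* each shoot block is its organ token followed by 4 shoot parameters, then
  its phytomers in order. A phytomer is internode (4 params), petiole
  (4 params unifoliate / 5 with leaflet_scale trifoliate) and the leaf
  tokens — the unifoliate pair as two code-3 tokens, trifoliate leaflets as
  codes 3, 4, 5 — each with 4 parameters. A child shoot's whole block is
  spliced in right after the phytomer it attaches to (depth-first), which is
  what lets the decoder rebuild parent ids and node indices from nesting
  alone.

Because organ IDs (0–23), parameter IDs (24–222) and specials (223–227) are
disjoint, the grammar is self-delimiting: the decoder reads parameter tokens
greedily after each organ token and checks the count against the organ's
schema. ``detokenize`` is exact on quantized plants, so
``tokenize ∘ detokenize ∘ tokenize == tokenize``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    Internode,
    Leaf,
    Petiole,
    Phytomer,
    PlantArchitecture,
    PlantMetadata,
    Shoot,
    TRIFOLIATE,
    UNIFOLIATE,
    copy_plant,
    validate_architecture,
)
from .vocab import (
    ORGAN_INTERNODE,
    ORGAN_LEAF_0,
    ORGAN_PETIOLE,
    ORGAN_SHOOT,
    Vocabulary,
    organ_token,
)

__all__ = [
    "TokenSequence",
    "TokenizeError",
    "DecodeError",
    "tokenize_architecture",
    "detokenize",
    "quantize_architecture",
]

# schema parameter names, in emission order, per organ kind
SHOOT_PARAMS = ("shoot_type_label", "shoot_base_pitch", "shoot_base_yaw", "shoot_base_roll")
INTERNODE_PARAMS = ("internode_length", "internode_radius", "internode_pitch",
                    "internode_phyllotactic_angle")
PETIOLE_PARAMS = ("petiole_length", "petiole_radius", "petiole_pitch", "petiole_curvature")
LEAF_PARAMS = ("leaf_scale", "leaf_pitch", "leaf_yaw", "leaf_roll")
HEADER_PARAMS = ("base_rotation_pitch", "base_rotation_yaw", "base_rotation_roll", "plant_age")
META_PARAMS = ("meta_width", "meta_height", "meta_vegetation_fraction")


class TokenizeError(ValueError):
    """The plant cannot be expressed in the token grammar."""


class DecodeError(ValueError):
    """The token sequence violates the grammar; carries the offending index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"token index {index}: {message}")


@dataclass(frozen=True)
class TokenSequence:
    """An immutable ordered list of token IDs in [0, 227]."""

    ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __getitem__(self, i):
        return self.ids[i]

    def to_line(self) -> str:
        return " ".join(str(i) for i in self.ids)

    @classmethod
    def from_line(cls, line: str) -> "TokenSequence":
        return cls(tuple(int(t) for t in line.split()))


def quantize_architecture(plant: PlantArchitecture, meta: PlantMetadata | None,
                          vocab: Vocabulary
                          ) -> tuple[PlantArchitecture, PlantMetadata | None]:
    """Replace every tokenized parameter by its quantized (grid) value.

    The result is the fixed point of the codec: tokenizing it and decoding
    returns an identical plant. Base position is not carried by tokens and is
    reset to the origin. ``meta`` may be None (architecture-only
    quantization), in which case None is returned in its place.
    """
    def q(value: float, name: str) -> float:
        return vocab.dequantize(vocab.quantize(value, name), name)

    p = copy_plant(plant)
    p.base_position = (0.0, 0.0, 0.0)
    p.base_rotation = tuple(q(v, n) for v, n in zip(p.base_rotation, HEADER_PARAMS[:3]))
    p.plant_age = q(p.plant_age, "plant_age")
    for s in p.shoots:
        s.shoot_type_label = int(round(q(s.shoot_type_label, "shoot_type_label")))
        s.base_pitch = q(s.base_pitch, "shoot_base_pitch")
        s.base_yaw = q(s.base_yaw, "shoot_base_yaw")
        s.base_roll = q(s.base_roll, "shoot_base_roll")
        for ph in s.phytomers:
            i = ph.internode
            i.length = q(i.length, "internode_length")
            i.radius = q(i.radius, "internode_radius")
            i.pitch = q(i.pitch, "internode_pitch")
            i.phyllotactic_angle = q(i.phyllotactic_angle, "internode_phyllotactic_angle")
            pt = ph.petiole
            pt.length = q(pt.length, "petiole_length")
            pt.radius = q(pt.radius, "petiole_radius")
            pt.pitch = q(pt.pitch, "petiole_pitch")
            pt.curvature = q(pt.curvature, "petiole_curvature")
            if pt.leaflet_scale is not None:
                pt.leaflet_scale = q(pt.leaflet_scale, "leaflet_scale")
            for leaf in ph.leaves:
                leaf.scale = q(leaf.scale, "leaf_scale")
                leaf.pitch = q(leaf.pitch, "leaf_pitch")
                leaf.yaw = q(leaf.yaw, "leaf_yaw")
                leaf.roll = q(leaf.roll, "leaf_roll")
    if meta is None:
        return p, None
    m = PlantMetadata(width_m=q(meta.width_m, "meta_width"),
                      height_m=q(meta.height_m, "meta_height"),
                      vegetation_fraction=q(meta.vegetation_fraction,
                                            "meta_vegetation_fraction"))
    return p, m


def tokenize_architecture(plant: PlantArchitecture, meta: PlantMetadata,
                          vocab: Vocabulary) -> TokenSequence:
    """Encode a valid plant plus its window metadata as a token sequence."""
    if not plant.shoots:
        raise TokenizeError("cannot tokenize a plant with no shoots")
    violations = validate_architecture(plant)
    if violations:
        raise TokenizeError("invalid plant: " + "; ".join(violations[:3]))
    for s in plant.shoots:
        if s.branching_order > 3:
            raise TokenizeError(f"shoot {s.shoot_id}: branching order > 3 unsupported")

    ids: list[int] = [vocab.sos, vocab.meta_open]
    for value, name in zip((meta.width_m, meta.height_m, meta.vegetation_fraction),
                           META_PARAMS):
        ids.append(vocab.quantize(value, name))
    ids.append(vocab.meta_close)
    for value, name in zip((*plant.base_rotation, plant.plant_age), HEADER_PARAMS):
        ids.append(vocab.quantize(value, name))

    children: dict[tuple[int, int], list[Shoot]] = {}
    for s in plant.shoots:
        if s.parent_shoot_id != -1:
            children.setdefault((s.parent_shoot_id, s.parent_node_index), []).append(s)

    def emit_shoot(s: Shoot) -> None:
        o = s.branching_order
        ids.append(organ_token(o, ORGAN_SHOOT))
        for value, name in zip((s.shoot_type_label, s.base_pitch, s.base_yaw, s.base_roll),
                               SHOOT_PARAMS):
            ids.append(vocab.quantize(value, name))
        for node, ph in enumerate(s.phytomers):
            i = ph.internode
            ids.append(organ_token(o, ORGAN_INTERNODE))
            for value, name in zip((i.length, i.radius, i.pitch, i.phyllotactic_angle),
                                   INTERNODE_PARAMS):
                ids.append(vocab.quantize(value, name))
            pt = ph.petiole
            ids.append(organ_token(o, ORGAN_PETIOLE))
            for value, name in zip((pt.length, pt.radius, pt.pitch, pt.curvature),
                                   PETIOLE_PARAMS):
                ids.append(vocab.quantize(value, name))
            if pt.leaflet_scale is not None:
                ids.append(vocab.quantize(pt.leaflet_scale, "leaflet_scale"))
            slots = (0, 0) if len(ph.leaves) == 2 else (0, 1, 2)
            for slot, leaf in zip(slots, ph.leaves):
                ids.append(organ_token(o, ORGAN_LEAF_0 + slot))
                for value, name in zip((leaf.scale, leaf.pitch, leaf.yaw, leaf.roll),
                                       LEAF_PARAMS):
                    ids.append(vocab.quantize(value, name))
            for child in children.get((s.shoot_id, node), ()):
                emit_shoot(child)

    primary = next(s for s in plant.shoots if s.parent_shoot_id == -1)
    emit_shoot(primary)
    ids.append(vocab.eos)
    return TokenSequence(tuple(ids))


class _Cursor:
    def __init__(self, seq: TokenSequence, vocab: Vocabulary):
        self.ids = seq.ids
        self.pos = 0
        self.vocab = vocab

    def peek(self) -> int | None:
        return self.ids[self.pos] if self.pos < len(self.ids) else None

    def take(self, what: str) -> int:
        tid = self.peek()
        if tid is None:
            raise DecodeError(len(self.ids), f"sequence ended while expecting {what}")
        self.pos += 1
        return tid

    def expect(self, tid: int, what: str) -> None:
        got = self.take(what)
        if got != tid:
            raise DecodeError(self.pos - 1, f"expected {what} (ID {tid}), found {got}")

    def params(self, names: tuple[str, ...], owner: str) -> list[float]:
        out = []
        for name in names:
            tid = self.peek()
            if tid is None or not self.vocab.is_param(tid):
                raise DecodeError(
                    self.pos, f"{owner}: expected parameter token for '{name}', "
                    f"found {'end of sequence' if tid is None else tid}")
            self.pos += 1
            out.append(self.vocab.dequantize(tid, name))
        return out


def detokenize(seq: TokenSequence, vocab: Vocabulary) -> tuple[PlantArchitecture, PlantMetadata]:
    """Decode a token sequence back to (PlantArchitecture, PlantMetadata).

    Exact inverse of :func:`tokenize_architecture` on quantized plants. Any
    grammar violation raises :class:`DecodeError` naming the token index.
    """
    c = _Cursor(seq, vocab)
    c.expect(vocab.sos, "SOS")
    c.expect(vocab.meta_open, "META_OPEN")
    w, h, vf = c.params(META_PARAMS, "metadata")
    c.expect(vocab.meta_close, "META_CLOSE")
    bp, by, br, age = c.params(HEADER_PARAMS, "plant header")
    plant = PlantArchitecture(base_position=(0.0, 0.0, 0.0),
                              base_rotation=(bp, by, br), plant_age=age, shoots=[])
    next_id = [0]

    def parse_shoot(order: int, parent_id: int, parent_node: int) -> None:
        start = c.pos
        tid = c.take("shoot token")
        if tid != organ_token(order, ORGAN_SHOOT):
            raise DecodeError(start, f"expected order-{order} shoot token, found {tid}")
        stype, sp, sy, sr = c.params(SHOOT_PARAMS, "shoot")
        stype = int(round(stype))
        if stype not in (UNIFOLIATE, TRIFOLIATE):
            raise DecodeError(start + 1, f"shoot type {stype} not in {{1, 3}}")
        shoot = Shoot(shoot_id=next_id[0], parent_shoot_id=parent_id,
                      parent_node_index=parent_node, branching_order=order,
                      shoot_type_label=stype, base_pitch=sp, base_yaw=sy, base_roll=sr)
        next_id[0] += 1
        plant.shoots.append(shoot)
        node = 0
        while c.peek() == organ_token(order, ORGAN_INTERNODE):
            c.pos += 1
            il, ir, ip, ia = c.params(INTERNODE_PARAMS, "internode")
            pstart = c.pos
            tid = c.take("petiole token")
            if tid != organ_token(order, ORGAN_PETIOLE):
                raise DecodeError(pstart, f"expected petiole token, found {tid}")
            pl, pr, pp, pc = c.params(PETIOLE_PARAMS, "petiole")
            leaflet_scale = None
            if c.peek() is not None and vocab.is_param(c.peek()):
                leaflet_scale = vocab.dequantize(c.take("leaflet_scale"), "leaflet_scale")
            trifoliate = leaflet_scale is not None
            expected_slots = (0, 1, 2) if trifoliate else (0, 0)
            leaves = []
            for slot in expected_slots:
                lstart = c.pos
                tid = c.take("leaf token")
                if tid != organ_token(order, ORGAN_LEAF_0 + slot):
                    raise DecodeError(
                        lstart, f"expected leaf token {organ_token(order, ORGAN_LEAF_0 + slot)}"
                        f" (slot {slot}), found {tid}")
                ls, lp, ly, lr = c.params(LEAF_PARAMS, "leaf")
                leaves.append(Leaf(scale=ls, pitch=lp, yaw=ly, roll=lr))
            shoot.phytomers.append(Phytomer(
                internode=Internode(length=il, radius=ir, pitch=ip, phyllotactic_angle=ia),
                petiole=Petiole(length=pl, radius=pr, pitch=pp, curvature=pc,
                                leaflet_scale=leaflet_scale),
                leaves=leaves))
            if order < 3:
                child_token = organ_token(order + 1, ORGAN_SHOOT)
                while c.peek() == child_token:
                    parse_shoot(order + 1, shoot.shoot_id, node)
            node += 1

    parse_shoot(0, -1, -1)
    c.expect(vocab.eos, "EOS")
    if c.pos != len(c.ids):
        raise DecodeError(c.pos, "trailing tokens after EOS")
    meta = PlantMetadata(width_m=w, height_m=h, vegetation_fraction=vf)
    return plant, meta


def human_tokens(seq: TokenSequence, vocab: Vocabulary) -> list[str]:
    """Human-readable rendering: two-digit organ strings, decoded parameter
    values and special-token names. Not re-ingestible."""
    names = {vocab.sos: "<SOS>", vocab.eos: "<EOS>", vocab.meta_open: "<META>",
             vocab.meta_close: "</META>", vocab.pad: "<PAD>"}
    out = []
    for tid in seq:
        if vocab.is_organ(tid):
            out.append(f"{tid // 6}{tid % 6}")
        elif vocab.is_param(tid):
            out.append(format(vocab.dequantize(tid), "g"))
        else:
            out.append(names.get(tid, f"<{tid}>"))
    return out
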