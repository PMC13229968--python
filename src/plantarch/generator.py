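"""Seeded procedural generator of vegetative cowpea architectures.

A plant starts on day 0 as a single order-0 shoot carrying one unifoliate
phytomer (the cowpea unifoliate leaf pair) and is advanced one day at a
time. Each day:

* every shoot apex accumulates thermal-time-like progress and initiates a
  new (trifoliate) phytomer once the phyllochron is reached;
* every node that has not yet branched may break its lateral bud
  (independent Bernoulli trial per day) and spawn a child shoot, one order
  deeper, up to order 3;
* internodes elongate from their initial length toward an asymptote with
  first-order (exponential-saturation) kinetics. All other organ
  dimensions are sampled at their mature value when the organ is created.

Organ parameters are drawn from the cowpea parameter table (uniform, normal
or constant per parameter and leaf-composition context). Each plant owns an
independent RNG stream seeded from ``seed_base + seed``, and the draws are
consumed in a fixed documented order (apex growth first, then bud break,
shoot by shoot in creation order), so a given (seed, config) reproduces the
same architecture on any platform, and the day-``d`` plant is an exact
prefix of the day-``d+1`` plant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import exp
from pathlib import Path

import numpy as np

from .model import (
    Internode,
    Leaf,
    ParameterSpec,
    Petiole,
    Phytomer,
    PlantArchitecture,
    Shoot,
    TRIFOLIATE,
    UNIFOLIATE,
)
from .tokenizer import tokenize_architecture
from .vocab import Vocabulary, build_vocabulary

__all__ = [
    "GeneratorConfig",
    "PlantState",
    "DEFAULT_PARAMETER_TABLE",
    "ParameterTable",
    "sample_parameters",
    "generate_plant",
    "grow_day",
    "generate_dataset",
    "MAX_AGE_DAYS",
]

MAX_AGE_DAYS = 39

#: Cowpea architectural parameter table: distributions per parameter and
#: leaf-composition context (angles deg, lengths m).
DEFAULT_PARAMETER_TABLE: list[ParameterSpec] = [
    ParameterSpec("base_rotation_pitch", "uniform", (0, 10), "both", "deg"),
    ParameterSpec("base_rotation_yaw", "uniform", (0, 360), "both", "deg"),
    ParameterSpec("base_rotation_roll", "uniform", (0, 360), "both", "deg"),
    ParameterSpec("plant_age", "uniform", (0, 39), "both", "days"),
    ParameterSpec("shoot_type_label", "constant", (1,), "unifoliate", "index"),
    ParameterSpec("shoot_type_label", "constant", (3,), "trifoliate", "index"),
    ParameterSpec("shoot_base_pitch", "constant", (40,), "unifoliate", "deg"),
    ParameterSpec("shoot_base_pitch", "uniform", (40, 60), "trifoliate", "deg"),
    ParameterSpec("shoot_base_yaw", "uniform", (0, 360), "unifoliate", "deg"),
    ParameterSpec("shoot_base_yaw", "uniform", (-20, 20), "trifoliate", "deg"),
    ParameterSpec("shoot_base_roll", "constant", (90,), "both", "deg"),
    ParameterSpec("internode_length", "constant", (0.002,), "both", "m"),
    ParameterSpec("internode_radius", "constant", (0.0015,), "both", "m"),
    ParameterSpec("internode_pitch", "constant", (0,), "unifoliate", "deg"),
    ParameterSpec("internode_pitch", "constant", (20,), "trifoliate", "deg"),
    ParameterSpec("internode_phyllotactic_angle", "uniform", (145, 215), "both", "deg"),
    ParameterSpec("petiole_length", "constant", (0.0004,), "unifoliate", "m"),
    ParameterSpec("petiole_length", "uniform", (0.06, 0.08), "trifoliate", "m"),
    ParameterSpec("petiole_radius", "constant", (0.0001,), "unifoliate", "m"),
    ParameterSpec("petiole_radius", "constant", (0.0018,), "trifoliate", "m"),
    ParameterSpec("petiole_pitch", "uniform", (60, 80), "unifoliate", "deg"),
    ParameterSpec("petiole_pitch", "uniform", (45, 60), "trifoliate", "deg"),
    ParameterSpec("petiole_curvature", "constant", (0,), "unifoliate", "deg"),
    ParameterSpec("petiole_curvature", "uniform", (-200, -50), "trifoliate", "deg"),
    ParameterSpec("leaflet_scale", "constant", (0.9,), "trifoliate", "dimensionless"),
    ParameterSpec("leaf_scale", "constant", (0.02,), "unifoliate", "dimensionless"),
    ParameterSpec("leaf_scale", "uniform", (0.09, 0.12), "trifoliate", "dimensionless"),
    ParameterSpec("leaf_pitch", "uniform", (-10, 10), "unifoliate", "deg"),
    ParameterSpec("leaf_pitch", "normal", (45, 20), "trifoliate", "deg"),
    ParameterSpec("leaf_yaw", "constant", (0,), "unifoliate", "deg"),
    ParameterSpec("leaf_yaw", "constant", (10,), "trifoliate", "deg"),
    ParameterSpec("leaf_roll", "constant", (-15,), "both", "deg"),
]


def sample_parameters(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """Draw one value from a parameter spec. Constants consume no RNG state."""
    if spec.distribution == "constant":
        return float(spec.args[0])
    if spec.distribution == "uniform":
        return float(rng.uniform(spec.args[0], spec.args[1]))
    if spec.distribution == "normal":
        return float(rng.normal(spec.args[0], spec.args[1]))
    raise ValueError(f"unknown distribution kind '{spec.distribution}'")


class ParameterTable:
    """Context-resolving lookup over a list of :class:`ParameterSpec`."""

    def __init__(self, specs: list[ParameterSpec]):
        self._by_key: dict[tuple[str, str], ParameterSpec] = {}
        for s in specs:
            self._by_key[(s.name, s.context)] = s

    def spec(self, name: str, context: str) -> ParameterSpec:
        s = self._by_key.get((name, context)) or self._by_key.get((name, "both"))
        if s is None:
            raise KeyError(f"no parameter spec for '{name}' in context '{context}'")
        return s

    def sample(self, name: str, context: str, rng: np.random.Generator) -> float:
        return sample_parameters(self.spec(name, context), rng)

    def specs(self) -> list[ParameterSpec]:
        return list(self._by_key.values())


@dataclass
class GeneratorConfig:
    """Growth-rule and sampling configuration.

    The parameter table defaults to the cowpea distributions; the growth
    constants (phyllochron, bud-break probability, internode elongation)
    are this package's own, chosen so day-39 plants reach the scale of a
    mature vegetative cowpea (organ counts in the hundreds, a few hundred
    leaves at most).
    """

    parameter_table: list[ParameterSpec] = field(
        default_factory=lambda: list(DEFAULT_PARAMETER_TABLE))
    phyllochron_days: float = 3.0          # days between successive phytomers
    lateral_bud_break_prob: float = 0.02   # per node per day
    max_branching_order: int = 3
    internode_growth_rate: float = 0.25    # 1/day, first-order approach to max
    internode_length_max: float = 0.05     # m, elongation asymptote
    max_phytomers_per_shoot: int = 20
    seed_base: int = 0
    window_m: float = 2.0                  # top-view metadata window side

    def __post_init__(self):
        if self.max_branching_order > 3:
            raise ValueError("max_branching_order cannot exceed 3")
        if not (0 <= self.lateral_bud_break_prob <= 1):
            raise ValueError("lateral_bud_break_prob must be in [0, 1]")
        if self.phyllochron_days <= 0:
            raise ValueError("phyllochron_days must be positive")

    @property
    def table(self) -> ParameterTable:
        return ParameterTable(self.parameter_table)


@dataclass
class _ShootState:
    shoot: Shoot
    apex_progress: float = 0.0             # days accumulated toward next phytomer
    node_branched: list[bool] = field(default_factory=list)
    internode_birth: list[int] = field(default_factory=list)   # creation day per node


@dataclass
class PlantState:
    """A growing plant: the architecture plus per-organ age bookkeeping."""

    day: int
    base_rotation: tuple[float, float, float]
    shoots: list[_ShootState] = field(default_factory=list)

    @property
    def n_phytomers(self) -> int:
        return sum(len(s.shoot.phytomers) for s in self.shoots)


def _make_phytomer(table: ParameterTable, context: str, rng: np.random.Generator) -> Phytomer:
    internode = Internode(
        length=table.sample("internode_length", context, rng),
        radius=table.sample("internode_radius", context, rng),
        pitch=table.sample("internode_pitch", context, rng),
        phyllotactic_angle=table.sample("internode_phyllotactic_angle", context, rng),
    )
    trifoliate = context == "trifoliate"
    petiole = Petiole(
        length=table.sample("petiole_length", context, rng),
        radius=table.sample("petiole_radius", context, rng),
        pitch=table.sample("petiole_pitch", context, rng),
        curvature=table.sample("petiole_curvature", context, rng),
        leaflet_scale=table.sample("leaflet_scale", context, rng) if trifoliate else None,
    )
    n_leaves = 3 if trifoliate else 2
    leaves = [Leaf(scale=table.sample("leaf_scale", context, rng),
                   pitch=table.sample("leaf_pitch", context, rng),
                   yaw=table.sample("leaf_yaw", context, rng),
                   roll=table.sample("leaf_roll", context, rng))
              for _ in range(n_leaves)]
    return Phytomer(internode=internode, petiole=petiole, leaves=leaves)


def _make_shoot(state: PlantState, table: ParameterTable, rng: np.random.Generator,
                order: int, parent_id: int, parent_node: int, context: str) -> _ShootState:
    shoot = Shoot(
        shoot_id=len(state.shoots),
        parent_shoot_id=parent_id,
        parent_node_index=parent_node,
        branching_order=order,
        shoot_type_label=UNIFOLIATE if context == "unifoliate" else TRIFOLIATE,
        base_pitch=table.sample("shoot_base_pitch", context, rng),
        base_yaw=table.sample("shoot_base_yaw", context, rng),
        base_roll=table.sample("shoot_base_roll", context, rng),
    )
    ss = _ShootState(shoot=shoot)
    shoot.phytomers.append(_make_phytomer(table, context, rng))
    ss.node_branched.append(False)
    ss.internode_birth.append(state.day)
    state.shoots.append(ss)
    return ss


def initial_state(rng: np.random.Generator, config: GeneratorConfig) -> PlantState:
    """The day-0 seedling: one order-0 shoot, one unifoliate phytomer."""
    table = config.table
    base_rotation = (table.sample("base_rotation_pitch", "both", rng),
                     table.sample("base_rotation_yaw", "both", rng),
                     table.sample("base_rotation_roll", "both", rng))
    state = PlantState(day=0, base_rotation=base_rotation)
    _make_shoot(state, table, rng, order=0, parent_id=-1, parent_node=-1,
                context="unifoliate")
    return state


def grow_day(state: PlantState, rng: np.random.Generator,
             config: GeneratorConfig) -> PlantState:
    """Advance the plant by one day (mutates and returns ``state``).

    Draw order is fixed: shoots in creation order — apex phytomer initiation
    first, then one bud-break Bernoulli trial per unbranched node. Shoots
    born today neither grow nor branch until tomorrow.
    """
    table = config.table
    state.day += 1
    existing = list(state.shoots)
    for ss in existing:
        ss.apex_progress += 1.0
        if (ss.apex_progress >= config.phyllochron_days
                and len(ss.shoot.phytomers) < config.max_phytomers_per_shoot):
            ss.apex_progress -= config.phyllochron_days
            ss.shoot.phytomers.append(_make_phytomer(table, "trifoliate", rng))
            ss.node_branched.append(False)
            ss.internode_birth.append(state.day)
    for ss in existing:
        order = ss.shoot.branching_order
        if order >= config.max_branching_order:
            continue
        for node in range(len(ss.node_branched)):
            if ss.node_branched[node]:
                continue
            if rng.random() < config.lateral_bud_break_prob:
                ss.node_branched[node] = True
                _make_shoot(state, table, rng, order=order + 1,
                            parent_id=ss.shoot.shoot_id, parent_node=node,
                            context="trifoliate")
    return state


def _snapshot(state: PlantState, config: GeneratorConfig) -> PlantArchitecture:
    """Freeze the growing state into a canonical PlantArchitecture.

    Internode lengths are evaluated at their current age with exponential-
    saturation elongation; shoots are re-ordered depth-first (child blocks
    after their attachment node) and re-numbered, matching the token layout.
    """
    lmax = config.internode_length_max
    r = config.internode_growth_rate
    children: dict[tuple[int, int], list[_ShootState]] = {}
    for ss in state.shoots:
        s = ss.shoot
        if s.parent_shoot_id != -1:
            children.setdefault((s.parent_shoot_id, s.parent_node_index), []).append(ss)

    plant = PlantArchitecture(base_position=(0.0, 0.0, 0.0),
                              base_rotation=state.base_rotation,
                              plant_age=float(state.day), shoots=[])

    def visit(ss: _ShootState, new_parent_id: int) -> None:
        old = ss.shoot
        new_id = len(plant.shoots)
        shoot = replace(old, shoot_id=new_id, parent_shoot_id=new_parent_id, phytomers=[])
        plant.shoots.append(shoot)
        for node, ph in enumerate(old.phytomers):
            age = state.day - ss.internode_birth[node]
            i = ph.internode
            grown = i.length if age == 0 else lmax + (i.length - lmax) * exp(-r * age)
            shoot.phytomers.append(Phytomer(
                internode=Internode(length=grown, radius=i.radius, pitch=i.pitch,
                                    phyllotactic_angle=i.phyllotactic_angle),
                petiole=replace(ph.petiole),
                leaves=[replace(l) for l in ph.leaves]))
            for child in children.get((old.shoot_id, node), ()):
                visit(child, new_id)

    primary = next(ss for ss in state.shoots if ss.shoot.parent_shoot_id == -1)
    visit(primary, -1)
    return plant


def generate_plant(seed: int, age_days: int,
                   config: GeneratorConfig | None = None) -> PlantArchitecture:
    """Deterministically generate one plant of the given seed and age.

    The same seed produces nested architectures over age: the day-``d``
    plant's organs are a prefix (up to elongation) of the day-``d+1`` plant's.
    """
    if config is None:
        config = GeneratorConfig()
    if not (0 <= age_days <= MAX_AGE_DAYS):
        raise ValueError(f"age_days {age_days} outside 0..{MAX_AGE_DAYS}")
    rng = np.random.default_rng(config.seed_base + seed)
    state = initial_state(rng, config)
    for _ in range(age_days):
        grow_day(state, rng, config)
    return _snapshot(state, config)


def collect_parameter_values(plants: list[PlantArchitecture]) -> dict[str, np.ndarray]:
    """Pool per-organ parameter values over a population of plants.

    Keys are ``name`` for plant-level parameters and ``name:context`` for
    organ parameters, mirroring the parameter table's context split — e.g.
    ``petiole_length:trifoliate``. Used to compare a generated population's
    empirical distributions against their specified distributions.
    """
    vals: dict[str, list[float]] = {}

    def add(key: str, v: float) -> None:
        vals.setdefault(key, []).append(v)

    for plant in plants:
        add("base_rotation_pitch", plant.base_rotation[0])
        add("base_rotation_yaw", plant.base_rotation[1])
        add("base_rotation_roll", plant.base_rotation[2])
        add("plant_age", plant.plant_age)
        for s in plant.shoots:
            ctx = "unifoliate" if s.shoot_type_label == UNIFOLIATE else "trifoliate"
            add(f"shoot_type_label:{ctx}", s.shoot_type_label)
            add(f"shoot_base_pitch:{ctx}", s.base_pitch)
            add(f"shoot_base_yaw:{ctx}", s.base_yaw)
            add(f"shoot_base_roll:{ctx}", s.base_roll)
            for ph in s.phytomers:
                pctx = "trifoliate" if ph.is_trifoliate else "unifoliate"
                i = ph.internode
                add(f"internode_length:{pctx}", i.length)
                add(f"internode_radius:{pctx}", i.radius)
                add(f"internode_pitch:{pctx}", i.pitch)
                add(f"internode_phyllotactic_angle:{pctx}", i.phyllotactic_angle)
                pt = ph.petiole
                add(f"petiole_length:{pctx}", pt.length)
                add(f"petiole_radius:{pctx}", pt.radius)
                add(f"petiole_pitch:{pctx}", pt.pitch)
                add(f"petiole_curvature:{pctx}", pt.curvature)
                if pt.leaflet_scale is not None:
                    add(f"leaflet_scale:{pctx}", pt.leaflet_scale)
                for leaf in ph.leaves:
                    add(f"leaf_scale:{pctx}", leaf.scale)
                    add(f"leaf_pitch:{pctx}", leaf.pitch)
                    add(f"leaf_yaw:{pctx}", leaf.yaw)
                    add(f"leaf_roll:{pctx}", leaf.roll)
    return {k: np.asarray(v) for k, v in vals.items()}


def generate_dataset(n_seeds: int, day_range: range, out_dir: str | Path,
                     config: GeneratorConfig | None = None,
                     vocab: Vocabulary | None = None) -> list[dict]:
    """Generate XML + token files for every (seed, day); return the manifest.

    Writes ``plant_<seed>_day<day>.xml`` per record, one token line per
    record into ``tokens.txt``, the JSON-Lines ``manifest.jsonl`` and a
    ``summary.json`` with achieved organ-count maxima.

    The stored architecture is grid-quantized before metadata computation
    and serialization, so each XML file is exactly the decode of its paired
    token line and ``detokenize → tokenize`` reproduces the line verbatim.
    """
    from .geometry import bounding_metadata, reconstruct_geometry
    from .model import write_architecture_xml
    from .tokenizer import quantize_architecture

    if config is None:
        config = GeneratorConfig()
    if vocab is None:
        vocab = build_vocabulary()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    max_counts = {"n_shoots": 0, "n_phytomers": 0, "n_leaves": 0}
    token_path = out / "tokens.txt"
    with open(token_path, "w") as tokens_f:
        line_no = 0
        for idx in range(n_seeds):
            # one pass per seed: simulate once to the max requested day,
            # snapshotting at each requested age keeps seeds consistent
            days = sorted(day_range)
            rng = np.random.default_rng(config.seed_base + idx)
            state = initial_state(rng, config)
            current = 0
            for day in days:
                while current < day:
                    grow_day(state, rng, config)
                    current += 1
                plant, _ = quantize_architecture(_snapshot(state, config), None, vocab)
                geom = reconstruct_geometry(plant)
                meta = bounding_metadata(geom, config.window_m)
                seq = tokenize_architecture(plant, meta, vocab)
                xml_path = out / f"plant_{idx}_day{day:02d}.xml"
                xml_path.write_text(write_architecture_xml(plant))
                tokens_f.write(seq.to_line() + "\n")
                n_leaves = sum(len(ph.leaves) for s in plant.shoots for ph in s.phytomers)
                n_phy = sum(len(s.phytomers) for s in plant.shoots)
                max_counts["n_shoots"] = max(max_counts["n_shoots"], len(plant.shoots))
                max_counts["n_phytomers"] = max(max_counts["n_phytomers"], n_phy)
                max_counts["n_leaves"] = max(max_counts["n_leaves"], n_leaves)
                manifest.append({"seed": idx, "day": day,
                                 "xml_path": xml_path.name,
                                 "token_path": token_path.name,
                                 "token_line": line_no})
                line_no += 1
    with open(out / "manifest.jsonl", "w") as f:
        for rec in manifest:
            f.write(json.dumps(rec) + "\n")
    (out / "summary.json").write_text(json.dumps(
        {"n_records": len(manifest), "max_counts": max_counts}, indent=2) + "\n")
    return manifest
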