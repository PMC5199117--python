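"""Wish-lists: hard constraints plus prioritized objectives.

A wish-list drives automated multi-criteria planning: hard constraints are
strictly met in every solve, while objectives are minimized one priority
level at a time (lower priority number = more important; equal numbers form
a group handled jointly). Goals may be absolute (Gy), relative (percent of
the prescription dose D^p, resolved at solve time) or unitless (LTCP).

The default wish-list shipped here is the clinically tuned cervix list:
three maximum-dose constraints (PTV, 40 mm PTV shell, unspecified tissue)
and fourteen priority levels headed by an LTCP coverage objective on the
PTV, followed by small-bowel sparing, dose fall-off shells, a skin ring,
and EUD/mean objectives for sigmoid, colon, bladder and rectum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import yaml

from .phantom import OPTIONAL_STRUCTURES, Phantom

__all__ = [
    "DoseGoal",
    "ConstraintSpec",
    "ObjectiveSpec",
    "WishList",
    "Issue",
    "default_wishlist",
    "parse_wishlist",
    "serialize_wishlist",
    "validate_against",
]

OBJECTIVE_KINDS = ("ltcp", "eud", "mean", "max")


@dataclass(frozen=True)
class DoseGoal:
    """A dose value, absolute (Gy) or a percentage of the prescription D^p."""

    value: float
    relative: bool = False   # True: value is percent of D^p

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"goal/limit must be > 0, got {self.value}")

    def resolve(self, prescription_dose: float) -> float:
        if self.relative:
            return self.value / 100.0 * prescription_dose
        return self.value

    def __str__(self) -> str:
        return f"{self.value:g}%" if self.relative else f"{self.value:g} Gy"

    @classmethod
    def parse(cls, spec) -> "DoseGoal":
        if isinstance(spec, DoseGoal):
            return spec
        if isinstance(spec, str):
            s = spec.strip()
            if s.endswith("%"):
                return cls(float(s[:-1]), relative=True)
            if s.lower().endswith("gy"):
                return cls(float(s[:-2]))
            return cls(float(s))
        return cls(float(spec))


@dataclass(frozen=True)
class ConstraintSpec:
    """Hard maximum-dose constraint on a structure."""

    structure: str
    limit: DoseGoal
    kind: str = "max"

    def __post_init__(self):
        if self.kind != "max":
            raise ValueError(f"unknown constraint kind {self.kind!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Prioritized minimization objective.

    kind: 'ltcp' (target coverage; goal unitless, requires alpha),
    'eud' (generalized EUD; requires volume-effect k >= 1),
    'mean' or 'max' (Gy or % of D^p goals).
    """

    priority: int
    structure: str
    kind: str
    goal: DoseGoal | float
    alpha: float | None = None
    k: float | None = None

    def __post_init__(self):
        if self.priority < 1:
            raise ValueError(f"priority must be >= 1, got {self.priority}")
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r} ({self.label})")
        if self.kind == "ltcp":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError(f"LTCP objective requires alpha > 0 ({self.label})")
            if not isinstance(self.goal, (int, float)) or self.goal <= 0:
                raise ValueError(f"LTCP goal must be a positive number ({self.label})")
        else:
            if not isinstance(self.goal, DoseGoal):
                raise ValueError(f"{self.kind} goal must be a DoseGoal ({self.label})")
        if self.kind == "eud":
            if self.k is None:
                raise ValueError(f"EUD objective requires volume-effect k ({self.label})")
            if self.k < 1:
                raise ValueError(f"EUD volume effect k must be >= 1 ({self.label})")

    @property
    def label(self) -> str:
        return f"p{self.priority}:{self.structure}:{self.kind}"

    def resolve_goal(self, prescription_dose: float) -> float:
        if isinstance(self.goal, DoseGoal):
            return self.goal.resolve(prescription_dose)
        return float(self.goal)


@dataclass
class WishList:
    """Prescription dose, hard constraints and priority-ordered objectives."""

    prescription_dose: float = 46.0
    constraints: list[ConstraintSpec] = field(default_factory=list)
    objectives: list[ObjectiveSpec] = field(default_factory=list)

    def __post_init__(self):
        self.prescription_dose = float(self.prescription_dose)
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        seen = set()
        for c in self.constraints:
            key = (c.structure, c.kind)
            if key in seen:
                raise ValueError(f"duplicate constraint on {c.structure!r} ({c.kind})")
            seen.add(key)
        # stable sort: ascending priority, listed order within equal priorities
        self.objectives = sorted(self.objectives, key=lambda o: o.priority)

    def priority_groups(self) -> list[tuple[int, list[ObjectiveSpec]]]:
        groups: dict[int, list[ObjectiveSpec]] = {}
        for o in self.objectives:
            groups.setdefault(o.priority, []).append(o)
        return sorted(groups.items())

    def structure_names(self) -> set[str]:
        return {c.structure for c in self.constraints} | {o.structure for o in self.objectives}


def default_wishlist(prescription_dose: float = 46.0) -> WishList:
    """The cervix wish-list used for every automatic plan generation."""
    pct = lambda v: DoseGoal(v, relative=True)
    gy = lambda v: DoseGoal(v)
    constraints = [
        ConstraintSpec("ptv", pct(105)),
        ConstraintSpec("shell_40mm", pct(50)),
        ConstraintSpec("unspecified_tissue", pct(105)),
    ]
    objectives = [
        ObjectiveSpec(1, "ptv", "ltcp", 0.5, alpha=0.8),
        ObjectiveSpec(2, "shell_3mm", "max", pct(95)),
        ObjectiveSpec(3, "shell_15mm", "max", pct(75)),
        ObjectiveSpec(4, "small_bowel", "eud", gy(45), k=4),
        ObjectiveSpec(5, "small_bowel", "eud", gy(15), k=3),
        ObjectiveSpec(6, "small_bowel", "mean", gy(10)),
        ObjectiveSpec(7, "sigmoid", "eud", gy(30), k=4),
        ObjectiveSpec(7, "colon", "eud", gy(30), k=4),
        ObjectiveSpec(8, "small_bowel", "max", pct(100)),
        ObjectiveSpec(9, "shell_25mm", "max", pct(60)),
        ObjectiveSpec(9, "skin_ring", "max", pct(35)),
        ObjectiveSpec(10, "bladder", "eud", gy(30), k=4),
        ObjectiveSpec(11, "rectum", "eud", gy(30), k=4),
        ObjectiveSpec(12, "sigmoid", "mean", gy(25)),
        ObjectiveSpec(12, "colon", "mean", gy(25)),
        ObjectiveSpec(13, "bladder", "mean", gy(25)),
        ObjectiveSpec(14, "rectum", "mean", gy(25)),
    ]
    return WishList(prescription_dose=prescription_dose,
                    constraints=constraints, objectives=objectives)


# ---------------------------------------------------------------------------
# (de)serialization — YAML/JSON-compatible plain structure
# ---------------------------------------------------------------------------

def _goal_to_plain(goal) -> str | float:
    if isinstance(goal, DoseGoal):
        return f"{goal.value:g}%" if goal.relative else f"{goal.value:g} Gy"
    return float(goal)


def serialize_wishlist(wl: WishList) -> str:
    doc = {
        "prescription_dose": wl.prescription_dose,
        "constraints": [
            {"structure": c.structure, "kind": c.kind, "limit": _goal_to_plain(c.limit)}
            for c in wl.constraints
        ],
        "objectives": [
            {k: v for k, v in (
                ("priority", o.priority), ("structure", o.structure),
                ("kind", o.kind), ("goal", _goal_to_plain(o.goal)),
                ("alpha", o.alpha), ("k", o.k)) if v is not None}
            for o in wl.objectives
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def parse_wishlist(config_text: str) -> WishList:
    """Parse a YAML/JSON wish-list document; round-trip stable."""
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict):
        raise ValueError("wish-list config must be a mapping")
    constraints = []
    for c in doc.get("constraints", []):
        constraints.append(ConstraintSpec(
            structure=c["structure"],
            limit=DoseGoal.parse(c["limit"]),
            kind=c.get("kind", "max"),
        ))
    objectives = []
    for o in doc.get("objectives", []):
        kind = o.get("kind")
        if kind not in OBJECTIVE_KINDS:
            raise ValueError(
                f"unknown objective kind {kind!r} for structure {o.get('structure')!r}")
        goal = float(o["goal"]) if kind == "ltcp" else DoseGoal.parse(o["goal"])
        objectives.append(ObjectiveSpec(
            priority=int(o["priority"]), structure=o["structure"], kind=kind,
            goal=goal, alpha=o.get("alpha"), k=o.get("k"),
        ))
    return WishList(
        prescription_dose=float(doc.get("prescription_dose", 46.0)),
        constraints=constraints, objectives=objectives,
    )


# ---------------------------------------------------------------------------
# validation against a phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    level: str          # 'error' | 'warning'
    message: str


def validate_against(wishlist: WishList, phantom: Phantom) -> list[Issue]:
    """Check every referenced structure exists and is nonempty.

    Missing optional structures (e.g. colon) yield warnings, not errors.
    """
    issues: list[Issue] = []
    for name in sorted(wishlist.structure_names()):
        if name not in phantom.structures:
            level = "warning" if name in OPTIONAL_STRUCTURES else "error"
            issues.append(Issue(level, f"structure {name!r} not present in phantom"))
        elif not phantom.structures[name].any():
            issues.append(Issue("error", f"structure {name!r} is empty"))
    return issues
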