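"""Proximal pulmonary arterial tree: representation, generation, disease
remodeling, and file I/O.

The anatomy is reduced to a rooted tree of straight segments, each carrying a
single lumen diameter and length (cm). The root is the main pulmonary artery
(MPA); its two children are the left and right pulmonary arteries (LPA, RPA).
Generated trees close Murray's bifurcation law
``D_parent**gamma = D_child1**gamma + D_child2**gamma`` exactly at every
bifurcation, with the diameter split controlled by an asymmetry parameter.

Outlet (leaf) ordering is fixed and documented: depth-first from the root,
children visited by descending diameter then lexical id. All per-outlet
parameter vectors downstream (Windkessel sets, flows) align with this order.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Group",
    "ArterialSegment",
    "ArterialTree",
    "TreeError",
    "generate_tree",
    "outlets",
    "apply_disease_remodeling",
    "read_tree",
    "write_tree",
]


class TreeError(ValueError):
    """Invalid tree structure or parameters."""


class Group(str, Enum):
    """Study group labels."""

    CTEPH = "CTEPH"
    CTEPD = "CTEPD"
    CONTROL = "CONTROL"


@dataclass
class ArterialSegment:
    """One straight vessel segment with uniform lumen.

    Parameters
    ----------
    id : str
        Opaque unique identifier.
    parent_id : str or None
        Parent segment id; ``None`` marks the root.
    name : str
        Free-text anatomical name ("MPA", "LPA", ...).
    length, diameter : float
        Segment length and lumen diameter, cm; both strictly positive.
    generation : int
        0 for the root, parent's generation + 1 otherwise.
    """

    id: str
    parent_id: str | None
    name: str
    length: float
    diameter: float
    generation: int = 0

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise TreeError(f"segment {self.id!r}: length must be > 0, got {self.length}")
        if not (self.diameter > 0):
            raise TreeError(f"segment {self.id!r}: diameter must be > 0, got {self.diameter}")
        if self.generation < 0:
            raise TreeError(f"segment {self.id!r}: generation must be >= 0")


# child may exceed parent diameter by at most 5% (anatomical sanity margin)
_DIAMETER_SLACK = 1.05


@dataclass
class ArterialTree:
    """Rooted tree of :class:`ArterialSegment`.

    ``segments`` preserves insertion order; topological (parent-before-child)
    insertion is maintained by all constructors in this module.
    """

    segments: dict[str, ArterialSegment] = field(default_factory=dict)
    root_id: str | None = None

    def add(self, seg: ArterialSegment) -> None:
        if seg.id in self.segments:
            raise TreeError(f"duplicate segment id {seg.id!r}")
        if seg.parent_id is None:
            if self.root_id is not None:
                raise TreeError("tree already has a root; second root " + repr(seg.id))
            self.root_id = seg.id
        elif seg.parent_id not in self.segments:
            raise TreeError(
                f"segment {seg.id!r} references unknown parent {seg.parent_id!r}"
            )
        self.segments[seg.id] = seg

    @property
    def root(self) -> ArterialSegment:
        if self.root_id is None:
            raise TreeError("tree has no root")
        return self.segments[self.root_id]

    def children(self, seg_id: str) -> list[ArterialSegment]:
        """Children ordered by descending diameter, then id (the canonical
        traversal order)."""
        kids = [s for s in self.segments.values() if s.parent_id == seg_id]
        return sorted(kids, key=lambda s: (-s.diameter, s.id))

    def walk(self) -> Iterator[ArterialSegment]:
        """Depth-first traversal in canonical order."""
        stack = [self.root]
        while stack:
            seg = stack.pop()
            yield seg
            stack.extend(reversed(self.children(seg.id)))

    def is_leaf(self, seg_id: str) -> bool:
        return not any(s.parent_id == seg_id for s in self.segments.values())

    def validate(self, require_outlets: int = 2) -> None:
        """Check structural invariants; raise :class:`TreeError` on violation.

        ``require_outlets`` may be lowered to admit degenerate single-outlet
        trees used by closed-form solver checks.
        """
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        if self.root_id != roots[0].id:
            raise TreeError("root_id does not match the parentless segment")
        seen = {s.id for s in self.walk()}
        if seen != set(self.segments):
            orphans = set(self.segments) - seen
            raise TreeError(f"tree is not connected; unreachable segments {sorted(orphans)}")
        for seg in self.segments.values():
            if seg.parent_id is not None:
                parent = self.segments[seg.parent_id]
                if seg.generation != parent.generation + 1:
                    raise TreeError(
                        f"segment {seg.id!r}: generation {seg.generation} != "
                        f"parent generation {parent.generation} + 1"
                    )
                if seg.diameter > parent.diameter * _DIAMETER_SLACK:
                    raise TreeError(
                        f"segment {seg.id!r}: diameter {seg.diameter:.4g} exceeds "
                        f"parent diameter {parent.diameter:.4g} by more than 5%"
                    )
        n_out = sum(1 for s in self.segments.values() if self.is_leaf(s.id))
        if n_out < require_outlets:
            raise TreeError(f"tree must have >= {require_outlets} outlets, found {n_out}")

    def copy(self) -> "ArterialTree":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArterialTree):
            return NotImplemented
        return self.root_id == other.root_id and self.segments == other.segments


def generate_tree(
    root_diameter: float,
    n_generations: int = 3,
    murray_exponent: float = 2.25,
    asymmetry: float = 0.0,
    length_to_diameter: float = 3.0,
    seed: int = 0,
) -> ArterialTree:
    """Generate a synthetic bifurcating proximal tree.

    Each bifurcation satisfies Murray closure
    ``Dp**g = D1**g + D2**g`` with ``g = murray_exponent``: the parent's
    ``Dp**g`` is split into fractions ``(1 + a)/2`` and ``(1 - a)/2`` where
    ``a = asymmetry``; a seeded RNG decides which daughter receives the larger
    share at each bifurcation, so the tree is deterministic per seed. Segment
    length is ``length_to_diameter * diameter``.

    Parameters
    ----------
    root_diameter : float
        MPA diameter, cm; > 0.
    n_generations : int
        Number of bifurcation generations below the root (>= 1); a symmetric
        tree has ``2**n_generations`` outlets.
    murray_exponent : float
        Bifurcation closure exponent; > 0. The default 2.25 matches the
        exponent used for outlet resistance apportionment; the classic
        morphometric value is 3.0.
    asymmetry : float
        Daughter-share asymmetry in [0, 1). 0 gives a symmetric tree.
    """
    if not (root_diameter > 0):
        raise TreeError(f"root_diameter must be > 0, got {root_diameter}")
    if not (murray_exponent > 0):
        raise TreeError(f"murray_exponent must be > 0, got {murray_exponent}")
    if n_generations < 1:
        raise TreeError(f"n_generations must be >= 1, got {n_generations}")
    if not (0 <= asymmetry < 1):
        raise TreeError(f"asymmetry must be in [0, 1), got {asymmetry}")
    if not (length_to_diameter > 0):
        raise TreeError(f"length_to_diameter must be > 0, got {length_to_diameter}")

    rng = np.random.default_rng(seed)
    tree = ArterialTree()
    tree.add(
        ArterialSegment(
            id="MPA", parent_id=None, name="MPA",
            length=length_to_diameter * root_diameter,
            diameter=root_diameter, generation=0,
        )
    )

    frontier = [("MPA", root_diameter)]
    for gen in range(1, n_generations + 1):
        next_frontier: list[tuple[str, float]] = []
        for parent_id, d_parent in frontier:
            hi = (1.0 + asymmetry) / 2.0
            lo = (1.0 - asymmetry) / 2.0
            fractions = (hi, lo) if rng.random() < 0.5 else (lo, hi)
            if gen == 1:
                child_ids = ["LPA", "RPA"]
            else:
                child_ids = [f"{parent_id}.1", f"{parent_id}.2"]
            for cid, frac in zip(child_ids, fractions):
                d_child = d_parent * frac ** (1.0 / murray_exponent)
                tree.add(
                    ArterialSegment(
                        id=cid, parent_id=parent_id, name=cid,
                        length=length_to_diameter * d_child,
                        diameter=d_child, generation=gen,
                    )
                )
                next_frontier.append((cid, d_child))
        frontier = next_frontier

    tree.validate()
    return tree


def outlets(tree: ArterialTree) -> list[ArterialSegment]:
    """All leaf segments in canonical (depth-first, diameter-descending) order.

    This ordering is the contract every per-outlet vector in the package
    aligns with; it is stable across repeated calls on the same tree.
    """
    return [seg for seg in tree.walk() if tree.is_leaf(seg.id)]


def apply_disease_remodeling(
    tree: ArterialTree,
    group: Group,
    mpa_diameter: float,
    occlusion_fraction: float = 0.0,
    seed: int = 0,
    stenosis_factor: float = 0.5,
) -> ArterialTree:
    """Rescale a template tree to a patient's MPA caliber and, for diseased
    groups, narrow a seeded subset of outlets.

    The whole tree is rescaled geometrically (diameters and lengths) so the
    root matches ``mpa_diameter`` (cm). For CTEPH/CTEPD,
    ``floor(occlusion_fraction * n_outlets)`` outlets chosen by a seeded RNG
    have their diameter multiplied by ``stenosis_factor``, emulating chronic
    thromboembolic narrowing of distal branches. CONTROL applies no occlusion.
    """
    if not (0 <= occlusion_fraction < 1):
        raise TreeError(f"occlusion_fraction must be in [0, 1), got {occlusion_fraction}")
    if not (mpa_diameter > 0):
        raise TreeError(f"mpa_diameter must be > 0, got {mpa_diameter}")
    if not (0 < stenosis_factor <= 1):
        raise TreeError(f"stenosis_factor must be in (0, 1], got {stenosis_factor}")

    out = tree.copy()
    scale = mpa_diameter / tree.root.diameter
    for seg in out.segments.values():
        seg.diameter *= scale
        seg.length *= scale

    if group is not Group.CONTROL and occlusion_fraction > 0:
        leaf_ids = [s.id for s in outlets(out)]
        n_occ = math.floor(occlusion_fraction * len(leaf_ids))
        if n_occ >= len(leaf_ids):
            raise TreeError("occlusion would narrow every outlet")
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(leaf_ids), size=n_occ, replace=False)
        for idx in chosen:
            out.segments[leaf_ids[idx]].diameter *= stenosis_factor
    return out


# ---------------------------------------------------------------------------
# File I/O: JSON list of {id, parent_id|null, name, length_cm, diameter_cm}.
# Units fixed to cm. Generations are recomputed on read.

_REQUIRED_FIELDS = ("id", "parent_id", "name", "length_cm", "diameter_cm")


def write_tree(tree: ArterialTree, path: str | Path) -> None:
    """Write a tree to a JSON file (topological record order)."""
    records = [
        {
            "id": seg.id,
            "parent_id": seg.parent_id,
            "name": seg.name,
            "length_cm": seg.length,
            "diameter_cm": seg.diameter,
        }
        for seg in tree.walk()
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_tree(path: str | Path) -> ArterialTree:
    """Read a tree file; raises :class:`TreeError` naming the offending field
    on any schema violation."""
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TreeError(f"not valid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise TreeError("tree file must contain a JSON list of segment records")

    by_id: dict[str, dict] = {}
    roots = []
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise TreeError(f"record {i}: not an object")
        for f in _REQUIRED_FIELDS:
            if f not in rec:
                raise TreeError(f"record {i}: missing field {f!r}")
        if rec["diameter_cm"] is None or not rec["diameter_cm"] > 0:
            raise TreeError(f"record {rec['id']!r}: field 'diameter_cm' must be > 0")
        if rec["length_cm"] is None or not rec["length_cm"] > 0:
            raise TreeError(f"record {rec['id']!r}: field 'length_cm' must be > 0")
        if rec["id"] in by_id:
            raise TreeError(f"record {rec['id']!r}: duplicate field 'id'")
        by_id[rec["id"]] = rec
        if rec["parent_id"] is None:
            roots.append(rec["id"])

    if len(roots) != 1:
        raise TreeError(
            f"field 'parent_id': expected exactly one null (root), found {len(roots)}"
        )

    # recompute generations from parentage, inserting parents first
    tree = ArterialTree()
    gen: dict[str, int] = {}

    def insert(rid: str, trail: set[str]) -> None:
        if rid in gen:
            return
        rec = by_id[rid]
        pid = rec["parent_id"]
        if pid is not None:
            if pid not in by_id:
                raise TreeError(f"record {rid!r}: field 'parent_id' references unknown id {pid!r}")
            if pid in trail:
                raise TreeError(f"record {rid!r}: field 'parent_id' creates a cycle")
            insert(pid, trail | {rid})
        gen[rid] = 0 if pid is None else gen[pid] + 1
        tree.add(
            ArterialSegment(
                id=rec["id"], parent_id=pid, name=rec["name"],
                length=rec["length_cm"], diameter=rec["diameter_cm"],
                generation=gen[rid],
            )
        )

    for rid in by_id:
        insert(rid, set())
    tree.validate(require_outlets=1)
    return tree
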