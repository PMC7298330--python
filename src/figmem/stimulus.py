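"""Item model for figural short-term-memory association tests.

An item presents ``n_units`` emblem--frame pairs in a 5 x 4 learning matrix;
at recall the emblems reappear in a new order, each with four candidate
frames (the correct one plus three distractors).  Difficulty is governed by a
single three-level *radical*, visual information load:

* level 1 (low load): 20 original emblems and 20 original frames, all
  distinguishable by shape alone;
* level 2 (medium load): the same emblems, but the frame inventory collapses
  to four base shapes (rectangle, trapeze, pentagon, hexagon), each in a
  complete form and four variants with one erased edge -- frames must now be
  remembered by shape *and* line completeness;
* level 3 (high load): the level-2 frames plus an emblem inventory built from
  four rotatable shapes at 0/90/180/270 degrees and four gapped rings --
  emblems must be remembered by shape *and* direction.

Everything that varies between items of the same family (the emblem-frame
pairing, learning order, recall order, distractor composition, answer-option
order) is an *incidental*, drawn deterministically from a single seed via
independent named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmblemSpec",
    "FrameSpec",
    "AssociationUnit",
    "ItemSpec",
    "ITEM_SPEC_VERSION",
    "build_emblem_inventory",
    "build_frame_inventory",
    "assign_distractors",
    "generate_item",
    "generate_parallel_set",
    "option_orders",
]

ITEM_SPEC_VERSION = 1

VALID_LEVELS = (1, 2, 3)

#: the 20 original emblem shapes (level 1 and 2 inventory).  The first six
#: are the shapes explicitly present in the original stimulus set; the rest
#: are simple, visually distinct filled glyphs.
ORIGINAL_EMBLEMS = (
    "right_triangle",
    "quadrant_gap_circle",
    "prong_circle",
    "l_shape",
    "black_ring",
    "plus_sign",
    "black_circle",
    "black_square",
    "diamond",
    "five_star",
    "arrow_up",
    "cross_x",
    "crescent",
    "t_shape",
    "u_shape",
    "z_shape",
    "bowtie",
    "black_triangle",
    "half_circle",
    "four_arrows",
)

#: the four level-3 emblem shapes that admit 90-degree rotations
ROTATABLE_EMBLEMS = (
    "right_triangle",
    "quadrant_gap_circle",
    "prong_circle",
    "l_shape",
)

GAP_POSITIONS = ("top", "right", "bottom", "left")

#: the 20 original frame shapes (level-1 inventory); all closed outlines
ORIGINAL_FRAMES = (
    "rectangle",
    "trapeze",
    "pentagon",
    "hexagon",
    "square",
    "triangle",
    "right_trapezoid",
    "parallelogram",
    "rhombus",
    "heptagon",
    "octagon",
    "house",
    "cross_frame",
    "arrow_frame",
    "chevron_frame",
    "six_star_frame",
    "l_frame",
    "t_frame",
    "tall_rectangle",
    "notched_square",
)

#: base shapes retained at levels 2-3, each with 4 single-edge-erased variants
ERASABLE_FRAMES = ("rectangle", "trapeze", "pentagon", "hexagon")


def _check_level(radical_level: int) -> None:
    if radical_level not in VALID_LEVELS:
        raise ValueError(
            f"radical_level must be one of {VALID_LEVELS}, got {radical_level!r}"
        )


@dataclass(frozen=True, order=True)
class EmblemSpec:
    """One emblem: a shape, an orientation and (for rings) a gap position."""

    shape_id: str
    orientation_deg: int = 0
    gap_position: str = "none"
    family_level: int = 1

    def __post_init__(self):
        if self.orientation_deg not in (0, 90, 180, 270):
            raise ValueError(f"invalid orientation {self.orientation_deg}")
        if self.gap_position not in ("none",) + GAP_POSITIONS:
            raise ValueError(f"invalid gap_position {self.gap_position!r}")
        if self.orientation_deg != 0 and self.shape_id not in ROTATABLE_EMBLEMS:
            raise ValueError(
                f"orientation != 0 only allowed for rotatable shapes, got {self.shape_id!r}"
            )
        if self.gap_position != "none" and self.shape_id != "black_ring":
            raise ValueError("gap_position != none only allowed for the ring shape")

    @property
    def key(self):
        return (self.shape_id, self.orientation_deg, self.gap_position)


@dataclass(frozen=True, order=True)
class FrameSpec:
    """One frame: a base outline shape, optionally with one erased edge."""

    base_shape: str
    missing_line: int = 0
    family_level: int = 1

    def __post_init__(self):
        if self.base_shape not in ORIGINAL_FRAMES:
            raise ValueError(f"unknown frame shape {self.base_shape!r}")
        if self.missing_line != 0:
            if self.family_level == 1:
                raise ValueError("erased edges only occur at levels 2-3")
            if self.base_shape not in ERASABLE_FRAMES:
                raise ValueError(
                    f"erased-edge variants exist only for {ERASABLE_FRAMES}"
                )
            if not 1 <= self.missing_line <= 4:
                raise ValueError("missing_line must be in 0..4")

    @property
    def key(self):
        return (self.base_shape, self.missing_line)


@dataclass(frozen=True)
class AssociationUnit:
    """One emblem-frame pair with its positions and distractor triple."""

    emblem: EmblemSpec
    correct_frame: FrameSpec
    learning_cell: int
    recall_position: int
    distractors: tuple  # 3 distinct FrameSpec, none equal to correct_frame

    def __post_init__(self):
        if len(self.distractors) != 3:
            raise ValueError("exactly 3 distractors required")
        keys = {d.key for d in self.distractors}
        if len(keys) != 3 or self.correct_frame.key in keys:
            raise ValueError("distractors must be distinct and differ from the correct frame")


@dataclass(frozen=True)
class ItemSpec:
    """A complete generated item."""

    radical_level: int
    incidental_seed: int
    n_units: int
    units: tuple  # of AssociationUnit

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        n = self.n_units
        if len(self.units) != n:
            raise ValueError("unit count mismatch")
        emblems = [u.emblem.key for u in self.units]
        frames = [u.correct_frame.key for u in self.units]
        if len(set(emblems)) != n:
            raise ValueError("emblems not pairwise distinct")
        if len(set(frames)) != n:
            raise ValueError("correct frames not pairwise distinct")
        if sorted(u.learning_cell for u in self.units) != list(range(n)):
            raise ValueError("learning cells are not a permutation of 0..n-1")
        if sorted(u.recall_position for u in self.units) != list(range(n)):
            raise ValueError("recall positions are not a permutation of 0..n-1")

    # --- JSON round trip ------------------------------------------------
    def to_json(self, indent: int | None = None) -> str:
        def enc_unit(u: AssociationUnit):
            return {
                "emblem": dataclasses.asdict(u.emblem),
                "correct_frame": dataclasses.asdict(u.correct_frame),
                "learning_cell": u.learning_cell,
                "recall_position": u.recall_position,
                "distractors": [dataclasses.asdict(d) for d in u.distractors],
            }

        payload = {
            "version": ITEM_SPEC_VERSION,
            "radical_level": self.radical_level,
            "incidental_seed": self.incidental_seed,
            "n_units": self.n_units,
            "units": [enc_unit(u) for u in self.units],
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "ItemSpec":
        payload = json.loads(text)
        if payload.get("version") != ITEM_SPEC_VERSION:
            raise ValueError(f"unsupported ItemSpec version {payload.get('version')!r}")
        units = tuple(
            AssociationUnit(
                emblem=EmblemSpec(**u["emblem"]),
                correct_frame=FrameSpec(**u["correct_frame"]),
                learning_cell=u["learning_cell"],
                recall_position=u["recall_position"],
                distractors=tuple(FrameSpec(**d) for d in u["distractors"]),
            )
            for u in payload["units"]
        )
        return ItemSpec(
            radical_level=payload["radical_level"],
            incidental_seed=payload["incidental_seed"],
            n_units=payload["n_units"],
            units=units,
        )


# --- inventories ---------------------------------------------------------


def build_emblem_inventory(radical_level: int) -> list[EmblemSpec]:
    """Return the 20-emblem inventory for a radical level.

    Levels 1 and 2 share the 20 original emblems.  Level 3 consists of the
    four rotatable shapes at four orientations (16 emblems) plus four gapped
    rings.
    """
    _check_level(radical_level)
    if radical_level in (1, 2):
        return [
            EmblemSpec(shape_id=s, family_level=radical_level)
            for s in ORIGINAL_EMBLEMS
        ]
    inv = [
        EmblemSpec(shape_id=s, orientation_deg=o, family_level=3)
        for s in ROTATABLE_EMBLEMS
        for o in (0, 90, 180, 270)
    ]
    inv += [
        EmblemSpec(shape_id="black_ring", gap_position=g, family_level=3)
        for g in GAP_POSITIONS
    ]
    return inv


def build_frame_inventory(radical_level: int) -> list[FrameSpec]:
    """Return the 20-frame inventory for a radical level.

    Level 1 holds the 20 complete original frames; levels 2 and 3 hold the
    four retained base shapes x five completeness states (complete plus four
    single-edge-erased variants).
    """
    _check_level(radical_level)
    if radical_level == 1:
        return [FrameSpec(base_shape=s, family_level=1) for s in ORIGINAL_FRAMES]
    return [
        FrameSpec(base_shape=s, missing_line=m, family_level=radical_level)
        for s in ERASABLE_FRAMES
        for m in range(5)
    ]


# --- distractor assignment ----------------------------------------------

_REPAIR_CAP = 10_000


def assign_distractors(correct_frames, inventory, rng) -> list[tuple]:
    """Deal three distractor frames to each unit with global balance.

    Every inventory frame must occur exactly ``3 * n_units / len(inventory)``
    times across all distractor slots, each unit's three distractors must be
    distinct, and none may equal the unit's correct frame.  The dealing is a
    deterministic function of ``rng``: a pool of balanced frame tokens is
    shuffled and dealt three per unit, then conflicts are repaired by random
    pairwise swaps (capped, raising if the cap is hit).
    """
    n_units = len(correct_frames)
    n_frames = len(inventory)
    if (3 * n_units) % n_frames != 0:
        raise ValueError(
            f"balanced assignment infeasible: 3*{n_units} slots not divisible "
            f"by inventory size {n_frames}"
        )
    inv_keys = {f.key for f in inventory}
    for f in correct_frames:
        if f.key not in inv_keys:
            raise ValueError(f"correct frame {f.key} not in inventory")
    copies = (3 * n_units) // n_frames

    pool = np.repeat(np.arange(n_frames), copies)
    pool = pool[rng.permutation(3 * n_units)]
    slots = pool.reshape(n_units, 3)
    correct_idx = np.array(
        [next(j for j, f in enumerate(inventory) if f.key == cf.key) for cf in correct_frames]
    )

    def violations(u):
        row = slots[u]
        return (3 - len(set(row.tolist()))) + int(correct_idx[u] in row)

    def bad_units():
        dup = (slots[:, 0] == slots[:, 1]) | (slots[:, 0] == slots[:, 2]) | (
            slots[:, 1] == slots[:, 2]
        )
        hit = (slots == correct_idx[:, None]).any(axis=1)
        return np.flatnonzero(dup | hit)

    # random pairwise swaps, kept only when they strictly reduce the total
    # violation count (duplicates within a unit / unit's own correct frame),
    # so the repair cannot cycle
    for _ in range(_REPAIR_CAP):
        bad = bad_units()
        if bad.size == 0:
            break
        u = int(bad[int(rng.integers(bad.size))])
        a = int(rng.integers(3))
        v = int(rng.integers(n_units))
        b = int(rng.integers(3))
        if v == u:
            continue
        before = violations(u) + violations(v)
        slots[u, a], slots[v, b] = slots[v, b], slots[u, a]
        if violations(u) + violations(v) >= before:
            slots[u, a], slots[v, b] = slots[v, b], slots[u, a]
    else:
        raise RuntimeError(
            f"distractor repair did not converge within {_REPAIR_CAP} swaps "
            f"(n_units={n_units}, n_frames={n_frames})"
        )

    return [tuple(inventory[j] for j in slots[u]) for u in range(n_units)]


# --- item generation ------------------------------------------------------

# named substreams off the item seed; appending new streams never perturbs
# draws from existing ones
_STREAM_SUBSAMPLE = 0
_STREAM_PAIRING = 1
_STREAM_LEARNING = 2
_STREAM_RECALL = 3
_STREAM_DISTRACTORS = 4
_STREAM_OPTIONS = 5


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_item(radical_level: int, seed: int, n_units: int = 20) -> ItemSpec:
    """Generate one item deterministically from ``(radical_level, seed)``.

    The emblem-frame bijection, learning order, recall order and balanced
    distractor triples are all incidentals drawn from named substreams of
    ``seed``.  ``n_units`` may be reduced below 20 (easier test forms); the
    inventories are then subsampled first.
    """
    _check_level(radical_level)
    # three distinct distractors plus the distinct correct frame need an
    # inventory of at least four frames, so fewer than 4 units is infeasible
    if not 4 <= n_units <= 20:
        raise ValueError(f"n_units must be in 4..20, got {n_units}")

    emblems = build_emblem_inventory(radical_level)
    frames = build_frame_inventory(radical_level)
    if n_units < 20:
        rng = _substream(seed, _STREAM_SUBSAMPLE)
        emblems = [emblems[i] for i in rng.choice(20, size=n_units, replace=False)]
        frames = [frames[i] for i in rng.choice(20, size=n_units, replace=False)]

    pairing = _substream(seed, _STREAM_PAIRING).permutation(n_units)
    learning = _substream(seed, _STREAM_LEARNING).permutation(n_units)
    recall = _substream(seed, _STREAM_RECALL).permutation(n_units)
    correct = [frames[pairing[j]] for j in range(n_units)]
    distractors = assign_distractors(correct, frames, _substream(seed, _STREAM_DISTRACTORS))

    units = tuple(
        AssociationUnit(
            emblem=emblems[j],
            correct_frame=correct[j],
            learning_cell=int(learning[j]),
            recall_position=int(recall[j]),
            distractors=distractors[j],
        )
        for j in range(n_units)
    )
    item = ItemSpec(
        radical_level=radical_level,
        incidental_seed=int(seed),
        n_units=n_units,
        units=units,
    )
    item.validate()
    return item


def option_orders(item: ItemSpec) -> list[list[int]]:
    """Left-to-right answer-option order per unit (0 = correct frame).

    Derived from the item's own seed substream so that rendering stays a pure
    function of the ItemSpec.  Entry ``k`` of the returned inner list is the
    option drawn at slot ``k``: 0 denotes the correct frame, 1-3 the unit's
    distractors in stored order.
    """
    rng = _substream(item.incidental_seed, _STREAM_OPTIONS)
    return [rng.permutation(4).tolist() for _ in range(item.n_units)]


def generate_parallel_set(radical_level: int, n_items: int, master_seed: int) -> list[ItemSpec]:
    """Generate ``n_items`` isomorphs (same radical level, distinct incidentals)."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    items = []
    seen = set()
    k = 0
    while len(items) < n_items:
        child = int(
            np.random.SeedSequence([int(master_seed), 7919, k]).generate_state(1)[0]
            % (2**31 - 1)
        )
        k += 1
        item = generate_item(radical_level, child)
        bij = tuple(u.correct_frame.key for u in sorted(item.units, key=lambda u: u.emblem.key))
        if bij in seen:  # pragma: no cover - ~1/20! collision chance
            continue
        seen.add(bij)
        items.append(item)
    return items
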