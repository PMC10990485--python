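"""Task design: feature manifolds, category templates, and trial schedules.

The categorisation task presents *quadruplets*: sequences of four stimuli,
each drawn from a 4x4 two-dimensional feature manifold. A category is an
ordered triple of compass transition vectors between adjacent cells; the
four visited cells always tile one unit square of the grid. Quadruplets can
be rotated (90/180/270 degrees counterclockwise) and/or embedded in a second
"far transfer" manifold, giving eight transformations in total.

Coordinates are 0-based ``(i, j)`` with ``i`` the first (horizontal)
dimension and ``j`` the second (vertical); north is ``+j`` and east is
``+i``. The translation of a quadruplet is described by its *anchor*, the
lower-left corner of the occupied unit square, drawn from the nine anchors
of the 3x3 unit squares that fit inside the grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GRID_SIZE = 4
N_CATEGORIES = 3
ROTATIONS = (0, 90, 180, 270)
#: lower-left corners of the unit squares that fit in the 4x4 grid
ANCHORS = tuple(itertools.product(range(GRID_SIZE - 1), range(GRID_SIZE - 1)))

COMPASS = {
    "N": (0, 1), "S": (0, -1), "E": (1, 0), "W": (-1, 0),
    "NE": (1, 1), "NW": (-1, 1), "SE": (1, -1), "SW": (-1, -1),
}
_COMPASS_INV = {v: k for k, v in COMPASS.items()}

EXPERIMENT_IDS = ("1a", "1b", "1c", "2a", "2b", "2c", "3a", "3b", "3c", "4a", "4b")


@dataclass(frozen=True)
class ManifoldSpec:
    """A 4x4 feature grid; physical feature levels are metadata only."""

    manifold_id: str  # "original" | "far_transfer"
    dim_i_label: str = "i"
    dim_j_label: str = "j"
    grid_size: int = GRID_SIZE
    level_values: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.manifold_id not in ("original", "far_transfer"):
            raise ValueError(f"unknown manifold_id {self.manifold_id!r}")
        if self.grid_size != GRID_SIZE:
            raise ValueError("the task is defined on a 4x4 grid")
        if self.level_values is not None:
            if any(len(v) != GRID_SIZE for v in self.level_values):
                raise ValueError("level_values must list 4 levels per dimension")


@dataclass(frozen=True)
class CategoryTemplate:
    """One category's canonical (or rotated) triple of transition vectors."""

    category: int
    vectors: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.vectors) != 3:
            raise ValueError("a template has exactly 3 transition vectors")
        for di, dj in self.vectors:
            if (di, dj) == (0, 0) or abs(di) > 1 or abs(dj) > 1:
                raise ValueError(f"invalid compass step {(di, dj)}")
        offs = self.offsets()
        if len(set(offs)) != 4:
            raise ValueError("template must visit 4 distinct cells")
        si = {o[0] for o in offs}
        sj = {o[1] for o in offs}
        if len(si) != 2 or len(sj) != 2:
            raise ValueError("template walk must tile a unit square")

    def offsets(self) -> tuple[tuple[int, int], ...]:
        """Cumulative positions of the walk, starting from (0, 0)."""
        pos = [(0, 0)]
        for di, dj in self.vectors:
            pos.append((pos[-1][0] + di, pos[-1][1] + dj))
        return tuple(pos)

    @property
    def compass(self) -> tuple[str, ...]:
        return tuple(_COMPASS_INV[v] for v in self.vectors)


@dataclass(frozen=True)
class Transformation:
    """Rotation (degrees CCW) plus an optional far-transfer manifold switch."""

    rotation: int = 0
    far_transfer: bool = False

    def __post_init__(self) -> None:
        if self.rotation not in ROTATIONS:
            raise ValueError("rotation must be a multiple of 90 in [0, 270]")

    @property
    def label(self) -> str:
        base = f"{self.rotation}"
        return f"far+{base}" if self.far_transfer else base


# the eight transformations of the design
CANONICAL = Transformation(0, False)
ALL_TRANSFORMATIONS = tuple(
    Transformation(r, f) for f in (False, True) for r in ROTATIONS
)


@dataclass(frozen=True)
class QuadrupletTrial:
    """A single categorisation trial."""

    category: int
    transformation: Transformation
    anchor: tuple[int, int]
    positions: tuple[tuple[int, int], ...]
    phase: str = "training"  # pretraining | training | near_transfer | far_transfer
    feedback: bool = True
    trial_index: int = -1
    block_index: int = -1


@dataclass(frozen=True)
class MappingTrial:
    """One cross-modal association trial: report the cell of the stimulus."""

    target_cell: tuple[int, int]
    restriction: str = "both"  # i_only | j_only | both
    block_index: int = -1
    trial_index: int = -1


@dataclass(frozen=True)
class FillerTrial:
    """Colour-count sequence trial (three categories, location irrelevant)."""

    category: int
    location: tuple[int, int]
    block_index: int = -1
    trial_index: int = -1


@dataclass
class Phase:
    """One row of an experiment's schedule table."""

    day: int
    task: str  # quadruplet | mapping | filler
    n_trials: int
    transformations: tuple[Transformation, ...] = ()
    feedback: bool = True
    role: str = "test"  # pre | bridge | test
    restriction: str | None = None
    trials: list = field(default_factory=list)


@dataclass
class TrialSchedule:
    """The complete task schedule of one experiment for one participant."""

    experiment_id: str
    phases: list[Phase]

    @property
    def quadruplet_trials(self) -> list[QuadrupletTrial]:
        """All categorisation trials in temporal order."""
        out = [t for ph in self.phases if ph.task == "quadruplet" for t in ph.trials]
        return sorted(out, key=lambda t: t.trial_index)

    @property
    def trained_rotations(self) -> tuple[int, ...]:
        """Rotations shown with feedback in the testing-modality task."""
        rots: set[int] = set()
        for ph in self.phases:
            if ph.task == "quadruplet" and ph.feedback and ph.role in ("test", "bridge"):
                rots.update(tr.rotation for tr in ph.transformations)
        return tuple(sorted(rots))

    def day_total(self, day: int) -> int:
        return sum(ph.n_trials for ph in self.phases if ph.day == day)


# ---------------------------------------------------------------------------
# templates and quadruplet realisation
# ---------------------------------------------------------------------------

def canonical_templates() -> list[CategoryTemplate]:
    """The three canonical category templates: {E,N,W}, {NE,W,SE}, {N,SE,N}."""
    specs = [("E", "N", "W"), ("NE", "W", "SE"), ("N", "SE", "N")]
    return [
        CategoryTemplate(c, tuple(COMPASS[s] for s in steps))
        for c, steps in enumerate(specs)
    ]


def rotate_vector(vector: tuple[int, int], rotation: int) -> tuple[int, int]:
    """Rotate a compass step counterclockwise by a multiple of 90 degrees."""
    if rotation % 90 or rotation % 360 not in ROTATIONS:
        raise ValueError("rotation must be a multiple of 90 degrees")
    di, dj = vector
    for _ in range((rotation % 360) // 90):
        di, dj = -dj, di
    return di, dj


def rotate_template(template: CategoryTemplate, rotation: int) -> CategoryTemplate:
    return CategoryTemplate(
        template.category, tuple(rotate_vector(v, rotation) for v in template.vectors)
    )


def realise_quadruplet(
    category: int,
    transformation: Transformation,
    anchor: tuple[int, int],
    phase: str = "training",
    feedback: bool = True,
    trial_index: int = -1,
    block_index: int = -1,
) -> QuadrupletTrial:
    """Place a rotated category template inside the unit square at ``anchor``.

    The start stimulus is the unique cell of the square from which the
    rotated walk stays inside the square (each template visits all four
    cells, so the start is ``anchor`` minus the walk's minimal offsets).
    """
    if not (0 <= anchor[0] <= 2 and 0 <= anchor[1] <= 2):
        raise ValueError(f"anchor {anchor} outside the 3x3 anchor range")
    if category not in range(N_CATEGORIES):
        raise ValueError(f"unknown category {category}")
    template = rotate_template(canonical_templates()[category], transformation.rotation)
    offs = template.offsets()
    start = (
        anchor[0] - min(o[0] for o in offs),
        anchor[1] - min(o[1] for o in offs),
    )
    positions = tuple((start[0] + o[0], start[1] + o[1]) for o in offs)
    return QuadrupletTrial(
        category=category,
        transformation=transformation,
        anchor=anchor,
        positions=positions,
        phase=phase,
        feedback=feedback,
        trial_index=trial_index,
        block_index=block_index,
    )


def enumerate_quadruplets(
    rotations, far_transfer: bool = False, phase: str = "training"
) -> list[QuadrupletTrial]:
    """All category x rotation x anchor trials, in deterministic order."""
    rotations = tuple(rotations)
    if not rotations:
        raise ValueError("rotations must be non-empty")
    return [
        realise_quadruplet(c, Transformation(r, far_transfer), a, phase=phase)
        for c in range(N_CATEGORIES)
        for r in rotations
        for a in ANCHORS
    ]


def pattern_of(trial: QuadrupletTrial, dimension: str, signed: bool = True) -> str:
    """4-letter level pattern of the trial on one dimension.

    'A' marks the lower of the two levels the quadruplet occupies on that
    dimension. The unsigned variant identifies a pattern with its A<->B
    swap, returning the lexicographically smaller representative.
    """
    axis = {"i": 0, "j": 1}[dimension]
    coords = [p[axis] for p in trial.positions]
    lo = min(coords)
    token = "".join("A" if c == lo else "B" for c in coords)
    return token if signed else unsigned_pattern(token)


def unsigned_pattern(token: str) -> str:
    swap = token.translate(str.maketrans("AB", "BA"))
    return min(token, swap)


# ---------------------------------------------------------------------------
# schedules (Exp. 1-4)
# ---------------------------------------------------------------------------

_T0 = Transformation(0)
_T90 = Transformation(90)
_T180 = Transformation(180)
_T270 = Transformation(270)
_F0 = Transformation(0, True)
_F90 = Transformation(90, True)
_F180 = Transformation(180, True)
_F270 = Transformation(270, True)

_EXP1_TRANSFER = (_T90, _T180, _T270, _F0, _F90, _F180, _F270)
_EXP234_TRANSFER = (_T180, _T270, _F0, _F90, _F180, _F270)


def _row(day, task, n, trans=(), fb=True, role="test", restriction=None, mixed=False):
    return dict(day=day, task=task, n=n, trans=tuple(trans), fb=fb, role=role,
                restriction=restriction, mixed=mixed)


def _mapping_day1_block():
    return [
        _row(1, "mapping", 48, restriction="i_only"),
        _row(1, "mapping", 48, restriction="j_only"),
        _row(1, "mapping", 48, restriction="both"),
        _row(1, "mapping", 48, restriction="i_only"),
        _row(1, "mapping", 48, restriction="j_only"),
        _row(1, "mapping", 96, restriction="both"),
    ]


def _exp1_rows():
    return [
        _row(1, "quadruplet", 120, (_T0,), True),
        _row(1, "quadruplet", 105, (_T0,), True, mixed=True),
        _row(1, "quadruplet", 105, _EXP1_TRANSFER, False),
    ]


def _exp23_rows(pretrain_trans):
    bridge_trans = pretrain_trans
    return [
        _row(1, "quadruplet", 60, pretrain_trans, True, role="pre"),
        *_mapping_day1_block(),
        _row(2, "quadruplet", 60, pretrain_trans, True, role="pre"),
        _row(2, "mapping", 48, restriction="i_only"),
        _row(2, "mapping", 48, restriction="j_only"),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 30, bridge_trans, True, role="bridge"),
        _row(2, "quadruplet", 30, (_T0, _T90), True),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 60, (_T0, _T90), True),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 90, (_T0, _T90), True, mixed=True),
        _row(2, "quadruplet", 90, _EXP234_TRANSFER, False),
    ]


def _exp4_rows():
    return [
        _row(1, "filler", 60),
        *_mapping_day1_block(),
        _row(2, "filler", 60),
        _row(2, "mapping", 48, restriction="i_only"),
        _row(2, "mapping", 48, restriction="j_only"),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 60, (_T0, _T90), True),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 60, (_T0, _T90), True),
        _row(2, "mapping", 48, restriction="both"),
        _row(2, "quadruplet", 90, (_T0, _T90), True, mixed=True),
        _row(2, "quadruplet", 90, _EXP234_TRANSFER, False),
    ]


def _schedule_rows(experiment_id: str):
    fam = experiment_id[0]
    if fam == "1":
        return _exp1_rows()
    if fam == "2":
        return _exp23_rows((_T0, _T90))
    if fam == "3":
        return _exp23_rows((_T0,))
    if fam == "4":
        return _exp4_rows()
    raise ValueError(f"unknown experiment id {experiment_id!r}")


def _phase_label(transformation: Transformation, feedback: bool, role: str) -> str:
    if transformation.far_transfer:
        return "far_transfer"
    if not feedback:
        return "near_transfer"
    return "pretraining" if role == "pre" else "training"


def _balanced_rotations(transformations, n: int, cursor: dict) -> list[Transformation]:
    """Round-robin assignment keeping transformation counts balanced."""
    key = transformations
    start = cursor.get(key, 0)
    out = [transformations[(start + k) % len(transformations)] for k in range(n)]
    cursor[key] = (start + n) % len(transformations)
    return out


def _training_block_trials(transformations, rng, cursor, feedback, role):
    """One 30-trial categorisation block: each category 10 times."""
    trials = []
    for c in range(N_CATEGORIES):
        for tf in _balanced_rotations(transformations, 10, cursor.setdefault(c, {})):
            a = ANCHORS[rng.integers(len(ANCHORS))]
            trials.append(realise_quadruplet(
                c, tf, a, phase=_phase_label(tf, feedback, role), feedback=feedback))
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def _mixed_block_trials(train_trans, transfer_trans, rng, train_cursor, transfer_cursor, role):
    """One mixed block: per category 5 feedback + 5 transfer trials."""
    trials = []
    for c in range(N_CATEGORIES):
        for tf in _balanced_rotations(train_trans, 5, train_cursor.setdefault(c, {})):
            a = ANCHORS[rng.integers(len(ANCHORS))]
            trials.append(realise_quadruplet(
                c, tf, a, phase=_phase_label(tf, True, role), feedback=True))
        for tf in _balanced_rotations(transfer_trans, 5, transfer_cursor.setdefault(c, {})):
            a = ANCHORS[rng.integers(len(ANCHORS))]
            trials.append(realise_quadruplet(
                c, tf, a, phase=_phase_label(tf, False, role), feedback=False))
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def build_mapping_block(
    restriction: str, rng: np.random.Generator, block_index: int = -1
) -> list[MappingTrial]:
    """A 48-trial mapping block: each of the 16 cells exactly three times.

    In restricted blocks the fixed dimension is held constant within runs of
    12 trials (one run per level), so within a run only the requested
    dimension varies.
    """
    if restriction not in ("i_only", "j_only", "both"):
        raise ValueError(f"unknown restriction {restriction!r}")
    cells = list(itertools.product(range(GRID_SIZE), range(GRID_SIZE)))
    trials: list[MappingTrial] = []
    if restriction == "both":
        targets = cells * 3
        order = rng.permutation(len(targets))
        targets = [targets[k] for k in order]
    else:
        fixed_axis = 1 if restriction == "i_only" else 0
        targets = []
        for level in rng.permutation(GRID_SIZE):
            run = [c for c in cells if c[fixed_axis] == level] * 3
            order = rng.permutation(len(run))
            targets.extend(run[k] for k in order)
    for t in targets:
        trials.append(MappingTrial(tuple(t), restriction, block_index=block_index))
    return trials


def _filler_block_trials(rng):
    trials = []
    for c in range(N_CATEGORIES):
        for _ in range(10):
            loc = (int(rng.integers(GRID_SIZE)), int(rng.integers(GRID_SIZE)))
            trials.append(FillerTrial(c, loc))
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def build_schedule(experiment_id: str, rng_seed: int = 0) -> TrialSchedule:
    """Generate the full pseudo-randomised schedule of one experiment.

    Trial counts, allowed transformations and feedback flags follow the
    published schedule tables row for row; every 30-trial categorisation
    block contains each category exactly 10 times; in mixed train/transfer
    phases the two row's trials are randomly interleaved within blocks.
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    rng = np.random.default_rng(rng_seed)
    rows = _schedule_rows(experiment_id)
    phases: list[Phase] = []
    quad_index = 0
    map_index = 0
    fill_index = 0
    block_counter = 0
    row_iter = iter(range(len(rows)))
    for r in row_iter:
        row = rows[r]
        if row["task"] == "quadruplet" and row["mixed"]:
            partner = rows[r + 1]
            next(row_iter)  # consume the transfer row
            n_blocks = (row["n"] + partner["n"]) // 30
            ph_train = Phase(row["day"], "quadruplet", row["n"], row["trans"],
                             True, row["role"])
            ph_transfer = Phase(partner["day"], "quadruplet", partner["n"],
                                partner["trans"], False, partner["role"])
            train_cur: dict = {}
            transfer_cur: dict = {}
            for _ in range(n_blocks):
                block = _mixed_block_trials(row["trans"], partner["trans"], rng,
                                            train_cur, transfer_cur, row["role"])
                for t in block:
                    t = replace(t, trial_index=quad_index, block_index=block_counter)
                    quad_index += 1
                    (ph_train if t.feedback else ph_transfer).trials.append(t)
                block_counter += 1
            phases.extend([ph_train, ph_transfer])
        elif row["task"] == "quadruplet":
            ph = Phase(row["day"], "quadruplet", row["n"], row["trans"],
                       row["fb"], row["role"])
            cursor: dict = {}
            for _ in range(row["n"] // 30):
                for t in _training_block_trials(row["trans"], rng, cursor,
                                                row["fb"], row["role"]):
                    ph.trials.append(replace(t, trial_index=quad_index,
                                             block_index=block_counter))
                    quad_index += 1
                block_counter += 1
            phases.append(ph)
        elif row["task"] == "mapping":
            ph = Phase(row["day"], "mapping", row["n"], (), True, "test",
                       row["restriction"])
            for _ in range(row["n"] // 48):
                for t in build_mapping_block(row["restriction"], rng, block_counter):
                    ph.trials.append(replace(t, trial_index=map_index))
                    map_index += 1
                block_counter += 1
            phases.append(ph)
        elif row["task"] == "filler":
            ph = Phase(row["day"], "filler", row["n"], (), True, "pre")
            for _ in range(row["n"] // 30):
                for t in _filler_block_trials(rng):
                    ph.trials.append(replace(t, trial_index=fill_index,
                                             block_index=block_counter))
                    fill_index += 1
                block_counter += 1
            phases.append(ph)
    return TrialSchedule(experiment_id, phases)


# ---------------------------------------------------------------------------
# delimited export
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "experiment_id", "day", "phase_index", "phase", "task", "trial_index",
    "block_index", "category", "rotation_deg", "far_transfer",
    "anchor_i", "anchor_j",
    "pos1_i", "pos1_j", "pos2_i", "pos2_j", "pos3_i", "pos3_j", "pos4_i", "pos4_j",
    "feedback",
]


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Flatten the categorisation trials of a schedule to a tidy table."""
    rows = []
    for k, ph in enumerate(schedule.phases):
        if ph.task != "quadruplet":
            continue
        for t in ph.trials:
            row = {
                "experiment_id": schedule.experiment_id,
                "day": ph.day,
                "phase_index": k,
                "phase": t.phase,
                "task": "quadruplet",
                "trial_index": t.trial_index,
                "block_index": t.block_index,
                "category": t.category,
                "rotation_deg": t.transformation.rotation,
                "far_transfer": int(t.transformation.far_transfer),
                "anchor_i": t.anchor[0],
                "anchor_j": t.anchor[1],
                "feedback": int(t.feedback),
            }
            for p, (pi, pj) in enumerate(t.positions, start=1):
                row[f"pos{p}_i"] = pi
                row[f"pos{p}_j"] = pj
            rows.append(row)
    frame = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return frame.sort_values("trial_index").reset_index(drop=True)


def trial_from_row(row) -> QuadrupletTrial:
    """Rebuild a :class:`QuadrupletTrial` from one exported table row."""
    return QuadrupletTrial(
        category=int(row["category"]),
        transformation=Transformation(int(row["rotation_deg"]),
                                      bool(int(row["far_transfer"]))),
        anchor=(int(row["anchor_i"]), int(row["anchor_j"])),
        positions=tuple((int(row[f"pos{p}_i"]), int(row[f"pos{p}_j"]))
                        for p in range(1, 5)),
        phase=str(row["phase"]),
        feedback=bool(int(row["feedback"])),
        trial_index=int(row["trial_index"]),
        block_index=int(row["block_index"]),
    )
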