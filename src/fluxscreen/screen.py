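"""Composable parallel screening of model variants.

This is the architectural core of the package. An analysis over many model
variants is decomposed into independent tasks -- one per cell of a Cartesian
variant grid -- executed by a single-machine worker pool and collected into
a dense multi-dimensional result array whose axes are the grid axes.

Three contracts make this safe and reproducible:

* **Purity** -- variants are applied to fresh copies; the base model is
  never mutated, so any number of cells may run concurrently.
* **Serializability** -- variants are plain-value transformation descriptors
  and analyses are referenced by registered name plus keyword arguments,
  never by closure, so tasks can cross process boundaries and screens are
  reproducible from their logs.
* **Determinism** -- cells are assembled in row-major grid order regardless
  of execution order, so results are identical for any worker count and any
  scheduling.

No in-scope analysis is stochastic; an optional integer seed is nevertheless
threaded to each cell (offset by the cell's flat index) for analyses that
declare a ``seed`` parameter.
"""

from __future__ import annotations

import inspect
import itertools
import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import ScreenConfigError, UnknownIdError
from .model import MetabolicModel, apply_knockout, change_bounds, set_objective

__all__ = [
    "Knockout",
    "BoundChange",
    "ObjectiveChange",
    "Variant",
    "VariantGrid",
    "variant_grid",
    "apply_variant",
    "register_analysis",
    "get_analysis",
    "list_analyses",
    "screen",
    "screen_fallible",
    "ScreenResult",
    "ScreenError",
    "parallel_map",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Transformation descriptors and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Knockout:
    """Knock out a set of genes (reactions whose GPR turns false get bounds
    (0, 0))."""

    genes: frozenset[str]

    def __init__(self, genes: Iterable[str]):
        object.__setattr__(self, "genes", frozenset(genes))

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        return apply_knockout(model, self.genes)

    def describe(self) -> str:
        return "ko:" + ",".join(sorted(self.genes)) if self.genes else "ko:-"


@dataclass(frozen=True)
class BoundChange:
    """Replace a reaction's bounds; a ``None`` side is kept unchanged."""

    reaction_id: str
    lower: Optional[float] = None
    upper: Optional[float] = None

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        return change_bounds(model, self.reaction_id, self.lower, self.upper)

    def describe(self) -> str:
        return f"bounds:{self.reaction_id}:{self.lower}:{self.upper}"


@dataclass(frozen=True)
class ObjectiveChange:
    """Replace the model objective with the given weight map (reactions not
    listed get coefficient zero)."""

    weights: tuple[tuple[str, float], ...]

    def __init__(self, weights: Mapping[str, float]):
        object.__setattr__(self, "weights", tuple(sorted(weights.items())))

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        return set_objective(model, dict(self.weights))

    def describe(self) -> str:
        return "obj:" + ",".join(f"{r}={w:g}" for r, w in self.weights)


@dataclass(frozen=True)
class Variant:
    """An ordered list of transformation descriptors plus a human-readable
    label. Descriptors are plain values (no live model references), so a
    variant can be pickled into a worker process and replayed there."""

    transforms: tuple = ()
    label: str = ""

    def __post_init__(self):
        if not self.label:
            text = ";".join(t.describe() for t in self.transforms) or "identity"
            object.__setattr__(self, "label", text)

    def __add__(self, other: "Variant") -> "Variant":
        return Variant(
            transforms=self.transforms + other.transforms,
            label=f"{self.label}|{other.label}",
        )


def apply_variant(model: MetabolicModel, variant: Variant) -> MetabolicModel:
    """Apply a variant's descriptors left-to-right to a fresh copy.

    Later descriptors win when they touch the same reaction. Unknown ids
    raise :class:`UnknownIdError` carrying the variant label.
    """
    out = model.copy()
    for t in variant.transforms:
        try:
            out = t.apply(out)
        except UnknownIdError as exc:
            raise UnknownIdError(
                f"variant {variant.label!r}: {exc}"
            ) from exc
    return out


@dataclass(frozen=True)
class VariantGrid:
    """Cartesian product of variant axes with shape metadata.

    Iteration yields combined variants (concatenated descriptor lists) in
    row-major order: the last axis varies fastest. Cell ``k`` of the flat
    iteration corresponds to ``numpy.unravel_index(k, shape)``.
    """

    axes: tuple[tuple[Variant, ...], ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(ax) for ax in self.axes)

    @property
    def size(self) -> int:
        return int(math.prod(self.shape))

    def __iter__(self) -> Iterator[Variant]:
        for combo in itertools.product(*self.axes):
            merged = combo[0]
            for v in combo[1:]:
                merged = merged + v
            yield merged

    def labels(self) -> tuple[tuple[str, ...], ...]:
        return tuple(tuple(v.label for v in ax) for ax in self.axes)


def variant_grid(axes: Sequence[Sequence[Variant]]) -> VariantGrid:
    """Build a :class:`VariantGrid` from per-axis variant lists."""
    if not axes:
        raise ScreenConfigError("variant grid needs at least one axis")
    for i, ax in enumerate(axes):
        if not ax:
            raise ScreenConfigError(f"variant axis {i} is empty")
    return VariantGrid(axes=tuple(tuple(ax) for ax in axes))


# ---------------------------------------------------------------------------
# Analysis registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable] = {}


def register_analysis(name: str):
    """Register a pure analysis function ``f(model, **kwargs) -> value``
    under a stable name so it can be referenced across process boundaries."""

    def deco(func):
        _REGISTRY[name] = func
        return func

    return deco


def get_analysis(name: str) -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ScreenConfigError(
            f"analysis {name!r} is not registered; known: "
            + ", ".join(sorted(_REGISTRY))
        ) from None


def list_analyses() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# Worker pool
# ---------------------------------------------------------------------------

def parallel_map(func, items, workers: int = 1, initializer=None, initargs=()):
    """Map ``func`` over ``items`` preserving order, optionally across a
    process pool.

    ``workers <= 1`` runs in-process (the initializer, if any, is called
    once first). Results are collected in input order regardless of
    completion order, which is what guarantees scheduling-invariant output.
    """
    items = list(items)
    if workers <= 1 or len(items) <= 1:
        if initializer is not None:
            initializer(*initargs)
        return [func(it) for it in items]
    chunksize = max(1, len(items) // (workers * 4))
    with ProcessPoolExecutor(
        max_workers=workers, initializer=initializer, initargs=initargs
    ) as pool:
        return list(pool.map(func, items, chunksize=chunksize))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenError:
    """Explicit error value stored in a result cell by
    :func:`screen_fallible` when that cell's task raised."""

    code: str
    message: str
    label: str


@dataclass
class ScreenResult:
    """Dense result array of a screen.

    ``values`` and ``labels`` are object ndarrays shaped like the variant
    grid; ``values[i, j, ...]`` is the analysis output for the variant
    combining element i of axis 0 with element j of axis 1, and so on.
    """

    values: np.ndarray
    labels: np.ndarray
    axis_labels: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.values.shape)

    @property
    def n_failed(self) -> int:
        return sum(
            1 for v in self.values.flat if isinstance(v, ScreenError)
        )

    def tolist(self):
        return self.values.tolist()


# Per-worker state installed by the pool initializer: the pickled base model
# and the analysis to run. Referencing analyses by name (not by function
# object) keeps tasks serializable and logs replayable.
_CELL_STATE: dict = {}


def _init_cells(model, analysis_name, kwargs, seed, fallible):
    func = get_analysis(analysis_name)
    takes_seed = seed is not None and "seed" in inspect.signature(func).parameters
    _CELL_STATE.update(
        model=model,
        func=func,
        kwargs=kwargs,
        seed=seed,
        takes_seed=takes_seed,
        fallible=fallible,
    )


def _run_cell(task):
    index, variant = task
    st = _CELL_STATE
    try:
        variant_model = apply_variant(st["model"], variant)
        kwargs = st["kwargs"]
        if st["takes_seed"]:
            kwargs = dict(kwargs, seed=st["seed"] + index)
        return st["func"](variant_model, **kwargs)
    except Exception as exc:
        if st["fallible"]:
            return ScreenError(
                code=type(exc).__name__, message=str(exc), label=variant.label
            )
        raise


def _screen_impl(
    model: MetabolicModel,
    axes: Sequence[Sequence[Variant]],
    analysis: str,
    analysis_args: Optional[Mapping] = None,
    workers: int = 1,
    seed: Optional[int] = None,
    fallible: bool = False,
) -> ScreenResult:
    grid = axes if isinstance(axes, VariantGrid) else variant_grid(axes)
    get_analysis(analysis)  # fail fast on unregistered names
    if workers < 1:
        raise ScreenConfigError("workers must be >= 1")
    kwargs = dict(analysis_args or {})

    variants = list(grid)
    tasks = list(enumerate(variants))
    cells = parallel_map(
        _run_cell,
        tasks,
        workers=workers,
        initializer=_init_cells,
        initargs=(model, analysis, kwargs, seed, fallible),
    )

    values = np.empty(grid.shape, dtype=object)
    labels = np.empty(grid.shape, dtype=object)
    for k, (cell, variant) in enumerate(zip(cells, variants)):
        idx = np.unravel_index(k, grid.shape)
        values[idx] = cell
        labels[idx] = variant.label

    result = ScreenResult(
        values=values, labels=labels, axis_labels=grid.labels()
    )
    if fallible and result.n_failed:
        failed = [
            v.label for v in result.values.flat if isinstance(v, ScreenError)
        ]
        logger.warning(
            "screen finished with %d/%d failed cells: %s",
            result.n_failed,
            grid.size,
            ", ".join(failed[:10]) + ("..." if len(failed) > 10 else ""),
        )
    return result


def screen(
    model: MetabolicModel,
    axes: Sequence[Sequence[Variant]],
    analysis: str,
    analysis_args: Optional[Mapping] = None,
    workers: int = 1,
    seed: Optional[int] = None,
) -> ScreenResult:
    """Run a registered analysis over every cell of a variant grid.

    Each cell applies its combined variant to a fresh copy of ``model`` and
    runs ``analysis`` on the result. Execution order is unspecified, but the
    assembled array is deterministic: identical for any ``workers`` count
    and any scheduling. A failing cell aborts the whole screen; use
    :func:`screen_fallible` to keep going.
    """
    return _screen_impl(
        model, axes, analysis, analysis_args, workers, seed, fallible=False
    )


def screen_fallible(
    model: MetabolicModel,
    axes: Sequence[Sequence[Variant]],
    analysis: str,
    analysis_args: Optional[Mapping] = None,
    workers: int = 1,
    seed: Optional[int] = None,
) -> ScreenResult:
    """Like :func:`screen`, but a cell whose task raises stores a
    :class:`ScreenError` value instead of aborting; no cell is ever a hole.
    A summary of failed cells is logged."""
    return _screen_impl(
        model, axes, analysis, analysis_args, workers, seed, fallible=True
    )
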