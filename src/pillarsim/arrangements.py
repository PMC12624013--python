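"""Pillar arrangements: soil-microstructure analogues on a pixel lattice.

A culture field is a ``field_size`` × ``field_size`` grid in which circular
pillars (radius ``pillar_radius`` px) stand in for soil particles; the empty
pixels between them are the pore space bacteria can occupy.  Four arrangement
families are supported:

``bulk``
    No pillars — an open chamber used as the control condition.
``array``
    A uniform square lattice of pillars (no aggregation), centre pitch
    ``2·radius + array_gap``.
``block``
    Periodic blocks of ``n×n`` densely packed pillars (intra-block
    edge-to-edge gap ``d``), interpolating between the array (``n=1``, or
    ``d=8``) and strongly aggregated layouts.
``fractal``
    A hierarchical, self-similar clustering of pillars whose box-counting
    dimension (~1.81) mimics the fractal pore-size distribution of soil
    aggregates, with a 3-px minimum gap between pillars.

All layouts are deterministic functions of their spec (the constructions are
themselves deterministic; the ``seed`` field is carried for provenance and
forward compatibility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ArrangementSpec",
    "PillarLayout",
    "PeripheryMask",
    "BoxCountResult",
    "ConfigurationError",
    "DEFAULT_FRACTAL_LEVELS",
    "DEFAULT_BOX_SIZES",
    "make_layout",
    "make_fractal_layout",
    "periphery_mask",
    "box_counting_dimension",
    "layout_summary",
]


class ConfigurationError(ValueError):
    """A geometrically or logically infeasible arrangement/simulation spec."""


#: Fractal hierarchy, innermost level first: (cells_per_side, edge-to-edge gap px).
#: Level 0 groups single pillars into clusters; each further level groups the
#: previous level's units with a geometrically larger gap.  With a 6-px pillar
#: radius this yields 2×2 pillars (gap 3) → 2×2 clusters (gap 6) → 3×3 groups
#: (gap 36): 144 pillars in a 252-px pattern, matching the 12×12 array count
#: exactly; the gap scale factors were calibrated once against the
#: box-counting dimension target (≈1.8) for the default field.
DEFAULT_FRACTAL_LEVELS: tuple[tuple[int, int], ...] = ((2, 3), (2, 6), (3, 36))

#: Grid-aligned box sizes for box counting (anchored at the (0,0) corner).
DEFAULT_BOX_SIZES: tuple[int, ...] = (64, 32, 16, 8, 4, 2)

_KINDS = ("fractal", "array", "bulk", "block")


@dataclass(frozen=True)
class ArrangementSpec:
    """Parameters defining a pillar arrangement.

    Parameters
    ----------
    kind:
        One of ``fractal``, ``array``, ``bulk``, ``block``.
    field_size:
        Side length of the square field in pixels.
    pillar_radius:
        Pillar radius in pixels; a pixel is a pillar pixel iff its centre lies
        within this Euclidean radius of a pillar centre.
    block_n:
        Pillars per block side (block kind only).
    intra_block_gap:
        Edge-to-edge gap *d* between pillars inside a block (block kind only).
    array_gap:
        Edge-to-edge gap between array pillars (array kind), default 8 px.
    fractal_min_gap:
        Minimum edge-to-edge gap in the fractal arrangement, default 3 px.
    seed:
        Carried into derived simulations; the layout constructions themselves
        are deterministic.
    """

    kind: str
    field_size: int = 256
    pillar_radius: int = 6
    block_n: int | None = None
    intra_block_gap: int | None = None
    array_gap: int = 8
    fractal_min_gap: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown arrangement kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.pillar_radius <= 0:
            raise ConfigurationError("pillar_radius must be positive")
        if self.field_size <= 4 * self.pillar_radius:
            raise ConfigurationError(
                "field_size must exceed 4×pillar_radius "
                f"(got {self.field_size} ≤ {4 * self.pillar_radius})"
            )
        is_block = self.kind == "block"
        has_block_params = self.block_n is not None or self.intra_block_gap is not None
        if is_block and (self.block_n is None or self.intra_block_gap is None):
            raise ConfigurationError("block arrangements require block_n and intra_block_gap")
        if not is_block and has_block_params:
            raise ConfigurationError(
                "block_n/intra_block_gap are only valid for kind='block'"
            )
        if is_block:
            if self.block_n < 1:
                raise ConfigurationError("block_n must be ≥ 1")
            if self.intra_block_gap < 1:
                raise ConfigurationError("intra_block_gap must be ≥ 1 px")
        if self.array_gap < 1:
            raise ConfigurationError("array_gap must be ≥ 1 px")
        if self.fractal_min_gap < 1:
            raise ConfigurationError("fractal_min_gap must be ≥ 1 px")


@dataclass
class PillarLayout:
    """A realised arrangement: obstacle mask plus pillar centres.

    Attributes
    ----------
    obstacle_mask:
        Boolean ``field_size × field_size`` grid, ``True`` on pillar pixels.
    centers:
        ``(m, 2)`` integer array of (row, col) pillar centres.
    spec:
        The :class:`ArrangementSpec` the layout was built from.
    """

    obstacle_mask: np.ndarray
    centers: np.ndarray
    spec: ArrangementSpec

    @property
    def field_size(self) -> int:
        return self.obstacle_mask.shape[0]

    @property
    def pillar_count(self) -> int:
        return len(self.centers)

    @property
    def empty_pixel_count(self) -> int:
        return int(self.obstacle_mask.size - self.obstacle_mask.sum())

    def min_edge_gap(self) -> float:
        """Minimum edge-to-edge distance between pillars (inf if < 2 pillars).

        Edge-to-edge distance is the Euclidean centre distance minus the two
        radii (pillars are circles of the spec's radius).
        """
        if len(self.centers) < 2:
            return float("inf")
        c = self.centers.astype(float)
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min() - 2 * self.spec.pillar_radius)


@dataclass
class PeripheryMask:
    """Non-pillar pixels lying within ``band_width`` px of a pillar pixel."""

    mask: np.ndarray
    band_width: int
    metric: str = "euclidean"


@dataclass
class BoxCountResult:
    """Box-counting estimate: fitted dimension plus per-size occupied counts."""

    dimension: float
    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]


# ---------------------------------------------------------------------------
# layout construction
# ---------------------------------------------------------------------------


def _rasterize(centers: np.ndarray, field_size: int, radius: int) -> np.ndarray:
    mask = np.zeros((field_size, field_size), dtype=bool)
    if len(centers) == 0:
        return mask
    offs = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    disc = dr * dr + dc * dc <= radius * radius
    dr, dc = dr[disc], dc[disc]
    for r, c in centers:
        mask[r + dr, c + dc] = True
    return mask


def _grid_1d(n_blocks: int, n: int, intra_pitch: int, block_pitch: int, field: int, radius: int):
    """Centred 1-D positions for an n-per-block, n_blocks-block pillar row."""
    span_centres = (n_blocks - 1) * block_pitch + (n - 1) * intra_pitch
    span = span_centres + 2 * radius
    if span > field:
        raise ConfigurationError(
            f"arrangement does not fit: pattern span {span} px exceeds field {field} px"
        )
    first = round((field - span) / 2) + radius
    pos = []
    for b in range(n_blocks):
        for i in range(n):
            pos.append(first + b * block_pitch + i * intra_pitch)
    return pos


def _block_centers(spec: ArrangementSpec, n: int, d: int) -> np.ndarray:
    """Pillar centres for a block layout (the array is the n=1 special case).

    Blocks sit on an n-scaled array grid: the block-centre pitch is
    ``n·(2r + array_gap)``, so the total pillar count equals the array's and
    the layouts with ``n=1`` (any d) or ``d=8`` (any n) coincide with the
    array exactly.
    """
    r = spec.pillar_radius
    array_pitch = 2 * r + spec.array_gap
    per_side = spec.field_size // array_pitch  # array pillars per side
    if per_side < 1:
        raise ConfigurationError("field too small for a single pillar at the array pitch")
    intra_pitch = 2 * r + d
    block_pitch = n * array_pitch
    if n > 1:
        inter_gap = block_pitch - (n - 1) * intra_pitch - 2 * r
        if inter_gap < 1:
            raise ConfigurationError(
                f"blocks overlap their neighbours: n={n}, d={d} leaves an "
                f"inter-block gap of {inter_gap} px"
            )
    if per_side % n == 0:
        n_blocks = per_side // n
    else:
        n_blocks = max(1, per_side // n)
        got = (n_blocks * n) ** 2
        want = per_side**2
        if abs(got - want) / want > 0.10:
            warnings.warn(
                f"block layout n={n} cannot match the array pillar count in a "
                f"{spec.field_size}-px field ({got} vs {want} pillars)",
                stacklevel=3,
            )
    rows = _grid_1d(n_blocks, n, intra_pitch, block_pitch, spec.field_size, r)
    cols = rows
    return np.array([(ri, ci) for ri in rows for ci in cols], dtype=np.int64)


def make_fractal_layout(
    spec: ArrangementSpec,
    levels: tuple[tuple[int, int], ...] = DEFAULT_FRACTAL_LEVELS,
) -> PillarLayout:
    """Build the hierarchical (self-similar) fractal arrangement.

    ``levels`` lists, innermost first, ``(cells_per_side, gap)`` pairs: single
    pillars are grouped into clusters with the first gap, clusters into groups
    with the second, and so on, with gaps growing geometrically.  The
    innermost gap is forced to ``spec.fractal_min_gap``.  The construction is
    deterministic.

    Raises
    ------
    ConfigurationError
        If the hierarchy does not fit in the field, or if the resulting
        pillar count deviates from the array count by more than 10%.
    """
    if spec.kind != "fractal":
        raise ConfigurationError("make_fractal_layout requires kind='fractal'")
    if len(levels) < 3:
        raise ConfigurationError("fractal hierarchy needs at least 3 levels")
    levels = ((levels[0][0], spec.fractal_min_gap),) + tuple(levels[1:])

    r = spec.pillar_radius
    # 1-D offsets of pillar centres inside one unit, built level by level.
    offsets = np.array([0.0])
    extent = 2.0 * r  # pixel extent of one unit along an axis
    for cells, gap in levels:
        pitch = extent + gap
        starts = np.arange(cells) * pitch
        offsets = (starts[:, None] + offsets[None, :]).ravel()
        extent = (cells - 1) * pitch + extent

    # pixel indices run 0..field_size-1, so a span of `extent` px needs
    # extent ≤ field_size - 1
    if extent > spec.field_size - 1:
        raise ConfigurationError(
            f"fractal hierarchy span {extent:.0f} px exceeds the {spec.field_size}-px field"
        )
    first = round((spec.field_size - extent) / 2) + r
    axis = np.round(first + offsets).astype(np.int64)
    centers = np.array([(ri, ci) for ri in axis for ci in axis], dtype=np.int64)

    array_count = (spec.field_size // (2 * r + spec.array_gap)) ** 2
    if array_count and abs(len(centers) - array_count) / array_count > 0.10:
        raise ConfigurationError(
            f"fractal hierarchy yields {len(centers)} pillars, more than 10% away "
            f"from the array count {array_count}; adjust the level structure"
        )
    return PillarLayout(_rasterize(centers, spec.field_size, r), centers, spec)


def make_layout(spec: ArrangementSpec) -> PillarLayout:
    """Realise an :class:`ArrangementSpec` as a :class:`PillarLayout`."""
    if spec.kind == "bulk":
        centers = np.empty((0, 2), dtype=np.int64)
        return PillarLayout(_rasterize(centers, spec.field_size, spec.pillar_radius), centers, spec)
    if spec.kind == "array":
        centers = _block_centers(spec, 1, spec.array_gap)
    elif spec.kind == "block":
        centers = _block_centers(spec, spec.block_n, spec.intra_block_gap)
    elif spec.kind == "fractal":
        return make_fractal_layout(spec)
    return PillarLayout(_rasterize(centers, spec.field_size, spec.pillar_radius), centers, spec)


# ---------------------------------------------------------------------------
# derived masks and statistics
# ---------------------------------------------------------------------------


def periphery_mask(
    layout: PillarLayout, band_width: int = 3, metric: str = "euclidean"
) -> PeripheryMask:
    """The pillar-periphery band: empty pixels within ``band_width`` of a pillar.

    ``metric`` selects the pixel distance used: ``"chebyshev"`` (chessboard
    distance, i.e. the band produced by ``band_width`` iterations of a 3×3
    morphological dilation, as thresholded-micrograph pipelines produce) or
    ``"euclidean"``.  The default follows the model's Moore-neighbourhood
    world.  With no pillars (bulk) or ``band_width=0`` the band is empty.
    """
    if band_width < 0:
        raise ConfigurationError("band_width must be ≥ 0")
    obstacle = layout.obstacle_mask
    out = np.zeros_like(obstacle)
    if band_width == 0 or not obstacle.any():
        return PeripheryMask(out, band_width, metric)
    if metric == "euclidean":
        dist = ndimage.distance_transform_edt(~obstacle)
    elif metric == "chebyshev":
        dist = ndimage.distance_transform_cdt(~obstacle, metric="chessboard")
    else:
        raise ConfigurationError(f"unknown periphery metric {metric!r}")
    out = (dist <= band_width) & ~obstacle
    return PeripheryMask(out, band_width, metric)


def box_counting_dimension(
    mask: np.ndarray, box_sizes: tuple[int, ...] | None = None
) -> BoxCountResult:
    """Box-counting (Minkowski–Bouligand) dimension of a binary mask.

    Boxes are grid-aligned, anchored at the (0,0) corner; partial boxes at the
    far edges count.  The dimension is the least-squares slope of
    ``log N(s)`` against ``log (1/s)`` over the given box sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ConfigurationError("mask is empty")
    if not mask.any():
        raise ConfigurationError("box-counting dimension undefined for an all-false mask")
    sizes = tuple(DEFAULT_BOX_SIZES if box_sizes is None else box_sizes)
    if len(sizes) < 4:
        raise ConfigurationError("need at least 4 box sizes")
    if any(s < 1 for s in sizes) or any(a <= b for a, b in zip(sizes, sizes[1:])):
        raise ConfigurationError("box_sizes must be a decreasing sequence of positive ints")
    counts = []
    for s in sizes:
        nr = -(-mask.shape[0] // s)
        nc = -(-mask.shape[1] // s)
        padded = np.zeros((nr * s, nc * s), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        occ = padded.reshape(nr, s, nc, s).any(axis=(1, 3))
        counts.append(int(occ.sum()))
    slope = np.polyfit(-np.log(sizes), np.log(counts), 1)[0]
    return BoxCountResult(float(slope), sizes, tuple(counts))


def layout_summary(layout: PillarLayout) -> dict:
    """Basic descriptive statistics of a layout."""
    obstacle = int(layout.obstacle_mask.sum())
    return {
        "pillar_count": layout.pillar_count,
        "obstacle_fraction": obstacle / layout.obstacle_mask.size,
        "min_gap": layout.min_edge_gap(),
        "empty_pixel_count": layout.obstacle_mask.size - obstacle,
    }
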