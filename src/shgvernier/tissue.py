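"""Parametric sarcomere geometry and scatterer-set construction.

A myofiber is modelled as a periodic train of sarcomeres.  Each sarcomere
contributes two rectangular "blocks" of myosin thick filament, one on
either side of its M-line, with the block pointing along the fiber axis
carrying ``+chi`` and the opposite block ``-chi`` (bipolar thick-filament
polarity; the sign flip across the M-line is what cancels SHG there).
Blocks are discretized on a regular lattice of point scatterers.

Fluorescent labels are attached to a chosen sarcomeric target:

* ``thick_filament`` — label co-localized with the myosin blocks
  (anti-myosin immunostain scenario);
* ``mline`` — a thin sheet of label on the M-line plane only
  (anti-myomesin scenario);
* ``thin_filament`` — label in the myosin-free region flanking the Z-disc
  (tropomyosin scenario).

Default geometry emulates embryonic zebrafish skeletal muscle: sarcomere
period 1.9 um, half thick-filament length 0.8 um (midpoint of the
physiological 0.6-1 um range).  All lengths in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SarcomereSpec",
    "MyofiberSpec",
    "ScattererSet",
    "MLineSet",
    "regular_myofiber",
    "build_myofiber",
    "build_staggered_pair",
    "build_filament_pair",
    "make_mline_lattice_fixture",
    "DEFAULT_PERIOD_UM",
    "DEFAULT_FILAMENT_LENGTH_UM",
    "DEFAULT_HALFWIDTH_UM",
    "DEFAULT_GAP_UM",
    "DEFAULT_SEPARATION_AXIS",
    "DEFAULT_SPACING_UM",
    "FLUOR_TARGETS",
]

#: Sarcomere period (M-line to M-line), embryonic zebrafish scale.  A model
#: default, not a measured value.
DEFAULT_PERIOD_UM = 1.9
#: Half thick-filament length (each half emanating from the M-line);
#: midpoint of the physiological 0.6-1 um range.
DEFAULT_FILAMENT_LENGTH_UM = 0.8
#: Transverse half-width of the myosin blocks (myofibril bundle scale).
DEFAULT_HALFWIDTH_UM = 0.35
#: Gap between the two fibers of the staggered-pair scenario, measured
#: along the separation axis between block centers minus both halfwidths
#: (fiber centers sit at +/- (gap/2 + halfwidth)).
DEFAULT_GAP_UM = 1.6
#: Fiber-stacking direction of the two-fiber scenario, tilted 30 degrees
#: from the optical (z) axis: adjacent myofibers in tissue are generically
#: offset both across and along the illumination direction.  The axial
#: component supplies the Gouy phase difference behind illusory inter-fiber
#: SHG; the transverse component lets TPEF resolve the two fibers.
DEFAULT_SEPARATION_AXIS = (0.0, 0.5, np.sqrt(3.0) / 2.0)
#: Lattice discretization step, lambda/10 at 0.850 um illumination.
DEFAULT_SPACING_UM = 0.085

PHYSIOLOGICAL_FILAMENT_RANGE = (0.6, 1.0)

FLUOR_TARGETS = ("thick_filament", "mline", "thin_filament")


@dataclass(frozen=True)
class SarcomereSpec:
    """One sarcomere: an M-line position plus local block geometry."""

    mline_position_um: np.ndarray
    fiber_axis: np.ndarray
    filament_length_um: float = DEFAULT_FILAMENT_LENGTH_UM
    lateral_halfwidth_um: float = DEFAULT_HALFWIDTH_UM
    period_um: float = DEFAULT_PERIOD_UM

    def __post_init__(self) -> None:
        pos = np.asarray(self.mline_position_um, dtype=float)
        axis = np.asarray(self.fiber_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("fiber_axis must be non-zero")
        object.__setattr__(self, "mline_position_um", pos)
        object.__setattr__(self, "fiber_axis", axis / norm)
        if 2.0 * self.filament_length_um >= self.period_um:
            raise ValueError(
                "filament halves overlap: need 2*filament_length_um < "
                f"period_um, got {self.filament_length_um} vs {self.period_um}"
            )


@dataclass(frozen=True)
class MyofiberSpec:
    """Ordered sarcomere train making up one fiber."""

    sarcomeres: tuple
    fiber_id: int = 0
    stagger_phase: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sarcomeres", tuple(self.sarcomeres))


@dataclass
class ScattererSet:
    """Discretized point scatterers: positions, signed chi, label density.

    ``chi_signed == 0`` marks points with no SHG-capable myosin (pure
    fluorophore carriers); ``fluor_density >= 0`` always.
    """

    positions_um: np.ndarray
    chi_signed: np.ndarray
    fluor_density: np.ndarray
    spacing_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, float))
        if self.positions_um.size == 0:
            self.positions_um = np.zeros((0, 3))
        self.chi_signed = np.asarray(self.chi_signed, float).ravel()
        self.fluor_density = np.asarray(self.fluor_density, float).ravel()
        n = len(self.positions_um)
        if len(self.chi_signed) != n or len(self.fluor_density) != n:
            raise ValueError("positions, chi_signed and fluor_density lengths differ")
        if np.any(self.fluor_density < 0):
            raise ValueError("fluor_density must be nonnegative")

    def __len__(self) -> int:
        return len(self.positions_um)

    @classmethod
    def empty(cls, spacing_um: float = DEFAULT_SPACING_UM) -> "ScattererSet":
        return cls(np.zeros((0, 3)), np.zeros(0), np.zeros(0), spacing_um)

    @classmethod
    def concatenate(cls, sets: Sequence["ScattererSet"]) -> "ScattererSet":
        sets = list(sets)
        if not sets:
            return cls.empty()
        return cls(
            np.vstack([s.positions_um for s in sets]),
            np.concatenate([s.chi_signed for s in sets]),
            np.concatenate([s.fluor_density for s in sets]),
            sets[0].spacing_um,
            provenance={"concatenated": [s.provenance for s in sets]},
        )

    def translated(self, offset_um) -> "ScattererSet":
        return ScattererSet(
            self.positions_um + np.asarray(offset_um, float),
            self.chi_signed.copy(),
            self.fluor_density.copy(),
            self.spacing_um,
            provenance=dict(self.provenance),
        )


@dataclass
class MLineSet:
    """3D M-line point set with per-point fiber-axis unit vectors."""

    points_um: np.ndarray
    axes: np.ndarray
    fiber_ids: Optional[np.ndarray] = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, float))
        if self.points_um.size == 0:
            self.points_um = np.zeros((0, 3))
        self.axes = np.atleast_2d(np.asarray(self.axes, float))
        if self.axes.size == 0:
            self.axes = np.zeros((0, 3))
        if len(self.axes) != len(self.points_um):
            raise ValueError("need one axis per M-line point")
        norms = np.linalg.norm(self.axes, axis=1)
        if len(norms) and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("axes must be unit vectors")
        if self.fiber_ids is not None:
            self.fiber_ids = np.asarray(self.fiber_ids)
            if len(self.fiber_ids) != len(self.points_um):
                raise ValueError("need one fiber_id per point")

    def __len__(self) -> int:
        return len(self.points_um)


def _transverse_frame(axis: np.ndarray):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    return axis, t1, t2


def _centered_lattice(extent: float, spacing: float) -> np.ndarray:
    """1D lattice of step ~spacing covering [-extent/2, extent/2]."""
    n = max(1, int(round(extent / spacing)))
    step = extent / n
    return (np.arange(n) + 0.5) * step - extent / 2.0


def build_filament_pair(
    mline_position_um,
    fiber_axis,
    filament_length_um: float,
    lateral_halfwidth_um: float,
    spacing_um: float,
    chi_amplitude: float = 1.0,
) -> "tuple[np.ndarray, np.ndarray]":
    """Lattice points and signed chi for one antiparallel half-filament pair.

    The half pointing along ``fiber_axis`` from the M-line carries
    ``+chi_amplitude``, the opposite half ``-chi_amplitude``; counts on the
    two sides are equal by construction, so the summed chi is exactly zero.
    """
    if spacing_um > filament_length_um / 4.0:
        raise ValueError(
            "lattice spacing too coarse to resolve the half-filament: need "
            f"spacing_um <= {filament_length_um / 4.0:g} "
            f"(filament_length_um / 4), got {spacing_um:g}"
        )
    axis, t1, t2 = _transverse_frame(fiber_axis)
    ax_half = _centered_lattice(filament_length_um, spacing_um) + filament_length_um / 2
    lat = _centered_lattice(2.0 * lateral_halfwidth_um, spacing_um)
    a, u, v = np.meshgrid(ax_half, lat, lat, indexing="ij")
    a, u, v = a.ravel(), u.ravel(), v.ravel()
    pos_plus = (
        np.asarray(mline_position_um, float)
        + a[:, None] * axis
        + u[:, None] * t1
        + v[:, None] * t2
    )
    pos_minus = (
        np.asarray(mline_position_um, float)
        - a[:, None] * axis
        + u[:, None] * t1
        + v[:, None] * t2
    )
    positions = np.vstack([pos_plus, pos_minus])
    chi = np.concatenate(
        [np.full(len(pos_plus), chi_amplitude), np.full(len(pos_minus), -chi_amplitude)]
    )
    return positions, chi


def regular_myofiber(
    n_sarcomeres: int,
    period_um: float = DEFAULT_PERIOD_UM,
    filament_length_um: float = DEFAULT_FILAMENT_LENGTH_UM,
    lateral_halfwidth_um: float = DEFAULT_HALFWIDTH_UM,
    fiber_axis=(1.0, 0.0, 0.0),
    origin_um=(0.0, 0.0, 0.0),
    stagger_phase: float = 0.0,
    fiber_id: int = 0,
    allow_nonphysiological: bool = False,
) -> MyofiberSpec:
    """Regular fiber: M-lines at origin + (j + stagger_phase) * period * axis.

    Filament lengths outside the physiological 0.6-1 um range are allowed
    only with ``allow_nonphysiological=True`` and emit a warning.
    """
    lo, hi = PHYSIOLOGICAL_FILAMENT_RANGE
    if not (lo <= filament_length_um <= hi):
        if not allow_nonphysiological:
            raise ValueError(
                f"filament_length_um={filament_length_um} outside the "
                f"physiological range [{lo}, {hi}]; pass "
                "allow_nonphysiological=True to override"
            )
        warnings.warn(
            f"filament_length_um={filament_length_um} outside physiological "
            f"range [{lo}, {hi}]",
            stacklevel=2,
        )
    axis = np.asarray(fiber_axis, float)
    axis = axis / np.linalg.norm(axis)
    origin = np.asarray(origin_um, float)
    sarcs = [
        SarcomereSpec(
            mline_position_um=origin + (j + stagger_phase) * period_um * axis,
            fiber_axis=axis,
            filament_length_um=filament_length_um,
            lateral_halfwidth_um=lateral_halfwidth_um,
            period_um=period_um,
        )
        for j in range(n_sarcomeres)
    ]
    return MyofiberSpec(sarcomeres=tuple(sarcs), fiber_id=fiber_id,
                        stagger_phase=stagger_phase)


def build_myofiber(
    spec: MyofiberSpec,
    spacing_um: float = DEFAULT_SPACING_UM,
    chi_amplitude: float = 1.0,
    fluor_target: str = "thick_filament",
) -> ScattererSet:
    """Discretize a fiber into scatterers with the requested fluorescent label."""
    if fluor_target not in FLUOR_TARGETS:
        raise ValueError(
            f"fluor_target must be one of {FLUOR_TARGETS}, got {fluor_target!r}"
        )
    all_pos, all_chi, all_fluor = [], [], []
    for sarc in spec.sarcomeres:
        pos, chi = build_filament_pair(
            sarc.mline_position_um,
            sarc.fiber_axis,
            sarc.filament_length_um,
            sarc.lateral_halfwidth_um,
            spacing_um,
            chi_amplitude,
        )
        fluor = np.ones(len(pos)) if fluor_target == "thick_filament" else np.zeros(len(pos))
        all_pos.append(pos)
        all_chi.append(chi)
        all_fluor.append(fluor)

        if fluor_target == "mline":
            # one transverse sheet of label on the M-line plane itself,
            # where no chi-carrying lattice point sits
            axis, t1, t2 = _transverse_frame(sarc.fiber_axis)
            lat = _centered_lattice(2.0 * sarc.lateral_halfwidth_um, spacing_um)
            u, v = np.meshgrid(lat, lat, indexing="ij")
            u, v = u.ravel(), v.ravel()
            sheet = sarc.mline_position_um + u[:, None] * t1 + v[:, None] * t2
            all_pos.append(sheet)
            all_chi.append(np.zeros(len(sheet)))
            all_fluor.append(np.ones(len(sheet)))
        elif fluor_target == "thin_filament":
            # myosin-free region between filament tip and the Z-disc at
            # +/- period/2 from the M-line
            axis, t1, t2 = _transverse_frame(sarc.fiber_axis)
            span = sarc.period_um / 2.0 - sarc.filament_length_um
            ax_off = (
                _centered_lattice(span, spacing_um)
                + sarc.filament_length_um
                + span / 2.0
            )
            lat = _centered_lattice(2.0 * sarc.lateral_halfwidth_um, spacing_um)
            a, u, v = np.meshgrid(ax_off, lat, lat, indexing="ij")
            a, u, v = a.ravel(), u.ravel(), v.ravel()
            for sign in (+1.0, -1.0):
                pts = (
                    sarc.mline_position_um
                    + sign * a[:, None] * axis
                    + u[:, None] * t1
                    + v[:, None] * t2
                )
                all_pos.append(pts)
                all_chi.append(np.zeros(len(pts)))
                all_fluor.append(np.ones(len(pts)))

    return ScattererSet(
        np.vstack(all_pos),
        np.concatenate(all_chi),
        np.concatenate(all_fluor),
        spacing_um,
        provenance={
            "builder": "build_myofiber",
            "fiber_id": spec.fiber_id,
            "n_sarcomeres": len(spec.sarcomeres),
            "fluor_target": fluor_target,
        },
    )


def build_staggered_pair(
    period_um: float = DEFAULT_PERIOD_UM,
    filament_length_um: float = DEFAULT_FILAMENT_LENGTH_UM,
    stagger_phase: float = 0.5,
    gap_um: float = DEFAULT_GAP_UM,
    n_sarcomeres: int = 4,
    spacing_um: float = DEFAULT_SPACING_UM,
    lateral_halfwidth_um: float = DEFAULT_HALFWIDTH_UM,
    fiber_axis=(1.0, 0.0, 0.0),
    separation_axis=DEFAULT_SEPARATION_AXIS,
    chi_amplitude: float = 1.0,
    fluor_target: str = "thick_filament",
) -> ScattererSet:
    """Two parallel fibers with an axial register offset between them.

    The fibers sit at ``-/+ (gap_um/2 + lateral_halfwidth_um)`` along
    ``separation_axis`` (edge-to-edge gap ``gap_um``); fiber 2's M-lines are
    shifted along the fiber axis by ``stagger_phase * period_um``.  A
    stagger of 0.5 realizes sarcomere registers out of phase by pi — the
    configuration that produces illusory inter-fiber SHG.
    """
    if gap_um < 0:
        raise ValueError(f"gap_um must be nonnegative, got {gap_um}")
    if not (0.0 <= stagger_phase < 1.0):
        raise ValueError(f"stagger_phase must lie in [0, 1), got {stagger_phase}")
    sep = np.asarray(separation_axis, float)
    sep = sep / np.linalg.norm(sep)
    offset = (gap_um / 2.0 + lateral_halfwidth_um) * sep
    fibers = []
    for fid, (center, phase) in enumerate(
        [(-offset, 0.0), (offset, stagger_phase)]
    ):
        spec = regular_myofiber(
            n_sarcomeres,
            period_um=period_um,
            filament_length_um=filament_length_um,
            lateral_halfwidth_um=lateral_halfwidth_um,
            fiber_axis=fiber_axis,
            origin_um=center,
            stagger_phase=phase,
            fiber_id=fid,
        )
        fibers.append(build_myofiber(spec, spacing_um, chi_amplitude, fluor_target))
    out = ScattererSet.concatenate(fibers)
    out.provenance = {
        "builder": "build_staggered_pair",
        "stagger_phase": stagger_phase,
        "gap_um": gap_um,
        "n_per_fiber": [len(f) for f in fibers],
    }
    return out


def make_mline_lattice_fixture(
    n_fibers: int,
    sarcomeres_per_fiber: int,
    period_um: float = DEFAULT_PERIOD_UM,
    stagger_phases: Optional[Sequence[float]] = None,
    jitter_um: float = 0.0,
    seed: int = 0,
    fiber_separation_um: float = DEFAULT_GAP_UM + 2 * DEFAULT_HALFWIDTH_UM,
    fiber_axis=(1.0, 0.0, 0.0),
    separation_axis=DEFAULT_SEPARATION_AXIS,
) -> MLineSet:
    """Deterministic-for-seed synthetic M-line point set.

    Emulates manually segmented anti-myomesin TPEF data: a regular lattice
    of M-line centroids (one per sarcomere per fiber), optionally perturbed
    by Gaussian jitter of scale ``jitter_um`` to mimic segmentation
    imprecision.
    """
    if jitter_um < 0:
        raise ValueError("jitter_um must be nonnegative")
    if stagger_phases is None:
        stagger_phases = [0.5 * (i % 2) for i in range(n_fibers)]
    if len(stagger_phases) != n_fibers:
        raise ValueError("need one stagger phase per fiber")
    axis = np.asarray(fiber_axis, float)
    axis = axis / np.linalg.norm(axis)
    sep = np.asarray(separation_axis, float)
    sep = sep / np.linalg.norm(sep)

    rng = np.random.default_rng(seed)
    points, axes, ids = [], [], []
    for i in range(n_fibers):
        center = (i - (n_fibers - 1) / 2.0) * fiber_separation_um * sep
        for j in range(sarcomeres_per_fiber):
            points.append(center + (j + stagger_phases[i]) * period_um * axis)
            axes.append(axis)
            ids.append(i)
    points = np.asarray(points)
    if jitter_um > 0:
        points = points + rng.normal(scale=jitter_um, size=points.shape)
    return MLineSet(
        points_um=points,
        axes=np.asarray(axes),
        fiber_ids=np.asarray(ids),
        source="synthetic",
    )
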