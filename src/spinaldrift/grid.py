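"""Rectilinear computational grids with solid-obstacle masks.

The package works on 2-D cell-centred rectilinear grids: an axial direction
``x`` (the direction of net solute transport, increasing caudally in the
spinal-canal application) and a transverse direction ``y`` spanning the fluid
gap.  Obstacles — the desk-scale stand-ins for nerve rootlets and denticulate
ligaments — are represented by a boolean solid mask on the cells (stair-step
masking; there is no body-fitted meshing).

A grid may be axially periodic, in which case it describes a single repeating
segment of the canal; :meth:`StructuredGrid.tile` replicates the segment to
build the longer open domain used for transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

#: implicit out-of-plane span of the 2-D model, cm.  Areas and volumes quoted
#: in cm^2 / mL assume this unit depth.
SPAN_CM = 1.0


@dataclass(frozen=True)
class StructuredGrid:
    """A 2-D rectilinear grid of ``n_axial`` x ``n_transverse`` cells.

    Parameters
    ----------
    n_axial, n_transverse
        Cell counts along x and y.
    dx, dy
        Cell spacings, cm.
    origin
        Coordinates ``(x0, y0)`` of the lower-left corner of the domain, cm.
    solid_mask
        Boolean array of shape ``(n_axial, n_transverse)``; True marks a
        solid (obstacle / wall-interior) cell.
    axial_periodic
        Whether the axial direction is periodic (single repeating segment).
    n_segments
        Default replication count used when tiling the segment for transport.
    """

    n_axial: int
    n_transverse: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)
    solid_mask: np.ndarray | None = None
    axial_periodic: bool = True
    n_segments: int = 5

    def __post_init__(self):
        if self.n_axial < 1 or self.n_transverse < 1:
            raise InputError("grid needs at least one cell per axis")
        if self.dx <= 0 or self.dy <= 0:
            raise InputError("grid spacing must be positive on every axis")
        mask = self.solid_mask
        if mask is None:
            mask = np.zeros((self.n_axial, self.n_transverse), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_axial, self.n_transverse):
                raise InputError(
                    f"solid_mask shape {mask.shape} does not match grid "
                    f"({self.n_axial}, {self.n_transverse})"
                )
        object.__setattr__(self, "solid_mask", mask)
        self._validate()

    # -- derived geometry ------------------------------------------------

    @property
    def fluid_mask(self) -> np.ndarray:
        return ~self.solid_mask

    @property
    def segment_length(self) -> float:
        """Axial extent of the grid, cm."""
        return self.n_axial * self.dx

    @property
    def height(self) -> float:
        """Transverse extent of the grid, cm."""
        return self.n_transverse * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n_axial) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.n_transverse) + 0.5) * self.dy

    @property
    def cell_volume(self) -> float:
        """Volume of one cell, cm^3 (unit out-of-plane span)."""
        return self.dx * self.dy * SPAN_CM

    def open_area(self) -> np.ndarray:
        """Open cross-sectional area A(x) per axial station, cm^2."""
        return self.fluid_mask.sum(axis=1) * self.dy * SPAN_CM

    def fluid_volume(self) -> float:
        """Total open volume of the domain, cm^3 (= mL)."""
        return float(self.fluid_mask.sum()) * self.cell_volume

    # -- validation ------------------------------------------------------

    def _validate(self):
        area = self.open_area()
        if np.any(area <= 0):
            blocked = np.flatnonzero(area <= 0)
            raise InputError(
                f"canal fully blocked at axial stations {blocked.tolist()}"
            )
        if self.axial_periodic and not np.array_equal(
            self.solid_mask[0], self.solid_mask[-1]
        ):
            raise InputError(
                "axially periodic grid requires identical solid masks at the "
                "first and last axial stations (section-stacking validity)"
            )
        # no isolated single-cell fluid holes: a fluid cell all of whose
        # neighbours are solid cannot be reached by the flow.
        fm = self.fluid_mask
        if fm.size > 1:
            solid = self.solid_mask
            pad_x = (
                (np.roll(solid, 1, axis=0), np.roll(solid, -1, axis=0))
                if self.axial_periodic
                else (
                    np.vstack([solid[:1], solid[:-1]]),
                    np.vstack([solid[1:], solid[-1:]]),
                )
            )
            up = np.hstack([np.ones((self.n_axial, 1), bool), solid[:, :-1]])
            dn = np.hstack([solid[:, 1:], np.ones((self.n_axial, 1), bool)])
            isolated = fm & pad_x[0] & pad_x[1] & up & dn
            if np.any(isolated):
                raise InputError(
                    "solid mask leaves isolated single-cell fluid holes"
                )

    # -- operations ------------------------------------------------------

    def tile(self, n_segments: int | None = None) -> "StructuredGrid":
        """Replicate the periodic segment ``n_segments`` times axially.

        Returns a non-periodic grid suitable for the open transport domain.
        """
        if not self.axial_periodic:
            raise InputError("only axially periodic segments can be tiled")
        n = self.n_segments if n_segments is None else int(n_segments)
        if n < 1:
            raise InputError("n_segments must be >= 1")
        return replace(
            self,
            n_axial=self.n_axial * n,
            solid_mask=np.tile(self.solid_mask, (n, 1)),
            axial_periodic=False,
            n_segments=1,
        )

    def locate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the cells containing points ``(x, y)`` (clipped)."""
        i = np.clip(
            np.floor((np.asarray(x) - self.origin[0]) / self.dx).astype(int),
            0,
            self.n_axial - 1,
        )
        j = np.clip(
            np.floor((np.asarray(y) - self.origin[1]) / self.dy).astype(int),
            0,
            self.n_transverse - 1,
        )
        return i, j

    def wrap_x(self, x: np.ndarray) -> np.ndarray:
        """Wrap axial coordinates into the periodic segment."""
        L = self.segment_length
        return self.origin[0] + np.mod(np.asarray(x) - self.origin[0], L)


def channel_grid(
    n_axial: int,
    n_transverse: int,
    length: float,
    height: float,
    origin: tuple[float, float] = (0.0, 0.0),
    wall_profile_bottom=None,
    wall_profile_top=None,
    axial_periodic: bool = True,
    n_segments: int = 5,
) -> StructuredGrid:
    """Build a plane-channel grid, optionally with wavy (masked) walls.

    ``wall_profile_bottom(x)`` / ``wall_profile_top(x)`` give the local wall
    intrusion depth (cm) into the channel measured from the flat bottom / top
    wall; cells whose centres fall inside the intrusion are masked solid.
    """
    dx = length / n_axial
    dy = height / n_transverse
    x = origin[0] + (np.arange(n_axial) + 0.5) * dx
    y = origin[1] + (np.arange(n_transverse) + 0.5) * dy
    mask = np.zeros((n_axial, n_transverse), dtype=bool)
    if wall_profile_bottom is not None:
        prof = np.broadcast_to(
            np.asarray(wall_profile_bottom(x), dtype=float), x.shape
        )
        mask |= y[None, :] < (origin[1] + prof)[:, None]
    if wall_profile_top is not None:
        prof = np.broadcast_to(
            np.asarray(wall_profile_top(x), dtype=float), x.shape
        )
        mask |= y[None, :] > (origin[1] + height - prof)[:, None]
    return StructuredGrid(
        n_axial=n_axial,
        n_transverse=n_transverse,
        dx=dx,
        dy=dy,
        origin=origin,
        solid_mask=mask,
        axial_periodic=axial_periodic,
        n_segments=n_segments,
    )
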