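"""Regular-grid trajectory container shared by every pipeline stage."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["TrajectorySet"]


class TrajectorySet:
    """Positions of a set of individuals on an exact fixed-interval time grid.

    Grid step ``k`` corresponds to clock time ``t0 + k * dt`` (epoch seconds,
    UTC). Positions are stored as an ``(n_individuals, n_steps, 2)`` float
    array in projected metres; a missing position is a NaN pair. Every
    (individual, step) cell has exactly one entry, so downstream stages can
    rely on purely positional arithmetic.

    Parameters
    ----------
    ids
        Ordered individual identifiers (unique strings).
    t0
        Epoch seconds (UTC) of step 0.
    dt
        Grid spacing in seconds (> 0).
    xy
        Array of shape ``(len(ids), n_steps, 2)``; NaN pairs mark missing
        positions.
    """

    def __init__(self, ids, t0: float, dt: float, xy) -> None:
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate individual ids")
        xy = np.array(xy, dtype=float)
        if xy.ndim != 3 or xy.shape[2] != 2:
            raise DataError("xy must have shape (n_individuals, n_steps, 2)")
        if xy.shape[0] != len(ids):
            raise DataError("xy first axis must match number of ids")
        if dt <= 0:
            raise DataError("dt must be positive")
        half = np.isnan(xy[..., 0]) != np.isnan(xy[..., 1])
        if half.any():
            raise DataError("coordinate pair with exactly one NaN")
        if np.isinf(xy).any():
            raise DataError("non-finite coordinate")
        self.ids: list[str] = ids
        self.t0 = float(t0)
        self.dt = float(dt)
        self.xy = xy

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_steps(self) -> int:
        return self.xy.shape[1]

    def times(self) -> np.ndarray:
        """Clock time (epoch seconds UTC) of every grid step."""
        return self.t0 + np.arange(self.n_steps) * self.dt

    def present(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_steps)`` mask of observed positions."""
        return ~np.isnan(self.xy[..., 0])

    def coverage(self) -> float:
        """Fraction of (individual, step) cells with a position."""
        if self.xy.size == 0:
            return 0.0
        return float(self.present().mean())

    def index_of(self, individual_id: str) -> int:
        try:
            return self.ids.index(str(individual_id))
        except ValueError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def positions_at(self, step: int) -> np.ndarray:
        """Positions of all individuals at one step, shape ``(n, 2)``."""
        return self.xy[:, step, :]

    # -- conversions -----------------------------------------------------
    def to_fixes(self) -> pd.DataFrame:
        """Implied fix table: one row per present (individual, step) cell."""
        ind, step = np.nonzero(self.present())
        return pd.DataFrame(
            {
                "id": [self.ids[i] for i in ind],
                "step": step,
                "time": self.t0 + step * self.dt,
                "x": self.xy[ind, step, 0],
                "y": self.xy[ind, step, 1],
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.t0 == other.t0
            and self.dt == other.dt
            and self.xy.shape == other.xy.shape
            and bool(
                np.all((self.xy == other.xy) | (np.isnan(self.xy) & np.isnan(other.xy)))
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TrajectorySet(n_individuals={self.n_individuals}, "
            f"n_steps={self.n_steps}, dt={self.dt}, coverage={self.coverage():.3f})"
        )
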