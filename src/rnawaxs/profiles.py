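"""1-D solution scattering profiles.

The momentum transfer is q = 4*pi*sin(theta)/lambda (units 1/Angstrom),
with 2*theta the scattering angle.  A :class:`ScatteringProfile` is the
exchange format between every stage of the pipeline: model profiles from
the Debye calculator, per-shot radial averages, reduced (background
subtracted) experimental profiles and decomposition bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ScatteringProfile"]


@dataclass
class ScatteringProfile:
    """Intensity versus momentum transfer.

    Parameters
    ----------
    q : array
        Strictly increasing grid, 1/Angstrom.
    I : array
        Intensity, arbitrary units.  Model-derived profiles are
        nonnegative; background-subtracted experimental profiles may dip
        below zero.
    sigma : array, optional
        Per-point 1-sigma uncertainty.
    label : str
        Free-text identifier carried through the pipeline.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.q.size >= 2 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")

    def __len__(self) -> int:
        return self.q.size

    # -- arithmetic helpers -------------------------------------------------

    def resample(self, qgrid: np.ndarray) -> "ScatteringProfile":
        """Piecewise-linear interpolation onto a new grid.

        The new grid must lie inside the profile's q range.
        """
        qgrid = np.asarray(qgrid, dtype=float)
        if qgrid.min() < self.q.min() - 1e-12 or qgrid.max() > self.q.max() + 1e-12:
            raise ValueError(
                f"target grid [{qgrid.min():g}, {qgrid.max():g}] outside "
                f"profile range [{self.q.min():g}, {self.q.max():g}]"
            )
        I = np.interp(qgrid, self.q, self.I)
        sigma = None
        if self.sigma is not None:
            sigma = np.interp(qgrid, self.q, self.sigma)
        return ScatteringProfile(qgrid, I, sigma, label=self.label)

    def window(self, qmin: float, qmax: float) -> "ScatteringProfile":
        """Restrict to qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        sigma = self.sigma[m] if self.sigma is not None else None
        return ScatteringProfile(self.q[m], self.I[m], sigma, label=self.label)

    # -- I/O ----------------------------------------------------------------

    def write_dat(self, path: str | Path) -> None:
        """Write as 3-column ASCII (q, I, sigma); '#'-prefixed header."""
        path = Path(path)
        sigma = self.sigma if self.sigma is not None else np.zeros_like(self.q)
        header = f"label: {self.label}\ncolumns: q(1/A) I(a.u.) sigma"
        np.savetxt(
            path,
            np.column_stack([self.q, self.I, sigma]),
            header=header,
            fmt="%.8e",
        )

    @classmethod
    def read_dat(cls, path: str | Path, label: str | None = None) -> "ScatteringProfile":
        """Read a 2- or 3-column ASCII profile, skipping '#' headers."""
        path = Path(path)
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected at least 2 columns")
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        if sigma is not None and np.all(sigma == 0):
            sigma = None
        if label is None:
            label = path.stem
            with open(path) as fh:
                first = fh.readline()
            if first.startswith("#") and "label:" in first:
                label = first.split("label:", 1)[1].strip()
        return cls(data[:, 0], data[:, 1], sigma, label=label)
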