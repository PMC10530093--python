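"""Orientationally averaged solution scattering via the Debye equation.

    I(q) = sum_i sum_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij)

The q -> 0 limit is handled analytically (sinc), never by division, so
I(0) = (sum_i f_i(0))^2 exactly.  Two evaluation modes:

``exact``
    Literal double sum over atom pairs, grouped by scattering species
    (element + merged-hydrogen count).
``histogram``
    Pair distances binned per species pair at a configurable width
    (default 0.01 A), then a single matrix product against a shared
    sinc kernel.  At wide angle (q <= 2.4 1/A) a 0.01 A bin keeps the
    error well under the width of any structural peak.

Scattering is computed with a uniform excluded-volume (displaced
solvent) correction by default: each atomic form factor has a
Gaussian-sphere solvent term subtracted, as solution experiments
measure excess intensity over the solvent.  In vacuum the strong
coherent decay of the unsubtracted form factors buries the wide-angle
features as shoulders; with solvent contrast they appear as the local
maxima seen experimentally.  Pass ``excluded_volume=False`` for vacuum
scattering.
"""

from __future__ import annotations

import numpy as np

from .builder import AtomicModel, ModelEnsemble
from .formfactors import atomic_form_factor
from .profiles import ScatteringProfile

__all__ = ["debye_profile", "ensemble_profile", "default_qgrid"]

# Average displaced-solvent volumes (A^3) for the excluded-volume option.
_ATOM_VOLUME = {"C": 16.4, "N": 11.0, "O": 9.1, "P": 5.7, "H": 5.15}
_RHO_SOLVENT = 0.334  # electrons / A^3, water


def default_qgrid(qmin: float = 0.05, qmax: float = 2.4,
                  dq: float = 0.005) -> np.ndarray:
    """Default evaluation grid: 0.05-2.4 1/A in 0.005 steps, bracketing
    the instrument's 0.12-2.4 range with margin."""
    n = int(round((qmax - qmin) / dq)) + 1
    return qmin + dq * np.arange(n)


def _species_split(model: AtomicModel):
    """Group atoms into (element, nH) species; returns labels + indices."""
    keys = [f"{el}:{nh}" for el, nh in zip(model.elements, model.n_hydrogens)]
    uniq, inv = np.unique(keys, return_inverse=True)
    species = []
    for k in uniq:
        el, nh = k.split(":")
        species.append((el, int(nh)))
    return species, inv


def _effective_f(element: str, n_h: int, q: np.ndarray,
                 excluded_volume: bool, ev_scale: float) -> np.ndarray:
    f = atomic_form_factor(element, q, n_h)
    if excluded_volume:
        v = _ATOM_VOLUME[element] + n_h * _ATOM_VOLUME["H"]
        f = f - ev_scale * _RHO_SOLVENT * v * np.exp(
            -(v ** (2.0 / 3.0)) * q ** 2 / (4.0 * np.pi))
    return f


def debye_profile(model: AtomicModel, qgrid: np.ndarray | None = None,
                  mode: str = "histogram", bin_width: float = 0.01,
                  excluded_volume: bool = True, ev_scale: float = 1.0,
                  chunk: int = 256) -> ScatteringProfile:
    """Debye-equation profile of one atomic model.

    Parameters
    ----------
    model : AtomicModel
        Non-empty model.
    qgrid : array, optional
        Strictly increasing grid inside 0-3 1/A; defaults to
        :func:`default_qgrid`.
    mode : ``"exact"`` or ``"histogram"``
    bin_width : float
        Pair-distance bin width for histogram mode, Angstrom.
    excluded_volume, ev_scale
        Toggle and scale the uniform displaced-solvent correction.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    qgrid = default_qgrid() if qgrid is None else np.asarray(qgrid, dtype=float)
    if qgrid.size >= 2 and not np.all(np.diff(qgrid) > 0):
        raise ValueError("qgrid must be strictly increasing")
    if qgrid.min() < 0 or qgrid.max() > 3.0:
        raise ValueError("qgrid must lie within 0-3 1/A")
    if mode not in ("exact", "histogram"):
        raise ValueError(f"unknown mode {mode!r}")

    species, inv = _species_split(model)
    ns = len(species)
    F = np.stack([_effective_f(el, nh, qgrid, excluded_volume, ev_scale)
                  for el, nh in species])          # (ns, nq)
    coords = model.coords
    groups = [coords[inv == s] for s in range(ns)]

    # self terms: sum_i f_i^2
    I = np.zeros_like(qgrid)
    for s in range(ns):
        I += len(groups[s]) * F[s] ** 2

    if mode == "exact":
        for s in range(ns):
            for t in range(s, ns):
                ff = F[s] * F[t]
                A, B = groups[s], groups[t]
                if len(A) == 0 or len(B) == 0:
                    continue
                for i0 in range(0, len(A), chunk):
                    a = A[i0:i0 + chunk]
                    d = np.linalg.norm(a[:, None, :] - B[None, :, :], axis=-1)
                    if s == t:
                        # unique unordered pairs: global row index < column
                        rows = i0 + np.arange(len(a))
                        r = d[rows[:, None] < np.arange(len(B))[None, :]]
                    else:
                        r = d.ravel()
                    if r.size == 0:
                        continue
                    # sinc(q r): np.sinc computes sin(pi x)/(pi x)
                    S = np.sinc(np.outer(qgrid, r) / np.pi)
                    I += 2.0 * ff * S.sum(axis=1)
    else:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        rmax = float(np.linalg.norm(hi - lo)) + bin_width
        nbins = max(1, int(np.ceil(rmax / bin_width)))
        edges = bin_width * np.arange(nbins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        npair = ns * (ns + 1) // 2
        H = np.zeros((npair, nbins))
        FF = np.zeros((npair, qgrid.size))
        pair_idx = 0
        for s in range(ns):
            for t in range(s, ns):
                A, B = groups[s], groups[t]
                h = np.zeros(nbins)
                for i0 in range(0, len(A), chunk):
                    a = A[i0:i0 + chunk]
                    d = np.linalg.norm(a[:, None, :] - B[None, :, :], axis=-1)
                    if s == t:
                        # unique unordered pairs: global row index < column
                        rows = i0 + np.arange(len(a))
                        keep = rows[:, None] < np.arange(len(B))[None, :]
                        r = d[keep]
                    else:
                        r = d.ravel()
                    if r.size:
                        h += np.histogram(r, bins=edges)[0]
                H[pair_idx] = h
                FF[pair_idx] = 2.0 * F[s] * F[t]
                pair_idx += 1
        used = H.any(axis=0)
        if used.any():
            # sinc(q r): np.sinc computes sin(pi x)/(pi x)
            S = np.sinc(np.outer(qgrid, centers[used]) / np.pi)  # (nq, nb)
            I += np.sum(FF * (H[:, used] @ S.T), axis=0)

    prof = ScatteringProfile(qgrid, I, label=model.label)
    prof.meta["mode"] = mode
    prof.meta["n_atoms"] = len(model)
    return prof


def ensemble_profile(ensemble: ModelEnsemble,
                     qgrid: np.ndarray | None = None,
                     mode: str = "histogram", **kwargs) -> ScatteringProfile:
    """Weighted mean Debye profile over an ensemble's members."""
    s = float(np.sum(ensemble.weights))
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"ensemble weights must sum to 1, got {s}")
    qgrid = default_qgrid() if qgrid is None else np.asarray(qgrid, dtype=float)
    I = np.zeros_like(qgrid)
    for w, m in zip(ensemble.weights, ensemble.members):
        I += w * debye_profile(m, qgrid, mode=mode, **kwargs).I
    prof = ScatteringProfile(qgrid, I, label=ensemble.label)
    prof.meta["n_members"] = len(ensemble)
    return prof
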