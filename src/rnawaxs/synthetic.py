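"""Ground-truth-labelled synthetic experiments.

Emulates the serial solution-scattering measurement end to end: basis
profiles computed from the idealized models, per-pulse frames with
log-normal pulse-energy jitter, Poisson photon counting on top of a
dominant water-like buffer background, sporadic ice-diffraction spikes,
and paired sample-present / sample-absent runs — so that reduction,
fingerprinting and decomposition can all be tested against known truth
without any measured data.

Frames are generated either as per-shot 1-D profiles with per-bin
Poisson statistics (the fast path used at the thousands-of-shots scale)
or as full 2-D detector images exercising the radial-average path at
small n.  Both carry the same truth schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .builder import (
    HelicalParams, build_a_form_helix, build_uau12_construct,
    parse_construct_spec, sample_disordered_ensemble, _concat_models,
)
from .debye import debye_profile, default_qgrid, ensemble_profile
from .decomposition import BasisSet, KineticParams, sequential_kinetics
from .profiles import ScatteringProfile
from .reduction import DetectorGeometry, ShotStack, build_q_map

__all__ = [
    "NoiseConfig", "SyntheticTruth", "ExperimentBundle",
    "buffer_background", "make_basis_set",
    "simulate_timepoint_stack", "simulate_experiment",
    "DEFAULT_TIME_POINTS_MS",
]

# Default series: initial state, early/mid/late intermediates, final.
DEFAULT_TIME_POINTS_MS = (0.0, 6.0, 10.0, 60.0, 1000.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Photon statistics and contamination of the synthetic beam.

    ``buffer_photons`` is the mean detected counts per q bin per pulse
    from the solvent; ``rna_photons`` the mean solute contribution —
    an order of magnitude smaller, as solution WAXS signals ride on a
    dominant background.  Pulse energies jitter log-normally.
    """

    buffer_photons: float = 15000.0
    rna_photons: float = 4000.0
    pulse_jitter_rel_sd: float = 0.15
    ice_rate: float = 0.02            # fraction of contaminated frames
    ice_amplitude: float = 50.0       # spike height, x buffer_photons
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ice_rate <= 1.0):
            raise ValueError("ice_rate must be in [0, 1]")
        if self.buffer_photons <= 0 or self.rna_photons <= 0:
            raise ValueError("photon scales must be > 0")
        if self.pulse_jitter_rel_sd < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class SyntheticTruth:
    """What the generator actually did, frame by frame."""

    pulse_energy: np.ndarray
    contaminated: np.ndarray            # bool per frame
    fractions: dict[str, float]
    photon_scale: float                 # basis units -> counts per bin
    generating_profile: ScatteringProfile
    seed: int


def buffer_background(q: np.ndarray, photons: float = 200.0) -> np.ndarray:
    """Smooth water-like background: a broad maximum near q = 2 1/A on
    a slowly varying base, scaled to ``photons`` mean counts per bin."""
    q = np.asarray(q, dtype=float)
    shape = 0.35 + 0.9 * np.exp(-((q - 2.0) / 0.75) ** 2) + 0.25 * np.exp(-q / 0.8)
    return photons * shape / shape.mean()


def _pulse_energies(rng, n: int, rel_sd: float) -> np.ndarray:
    if rel_sd == 0:
        return np.ones(n)
    s2 = np.log1p(rel_sd ** 2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# basis states
# ---------------------------------------------------------------------------

def make_basis_set(qgrid: np.ndarray | None = None, seed: int = 0,
                   n_ss_conformers: int = 24, n_tail_conformers: int = 8,
                   stacking_propensity: float = 0.15,
                   ) -> tuple[BasisSet, dict]:
    """Compute the three folding-state basis profiles.

    * ``unstructured`` — disordered ensemble of the full 46-nt
      12U-5C-12U-5C-12A construct;
    * ``duplex`` — the 29-nt 12U-5C-12A hairpin (12-bp A-U stem, 5-C
      loop) with the remaining 17 nt as a disordered tail, averaged
      over tail conformers;
    * ``triplex`` — the folded 46-nt construct: 12 U·A-U triples capped
      by the two 5-C linkers.

    Returns (basis, models) where ``models`` maps label to the
    structural object(s) behind each profile.
    """
    qgrid = default_qgrid() if qgrid is None else np.asarray(qgrid, dtype=float)
    uau12 = parse_construct_spec("12U-5C-12U-5C-12A")

    ss_ens = sample_disordered_ensemble(
        uau12, n_ss_conformers, seed=seed,
        stacking_propensity=stacking_propensity, label="unstructured")
    ss = ensemble_profile(ss_ens, qgrid)
    ss.label = "unstructured"

    hairpin = build_a_form_helix(parse_construct_spec("12U-5C-12A"), 5,
                                 label="duplex_intermediate")
    tail_spec = parse_construct_spec("12U-5C")
    tail_ens = sample_disordered_ensemble(tail_spec, n_tail_conformers,
                                          seed=seed + 1, label="tail")
    # anchor each tail conformer below the hairpin's open end
    anchor = np.array([0.0, 0.0, -6.0])
    members = []
    for tail in tail_ens.members:
        shifted = tail.transformed(translation=anchor - tail.coords[0])
        shifted.res_index = shifted.res_index + 29
        members.append(_concat_models([hairpin, shifted], label="duplex"))
    I = np.zeros_like(qgrid)
    for m in members:
        I += debye_profile(m, qgrid).I / len(members)
    duplex = ScatteringProfile(qgrid, I, label="duplex")

    triplex_model = build_uau12_construct()
    triplex = debye_profile(triplex_model, qgrid)
    triplex.label = "triplex"

    basis = BasisSet({"unstructured": ss, "duplex": duplex,
                      "triplex": triplex})
    models = {"unstructured": ss_ens, "duplex": members,
              "triplex": triplex_model}
    return basis, models


# ---------------------------------------------------------------------------
# shot stacks
# ---------------------------------------------------------------------------

def _mixture_counts(fractions: dict[str, float], basis: BasisSet,
                    noise: NoiseConfig) -> tuple[np.ndarray, float]:
    """Expected solute counts per bin and the basis->counts scale."""
    labels = basis.labels
    f = np.array([fractions.get(l, 0.0) for l in labels])
    if abs(f.sum() - 1.0) > 1e-6 or np.any(f < 0):
        raise ValueError(f"fractions must be nonnegative and sum to 1: {fractions}")
    _, A = basis.matrix()
    scale = noise.rna_photons / float(A.mean())
    return scale * (A @ f), scale


def simulate_timepoint_stack(fractions: dict[str, float], basis: BasisSet,
                             n_frames: int, noise: NoiseConfig,
                             seed: int = 0, path: str = "1d",
                             geometry: DetectorGeometry | None = None,
                             qmin_instrument: float = 0.12,
                             ) -> tuple[ShotStack, ShotStack, SyntheticTruth]:
    """Paired sample and buffer runs for one time point.

    ``path='1d'``: per-shot profiles with per-bin Poisson counting on
    the basis grid (restricted to the instrument's q range).
    ``path='2d'``: full detector images through the given geometry.
    Identical (inputs, seed) reproduce the stacks bit for bit.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    mix_full, scale = _mixture_counts(fractions, basis, noise)
    qfull = basis.qgrid
    keep = qfull >= qmin_instrument
    q = qfull[keep]
    mix = mix_full[keep]
    bg = buffer_background(q, noise.buffer_photons)

    stacks = {}
    contaminated = None
    pulses_sample = None
    for role, expected in (("sample", mix + bg), ("buffer", bg)):
        pulses = _pulse_energies(rng, n_frames, noise.pulse_jitter_rel_sd)
        flags = rng.random(n_frames) < noise.ice_rate
        if path == "1d":
            lam = np.outer(pulses, expected)
            counts = rng.poisson(lam).astype(float)
            n_spike_bins = rng.integers(1, 4, size=n_frames)
            for i in np.flatnonzero(flags):
                bins = rng.integers(0, q.size, size=n_spike_bins[i])
                counts[i, bins] += noise.ice_amplitude * noise.buffer_photons
            stacks[role] = ShotStack(
                pulse_energy=pulses, role=role, profiles=counts, qgrid=q,
                truth={"contaminated": flags})
        elif path == "2d":
            if geometry is None:
                raise ValueError("2-D path requires a detector geometry")
            qmap = build_q_map(geometry)
            exp_img = np.interp(qmap, q, expected, left=0.0, right=0.0)
            frames = np.empty((n_frames,) + tuple(geometry.shape))
            for i in range(n_frames):
                frames[i] = rng.poisson(pulses[i] * exp_img)
                if flags[i]:
                    ny, nx = geometry.shape
                    cy = rng.integers(2, ny - 2)
                    cx = rng.integers(2, nx - 2)
                    frames[i, cy - 1:cy + 2, cx - 1:cx + 2] += (
                        noise.ice_amplitude * noise.buffer_photons)
            stacks[role] = ShotStack(
                pulse_energy=pulses, role=role, frames=frames,
                truth={"contaminated": flags})
        else:
            raise ValueError(f"unknown path {path!r}")
        if role == "sample":
            contaminated = flags
            pulses_sample = pulses

    truth = SyntheticTruth(
        pulse_energy=pulses_sample, contaminated=contaminated,
        fractions=dict(fractions), photon_scale=scale,
        generating_profile=ScatteringProfile(q, mix, label="mixture"),
        seed=seed)
    return stacks["sample"], stacks["buffer"], truth


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentBundle:
    """A complete synthetic time-resolved experiment."""

    time_points_ms: tuple[float, ...]
    stacks: dict[float, tuple[ShotStack, ShotStack]]
    truths: dict[float, SyntheticTruth]
    basis: BasisSet
    kinetics: KineticParams
    noise: NoiseConfig
    seed: int

    # -- HDF5 container -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["time_points_ms"] = list(self.time_points_ms)
            f.attrs["k1"] = self.kinetics.k1
            f.attrs["k2"] = self.kinetics.k2
            for key, val in vars(self.noise).items():
                f.attrs[f"noise_{key}"] = val
            g = f.create_group("basis")
            g.attrs["labels"] = list(self.basis.labels)
            g.create_dataset("q", data=self.basis.qgrid)
            for label, prof in self.basis.profiles.items():
                g.create_dataset(label, data=prof.I)
            for i, t in enumerate(self.time_points_ms):
                gt = f.create_group(f"t{i}")
                gt.attrs["t_ms"] = t
                truth = self.truths[t]
                gt.attrs["fractions"] = [truth.fractions[l]
                                         for l in self.basis.labels]
                gt.attrs["photon_scale"] = truth.photon_scale
                gt.attrs["truth_seed"] = truth.seed
                gt.create_dataset("generating_q",
                                  data=truth.generating_profile.q)
                gt.create_dataset("generating_I",
                                  data=truth.generating_profile.I)
                for role, stack in zip(("sample", "buffer"), self.stacks[t]):
                    gr = gt.create_group(role)
                    gr.create_dataset("pulse_energy", data=stack.pulse_energy)
                    if stack.profiles is not None:
                        gr.create_dataset("profiles", data=stack.profiles)
                        gr.create_dataset("q", data=stack.qgrid)
                    else:
                        gr.create_dataset("frames", data=stack.frames)
                    gr.create_dataset(
                        "contaminated",
                        data=stack.truth["contaminated"].astype(np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentBundle":
        with h5py.File(path, "r") as f:
            tpts = tuple(float(t) for t in f.attrs["time_points_ms"])
            kin = KineticParams(float(f.attrs["k1"]), float(f.attrs["k2"]))
            noise = NoiseConfig(
                buffer_photons=float(f.attrs["noise_buffer_photons"]),
                rna_photons=float(f.attrs["noise_rna_photons"]),
                pulse_jitter_rel_sd=float(f.attrs["noise_pulse_jitter_rel_sd"]),
                ice_rate=float(f.attrs["noise_ice_rate"]),
                ice_amplitude=float(f.attrs["noise_ice_amplitude"]),
                seed=int(f.attrs["noise_seed"]))
            q = f["basis/q"][...]
            labels = [str(l) for l in f["basis"].attrs["labels"]]
            profs = {label: ScatteringProfile(q, f[f"basis/{label}"][...],
                                              label=label)
                     for label in labels}
            basis = BasisSet(profs)
            stacks, truths = {}, {}
            for i, t in enumerate(tpts):
                gt = f[f"t{i}"]
                pair = []
                for role in ("sample", "buffer"):
                    gr = gt[role]
                    kwargs = dict(pulse_energy=gr["pulse_energy"][...],
                                  role=role,
                                  truth={"contaminated":
                                         gr["contaminated"][...].astype(bool)})
                    if "profiles" in gr:
                        kwargs["profiles"] = gr["profiles"][...]
                        kwargs["qgrid"] = gr["q"][...]
                    else:
                        kwargs["frames"] = gr["frames"][...]
                    pair.append(ShotStack(**kwargs))
                stacks[t] = tuple(pair)
                fr = dict(zip(basis.labels, gt.attrs["fractions"]))
                truths[t] = SyntheticTruth(
                    pulse_energy=pair[0].pulse_energy,
                    contaminated=pair[0].truth["contaminated"],
                    fractions=fr,
                    photon_scale=float(gt.attrs["photon_scale"]),
                    generating_profile=ScatteringProfile(
                        gt["generating_q"][...], gt["generating_I"][...],
                        label="mixture"),
                    seed=int(gt.attrs["truth_seed"]))
            return cls(tpts, stacks, truths, basis, kin, noise,
                       seed=int(f.attrs["seed"]))


def simulate_experiment(kinetics: KineticParams = KineticParams(),
                        time_points_ms=DEFAULT_TIME_POINTS_MS,
                        n_frames: int = 2000,
                        noise: NoiseConfig = NoiseConfig(),
                        basis: BasisSet | None = None,
                        seed: int = 0) -> ExperimentBundle:
    """Simulate a full time course.

    Per-time-point true fractions follow the sequential first-order
    scheme; each point gets paired sample/buffer stacks.  Per-stage
    sub-seeds derive deterministically from the master seed, so the
    whole bundle is bit-reproducible.
    """
    if len(time_points_ms) < 1:
        raise ValueError("need at least one time point")
    if basis is None:
        basis, _ = make_basis_set(seed=seed)
    labels = basis.labels
    stacks, truths = {}, {}
    for i, t in enumerate(time_points_ms):
        f = sequential_kinetics(t, kinetics)
        fractions = dict(zip(("unstructured", "duplex", "triplex"), f))
        fractions = {l: float(fractions.get(l, 0.0)) for l in labels}
        sub_seed = int(np.random.SeedSequence([seed, 1000 + i])
                       .generate_state(1)[0] % (2 ** 31))
        s, b, truth = simulate_timepoint_stack(
            fractions, basis, n_frames, noise, seed=sub_seed)
        stacks[float(t)] = (s, b)
        truths[float(t)] = truth
    return ExperimentBundle(tuple(float(t) for t in time_points_ms),
                            stacks, truths, basis, kinetics, noise, seed)
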