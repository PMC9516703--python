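"""Synthetic CD melts and toy trajectories with known ground truth.

Every downstream stage of the pipeline is testable against data whose
generating parameters are known exactly:

* :func:`generate_melt` builds a single-wavelength CD melt from a sum of
  two-state van't Hoff transitions,

      f_i(T) = 1 / (1 + exp[(dH_i / R) (1/T - 1/Tm_i)])   (T in kelvin)

  so each component population is exactly 1/2 at its Tm and the free
  energy of a lone transition is exactly linear in temperature,
  dG(T) = dH_i (1 - T/Tm_i).  Opposite-sign amplitudes on successive
  transitions emulate the band-deepening-then-loss shape of real antibody
  melts.  Instrument noise is homoscedastic Gaussian.

* :func:`generate_trajectory` places a rigid bead-cluster solute at the
  centre of a periodic box and scatters single-bead cation / anion / water
  molecules uniformly, except inside a spherical shell around the solute
  where the acceptance is multiplied by a per-species enrichment factor.
  The returned ground truth computes Gamma at any cutoff by direct
  counting with plain Python loops — an oracle independent of the
  vectorized trajectory module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cdio import CDSpectrumSeries, SampleMeta
from .errors import PreconditionError
from .thermo import KELVIN, R_GAS
from .trajectory import FrameSet

__all__ = [
    "MeltTransition",
    "MeltSpec",
    "TrajectorySpec",
    "MeltGroundTruth",
    "TrajectoryGroundTruth",
    "generate_melt",
    "generate_trajectory",
    "default_solute",
]


@dataclass(frozen=True)
class MeltTransition:
    """One two-state component: midpoint, van't Hoff enthalpy, amplitude."""

    tm: float                 # degC
    dh_vanthoff: float        # kJ/mol, > 0
    amplitude: float          # trace units (e.g. deg cm^2 dmol^-1)
    sign: int = 1             # +1 deepens the band, -1 recovers it

    def population(self, t_celsius: np.ndarray) -> np.ndarray:
        """Fraction in the final ensemble, exactly 1/2 at Tm."""
        t_k = np.asarray(t_celsius, dtype=float) + KELVIN
        tm_k = self.tm + KELVIN
        arg = (self.dh_vanthoff * 1000.0 / R_GAS) * (1.0 / t_k - 1.0 / tm_k)
        return 1.0 / (1.0 + np.exp(arg))


@dataclass(frozen=True)
class MeltSpec:
    """Parameters of a synthetic melt curve (the study acquisition grid
    by default: 25-97 degC in 2 degC steps)."""

    transitions: Tuple[MeltTransition, ...]
    baseline: float = -3000.0
    temperature_grid: Tuple[float, ...] = tuple(np.arange(25.0, 97.0 + 1e-9, 2.0))
    noise_sigma: float = 0.0
    seed: int = 0
    wavelength: float = 218.0

    def __post_init__(self) -> None:
        tms = [tr.tm for tr in self.transitions]
        if tms != sorted(tms):
            raise PreconditionError("transitions must be ordered by tm")
        if any(tr.dh_vanthoff <= 0 for tr in self.transitions):
            raise PreconditionError("dh_vanthoff must be positive")
        grid = np.asarray(self.temperature_grid)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise PreconditionError("temperature grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise PreconditionError("noise_sigma must be non-negative")


@dataclass
class MeltGroundTruth:
    """Spec echo plus the noiseless signal, for parameter-recovery tests."""

    spec: MeltSpec
    noiseless: np.ndarray
    populations: np.ndarray   # (n_transitions, n_temps)


def generate_melt(spec: MeltSpec,
                  meta: Optional[SampleMeta] = None
                  ) -> Tuple[CDSpectrumSeries, MeltGroundTruth]:
    """Synthesize a single-wavelength CD melt and its ground truth.

    y(T) = baseline + sum_i sign_i * amplitude_i * f_i(T) + N(0, noise_sigma),
    with the noise drawn from ``numpy.random.default_rng(spec.seed)`` —
    identical specs and seeds give bit-identical series.
    """
    t = np.asarray(spec.temperature_grid, dtype=float)
    pops = np.array([tr.population(t) for tr in spec.transitions]) \
        if spec.transitions else np.zeros((0, t.size))
    signal = spec.baseline + sum(
        tr.sign * tr.amplitude * pops[i] for i, tr in enumerate(spec.transitions)
    )
    signal = np.asarray(signal, dtype=float) * np.ones_like(t)
    noiseless = signal.copy()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=t.size)
    if meta is None:
        meta = SampleMeta(sample_id=f"synthetic-melt-seed{spec.seed}")
    series = CDSpectrumSeries(
        temperatures=t,
        wavelengths=np.array([spec.wavelength]),
        ellipticity=signal[:, None],
        meta=meta,
        units="mre",
    )
    return series, MeltGroundTruth(spec=spec, noiseless=noiseless, populations=pops)


def default_solute(n_beads: int = 7, spacing: float = 2.5) -> np.ndarray:
    """A small rigid bead cluster: one centre bead plus an octahedral shell."""
    pts = [np.zeros(3)]
    for axis in range(3):
        for s in (+1.0, -1.0):
            v = np.zeros(3)
            v[axis] = s * spacing
            pts.append(v)
    return np.array(pts[:n_beads])


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a toy solvated-solute trajectory.

    ``shell_bias`` multiplies the placement acceptance for a species inside
    the spherical shell [r1, r2] (min-distance to the solute); factors
    above 1 enrich, below 1 deplete, 1 is an ideal uniform solution.
    """

    n_frames: int = 20
    box: Tuple[float, float, float] = (60.0, 60.0, 60.0)
    solute: Optional[np.ndarray] = None       # (n_beads, 3), centred
    species_counts: Dict[str, int] = field(
        default_factory=lambda: {"cation": 150, "anion": 150, "water": 600})
    shell_bias: Dict[str, float] = field(default_factory=dict)
    shell: Tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise PreconditionError("need at least one frame")
        if any(c < 0 for c in self.species_counts.values()):
            raise PreconditionError("species counts must be non-negative")
        r1, r2 = self.shell
        if not 0 <= r1 < r2:
            raise PreconditionError("shell must satisfy 0 <= r1 < r2")
        if r2 >= min(self.box) / 2.0:
            raise PreconditionError("shell outer radius must fit inside half the box")
        if any(f <= 0 for f in self.shell_bias.values()):
            raise PreconditionError("enrichment factors must be positive")


@dataclass
class TrajectoryGroundTruth:
    """Direct-counting oracle for the generated trajectory.

    Distances and counts are computed with explicit per-molecule Python
    loops (independent of the vectorized analysis code) so the trajectory
    module can be tested for exact agreement frame by frame.
    """

    spec: TrajectorySpec
    frames: FrameSet

    def _min_dist(self, frame: int, atom: int) -> float:
        coords = self.frames.frames[frame]
        box = self.frames.box_of(frame)
        solute_idx = [i for i, s in enumerate(self.frames.species) if s == "solute"]
        best = math.inf
        for j in solute_idx:
            d2 = 0.0
            for k in range(3):
                delta = coords[atom, k] - coords[j, k]
                delta -= box[k] * round(delta / box[k])
                d2 += delta * delta
            best = min(best, math.sqrt(d2))
        return best

    def gamma(self, species: str, cutoff_r: float,
              water_species: str = "water") -> np.ndarray:
        """Per-frame Gamma by direct counting (single-bead molecules)."""
        sp = self.frames.species
        s_atoms = [i for i, s in enumerate(sp) if s == species]
        w_atoms = [i for i, s in enumerate(sp) if s == water_species]
        out = np.empty(self.frames.n_frames)
        for fr in range(self.frames.n_frames):
            d_s = [self._min_dist(fr, i) for i in s_atoms]
            d_w = d_s if species == water_species else \
                [self._min_dist(fr, i) for i in w_atoms]
            n_s_in = sum(1 for d in d_s if d <= cutoff_r)
            n_w_in = sum(1 for d in d_w if d <= cutoff_r)
            n_s_out = len(d_s) - n_s_in
            n_w_out = len(d_w) - n_w_in
            out[fr] = n_s_in - (n_s_out / n_w_out) * n_w_in
        return out


def generate_trajectory(spec: TrajectorySpec) -> Tuple[FrameSet, TrajectoryGroundTruth]:
    """Generate a toy solvated trajectory with a known solvation structure.

    The solute sits rigidly at the box centre; each frame independently
    re-samples solvent bead positions by rejection sampling against the
    shell-bias weight.  Particle counts are conserved across frames by
    construction.  Seed determinism: identical specs give bit-identical
    frames.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    solute = spec.solute if spec.solute is not None else default_solute()
    solute = np.asarray(solute, dtype=float) + box / 2.0
    r1, r2 = spec.shell

    species_order = sorted(spec.species_counts)
    labels = ["solute"] * len(solute)
    mol_ids = [0] * len(solute)
    next_mol = 1
    for sp_name in species_order:
        n = spec.species_counts[sp_name]
        labels += [sp_name] * n
        mol_ids += list(range(next_mol, next_mol + n))
        next_mol += n
    n_atoms = len(labels)

    def sample_positions(n: int, factor: float) -> np.ndarray:
        """Rejection-sample n points with density proportional to the
        shell weight (factor inside [r1, r2], 1 outside)."""
        w_max = max(factor, 1.0)
        out = np.empty((n, 3))
        got = 0
        while got < n:
            batch = max(2 * (n - got), 64)
            pts = rng.random((batch, 3)) * box
            delta = pts[:, None, :] - solute[None, :, :]
            delta -= box * np.round(delta / box)
            d = np.sqrt((delta ** 2).sum(axis=-1)).min(axis=1)
            w = np.where((d >= r1) & (d <= r2), factor, 1.0)
            accept = rng.random(batch) < w / w_max
            take = pts[accept][: n - got]
            out[got: got + take.shape[0]] = take
            got += take.shape[0]
        return out

    frames = []
    for _ in range(spec.n_frames):
        coords = np.empty((n_atoms, 3))
        coords[: len(solute)] = solute
        offset = len(solute)
        for sp_name in species_order:
            n = spec.species_counts[sp_name]
            factor = spec.shell_bias.get(sp_name, 1.0)
            coords[offset: offset + n] = sample_positions(n, factor)
            offset += n
        frames.append(coords)

    frameset = FrameSet(
        frames=frames,
        species=np.array(labels, dtype=object),
        molecule_ids=np.array(mol_ids),
        box=box,
        selections={"solute": np.arange(len(solute))},
    )
    return frameset, TrajectoryGroundTruth(spec=spec, frames=frameset)
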