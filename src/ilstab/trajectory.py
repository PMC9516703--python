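"""Trajectory post-processing: solvation structure and antibody geometry.

Operates on multi-frame coordinate sets with per-atom species labels
(solute / cation / anion / water) in orthorhombic periodic boxes.

Solvation structure is described through per-molecule minimum distances to
the solute: their histogram (the minimum-distance distribution function,
MDDF) and the preferential interaction coefficient

    Gamma_s = < n_s(<=R) - (N_s^bulk / N_w^bulk) * n_w(<=R) >_frames

which counts the excess of species s inside the cutoff R relative to the
bulk s:water stoichiometry (Kirkwood-Buff-style counting at a finite
cutoff).  Cation and anion coefficients are combined into a single
co-solute Gamma_23 by the indistinguishable-ion approach, with the protein
net charge Z2 entering the default combination form.

Antibody global geometry is summarized by least-squares superposition RMSD
and RMSF and by domain centre-of-mass distances, which classify each
conformation as Y-shaped (Fab arms away from Fc) or lambda-shaped (one Fab
arm folded onto Fc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import PreconditionError

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSet",
    "MDDFResult",
    "SpeciesGamma",
    "PreferentialInteraction",
    "ConformerCall",
    "min_distances",
    "mddf",
    "gamma_species",
    "combine_ion_gammas",
    "preferential_interaction",
    "superpose_rmsd",
    "rmsf",
    "domain_distances",
]

GAMMA23_FORMS = ("sum", "half_sum", "half_sum_minus_half_z")


@dataclass
class FrameSet:
    """Multi-frame coordinates with species and molecule labels.

    frames : list of (n_atoms, 3) float arrays, Angstrom.
    species : length-n_atoms array of labels (solute|cation|anion|water|...).
    molecule_ids : length-n_atoms int array; atoms sharing an id form one
        molecule (the counting unit for MDDF and Gamma).
    box : (3,) edge lengths (Angstrom), shared by all frames, or a list of
        per-frame (3,) arrays.
    selections : named atom-index sets, e.g. Fab1 / Fab2 / Fc.
    """

    frames: List[np.ndarray]
    species: np.ndarray
    molecule_ids: np.ndarray
    box: np.ndarray
    selections: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.species = np.asarray(self.species, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = self.species.size
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise PreconditionError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
        if self.molecule_ids.size != n:
            raise PreconditionError("molecule_ids length must match atom count")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            if self.box.shape != (3,):
                raise PreconditionError("box must be (3,) or (n_frames, 3)")
            if np.any(self.box <= 0):
                raise PreconditionError("box edges must be positive")
        else:
            if self.box.shape != (len(self.frames), 3) or np.any(self.box <= 0):
                raise PreconditionError("per-frame box must be (n_frames, 3), positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.species.size

    def box_of(self, frame: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[frame]

    def atoms_of(self, species: str) -> np.ndarray:
        return np.flatnonzero(self.species == species)

    def molecules_of(self, species: str) -> List[np.ndarray]:
        """Atom-index groups, one per molecule of the species, in id order."""
        idx = self.atoms_of(species)
        if idx.size == 0:
            return []
        ids = self.molecule_ids[idx]
        order = np.argsort(ids, kind="stable")
        idx, ids = idx[order], ids[order]
        splits = np.flatnonzero(np.diff(ids)) + 1
        return np.split(idx, splits)


@dataclass
class MDDFResult:
    """Histogram of per-molecule minimum distances with bulk normalization."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized_density: np.ndarray   # NaN where undefined (empty species)
    n_frames: int
    species: str
    bulk_density: float              # molecules / A^3, NaN if undefined

    def total_count(self) -> float:
        return float(self.counts.sum())


@dataclass
class SpeciesGamma:
    """Per-species preferential interaction coefficient with block-average SE."""

    species: str
    gamma: float
    se: float
    cutoff_r: float
    per_frame: np.ndarray


@dataclass
class PreferentialInteraction:
    """Combined co-solute coefficient from the indistinguishable-ion approach."""

    gamma_plus: float
    gamma_minus: float
    gamma_23: float
    cutoff_r: float
    z2: float
    se: float
    form: str


@dataclass
class ConformerCall:
    """Domain COM distances and the Y/lambda conformer assignment."""

    fab1_fab2: float
    fab1_fc: float
    fab2_fc: float
    label: Literal["Y", "lambda", "ambiguous"]
    per_frame_labels: List[str]
    lambda_fraction: float


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def min_distances(frames: FrameSet, frame: int, species: str,
                  solute_species: str = "solute") -> np.ndarray:
    """Per-molecule minimum distance (Angstrom) from a species to the solute.

    For each molecule of ``species``, the minimum over all (molecule atom,
    solute atom) pairs of the periodic (minimum-image) distance in the
    given frame.  Orthorhombic boxes only.
    """
    solute_idx = frames.atoms_of(solute_species)
    if solute_idx.size == 0:
        raise PreconditionError(f"no atoms labelled {solute_species!r}")
    mols = frames.molecules_of(species)
    if not mols:
        raise PreconditionError(f"species {species!r} not present")
    coords = frames.frames[frame]
    box = frames.box_of(frame)
    solute = coords[solute_idx]
    out = np.empty(len(mols))
    for i, mol in enumerate(mols):
        delta = _min_image(coords[mol][:, None, :] - solute[None, :, :], box)
        out[i] = np.sqrt((delta ** 2).sum(axis=-1)).min()
    return out


def _solute_volume_fractions(frames: FrameSet, edges: np.ndarray,
                             solute_species: str, n_samples: int = 200_000,
                             mc_seed: int = 1_234_567) -> np.ndarray:
    """Monte-Carlo volume of each min-distance shell around the solute.

    The level sets of the min-distance-to-solute field are not spherical
    shells for a multi-atom solute, so shell volumes are estimated by
    uniform sampling of the box (fixed internal seed: deterministic).
    Returns the volume (A^3) of each [edges[i], edges[i+1]) shell.
    """
    rng = np.random.default_rng(mc_seed)
    box = frames.box_of(0)
    pts = rng.random((n_samples, 3)) * box
    solute = frames.frames[0][frames.atoms_of(solute_species)]
    delta = _min_image(pts[:, None, :] - solute[None, :, :], box)
    d = np.sqrt((delta ** 2).sum(axis=-1)).min(axis=1)
    hist, _ = np.histogram(d, bins=edges)
    return hist / n_samples * float(np.prod(box))


def mddf(frames: FrameSet, species: str, bin_width: float = 0.2,
         r_max: float = 20.0, solute_species: str = "solute",
         bulk_fraction: float = 0.25) -> MDDFResult:
    """Minimum-distance distribution function of a species around the solute.

    Histograms per-molecule minimum distances over all frames.  The
    normalized density divides observed shell counts by the expectation
    from uniform placement at the species' bulk density, estimated from
    the outer ``bulk_fraction`` of ``r_max``; shell volumes are the
    Monte-Carlo volumes of the min-distance level sets.  An absent species
    yields zero counts and NaN densities (flagged, no failure).
    """
    if frames.n_frames < 1:
        raise PreconditionError("need at least one frame")
    box = frames.box_of(0)
    if r_max > box.min() / 2.0:
        raise PreconditionError(
            f"r_max {r_max} exceeds half the minimum box edge {box.min() / 2:.3g}"
        )
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    n_bins = edges.size - 1
    if not frames.atoms_of(species).size:
        logger.warning("species %r absent: MDDF undefined", species)
        return MDDFResult(edges, np.zeros(n_bins), np.full(n_bins, np.nan),
                          frames.n_frames, species, float("nan"))

    counts = np.zeros(n_bins)
    for fr in range(frames.n_frames):
        d = min_distances(frames, fr, species, solute_species)
        hist, _ = np.histogram(d, bins=edges)
        counts += hist

    shell_vol = _solute_volume_fractions(frames, edges, solute_species)
    bulk_lo = (1.0 - bulk_fraction) * r_max
    bulk_bins = edges[:-1] >= bulk_lo
    bulk_vol = shell_vol[bulk_bins].sum()
    bulk_count = counts[bulk_bins].sum()
    if bulk_vol <= 0 or bulk_count == 0:
        logger.warning("no bulk reference beyond %.3g A; densities undefined", bulk_lo)
        rho = float("nan")
    else:
        rho = bulk_count / (bulk_vol * frames.n_frames)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = counts / (rho * shell_vol * frames.n_frames)
    return MDDFResult(edges, counts, norm, frames.n_frames, species, rho)


def gamma_species(frames: FrameSet, species: str, cutoff_r: float = 12.0,
                  n_blocks: int = 5, water_species: str = "water",
                  solute_species: str = "solute") -> SpeciesGamma:
    """Preferential interaction coefficient of one species at cutoff R.

    Per frame, Gamma_s = n_s(<=R) - (N_s^bulk / N_w^bulk) * n_w(<=R),
    where n(<=R) counts molecules whose minimum distance to the solute is
    at most R and the bulk ratio uses molecules beyond R.  The result is
    the frame average; the standard error comes from block averaging
    (``n_blocks`` contiguous blocks).
    """
    if cutoff_r <= 0:
        raise PreconditionError("cutoff_r must be positive")
    if not frames.atoms_of(water_species).size:
        raise PreconditionError(f"reference species {water_species!r} not present")
    per_frame = np.empty(frames.n_frames)
    for fr in range(frames.n_frames):
        d_s = min_distances(frames, fr, species, solute_species)
        d_w = (d_s if species == water_species
               else min_distances(frames, fr, water_species, solute_species))
        n_s_in = int((d_s <= cutoff_r).sum())
        n_w_in = int((d_w <= cutoff_r).sum())
        n_s_out = d_s.size - n_s_in
        n_w_out = d_w.size - n_w_in
        if n_w_out == 0:
            raise PreconditionError(
                f"no {water_species} beyond R={cutoff_r} in frame {fr}: box too small"
            )
        per_frame[fr] = n_s_in - (n_s_out / n_w_out) * n_w_in
    se = _block_se(per_frame, n_blocks)
    return SpeciesGamma(species=species, gamma=float(per_frame.mean()), se=se,
                        cutoff_r=cutoff_r, per_frame=per_frame)


def _block_se(values: np.ndarray, n_blocks: int) -> float:
    n_blocks = min(n_blocks, values.size)
    if n_blocks < 2:
        return float("nan")
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def combine_ion_gammas(gamma_plus: float, gamma_minus: float, z2: float,
                       form: str = "half_sum_minus_half_z") -> float:
    """Combine cation and anion coefficients into a single co-solute Gamma_23.

    The indistinguishable-ion approach treats the 1:1 salt as one co-solute
    component.  Three combination conventions are selectable:

    - ``"sum"``:                    Gamma_+ + Gamma_-
    - ``"half_sum"``:               (Gamma_+ + Gamma_-) / 2
    - ``"half_sum_minus_half_z"``:  (Gamma_+ + Gamma_-) / 2 - Z2 / 2  (default)

    The default subtracts half the protein net charge Z2 (in e), the
    counter-charge correction for a charged protein; all forms are
    symmetric under cation/anion exchange.
    """
    if form not in GAMMA23_FORMS:
        raise PreconditionError(f"form must be one of {GAMMA23_FORMS}, got {form!r}")
    if not (np.isfinite(gamma_plus) and np.isfinite(gamma_minus) and np.isfinite(z2)):
        raise PreconditionError("inputs must be finite")
    s = gamma_plus + gamma_minus
    if form == "sum":
        return s
    if form == "half_sum":
        return s / 2.0
    return s / 2.0 - z2 / 2.0


def preferential_interaction(frames: FrameSet, z2: float, cutoff_r: float = 12.0,
                             cation: str = "cation", anion: str = "anion",
                             form: str = "half_sum_minus_half_z",
                             n_blocks: int = 5) -> PreferentialInteraction:
    """Full Gamma_23 pipeline: per-ion coefficients combined with Z2."""
    gp = gamma_species(frames, cation, cutoff_r, n_blocks)
    gm = gamma_species(frames, anion, cutoff_r, n_blocks)
    g23 = combine_ion_gammas(gp.gamma, gm.gamma, z2, form)
    per_frame = np.array([
        combine_ion_gammas(p, m, z2, form)
        for p, m in zip(gp.per_frame, gm.per_frame)
    ])
    return PreferentialInteraction(
        gamma_plus=gp.gamma, gamma_minus=gm.gamma, gamma_23=g23,
        cutoff_r=cutoff_r, z2=z2, se=_block_se(per_frame, n_blocks), form=form,
    )


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``reference`` (least squares)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, rc - mc @ rot


def superpose_rmsd(frames: FrameSet, selection: Optional[np.ndarray] = None,
                   reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after optimal rigid superposition.

    Each frame's selection is superposed (rotation + translation, least
    squares) onto the reference frame before the RMSD is taken.
    """
    sel = _resolve_selection(frames, selection)
    ref = frames.frames[reference_frame][sel]
    out = np.empty(frames.n_frames)
    for fr in range(frames.n_frames):
        mob = frames.frames[fr][sel]
        rot, trans = _kabsch(mob, ref)
        fitted = mob @ rot + trans
        out[fr] = np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean())
    return out


def rmsf(frames: FrameSet, selection: Optional[np.ndarray] = None,
         reference_frame: int = 0) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    All frames are first superposed onto the reference; the RMSF of each
    selected atom is taken about the superposed-ensemble mean position.
    """
    if frames.n_frames < 2:
        raise PreconditionError("RMSF needs at least 2 frames")
    sel = _resolve_selection(frames, selection)
    ref = frames.frames[reference_frame][sel]
    stack = np.empty((frames.n_frames, sel.size, 3))
    for fr in range(frames.n_frames):
        mob = frames.frames[fr][sel]
        rot, trans = _kabsch(mob, ref)
        stack[fr] = mob @ rot + trans
    mean = stack.mean(axis=0)
    return np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=0))


def _resolve_selection(frames: FrameSet, selection) -> np.ndarray:
    if selection is None:
        sel = frames.atoms_of("solute")
    elif isinstance(selection, str):
        if selection not in frames.selections:
            raise PreconditionError(f"selection {selection!r} not defined")
        sel = np.asarray(frames.selections[selection], dtype=int)
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise PreconditionError(
            f"superposition needs >= 3 atoms, selection has {sel.size}"
        )
    return sel


def domain_distances(frames: FrameSet, alpha: float = 0.75,
                     lambda_fraction: float = 0.60,
                     y_fraction: float = 0.40) -> ConformerCall:
    """Domain COM distances and Y/lambda conformer classification.

    Per frame, the centres of mass (equal atom weights) of the Fab1, Fab2
    and Fc selections give the Fab-Fab and two Fab-Fc distances.  A frame
    is lambda-shaped when min(Fab1-Fc, Fab2-Fc) < alpha x Fab1-Fab2 — one
    Fab arm folded onto Fc.  The trajectory label is lambda when at least
    ``lambda_fraction`` of frames are lambda-shaped, Y when at most
    ``y_fraction`` are, and ambiguous in between.
    """
    for name in ("Fab1", "Fab2", "Fc"):
        if name not in frames.selections:
            raise PreconditionError(f"selection {name!r} not defined")
    f1 = np.asarray(frames.selections["Fab1"], dtype=int)
    f2 = np.asarray(frames.selections["Fab2"], dtype=int)
    fc = np.asarray(frames.selections["Fc"], dtype=int)

    labels = []
    d12s, d1cs, d2cs = [], [], []
    for fr in range(frames.n_frames):
        coords = frames.frames[fr]
        c1, c2, cc = coords[f1].mean(axis=0), coords[f2].mean(axis=0), coords[fc].mean(axis=0)
        d12 = float(np.linalg.norm(c1 - c2))
        d1c = float(np.linalg.norm(c1 - cc))
        d2c = float(np.linalg.norm(c2 - cc))
        d12s.append(d12)
        d1cs.append(d1c)
        d2cs.append(d2c)
        labels.append("lambda" if min(d1c, d2c) < alpha * d12 else "Y")
    lam_frac = labels.count("lambda") / len(labels)
    if lam_frac >= lambda_fraction:
        label = "lambda"
    elif lam_frac <= y_fraction:
        label = "Y"
    else:
        label = "ambiguous"
    return ConformerCall(
        fab1_fab2=float(np.mean(d12s)), fab1_fc=float(np.mean(d1cs)),
        fab2_fc=float(np.mean(d2cs)), label=label,
        per_frame_labels=labels, lambda_fraction=lam_frac,
    )
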