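"""Synthetic inputs with known ground truth for every analysis stage.

Three generators, all pure functions of (spec, seed):

* adsorbed-peptide trajectories whose per-residue contact pattern follows a
  two-state Markov chain with prescribed stationary probability and
  persistence, over a three-layer Au(111)-like slab;
* conformational ensembles drawn from planted templates plus isotropic
  Gaussian noise (and optional random rigid motion);
* umbrella-window samples drawn exactly (inverse-CDF on a fine grid) from the
  Boltzmann density of a known PMF under a harmonic bias.

Each generator returns its ground truth (contact matrix, template labels, the
analytic PMF) so recovery tests can compare estimates against what was
planted rather than against another estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Conformation
from .contacts import DEFAULT_CUTOFF
from .errors import InputError, NumericError
from .trajectory import Atom, Frame, Trajectory
from .wham import KB_KJ_PER_MOL_K, UmbrellaWindow

__all__ = [
    "ContactSpec",
    "PMFSpec",
    "gen_contact_trajectory",
    "gen_cluster_ensemble",
    "gen_umbrella_samples",
    "random_templates",
    "AU_LAYER_SPACING",
]

#: Representative Au(111) interlayer spacing (Angstrom); only the relative
#: placement of reference sites versus the cut-off matters for the analyses.
AU_LAYER_SPACING = 2.35
_AU_NN_DISTANCE = 2.884  # in-plane nearest-neighbour spacing, Angstrom


@dataclass
class ContactSpec:
    """Prescription for a synthetic adsorbed-peptide trajectory.

    Per residue, a two-state (contact/no-contact) Markov chain with stationary
    probability ``contact_probabilities[i]`` and lag-1 autocorrelation
    ``correlation`` decides the contact state each frame.  Contact frames put
    the residue's reference site ``contact_offset`` above cut-off height;
    non-contact frames ``noncontact_offset`` above it.
    """

    contact_probabilities: tuple[float, ...]
    n_frames: int
    correlation: float = 0.5  # first-order Markov persistence rho in [0, 1)
    residue_names: tuple[str, ...] | None = None  # defaults to all MET
    cutoff: float = DEFAULT_CUTOFF
    contact_offset: float = -0.5  # site at cutoff - 0.5 A when in contact
    noncontact_offset: float = 3.0  # site at cutoff + 3 A otherwise
    n_layers: int = 3
    atoms_per_side: int = 4  # slab is an atoms_per_side^2 grid per layer
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.contact_probabilities, dtype=float)
        if probs.size == 0:
            raise InputError("need at least one residue contact probability")
        if np.any((probs < 0) | (probs > 1)):
            raise InputError("contact probabilities must lie in [0, 1]")
        if not (0 <= self.correlation < 1):
            raise InputError(f"correlation must be in [0, 1), got {self.correlation}")
        if self.n_frames < 1:
            raise InputError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.residue_names is not None and len(self.residue_names) != probs.size:
            raise InputError("residue_names length must match probabilities")


# Reference-site atom name per residue type, matching the default reference
# table so generated trajectories analyse out of the box.
_SITE_ATOM = {
    "MET": "SD", "CYS": "SG", "MOX": "SD", "CTB": "SG", "COX": "SG",
    "THR": "OG1", "SER": "OG", "ALA": "CB", "GLY": "CA", "TYR": "OH",
    "PHE": "CZ", "LYS": "NZ", "PRO": "CG", "ILE": "CD1",
}


def _markov_chain(
    rng: np.random.Generator, p: np.ndarray, rho: float, n_frames: int
) -> np.ndarray:
    """Stationary two-state chains, one per column; lag-1 autocorrelation rho.

    Transition probabilities: P(1|1) = p + rho (1-p), P(1|0) = p (1-rho),
    which leaves the stationary distribution at p and the autocorrelation at
    rho for every residue.
    """
    u = rng.random((n_frames, p.size))
    states = np.empty((n_frames, p.size), dtype=bool)
    states[0] = u[0] < p
    p_stay = p + rho * (1 - p)
    p_gain = p * (1 - rho)
    for t in range(1, n_frames):
        thresh = np.where(states[t - 1], p_stay, p_gain)
        states[t] = u[t] < thresh
    return states


def gen_contact_trajectory(spec: ContactSpec) -> tuple[Trajectory, np.ndarray]:
    """Synthetic peptide-on-gold trajectory plus its ground-truth contact matrix.

    Returns ``(trajectory, contacts)`` where ``contacts`` is the planted
    (n_frames, n_residues) boolean matrix; ``compute_contact_fractions`` on
    the trajectory reproduces its column means exactly by construction.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.contact_probabilities, dtype=float)
    n_res = probs.size
    names = (
        tuple(spec.residue_names)
        if spec.residue_names is not None
        else ("MET",) * n_res
    )
    unknown = sorted(set(names) - set(_SITE_ATOM))
    if unknown:
        raise InputError(
            "no reference-site atom known for residue types: " + ", ".join(unknown)
        )

    # --- slab: n_layers square grids, top layer at z = (n_layers-1) * spacing
    side = spec.atoms_per_side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    layer_xy = np.column_stack([xs.ravel(), ys.ravel()]) * _AU_NN_DISTANCE
    slab_coords = np.concatenate(
        [
            np.column_stack([layer_xy, np.full(side * side, k * AU_LAYER_SPACING)])
            for k in range(spec.n_layers)
        ]
    )
    n_slab = slab_coords.shape[0]
    top_z = (spec.n_layers - 1) * AU_LAYER_SPACING

    atoms: list[Atom] = [
        Atom(index=i, name="AU", element="Au", residue_index=0,
             residue_name="AUS", is_slab=True)
        for i in range(n_slab)
    ]
    # peptide: per residue a CA plus the reference-site atom, strung along x
    site_rows: list[int] = []
    for r, name in enumerate(names):
        base = n_slab + 2 * r
        atoms.append(Atom(index=base, name="CA", element="C",
                          residue_index=r + 1, residue_name=name))
        atoms.append(Atom(index=base + 1, name=_SITE_ATOM[name], element="S",
                          residue_index=r + 1, residue_name=name))
        site_rows.append(base + 1)

    contacts = _markov_chain(rng, probs, spec.correlation, spec.n_frames)
    z_contact = top_z + spec.cutoff + spec.contact_offset
    z_free = top_z + spec.cutoff + spec.noncontact_offset

    peptide_x = 2.0 + 3.5 * np.arange(n_res)
    box = (
        max(side * _AU_NN_DISTANCE, peptide_x[-1] + 4.0),
        side * _AU_NN_DISTANCE,
        top_z + spec.cutoff + spec.noncontact_offset + 20.0,
    )

    n_atoms = n_slab + 2 * n_res
    frames: list[Frame] = []
    for t in range(spec.n_frames):
        coords = np.empty((n_atoms, 3))
        coords[:n_slab] = slab_coords
        site_z = np.where(contacts[t], z_contact, z_free)
        for r in range(n_res):
            base = n_slab + 2 * r
            coords[base] = (peptide_x[r], 2.0, site_z[r] + 1.5)  # CA above site
            coords[base + 1] = (peptide_x[r], 2.0, site_z[r])
        frames.append(Frame(coordinates=coords, box=box, time=float(t)))

    return Trajectory(atoms=atoms, frames=frames), contacts


def gen_cluster_ensemble(
    templates: list[Conformation] | list[np.ndarray],
    weights: tuple[float, ...] | np.ndarray,
    noise_rms: float,
    n: int,
    seed: int = 0,
    random_pose: bool = False,
) -> tuple[list[Conformation], np.ndarray]:
    """Ensemble of conformations drawn from planted templates, plus true labels.

    Each conformation is a weight-chosen template perturbed by isotropic
    Gaussian noise with per-atom RMS displacement ``noise_rms`` (Angstrom);
    with ``random_pose`` it is additionally rigidly rotated and translated,
    which fitted RMSD is blind to.
    """
    if not templates:
        raise InputError("need at least one template")
    coords = [np.asarray(getattr(t, "coordinates", t), dtype=float) for t in templates]
    if len({c.shape for c in coords}) != 1:
        raise InputError("templates must share one atom count")
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(coords) or np.any(weights < 0):
        raise InputError("weights must be non-negative, one per template")
    if not np.isclose(weights.sum(), 1.0):
        raise InputError(f"weights must sum to 1, got {weights.sum()}")
    if noise_rms < 0:
        raise InputError(f"noise_rms must be >= 0, got {noise_rms}")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(coords), size=n, p=weights)
    sigma = noise_rms / np.sqrt(3.0)  # per-coordinate sd -> per-atom RMS = noise_rms
    ensemble: list[Conformation] = []
    for i, lab in enumerate(labels):
        c = coords[lab] + rng.normal(0.0, sigma, size=coords[lab].shape)
        if random_pose:
            # uniform random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            center = c.mean(axis=0)
            c = (c - center) @ q.T + center + rng.uniform(-5.0, 5.0, size=3)
        ensemble.append(Conformation(coordinates=c, frame_index=i))
    return ensemble, labels


def random_templates(
    k: int,
    n_atoms: int,
    seed: int = 0,
    min_rmsd: float = 6.0,
    scale: float = 4.0,
    max_tries: int = 1000,
) -> list[Conformation]:
    """k random smooth-ish chain templates with pairwise fitted RMSD > min_rmsd.

    Templates are cumulative random walks (step scale ``scale`` Angstrom),
    re-drawn until all pairs are separated; used to plant well-separated
    conformational clusters.
    """
    from .clustering import backbone_rmsd

    rng = np.random.default_rng(seed)
    templates: list[Conformation] = []
    for _ in range(max_tries):
        cand = Conformation(
            coordinates=np.cumsum(rng.normal(0, scale, size=(n_atoms, 3)), axis=0)
        )
        if all(backbone_rmsd(cand, t) > min_rmsd for t in templates):
            templates.append(cand)
        if len(templates) == k:
            return templates
    raise InputError(
        f"could not draw {k} templates with pairwise RMSD > {min_rmsd} A "
        f"in {max_tries} tries; lower min_rmsd or raise scale"
    )


@dataclass
class PMFSpec:
    """An analytic potential of mean force used as a sampling ground truth.

    Forms (xi in nm, energies kJ/mol):

    * ``flat``: U = 0
    * ``harmonic``: U = kappa/2 (xi - center)^2, params ``center``, ``kappa``
    * ``double-well``: U = a (xi^2 - b^2)^2, params ``a`` (kJ mol^-1 nm^-4),
      ``b`` (nm; the wells sit at +-b)
    """

    form: str
    range: tuple[float, float]
    params: dict[str, float] = field(default_factory=dict)
    temperature: float = 300.0

    def __post_init__(self):
        if self.form not in ("flat", "harmonic", "double-well"):
            raise InputError(f"unknown PMF form {self.form!r}")
        lo, hi = self.range
        if not (hi > lo):
            raise InputError(f"empty range {self.range}")
        if self.form == "harmonic" and not {"center", "kappa"} <= set(self.params):
            raise InputError("harmonic form needs params center, kappa")
        if self.form == "double-well" and not {"a", "b"} <= set(self.params):
            raise InputError("double-well form needs params a, b")
        if any(not np.isfinite(v) for v in self.params.values()):
            raise InputError("PMF parameters must be finite")

    def energy(self, xi: np.ndarray) -> np.ndarray:
        """U(xi) in kJ/mol."""
        xi = np.asarray(xi, dtype=float)
        if self.form == "flat":
            return np.zeros_like(xi)
        if self.form == "harmonic":
            return 0.5 * self.params["kappa"] * (xi - self.params["center"]) ** 2
        a, b = self.params["a"], self.params["b"]
        return a * (xi**2 - b**2) ** 2


def gen_umbrella_samples(
    pmf: PMFSpec,
    centers: list[float] | np.ndarray,
    k: float,
    n_per_window: int,
    seed: int = 0,
    grid_points: int = 10_000,
) -> list[UmbrellaWindow]:
    """Exact Boltzmann samples from each biased window density.

    For window centre z0 the density is p(xi) ∝ exp(-[U(xi) + k/2 (xi-z0)^2]
    / kT), sampled by inverse-CDF interpolation on a ``grid_points`` grid over
    the PMF range.  Deterministic for a given seed; windows are drawn from
    independent child seeds so dropping one window does not shift the others.
    """
    centers = np.asarray(centers, dtype=float)
    lo, hi = pmf.range
    if np.any((centers < lo) | (centers > hi)):
        raise InputError("all window centres must lie within the PMF range")
    if k <= 0:
        raise InputError(f"force constant must be > 0, got {k}")
    if n_per_window < 1:
        raise InputError(f"n_per_window must be >= 1, got {n_per_window}")

    kt = KB_KJ_PER_MOL_K * pmf.temperature
    grid = np.linspace(lo, hi, grid_points)
    u_grid = pmf.energy(grid)
    seeds = np.random.SeedSequence(seed).spawn(centers.size)

    windows: list[UmbrellaWindow] = []
    for z0, child in zip(centers, seeds):
        total = u_grid + 0.5 * k * (grid - z0) ** 2
        log_w = -(total - total.min()) / kt
        weights = np.exp(log_w)
        cdf = np.concatenate([[0.0], np.cumsum((weights[1:] + weights[:-1]) / 2)])
        if not np.isfinite(cdf[-1]) or cdf[-1] <= 0:
            raise NumericError(f"unnormalizable window density at z0 = {z0} nm")
        cdf /= cdf[-1]
        rng = np.random.default_rng(child)
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(z0), force_constant=k,
                                      samples=samples))
    return windows
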