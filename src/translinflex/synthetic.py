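"""Synthetic translin-like assemblies and noisy SAXS curves.

The generator emulates the features the analysis pipeline assumes: a hollow
dimer-of-tetramers octamer with one four-fold (C4) axis and one two-fold (C2)
axis, an opening motion that separates the two tetramers along the polar
direction, disordered terminal tails (12 N-terminal + 11 C-terminal residues
per subunit), a (GU)-repeat ssRNA placed in the interior cavity, and
Gaussian-noise scattering curves on the momentum-transfer range used for the
analysis windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import Bead, ScatteringCurve, Structure
from . import saxs

logger = logging.getLogger("translinflex")

__all__ = [
    "AssemblyParams",
    "NoiseModel",
    "make_octamer",
    "add_terminal_tails",
    "simulate_curve",
    "make_cavity_rna",
    "default_s_grid",
]

#: default simulation grid: 201 points spanning the analysis windows (1/A)
def default_s_grid(n: int = 201, s_min: float = 0.009, s_max: float = 0.40) -> np.ndarray:
    return np.linspace(s_min, s_max, n)


@dataclass(frozen=True)
class AssemblyParams:
    """Geometry of the toy hollow octamer.

    The assembly is a spherical shell of radius ``outer_radius`` tiled by
    curved-slab subunits; ``hinge_opening`` rigidly translates the two
    tetramer halves apart along the polar (C2-relating) direction, 0 being
    the compact state.
    """

    n_subunits: int = 8
    beads_per_subunit: int = 160
    outer_radius: float = 45.0
    hinge_opening: float = 0.0
    symmetric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hinge_opening < 0:
            raise ValueError("hinge_opening must be >= 0")
        if self.symmetric and (self.n_subunits % 2 or self.n_subunits % 4):
            raise ValueError("symmetric assembly needs n_subunits divisible by 2 and 4")
        if self.n_subunits % 2:
            raise ValueError("n_subunits must be even (two rings of subunits)")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise: sigma(s) = level * I(s) + floor."""

    level: float = 0.01
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0 or self.floor < 0:
            raise ValueError("noise level and floor must be >= 0")


#: residue number of the first core bead, leaving room for a 12-residue N-tail
CORE_FIRST_RESNUM = 13

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWX"


def _subunit_template(params: AssemblyParams) -> np.ndarray:
    """Beads of one subunit: a serpentine Calpha-like trace on a shell sector.

    The chain snakes along constant-latitude rows of a spherical sector
    (polar angle 12-84 deg, azimuthal width 2 pi / (n_subunits/2)) with
    near-uniform arc spacing, chosen so consecutive residues sit within the
    5 A distortion-filter bond window and within the elastic-network cutoff.
    """
    n = params.beads_per_subunit
    r = params.outer_radius
    th0, th1 = np.deg2rad(12.0), np.deg2rad(84.0)
    sector = 2.0 * np.pi / (params.n_subunits // 2)

    def census(c: float) -> tuple[list[float], list[int]]:
        n_rows = max(2, int(round(r * (th1 - th0) / c)))
        thetas = list(np.linspace(th0, th1, n_rows))
        counts = [max(2, int(round(r * sector * np.sin(t) / c))) for t in thetas]
        return thetas, counts

    # bisect the target spacing so the serpentine carries at least n beads
    lo, hi = 0.5, r
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if sum(census(mid)[1]) >= n else (lo, mid)
    thetas, counts = census(lo)
    pts: list[list[float]] = []
    for i, (th, n_k) in enumerate(zip(thetas, counts)):
        phis = sector * (np.arange(n_k) + 0.5) / n_k
        if i % 2 == 1:
            phis = phis[::-1]
        for ph in phis:
            pts.append(
                [
                    r * np.sin(th) * np.cos(ph),
                    r * np.sin(th) * np.sin(ph),
                    r * np.cos(th),
                ]
            )
            if len(pts) == n:
                return np.array(pts)
    return np.array(pts[:n])


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

#: two-fold rotation about x, mapping the upper tetramer onto the lower
_C2X = np.diag([1.0, -1.0, -1.0])


def make_octamer(params: AssemblyParams) -> Structure:
    """Build the hollow dimer-of-tetramers assembly.

    The upper ring of ``n_subunits/2`` subunits is generated by the C4 (or
    C_{n/2}) rotation about z from one template; the lower ring is its exact
    C2 image about x, so the compact assembly carries both symmetry axes by
    construction. ``hinge_opening`` translates the rings +/- h/2 along z.
    """
    if params.hinge_opening > params.outer_radius:
        raise ValueError("hinge_opening exceeds the outer radius")
    template = _subunit_template(params)
    half = params.n_subunits // 2
    sector = 2.0 * np.pi / half
    beads: list[Bead] = []
    shift = np.array([0.0, 0.0, params.hinge_opening / 2.0])
    for k in range(params.n_subunits):
        ring, idx = divmod(k, half)
        xyz = template @ _rot_z(sector * idx).T
        if ring == 1:
            xyz = xyz @ _C2X.T
        xyz = xyz + (shift if ring == 0 else -shift)
        chain = _CHAIN_IDS[k]
        for r, p in enumerate(xyz):
            beads.append(
                Bead(chain, CORE_FIRST_RESNUM + r, "ALA", "CA", p[0], p[1], p[2], 1.0)
            )
    s = Structure(beads, metadata=f"synthetic octamer hinge={params.hinge_opening}")
    return s


def _grow_tail(
    rng: np.random.Generator,
    anchor: np.ndarray,
    direction: np.ndarray,
    length: int,
    avoid: np.ndarray,
    step: float = 3.8,
    min_sep: float = 3.0,
    max_tries: int = 200,
) -> np.ndarray:
    """Self-avoiding random walk of ``length`` beads from ``anchor``.

    Successive beads are exactly ``step`` apart; each new bead must keep
    ``min_sep`` from the avoid set and from earlier tail beads.
    """
    placed: list[np.ndarray] = []
    pos = anchor.copy()
    d = direction / np.linalg.norm(direction)
    for _ in range(length):
        for attempt in range(max_tries):
            persist = 0.7 if attempt < max_tries // 2 else 0.0
            prop = persist * d + np.asarray(rng.normal(size=3))
            prop /= np.linalg.norm(prop)
            cand = pos + step * prop
            obstacles = avoid if len(placed) < 2 else np.vstack([avoid] + placed[:-1])
            if cdist(cand[None, :], obstacles).min() >= min_sep:
                break
        else:
            raise RuntimeError("tail growth failed: persistent clash")
        placed.append(cand)
        d = prop
        pos = cand
    return np.array(placed)


def add_terminal_tails(
    structure: Structure,
    n_term_len: int = 12,
    c_term_len: int = 11,
    n_conformers: int = 1,
    seed: int = 0,
) -> list[Structure]:
    """Attach random disordered tails to every chain of the assembly.

    Each conformer gets an independent self-avoiding random-walk N-tail
    (``n_term_len`` residues, numbered below the chain's first residue) and
    C-tail (``c_term_len`` residues, numbered above the last) per chain, with
    successive-bead distance 3.8 A. Core beads are untouched; tail beads are
    inserted so each chain stays ordered by residue number.
    """
    if n_term_len < 0 or c_term_len < 0:
        raise ValueError("tail lengths must be >= 0")
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    logger.info("add_terminal_tails: n=%d c=%d conformers=%d seed=%d",
                n_term_len, c_term_len, n_conformers, seed)
    core_xyz = structure.coords
    center = core_xyz.mean(axis=0)
    out: list[Structure] = []
    for ic in range(n_conformers):
        rng = np.random.default_rng((seed, ic))
        beads: list[Bead] = []
        for chain in structure.chains:
            cb = structure.chain_beads(chain)
            first, last = cb[0], cb[-1]
            chain_beads: list[Bead] = list(cb)
            if n_term_len:
                anchor = np.array([first.x, first.y, first.z])
                walk = _grow_tail(rng, anchor, anchor - center, n_term_len, core_xyz)
                ntail = [
                    Bead(chain, first.resnum - 1 - i, "GLY", "CA", *walk[i], 1.0)
                    for i in range(n_term_len)
                ]
                chain_beads = ntail[::-1] + chain_beads
            if c_term_len:
                anchor = np.array([last.x, last.y, last.z])
                walk = _grow_tail(rng, anchor, anchor - center, c_term_len, core_xyz)
                ctail = [
                    Bead(chain, last.resnum + 1 + i, "GLY", "CA", *walk[i], 1.0)
                    for i in range(c_term_len)
                ]
                chain_beads = chain_beads + ctail
            beads.extend(chain_beads)
        out.append(Structure(beads, metadata=structure.metadata + " +tails"))
    return out


def simulate_curve(
    structure_or_mixture: Structure | list[tuple[Structure, float]],
    s_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    label: str = "synthetic",
) -> ScatteringCurve:
    """Noisy SAXS curve of a structure or a weighted two-state mixture.

    The noise-free intensity is the weight-averaged Debye profile of the
    components; Gaussian noise of the stated sigma is added and the sigma
    column reports the sigma that was applied.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    if isinstance(structure_or_mixture, Structure):
        mixture = [(structure_or_mixture, 1.0)]
    else:
        mixture = list(structure_or_mixture)
    if not mixture:
        raise ValueError("empty mixture")
    wts = np.array([w for _, w in mixture], dtype=float)
    if np.any(wts < 0) or not np.isclose(wts.sum(), 1.0):
        raise ValueError("mixture weights must be >= 0 and sum to 1")
    inten = np.zeros_like(np.asarray(s_grid, dtype=float))
    for struct, w in mixture:
        if w == 0:
            continue
        inten = inten + w * saxs.debye_profile(struct, s_grid).intensity
    noise = noise or NoiseModel(level=0.0)
    sigma = noise.level * np.abs(inten) + noise.floor
    if noise.level > 0 or noise.floor > 0:
        rng = np.random.default_rng(noise.seed)
        inten = inten + rng.normal(scale=np.where(sigma > 0, sigma, 0.0))
    return ScatteringCurve(np.asarray(s_grid, dtype=float), inten, sigma, label)


_RNA_ALPHABET = set("ACGU")


def make_cavity_rna(
    sequence: str,
    cavity_center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    cavity_radius: float = 18.0,
    seed: int = 0,
) -> Structure:
    """Random smooth ssRNA conformation confined to the interior cavity.

    Three beads per nucleotide (phosphate P, sugar C4', base centroid) follow
    a persistent random walk of the C4' trace with successive C4'-C4'
    distances in [5, 7] A, reflected back whenever it would leave the cavity
    sphere.
    """
    sequence = sequence.upper().replace("T", "U")
    if not sequence or set(sequence) - _RNA_ALPHABET:
        raise ValueError("sequence must be non-empty over {A,C,G,U}")
    n = len(sequence)
    center = np.asarray(cavity_center, dtype=float)
    # minimum compaction heuristic: n spheres of 2.8 A radius at 50% packing
    min_radius = 2.8 * (2.0 * n) ** (1.0 / 3.0)
    if cavity_radius < min_radius:
        raise ValueError(
            f"cavity radius {cavity_radius:.1f} A too small for {n} nt "
            f"(needs >= {min_radius:.1f} A)"
        )
    rng = np.random.default_rng(seed)
    margin = 3.5  # keep P/base offsets inside the sphere too
    r_eff = cavity_radius - margin
    c4 = [center + rng.normal(scale=0.3 * r_eff, size=3).clip(-0.5 * r_eff, 0.5 * r_eff)]
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for _ in range(n - 1):
        for _try in range(500):
            step = rng.uniform(5.0, 7.0)
            prop = 0.8 * d + rng.normal(size=3)
            prop /= np.linalg.norm(prop)
            cand = c4[-1] + step * prop
            if np.linalg.norm(cand - center) <= r_eff:
                break
        else:
            raise RuntimeError("could not keep RNA walk inside cavity")
        c4.append(cand)
        d = prop
    beads: list[Bead] = []
    for i, nt in enumerate(sequence):
        pos = c4[i]
        radial = pos - center
        rn = np.linalg.norm(radial)
        radial = radial / rn if rn > 1e-9 else np.array([0.0, 0.0, 1.0])
        p_pos = pos + 2.0 * radial
        tang = np.cross(radial, d)
        tn = np.linalg.norm(tang)
        tang = tang / tn if tn > 1e-9 else np.array([1.0, 0.0, 0.0])
        b_pos = pos - 3.0 * radial + 1.0 * tang
        beads.append(Bead("R", i + 1, nt, "P", *p_pos, 1.0))
        beads.append(Bead("R", i + 1, nt, "C4'", *pos, 1.0))
        beads.append(Bead("R", i + 1, nt, "BAS", *b_pos, 1.0))
    return Structure(beads, metadata=f"cavity ssRNA {sequence}")
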