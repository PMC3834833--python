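"""Shared fixtures: analytic bead bodies, synthetic assemblies, demo runs."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from translinflex.io_core import Bead, Structure
from translinflex import docking, pipeline, synthetic


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def onion_sphere(radius: float, n_total: int = 2000, n_shells: int = 18) -> Structure:
    """Quasi-uniform bead filling of a solid sphere.

    Concentric Fibonacci shells at the volume-centroid radius of equal-width
    radial bins; the smooth angular structure suppresses the incoherent
    bead-discreteness floor that a Poisson point cloud would add to the
    scattering profile.
    """
    edges = radius * np.linspace(0.0, 1.0, n_shells + 1)
    pts = []
    for k in range(n_shells):
        nk = max(1, int(round(n_total * (edges[k + 1] ** 3 - edges[k] ** 3) / radius**3)))
        rk = 0.75 * (edges[k + 1] ** 4 - edges[k] ** 4) / (edges[k + 1] ** 3 - edges[k] ** 3)
        pts.append(rk * fibonacci_sphere(nk))
    xyz = np.vstack(pts)
    return Structure(
        [Bead("A", i + 1, "ALA", "CA", *p, 1.0) for i, p in enumerate(xyz)],
        metadata=f"onion sphere R={radius}",
    )


def structure_from_coords(xyz: np.ndarray, chain: str = "A") -> Structure:
    return Structure(
        [Bead(chain, i + 1, "ALA", "CA", *p, 1.0) for i, p in enumerate(np.asarray(xyz))]
    )


@pytest.fixture(scope="session")
def sphere50() -> Structure:
    return onion_sphere(50.0, 2000)


@pytest.fixture(scope="session")
def s_grid() -> np.ndarray:
    return synthetic.default_s_grid()


@pytest.fixture(scope="session")
def octamer() -> Structure:
    return synthetic.make_octamer(synthetic.AssemblyParams())


@pytest.fixture(scope="session")
def small_octamer() -> Structure:
    """Coarser assembly for fast tests; still mechanically rigid at the
    default elastic-network cutoff."""
    return synthetic.make_octamer(synthetic.AssemblyParams(beads_per_subunit=80))


# --- docking fixtures -------------------------------------------------------

def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


#: maps the dinucleotide template's helix axis (z) onto the ring tangent (y)
RING_AXIS_TO_TANGENT = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])


def build_ring_fixture(ligand) -> dict:
    """Ball receptor with 12 planted dinucleotide pockets on an equatorial ring.

    Pockets are carved snugly (3.0 A) around planted poses and a wider
    channel (5.5 A) around a reference (GU)12 ring threaded through them, so
    ring-following threaded models are sterically possible. Binding-site
    residues are the deep pocket floors, which keeps the kept pose set
    sparse (no percolation of the pose clusters along the ring).
    """
    lxyz = ligand.coords
    lc = lxyz.mean(axis=0)
    rho, rb = 27.0, 30.0
    placements, centers = [], []
    for k in range(12):
        ang = 2 * np.pi * k / 12
        rot = _rz(ang) @ RING_AXIS_TO_TANGENT
        center = np.array([rho * np.cos(ang), rho * np.sin(ang), 0.0])
        centers.append(center)
        placements.append((rot, (lxyz - lc) @ rot.T + center))
    centers = np.array(centers)
    allp = np.vstack([c for _, c in placements])
    i5, i3 = docking._c4_indices(ligand)
    planted = [
        docking.DockPose(k, placements[k][0], np.zeros(3), 20.0, placements[k][1],
                         placements[k][1][i5], placements[k][1][i3])
        for k in range(12)
    ]
    chains = docking.enumerate_chains(planted, d_min=4.0, d_max=11.0, gap_max=1,
                                      max_len=12)
    ring_path = max(chains, key=lambda c: len(c.pose_ids))
    ref_model = docking.thread_rna(ring_path, planted, max_iter=3000)

    rng = np.random.default_rng(7)
    g = np.arange(-rb, rb + 0.1, 2.0)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3) + rng.uniform(
        -0.7, 0.7, (g.size**3, 3)
    )
    ang = np.arctan2(pts[:, 1], pts[:, 0]) % (2 * np.pi)
    wedge = pts[(ang < 2 * np.pi / 12) & (np.linalg.norm(pts, axis=1) <= rb)]
    sym = np.vstack([wedge @ _rz(2 * np.pi * k / 12).T for k in range(12)])
    keep = (cdist(sym, allp).min(axis=1) >= 3.0) & (
        cdist(sym, ref_model.rna.coords).min(axis=1) >= 5.5
    )
    receptor = structure_from_coords(sym[keep])
    floors = tuple(
        sorted(
            {
                (b.chain, b.resnum)
                for b in receptor.beads
                if np.linalg.norm([b.x, b.y, b.z]) < 21.5
                and cdist(np.array([[b.x, b.y, b.z]]), centers).min() < 9.5
            }
        )
    )
    site = docking.BindingSite(floors, cutoff=5.0)
    rotations = [_rz(2 * np.pi * k / 12) @ RING_AXIS_TO_TANGENT for k in range(12)]
    return {
        "receptor": receptor,
        "site": site,
        "centers": centers,
        "planted": planted,
        "ring_path": ring_path,
        "ref_model": ref_model,
        "rotations": rotations,
    }


def build_pocket_slab(ligand):
    """Disc-shaped slab with a fully buried ligand-shaped cavity: the unique
    optimum of the surface-contact score, for translation-scan oracles."""
    lxyz = ligand.coords
    target = lxyz - lxyz.mean(axis=0) + np.array([4.0, -3.0, -5.0])
    rng = np.random.default_rng(20)
    pts = []
    for x in np.arange(-20, 20.1, 2.1):
        for y in np.arange(-20, 20.1, 2.1):
            for z in np.arange(-12, 2.01, 2.1):
                p = np.array([x, y, z]) + rng.uniform(-0.3, 0.3, 3)
                if np.hypot(p[0], p[1]) > 18.0:
                    continue
                if cdist(p[None, :], target).min() > 3.4:
                    pts.append(p)
    return structure_from_coords(np.array(pts)), target


@pytest.fixture(scope="session")
def ring_fixture():
    return build_ring_fixture(docking.make_gu_dinucleotide())


# --- demo pipeline runs (shared across modules) -----------------------------

@pytest.fixture(scope="session")
def free_report():
    return pipeline.run_free_analysis(pipeline.demo_free_config(0))


@pytest.fixture(scope="session")
def complex_report():
    return pipeline.run_complex_analysis(pipeline.demo_complex_config(0))
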