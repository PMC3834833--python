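"""Fragment-based flexible ssRNA docking.

The procedure mirrors dinucleotide-anchored docking: (1) rigid GU
dinucleotides are docked over the receptor surface by FFT shape
complementarity; (2) poses are kept only near the known nucleic-acid-binding
residues (5 A); (3) surviving poses are clustered at 10 A; (4) compatible
poses are chained through a directed graph into combinations of up to 12
consecutive dinucleotides, allowing gaps; (5) a helicoidal ssRNA is threaded
through each chain and relaxed by quasi-Newton minimization restrained to
the docked C4' positions; (6) models with too many steric clashes are
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io_core import Bead, Structure

logger = logging.getLogger("translinflex")

__all__ = [
    "DockPose",
    "BindingSite",
    "ChainPath",
    "RNAComplexModel",
    "make_gu_dinucleotide",
    "dock_dinucleotide",
    "binding_site_filter",
    "cluster_poses",
    "enumerate_chains",
    "cluster_chains",
    "thread_rna",
    "clash_filter",
]


@dataclass
class DockPose:
    """A rigid placement of the dinucleotide template.

    ``coords`` are the transformed template bead positions; ``anchor5`` and
    ``anchor3`` are the C4' positions of the 5' and 3' nucleotides used for
    graph chaining and threading restraints.
    """

    pose_id: int
    rotation: np.ndarray
    translation: np.ndarray
    score: float
    coords: np.ndarray
    anchor5: np.ndarray
    anchor3: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-6) \
                or np.linalg.det(r) < 0:
            raise ValueError("rotation must be a proper orthonormal matrix")


@dataclass(frozen=True)
class BindingSite:
    """Receptor residues known to contact nucleic acids, with a cutoff."""

    residues: tuple[tuple[str, int], ...]
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must name at least one residue")


@dataclass
class ChainPath:
    """Ordered dinucleotide slots; ``None`` marks a gap slot."""

    slots: list[int | None]

    def __post_init__(self) -> None:
        if not self.slots or self.slots[0] is None or self.slots[-1] is None:
            raise ValueError("first and last slots must be poses")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def pose_ids(self) -> list[int]:
        return [s for s in self.slots if s is not None]


@dataclass
class RNAComplexModel:
    """A threaded ssRNA model with its refinement diagnostics."""

    rna: Structure
    path: ChainPath
    anchor_residuals: np.ndarray
    clash_count: int = -1
    converged: bool = True
    energy: float = 0.0


# ---------------------------------------------------------------------------
# dinucleotide template

#: ideal single-stranded helix parameters (configurable in thread_rna)
HELIX_RISE = 5.9
HELIX_TWIST_DEG = 32.7
HELIX_RADIUS = 4.0


def _helix_coords(n_nt: int, rise: float = HELIX_RISE, twist_deg: float = HELIX_TWIST_DEG,
                  radius: float = HELIX_RADIUS) -> np.ndarray:
    """(3*n_nt, 3) bead coordinates (P, C4', base per nucleotide) of an ideal
    helicoidal single strand along z."""
    out = []
    for i in range(n_nt):
        ang = np.deg2rad(twist_deg) * i
        z = rise * i
        c, s = np.cos(ang), np.sin(ang)
        out.append([(radius + 2.0) * c, (radius + 2.0) * s, z - 1.0])  # P
        out.append([radius * c, radius * s, z])  # C4'
        out.append([(radius - 3.0) * c, (radius - 3.0) * s, z + 0.5])  # base
    return np.array(out)


def make_gu_dinucleotide() -> Structure:
    """Rigid GU dinucleotide template.

    Three beads per nucleotide (P, C4', base centroid) plus a second base
    bead on the guanine: purines carry two rings, which makes the template
    directional — a reversed placement presents the bulky end where the
    pyrimidine sat.
    """
    xyz = _helix_coords(2)
    names = ["P", "C4'", "BAS"]
    resnames = ["G", "U"]
    beads = [
        Bead("L", i // 3 + 1, resnames[i // 3], names[i % 3], *xyz[i], 1.0)
        for i in range(6)
    ]
    # second ring of the guanine: further inward from the base centroid
    g_c4, g_bas = xyz[1], xyz[2]
    ext = g_bas + (g_bas - g_c4) * 0.8
    beads.append(Bead("L", 1, "G", "BA2", *ext, 1.0))
    return Structure(beads, metadata="GU dinucleotide template")


def _c4_indices(ligand: Structure) -> tuple[int, int]:
    idx = [i for i, b in enumerate(ligand.beads) if b.name == "C4'"]
    if len(idx) < 2:
        raise ValueError("ligand must expose C4' beads on both nucleotides")
    return idx[0], idx[-1]


# ---------------------------------------------------------------------------
# FFT shape-complementarity docking

SURFACE_SCORE = 1.0
CORE_PENALTY = -15.0


def dock_dinucleotide(
    receptor: Structure,
    dinucleotide: Structure | None = None,
    grid_spacing: float = 2.0,
    n_rotations: int = 24,
    top_k: int = 100,
    bead_radius: float = 2.0,
    contact_radius: float = 3.0,
    seed: int = 0,
    rotations: list[np.ndarray] | None = None,
    per_rotation: int | None = None,
    min_separation: float | None = None,
) -> list[DockPose]:
    """Rigid-body docking by grid correlation.

    The receptor is discretized onto a cubic grid: surface cells score +1 and
    buried core cells -15; the ligand occupies cells at +1. For each sampled
    rotation the correlation over all translations is computed by FFT; the
    ``top_k`` clash-free placements (no ligand cell on a core cell) by score
    are returned.
    """
    ligand = dinucleotide if dinucleotide is not None else make_gu_dinucleotide()
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("receptor and ligand must be non-empty")
    h = grid_spacing
    rxyz = receptor.coords
    pad = bead_radius + 1.0
    origin = rxyz.min(axis=0) - pad
    extent = rxyz.max(axis=0) + pad - origin
    shape = np.ceil(extent / h).astype(int) + 1
    lig_extent = np.ptp(ligand.coords, axis=0).max()
    if lig_extent >= extent.min():
        raise ValueError("ligand larger than the receptor grid")

    occ = np.zeros(shape, dtype=bool)
    idx = np.round((rxyz - origin) / h).astype(int)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    r_cells = max(1, int(round(bead_radius / h)))
    ball = _ball(r_cells)
    occ = ndimage.binary_dilation(occ, structure=ball)
    core = ndimage.binary_erosion(occ)
    surface = (occ & ~core).astype(float)

    lxyz0 = ligand.coords
    lig_center = lxyz0.mean(axis=0)
    i5, i3 = _c4_indices(ligand)
    if rotations is not None:
        rots = [np.asarray(r, dtype=float) for r in rotations]
    else:
        rots = [np.eye(3)] + list(
            Rotation.random(max(n_rotations - 1, 0), random_state=seed).as_matrix()
        )
    candidates: list[tuple[float, int, tuple[int, int, int]]] = []
    lig_grids = []
    for ri, rot in enumerate(rots):
        lxyz = (lxyz0 - lig_center) @ rot.T
        lpad = h * (max(r_cells, int(round(contact_radius / h))) + 1)
        lorigin = lxyz.min(axis=0) - lpad
        lshape = np.ceil((lxyz.max(axis=0) - lorigin + lpad) / h).astype(int) + 1
        lgrid = np.zeros(lshape)
        lidx = np.round((lxyz - lorigin) / h).astype(int)
        lgrid[lidx[:, 0], lidx[:, 1], lidx[:, 2]] = 1.0
        # contact footprint: the ligand cells grown to contact range, so the
        # score counts receptor-surface cells within touching distance —
        # placements wrapped by a pocket reach more surface than flat ones
        c_cells = max(1, int(round(contact_radius / h)))
        lcontact = ndimage.binary_dilation(lgrid > 0, structure=_ball(c_cells)).astype(float)
        lig_grids.append((lorigin, lgrid))
        flipped = lcontact[::-1, ::-1, ::-1]
        corr = SURFACE_SCORE * fftconvolve(surface, flipped, mode="full")
        core_overlap = fftconvolve(core.astype(float), lgrid[::-1, ::-1, ::-1], mode="full")
        corr[core_overlap > 0.5] = -np.inf
        n_keep = min(per_rotation or top_k, corr.size)
        if min_separation is None:
            flat = np.argpartition(corr.ravel(), -n_keep)[-n_keep:]
        else:
            # non-maximum suppression: greedily pick translation peaks at
            # least min_separation apart, so one deep site cannot soak up
            # the whole per-rotation quota
            sep_cells = max(1, int(round(min_separation / h)))
            n_pool = min(corr.size, 50 * n_keep)
            pool = np.argpartition(corr.ravel(), -n_pool)[-n_pool:]
            pool = pool[np.argsort(corr.ravel()[pool])[::-1]]
            taken: list[np.ndarray] = []
            flat = []
            for f in pool:
                t = np.array(np.unravel_index(f, corr.shape))
                if not np.isfinite(corr.ravel()[f]):
                    continue
                if taken and (np.abs(np.array(taken) - t).max(axis=1) < sep_cells).any():
                    continue
                taken.append(t)
                flat.append(f)
                if len(flat) >= n_keep:
                    break
        for f in flat:
            t = np.unravel_index(f, corr.shape)
            sc = corr[t]
            if np.isfinite(sc):
                candidates.append((float(sc), ri, tuple(int(x) - (lgrid.shape[d] - 1)
                                                        for d, x in enumerate(t))))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    poses: list[DockPose] = []
    for pid, (sc, ri, t) in enumerate(candidates[:top_k]):
        rot = rots[ri]
        lorigin, _ = lig_grids[ri]
        delta = origin + np.array(t) * h - lorigin
        coords = (lxyz0 - lig_center) @ rot.T + delta
        translation = coords[0] - rot @ lxyz0[0]
        poses.append(
            DockPose(pid, rot, translation, sc, coords, coords[i5], coords[i3])
        )
    logger.info("dock_dinucleotide: %d poses from %d rotations", len(poses), len(rots))
    return poses


def _ball(r: int) -> np.ndarray:
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


# ---------------------------------------------------------------------------
# pose filtering / clustering

def _site_coords(receptor: Structure, site: BindingSite) -> np.ndarray:
    wanted = set(site.residues)
    xyz = np.array(
        [[b.x, b.y, b.z] for b in receptor.beads if (b.chain, b.resnum) in wanted]
    )
    if xyz.size == 0:
        raise ValueError("no binding-site residues found in receptor")
    return xyz


def binding_site_filter(
    poses: list[DockPose], receptor: Structure, site: BindingSite
) -> list[DockPose]:
    """Keep poses whose minimum bead distance to any site residue is within
    the site cutoff (default 5 A)."""
    sxyz = _site_coords(receptor, site)
    kept = [p for p in poses if cdist(p.coords, sxyz).min() <= site.cutoff]
    logger.info("binding_site_filter: kept %d / %d", len(kept), len(poses))
    return kept


def cluster_poses(poses: list[DockPose], cutoff: float = 10.0) -> list[DockPose]:
    """Single-linkage clustering on the maximum corresponding-bead distance;
    the best-scoring pose of each cluster is its representative (ties broken
    by lowest pose id)."""
    if not poses:
        raise ValueError("no poses to cluster")
    if len(poses) == 1:
        return list(poses)
    n = len(poses)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(poses[i].coords - poses[j].coords, axis=1).max()
            dm[i, j] = dm[j, i] = d
    cond = dm[np.triu_indices(n, k=1)]
    labels = fcluster(linkage(cond, method="single"), t=cutoff, criterion="distance")
    reps: list[DockPose] = []
    for lab in np.unique(labels):
        members = [p for p, l in zip(poses, labels) if l == lab]
        reps.append(max(members, key=lambda p: (p.score, -p.pose_id)))
    reps.sort(key=lambda p: p.pose_id)
    return reps


# ---------------------------------------------------------------------------
# graph chaining

def enumerate_chains(
    poses: list[DockPose],
    d_min: float = 4.5,
    d_max: float = 8.0,
    gap_max: int = 1,
    max_len: int = 12,
    max_paths: int | None = 500_000,
) -> list[ChainPath]:
    """All simple pose chains of up to ``max_len`` slots, allowing gaps.

    A directed edge i -> j with gap count g (0 <= g <= gap_max) exists when
    the 3' anchor of i and the 5' anchor of j are separated by a distance in
    [d_min*(g+1), d_max*(g+1)]; a path's slot count is its poses plus its
    gaps. Single-pose paths are included.
    """
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    if max_len < 1 or gap_max < 0:
        raise ValueError("max_len >= 1 and gap_max >= 0 required")
    edges: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(poses))}
    for i, pi in enumerate(poses):
        for j, pj in enumerate(poses):
            if i == j:
                continue
            d = float(np.linalg.norm(pj.anchor5 - pi.anchor3))
            for g in range(gap_max + 1):
                if d_min * (g + 1) <= d <= d_max * (g + 1):
                    edges[i].append((j, g))
    paths: list[ChainPath] = []

    class _Full(Exception):
        pass

    def dfs(node: int, slots: list[int | None], used: set[int]) -> None:
        paths.append(ChainPath([poses[s].pose_id if s is not None else None for s in slots]))
        if max_paths is not None and len(paths) >= max_paths:
            raise _Full
        for nxt, g in edges[node]:
            if nxt in used:
                continue
            extra = g + 1
            if len(slots) + extra > max_len:
                continue
            dfs(nxt, slots + [None] * g + [nxt], used | {nxt})

    try:
        for start in range(len(poses)):
            dfs(start, [start], {start})
    except _Full:
        logger.warning("enumerate_chains: truncated at %d paths", max_paths)
    logger.info("enumerate_chains: %d paths from %d poses", len(paths), len(poses))
    return paths


def chain_identity(a: ChainPath, b: ChainPath) -> float:
    """Fraction of shared poses over the longer path's slot count.

    Two combinations count as identical in a pose when both use it, wherever
    it sits; e.g. two 12-slot paths sharing 9 poses are 75% identical.
    """
    shared = len(set(a.pose_ids) & set(b.pose_ids))
    return shared / max(a.n_slots, b.n_slots)


def cluster_chains(paths: list[ChainPath], identity: float = 0.70) -> list[ChainPath]:
    """Greedy clustering of chain paths by slotwise identity.

    Paths are ranked by filled-slot count (ties by nothing further needed:
    deterministic input order); each path joins the first representative it
    is at least ``identity`` identical to, else founds a new cluster.
    """
    if not paths:
        raise ValueError("no paths to cluster")
    order = sorted(
        range(len(paths)),
        key=lambda i: (-len(paths[i].pose_ids), i),
    )
    reps: list[ChainPath] = []
    for i in order:
        p = paths[i]
        for r in reps:
            if chain_identity(p, r) >= identity:
                break
        else:
            reps.append(p)
    return reps


# ---------------------------------------------------------------------------
# threading and refinement

def thread_rna(
    path: ChainPath,
    poses: dict[int, DockPose] | list[DockPose],
    sequence: str = "GU" * 12,
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST_DEG,
    bond_k: float = 10.0,
    angle_k: float = 2.0,
    anchor_k: float = 20.0,
    max_iter: int = 500,
) -> RNAComplexModel:
    """Thread a helicoidal ssRNA through the chained dinucleotide anchors.

    An ideal single-stranded helix (3 beads per nucleotide) is rigidly
    superposed onto the anchor C4' positions, then relaxed by quasi-Newton
    (L-BFGS) minimization of a harmonic energy: bond terms (successive
    backbone and intra-nucleotide distances at their ideal-helix values),
    1-3 angle-surrogate terms on the C4' trace, and anchor restraints.
    """
    if isinstance(poses, list):
        poses = {p.pose_id: p for p in poses}
    sequence = sequence.upper()
    n_nt = len(sequence)
    if n_nt < 2 * len(path.pose_ids):
        raise ValueError("sequence shorter than 2 nucleotides per filled slot")
    template = _helix_coords(n_nt, rise, twist_deg)
    c4_idx = np.arange(n_nt) * 3 + 1

    # anchors: slot s (0-based) pins nucleotides 2s and 2s+1
    anchor_nt: list[int] = []
    anchor_pos: list[np.ndarray] = []
    for slot_i, slot in enumerate(path.slots):
        if slot is None:
            continue
        pose = poses[slot]
        anchor_nt.extend([2 * slot_i, 2 * slot_i + 1])
        anchor_pos.extend([pose.anchor5, pose.anchor3])
    if max(anchor_nt) >= n_nt:
        raise ValueError("path needs more nucleotides than the sequence provides")
    anchor_nt_arr = np.array(anchor_nt)
    anchor_pos_arr = np.array(anchor_pos)

    # rigid pre-placement onto the anchors (Kabsch)
    src = template[c4_idx[anchor_nt_arr]]
    rot, trans = _kabsch(src, anchor_pos_arr)
    x0 = template @ rot.T + trans

    # harmonic terms with ideal-helix equilibrium values
    bonds: list[tuple[int, int, float]] = []
    for i in range(n_nt):
        p, c4, bs = 3 * i, 3 * i + 1, 3 * i + 2
        bonds.append((p, c4, float(np.linalg.norm(template[p] - template[c4]))))
        bonds.append((c4, bs, float(np.linalg.norm(template[c4] - template[bs]))))
        if i + 1 < n_nt:
            c4n = 3 * (i + 1) + 1
            bonds.append((c4, c4n, float(np.linalg.norm(template[c4] - template[c4n]))))
    thirteens: list[tuple[int, int, float]] = []
    for i in range(n_nt - 2):
        a, b = 3 * i + 1, 3 * (i + 2) + 1
        thirteens.append((a, b, float(np.linalg.norm(template[a] - template[b]))))
    bi = np.array([b[0] for b in bonds] + [t[0] for t in thirteens])
    bj = np.array([b[1] for b in bonds] + [t[1] for t in thirteens])
    b0 = np.array([b[2] for b in bonds] + [t[2] for t in thirteens])
    bk = np.array([bond_k] * len(bonds) + [angle_k] * len(thirteens))
    anchor_bead = 3 * anchor_nt_arr + 1

    def energy_grad(flat: np.ndarray) -> tuple[float, np.ndarray]:
        x = flat.reshape(-1, 3)
        grad = np.zeros_like(x)
        diff = x[bi] - x[bj]
        d = np.linalg.norm(diff, axis=1)
        d = np.where(d > 1e-12, d, 1e-12)
        dev = d - b0
        e = float(np.sum(bk * dev**2))
        g = (2.0 * bk * dev / d)[:, None] * diff
        np.add.at(grad, bi, g)
        np.add.at(grad, bj, -g)
        adiff = x[anchor_bead] - anchor_pos_arr
        e += float(anchor_k * np.sum(adiff**2))
        np.add.at(grad, anchor_bead, 2.0 * anchor_k * adiff)
        return e, grad.ravel()

    res = minimize(
        energy_grad, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    xf = res.x.reshape(-1, 3)
    residuals = np.linalg.norm(xf[anchor_bead] - anchor_pos_arr, axis=1)
    names = ["P", "C4'", "BAS"]
    beads = [
        Bead("R", i // 3 + 1, sequence[i // 3], names[i % 3], *xf[i], 1.0)
        for i in range(3 * n_nt)
    ]
    converged = bool(res.success) or res.fun <= energy_grad(x0.ravel())[0] + 1e-9
    if not res.success:
        logger.warning("thread_rna: optimizer stopped early (%s)", res.message)
    return RNAComplexModel(
        Structure(beads, metadata="threaded ssRNA"),
        path,
        residuals,
        converged=converged,
        energy=float(res.fun),
    )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cd - rot @ cs


# ---------------------------------------------------------------------------
# clash filtering

def count_clashes(
    model: RNAComplexModel,
    receptor: Structure,
    clash_dist: float = 3.5,
    site: BindingSite | None = None,
) -> int:
    """Receptor-bead / RNA-bead pairs closer than ``clash_dist``.

    If a binding site is given, contacts of anchored nucleotides with beads
    of site residues are not counted (those contacts are the docking signal,
    not steric violations).
    """
    rxyz = receptor.coords
    mxyz = model.rna.coords
    close = cdist(rxyz, mxyz) < clash_dist
    if site is not None:
        wanted = set(site.residues)
        site_mask = np.array([(b.chain, b.resnum) in wanted for b in receptor.beads])
        anchored_nt = {2 * i for i, s in enumerate(model.path.slots) if s is not None}
        anchored_nt |= {nt + 1 for nt in anchored_nt}
        rna_mask = np.array([i // 3 in anchored_nt for i in range(mxyz.shape[0])])
        close[np.ix_(site_mask, rna_mask)] = False
    return int(close.sum())


def clash_filter(
    models: list[RNAComplexModel],
    receptor: Structure,
    clash_dist: float = 3.5,
    max_clashes: int = 150,
    site: BindingSite | None = None,
) -> list[RNAComplexModel]:
    """Keep models with at most ``max_clashes`` steric clashes."""
    kept = []
    for m in models:
        m.clash_count = count_clashes(m, receptor, clash_dist, site)
        if m.clash_count <= max_clashes:
            kept.append(m)
    logger.info("clash_filter: kept %d / %d", len(kept), len(models))
    return kept
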