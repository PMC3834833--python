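"""Elastic-network normal modes and conformer generation.

An anisotropic network model with uniform springs over Calpha-like beads
within a distance cutoff supplies low-frequency modes; three samplers
(exhaustive amplitude grid, Monte-Carlo Gaussian amplitudes, iterative
random-mode walk) displace the reference structure along those modes, and a
distortion filter removes conformers with too many broken consecutive-bead
pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .io_core import Structure

logger = logging.getLogger("translinflex")

__all__ = [
    "ModeSet",
    "ConformerRecord",
    "build_modes",
    "grid_sample",
    "mc_sample",
    "iterative_sample",
    "distortion_filter",
    "broken_pair_count",
]

#: number of rigid-body modes of a connected 3-D network
N_RIGID_MODES = 6

#: largest 3N for which the Hessian is diagonalized densely
DENSE_LIMIT = 1500


@dataclass
class ModeSet:
    """Low-frequency modes of the elastic network.

    ``eigenvectors`` has shape (3N, n_modes), columns unit-norm and mutually
    orthogonal; ``eigenvalues`` ascend. The displacement convention maps an
    amplitude A in arbitrary units to (A * r0 / 1000) * u, with ``r0`` a
    length scale in Angstrom, so A = 1000 moves the whole bead set by r0
    in the 3N-norm.
    """

    reference: Structure
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cutoff: float
    n_skipped: int = N_RIGID_MODES
    r0: float = 100.0
    rigid_eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(N_RIGID_MODES))

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def displacement(self, amplitudes: dict[int, float]) -> np.ndarray:
        """(N, 3) displacement for {mode index: amplitude} in arbitrary units."""
        delta = np.zeros(self.eigenvectors.shape[0])
        for mode, amp in amplitudes.items():
            delta += (amp * self.r0 / 1000.0) * self.eigenvectors[:, mode]
        return delta.reshape(-1, 3)

    def displace(self, amplitudes: dict[int, float]) -> Structure:
        return self.reference.with_coords(self.reference.coords + self.displacement(amplitudes))


@dataclass
class ConformerRecord:
    """One generated conformer with its generating recipe."""

    structure: Structure
    mode_amplitudes: dict[int, float]
    sampler: str
    conformer_id: int = 0


def build_modes(structure: Structure, cutoff: float = 12.0, n_modes: int = 5,
                r0: float = 100.0) -> ModeSet:
    """Diagonalize the uniform-spring anisotropic network Hessian.

    The six near-zero rigid-body modes are identified and skipped; the next
    ``n_modes`` non-trivial modes are returned. A network that is
    disconnected at the cutoff is rejected (it would carry more than six
    zero modes).
    """
    xyz = structure.coords
    n = xyz.shape[0]
    if n < 3:
        raise ValueError("need at least 3 beads for normal modes")
    dmat = squareform(pdist(xyz))
    adj = (dmat < cutoff) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} A: "
            f"{n_comp} components of sizes {sizes.tolist()} "
            f"({N_RIGID_MODES * n_comp} near-zero modes expected)"
        )
    ii, jj = np.nonzero(np.triu(adj, k=1))
    n_want = min(3 * n, N_RIGID_MODES + n_modes)
    if 3 * n <= DENSE_LIMIT:
        hess = np.zeros((3 * n, 3 * n))
        for i, j in zip(ii, jj):
            rij = xyz[j] - xyz[i]
            block = -np.outer(rij, rij) / (rij @ rij)
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
        vals, vecs = eigh(hess, subset_by_index=(0, n_want - 1))
    else:
        # large assemblies: sparse Hessian + shift-invert around zero
        from scipy.sparse import coo_matrix
        from scipy.sparse.linalg import eigsh

        rows, cols, data = [], [], []
        diag = np.zeros((n, 3, 3))
        for i, j in zip(ii, jj):
            rij = xyz[j] - xyz[i]
            block = -np.outer(rij, rij) / (rij @ rij)
            diag[i] -= block
            diag[j] -= block
            for a in range(3):
                for b in range(3):
                    rows += [3 * i + a, 3 * j + a]
                    cols += [3 * j + b, 3 * i + b]
                    data += [block[a, b], block[a, b]]
        for i in range(n):
            for a in range(3):
                for b in range(3):
                    rows.append(3 * i + a)
                    cols.append(3 * i + b)
                    data.append(diag[i, a, b])
        hess_sp = coo_matrix((data, (rows, cols)), shape=(3 * n, 3 * n)).tocsc()
        v0 = np.cos(np.arange(3 * n, dtype=float))  # deterministic Lanczos start
        vals, vecs = eigsh(hess_sp, k=n_want, sigma=-1e-4, which="LM", v0=v0)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    if vals[N_RIGID_MODES] <= 1e-8 * max(vals[-1], 1e-300):
        raise ValueError("more than 6 near-zero modes: network effectively disconnected")
    # sign convention: largest-magnitude component of each mode is positive
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    logger.info("build_modes: N=%d cutoff=%.1f lowest nontrivial eigenvalue %.3e",
                n, cutoff, vals[N_RIGID_MODES])
    return ModeSet(
        reference=structure,
        eigenvalues=vals[N_RIGID_MODES : N_RIGID_MODES + n_modes],
        eigenvectors=vecs[:, N_RIGID_MODES : N_RIGID_MODES + n_modes],
        cutoff=cutoff,
        r0=r0,
        rigid_eigenvalues=vals[:N_RIGID_MODES],
    )


def grid_sample(
    modes: ModeSet,
    single_step: float = 100.0,
    pair_step: float = 500.0,
    a_max: float = 2000.0,
) -> list[ConformerRecord]:
    """Exhaustive single-mode and mode-pair amplitude grid.

    Singles: every mode at each nonzero amplitude in [-a_max, a_max] with
    ``single_step``; pairs: every mode pair on the coarser ``pair_step``
    grid excluding the origin. With 5 modes and the defaults this yields
    5*40 + 10*(9^2 - 1) = 1000 conformers before filtering.
    """
    if single_step <= 0 or pair_step <= 0:
        raise ValueError("step sizes must be > 0")
    for step in (single_step, pair_step):
        if abs(a_max / step - round(a_max / step)) > 1e-9:
            raise ValueError("a_max must be divisible by both steps")
    records: list[ConformerRecord] = []
    cid = 0
    single_amps = [a for a in np.arange(-a_max, a_max + single_step / 2, single_step) if a != 0]
    for m in range(modes.n_modes):
        for a in single_amps:
            records.append(ConformerRecord(modes.displace({m: a}), {m: float(a)}, "grid", cid))
            cid += 1
    pair_amps = list(np.arange(-a_max, a_max + pair_step / 2, pair_step))
    for m1, m2 in itertools.combinations(range(modes.n_modes), 2):
        for a1 in pair_amps:
            for a2 in pair_amps:
                if a1 == 0 and a2 == 0:
                    continue
                amps = {m1: float(a1), m2: float(a2)}
                records.append(ConformerRecord(modes.displace(amps), amps, "grid", cid))
                cid += 1
    logger.info("grid_sample: %d conformers", len(records))
    return records


def mc_sample(modes: ModeSet, n: int, amp_sd: float = 700.0, seed: int = 0) -> list[ConformerRecord]:
    """Monte-Carlo sampler: independent Gaussian amplitudes on all modes."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if amp_sd <= 0:
        raise ValueError("amp_sd must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for cid in range(n):
        amps = {m: float(a) for m, a in enumerate(rng.normal(scale=amp_sd, size=modes.n_modes))}
        records.append(ConformerRecord(modes.displace(amps), amps, "mc", cid))
    return records


def iterative_sample(
    modes: ModeSet,
    n: int,
    n_steps: int = 10,
    step_amp: float = 400.0,
    seed: int = 0,
) -> list[ConformerRecord]:
    """Iterative sampler: a random walk in mode-amplitude space.

    Each conformer is the end state of ``n_steps`` iterations, each adding a
    displacement along one uniformly chosen mode with a uniform amplitude in
    [-step_amp, step_amp]. Displacements are linear in amplitude, so the end
    state is reproduced exactly by the accumulated per-mode amplitudes that
    the record stores.
    """
    if n <= 0 or n_steps <= 0:
        raise ValueError("n and n_steps must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for cid in range(n):
        acc = np.zeros(modes.n_modes)
        for _ in range(n_steps):
            m = int(rng.integers(modes.n_modes))
            acc[m] += rng.uniform(-step_amp, step_amp)
        amps = {m: float(a) for m, a in enumerate(acc) if a != 0.0}
        records.append(ConformerRecord(modes.displace(amps), amps, "iterative", cid))
    return records


def broken_pair_count(structure: Structure, d_break: float = 5.0) -> int:
    """Within-chain consecutive-bead pairs farther apart than ``d_break`` A."""
    count = 0
    for chain in structure.chains:
        cb = structure.chain_beads(chain)
        xyz = np.array([[b.x, b.y, b.z] for b in cb])
        if len(cb) > 1:
            count += int(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1) > d_break))
    return count


def distortion_filter(
    conformers: list[ConformerRecord],
    max_bad: int = 200,
    d_break: float = 5.0,
) -> list[ConformerRecord]:
    """Drop highly distorted conformers.

    Keeps conformers with at most ``max_bad`` within-chain consecutive-bead
    pairs stretched beyond ``d_break`` A; inter-chain gaps never count.
    """
    kept = [c for c in conformers if broken_pair_count(c.structure, d_break) <= max_bad]
    logger.info("distortion_filter: kept %d / %d", len(kept), len(conformers))
    return kept
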