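"""Terminal-tail ensembles and tail-averaged theoretical curves.

Every structural model that is compared with data carries disordered
N-terminal (His-tag, 12 residues) and C-terminal (11 residues) tails per
subunit; their conformational averaging is emulated by attaching several
random tail conformers and averaging the resulting Debye profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import ScatteringCurve, Structure
from . import saxs, synthetic

logger = logging.getLogger("translinflex")

__all__ = ["TailEnsemble", "make_tail_ensemble", "averaged_profile"]

#: minimum tail-to-core bead separation (A) accepted without resampling
CLASH_DISTANCE = 3.0


@dataclass
class TailEnsemble:
    """A base structure and its tail-conformer members (cores identical)."""

    base: Structure
    members: list[Structure]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.members)


def make_tail_ensemble(
    structure: Structure,
    n: int = 10,
    n_term_len: int = 12,
    c_term_len: int = 11,
    seed: int = 0,
    max_retries: int = 100,
) -> TailEnsemble:
    """Attach ``n`` independent random tail conformers to a core structure.

    Each member is resampled (up to ``max_retries`` times) until every tail
    bead keeps at least 3.0 A from all core beads.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    core_xyz = structure.coords
    n_core = len(structure)
    first = {c: structure.chain_beads(c)[0].resnum for c in structure.chains}
    last = {c: structure.chain_beads(c)[-1].resnum for c in structure.chains}
    members: list[Structure] = []
    for i in range(n):
        for attempt in range(max_retries):
            try:
                (member,) = synthetic.add_terminal_tails(
                    structure, n_term_len, c_term_len, 1,
                    seed=1_000_003 * i + attempt + seed,
                )
            except RuntimeError:
                continue  # tangled walk: resample with the next seed
            tail_xyz = np.array(
                [
                    [b.x, b.y, b.z]
                    for b in member.beads
                    if b.resnum < first[b.chain] or b.resnum > last[b.chain]
                ]
            )
            if tail_xyz.size == 0 or cdist(tail_xyz, core_xyz).min() >= CLASH_DISTANCE:
                members.append(member)
                break
        else:
            raise RuntimeError(f"member {i}: persistent tail/core clash after {max_retries} tries")
    logger.info("make_tail_ensemble: %d members, %d core beads", n, n_core)
    return TailEnsemble(structure, members, seed)


def averaged_profile(ensemble: TailEnsemble, s_grid: np.ndarray) -> ScatteringCurve:
    """Pointwise arithmetic mean of the members' Debye profiles."""
    if not ensemble.members:
        raise ValueError("empty tail ensemble")
    total = np.zeros(np.asarray(s_grid).shape, dtype=float)
    for member in ensemble.members:
        total += saxs.debye_profile(member, s_grid).intensity
    return ScatteringCurve(
        np.asarray(s_grid, dtype=float),
        total / len(ensemble.members),
        np.zeros_like(total),
        label="tail-averaged profile",
    )
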