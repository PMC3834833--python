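"""Ensemble selection against a SAXS curve.

Three layers: exact non-negative least-squares weight fitting on a fixed
conformer subset; a minimal-ensemble search (genetic algorithm over subsets
of up to 5 states, smallest ensemble within 5% of the best fit); and a
large-ensemble search in the EOM spirit (fixed-size multisets of up to 50
states with repetition, several independent runs, populations read off as
occurrence frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io_core import ScatteringCurve
from .saxs import CHI_WINDOW

logger = logging.getLogger("translinflex")

__all__ = [
    "CurveLibrary",
    "EnsembleFit",
    "GAConfig",
    "fit_weights",
    "mes_search",
    "eom_search",
    "classify_states",
]


@dataclass
class CurveLibrary:
    """Theoretical curves of candidate conformers on one common s grid."""

    ids: list[str]
    s: np.ndarray
    intensities: np.ndarray  # shape (n_curves, n_points)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape != (len(self.ids), self.s.size):
            raise ValueError("intensities must be (n_curves, n_points)")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: list[int]) -> "CurveLibrary":
        return CurveLibrary(
            [self.ids[i] for i in indices], self.s, self.intensities[list(indices)],
            self.provenance,
        )

    @classmethod
    def from_curves(cls, ids: list[str], curves: list[ScatteringCurve],
                    provenance: dict | None = None) -> "CurveLibrary":
        s = curves[0].s
        for c in curves[1:]:
            if c.s.shape != s.shape or not np.allclose(c.s, s):
                raise ValueError("all library curves must share the s grid")
        return cls(list(ids), s, np.vstack([c.intensity for c in curves]),
                   provenance or {})


@dataclass
class EnsembleFit:
    """Selected conformers with normalized weights and goodness of fit."""

    ids: list[str]
    weights: np.ndarray
    chi: float
    method: str
    scale: float = 1.0
    seed: int | None = None
    per_k_chi: dict[int, float] = field(default_factory=dict)
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm knobs shared by the MES- and EOM-style searches."""

    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.05
    elitism: int = 1
    tournament: int = 3

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def _prepare(exp: ScatteringCurve, library: CurveLibrary,
             window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate library curves onto the experimental grid in the window,
    returning (A rows = model curves / sigma, b = I_exp / sigma, mask)."""
    m = (exp.s >= window[0]) & (exp.s <= window[1])
    if m.sum() < 3:
        raise ValueError(f"fewer than 3 experimental points in window {window}")
    s, ie = exp.s[m], exp.intensity[m]
    sig = exp.sigma[m]
    sig = np.where(sig > 0, sig, 0.01 * np.abs(ie) + 1e-12)
    rows = np.vstack([np.interp(s, library.s, inten) for inten in library.intensities])
    return rows / sig, ie / sig, rows


def fit_weights(
    exp: ScatteringCurve,
    library: CurveLibrary,
    window: tuple[float, float] = CHI_WINDOW,
) -> EnsembleFit:
    """Exact non-negative weight fit of a conformer set to the data.

    Solves min_w>=0 || (I_exp - sum_j w_j I_j) / sigma ||; the overall scale
    c = sum w is absorbed so the reported weights sum to 1, and
    chi = sqrt(residual^2 / (N - 1)).
    """
    if len(library) < 1:
        raise ValueError("need at least one curve")
    if not np.any(np.abs(library.intensities) > 0):
        raise ValueError("all library curves are zero")
    a, b, _ = _prepare(exp, library, window)
    w, rnorm = nnls(a.T, b)
    c = w.sum()
    if c <= 0:
        raise ValueError("NNLS returned an all-zero weight vector")
    chi = float(np.sqrt(rnorm**2 / max(b.size - 1, 1)))
    return EnsembleFit(list(library.ids), w / c, chi, "nnls", scale=float(c))


def _subset_chi(a: np.ndarray, b: np.ndarray, idx: tuple[int, ...]) -> float:
    w, rnorm = nnls(a[list(idx)].T, b)
    if w.sum() <= 0:
        return np.inf
    return float(np.sqrt(rnorm**2 / max(b.size - 1, 1)))


def mes_search(
    exp: ScatteringCurve,
    library: CurveLibrary,
    max_states: int = 5,
    ga: GAConfig | None = None,
    seed: int = 0,
    window: tuple[float, float] = CHI_WINDOW,
    parsimony_tol: float = 0.05,
) -> EnsembleFit:
    """Minimal-ensemble search over conformer subsets of size 1..max_states.

    For each ensemble size K a genetic algorithm evolves id subsets
    (fitness = chi after the exact weight fit); the reported ensemble is the
    smallest K whose best chi is within ``parsimony_tol`` of the best chi
    over all K.
    """
    ga = ga or GAConfig()
    if len(library) < max_states:
        raise ValueError("library smaller than max_states")
    a, b, _ = _prepare(exp, library, window)
    rng = np.random.default_rng(seed)
    n_lib = len(library)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(idx: tuple[int, ...]) -> float:
        key = tuple(sorted(set(idx)))
        if key not in cache:
            cache[key] = _subset_chi(a, b, key)
        return cache[key]

    best_per_k: dict[int, tuple[float, tuple[int, ...]]] = {}
    for k in range(1, max_states + 1):
        if k == 1:
            # exhaustive: single-state fits are cheap
            scores = [(fitness((i,)), (i,)) for i in range(n_lib)]
            best_per_k[1] = min(scores)
            continue
        pop = [tuple(rng.choice(n_lib, size=k, replace=False)) for _ in range(ga.population)]
        best = min(((fitness(p), p) for p in pop), key=lambda t: t[0])
        for _ in range(ga.generations):
            scored = sorted(((fitness(p), p) for p in pop), key=lambda t: t[0])
            if scored[0][0] < best[0]:
                best = scored[0]
            elite = [p for _, p in scored[: ga.elitism]]
            children: list[tuple[int, ...]] = list(elite)
            while len(children) < ga.population:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(len(pop), size=ga.tournament)
                    parents.append(min((scored[c] for c in contenders), key=lambda t: t[0])[1])
                genes = list(set(parents[0]) | set(parents[1]))
                child = list(rng.choice(genes, size=k, replace=False)) if len(genes) >= k else list(genes)
                while len(child) < k:
                    g = int(rng.integers(n_lib))
                    if g not in child:
                        child.append(g)
                for gi in range(k):
                    if rng.random() < ga.mutation_rate:
                        g = int(rng.integers(n_lib))
                        if g not in child:
                            child[gi] = g
                children.append(tuple(child))
            pop = children
        final_best = min(((fitness(p), p) for p in pop), key=lambda t: t[0])
        best_per_k[k] = min(best, final_best)
    best_chi = min(chi for chi, _ in best_per_k.values())
    for k in range(1, max_states + 1):
        chi_k, idx_k = best_per_k[k]
        if chi_k <= best_chi * (1 + parsimony_tol):
            break
    sub = library.subset(sorted(set(idx_k)))
    fit = fit_weights(exp, sub, window)
    return EnsembleFit(fit.ids, fit.weights, fit.chi, "mes", scale=fit.scale, seed=seed,
                       per_k_chi={k: v[0] for k, v in best_per_k.items()})


def eom_search(
    exp: ScatteringCurve,
    library: CurveLibrary,
    max_states: int = 50,
    runs: int = 5,
    ga: GAConfig | None = None,
    seed: int = 0,
    window: tuple[float, float] = CHI_WINDOW,
) -> EnsembleFit:
    """Large-ensemble search: fixed-size multisets with repetition.

    Each chromosome is a multiset of ``max_states`` conformer ids with
    uniform weights; fitness is chi of the multiset-average curve after an
    optimal overall scale. ``runs`` independent GAs are evolved; the best is
    reported, with selection frequencies aggregated over all runs.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if len(library) < 1:
        raise ValueError("library is empty")
    ga = ga or GAConfig()
    a, b, _ = _prepare(exp, library, window)
    n_lib = len(library)

    def fitness(counts: np.ndarray) -> float:
        model = counts @ a / max_states
        denom = model @ model
        if denom <= 0:
            return np.inf
        c = (b @ model) / denom
        resid = b - c * model
        return float(np.sqrt(resid @ resid / max(b.size - 1, 1)))

    def counts_of(chrom: np.ndarray) -> np.ndarray:
        return np.bincount(chrom, minlength=n_lib).astype(float)

    overall_best: tuple[float, np.ndarray] | None = None
    freq_accum = np.zeros(n_lib)
    for run in range(runs):
        rng = np.random.default_rng((seed, run))
        pop = [rng.integers(n_lib, size=max_states) for _ in range(ga.population)]
        best = min(((fitness(counts_of(p)), p) for p in pop), key=lambda t: t[0])
        for _ in range(ga.generations):
            scored = sorted(((fitness(counts_of(p)), p) for p in pop), key=lambda t: t[0])
            if scored[0][0] < best[0]:
                best = scored[0]
            children = [p for _, p in scored[: ga.elitism]]
            while len(children) < ga.population:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(len(pop), size=ga.tournament)
                    parents.append(min((scored[c] for c in contenders), key=lambda t: t[0])[1])
                mask = rng.random(max_states) < 0.5
                child = np.where(mask, parents[0], parents[1]).copy()
                mut = rng.random(max_states) < ga.mutation_rate
                child[mut] = rng.integers(n_lib, size=int(mut.sum()))
                children.append(child)
            pop = children
        run_best = min(((fitness(counts_of(p)), p) for p in pop), key=lambda t: t[0])
        if run_best[0] < best[0]:
            best = run_best
        freq_accum += counts_of(best[1]) / max_states
        if overall_best is None or best[0] < overall_best[0]:
            overall_best = best
    chi, chrom = overall_best
    counts = counts_of(chrom)
    sel = np.nonzero(counts)[0]
    weights = counts[sel] / max_states
    model = counts @ a / max_states
    scale = float((b @ model) / (model @ model))
    freqs = freq_accum / runs
    return EnsembleFit(
        [library.ids[i] for i in sel], weights, chi, "eom", scale=scale, seed=seed,
        frequencies={library.ids[i]: float(freqs[i]) for i in np.nonzero(freqs)[0]},
    )


def classify_states(
    fit: EnsembleFit,
    manifest: dict[str, dict],
    rg_threshold: float | None = None,
) -> dict[str, float]:
    """Aggregate ensemble weights into compact/open state populations.

    ``manifest`` maps conformer id to a record carrying either an explicit
    ``class`` label or an ``rg`` value compared against ``rg_threshold``
    (below: compact, at or above: open).
    """
    pops = {"compact": 0.0, "open": 0.0}
    for cid, w in zip(fit.ids, fit.weights):
        if cid not in manifest:
            raise KeyError(f"conformer {cid!r} missing from manifest")
        rec = manifest[cid]
        if "class" in rec:
            label = rec["class"]
        elif "rg" in rec:
            if rg_threshold is None:
                raise ValueError("rg_threshold required when manifest has no class labels")
            label = "compact" if rec["rg"] < rg_threshold else "open"
        else:
            raise KeyError(f"manifest entry for {cid!r} has neither class nor rg")
        if label not in pops:
            raise ValueError(f"unknown state class {label!r}")
        pops[label] += float(w)
    return pops
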