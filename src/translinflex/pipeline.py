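"""End-to-end analyses: free assembly and assembly-RNA complex.

``run_free_analysis`` reproduces the free-state workflow on synthetic data:
generate (or load) a two-state experimental curve, sample conformers by
normal modes, filter distorted ones, attach tail ensembles, average
profiles, select ensembles by MES and EOM, and classify compact/open
populations. ``run_complex_analysis`` adds the dinucleotide-anchored ssRNA
docking over each receptor conformer and fits ensembles of complex models.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .io_core import Bead, ScatteringCurve, Structure
from . import docking, ensemble, nma, saxs, synthetic, tails

logger = logging.getLogger("translinflex")

__all__ = [
    "PipelineReport",
    "demo_free_config",
    "demo_complex_config",
    "run_free_analysis",
    "run_complex_analysis",
]


@dataclass
class PipelineReport:
    """Structured result of a pipeline run; serializes to YAML."""

    guinier: dict = field(default_factory=dict)
    pofr: dict = field(default_factory=dict)
    mass: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    populations: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def demo_free_config(seed: int = 0) -> dict:
    """Built-in synthetic two-state demo configuration."""
    return {
        "seed": seed,
        "assembly": {"beads_per_subunit": 160, "outer_radius": 45.0},
        "sampling": {
            "cutoff": 12.0,
            "n_modes": 5,
            "r0": 100.0,
            "single_step": 500.0,
            "pair_step": 1000.0,
            "a_max": 2000.0,
        },
        "filter": {"max_bad": 200, "d_break": 5.0},
        "mixture": {
            "compact_fraction": 0.18,
            "open_split": [45.8, 23.3, 13.3],
        },
        "noise": {"level": 0.01, "floor": 0.0},
        "tails": {"n": 2, "n_term_len": 12, "c_term_len": 11},
        "classify": {"rg_delta": 0.5},
        "fit": {
            "max_states": 5,
            "eom_states": 50,
            "eom_runs": 5,
            "ga": {"population": 40, "generations": 60, "mutation_rate": 0.05},
        },
    }


def demo_complex_config(seed: int = 0) -> dict:
    cfg = demo_free_config(seed)
    cfg.update(
        {
            "rna": {"sequence": "GU" * 12, "stoichiometry": "1:1.5"},
            "docking": {
                "grid_spacing": 2.5,
                "n_rotations": 12,
                "top_k": 120,
                "site_cutoff": 5.0,
                "pose_cluster_cutoff": 10.0,
                "d_min": 4.5,
                "d_max": 8.0,
                "gap_max": 1,
                "max_len": 12,
                "chain_identity": 0.70,
                "clash_dist": 3.5,
                "max_clashes": 150,
                "max_models": 24,
                "n_receptors": 4,
                "interior_only": False,
            },
        }
    )
    return cfg


def _tail_averaged_curve(structure: Structure, s_grid: np.ndarray,
                         tail_cfg: dict, seed: int) -> ScatteringCurve:
    n = tail_cfg.get("n", 10)
    if n <= 0:
        return saxs.debye_profile(structure, s_grid)
    ens = tails.make_tail_ensemble(
        structure, n=n,
        n_term_len=tail_cfg.get("n_term_len", 12),
        c_term_len=tail_cfg.get("c_term_len", 11),
        seed=seed,
    )
    return tails.averaged_profile(ens, s_grid)


def _sample_and_profile(config: dict):
    """Shared front half: assembly, modes, conformers, filtered library."""
    seed = int(config.get("seed", 0))
    asm_cfg = config.get("assembly", {})
    params = synthetic.AssemblyParams(
        beads_per_subunit=asm_cfg.get("beads_per_subunit", 160),
        outer_radius=asm_cfg.get("outer_radius", 45.0),
        seed=seed,
    )
    reference = synthetic.make_octamer(params)
    smp = config.get("sampling", {})
    modes = nma.build_modes(
        reference, cutoff=smp.get("cutoff", 12.0),
        n_modes=smp.get("n_modes", 5), r0=smp.get("r0", 100.0),
    )
    conformers = nma.grid_sample(
        modes,
        single_step=smp.get("single_step", 100.0),
        pair_step=smp.get("pair_step", 500.0),
        a_max=smp.get("a_max", 2000.0),
    )
    flt = config.get("filter", {})
    conformers = nma.distortion_filter(
        conformers, max_bad=flt.get("max_bad", 200), d_break=flt.get("d_break", 5.0)
    )
    return reference, modes, conformers


def _build_library(reference: Structure, conformers, config: dict):
    """Tail-averaged curves for the reference + every conformer."""
    seed = int(config.get("seed", 0))
    s_grid = synthetic.default_s_grid()
    tail_cfg = config.get("tails", {})
    ids = ["ref"] + [f"{c.sampler}-{c.conformer_id}" for c in conformers]
    structures = [reference] + [c.structure for c in conformers]
    curves = [
        _tail_averaged_curve(st, s_grid, tail_cfg, seed + 7919 * i)
        for i, st in enumerate(structures)
    ]
    manifest = {
        cid: {"rg": st.rg(), "dmax": _max_dist(st)}
        for cid, st in zip(ids, structures)
    }
    library = ensemble.CurveLibrary.from_curves(ids, curves, provenance={"n": len(ids)})
    return s_grid, ids, structures, curves, manifest, library


def _max_dist(structure: Structure) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(structure.coords).max())


def _generating_mixture(ids, structures, curves, manifest, config):
    """Pick the generating two-state mixture: the reference as the compact
    state and the three largest-Rg conformers as the open ensemble."""
    mix_cfg = config.get("mixture", {})
    compact_fraction = float(mix_cfg.get("compact_fraction", 0.18))
    split = np.array(mix_cfg.get("open_split", [45.8, 23.3, 13.3]), dtype=float)
    split = split / split.sum() * (1.0 - compact_fraction)
    order = sorted(range(1, len(ids)), key=lambda i: -manifest[ids[i]]["rg"])
    open_idx = order[: split.size]
    chosen = [(0, compact_fraction)] + list(zip(open_idx, split))
    return chosen


def _synthesize_experiment(chosen, curves, config, seed) -> ScatteringCurve:
    noise_cfg = config.get("noise", {})
    level = float(noise_cfg.get("level", 0.01))
    floor = float(noise_cfg.get("floor", 0.0))
    s = curves[0].s
    inten = np.zeros_like(s)
    for idx, w in chosen:
        inten = inten + w * curves[idx].intensity
    sigma = level * np.abs(inten) + floor
    rng = np.random.default_rng(seed)
    noisy = inten + rng.normal(scale=np.where(sigma > 0, sigma, 0.0))
    return ScatteringCurve(s, noisy, np.where(sigma > 0, sigma, 1e-12), "synthetic experiment")


def _fit_and_classify(exp_curve, library, manifest, rg_threshold, config, seed):
    fit_cfg = config.get("fit", {})
    ga = ensemble.GAConfig(
        population=fit_cfg.get("ga", {}).get("population", 100),
        generations=fit_cfg.get("ga", {}).get("generations", 200),
        mutation_rate=fit_cfg.get("ga", {}).get("mutation_rate", 0.05),
    )
    mes = ensemble.mes_search(
        exp_curve, library, max_states=fit_cfg.get("max_states", 5), ga=ga, seed=seed
    )
    eom = ensemble.eom_search(
        exp_curve, library, max_states=fit_cfg.get("eom_states", 50),
        runs=fit_cfg.get("eom_runs", 5), ga=ga, seed=seed,
    )
    mes_pops = ensemble.classify_states(mes, manifest, rg_threshold)
    eom_pops = ensemble.classify_states(eom, manifest, rg_threshold)
    return mes, eom, mes_pops, eom_pops


def run_free_analysis(config: dict | None = None) -> PipelineReport:
    """Free-assembly workflow on a synthetic two-state equilibrium."""
    config = config or demo_free_config()
    seed = int(config.get("seed", 0))
    reference, modes, conformers = _sample_and_profile(config)
    s_grid, ids, structures, curves, manifest, library = _build_library(
        reference, conformers, config
    )
    chosen = _generating_mixture(ids, structures, curves, manifest, config)
    exp_curve = _synthesize_experiment(chosen, curves, config, seed)

    g = saxs.guinier_fit(exp_curve)
    d_max_model = max(manifest[ids[i]]["dmax"] for i, _ in chosen)
    pofr = saxs.pair_distribution_from_curve(exp_curve, d_max=d_max_model * 1.05)
    mass = saxs.porod_mass(exp_curve)
    rg_threshold = manifest["ref"]["rg"] + config.get("classify", {}).get("rg_delta", 2.0)
    mes, eom, mes_pops, eom_pops = _fit_and_classify(
        exp_curve, library, manifest, rg_threshold, config, seed
    )

    report = PipelineReport(
        guinier={"i0": g.i0, "rg": g.rg, "window": [g.s_min, g.s_max]},
        pofr={
            "d_max_model": d_max_model,
            "peak_r": float(pofr.r[np.argmax(pofr.p)]),
            "d_max_transform": pofr.d_max,
        },
        mass={
            "porod_volume_nm3": mass.porod_volume_nm3,
            "mass_kda": mass.mass_kda,
            "subunit_count": saxs.subunit_count(mass.mass_kda)
            if mass.mass_kda > 0 else None,
        },
        fits={
            "mes": {"ids": mes.ids, "weights": mes.weights.tolist(), "chi": mes.chi},
            "eom": {"ids": eom.ids, "weights": eom.weights.tolist(), "chi": eom.chi},
        },
        populations={
            "generating_compact": float(
                sum(w for i, w in _generating_mixture(ids, structures, curves, manifest, config)
                    if ids[i] == "ref")
            ),
            "mes": mes_pops,
            "eom": eom_pops,
        },
        provenance={
            "seed": seed,
            "n_conformers": len(conformers),
            "n_library": len(library),
            "rg_threshold": float(rg_threshold),
        },
    )
    return report


def _equatorial_site(receptor: Structure, n_per_chain: int = 3,
                     cutoff: float = 5.0) -> docking.BindingSite:
    """Site residues: the beads nearest the equatorial plane of each chain
    (the synthetic analogue of the nucleic-acid-binding equatorial region)."""
    residues: list[tuple[str, int]] = []
    for chain in receptor.chains:
        cb = receptor.chain_beads(chain)
        ranked = sorted(cb, key=lambda b: abs(b.z))
        residues.extend((chain, b.resnum) for b in ranked[:n_per_chain])
    return docking.BindingSite(tuple(sorted(set(residues))), cutoff=cutoff)


def run_complex_analysis(config: dict | None = None) -> PipelineReport:
    """Assembly-RNA workflow: dock, chain, thread and fit complex ensembles."""
    config = config or demo_complex_config()
    seed = int(config.get("seed", 0))
    dk = config.get("docking", {})
    rna_cfg = config.get("rna", {})
    sequence = rna_cfg.get("sequence", "GU" * 12)

    reference, modes, conformers = _sample_and_profile(config)
    s_grid, ids, structures, curves, manifest, library = _build_library(
        reference, conformers, config
    )
    chosen = _generating_mixture(ids, structures, curves, manifest, config)
    # receptors: the generating conformers (compact reference + top opens)
    receptor_idx = [i for i, _ in chosen][: dk.get("n_receptors", 2)]

    complex_structs: list[Structure] = []
    complex_ids: list[str] = []
    complex_manifest: dict[str, dict] = {}
    n_surviving = 0
    for ri in receptor_idx:
        receptor = structures[ri]
        site = _equatorial_site(receptor, cutoff=dk.get("site_cutoff", 5.0))
        poses = docking.dock_dinucleotide(
            receptor,
            grid_spacing=dk.get("grid_spacing", 2.5),
            n_rotations=dk.get("n_rotations", 12),
            top_k=dk.get("top_k", 120),
            seed=seed,
        )
        poses = docking.binding_site_filter(poses, receptor, site)
        if dk.get("interior_only", False):
            # the nucleic acid binds inside the hollow cavity: keep poses on
            # the interior face of the shell
            center = receptor.coords.mean(axis=0)
            r_shell = float(np.median(np.linalg.norm(receptor.coords - center, axis=1)))
            poses = [
                p for p in poses
                if np.linalg.norm(p.coords.mean(axis=0) - center) < r_shell - 2.0
            ]
        if not poses:
            continue
        poses = docking.cluster_poses(poses, cutoff=dk.get("pose_cluster_cutoff", 10.0))
        paths = docking.enumerate_chains(
            poses,
            d_min=dk.get("d_min", 4.5),
            d_max=dk.get("d_max", 8.0),
            gap_max=dk.get("gap_max", 1),
            max_len=dk.get("max_len", 12),
        )
        paths = [p for p in paths if len(p.pose_ids) >= 1]
        paths = docking.cluster_chains(paths, identity=dk.get("chain_identity", 0.70))
        paths = paths[: dk.get("max_models", 24)]
        # thread as much of the sequence as the anchor path spans, so the
        # modelled RNA stays within the cavity rather than dangling outside
        models = [
            docking.thread_rna(
                p, poses,
                sequence=sequence[: max(2 * p.n_slots, 4)]
                if dk.get("truncate_to_path", True) else sequence,
            )
            for p in paths
        ]
        models = docking.clash_filter(
            models, receptor,
            clash_dist=dk.get("clash_dist", 3.5),
            max_clashes=dk.get("max_clashes", 150),
            site=site,
        )
        n_surviving += len(models)
        for mi, model in enumerate(models):
            combined = Structure(
                list(receptor.beads) + list(model.rna.beads),
                metadata=f"complex receptor={ids[ri]} model={mi}",
            )
            cid = f"cplx-{ids[ri]}-{mi}"
            complex_ids.append(cid)
            complex_structs.append(combined)
            complex_manifest[cid] = {
                "rg": manifest[ids[ri]]["rg"],
                "dmax": _max_dist(combined),
                "receptor": ids[ri],
                "clashes": model.clash_count,
            }
    if not complex_structs:
        raise RuntimeError("complex stage: no threaded model survived the clash filter")

    tail_cfg = config.get("tails", {})
    complex_curves = [
        _tail_averaged_curve(st, s_grid, tail_cfg, seed + 104729 + 7919 * i)
        for i, st in enumerate(complex_structs)
    ]
    complex_library = ensemble.CurveLibrary.from_curves(complex_ids, complex_curves)

    # synthetic complex experiment: compact-receptor complex vs open ones
    compact_ids = [c for c in complex_ids if "-ref-" in c]
    open_ids = [c for c in complex_ids if "-ref-" not in c]
    mix_cfg = config.get("mixture", {})
    cf = float(mix_cfg.get("compact_fraction", 0.18))
    gen: list[tuple[int, float]] = []
    if compact_ids and open_ids:
        gen.append((complex_ids.index(compact_ids[0]), cf))
        w_open = (1.0 - cf) / min(len(open_ids), 3)
        gen.extend((complex_ids.index(o), w_open) for o in open_ids[:3])
        total = sum(w for _, w in gen)
        gen = [(i, w / total) for i, w in gen]
    else:
        gen = [(i, 1.0 / len(complex_ids)) for i in range(len(complex_ids))]
    exp_curve = _synthesize_experiment(gen, complex_curves, config, seed + 1)

    g = saxs.guinier_fit(exp_curve)
    rg_threshold = manifest["ref"]["rg"] + config.get("classify", {}).get("rg_delta", 2.0)
    fit_cfg = config.get("fit", {})
    ga = ensemble.GAConfig(
        population=fit_cfg.get("ga", {}).get("population", 100),
        generations=fit_cfg.get("ga", {}).get("generations", 200),
        mutation_rate=fit_cfg.get("ga", {}).get("mutation_rate", 0.05),
    )
    max_states = min(fit_cfg.get("max_states", 5), len(complex_library))
    mes = ensemble.mes_search(exp_curve, complex_library, max_states=max_states,
                              ga=ga, seed=seed)
    mes_pops = ensemble.classify_states(mes, complex_manifest, rg_threshold)
    d_max_complex = max(complex_manifest[c]["dmax"] for c in complex_ids)

    report = PipelineReport(
        guinier={"i0": g.i0, "rg": g.rg, "window": [g.s_min, g.s_max]},
        pofr={"d_max_model": d_max_complex},
        fits={"mes": {"ids": mes.ids, "weights": mes.weights.tolist(), "chi": mes.chi}},
        populations={"mes": mes_pops},
        provenance={
            "seed": seed,
            "n_receptors": len(receptor_idx),
            "n_complex_models": len(complex_structs),
            "n_surviving_models": n_surviving,
        },
        extras={
            "stoichiometry": rna_cfg.get("stoichiometry", "1:1.5"),
            "sequence": sequence,
        },
    )
    return report
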