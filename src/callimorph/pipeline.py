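"""End-to-end analysis pipeline.

Runs the full study workflow on one bone dataset: (optional) curve
resampling, surface patching, bending-energy sliding, Procrustes
superimposition, species mean forms, size statistics, phylogenetic signal,
MANCOVA on retained PCs, between-group PCA with typicality reclassification
and a permutation test, phylomorphospace, ridge-regression rates with clade
shift search, and ancestral-state reconstruction of the locomotor character.

Every stochastic stage draws its seed deterministically from the config
seed, so a rerun with the same config produces a bit-identical report
bundle.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .ancestral import asr_parsimony, simmap_er
from .comparative import blomberg_k, k_mult, mancova_pillai, retain_pcs, size_comparison
from .landmarks import LandmarkConfiguration, centroid_size, read_landmark_csv
from .ordination import (
    between_group_pca,
    bgpca_classify,
    pca,
    permutation_group_distance,
    phylomorphospace,
)
from .procrustes import gpa, species_means
from .rates import rr_rates, search_shift_clades
from .semilandmarks import place_patch, relax_to_consensus, resample_curve
from .synthetic import SyntheticDataset
from .trees import PhyloTree, read_trait_csv

log = logging.getLogger("callimorph.pipeline")

_STAGES = (
    "resample",
    "patch",
    "slide",
    "gpa",
    "species_means",
    "size_stats",
    "signal",
    "mancova",
    "bgpca",
    "phylomorphospace",
    "rates",
    "shifts",
    "asr",
)


@dataclass
class PipelineConfig:
    """Paths, stage toggles and analysis parameters.

    Defaults are the study's stated settings: three sliding iterations, PCs
    retained at 95% cumulative variance, 10,000 permutations, 1000 Brownian
    simulations, and clade shift candidates between 2 tips and half the tree.
    """

    out_dir: str | Path = "pipeline_out"
    landmarks: str | Path | None = None
    meshes_dir: str | Path | None = None
    tree: str | Path | None = None
    traits: str | Path | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in _STAGES})
    resample_counts: dict[str, int] | None = None
    slide_iterations: int = 3
    pc_variance_threshold: float = 0.95
    n_perm: int = 10000
    n_sim: int = 1000
    simmap_nsim: int = 1000
    clade_min_tips: int = 2
    seed: int = 0

    def echo(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for key in ("landmarks", "meshes_dir", "tree", "traits"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("version", None)
        cfg = cls(**raw)
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str], index: bool = True) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=index, float_format="%.10g")
    path.write_text(buf.getvalue())


class StageError(RuntimeError):
    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed on input {digest}: {cause}")
        self.stage = stage


def run(config: PipelineConfig, dataset: SyntheticDataset | None = None) -> dict:
    """Execute the pipeline; returns the report bundle as a dict and writes it
    to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s:%(name)s:%(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run_inner(config, dataset, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_inner(config: PipelineConfig, dataset: SyntheticDataset | None, out: Path) -> dict:
    stages = {s: config.stages.get(s, True) for s in _STAGES}
    echo = [f"callimorph {__version__}"] + [f"{k}={v}" for k, v in sorted(config.echo().items()) if k != "stages"]
    report: dict = {"config": config.echo()}
    skipped: list[str] = []

    def on(stage: str, *needs: str) -> bool:
        if not stages[stage]:
            log.warning("stage %s toggled off; downstream results use unprocessed input", stage)
            skipped.append(stage)
            return False
        for need in needs:
            if need in skipped:
                log.warning("stage %s runs although upstream %s was skipped", stage, need)
        return True

    # ------------------------------------------------------------------ load
    if dataset is not None:
        configs = list(dataset.configs)
        meshes = {c.specimen_id: dataset.meshes.get(c.specimen_id) for c in configs}
        tree = dataset.tree
        traits = dict(dataset.traits)
        atlas = dataset.atlas
        digest = f"synthetic(n={len(configs)})"
    else:
        if config.landmarks is None or config.tree is None or config.traits is None:
            raise ValueError("file-driven run needs landmarks, tree and traits paths")
        configs = read_landmark_csv(config.landmarks)
        meshes = {}
        if config.meshes_dir:
            for c in configs:
                p = Path(config.meshes_dir) / f"{c.specimen_id}.ply"
                meshes[c.specimen_id] = trimesh.load(str(p), process=False) if p.exists() else None
        else:
            meshes = {c.specimen_id: None for c in configs}
        tree = PhyloTree.read(config.tree)
        traits = read_trait_csv(config.traits)
        atlas = None
        digest = f"{config.landmarks}(n={len(configs)})"
    log.info("loaded %d specimens, %d tips", len(configs), tree.n_tips)

    try:
        # -------------------------------------------------------------- resample
        if on("resample") and config.resample_counts:
            new = []
            for c in configs:
                pts = c.points.copy()
                for cid, count in config.resample_counts.items():
                    idx = c.curve_indices(cid)
                    if len(idx) != count:
                        raise ValueError(
                            f"curve {cid!r} has {len(idx)} points; in-place resample must keep count"
                        )
                    pts[idx] = resample_curve(c.points[idx], count)
                new.append(c.with_points(pts))
            configs = new

        # -------------------------------------------------------------- patch
        if on("patch") and atlas is not None and any(m is not None for m in meshes.values()):
            configs = [
                place_patch(atlas, c, meshes[c.specimen_id]) if meshes[c.specimen_id] is not None else c
                for c in configs
            ]
            log.info("patched surface semilandmarks onto %d specimens", len(configs))

        # -------------------------------------------------------------- slide
        if on("slide", "patch"):
            mesh_list = [meshes[c.specimen_id] for c in configs]
            configs, trace = relax_to_consensus(
                configs, mesh_list, iterations=config.slide_iterations
            )
            trace.to_json(out / "sliding_trace.json")
            report["sliding_energy"] = trace.energies

        # -------------------------------------------------------------- gpa
        aligned = None
        if on("gpa", "slide"):
            aligned = gpa(configs)
            report["gpa"] = {"converged": aligned.converged, "iterations": aligned.iterations}

        # ------------------------------------------------------ species means
        means = species_means(configs)
        sp_ids = sorted(means)
        mean_arrays = [means[s].mean_form for s in sp_ids]
        sp_aligned = gpa(np.stack(mean_arrays))
        sp_flat = {s: sp_aligned.shapes[i].ravel() for i, s in enumerate(sp_ids)}
        log_cs = {s: float(np.log(means[s].mean_cs)) for s in sp_ids}
        if on("species_means"):
            df = pd.DataFrame(
                {
                    "species_id": sp_ids,
                    "mean_cs_mm": [means[s].mean_cs for s in sp_ids],
                    "log_cs": [log_cs[s] for s in sp_ids],
                    "n_specimens": [means[s].n_specimens for s in sp_ids],
                }
            ).set_index("species_id")
            _write_csv(df, out / "species_means.csv", echo)
            report["n_species"] = len(sp_ids)

        groups = {s: traits[s] for s in sp_ids}
        group_list = [groups[s] for s in sp_ids]

        # ---------------------------------------------------------- size stats
        if on("size_stats"):
            size_res = size_comparison(
                log_cs, groups, tree, n_sim=config.n_sim, seed=_stage_seed(config.seed, "size_stats")
            )
            report["size"] = size_res

        # -------------------------------------------------------------- signal
        if on("signal"):
            kres = blomberg_k(tree, log_cs, n_perm=config.n_perm, seed=_stage_seed(config.seed, "signal"))
            kmres = k_mult(tree, sp_flat, n_perm=config.n_perm, seed=_stage_seed(config.seed, "signal") + 1)
            report["signal"] = {
                "K_size": kres.statistic,
                "K_size_p": kres.p_value,
                "Kmult_shape": kmres.statistic,
                "Kmult_shape_p": kmres.p_value,
            }

        # ------------------------------------------------------------- mancova
        X = np.vstack([sp_flat[s] for s in sp_ids])
        retained = retain_pcs(X, config.pc_variance_threshold)
        scores = retained.scores
        max_q = max(1, len(sp_ids) - 5)
        if scores.shape[1] > max_q:
            log.warning("capping retained PCs at %d for MANCOVA df", max_q)
            scores = scores[:, :max_q]
        report["n_pcs_retained"] = int(scores.shape[1])
        sizes_arr = np.array([log_cs[s] for s in sp_ids])
        if on("mancova"):
            table = mancova_pillai(scores, sizes_arr, group_list)
            _write_csv(table.table, out / "mancova.csv", echo)
            report["mancova_p"] = {
                t: (None if np.isnan(table.table.loc[t, "p"]) else float(table.table.loc[t, "p"]))
                for t in ("size", "locomotion", "interaction")
            }

        # --------------------------------------------------------------- bgpca
        if on("bgpca"):
            bg = between_group_pca(scores, group_list, row_ids=sp_ids)
            _write_csv(
                bg.scores_frame().assign(group=group_list), out / "bgpca_scores.csv", echo
            )
            cls = bgpca_classify(scores, group_list, cross_validate=True, row_ids=sp_ids)
            cls.to_json(out / "classification.json")
            perm = permutation_group_distance(
                scores, group_list, n_perm=config.n_perm, seed=_stage_seed(config.seed, "bgpca")
            )
            report["bgpca"] = {
                "accuracy_percent": cls.accuracy,
                "permutation_distance": perm.observed,
                "permutation_p": perm.p_value,
            }

        # ---------------------------------------------- phylomorphospace
        if on("phylomorphospace"):
            ord_res = pca(X, row_ids=sp_ids)
            pm = phylomorphospace(tree, ord_res)
            node_rows = pd.DataFrame(
                {lab: v[:2] for lab, v in pm.node_scores.items()}, index=["axis1", "axis2"]
            ).T
            _write_csv(node_rows, out / "phylomorphospace_nodes.csv", echo)
            report["pc_variance"] = [float(v) for v in ord_res.variance_fraction[:4]]

        # --------------------------------------------------------------- rates
        shape_rates = size_rates = None
        if on("rates"):
            shape_rates = rr_rates(tree, {s: scores[i] for i, s in enumerate(sp_ids)})
            size_rates = rr_rates(tree, {s: np.array([log_cs[s]]) for s in sp_ids})
            report["rates"] = {
                "lambda_shape": shape_rates.lam,
                "lambda_size": size_rates.lam,
            }

        # -------------------------------------------------------------- shifts
        if on("shifts", "rates") and shape_rates is not None:
            seed_s = _stage_seed(config.seed, "shifts")
            rep_shape = search_shift_clades(
                tree, shape_rates, n_rand=config.n_sim, seed=seed_s, min_tips=config.clade_min_tips
            )
            rep_size = search_shift_clades(
                tree, size_rates, n_rand=config.n_sim, seed=seed_s + 1, min_tips=config.clade_min_tips
            )
            _write_csv(rep_shape.table, out / "rate_shifts_shape.csv", echo)
            _write_csv(rep_size.table, out / "rate_shifts_size.csv", echo)
            report["shifts"] = {
                "shape_significant": rep_shape.significant().index.tolist(),
                "size_significant": rep_size.significant().index.tolist(),
            }

        # ----------------------------------------------------------------- asr
        if on("asr"):
            pars = asr_parsimony(tree, groups)
            sm = simmap_er(tree, groups, nsim=config.simmap_nsim, seed=_stage_seed(config.seed, "asr"))
            report["asr"] = {
                "states": pars.states,
                "parsimony_root": [float(p) for p in pars.root_probabilities],
                "parsimony_score": pars.score,
                "simmap_rate": sm.rate,
                "simmap_root": [float(p) for p in sm.node_frequencies[_root_label(tree)]],
            }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(getattr(exc, "stage", "unknown"), digest, exc) from exc

    report["skipped_stages"] = skipped
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config.echo()))
    log.info("pipeline complete; bundle written to %s", out)
    return report


def _root_label(tree: PhyloTree) -> str:
    from .trees import node_label

    return node_label(tree.dendropy_tree.seed_node)


def size_ratio_table(
    log_cs_humerus: Mapping[str, float], log_cs_femur: Mapping[str, float]
) -> pd.DataFrame:
    """Per-species ratio of log humeral over log femoral centroid size."""
    species = sorted(set(log_cs_humerus) & set(log_cs_femur))
    return pd.DataFrame(
        {
            "log_cs_humerus": [log_cs_humerus[s] for s in species],
            "log_cs_femur": [log_cs_femur[s] for s in species],
            "ratio": [log_cs_humerus[s] / log_cs_femur[s] for s in species],
        },
        index=pd.Index(species, name="species_id"),
    )
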