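"""End-to-end pipeline: impute -> distances -> ordination ->
phylomorphospace -> disparity -> DTT -> complexity -> correlation reports.

Every stage writes its artifacts under the output directory, and a
machine-readable manifest records versions, the master seed, named
per-stage seeds and the full parameter echo, sufficient to reproduce every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import (
    ancestral_complexity,
    complexity_scores,
    ploidy_complexity_correlation,
)
from .disparity import (
    GroupAssignment,
    disparity_diversity_tests,
    dtt,
    groups_from_tree,
    mean_disparity,
    partial_disparity,
    sum_of_variances,
)
from .distances import euclidean, gower
from .matrix_io import applicable_proportion, recode_presence, write_matrix
from .mk import focal_with_nodes, impute_matrix
from .ordination import nmds, ordination_concordance, pcoa, phylomorphospace
from .stats import mantel
from .synthetic import SyntheticScenario, generate
from .trees import write_trees

logger = logging.getLogger("phytodisparity")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; round-trips to JSON."""

    seed: int = 0
    out_dir: str = "results"
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    n_sims: int = 1000  # stochastic maps per character per tree
    n_boot: int = 1000
    bin_Myr: float = 50.0
    k: int = 2
    n_starts: int = 20
    zero_mode: str = "ignore_matching_zeros"
    dtt_models: tuple[str, ...] = ("gradual", "punctuated")
    clade_cut_fraction: float = 0.7  # clades = lineages at this fraction of root age
    n_perm: int = 999

    def to_json(self, path: str | Path | None = None) -> str:
        data = asdict(self)
        text = json.dumps(data, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "scenario" in data:
            sc = data["scenario"]
            for key in ("state_counts", "state_count_probs", "fossil_missing_categories"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            data["scenario"] = SyntheticScenario(**sc)
        if "dtt_models" in data:
            data["dtt_models"] = tuple(data["dtt_models"])
        return cls(**data)


def _stage_seed(master: int, name: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    h = np.random.SeedSequence(
        entropy=master, spawn_key=(sum(ord(c) for c in name), len(name))
    )
    return int(h.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a generated synthetic study; returns the
    in-memory results and writes all artifacts plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    seeds = {
        name: _stage_seed(config.seed, name)
        for name in ("generate", "impute", "nmds", "mantel", "disparity", "dtt",
                     "complexity", "phylo_nmds")
    }
    stage = "generate"
    try:
        data = generate(config.scenario, seed=seeds["generate"])
        write_matrix(data.matrix, out / "matrix.csv")
        write_matrix(data.truth_matrix, out / "matrix_truth.csv")
        write_trees(data.trees, out / "trees.nwk")
        data.ploidy.to_frame().to_csv(out / "ploidy.csv", index=False, float_format="%.10g")
        results["data"] = data

        stage = "impute"
        focal, imput = impute_matrix(
            data.matrix, data.trees, n_sims=config.n_sims, seed=seeds["impute"]
        )
        write_matrix(focal, out / "focal.csv")
        imput.to_frame().to_csv(out / "imputation.csv", index=False, float_format="%.10g")
        combined = focal_with_nodes(focal, imput, data.tree)
        results["focal"], results["imputation"] = focal, imput

        stage = "distances"
        d_gower = gower(focal, zero_mode=config.zero_mode)
        d_gower.to_csv(out / "distances_gower.csv")
        d_eucl = euclidean(focal)
        d_patristic = data.tree.patristic_distances()
        results["gower"] = d_gower

        stage = "ordination"
        ord_nmds = nmds(
            d_gower, k=config.k, n_starts=config.n_starts, seed=seeds["nmds"]
        )
        ord_pcoa = pcoa(d_eucl)
        concord = ordination_concordance(
            ord_nmds, ord_pcoa, n_perm=config.n_perm, seed=seeds["mantel"]
        )
        sub = d_patristic.submatrix(d_gower.labels)  # same tip order
        morph_patristic = mantel(
            d_gower, sub, n_perm=config.n_perm, seed=seeds["mantel"]
        )
        ord_nmds.to_frame().to_csv(out / "nmds.csv", index=False, float_format="%.10g")
        pd.DataFrame(ord_nmds.shepard, columns=["dissimilarity", "distance"]).to_csv(
            out / "shepard.csv", index=False, float_format="%.10g"
        )
        results.update(
            nmds=ord_nmds, pcoa=ord_pcoa, concordance=concord,
            morphology_vs_patristic=morph_patristic,
        )

        stage = "phylomorphospace"
        node_set = set(imput.node_labels)
        phylo_ord, edges = phylomorphospace(
            combined, data.tree, seed=seeds["phylo_nmds"],
            distance_fun=lambda m: gower(m, zero_mode=config.zero_mode),
        )
        phylo_ord.to_frame(is_node=lambda l: l in node_set).to_csv(
            out / "phylomorphospace.csv", index=False, float_format="%.10g"
        )
        pd.DataFrame(edges, columns=["parent", "child"]).to_csv(
            out / "edges.csv", index=False
        )
        results["phylomorphospace"] = (phylo_ord, edges)

        stage = "disparity"
        cut = config.clade_cut_fraction * data.tree.root_age
        groups = groups_from_tree(data.tree, cut)
        # plausible diversity counts: clade size scaled by lognormal sampling noise
        div_rng = np.random.default_rng(seeds["disparity"])
        sizes = {g: len(m) for g, m in groups.members().items()}
        groups.diversity = {
            g: float(np.round(s * np.exp(div_rng.normal(0, 0.5)) * 10))
            for g, s in sorted(sizes.items())
        }
        tip_groups = GroupAssignment(
            {u: g for u, g in groups.groups.items() if u in set(d_gower.labels)},
            groups.diversity, groups.ages,
        )
        md = mean_disparity(d_gower, tip_groups, n_boot=config.n_boot, seed=seeds["disparity"])
        tips_only = GroupAssignment(
            {u: g for u, g in tip_groups.groups.items() if u in set(ord_nmds.labels)}
        )
        pdisp = partial_disparity(
            ord_nmds, tips_only, n_boot=config.n_boot, seed=seeds["disparity"]
        )
        md.to_frame().to_csv(out / "disparity_mean.csv", index=False, float_format="%.10g")
        pdisp.to_frame().to_csv(out / "disparity_partial.csv", index=False, float_format="%.10g")
        try:
            dd_tests = disparity_diversity_tests(md, tip_groups)
        except ValueError as exc:
            logger.warning("disparity-diversity tests skipped: %s", exc)
            dd_tests = {}
        results.update(mean_disparity=md, partial_disparity=pdisp, dd_tests=dd_tests)

        stage = "dtt"
        curves = {}
        for model in config.dtt_models:
            curve = dtt(
                phylo_ord, data.tree, model=model, bin_Myr=config.bin_Myr,
                n_boot=config.n_boot, seed=seeds["dtt"],
            )
            curves[model] = curve
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out / "dtt.csv", index=False, float_format="%.10g"
        )
        results["dtt"] = curves

        stage = "complexity"
        presence = recode_presence(
            focal, {c: {s: int(s > 0) for s in range(10)} for c in focal.characters}
        )
        profile = ancestral_complexity(
            presence, data.trees, n_sims=config.n_sims, seed=seeds["complexity"]
        )
        profile.prop_applicable = {
            t: applicable_proportion(focal, t) for t in focal.taxa
        }
        profile.to_frame().to_csv(out / "complexity.csv", index=False, float_format="%.10g")
        from .stats import CorrelationReport

        def _try_corr(method: str) -> CorrelationReport:
            try:
                return ploidy_complexity_correlation(profile, data.ploidy, data.tree, method)
            except ValueError as exc:  # e.g. no WGD events on a small tree
                logger.warning("ploidy-complexity %s undefined: %s", method, exc)
                return CorrelationReport(method, float("nan"), float("nan"), 0)

        pic = _try_corr("pic_pearson")
        rho = _try_corr("spearman")
        results.update(complexity=profile, ploidy_pic=pic, ploidy_spearman=rho)

        stage = "stats"
        reports = {
            "nmds_stress": ord_nmds.stress,
            "nmds_vs_pcoa_mantel": asdict(concord),
            "morphology_vs_patristic_mantel": asdict(morph_patristic),
            "ploidy_complexity_pic": asdict(pic),
            "ploidy_complexity_spearman": asdict(rho),
            "disparity_tests": {k: asdict(v) for k, v in dd_tests.items()},
            "dtt_at_present": {m: float(c.estimates[-1]) for m, c in curves.items()},
            "extant_sum_of_variances": sum_of_variances(
                phylo_ord.coords_of([t for t in data.tree.tip_labels
                                     if data.tree.ages[data.tree.labels.index(t)] <= 1e-6])
            ),
        }
        (out / "reports.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
        results["reports"] = reports
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        raise

    config_echo = json.loads(config.to_json())
    config_echo.pop("out_dir", None)  # not part of the scientific identity
    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": config_echo,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
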