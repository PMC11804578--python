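"""End-to-end orchestration: simulate (or load) -> DE contrasts -> classify
-> randomization/proportion tests -> P_ST-F_ST screen -> recovery scoring.

A run is configured by a YAML file (or dicts), is fully reproducible from a
single seed (fanned out to per-stage child seeds), and leaves behind TSV
tables plus a YAML manifest with input digests, per-stage timings and the
config snapshot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassificationReport,
    changed_plasticity_mask,
    classify,
    cue_transfer_mask,
    expand_report,
    genetic_adoption_mask,
    summarize_report,
)
from .contrasts import PAIR_POPULATIONS, ContrastCatalog, build_catalog, prepare_experiment
from .core import AnalysisConfig, CountMatrix, FstDistribution, read_experiment, write_results
from .de import normalized_counts
from .simulate import (
    PlantedTruth,
    SimulationConfig,
    score_recovery,
    simulate_experiments,
    simulate_fst_null,
)
from .stats import (
    chance_proportion,
    fraction_exceeding,
    log_ratio_trait,
    overlap_randomization,
    proportion_chisq,
    pst_table,
)

_STAGES = ("simulate", "fst", "permtest", "chance", "pst")


def _child_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES), dtype=np.uint32)
    return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


@dataclass
class RunManifest:
    seed: int
    config: dict
    package_version: str
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    catalog: ContrastCatalog
    report: ClassificationReport
    report_full: pd.DataFrame  # over the simulated/loaded universe
    summary: pd.DataFrame
    tests: pd.DataFrame
    pst: pd.DataFrame
    recovery: pd.DataFrame | None
    truth: PlantedTruth | None
    salt_cm: CountMatrix
    zinc_cm: CountMatrix
    sheet: pd.DataFrame
    fst: dict
    manifest: RunManifest


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def _catalog_long_table(catalog: ContrastCatalog) -> pd.DataFrame:
    blocks = []
    for kind, table_map in (("P", catalog.P), ("D", catalog.D), ("X", catalog.X)):
        for key, tab in sorted(table_map.items(), key=lambda kv: str(kv[0])):
            name = ":".join(key) if isinstance(key, tuple) else str(key)
            block = tab.copy()
            block.insert(0, "contrast", f"{kind}:{name}")
            blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def _pst_stage(
    result_frames: list,
    zinc_ed,
    catalog: ContrastCatalog,
    report: ClassificationReport,
    fst: dict,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """P_ST for the constitutive-EC set (control expression) and the shared
    mine-zinc-plastic set (log zinc/control ratio), per pair, against each
    pair's F_ST null."""
    norm = normalized_counts(zinc_ed.cm, zinc_ed.size_factors)
    genes_ec = report.genes.loc[report.genes["ec_direction"] != "ns", "gene_id"]
    genes_zp = report.genes.loc[report.genes["mine_zinc_shared"] != "ns", "gene_id"]
    rows = []
    for pair, (coast_pop, mine_pop) in PAIR_POPULATIONS.items():
        sheet = zinc_ed.sheet
        # control-expression trait, log scale
        traits_ctl = {}
        for pop in (coast_pop, mine_pop):
            cols = zinc_ed.samples_where(population=pop, treatment="control")
            traits_ctl[pop] = np.log2(np.maximum(norm[cols], 0.5))
        # zinc/control ratio trait per individual
        traits_ratio = {
            pop: log_ratio_trait(norm, sheet, pop, "zinc")
            for pop in (coast_pop, mine_pop)
        }
        for set_name, genes, traits in (
            ("constitutive_ec", genes_ec, traits_ctl),
            ("mine_zinc_plastic", genes_zp, traits_ratio),
        ):
            genes_here = [g for g in genes if g in norm.index]
            if not genes_here:
                rows.append(
                    dict(pair=pair, gene_set=set_name, n_genes=0,
                         fraction_exceeding=np.nan)
                )
                continue
            sub = {p: t.loc[genes_here] for p, t in traits.items()}
            tab = pst_table(sub, cfg.c_over_h2)
            tab = tab.reset_index(names="gene_id")
            tab.insert(0, "gene_set", set_name)
            tab.insert(0, "pair", pair)
            result_frames.append(tab)
            frac = fraction_exceeding(
                tab["pst"].to_numpy(), fst[pair].values, cfg.alpha
            )
            rows.append(
                dict(
                    pair=pair,
                    gene_set=set_name,
                    n_genes=len(genes_here),
                    fraction_exceeding=frac,
                )
            )
    return pd.DataFrame(rows)


def run_full(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the whole pipeline from a config mapping or YAML path.

    Config keys: ``seed``; ``out_dir``; ``simulate`` (SimulationConfig
    fields) OR ``inputs`` (paths: salt_counts, zinc_counts, sheet, and
    fst_w/fst_e TSVs); ``analysis`` (AnalysisConfig fields); ``fst``
    (n_loci/shape_a/shape_b for the synthetic F_ST null).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    seed = int(config.get("seed", 0))
    seeds = _child_seeds(seed)
    out_dir = out_dir if out_dir is not None else config.get("out_dir")
    if out_dir is not None:
        out_dir = Path(out_dir)
    analysis = AnalysisConfig(**{**config.get("analysis", {}), "seed": seed})
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    truth = None
    if "inputs" in config:
        paths = config["inputs"]
        salt_cm, _ = read_experiment(paths["salt_counts"], paths["sheet"])
        zinc_cm, _ = read_experiment(paths["zinc_counts"], paths["sheet"])
        sheet = pd.read_csv(paths["sheet"], sep="\t")
        fst = {
            "W": FstDistribution.read_tsv(paths["fst_w"], "W"),
            "E": FstDistribution.read_tsv(paths["fst_e"], "E"),
        }
    else:
        sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seeds["simulate"]})
        salt_cm, zinc_cm, sheet, truth = simulate_experiments(sim_cfg)
        fst_cfg = config.get("fst", {})
        fst = {
            pair: FstDistribution(
                pair,
                simulate_fst_null(
                    int(fst_cfg.get("n_loci", 10_000)),
                    float(fst_cfg.get("shape_a", 0.8)),
                    float(fst_cfg.get("shape_b", 3.0)),
                    seed=seeds["fst"] + k,
                ),
            )
            for k, pair in enumerate(("W", "E"))
        }
    timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    catalog = build_catalog(salt_cm, zinc_cm, sheet, analysis)
    timings["contrasts"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = classify(catalog)
    report_full = expand_report(report, salt_cm.gene_ids.union(zinc_cm.gene_ids))
    summary = summarize_report(report)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    test_rows = []
    universe = catalog.genes
    for k, (eco, pops) in enumerate(
        (("coast", ("Coast-W", "Coast-E")), ("mine", ("Mine-W", "Mine-E")))
    ):
        rr = overlap_randomization(
            catalog.P[(pops[0], "salt")],
            catalog.P[(pops[1], "salt")],
            universe,
            n_permutations=analysis.n_permutations,
            seed=seeds["permtest"] + k,
        )
        test_rows.append(
            dict(
                test=f"{eco}_salt_shared_randomization",
                statistic=rr.observed_overlap,
                expected=rr.expected_overlap,
                p_value=rr.p_value,
                n=rr.n_permutations,
            )
        )
    frame = catalog.frame()
    for name, mask_fn, x_key, n_key in (
        ("cue_transfer_proportion", cue_transfer_mask, "cue_transfer", "ChangedPlasticity"),
        ("genetic_adoption_proportion", genetic_adoption_mask, "genetic_adoption", "ConstitutiveEC"),
    ):
        p0, p0_se = chance_proportion(
            frame, mask_fn, n_permutations=100, seed=seeds["chance"]
        )
        n = report.sizes[n_key]
        x = report.sizes[x_key]
        if n > 0:
            p0_floor = max(p0, 1.0 / (100 * len(universe) + 1))
            pt = proportion_chisq(x, n, min(p0_floor, 1 - 1e-12))
            test_rows.append(
                dict(
                    test=name,
                    statistic=pt.chi2,
                    expected=pt.p0,
                    p_value=pt.p_value,
                    n=n,
                )
            )
    tests = pd.DataFrame(test_rows)
    timings["resampling"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    zinc_ed = prepare_experiment(
        zinc_cm.subset_genes(catalog.genes), sheet, "zinc_expt",
        analysis.min_count, analysis.filter_mode,
    )
    pst_frames: list = []
    pst_summary = _pst_stage(pst_frames, zinc_ed, catalog, report, fst, analysis)
    pst_genes = (
        pd.concat(pst_frames, ignore_index=True) if pst_frames else pd.DataFrame()
    )
    timings["pst"] = time.perf_counter() - t0

    recovery = None
    if truth is not None:
        recovery = score_recovery(truth, report_full)

    manifest = RunManifest(
        seed=seed,
        config={
            "analysis": analysis.to_dict(),
            **{k: v for k, v in config.items() if k not in ("analysis",)},
        },
        package_version=__version__,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        input_digests={
            "salt_counts": _digest(salt_cm.counts),
            "zinc_counts": _digest(zinc_cm.counts),
            "sheet": _digest(sheet),
        },
    )

    result = PipelineResult(
        catalog=catalog,
        report=report,
        report_full=report_full,
        summary=summary,
        tests=tests,
        pst=pst_summary,
        recovery=recovery,
        truth=truth,
        salt_cm=salt_cm,
        zinc_cm=zinc_cm,
        sheet=sheet,
        fst=fst,
        manifest=manifest,
    )

    if out_dir is not None:
        tables = {
            "classification_report": report_full,
            "summary": summary,
            "test_summary": tests,
            "pst_summary": pst_summary,
            "contrast_calls": _catalog_long_table(catalog),
        }
        if len(pst_genes):
            tables["pst_genes"] = pst_genes
        if recovery is not None:
            tables["recovery"] = recovery
        if truth is not None:
            tables["planted_truth"] = truth.table
        manifest.outputs = write_results(tables, out_dir)
        manifest.to_yaml(Path(out_dir) / "manifest.yaml")
        manifest.outputs["manifest"] = str(Path(out_dir) / "manifest.yaml")
    return result


def relaxed_fdr_rerun(result: PipelineResult, alpha2: float) -> pd.DataFrame:
    """Re-threshold stored adjusted p-values at ``alpha2`` and reclassify.

    The comparable gene universe is kept fixed (the comparability filter is
    part of the data-assembly step, not of the hypothesis tests). Returns
    per-category counts at the original and relaxed levels with deltas.
    """
    if not 0 < alpha2 < 1:
        raise ValueError("alpha2 must be in (0, 1)")
    cat2 = result.catalog.with_alpha(alpha2)
    report2 = classify(cat2)
    before = result.report.category_counts()
    after = report2.category_counts()
    return pd.DataFrame(
        {
            "category": before.index,
            "count_original": before.to_numpy(),
            "count_relaxed": after.to_numpy(),
            "delta": (after - before).to_numpy(),
        }
    )


def write_simulation(cfg: SimulationConfig, out_dir, fst_n_loci: int = 10_000) -> dict:
    """Simulate and write count TSVs, sample sheet, truth, and F_ST nulls."""
    salt_cm, zinc_cm, sheet, truth = simulate_experiments(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cm in (("salt_counts", salt_cm), ("zinc_counts", zinc_cm)):
        p = out_dir / f"{name}.tsv"
        cm.counts.to_csv(p, sep="\t")
        paths[name] = str(p)
    tables = {
        "sample_sheet": sheet,
        "planted_truth": truth.table,
        "planted_means": truth.means,
    }
    for k, pair in enumerate(("W", "E")):
        vals = simulate_fst_null(fst_n_loci, seed=cfg.seed + 1000 + k)
        tables[f"fst_{pair.lower()}"] = pd.DataFrame({"fst": vals})
    paths.update(write_results(tables, out_dir, metadata=dataclasses.asdict(cfg)))
    return paths
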