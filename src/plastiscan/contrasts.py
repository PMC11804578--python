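"""The contrast catalog: every differential-expression comparison the
classification framework consumes.

Per comparable gene the catalog holds direction calls for:

- ``P(pop, cue)`` — treatment vs control within each of the four populations,
  for each experiment's cue (individual-paired, the nested-individual model);
- ``D(pair, treatment)`` — mine vs coast within each pair, in control, salt
  and zinc (single combined population+treatment factor; positive log2fc =
  higher in mine);
- ``X(pop)`` — salt-experiment control vs zinc-experiment control per
  population, used only to filter genes to a cross-experiment comparable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    EXPERIMENT_CUE,
    PAIRS,
    POPULATIONS,
    AnalysisConfig,
    CountMatrix,
    low_count_filter,
)
from .de import (
    bh_adjust,
    call_genes,
    estimate_dispersions,
    median_ratio_size_factors,
    nb_wald_contrast,
)

PAIR_POPULATIONS = {"W": ("Coast-W", "Mine-W"), "E": ("Coast-E", "Mine-E")}


@dataclass
class ExperimentData:
    """One experiment's filtered matrix with its normalization/dispersion."""

    name: str
    cue: str
    cm: CountMatrix
    sheet: pd.DataFrame  # rows for this experiment only
    size_factors: pd.Series
    dispersions: pd.DataFrame

    def samples_where(self, **conditions) -> list[str]:
        mask = np.ones(len(self.sheet), dtype=bool)
        for col, val in conditions.items():
            mask &= self.sheet[col].to_numpy() == val
        return self.sheet.loc[mask, "sample_id"].tolist()


def prepare_experiment(
    cm: CountMatrix,
    sheet: pd.DataFrame,
    experiment: str,
    min_count: int = 10,
    filter_mode: str = "any_sample",
) -> ExperimentData:
    """Filter low-count genes and precompute size factors and dispersions."""
    sub_sheet = sheet[sheet["experiment"] == experiment].reset_index(drop=True)
    if sub_sheet.empty:
        raise ValueError(f"no samples for experiment {experiment!r}")
    cm = cm.subset_samples(sub_sheet["sample_id"])
    cm = low_count_filter(cm, min_count, mode=filter_mode)
    nf = median_ratio_size_factors(cm)
    groups = pd.Series(
        (sub_sheet["population"] + ":" + sub_sheet["treatment"]).to_numpy(),
        index=sub_sheet["sample_id"].to_numpy(),
    )
    disp = estimate_dispersions(cm, nf, groups)
    return ExperimentData(
        name=experiment,
        cue=EXPERIMENT_CUE[experiment],
        cm=cm,
        sheet=sub_sheet,
        size_factors=nf,
        dispersions=disp,
    )


def _finish(res: pd.DataFrame, alpha: float) -> pd.DataFrame:
    res = res.copy()
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return call_genes(res, alpha)


def plasticity_contrast(
    expt: ExperimentData, population: str, alpha: float = 0.05, paired: bool = True
) -> pd.DataFrame:
    """Cue-vs-control direction calls within one population."""
    cue = expt.cue
    samples = expt.samples_where(population=population)
    if not samples:
        raise ValueError(f"population {population!r} absent from {expt.name}")
    sub = expt.cm.subset_samples(samples)
    sheet = expt.sheet.set_index("sample_id").loc[samples]
    design = sheet["treatment"]
    paired_by = sheet["individual"] if paired else None
    res = nb_wald_contrast(
        sub,
        expt.size_factors,
        expt.dispersions,
        design,
        (cue, "control"),
        paired_by=paired_by,
    )
    return _finish(res, alpha)


def divergence_contrast(
    expt: ExperimentData, pair: str, treatment: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Mine-vs-coast direction calls within one treatment (positive = mine)."""
    coast_pop, mine_pop = PAIR_POPULATIONS[pair]
    samples = [
        s
        for pop in (coast_pop, mine_pop)
        for s in expt.samples_where(population=pop, treatment=treatment)
    ]
    sheet = expt.sheet.set_index("sample_id")
    for pop in (coast_pop, mine_pop):
        if not any(sheet.loc[s, "population"] == pop for s in samples):
            raise ValueError(f"population {pop!r} missing in {expt.name}/{treatment}")
    sub = expt.cm.subset_samples(samples)
    design = sheet.loc[samples, "population"]
    res = nb_wald_contrast(
        sub, expt.size_factors, expt.dispersions, design, (mine_pop, coast_pop)
    )
    return _finish(res, alpha)


def _combined_controls(salt: ExperimentData, zinc: ExperimentData):
    """Control samples of both experiments on the shared gene universe,
    with experiment-prefixed sample ids and joint normalization."""
    shared = salt.cm.gene_ids.intersection(zinc.cm.gene_ids)
    if len(shared) < 2:
        raise ValueError("experiments share fewer than 2 genes after filtering")
    frames, labels, pops = [], {}, {}
    for expt in (salt, zinc):
        cols = expt.samples_where(treatment="control")
        block = expt.cm.counts.loc[shared, cols]
        block.columns = [f"{expt.name}:{s}" for s in cols]
        sheet = expt.sheet.set_index("sample_id")
        for orig, new in zip(cols, block.columns):
            labels[new] = expt.name
            pops[new] = sheet.loc[orig, "population"]
        frames.append(block)
    cm = CountMatrix(pd.concat(frames, axis=1))
    nf = median_ratio_size_factors(cm)
    pop_s = pd.Series(pops)
    expt_s = pd.Series(labels)
    groups = pop_s + ":" + expt_s
    disp = estimate_dispersions(cm, nf, groups)
    return cm, nf, disp, pop_s, expt_s


def cross_experiment_contrasts(
    salt: ExperimentData, zinc: ExperimentData, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """X(pop): salt-experiment controls vs zinc-experiment controls."""
    cm, nf, disp, pop_s, expt_s = _combined_controls(salt, zinc)
    out = {}
    for pop in POPULATIONS:
        cols = pop_s.index[pop_s == pop]
        design = (pop_s + ":" + expt_s).loc[cols]
        res = nb_wald_contrast(
            cm.subset_samples(cols),
            nf,
            disp,
            design,
            (f"{pop}:{salt.name}", f"{pop}:{zinc.name}"),
        )
        out[pop] = _finish(res, alpha)
    return out


def cross_experiment_filter(
    salt: ExperimentData,
    zinc: ExperimentData,
    alpha: float = 0.05,
    mode: str = "per_population",
) -> tuple[pd.Index, dict]:
    """Genes comparable across experiments: no significant control shift.

    mode="per_population" (default): the X(pop) call must be ns in every one
    of the four populations. mode="pooled": a single contrast pooling all
    control samples per experiment must be ns.
    """
    if mode == "per_population":
        x_calls = cross_experiment_contrasts(salt, zinc, alpha)
        keep = None
        for pop, tab in x_calls.items():
            ns = tab.set_index("gene_id")["call"] == "ns"
            keep = ns if keep is None else (keep & ns)
    elif mode == "pooled":
        cm, nf, disp, pop_s, expt_s = _combined_controls(salt, zinc)
        res = nb_wald_contrast(cm, nf, disp, expt_s, (salt.name, zinc.name))
        tab = _finish(res, alpha)
        x_calls = {"pooled": tab}
        keep = tab.set_index("gene_id")["call"] == "ns"
    else:
        raise ValueError(f"unknown comparability mode {mode!r}")
    genes = keep.index[keep]
    if len(genes) == 0:
        raise ValueError("comparability filter removed every gene")
    return pd.Index(genes), x_calls


def shared_call(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Direction-matched shared calls of two tables on one gene universe.

    Returns gene_id, shared (bool) and direction ("up"/"down", NA when not
    shared); ``.attrs["n_shared"]`` carries the shared-set size.
    """
    a = calls_a.set_index("gene_id")["call"]
    b = calls_b.set_index("gene_id")["call"]
    if set(a.index) != set(b.index):
        raise ValueError("shared_call requires identical gene universes")
    b = b.loc[a.index]
    shared = (a == b) & a.isin(["up", "down"])
    out = pd.DataFrame(
        {
            "gene_id": a.index,
            "shared": shared.to_numpy(),
            "direction": np.where(shared, a.to_numpy(), None),
        }
    )
    out.attrs["n_shared"] = int(shared.sum())
    return out


@dataclass
class ContrastCatalog:
    """All direction calls on the comparable gene universe."""

    genes: pd.Index
    alpha: float
    P: dict = field(default_factory=dict)  # (population, cue) -> call table
    D: dict = field(default_factory=dict)  # (pair, treatment) -> call table
    X: dict = field(default_factory=dict)  # population -> call table

    def validate(self) -> None:
        expected_p = {(p, c) for p in POPULATIONS for c in ("salt", "zinc")}
        expected_d = {(pr, t) for pr in PAIRS for t in ("control", "salt", "zinc")}
        if set(self.P) != expected_p:
            raise ValueError("incomplete P contrasts")
        if set(self.D) != expected_d:
            raise ValueError("incomplete D contrasts")
        universe = set(self.genes)
        for tab in list(self.P.values()) + list(self.D.values()):
            if set(tab["gene_id"]) != universe:
                raise ValueError("catalog entry universe mismatch")

    def frame(self) -> pd.DataFrame:
        """One ternary-call column per contrast, indexed by gene id."""
        cols = {}
        for (pop, cue), tab in sorted(self.P.items()):
            cols[f"P:{pop}:{cue}"] = tab.set_index("gene_id")["call"]
        for (pair, treat), tab in sorted(self.D.items()):
            cols[f"D:{pair}:{treat}"] = tab.set_index("gene_id")["call"]
        return pd.DataFrame(cols).loc[self.genes]

    def with_alpha(self, alpha2: float) -> "ContrastCatalog":
        """Re-threshold every stored padj at a new significance level."""
        if not 0 < alpha2 < 1:
            raise ValueError("alpha2 must be in (0, 1)")
        recall = lambda tab: call_genes(tab.drop(columns=["call"]), alpha2)
        return replace(
            self,
            alpha=alpha2,
            P={k: recall(v) for k, v in self.P.items()},
            D={k: recall(v) for k, v in self.D.items()},
            X={k: recall(v) for k, v in self.X.items()},
        )


def build_catalog(
    salt_cm: CountMatrix,
    zinc_cm: CountMatrix,
    sheet: pd.DataFrame,
    config: AnalysisConfig | None = None,
    control_divergence_from: str = "zinc_expt",
) -> ContrastCatalog:
    """Run the full contrast set for two experiments.

    Each experiment is low-count filtered, the cross-experiment
    comparability filter is applied, and all P and D contrasts are computed
    (with BH adjustment) on the comparable gene universe. Constitutive
    divergence D(pair, control) is taken from ``control_divergence_from``.
    """
    cfg = config or AnalysisConfig()
    salt = prepare_experiment(salt_cm, sheet, "salt_expt", cfg.min_count, cfg.filter_mode)
    zinc = prepare_experiment(zinc_cm, sheet, "zinc_expt", cfg.min_count, cfg.filter_mode)
    genes, x_calls = cross_experiment_filter(
        salt, zinc, cfg.alpha, mode=cfg.comparability_mode
    )
    # restrict to the comparable universe and re-estimate normalization there
    salt = prepare_experiment(
        salt_cm.subset_genes(genes), sheet, "salt_expt", cfg.min_count, cfg.filter_mode
    )
    zinc = prepare_experiment(
        zinc_cm.subset_genes(genes), sheet, "zinc_expt", cfg.min_count, cfg.filter_mode
    )
    cat = ContrastCatalog(genes=pd.Index(genes), alpha=cfg.alpha, X=x_calls)
    for pop in POPULATIONS:
        cat.P[(pop, "salt")] = plasticity_contrast(
            salt, pop, cfg.alpha, paired=cfg.paired_plasticity
        )
        cat.P[(pop, "zinc")] = plasticity_contrast(
            zinc, pop, cfg.alpha, paired=cfg.paired_plasticity
        )
    control_expt = salt if control_divergence_from == "salt_expt" else zinc
    for pair in PAIRS:
        cat.D[(pair, "control")] = divergence_contrast(control_expt, pair, "control", cfg.alpha)
        cat.D[(pair, "salt")] = divergence_contrast(salt, pair, "salt", cfg.alpha)
        cat.D[(pair, "zinc")] = divergence_contrast(zinc, pair, "zinc", cfg.alpha)
    cat.validate()
    return cat
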