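"""Synthetic paired-experiment generator with planted gene classes.

Emulates the study design: two coast/mine population pairs (W and E), three
individuals per population, two treatments per experiment (control + salt,
control + zinc), one pooled RNA-seq sample per individual per treatment —
24 samples per experiment. Counts are negative binomial with
variance = mu + alpha * mu^2 and a per-sample multiplicative library factor.

Planted classes (directions randomized up/down per gene, magnitude
``effect_log2fc``):

- ``null``: no effects anywhere.
- ``coast_salt_plastic``: both coasts respond to salt; mines do not.
- ``preadaptive``: same-direction salt AND zinc responses in all four
  populations, no constitutive change.
- ``cue_transfer``: coastal salt response; mine zinc response in the SAME
  direction; coastal zinc response absent or opposite (p = 1/2 each).
- ``genetic_adoption``: coastal salt response; constitutive mine-vs-coast
  shift in the same direction; no mine zinc plasticity; coastal zinc response
  absent or opposite.
- ``genetic_assimilation``: ancestral (coastal) zinc plasticity canalized —
  constitutive shift in the coastal-zinc direction, mine zinc response lost,
  no salt response.
- ``evolved_plasticity_other``: mine-only zinc plasticity with no ancestral
  salt or zinc response (evolved zinc plasticity not traceable to the past
  cue).
- ``lineage_specific``: salt response in a single random population
  (non-parallel; should never be classified).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    EXPERIMENT_CUE,
    POPULATIONS,
    CountMatrix,
)

GENE_CLASSES = (
    "null",
    "coast_salt_plastic",
    "preadaptive",
    "cue_transfer",
    "genetic_adoption",
    "genetic_assimilation",
    "evolved_plasticity_other",
    "lineage_specific",
)

DEFAULT_PROPORTIONS = {
    "null": 0.84,
    "coast_salt_plastic": 0.04,
    "preadaptive": 0.02,
    "cue_transfer": 0.02,
    "genetic_adoption": 0.02,
    "genetic_assimilation": 0.02,
    "evolved_plasticity_other": 0.02,
    "lineage_specific": 0.02,
}

_COASTS = ("Coast-W", "Coast-E")
_MINES = ("Mine-W", "Mine-E")


@dataclass
class SimulationConfig:
    n_genes: int = 20_000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    base_mean_log_mu: float = 6.5
    base_mean_log_sd: float = 1.0
    dispersion_a0: float = 0.05
    dispersion_a1: float = 0.0
    effect_log2fc: float = 2.0
    library_size_sd: float = 0.15
    n_individuals: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion coefficients must be >= 0")
        for cls_name, frac in self.class_proportions.items():
            if frac > 0 and self.n_genes * frac < 1:
                raise ValueError(
                    f"class {cls_name!r}: n_genes x fraction < 1 gene"
                )


@dataclass
class PlantedTruth:
    """Ground truth for a simulation run.

    ``table`` holds per gene: planted class, signed direction columns
    (up/down/ns) for the coastal/mine salt and zinc responses and the
    constitutive mine-vs-coast difference, plus the signed log2 effects.
    ``means`` holds the true per-condition means (columns
    ``<experiment>:<population>:<treatment>``) before library-size noise.
    """

    table: pd.DataFrame
    means: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])


def _dir(x: float) -> str:
    if x > 0:
        return "up"
    if x < 0:
        return "down"
    return "ns"


def _class_counts(cfg: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    fracs = {c: cfg.class_proportions.get(c, 0.0) for c in GENE_CLASSES}
    raw = {c: cfg.n_genes * f for c, f in fracs.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = cfg.n_genes - sum(counts.values())
    order = sorted(GENE_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def _plant_effects(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene signed log2 effects: salt/zinc response per population and
    the constitutive mine shift."""
    counts = _class_counts(cfg)
    classes = np.repeat(
        [c for c in GENE_CLASSES for _ in range(counts[c])], 1
    )
    n = cfg.n_genes
    e = cfg.effect_log2fc
    sign = rng.choice([-1.0, 1.0], size=n)
    # coastal zinc response for cue_transfer/adoption: 0 or opposite to salt
    cz_opposite = rng.random(n) < 0.5
    lineage_pop = rng.integers(0, len(POPULATIONS), size=n)

    cols = {f"salt_resp:{p}": np.zeros(n) for p in POPULATIONS}
    cols.update({f"zinc_resp:{p}": np.zeros(n) for p in POPULATIONS})
    cols["constitutive"] = np.zeros(n)

    for i, cls_name in enumerate(classes):
        s = sign[i] * e
        if cls_name == "coast_salt_plastic":
            for p in _COASTS:
                cols[f"salt_resp:{p}"][i] = s
        elif cls_name == "preadaptive":
            for p in POPULATIONS:
                cols[f"salt_resp:{p}"][i] = s
                cols[f"zinc_resp:{p}"][i] = s
        elif cls_name == "cue_transfer":
            for p in _COASTS:
                cols[f"salt_resp:{p}"][i] = s
                cols[f"zinc_resp:{p}"][i] = -s if cz_opposite[i] else 0.0
            for p in _MINES:
                cols[f"zinc_resp:{p}"][i] = s
        elif cls_name == "genetic_adoption":
            for p in _COASTS:
                cols[f"salt_resp:{p}"][i] = s
                cols[f"zinc_resp:{p}"][i] = -s if cz_opposite[i] else 0.0
            cols["constitutive"][i] = s
        elif cls_name == "genetic_assimilation":
            for p in _COASTS:
                cols[f"zinc_resp:{p}"][i] = s
            cols["constitutive"][i] = s
        elif cls_name == "evolved_plasticity_other":
            for p in _MINES:
                cols[f"zinc_resp:{p}"][i] = s
        elif cls_name == "lineage_specific":
            p = POPULATIONS[lineage_pop[i]]
            cols[f"salt_resp:{p}"][i] = s

    table = pd.DataFrame(cols)
    table.insert(0, "gene_id", [f"g{i:06d}" for i in range(n)])
    table.insert(1, "class", classes)
    return table


def _truth_directions(effects: pd.DataFrame) -> pd.DataFrame:
    t = effects.copy()
    t["salt_dir_coast"] = t["salt_resp:Coast-W"].map(_dir)
    t["salt_dir_mine"] = t["salt_resp:Mine-W"].map(_dir)
    t["zinc_dir_coast"] = t["zinc_resp:Coast-W"].map(_dir)
    t["zinc_dir_mine"] = t["zinc_resp:Mine-W"].map(_dir)
    t["constitutive_dir"] = t["constitutive"].map(_dir)
    return t


def validate_truth(truth: PlantedTruth) -> None:
    """Assert planted directions are internally consistent per class."""
    t = truth.table
    ct = t[t["class"] == "cue_transfer"]
    assert (ct["zinc_dir_mine"] == ct["salt_dir_coast"]).all()
    assert (ct["salt_dir_coast"] != "ns").all()
    assert (ct["zinc_dir_coast"] != ct["salt_dir_coast"]).all()
    ga = t[t["class"] == "genetic_adoption"]
    assert (ga["constitutive_dir"] == ga["salt_dir_coast"]).all()
    assert (ga["zinc_dir_mine"] == "ns").all()
    assert (ga["zinc_dir_coast"] != ga["salt_dir_coast"]).all()
    gs = t[t["class"] == "genetic_assimilation"]
    assert (gs["constitutive_dir"] == gs["zinc_dir_coast"]).all()
    assert (gs["zinc_dir_coast"] != "ns").all()
    assert (gs["zinc_dir_mine"] == "ns").all()
    pre = t[t["class"] == "preadaptive"]
    for col in ("salt_dir_coast", "salt_dir_mine", "zinc_dir_coast", "zinc_dir_mine"):
        assert (pre[col] == pre["salt_dir_coast"]).all()
        assert (pre[col] != "ns").all()
    nul = t[t["class"] == "null"]
    assert (nul["constitutive_dir"] == "ns").all()


def _condition_means(effects: pd.DataFrame, base_mu: np.ndarray) -> pd.DataFrame:
    """True mean per (experiment, population, treatment) before library noise."""
    cols = {}
    for expt, cue in EXPERIMENT_CUE.items():
        for pop in POPULATIONS:
            constit = effects["constitutive"].to_numpy() if pop in _MINES else 0.0
            base = base_mu * 2.0 ** constit
            cols[f"{expt}:{pop}:control"] = base
            resp = effects[f"{cue}_resp:{pop}"].to_numpy()
            cols[f"{expt}:{pop}:{cue}"] = base * 2.0 ** resp
    means = pd.DataFrame(cols)
    means.insert(0, "gene_id", effects["gene_id"].to_numpy())
    return means


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_experiments(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate the paired salt and zinc experiments.

    Returns the two count matrices, one combined sample sheet covering both
    experiments, and the planted truth. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = _plant_effects(cfg, rng)
    base_mu = np.exp(rng.normal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, cfg.n_genes))
    alpha_g = cfg.dispersion_a0 + cfg.dispersion_a1 / base_mu
    means = _condition_means(effects, base_mu)
    truth = PlantedTruth(table=_truth_directions(effects), means=means)

    sheet_rows = []
    matrices: dict[str, dict[str, np.ndarray]] = {"salt_expt": {}, "zinc_expt": {}}
    for expt, cue in EXPERIMENT_CUE.items():
        for pop in POPULATIONS:
            eco = "coast" if pop in _COASTS else "mine"
            pair = pop.split("-")[1]
            for k in range(cfg.n_individuals):
                ind = f"i{k + 1}"
                for treatment in ("control", cue):
                    sid = f"{expt}.{pop}.{ind}.{treatment}"
                    mu = means[f"{expt}:{pop}:{treatment}"].to_numpy()
                    s_j = np.exp(rng.normal(0.0, cfg.library_size_sd))
                    matrices[expt][sid] = _nb_draw(rng, mu * s_j, alpha_g)
                    sheet_rows.append(
                        dict(
                            sample_id=sid,
                            population=pop,
                            ecotype=eco,
                            pair=pair,
                            individual=ind,
                            treatment=treatment,
                            experiment=expt,
                        )
                    )
    gene_ids = effects["gene_id"].to_numpy()
    salt_cm = CountMatrix(pd.DataFrame(matrices["salt_expt"], index=gene_ids))
    zinc_cm = CountMatrix(pd.DataFrame(matrices["zinc_expt"], index=gene_ids))
    sheet = pd.DataFrame(sheet_rows)
    return salt_cm, zinc_cm, sheet, truth


def simulate_fst_null(
    n_loci: int, shape_a: float = 0.8, shape_b: float = 3.0, seed: int = 0
) -> np.ndarray:
    """Draw a synthetic genome-wide F_ST distribution from Beta(a, b).

    The default Beta(0.8, 3) gives a right-skewed distribution with mean
    ~0.21, a plausible genome-wide profile for recently diverged
    coast/mine pairs.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if shape_a <= 0 or shape_b <= 0:
        raise ValueError("Beta shapes must be > 0")
    rng = np.random.default_rng(seed)
    return rng.beta(shape_a, shape_b, size=n_loci)


#: planted class -> category the classifier should assign
EXPECTED_CATEGORY = {
    "null": "none",
    "coast_salt_plastic": "none",
    "preadaptive": "preadaptive",
    "cue_transfer": "cue_transfer",
    "genetic_adoption": "genetic_adoption",
    "genetic_assimilation": "genetic_assimilation",
    "evolved_plasticity_other": "evolved_plasticity_unclassified",
    "lineage_specific": "none",
}


def score_recovery(truth: PlantedTruth, report: pd.DataFrame) -> pd.DataFrame:
    """Per-class precision/recall/F1 of assigned categories against truth.

    ``report`` must carry ``gene_id`` and ``category`` over exactly the
    simulated gene universe (genes dropped by filters should appear with
    category "none"). Precision/recall are computed on category labels after
    mapping each planted class to its expected category.
    """
    if set(report["gene_id"]) != set(truth.gene_ids):
        raise ValueError("report and truth cover different gene sets")
    merged = truth.table[["gene_id", "class"]].merge(report[["gene_id", "category"]], on="gene_id")
    expected = merged["class"].map(EXPECTED_CATEGORY)
    assigned = merged["category"]
    labels = sorted(set(expected) | set(assigned))
    rows = []
    for lab in labels:
        tp = int(((expected == lab) & (assigned == lab)).sum())
        fp = int(((expected != lab) & (assigned == lab)).sum())
        fn = int(((expected == lab) & (assigned != lab)).sum())
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (
            2 * prec * rec / (prec + rec)
            if tp + fp and tp + fn and (prec + rec) > 0
            else np.nan
        )
        rows.append(dict(label=lab, tp=tp, fp=fp, fn=fn, precision=prec, recall=rec, f1=f1))
    out = pd.DataFrame(rows)
    out.attrs["accuracy"] = float((expected == assigned).mean())
    out.attrs["n_unclassified"] = int((assigned == "none").sum())
    return out


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
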